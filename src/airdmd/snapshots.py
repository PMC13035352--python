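"""Snapshot data model, matrix arrangement, frame filtering and I/O.

A :class:`SnapshotSet` is the central container of the package: a
3-component field (velocity components ``u,v,w`` or particle coordinates
``x,y,z``) sampled on ``N`` entities over ``Nt`` uniformly spaced time
steps, stored as a ``(3, N, Nt)`` tensor.

Flattening convention
---------------------
``flatten`` reshapes each frame to a column vector of length ``3N`` with
*component-major* ordering: first the first component for entities
``0..N-1``, then the second component, then the third.  Any consistent
ordering yields identical DMD spectra; this one is fixed so that models,
bundles and decks interoperate.

Frame indices are 0-based throughout the in-memory API; on-disk tables
use whatever frame index they were written with (round trips preserve
it).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DegenerateDeckError,
    EmptyResultError,
    InsufficientDataError,
    MaskLookupError,
    ShapeMismatchError,
)

FORMAT_VERSION = 1

#: default relative frame-norm threshold for the trailing-frame discard
#: rule.  Tuned so that the default 160-frame sinusoidal breathing-cycle
#: deck loses exactly its final 16 frames (the end-of-cycle lull where
#: the field decays toward zero); see :func:`drop_trailing_low_energy`.
DEFAULT_TAIL_THRESHOLD = 0.6
#: hard cap on how many trailing frames the discard rule may remove.
DEFAULT_MAX_DROP = 16


@dataclasses.dataclass
class SnapshotSet:
    """A 3-component field on N entities over Nt uniform time steps.

    Parameters
    ----------
    kind:
        ``"fluid"`` (velocity field on mesh nodes) or ``"particles"``
        (positions of tracked particles).
    values:
        ``(3, N, Nt)`` real tensor.
    dt:
        Uniform time spacing in seconds.
    times:
        Length-``Nt`` strictly increasing instants; defaults to
        ``arange(Nt) * dt``.
    coords:
        Optional ``(N, 3)`` per-entity reference coordinates (mesh node
        positions for fluid decks).
    ids:
        Optional length-``N`` integer entity identifiers.
    masks:
        Optional mapping of region name (``"wall"``, ``"inlet"``,
        ``"outlet"``) to boolean arrays of length ``N``.
    parameter:
        Scalar flow-rate parameter (L/min) or ``None``.
    """

    kind: str
    values: np.ndarray
    dt: float
    times: np.ndarray | None = None
    coords: np.ndarray | None = None
    ids: np.ndarray | None = None
    masks: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    parameter: float | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != 3:
            raise ShapeMismatchError(
                f"values must have shape (3, N, Nt), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("snapshot values contain non-finite entries")
        if self.dt <= 0:
            raise DataError(f"dt must be positive, got {self.dt}")
        if self.times is None:
            self.times = np.arange(self.n_frames) * self.dt
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise ShapeMismatchError(
                    f"times has length {self.times.shape}, expected {self.n_frames}"
                )
            spacing = np.diff(self.times)
            if self.n_frames > 1 and not np.allclose(
                spacing, self.dt, rtol=0, atol=1e-9 * self.dt
            ):
                raise DataError("times are not uniformly spaced at dt")
        if self.ids is None:
            self.ids = np.arange(self.n_entities)
        else:
            self.ids = np.asarray(self.ids)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.n_entities, 3):
                raise ShapeMismatchError("coords must have shape (N, 3)")
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.n_entities,):
                raise ShapeMismatchError(f"mask {name!r} must have length N")
            self.masks[name] = mask

    @property
    def n_entities(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    def frame_norms(self) -> np.ndarray:
        """2-norm of each flattened frame (length ``Nt``)."""
        return np.linalg.norm(self.values.reshape(-1, self.n_frames), axis=0)

    def replace(self, **changes) -> "SnapshotSet":
        return dataclasses.replace(self, **changes)


@dataclasses.dataclass(frozen=True)
class SnapshotMatrixPair:
    """Lagged/shifted matrix pair derived from a flattened deck.

    ``x_minus`` holds flattened snapshots ``1..m-1`` as columns,
    ``x_plus`` snapshots ``2..m`` (1-based), so that the best-fit linear
    propagator satisfies ``x_plus ≈ A @ x_minus``.
    """

    x_minus: np.ndarray
    x_plus: np.ndarray
    m: int
    dt: float
    parameter: float | None = None

    def __post_init__(self) -> None:
        if self.x_minus.shape != self.x_plus.shape:
            raise ShapeMismatchError("x_minus and x_plus must share shape")


def flatten(sset: SnapshotSet) -> np.ndarray:
    """Return the ``(3N, Nt)`` snapshot matrix (component-major rows)."""
    return sset.values.reshape(3 * sset.n_entities, sset.n_frames)


def unflatten(matrix: np.ndarray, n_entities: int) -> np.ndarray:
    """Inverse of :func:`flatten`; returns a ``(3, N, Nt)`` tensor."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[0] != 3 * n_entities:
        raise ShapeMismatchError(
            f"matrix has {matrix.shape[0]} rows, expected {3 * n_entities}"
        )
    return matrix.reshape(3, n_entities, matrix.shape[1])


def build_pair(sset: SnapshotSet) -> SnapshotMatrixPair:
    """Split a deck into the lagged/shifted snapshot-matrix pair."""
    if sset.n_frames < 3:
        raise InsufficientDataError(
            f"need at least 3 frames to build a matrix pair, got {sset.n_frames}"
        )
    x = flatten(sset)
    return SnapshotMatrixPair(
        x_minus=x[:, :-1],
        x_plus=x[:, 1:],
        m=sset.n_frames,
        dt=sset.dt,
        parameter=sset.parameter,
    )


def drop_trailing_low_energy(
    sset: SnapshotSet,
    threshold: float = DEFAULT_TAIL_THRESHOLD,
    max_drop: int = DEFAULT_MAX_DROP,
) -> SnapshotSet:
    """Discard the trailing run of low-energy frames.

    Removes the maximal trailing run of frames whose flattened 2-norm
    falls below ``threshold`` times the maximum frame norm of the deck,
    removing at most ``max_drop`` frames and never touching interior
    frames.  This is the bookkeeping step that trims the near-zero lull
    at the end of a breathing cycle (160 generated frames -> 144
    retained under the defaults) before DMD fitting.
    """
    if not 0 <= threshold < 1:
        raise DataError(f"threshold must lie in [0, 1), got {threshold}")
    if threshold == 0 or max_drop <= 0:
        return sset
    norms = sset.frame_norms()
    cutoff = threshold * norms.max()
    if np.all(norms < cutoff) or norms.max() == 0:
        raise DegenerateDeckError("every frame is below the energy threshold")
    n_drop = 0
    for k in range(sset.n_frames - 1, -1, -1):
        if norms[k] < cutoff and n_drop < max_drop:
            n_drop += 1
        else:
            break
    if n_drop == 0:
        return sset
    keep = sset.n_frames - n_drop
    return sset.replace(
        values=sset.values[:, :, :keep],
        times=sset.times[:keep],
    )


def region_view(sset: SnapshotSet, mask_name: str) -> SnapshotSet:
    """Restrict a deck to the entities selected by a region mask."""
    if mask_name not in sset.masks:
        raise MaskLookupError(
            f"mask {mask_name!r} not present; available: {sorted(sset.masks)}"
        )
    mask = sset.masks[mask_name]
    if not mask.any():
        raise EmptyResultError(f"mask {mask_name!r} selects no entities")
    return sset.replace(
        values=sset.values[:, mask, :],
        coords=None if sset.coords is None else sset.coords[mask],
        ids=sset.ids[mask],
        masks={name: m[mask] for name, m in sset.masks.items()},
    )


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

_KIND_COLUMNS = {
    "fluid": ("u", "v", "w"),
    "particles": ("x", "y", "z"),
}


def write_table(sset: SnapshotSet, path: str | Path) -> None:
    """Write a deck as a long-format CSV plus a JSON metadata sidecar.

    Columns: ``frame, id, c1, c2, c3``.  The sidecar ``<path>.meta.json``
    records dt, kind, parameter, masks and coordinates so that
    :func:`read_table` restores the full :class:`SnapshotSet`.
    """
    path = Path(path)
    n, nt = sset.n_entities, sset.n_frames
    cols = _KIND_COLUMNS.get(sset.kind, ("c1", "c2", "c3"))
    frame = np.repeat(np.arange(nt), n)
    ids = np.tile(np.asarray(sset.ids), nt)
    # values[c, e, t] -> row order: all entities of frame 0, frame 1, ...
    table = pd.DataFrame(
        {
            "frame": frame,
            "id": ids,
            cols[0]: sset.values[0].T.ravel(),
            cols[1]: sset.values[1].T.ravel(),
            cols[2]: sset.values[2].T.ravel(),
        }
    )
    table.to_csv(path, index=False)
    meta = {
        "format_version": FORMAT_VERSION,
        "kind": sset.kind,
        "dt": sset.dt,
        "parameter": sset.parameter,
        "n_entities": n,
        "n_frames": nt,
        "value_columns": list(cols),
        "times": sset.times.tolist(),
        "masks": {k: np.flatnonzero(v).tolist() for k, v in sset.masks.items()},
        "coords": None if sset.coords is None else sset.coords.tolist(),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def read_table(path: str | Path) -> SnapshotSet:
    """Read a deck written by :func:`write_table`."""
    path = Path(path)
    meta_path = Path(str(path) + ".meta.json")
    if not meta_path.exists():
        raise DataError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    table = pd.read_csv(path)
    n, nt = meta["n_entities"], meta["n_frames"]
    cols = meta["value_columns"]
    if len(table) != n * nt:
        raise DataError(
            f"table has {len(table)} rows, expected {n}*{nt}={n * nt}"
        )
    table = table.sort_values(["frame", "id"], kind="stable")
    values = np.empty((3, n, nt))
    for c, col in enumerate(cols):
        values[c] = table[col].to_numpy().reshape(nt, n).T
    ids = table["id"].to_numpy()[:n]
    masks = {
        name: np.isin(np.arange(n), idx)
        for name, idx in meta.get("masks", {}).items()
    }
    coords = meta.get("coords")
    return SnapshotSet(
        kind=meta["kind"],
        values=values,
        dt=meta["dt"],
        times=np.asarray(meta["times"]),
        coords=None if coords is None else np.asarray(coords),
        ids=ids,
        masks=masks,
        parameter=meta.get("parameter"),
    )


def write_geometry_table(
    coords: np.ndarray, masks: Mapping[str, np.ndarray], path: str | Path
) -> None:
    """Write a node table (id, x, y, z, region) as CSV."""
    coords = np.asarray(coords, dtype=float)
    region = np.array(["interior"] * len(coords), dtype=object)
    for name, mask in masks.items():
        region[np.asarray(mask, dtype=bool)] = name
    pd.DataFrame(
        {
            "id": np.arange(len(coords)),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "region": region,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Legacy-VTK point-data export (visualization plumbing)
# ---------------------------------------------------------------------------


def write_vtk_frame(
    sset: SnapshotSet, frame: int, path: str | Path, field_name: str = "field"
) -> None:
    """Write one frame as an ASCII legacy-VTK polydata point cloud.

    One file per frame; requires entity coordinates for fluid decks
    (particle decks use the frame positions themselves as points).
    """
    if sset.kind == "particles":
        points = sset.values[:, :, frame].T
    elif sset.coords is not None:
        points = sset.coords
    else:
        raise DataError("fluid deck needs coords for VTK export")
    vec = sset.values[:, :, frame].T
    n = len(points)
    lines = [
        "# vtk DataFile Version 3.0",
        f"airdmd frame {frame} t={sset.times[frame]:.6g}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{x:.17g}" for x in p) for p in points]
    lines += [f"POINT_DATA {n}", f"VECTORS {field_name} double"]
    lines += [" ".join(f"{x:.17g}" for x in v) for v in vec]
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_series(
    sset: SnapshotSet, directory: str | Path, prefix: str = "frame"
) -> list[Path]:
    """Write every frame of a deck as legacy-VTK files; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(sset.n_frames):
        p = directory / f"{prefix}_{k:04d}.vtk"
        write_vtk_frame(sset, k, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# ModelBundle: versioned array-container serialization
# ---------------------------------------------------------------------------


def save_bundle(
    path: str | Path,
    arrays: Mapping[str, np.ndarray],
    metadata: Mapping | None = None,
) -> None:
    """Persist named arrays plus a JSON manifest into a directory.

    Arrays go to ``<name>.npy`` (bit-exact round trip); the manifest
    records shapes, dtypes, a format version and caller metadata.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "metadata": dict(metadata or {}),
        "arrays": {},
    }
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        np.save(path / f"{name}.npy", arr)
        manifest["arrays"][name] = {
            "shape": list(arr.shape),
            "dtype": str(arr.dtype),
        }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_bundle(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Load a bundle written by :func:`save_bundle`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"{path} is not a model bundle (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise DataError(
            f"unsupported bundle format version {manifest.get('format_version')}"
        )
    arrays = {}
    for name, info in manifest["arrays"].items():
        arr = np.load(path / f"{name}.npy")
        if list(arr.shape) != info["shape"] or str(arr.dtype) != info["dtype"]:
            raise DataError(f"array {name!r} does not match its manifest entry")
        arrays[name] = arr
    return arrays, manifest["metadata"]
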