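"""Reconstruction-error metrics: per-snapshot relative L2 error, mean
and maximum relative error, and region-restricted error tables.

The per-snapshot error is

    eps_k = ||x_k_truth - x_k_recon||_2 / ||x_k_truth||_2 * 100 %,

computed on flattened frames.  Frames whose truth norm falls below a
relative low-energy threshold are excluded (reported as NaN and
counted) instead of producing unbounded ratios; with pre-trimmed decks
the default threshold only guards against exact zeros.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import DataError, ShapeMismatchError
from .snapshots import SnapshotSet, flatten, region_view

#: frames with ||x_truth|| below this fraction of the peak frame norm
#: are excluded from the error series
DEFAULT_LOW_ENERGY_THRESHOLD = 1e-12


@dataclasses.dataclass(frozen=True)
class RegionErrors:
    eps_max: float  # max over frames of eps_k, %
    mre: float  # mean over frames of eps_k, %
    max_cell_error: float  # max single-entity relative error, %
    n_excluded_frames: int


@dataclasses.dataclass(frozen=True)
class ErrorReport:
    """Full-field and per-region error metrics for one reconstruction."""

    eps_k: np.ndarray  # per-frame %, NaN where excluded
    regions: dict[str, RegionErrors]  # includes "full"
    metadata: dict

    @property
    def mre(self) -> float:
        return self.regions["full"].mre

    @property
    def eps_max(self) -> float:
        return self.regions["full"].eps_max

    def to_frame(self) -> pd.DataFrame:
        """Metrics as a table (rows: metric, columns: region)."""
        rows = {
            "Maximum Error [%]": {k: v.eps_max for k, v in self.regions.items()},
            "Mean Relative Error [%]": {k: v.mre for k, v in self.regions.items()},
            "Max Single-Cell Error [%]": {
                k: v.max_cell_error for k, v in self.regions.items()
            },
            "Excluded Frames": {
                k: v.n_excluded_frames for k, v in self.regions.items()
            },
        }
        return pd.DataFrame(rows).T


def snapshot_errors(
    truth: SnapshotSet,
    recon: SnapshotSet,
    low_energy_threshold: float = DEFAULT_LOW_ENERGY_THRESHOLD,
) -> np.ndarray:
    """Per-frame relative L2 error in percent (NaN at excluded frames)."""
    if truth.values.shape != recon.values.shape:
        raise ShapeMismatchError(
            f"deck shapes differ: {truth.values.shape} vs {recon.values.shape}"
        )
    xt = flatten(truth)
    xr = flatten(recon)
    denom = np.linalg.norm(xt, axis=0)
    num = np.linalg.norm(xt - xr, axis=0)
    cutoff = low_energy_threshold * denom.max()
    eps = np.full(truth.n_frames, np.nan)
    ok = denom > cutoff
    eps[ok] = num[ok] / denom[ok] * 100.0
    return eps


def mean_relative_error(eps: np.ndarray) -> float:
    """Arithmetic mean of the (included) per-frame errors, %."""
    eps = np.asarray(eps, dtype=float)
    eps = eps[np.isfinite(eps)]
    if eps.size == 0:
        raise DataError("error series is empty")
    return float(eps.mean())


def max_relative_error(eps: np.ndarray) -> float:
    """Maximum of the (included) per-frame errors, %."""
    eps = np.asarray(eps, dtype=float)
    eps = eps[np.isfinite(eps)]
    if eps.size == 0:
        raise DataError("error series is empty")
    return float(eps.max())


def _cellwise_max_error(
    truth: SnapshotSet, recon: SnapshotSet, low_energy_threshold: float
) -> float:
    """Worst single-entity relative error over all entities and frames:
    per-entity 3-vector difference norm over truth vector norm."""
    tn = np.linalg.norm(truth.values, axis=0)  # (N, Nt)
    dn = np.linalg.norm(truth.values - recon.values, axis=0)
    cutoff = max(low_energy_threshold * tn.max(), 1e-300)
    ok = tn > cutoff
    if not ok.any():
        return float("nan")
    return float((dn[ok] / tn[ok]).max() * 100.0)


def _region_errors(
    truth: SnapshotSet, recon: SnapshotSet, low_energy_threshold: float
) -> RegionErrors:
    eps = snapshot_errors(truth, recon, low_energy_threshold)
    degenerate = not np.isfinite(eps).any()  # e.g. identically-zero region
    return RegionErrors(
        eps_max=float("nan") if degenerate else max_relative_error(eps),
        mre=float("nan") if degenerate else mean_relative_error(eps),
        max_cell_error=_cellwise_max_error(truth, recon, low_energy_threshold),
        n_excluded_frames=int(np.sum(~np.isfinite(eps))),
    )


def region_error_table(
    truth: SnapshotSet,
    recon: SnapshotSet,
    masks: list[str] | None = None,
    low_energy_threshold: float = DEFAULT_LOW_ENERGY_THRESHOLD,
    metadata: dict | None = None,
) -> ErrorReport:
    """Assemble full-field and per-region error metrics.

    Region metrics apply the same per-frame formula to the decks
    restricted to each mask (both decks restricted before the norms).
    ``masks`` defaults to every mask present on the truth deck.
    """
    if masks is None:
        masks = sorted(truth.masks)
    eps_full = snapshot_errors(truth, recon, low_energy_threshold)
    regions = {"full": _region_errors(truth, recon, low_energy_threshold)}
    for name in masks:
        t_sub = region_view(truth, name)
        r_sub = recon.replace(
            values=recon.values[:, truth.masks[name], :], masks={}, coords=None,
            ids=None,
        )
        regions[name] = _region_errors(t_sub, r_sub, low_energy_threshold)
    meta = {
        "n_frames": truth.n_frames,
        "n_entities": truth.n_entities,
        "parameter": truth.parameter,
    }
    meta.update(metadata or {})
    return ErrorReport(eps_k=eps_full, regions=regions, metadata=meta)
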