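"""Deposition analytics: filtering, radial PDFs and distribution overlap.

The trajectory-phase pipeline trains a DMD model on deposited-only
particle trajectories, reconstructs them, and compares the radial
deposition distributions of truth and reconstruction (final-frame
positions, binned uniformly at ``dr = 0.01 R`` around a carina-like
reference point) through the Bhattacharyya coefficient.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .errors import BinningError, DataError, EmptyResultError
from .snapshots import SnapshotSet

logger = logging.getLogger(__name__)

#: bin width as a fraction of the radial extent R
BIN_FRACTION = 0.01


@dataclasses.dataclass
class ParticleEnsemble:
    """Per-particle trajectories with deposition bookkeeping.

    ``trajectories`` is ``(3, Np, Nt)`` positions in metres.  A deposited
    particle's position is held constant after its deposition frame; its
    final position is its deposition site.  ``deposited`` and
    ``escaped`` are mutually exclusive.
    """

    trajectories: np.ndarray
    dt: float
    diameters: np.ndarray | None = None
    density: float | None = None
    deposited: np.ndarray | None = None
    deposition_frame: np.ndarray | None = None
    deposition_site: np.ndarray | None = None
    escaped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trajectories = np.asarray(self.trajectories, dtype=float)
        if self.trajectories.ndim != 3 or self.trajectories.shape[0] != 3:
            raise DataError("trajectories must have shape (3, Np, Nt)")
        n = self.n_particles
        if self.deposited is None:
            self.deposited = np.zeros(n, dtype=bool)
        else:
            self.deposited = np.asarray(self.deposited, dtype=bool)
        if self.escaped is None:
            self.escaped = np.zeros(n, dtype=bool)
        else:
            self.escaped = np.asarray(self.escaped, dtype=bool)
        if np.any(self.deposited & self.escaped):
            raise DataError("a particle cannot be both deposited and escaped")
        if self.diameters is not None:
            self.diameters = np.asarray(self.diameters, dtype=float)

    @property
    def n_particles(self) -> int:
        return self.trajectories.shape[1]

    @property
    def n_frames(self) -> int:
        return self.trajectories.shape[2]

    def final_positions(self) -> np.ndarray:
        """``(Np, 3)`` last-frame positions (deposition sites for
        deposited particles)."""
        return self.trajectories[:, :, -1].T

    def to_snapshot_set(self) -> SnapshotSet:
        return SnapshotSet(kind="particles", values=self.trajectories, dt=self.dt)

    def subset(self, mask: np.ndarray) -> "ParticleEnsemble":
        mask = np.asarray(mask, dtype=bool)

        def take(a):
            return None if a is None else a[mask]

        return ParticleEnsemble(
            trajectories=self.trajectories[:, mask, :],
            dt=self.dt,
            diameters=take(self.diameters),
            density=self.density,
            deposited=take(self.deposited),
            deposition_frame=take(self.deposition_frame),
            deposition_site=None
            if self.deposition_site is None
            else self.deposition_site[mask],
            escaped=take(self.escaped),
        )


@dataclasses.dataclass(frozen=True)
class DepositionPDF:
    """Radial deposition histogram normalized to a density.

    Bins are ``[(i-1) dr, i dr)`` for ``i = 1..round(R/dr)`` with
    ``dr = 0.01 R``; ``densities[i] = counts[i] / (N dr)`` so that
    ``sum(densities) * dr == 1``.
    """

    p0: np.ndarray
    R: float
    dr: float
    counts: np.ndarray
    densities: np.ndarray
    n_total: int

    @property
    def masses(self) -> np.ndarray:
        """Per-bin probability masses ``p_i * dr = n_i / N``."""
        return self.densities * self.dr

    def bin_edges(self) -> np.ndarray:
        return np.arange(len(self.counts) + 1) * self.dr

    def same_binning(self, other: "DepositionPDF") -> bool:
        return (
            np.allclose(self.p0, other.p0)
            and np.isclose(self.R, other.R)
            and np.isclose(self.dr, other.dr)
            and len(self.counts) == len(other.counts)
        )


def filter_deposited(ens: ParticleEnsemble) -> ParticleEnsemble:
    """Keep only deposited particles (frame grid preserved)."""
    if not ens.deposited.any():
        raise EmptyResultError("no deposited particles in ensemble")
    return ens.subset(ens.deposited)


def radial_distance(point: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """Euclidean distance from ``point`` (or an array of points, last
    axis length 3) to the reference point ``p0``."""
    point = np.asarray(point, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    return np.linalg.norm(point - p0, axis=-1)


def deposition_pdf(
    final_positions: np.ndarray,
    p0: np.ndarray,
    R: float,
    bin_fraction: float = BIN_FRACTION,
) -> DepositionPDF:
    """Bin final positions by radial distance from ``p0``.

    ``final_positions`` is ``(Np, 3)``.  If any particle lies beyond
    ``R``, the radius is raised to cover it (logged).  Bin width is
    ``bin_fraction * R``.
    """
    final_positions = np.asarray(final_positions, dtype=float).reshape(-1, 3)
    if len(final_positions) == 0:
        raise EmptyResultError("no particles to bin")
    if R <= 0:
        raise DataError(f"R must be positive, got {R}")
    radii = radial_distance(final_positions, p0)
    rmax = radii.max()
    if rmax > R:
        logger.info("raising R from %g to %g to cover all particles", R, rmax)
        R = float(rmax) * (1 + 1e-12)
    dr = bin_fraction * R
    n_bins = int(round(R / dr))
    edges = np.arange(n_bins + 1) * dr
    # right-inclusive last edge so r == R lands in the final bin
    counts, _ = np.histogram(np.minimum(radii, edges[-1] * (1 - 1e-15)), bins=edges)
    n = len(radii)
    densities = counts / (n * dr)
    return DepositionPDF(
        p0=np.asarray(p0, dtype=float),
        R=float(R),
        dr=float(dr),
        counts=counts,
        densities=densities,
        n_total=n,
    )


def bhattacharyya(
    d1: DepositionPDF, d2: DepositionPDF, literal_form: bool = False
) -> float:
    """Overlap coefficient between two radial deposition distributions.

    Computed as ``sum_i sqrt(q1_i * q2_i)`` on per-bin probability
    masses ``q_i = p_i * dr``: 1 for identical distributions, 0 for
    disjoint support, symmetric, bounded in [0, 1].

    ``literal_form=True`` instead returns the plain product-sum
    ``sum_i q1_i * q2_i`` (a compatibility variant that does *not*
    equal 1 for identical non-degenerate distributions).
    """
    if not d1.same_binning(d2):
        raise BinningError("distributions do not share binning (p0, R, dr)")
    q1, q2 = d1.masses, d2.masses
    if literal_form:
        return float(np.sum(q1 * q2))
    return float(np.sum(np.sqrt(q1 * q2)))


@dataclasses.dataclass(frozen=True)
class ParticlePhaseResult:
    """Output of the trajectory-phase pipeline."""

    truth_pdf: DepositionPDF
    recon_pdf: DepositionPDF
    bhattacharyya: float
    trajectory_rmse: np.ndarray  # per particle, metres


def particle_phase_pipeline(
    truth: ParticleEnsemble,
    model,
    p0: np.ndarray,
    R: float | None = None,
) -> ParticlePhaseResult:
    """Compare truth vs DMD-reconstructed deposition distributions.

    ``model`` is a fitted :class:`~airdmd.dmd.DMDModel` trained on the
    deposited-only trajectory deck of ``truth``.  Trajectories are
    reconstructed on the truth frame grid; final-frame positions define
    deposition sites.  If ``R`` is omitted it defaults to the maximum
    radial distance over both ensembles' final positions.
    """
    from .dmd import reconstruct_deck

    times = np.arange(truth.n_frames) * truth.dt
    recon = reconstruct_deck(model, times)
    if recon.n_entities != truth.n_particles:
        raise DataError(
            "model entity count does not match ensemble particle count"
        )
    truth_final = truth.final_positions()
    recon_final = recon.values[:, :, -1].T
    if R is None:
        r_all = np.concatenate(
            [radial_distance(truth_final, p0), radial_distance(recon_final, p0)]
        )
        R = float(r_all.max())
    truth_pdf = deposition_pdf(truth_final, p0, R)
    recon_pdf = deposition_pdf(recon_final, p0, R)
    # force shared binning even if one cloud spills past R
    if not truth_pdf.same_binning(recon_pdf):
        R = max(truth_pdf.R, recon_pdf.R)
        truth_pdf = deposition_pdf(truth_final, p0, R)
        recon_pdf = deposition_pdf(recon_final, p0, R)
    coeff = bhattacharyya(truth_pdf, recon_pdf)
    diff = truth.trajectories - recon.values
    rmse = np.sqrt(np.mean(np.sum(diff**2, axis=0), axis=-1))
    return ParticlePhaseResult(
        truth_pdf=truth_pdf,
        recon_pdf=recon_pdf,
        bhattacharyya=coeff,
        trajectory_rmse=rmse,
    )
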