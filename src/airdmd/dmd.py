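"""Exact dynamic mode decomposition: fit, spectrum, reconstruction.

Given the lagged/shifted snapshot pair ``(X-, X+)``, the fit computes a
thin SVD ``X- = U S V^T``, projects the best-fit one-step propagator
onto the leading ``r`` left singular vectors,

    A_tilde = U_r^T X+ V_r S_r^{-1},

eigendecomposes ``A_tilde W = W diag(Lambda)``, forms the exact modes
``Phi = X+ V_r S_r^{-1} W`` and the amplitudes ``b0 = pinv(Phi) x1``.
Snapshots at dimensionless time ``t/dt`` are reconstructed as the real
part of ``Phi Lambda^{t/dt} b0`` (principal branch for non-integer
powers; at integer steps this equals repeated multiplication).

Eigenpairs are put in a canonical order (|arg| ascending, then |lambda|
descending, then positive-argument member of each conjugate pair first)
and eigenvectors are normalized to unit 2-norm with the phase fixed so
the largest-magnitude entry is real and positive.  Both conventions
remove the scale/phase/order ambiguity that would otherwise corrupt
cross-model mode pairing.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError, NumericalError, RankDeficiencyError
from .snapshots import SnapshotMatrixPair, SnapshotSet, load_bundle, save_bundle, unflatten

logger = logging.getLogger(__name__)

#: singular values below ``max(s) * RANK_TOL`` count as numerically zero
RANK_TOL = 1e-12


@dataclasses.dataclass
class DMDModel:
    """Fitted exact-DMD model (truncated SVD factors, reduced operator,
    eigenpairs, exact modes, amplitudes).

    ``x1`` keeps the first flattened snapshot so that alternative
    amplitude projections (used by the parametric interpolation) can be
    recomputed without the original deck.
    """

    Ur: np.ndarray
    Sr: np.ndarray
    Vr: np.ndarray
    A_tilde: np.ndarray
    Lambda: np.ndarray
    W: np.ndarray
    Phi: np.ndarray
    b0: np.ndarray
    x1: np.ndarray
    dt: float
    r: int
    parameter: float | None = None

    @property
    def n_rows(self) -> int:
        return self.Ur.shape[0]

    @property
    def n_entities(self) -> int:
        return self.n_rows // 3

    def validate(self, atol: float = 1e-10) -> None:
        """Check the structural invariants of a fitted model."""
        if self.r > self.Vr.shape[0]:
            raise DataError("rank exceeds m-1")
        if np.any(self.Sr <= 0):
            raise DataError("retained singular values must be positive")
        resid = np.linalg.norm(self.A_tilde @ self.W - self.W * self.Lambda)
        scale = max(np.linalg.norm(self.A_tilde), 1e-300)
        if resid > atol * scale * np.sqrt(self.r):
            raise NumericalError("eigenpair residual exceeds tolerance")
        lam = self.Lambda
        conj_dist = np.abs(np.sort_complex(lam) - np.sort_complex(lam.conj()))
        if conj_dist.max(initial=0.0) > 1e-10 * max(np.abs(lam).max(), 1.0):
            raise NumericalError("spectrum not closed under conjugation")


def canonical_eig_order(lam: np.ndarray) -> np.ndarray:
    """Indices sorting eigenvalues by |arg| ascending, then |lambda|
    descending, then positive argument first."""
    arg = np.angle(lam)
    return np.lexsort((-np.sign(arg), -np.abs(lam), np.abs(arg)))


def normalize_eigvecs(W: np.ndarray) -> np.ndarray:
    """Unit 2-norm columns with the largest-magnitude entry made real
    and positive."""
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    lead = np.abs(W).argmax(axis=0)
    pivot = W[lead, np.arange(W.shape[1])]
    phase = pivot / np.abs(pivot)
    return W / phase


def choose_rank(singular_values: np.ndarray, energy: float) -> int:
    """Smallest r capturing the requested squared-singular-value energy
    fraction."""
    if not 0 < energy <= 1:
        raise ConfigurationError(f"energy must lie in (0, 1], got {energy}")
    s = np.asarray(singular_values, dtype=float)
    s = s[s > s.max() * RANK_TOL]
    frac = np.cumsum(s**2) / np.sum(s**2)
    return int(np.searchsorted(frac, energy - 1e-12) + 1)


def _eig_sorted(A_tilde: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, W = np.linalg.eig(A_tilde)
    order = canonical_eig_order(lam)
    return lam[order], normalize_eigvecs(W[:, order])


def fit(
    pair: SnapshotMatrixPair,
    rank: int | None = None,
    energy: float | None = None,
) -> DMDModel:
    """Fit an exact-DMD model to a snapshot-matrix pair.

    Rank selection: ``rank`` (fixed r) takes precedence, then
    ``energy`` (squared-singular-value fraction), else the full
    numerical rank of ``X-`` is retained.

    Amplitudes are fit to the first snapshot only (``b0 = pinv(Phi)
    x1``); a least-squares fit over all snapshots would weight later
    frames but is deliberately not offered here.
    """
    if rank is not None and energy is not None:
        raise ConfigurationError("give either rank or energy, not both")
    U, s, Vt = np.linalg.svd(pair.x_minus, full_matrices=False)
    if s[0] == 0:
        raise RankDeficiencyError("zero snapshot matrix", attainable_rank=0)
    num_rank = int(np.sum(s > s[0] * RANK_TOL))
    if rank is not None:
        if rank < 1:
            raise ConfigurationError("rank must be >= 1")
        if rank > num_rank:
            raise RankDeficiencyError(
                f"requested rank {rank} exceeds numerical rank {num_rank}",
                attainable_rank=num_rank,
            )
        r = rank
    elif energy is not None:
        r = choose_rank(s, energy)
    else:
        r = num_rank

    Ur = U[:, :r]
    Sr = s[:r]
    Vr = Vt[:r].T
    B = pair.x_plus @ (Vr / Sr)  # X+ V_r S_r^{-1}
    A_tilde = Ur.T @ B
    lam, W = _eig_sorted(A_tilde)
    Phi = B.astype(complex) @ W
    x1 = pair.x_minus[:, 0]
    b0, *_ = np.linalg.lstsq(Phi, x1.astype(complex), rcond=None)
    model = DMDModel(
        Ur=Ur,
        Sr=Sr,
        Vr=Vr,
        A_tilde=A_tilde,
        Lambda=lam,
        W=W,
        Phi=Phi,
        b0=b0,
        x1=x1,
        dt=pair.dt,
        r=r,
        parameter=pair.parameter,
    )
    return model


def _lambda_power(lam: np.ndarray, t_over_dt: float) -> np.ndarray:
    if t_over_dt < 0 and np.any(lam == 0):
        raise ConfigurationError("negative time with a zero eigenvalue")
    if t_over_dt == int(t_over_dt):
        return lam ** int(t_over_dt)
    return lam ** complex(t_over_dt)  # principal branch


def reconstruct(model: DMDModel, t_over_dt: float) -> np.ndarray:
    """Reconstruct one flattened snapshot at dimensionless time
    ``t/dt`` (real part of ``Phi Lambda^{t/dt} b0``)."""
    z = model.Phi @ (_lambda_power(model.Lambda, t_over_dt) * model.b0)
    real_norm = np.linalg.norm(z.real)
    imag_norm = np.linalg.norm(z.imag)
    if real_norm > 0 and imag_norm > 1e-8 * real_norm:
        logger.debug(
            "discarded imaginary part is %.3g of the real magnitude at t/dt=%g",
            imag_norm / real_norm,
            t_over_dt,
        )
    return z.real


def reconstruct_deck(
    model: DMDModel, times: np.ndarray, kind: str = "fluid"
) -> SnapshotSet:
    """Reconstruct a deck at the given instants (seconds)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise ConfigurationError("times must be non-empty")
    powers = np.empty((model.r, times.size), dtype=complex)
    for k, t in enumerate(times):
        powers[:, k] = _lambda_power(model.Lambda, t / model.dt)
    X = (model.Phi @ (powers * model.b0[:, None])).real
    dt = model.dt if times.size == 1 else float(times[1] - times[0])
    return SnapshotSet(
        kind=kind,
        values=unflatten(X, model.n_entities),
        dt=dt,
        times=times,
        parameter=model.parameter,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_model(model: DMDModel, path: str | Path) -> None:
    """Persist a model as an array bundle (bit-exact round trip)."""
    arrays = {
        name: getattr(model, name)
        for name in ("Ur", "Sr", "Vr", "A_tilde", "Lambda", "W", "Phi", "b0", "x1")
    }
    save_bundle(
        path,
        arrays,
        metadata={
            "dt": model.dt,
            "r": model.r,
            "parameter": model.parameter,
            "object": "DMDModel",
        },
    )


def load_model(path: str | Path) -> DMDModel:
    arrays, meta = load_bundle(path)
    if meta.get("object") != "DMDModel":
        raise DataError(f"{path} does not contain a DMDModel")
    return DMDModel(
        dt=meta["dt"], r=meta["r"], parameter=meta.get("parameter"), **arrays
    )
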