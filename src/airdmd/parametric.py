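"""Parametric interpolation of reduced propagators between flow rates.

Given models trained at two flow rates bracketing a target rate, the
reduced operators, truncated bases and amplitudes are blended linearly
with the weight

    theta = (vdot_theta - vdot_2) / (vdot_1 - vdot_2),

the blended operator is eigendecomposed, and the target-rate deck is
reconstructed from the blended modes ``Phi_theta = U_theta W_theta``.

Two details are handled explicitly because raw linear blending is
ill-defined without them:

* **Mode alignment** (:func:`align_models`): SVD columns carry an
  arbitrary sign and, under near-degenerate singular values, an
  arbitrary order.  The second model is sign-flipped and re-ordered,
  column by column, to maximize correlation with the first model's
  basis before any blending.
* **Amplitude convention**: the blended modes are *projected* modes
  (``U W``), so the blended amplitudes use the matching projected-mode
  amplitudes ``b = W^{-1} U^T x1`` rather than the exact-mode
  amplitudes stored on each model.  Mixing the two conventions would
  shift the reconstruction by one time step even at a trained rate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .dmd import DMDModel, _eig_sorted, _lambda_power
from .errors import CoverageError, DataError, ExtrapolationError
from .snapshots import SnapshotSet, unflatten

logger = logging.getLogger(__name__)

#: two basis-correlation candidates closer than this are ambiguous
ALIGN_AMBIGUITY_TOL = 1e-6


@dataclasses.dataclass
class ParametricModelSet:
    """Interpolation products at a target flow rate."""

    models: dict[float, DMDModel]
    vdot_theta: float
    bracket: tuple[float, float]  # (vdot_1, vdot_2) with weight theta on 1
    theta: float
    A_theta: np.ndarray
    U_theta: np.ndarray
    Lambda_theta: np.ndarray
    W_theta: np.ndarray
    Phi_theta: np.ndarray
    b0_theta: np.ndarray
    dt: float
    r: int

    @property
    def n_entities(self) -> int:
        return self.U_theta.shape[0] // 3


def interpolation_weight(
    vdot_theta: float,
    vdot_1: float,
    vdot_2: float,
    allow_extrapolation: bool = False,
) -> float:
    """Linear blending weight on model 1; 1 at ``vdot_1``, 0 at ``vdot_2``."""
    if vdot_1 == vdot_2:
        raise DataError("bracketing flow rates must differ")
    theta = (vdot_theta - vdot_2) / (vdot_1 - vdot_2)
    if not allow_extrapolation and not -1e-12 <= theta <= 1 + 1e-12:
        raise ExtrapolationError(
            f"target rate {vdot_theta} lies outside the bracket "
            f"({vdot_1}, {vdot_2}); pass allow_extrapolation=True to override"
        )
    return float(min(max(theta, 0.0), 1.0)) if not allow_extrapolation else float(theta)


def projected_amplitudes(model: DMDModel) -> np.ndarray:
    """Amplitudes of the first snapshot in the projected-mode basis
    ``U W``: ``b = W^{-1} U^T x1``."""
    return np.linalg.solve(model.W, model.Ur.T @ model.x1)


def align_models(m1: DMDModel, m2: DMDModel) -> DMDModel:
    """Return a copy of ``m2`` whose basis columns are sign-flipped and
    re-ordered to match ``m1`` column by column.

    The signed permutation is applied consistently to ``Ur``, ``Sr``
    and ``Vr``; the reduced operator, eigenpairs, modes and amplitudes
    are then recomputed from the transformed factors, so the aligned
    model reconstructs identically to the original.  Idempotent.
    """
    if m1.r != m2.r or m1.n_rows != m2.n_rows:
        raise DataError("models must share rank and state dimension")
    r = m1.r
    corr = np.abs(m1.Ur.T @ m2.Ur)  # (r, r)
    perm = np.full(r, -1, dtype=int)
    used = np.zeros(r, dtype=bool)
    for i in range(r):
        scores = np.where(used, -np.inf, corr[i])
        j = int(np.argmax(scores))
        runner_up = np.max(np.where(used | (np.arange(r) == j), -np.inf, scores))
        if np.isfinite(runner_up) and scores[j] - runner_up < ALIGN_AMBIGUITY_TOL:
            logger.warning(
                "ambiguous basis pairing for column %d (correlations %.6g vs %.6g); "
                "keeping canonical order",
                i,
                scores[j],
                runner_up,
            )
            j = i if not used[i] else j
        perm[i] = j
        used[j] = True
    signs = np.sign(np.einsum("ij,ij->j", m1.Ur, m2.Ur[:, perm]))
    signs[signs == 0] = 1.0

    if np.array_equal(perm, np.arange(r)) and np.all(signs == 1.0):
        return m2
    return apply_signed_permutation(m2, perm, signs)


def apply_signed_permutation(
    model: DMDModel, perm: np.ndarray, signs: np.ndarray
) -> DMDModel:
    """Re-order and sign-flip a model's basis columns.

    Produces an equally valid model (same reconstruction) whose SVD
    factors carry a different column order/sign convention — the
    ambiguity :func:`align_models` exists to undo.
    """
    r = model.r
    perm = np.asarray(perm, dtype=int)
    signs = np.asarray(signs, dtype=float)
    S = np.zeros((r, r))
    S[perm, np.arange(r)] = signs
    A_tilde = S.T @ model.A_tilde @ S
    lam, W = _eig_sorted(A_tilde)
    Phi = model.Phi @ np.linalg.solve(model.W, S.astype(complex) @ W)
    b0, *_ = np.linalg.lstsq(Phi, model.x1.astype(complex), rcond=None)
    return DMDModel(
        Ur=model.Ur[:, perm] * signs,
        Sr=model.Sr[perm],
        Vr=model.Vr[:, perm] * signs,
        A_tilde=A_tilde,
        Lambda=lam,
        W=W,
        Phi=Phi,
        b0=b0,
        x1=model.x1,
        dt=model.dt,
        r=r,
        parameter=model.parameter,
    )


def _select_bracket(rates: list[float], vdot_theta: float) -> tuple[float, float]:
    """Two nearest trained rates, ordered (lower, upper); ties toward
    the lower rate."""
    rates = sorted(rates)
    if len(rates) < 2:
        raise CoverageError("need at least two trained flow rates")
    by_distance = sorted(rates, key=lambda v: (abs(v - vdot_theta), v))
    pair = sorted(by_distance[:2])
    return pair[0], pair[1]


def interpolate(
    models: dict[float, DMDModel],
    vdot_theta: float,
    allow_extrapolation: bool = False,
    re_orthonormalize: bool = False,
) -> ParametricModelSet:
    """Blend the two nearest trained models at a target flow rate.

    ``models`` maps trained flow rates (L/min) to fitted models sharing
    rank, state dimension and dt.  Extrapolation beyond the trained
    range is refused unless ``allow_extrapolation`` is set.
    ``re_orthonormalize`` replaces the blended basis with its QR
    orthonormalization (the deviation is logged); by default the raw
    linear blend is used.
    """
    lo, hi = _select_bracket(list(models), vdot_theta)
    if not allow_extrapolation and not lo - 1e-12 <= vdot_theta <= hi + 1e-12:
        raise CoverageError(
            f"no trained pair brackets {vdot_theta}; trained rates: {sorted(models)}"
        )
    m1, m2 = models[lo], models[hi]
    if not np.isclose(m1.dt, m2.dt):
        raise DataError("bracketing models must share dt")
    theta = interpolation_weight(
        vdot_theta, lo, hi, allow_extrapolation=allow_extrapolation
    )
    m2 = align_models(m1, m2)

    A_theta = theta * m1.A_tilde + (1 - theta) * m2.A_tilde
    lam, W = _eig_sorted(A_theta)
    U_theta = theta * m1.Ur + (1 - theta) * m2.Ur
    if re_orthonormalize:
        gram_dev = np.linalg.norm(U_theta.T @ U_theta - np.eye(m1.r))
        logger.info("re-orthonormalizing blended basis; ||U^T U - I|| = %.3g", gram_dev)
        Q, Rfac = np.linalg.qr(U_theta)
        U_theta = Q * np.sign(np.diag(Rfac))
    Phi_theta = U_theta.astype(complex) @ W
    b0_theta = theta * projected_amplitudes(m1) + (1 - theta) * projected_amplitudes(m2)
    return ParametricModelSet(
        models=models,
        vdot_theta=float(vdot_theta),
        bracket=(lo, hi),
        theta=theta,
        A_theta=A_theta,
        U_theta=U_theta,
        Lambda_theta=lam,
        W_theta=W,
        Phi_theta=Phi_theta,
        b0_theta=b0_theta,
        dt=m1.dt,
        r=m1.r,
    )


def reconstruct_interpolated(
    pset: ParametricModelSet, times: np.ndarray, kind: str = "fluid"
) -> SnapshotSet:
    """Reconstruct a deck at the target flow rate (real part of
    ``Phi_theta Lambda_theta^{t/dt} b0_theta``)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise DataError("times must be non-empty")
    powers = np.empty((pset.r, times.size), dtype=complex)
    for k, t in enumerate(times):
        powers[:, k] = _lambda_power(pset.Lambda_theta, t / pset.dt)
    X = (pset.Phi_theta @ (powers * pset.b0_theta[:, None])).real
    dt = pset.dt if times.size == 1 else float(times[1] - times[0])
    return SnapshotSet(
        kind=kind,
        values=unflatten(X, pset.n_entities),
        dt=dt,
        times=times,
        parameter=pset.vdot_theta,
    )
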