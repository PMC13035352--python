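"""Synthetic snapshot decks, aerosol ensembles and analytic fixtures.

This module emulates the statistical structure of the CFD/Lagrangian
snapshot decks that the decomposition pipeline consumes, so every stage
of the analysis can run on desk-scale, fully reproducible inputs:

* a sinusoidally forced breathing cycle (period ``T``, peak flow
  ``vdot_max``) sampled at a uniform step ``dt``;
* a parametric family of velocity decks whose mode amplitudes scale
  linearly with the peak flow rate, on an analytic Y-bifurcation
  point-cloud geometry with wall/inlet/outlet region labels;
* particle ensembles with log-normal diameters, advected as passive
  tracers (plus an optional seeded random walk) to wall deposition;
* exact linear-propagator fixtures whose spectra are known in closed
  form — the analytic oracles for the decomposition.

The tracer advection is deliberately simple (explicit first-order
stepping, nearest-node velocity lookup, capture-radius deposition): the
pipeline only needs trajectory decks with the right tensor structure,
not a faithful transport model.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .deposition import ParticleEnsemble
from .errors import ConfigurationError, DataError
from .snapshots import SnapshotSet

#: reference flow rate for the default linear amplitude scaling (L/min)
REFERENCE_FLOW_RATE = 50.0


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class WaveformConfig:
    """Sinusoidal inlet waveform: ``vdot(t) = vdot_max * sin(2 pi t / T)``."""

    vdot_max: float = REFERENCE_FLOW_RATE  # peak volumetric flow, L/min
    T: float = 2.4  # breathing period, s
    dt: float = 0.015  # time step, s
    n_frames: int = 160  # frames generated before trailing discard

    def __post_init__(self) -> None:
        if self.T <= 0 or self.dt <= 0 or self.vdot_max <= 0:
            raise ConfigurationError("T, dt and vdot_max must be positive")
        if self.n_frames * self.dt > self.T + self.dt / 2:
            raise ConfigurationError(
                f"{self.n_frames} frames at dt={self.dt} overrun the period T={self.T}"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclasses.dataclass(frozen=True)
class AerosolSpec:
    """Log-normal aerosol: median ``mu`` (um), geometric SD ``sigma_g``,
    density ``rho`` (kg/m^3).  Defaults follow an iodine-131-like
    polydisperse aerosol (median 0.42 um, GSD 3.5, 4390 kg/m^3)."""

    mu: float = 0.42
    sigma_g: float = 3.5
    rho: float = 4390.0
    n_particles: int = 1000
    n_injectors: int = 20

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ConfigurationError("mu and rho must be positive")
        if self.sigma_g < 1:
            raise ConfigurationError("sigma_g must be >= 1")
        if self.n_particles < 1 or self.n_injectors < 1:
            raise ConfigurationError("n_particles and n_injectors must be >= 1")


@dataclasses.dataclass
class ToyGeometry:
    """Point-cloud airway stand-in with region labels.

    ``coords`` is ``(N, 3)`` node positions (m); ``wall``, ``inlet`` and
    ``outlet`` are disjoint boolean masks; ``p0`` is the carina-like
    reference point and ``R`` the maximum radial extent from it.
    """

    coords: np.ndarray
    wall: np.ndarray
    inlet: np.ndarray
    outlet: np.ndarray
    p0: np.ndarray
    R: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.p0 = np.asarray(self.p0, dtype=float)
        n = len(self.coords)
        for name in ("wall", "inlet", "outlet"):
            mask = np.asarray(getattr(self, name), dtype=bool)
            if mask.shape != (n,):
                raise ConfigurationError(f"mask {name!r} must have length {n}")
            setattr(self, name, mask)
        if np.any(self.wall & self.inlet) or np.any(self.wall & self.outlet) or np.any(
            self.inlet & self.outlet
        ):
            raise ConfigurationError("region masks must be disjoint")
        if self.R <= 0:
            raise ConfigurationError("R must be positive")
        radii = np.linalg.norm(self.coords - self.p0, axis=1)
        if radii.max() > self.R * (1 + 1e-9):
            raise ConfigurationError("every node must lie within R of p0")

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def masks(self) -> dict[str, np.ndarray]:
        return {"wall": self.wall, "inlet": self.inlet, "outlet": self.outlet}

    def node_spacing(self) -> float:
        """Median nearest-neighbour distance (used as capture radius)."""
        tree = cKDTree(self.coords)
        d, _ = tree.query(self.coords, k=2)
        return float(np.median(d[:, 1]))


@dataclasses.dataclass
class FieldMode:
    """One spatio-temporal mode: ``amp(vdot) * pattern * sin(2 pi f t + phase)``."""

    pattern: np.ndarray  # (3, N)
    frequency: float  # Hz
    phase: float  # rad
    rel_amplitude: float  # amplitude at the reference flow rate


@dataclasses.dataclass
class ParametricFieldSpec:
    """Analytic velocity-field family parameterized by peak flow rate.

    ``u(x, t; vdot) = sum_j scale(vdot) * rel_amp_j * pattern_j(x)
    * sin(2 pi f_j t + phi_j)``, with ``scale`` monotone in ``vdot``
    (default linear, ``vdot / 50``).  Optional additive Gaussian noise
    (``noise_level`` relative to the deck's peak frame norm) is drawn
    from the seed passed to :func:`generate_flow_snapshots`.
    """

    geometry: ToyGeometry
    waveform: WaveformConfig
    modes: list[FieldMode]
    amplitude_scale: Callable[[float], float] | None = None
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        if not self.modes:
            raise ConfigurationError("spec needs at least one mode")
        n = self.geometry.n_nodes
        for mode in self.modes:
            mode.pattern = np.asarray(mode.pattern, dtype=float)
            if mode.pattern.shape != (3, n):
                raise ConfigurationError("mode patterns must have shape (3, N)")
        if self.amplitude_scale is None:
            self.amplitude_scale = lambda vdot: vdot / REFERENCE_FLOW_RATE


@dataclasses.dataclass(frozen=True)
class LinearFixture:
    """Ground-truth linear system ``x_{k+1} = A x_k`` for oracle tests."""

    A: np.ndarray
    x1: np.ndarray
    n_snapshots: int

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "x1", np.asarray(self.x1, dtype=float))
        if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] < 1:
            raise ConfigurationError("A must be square and non-empty")
        if self.x1.shape != (A.shape[0],):
            raise ConfigurationError("x1 must match the dimension of A")
        if self.n_snapshots < 3:
            raise ConfigurationError("need at least 3 snapshots")


# ---------------------------------------------------------------------------
# Waveform
# ---------------------------------------------------------------------------


def sample_inlet_waveform(cfg: WaveformConfig, t: float | np.ndarray) -> float | np.ndarray:
    """Volumetric inlet flow (L/min) at time ``t``; positive during
    inhalation, negative during exhalation."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > cfg.T):
        raise ConfigurationError(f"t must lie in [0, {cfg.T}]")
    out = cfg.vdot_max * np.sin(2 * np.pi * t / cfg.T)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Toy geometry
# ---------------------------------------------------------------------------


def _tube_nodes(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    radius: float,
    n_axial: int,
    n_circ: int,
    n_radial_interior: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled tube: returns (coords, is_wall). Interior nodes sit on the
    axis and on interior rings; wall nodes on the surface ring."""
    direction = direction / np.linalg.norm(direction)
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    coords, is_wall = [], []
    for s in np.linspace(0.0, length, n_axial):
        center = start + s * direction
        coords.append(center)
        is_wall.append(False)
        for frac in np.linspace(0, 1, n_radial_interior + 2)[1:-1]:
            for k in range(max(3, n_circ // 2)):
                ang = 2 * np.pi * k / max(3, n_circ // 2)
                coords.append(
                    center + frac * radius * (np.cos(ang) * e1 + np.sin(ang) * e2)
                )
                is_wall.append(False)
        for k in range(n_circ):
            ang = 2 * np.pi * k / n_circ
            coords.append(center + radius * (np.cos(ang) * e1 + np.sin(ang) * e2))
            is_wall.append(True)
    return np.asarray(coords), np.asarray(is_wall)


def y_bifurcation_geometry(
    parent_length: float = 0.06,
    parent_radius: float = 0.008,
    daughter_length: float = 0.05,
    daughter_radius: float = 0.006,
    branch_angle_deg: float = 35.0,
    n_axial: int = 10,
    n_circ: int = 14,
) -> ToyGeometry:
    """Analytic Y-bifurcation point cloud (one parent, two daughters).

    The carina-like reference point ``p0`` sits at the origin where the
    parent tube (extending up +z) splits into two daughters angled
    downward in the x-z plane.  The inlet is the top cross-section of
    the parent; outlets are the far cross-sections of the daughters.
    """
    ang = math.radians(branch_angle_deg)
    up = np.array([0.0, 0.0, 1.0])
    d1 = np.array([math.sin(ang), 0.0, -math.cos(ang)])
    d2 = np.array([-math.sin(ang), 0.0, -math.cos(ang)])

    parent, parent_wall = _tube_nodes(
        np.zeros(3), up, parent_length, parent_radius, n_axial, n_circ
    )
    c1, w1 = _tube_nodes(np.zeros(3), d1, daughter_length, daughter_radius, n_axial, n_circ)
    c2, w2 = _tube_nodes(np.zeros(3), d2, daughter_length, daughter_radius, n_axial, n_circ)

    coords = np.vstack([parent, c1, c2])
    wall = np.concatenate([parent_wall, w1, w2])

    inlet = np.zeros(len(coords), dtype=bool)
    outlet = np.zeros(len(coords), dtype=bool)
    # inlet: non-wall nodes of the parent's top cross-section
    top = np.isclose(coords[: len(parent), 2], parent_length, atol=1e-12)
    inlet[: len(parent)] = top & ~parent_wall
    # outlets: non-wall nodes of each daughter's far cross-section
    for offset, (cc, ww, direction) in (
        (len(parent), (c1, w1, d1)),
        (len(parent) + len(c1), (c2, w2, d2)),
    ):
        proj = cc @ direction
        far = np.isclose(proj, daughter_length, atol=1e-12)
        outlet[offset : offset + len(cc)] = far & ~ww
    wall = wall & ~inlet & ~outlet

    p0 = np.zeros(3)
    R = float(np.linalg.norm(coords - p0, axis=1).max()) * (1 + 1e-9)
    return ToyGeometry(coords=coords, wall=wall, inlet=inlet, outlet=outlet, p0=p0, R=R)


# ---------------------------------------------------------------------------
# Parametric velocity-field family
# ---------------------------------------------------------------------------


def _axial_direction_field(geom: ToyGeometry) -> np.ndarray:
    """Unit inhalation-flow direction per node: down the parent, then
    radially outward from the carina along whichever daughter the node
    sits in."""
    dirs = np.zeros((geom.n_nodes, 3))
    z = geom.coords[:, 2]
    in_parent = z > 1e-12
    dirs[in_parent] = [0.0, 0.0, -1.0]
    rel = geom.coords[~in_parent] - geom.p0
    norms = np.linalg.norm(rel, axis=1)
    safe = norms > 1e-12
    out = np.tile([0.0, 0.0, -1.0], (len(rel), 1))
    out[safe] = rel[safe] / norms[safe, None]
    dirs[~in_parent] = out
    return dirs


def _orthonormal_patterns(raw: list[np.ndarray]) -> list[np.ndarray]:
    """Gram-Schmidt over flattened (3, N) patterns -> unit, orthogonal."""
    out: list[np.ndarray] = []
    for p in raw:
        v = p.ravel().astype(float).copy()
        for q in out:
            v -= (q.ravel() @ v) * q.ravel()
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise ConfigurationError("degenerate pattern in Gram-Schmidt")
        out.append((v / nrm).reshape(p.shape))
    return out


def default_field_spec(
    geometry: ToyGeometry | None = None,
    waveform: WaveformConfig | None = None,
    noise_level: float = 0.0,
    peak_speed: float = 0.6,
) -> ParametricFieldSpec:
    """Default two-harmonic breathing-flow family.

    Four orthonormal spatial patterns: a dominant axial inhalation
    pattern driven by ``sin(2 pi t / T)``, a weak quadrature partner
    (5%), a second-harmonic secondary pattern (10%) and its quadrature
    partner.  The quadrature partners make the deck an exactly linear
    dynamical system (two rotation pairs) while keeping the end-of-cycle
    frame norms near zero, as a breathing cycle demands.  Amplitudes are
    linear in the peak flow rate; ``peak_speed`` (m/s) sets the maximum
    nodal speed at the reference flow rate of 50 L/min.
    """
    geometry = geometry or y_bifurcation_geometry()
    waveform = waveform or WaveformConfig()
    dirs = _axial_direction_field(geometry)  # (N, 3)
    radii = np.linalg.norm(geometry.coords - geometry.p0, axis=1)
    rmax = radii.max()
    # dominant mode: axial flow, strongly attenuated (not exactly zero,
    # like vertex-sampled CFD fields) at walls
    profile = np.where(geometry.wall, 0.05, 1.0)
    p1 = (dirs * profile[:, None]).T
    # quadrature partner: axial flow weighted toward the carina
    p2 = (dirs * (profile * np.cos(np.pi * radii / (2 * rmax)))[:, None]).T
    # second harmonic: axial flow weighted toward the periphery
    p3 = (dirs * (profile * np.sin(np.pi * radii / (2 * rmax)))[:, None]).T
    # its quadrature partner: a transverse (x) pattern in the open lumen
    p4 = np.zeros_like(p1)
    p4[0] = profile * np.cos(np.pi * radii / rmax)
    patterns = _orthonormal_patterns([p1, p2, p3, p4])

    # calibrate so the dominant mode peaks at `peak_speed` m/s at 50 L/min
    node_speed = np.linalg.norm(patterns[0], axis=0).max()
    base = peak_speed / node_speed
    f1 = 1.0 / waveform.T
    modes = [
        FieldMode(patterns[0], f1, 0.0, base),
        FieldMode(patterns[1], f1, np.pi / 2, 0.05 * base),
        FieldMode(patterns[2], 2 * f1, 0.0, 0.10 * base),
        FieldMode(patterns[3], 2 * f1, np.pi / 2, 0.005 * base),
    ]
    return ParametricFieldSpec(
        geometry=geometry,
        waveform=waveform,
        modes=modes,
        noise_level=noise_level,
    )


def generate_flow_snapshots(
    spec: ParametricFieldSpec,
    vdot: float,
    seed: int = 0,
    n_frames: int | None = None,
) -> SnapshotSet:
    """Generate a velocity deck at peak flow rate ``vdot`` (L/min).

    Deterministic given ``seed``; the seed only drives the optional
    additive noise term (``spec.noise_level``), so noiseless decks are
    identical across seeds.
    """
    wf = spec.waveform
    nt = n_frames if n_frames is not None else wf.n_frames
    times = np.arange(nt) * wf.dt
    n = spec.geometry.n_nodes
    scale = spec.amplitude_scale(vdot)
    values = np.zeros((3, n, nt))
    for mode in spec.modes:
        temporal = np.sin(2 * np.pi * mode.frequency * times + mode.phase)
        values += (scale * mode.rel_amplitude) * mode.pattern[:, :, None] * temporal
    if spec.noise_level > 0:
        rng = np.random.default_rng(seed)
        peak = np.linalg.norm(values.reshape(-1, nt), axis=0).max()
        values = values + spec.noise_level * peak / np.sqrt(3 * n) * rng.standard_normal(
            values.shape
        )
    return SnapshotSet(
        kind="fluid",
        values=values,
        dt=wf.dt,
        times=times,
        coords=spec.geometry.coords,
        masks=dict(spec.geometry.masks),
        parameter=float(vdot),
    )


# ---------------------------------------------------------------------------
# Aerosol sampling and tracer advection
# ---------------------------------------------------------------------------


def sample_particle_diameters(spec: AerosolSpec, seed: int = 0) -> np.ndarray:
    """Draw ``n_particles`` diameters (um): ``ln d ~ N(ln mu, ln^2 sigma_g)``."""
    rng = np.random.default_rng(seed)
    if spec.sigma_g == 1.0:
        return np.full(spec.n_particles, spec.mu)
    return np.exp(
        rng.normal(np.log(spec.mu), np.log(spec.sigma_g), size=spec.n_particles)
    )


def advect_particles(
    field_deck: SnapshotSet,
    spec: AerosolSpec,
    geometry: ToyGeometry,
    seed: int = 0,
    capture_radius: float | None = None,
    random_walk: float = 0.0,
) -> ParticleEnsemble:
    """Advect passive tracers through a velocity deck to deposition.

    Particles start at ``spec.n_injectors`` injection points sampled
    uniformly from the inlet nodes (with a small in-plane jitter) and
    follow ``dx/dt = u(x, t)`` by explicit first-order steps at the deck
    ``dt``, with velocity taken from the nearest field node, plus an
    optional isotropic random walk of strength ``random_walk``
    (m / sqrt(s)).  A particle deposits when it comes within
    ``capture_radius`` (default: one median inter-node spacing) of a
    wall node, after which its position is frozen; particles reaching an
    outlet or inlet node are flagged escaped and likewise frozen.
    """
    if field_deck.n_entities != geometry.n_nodes:
        raise DataError("field deck and geometry must share nodes")
    inlet_idx = np.flatnonzero(geometry.inlet)
    if len(inlet_idx) == 0:
        raise ConfigurationError("geometry has no inlet nodes")
    rng = np.random.default_rng(seed)
    if capture_radius is None:
        capture_radius = geometry.node_spacing()

    wall_tree = cKDTree(geometry.coords[geometry.wall])
    exit_mask = geometry.outlet | geometry.inlet
    exit_tree = cKDTree(geometry.coords[exit_mask])
    exit_is_inlet = geometry.inlet[exit_mask]
    field_tree = cKDTree(geometry.coords)

    n_p, nt = spec.n_particles, field_deck.n_frames
    injectors = rng.choice(inlet_idx, size=spec.n_injectors, replace=True)
    assign = rng.integers(0, spec.n_injectors, size=n_p)
    pos = geometry.coords[injectors[assign]].copy()
    pos += 0.25 * capture_radius * rng.standard_normal(pos.shape)

    diameters = sample_particle_diameters(spec, seed=seed + 1)
    traj = np.empty((3, n_p, nt))
    deposited = np.zeros(n_p, dtype=bool)
    escaped = np.zeros(n_p, dtype=bool)
    deposition_frame = np.full(n_p, -1, dtype=int)
    escape_frame = np.full(n_p, -1, dtype=int)
    dt = field_deck.dt
    sqrt_dt = np.sqrt(dt)

    for k in range(nt):
        active = ~(deposited | escaped)
        if active.any():
            d_wall, _ = wall_tree.query(pos[active])
            hit = d_wall < capture_radius
            idx = np.flatnonzero(active)
            newly = idx[hit]
            deposited[newly] = True
            deposition_frame[newly] = k
            still = idx[~hit]
            if len(still):
                d_exit, j_exit = exit_tree.query(pos[still])
                out = (d_exit < capture_radius) & (
                    (k > 0) | ~exit_is_inlet[j_exit]
                )  # don't flag freshly injected particles at their own inlet
                gone = still[out]
                escaped[gone] = True
                escape_frame[gone] = k
        traj[:, :, k] = pos.T
        if k == nt - 1:
            break
        active = ~(deposited | escaped)
        if active.any():
            _, nearest = field_tree.query(pos[active])
            u = field_deck.values[:, nearest, k].T
            step = u * dt
            if random_walk > 0:
                step = step + random_walk * sqrt_dt * rng.standard_normal(step.shape)
            pos[active] += step

    site = traj[:, :, -1].T.copy()
    return ParticleEnsemble(
        trajectories=traj,
        dt=dt,
        diameters=diameters,
        density=spec.rho,
        deposited=deposited,
        deposition_frame=deposition_frame,
        deposition_site=site,
        escaped=escaped,
    )


# ---------------------------------------------------------------------------
# Linear fixtures (analytic oracles)
# ---------------------------------------------------------------------------


def _embed_state(states: np.ndarray) -> np.ndarray:
    """Pack an (n, Nt) state sequence into a (3, N, Nt) tensor,
    zero-padding so 3N >= n."""
    n, nt = states.shape
    n_entities = -(-n // 3)
    padded = np.zeros((3 * n_entities, nt))
    padded[:n] = states
    return padded.reshape(3, n_entities, nt)


def make_linear_fixture(fix: LinearFixture) -> SnapshotSet:
    """Roll out ``x_{k+1} = A x_k`` into a deck.

    The state is packed into the 3-component tensor layout (zero-padded
    to a multiple of 3); ``meta["spectrum"]`` records the true
    eigenvalues of ``A`` and ``meta["propagator"]`` the matrix itself.
    """
    n = fix.A.shape[0]
    states = np.empty((n, fix.n_snapshots))
    states[:, 0] = fix.x1
    for k in range(1, fix.n_snapshots):
        states[:, k] = fix.A @ states[:, k - 1]
    return SnapshotSet(
        kind="fluid",
        values=_embed_state(states),
        dt=1.0,
        meta={
            "spectrum": np.linalg.eigvals(fix.A),
            "propagator": fix.A.copy(),
            "state_dim": n,
        },
    )


def random_linear_fixture(
    n: int,
    seed: int,
    n_snapshots: int | None = None,
    magnitude_range: tuple[float, float] = (0.85, 1.0),
    min_separation: float = 0.08,
) -> LinearFixture:
    """Random well-conditioned propagator with a mixed real/complex
    spectrum of known closed form.

    Built as ``A = Q D Q^T`` with ``Q`` a random orthogonal matrix and
    ``D`` block-diagonal: 2x2 scaled-rotation blocks (complex-conjugate
    eigenpairs) plus real eigenvalues, all with magnitude inside
    ``magnitude_range`` so that no mode decays below numerical
    significance over the rollout.  Eigenvalues are rejection-sampled to
    keep a pairwise separation of ``min_separation`` in the complex
    plane — clustered spectra make the snapshot matrix (a
    Vandermonde-like structure in the eigenvalues) too ill-conditioned
    for tight oracle comparisons.
    """
    rng = np.random.default_rng(seed)
    lo, hi = magnitude_range
    blocks: list[np.ndarray] = []
    spectrum: list[complex] = []

    def separated(*candidates: complex) -> bool:
        return all(
            abs(c - e) >= min_separation for c in candidates for e in spectrum
        )

    # real eigenvalues live on two short axis segments and crowd out
    # quickly; cap their count and give the rest to conjugate pairs
    n_real = n % 2 + 2 * int(rng.integers(0, 2)) if n >= 2 else 1
    plan = ["real"] * n_real + ["pair"] * ((n - n_real) // 2)
    rng.shuffle(plan)
    for kind in plan:
        for _ in range(1000):
            rho = rng.uniform(lo, hi)
            if kind == "pair":
                phi = rng.uniform(0.1, np.pi - 0.1)
                pair = (rho * np.exp(1j * phi), rho * np.exp(-1j * phi))
                if separated(*pair):
                    c, s = np.cos(phi), np.sin(phi)
                    blocks.append(rho * np.array([[c, -s], [s, c]]))
                    spectrum.extend(pair)
                    break
            else:
                lam = rho * rng.choice([-1.0, 1.0])
                if separated(lam):
                    blocks.append(np.array([[lam]]))
                    spectrum.append(lam)
                    break
        else:
            raise ConfigurationError(
                f"could not place {n} eigenvalues with separation {min_separation}"
            )
    D = np.zeros((n, n))
    i = 0
    for b in blocks:
        k = b.shape[0]
        D[i : i + k, i : i + k] = b
        i += k
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    A = Q @ D @ Q.T
    x1 = rng.standard_normal(n)
    return LinearFixture(A=A, x1=x1, n_snapshots=n_snapshots or max(2 * n, n + 6))
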