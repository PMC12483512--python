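"""Overdamped Langevin search of the TF chain for its DBD target.

The ``n_tilde``-site bead-spring TF diffuses inside a reflecting sphere of
radius ``R``.  A straight antenna along z through the centre carries the
absorbing DBD target (capture radius ``a``) at the origin and IDR targets
at spacing ``d`` out to length ``L``; every site feels a Gaussian well of
depth ``E_B`` and width ``w_d`` at every target.  Near the antenna the
chain evolves by per-site Euler-Maruyama steps with an adaptive time step
and WCA excluded volume between sites; far from it (beyond
``far_threshold``) the TF translates as a rigid body with centre-of-mass
diffusion coefficient ``D/n_tilde``.  A search ends when the DBD site
first enters the capture radius.

Units: bp, k_BT and t0 = bp^2/D with the single-site D = 1.

The module exposes both a jitted production path (:func:`run_search`,
:func:`estimate_mfpt`) and pure-numpy building blocks
(:func:`total_force`, :func:`adaptive_dt`, :func:`step_near`,
:func:`step_far`) that support batched states and are used for the
integrator audits (force = -grad U, free-diffusion MSD, Boltzmann
occupancy of a single well).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "FirstPassageRecord",
    "MFPTEstimate",
    "antenna_targets",
    "sample_initial_state",
    "total_force",
    "adaptive_dt",
    "step_near",
    "step_far",
    "run_search",
    "estimate_mfpt",
    "point_searcher_reference",
]


def antenna_targets(L: float, d: float) -> np.ndarray:
    """Target positions on the antenna: DBD at the origin, IDR targets at
    z = +-d, +-2d, ... while |z| <= L/2."""
    n_side = int(math.floor(L / 2.0 / d + 1e-12))
    z = [0.0]
    for k in range(1, n_side + 1):
        z.extend([k * d, -k * d])
    tgt = np.zeros((len(z), 3))
    tgt[:, 2] = z
    return tgt


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one search setup (lengths bp, energies k_BT)."""

    R: float = 60.0
    a: float = 1.0
    d: float = 5.0
    L: float = 20.0
    l0: float = 5.0
    n_tilde: int = 4
    E_B: float = 7.0
    w_d: float = 1.0
    sigma: float = 1.0
    far_threshold: float = 10.0
    dt_base: float = 0.01
    max_time: Optional[float] = None
    sample_dt: float = 0.0
    max_samples: int = 2_000_000
    init_mode: str = "bulk"  # bulk | attached
    absorb: bool = True
    use_wca: bool = True

    def __post_init__(self) -> None:
        if not (self.a < self.d < self.L < 2.0 * self.R):
            raise ValueError("need a < d < L < 2R")
        if self.far_threshold <= self.w_d:
            raise ValueError("far_threshold must exceed w_d")
        for name in ("R", "a", "d", "L", "l0", "w_d", "sigma", "dt_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_tilde < 1:
            raise ValueError("n_tilde must be >= 1")
        if self.init_mode not in ("bulk", "attached"):
            raise ValueError("init_mode must be 'bulk' or 'attached'")

    @property
    def targets(self) -> np.ndarray:
        return antenna_targets(self.L, self.d)

    @property
    def spring_k(self) -> float:
        return 3.0 / self.l0**2

    @property
    def tau_relax(self) -> float:
        """Rouse relaxation estimate n_tilde^2 l0^2 / D (t0)."""
        return self.n_tilde**2 * self.l0**2

    def predicted_search_time(self, alpha: float = 0.5, beta: float = 14.5) -> float:
        """Semi-analytic total-time estimate used to size max_time."""
        r_p = math.sqrt(self.n_tilde / 6.0) * self.l0
        l_eff = max(self.L, math.e * r_p)
        t3 = alpha * self.n_tilde * self.R**3 / l_eff * math.log(l_eff / r_p)
        t1 = beta * l_eff**2
        # a chain with no antenna targets is a plain point-like searcher
        t_point = self.n_tilde * self.R**3 / (3.0 * self.a)
        return min(t3 + t1, t_point) + t1

    def resolved_max_time(self) -> float:
        if self.max_time is not None:
            return self.max_time
        return 50.0 * self.predicted_search_time()


@dataclass
class FirstPassageRecord:
    """Outcome of one search run."""

    t_total: float
    t_3d: float  # time of first antenna attachment (-1 if never attached)
    n_rounds: int
    time_attached: float
    terminated: str  # "success" | "max_time"
    seed: int
    config: SimulationConfig
    sample_times: Optional[np.ndarray] = None
    site_target_dist: Optional[np.ndarray] = None  # (n_samples, n_tilde)
    axial_position_series: Optional[np.ndarray] = None  # COM z per sample
    attached_series: Optional[np.ndarray] = None
    n_force_caps: int = 0

    @property
    def t_1d(self) -> float:
        """Time spent attached to the antenna (octopusing walk)."""
        return self.time_attached

    @property
    def t_3d_total(self) -> float:
        """Total time diffusing in 3D (everything not attached)."""
        return self.t_total - self.time_attached

    def bound_count_series(self, capture_radius: Optional[float] = None) -> np.ndarray:
        if self.site_target_dist is None:
            raise ValueError("run was recorded without series (sample_dt == 0)")
        rc = 2.0 * self.config.w_d if capture_radius is None else capture_radius
        return (self.site_target_dist < rc).sum(axis=1)


# ---------------------------------------------------------------------------
# pure-numpy building blocks (batched over leading axes)
# ---------------------------------------------------------------------------


def sample_initial_state(
    config: SimulationConfig, rng: np.random.Generator, size: Optional[int] = None
) -> np.ndarray:
    """Equilibrium chain conformation at a uniform position in the sphere.

    The chain centre of mass is uniform in the sphere; bond vectors are
    i.i.d. Gaussian with <b^2> = l0^2; any draw with a site outside the
    sphere is rejected and redrawn.  With ``init_mode='attached'`` the
    chain is laid along the antenna instead, one site per nearest target
    region, to start the 1D walk directly.
    """
    n = config.n_tilde
    single = size is None
    m = 1 if single else size
    out = np.empty((m, n, 3))
    if config.init_mode == "attached":
        z0 = np.linspace(0.0, (n - 1) * config.l0, n)
        for b in range(m):
            out[b, :, 0] = 0.0
            out[b, :, 1] = 0.0
            out[b, :, 2] = z0 - z0.mean()
            out[b] += 0.1 * rng.standard_normal((n, 3))
        return out[0] if single else out
    sig_b = config.l0 / math.sqrt(3.0)
    for b in range(m):
        while True:
            while True:
                com = (2.0 * rng.random(3) - 1.0) * config.R
                if np.dot(com, com) <= config.R**2:
                    break
            bonds = sig_b * rng.standard_normal((n - 1, 3)) if n > 1 else np.zeros((0, 3))
            pos = np.concatenate([np.zeros((1, 3)), np.cumsum(bonds, axis=0)])
            pos += com - pos.mean(axis=0)
            if np.all(np.linalg.norm(pos, axis=1) <= config.R):
                out[b] = pos
                break
    return out[0] if single else out


def total_force(positions: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """-grad U for springs + Gaussian wells + WCA (batched, analytic)."""
    pos = np.asarray(positions, dtype=float)
    squeeze = pos.ndim == 2
    if squeeze:
        pos = pos[None]
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    f = np.zeros_like(pos)
    k = config.spring_k
    if config.n_tilde > 1:
        dr = pos[:, 1:] - pos[:, :-1]
        f[:, :-1] += k * dr
        f[:, 1:] -= k * dr
    tgt = config.targets
    w2 = config.w_d**2
    dv = pos[:, :, None, :] - tgt[None, None, :, :]  # (B, n, m, 3)
    r2 = np.sum(dv * dv, axis=-1)
    g = config.E_B * np.exp(-r2 / (2.0 * w2)) / w2
    f -= np.sum(g[..., None] * dv, axis=2)
    if config.use_wca and config.n_tilde > 1:
        dij = pos[:, :, None, :] - pos[:, None, :, :]
        r2ij = np.sum(dij * dij, axis=-1)
        np.einsum("bii->bi", r2ij)[:] = np.inf  # no self-interaction
        tiny = r2ij < 1e-12
        r2ij = np.where(tiny, 1e-12, r2ij)
        mask = r2ij < config.sigma**2
        rij = np.sqrt(np.where(mask, r2ij, 1.0))
        s2 = np.where(mask, config.sigma**2 / r2ij, 0.0)
        s6 = s2**3
        coef = np.where(mask, 12.0 * (s6 * s6 - s6) / r2ij, 0.0)
        over = np.abs(coef) * rij > 1.0e3
        coef = np.where(over, 1.0e3 / rij, coef)
        f += np.sum(coef[..., None] * dij, axis=2)
    return f[0] if squeeze else f


def potential_energy(positions: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """U_total (springs + wells + WCA), batched; used by the force audit."""
    pos = np.asarray(positions, dtype=float)
    squeeze = pos.ndim == 2
    if squeeze:
        pos = pos[None]
    u = np.zeros(pos.shape[0])
    if config.n_tilde > 1:
        dr = pos[:, 1:] - pos[:, :-1]
        u += 0.5 * config.spring_k * np.sum(dr * dr, axis=(1, 2))
    tgt = config.targets
    dv = pos[:, :, None, :] - tgt[None, None, :, :]
    r2 = np.sum(dv * dv, axis=-1)
    u -= config.E_B * np.sum(np.exp(-r2 / (2.0 * config.w_d**2)), axis=(1, 2))
    if config.use_wca and config.n_tilde > 1:
        dij = pos[:, :, None, :] - pos[:, None, :, :]
        r2ij = np.sum(dij * dij, axis=-1)
        iu = np.triu_indices(config.n_tilde, 1)
        r2ij = r2ij[:, iu[0], iu[1]]
        mask = r2ij < config.sigma**2
        s2 = np.where(mask, config.sigma**2 / np.maximum(r2ij, 1e-12), 0.0)
        s6 = s2**3
        u += np.sum(np.where(mask, s6 * s6 - 2.0 * s6 + 1.0, 0.0), axis=1)
    return u[0] if squeeze else u


def adaptive_dt(forces: np.ndarray, config: SimulationConfig):
    """Near-field adaptive step dt = dt_base * min(1, k_BT / (max|f| bp))."""
    f = np.asarray(forces, dtype=float)
    squeeze = f.ndim == 2
    if squeeze:
        f = f[None]
    fmax = np.max(np.linalg.norm(f, axis=-1), axis=-1)
    dt = config.dt_base * np.minimum(1.0, 1.0 / np.maximum(fmax, 1.0))
    return float(dt[0]) if squeeze else dt


def _reflect(pos: np.ndarray, R: float) -> np.ndarray:
    r = np.linalg.norm(pos, axis=-1)
    out = np.where(r > R)
    if len(out[0]):
        scale = np.clip((2.0 * R - r[out]) / r[out], 0.0, None)
        pos[out] *= scale[..., None]
    return pos


def step_near(state: np.ndarray, config: SimulationConfig, rng: np.random.Generator):
    """One near-field Euler-Maruyama update (batched). Returns (state, dt)."""
    pos = np.array(state, dtype=float)
    squeeze = pos.ndim == 2
    if squeeze:
        pos = pos[None]
    f = total_force(pos, config)
    dt = np.asarray(adaptive_dt(f, config))
    if dt.ndim == 0:
        dt = np.full(pos.shape[0], float(dt))
    noise = rng.standard_normal(pos.shape)
    pos += f * dt[:, None, None] + np.sqrt(2.0 * dt)[:, None, None] * noise
    _reflect(pos, config.R)
    return (pos[0], float(dt[0])) if squeeze else (pos, dt)


def step_far(state: np.ndarray, config: SimulationConfig, rng: np.random.Generator):
    """One rigid-body far-field update (batched). Returns (state, dt)."""
    pos = np.array(state, dtype=float)
    squeeze = pos.ndim == 2
    if squeeze:
        pos = pos[None]
    d_com = 1.0 / config.n_tilde
    dt = (config.far_threshold / 5.0) ** 2 / (6.0 * d_com)
    disp = math.sqrt(2.0 * d_com * dt) * rng.standard_normal((pos.shape[0], 3))
    com = pos.mean(axis=1)
    r_ext = np.max(np.linalg.norm(pos - com[:, None, :], axis=-1), axis=-1)
    r_eff = np.maximum(config.R - r_ext, config.far_threshold)
    new_com = com + disp
    rn = np.linalg.norm(new_com, axis=-1)
    out = rn > r_eff
    if np.any(out):
        scale = np.clip((2.0 * r_eff[out] - rn[out]) / rn[out], 0.0, None)
        new_com[out] *= scale[:, None]
    pos += (new_com - com)[:, None, :]
    return (pos[0], dt) if squeeze else (pos, dt)


# ---------------------------------------------------------------------------
# production path (jitted)
# ---------------------------------------------------------------------------


def run_search(config: SimulationConfig, rng=None, seed: Optional[int] = None):
    """Run one first-passage search and return a :class:`FirstPassageRecord`.

    ``seed`` (or ``config`` + a default seed of 0) fixes both the initial
    state and the noise; identical seeds give bit-identical records.
    """
    from ._kernels import search_kernel

    if seed is None:
        seed = 0 if rng is None else int(rng.integers(0, 2**31 - 1))
    init_rng = np.random.default_rng(seed)
    kernel_seed = int(init_rng.integers(0, 2**31 - 1))
    pos = sample_initial_state(config, init_rng)
    max_time = config.resolved_max_time()
    max_samples = 0
    if config.sample_dt > 0:
        max_samples = min(
            int(max_time / config.sample_dt) + 2, config.max_samples
        )
    (
        t,
        first_attach,
        n_rounds,
        time_attached,
        terminated,
        n_samples,
        samp_sitedist,
        samp_comz,
        samp_att,
        n_caps,
    ) = search_kernel(
        np.ascontiguousarray(pos),
        np.ascontiguousarray(np.sort(config.targets[:, 2])),
        float(config.d),
        float(config.R),
        float(config.a),
        float(config.L),
        float(config.l0),
        float(config.E_B),
        float(config.w_d),
        float(config.sigma),
        float(config.far_threshold),
        float(config.dt_base),
        float(max_time),
        float(config.tau_relax),
        float(config.sample_dt),
        int(max_samples),
        int(kernel_seed),
        bool(config.absorb),
        bool(config.use_wca),
    )
    rec = FirstPassageRecord(
        t_total=float(t),
        t_3d=float(first_attach),
        n_rounds=int(n_rounds),
        time_attached=float(time_attached),
        terminated="success" if terminated == 0 else "max_time",
        seed=seed,
        config=config,
        n_force_caps=int(n_caps),
    )
    if config.sample_dt > 0:
        rec.sample_times = np.arange(n_samples) * config.sample_dt
        rec.site_target_dist = np.array(samp_sitedist[:n_samples])
        rec.axial_position_series = np.array(samp_comz[:n_samples])
        rec.attached_series = np.array(samp_att[:n_samples], dtype=bool)
    return rec


@dataclass
class MFPTEstimate:
    """Mean first-passage time over independent seeded runs."""

    mean: float
    se: float
    times: np.ndarray
    records: List[FirstPassageRecord]
    n_censored: int
    config: SimulationConfig

    @property
    def censored_fraction(self) -> float:
        n = len(self.times) + self.n_censored
        return self.n_censored / n if n else 0.0

    def summary(self) -> str:
        lines = [
            f"MFPT over {len(self.times)} successful runs "
            f"({self.n_censored} censored): {self.mean:.4g} +- {self.se:.2g} t0",
        ]
        if self.censored_fraction > 0.10:
            lines.append(
                "WARNING: more than 10% of runs hit max_time; the mean is "
                "biased low"
            )
        return "\n".join(lines)


def estimate_mfpt(
    config: SimulationConfig, n_runs: int, seed: int, keep_records: bool = True
) -> MFPTEstimate:
    """Average ``n_runs`` independent searches (seeds spawned from ``seed``)."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31 - 1)
    times = []
    records = []
    n_censored = 0
    for i in range(n_runs):
        rec = run_search(config, seed=int(child_seeds[i]))
        if rec.terminated == "success" or not config.absorb:
            # without an absorber the run duration is max_time by design,
            # not a censored first passage
            times.append(rec.t_total)
            if keep_records:
                records.append(rec)
        else:
            n_censored += 1
    times = np.asarray(times)
    mean = float(times.mean()) if len(times) else math.nan
    se = float(times.std(ddof=1) / math.sqrt(len(times))) if len(times) > 1 else math.nan
    return MFPTEstimate(
        mean=mean,
        se=se,
        times=times,
        records=records,
        n_censored=n_censored,
        config=config,
    )


def point_searcher_reference(
    R: float,
    absorber: str = "sphere",
    a: float = 0.5,
    L: float = 100.0,
    r_p: float = 4.0,
    n_runs: int = 400,
    seed: int = 0,
    step_frac: float = 0.1,
    max_time: Optional[float] = None,
):
    """MFPT of a single diffusing point to a central absorber.

    ``absorber='sphere'``: absorbing sphere radius ``a`` (the simple-TF
    baseline, analytically R^3/(3 D a) for a << R).  ``absorber='antenna'``:
    absorbing cylinder of length ``L`` and capture radius ``r_p`` (the thin
    prolate-spheroid capture problem, MFPT ~ alpha R^3 ln(L/r_p)/(D L) with
    alpha = 2/3).  Distance-adaptive stepping, uniform start, reflecting
    sphere.  Returns (mean, se, times).
    """
    from ._kernels import point_mfpt_kernel

    mode = {"sphere": 0, "antenna": 1}[absorber]
    if max_time is None:
        max_time = 1e4 * R**3 / (3.0 * max(a, 1e-6)) if mode == 0 else 1e4 * R**2
    kseed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    times = point_mfpt_kernel(
        float(R), mode, float(a), float(L), float(r_p), float(step_frac),
        int(n_runs), float(max_time), kseed,
    )
    mean = float(times.mean())
    se = float(times.std(ddof=1) / math.sqrt(len(times)))
    return mean, se, times
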