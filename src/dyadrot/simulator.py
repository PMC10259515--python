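"""Monte Carlo Metropolis model of a two-cell rotation on a circle.

Each sibling is a particle on a circle of fixed radius, its angle
against the anteroposterior (+x) axis being the only degree of freedom.
The cells repel through the repulsive r^-12 term of a Lennard-Jones
potential evaluated on circular distance (soft-sphere exclusion: the
pair stays in contact, so the interaction distance d spans the whole
domain, 180 deg) and each cell is attracted by one Gaussian well.  The
energy is

    H = rho * (d / dist(th1, th2))**12
        - active * (omega1 * exp(-dist(th1, mu1)**2 / (2 sigma**2))
                    + omega2 * exp(-dist(th2, mu2)**2 / (2 sigma**2)))

Sampling follows a Metropolis-Hastings scheme on a 0.25-degree lattice:
one cell at a time proposes a one-lattice-step move clockwise or
anti-clockwise, accepted with probability min(1, exp(-beta dH)).  The
attractor wells are switched off during an initial breaking time.

Two canonical configurations mirror the biology: the *asymmetric* model
places the wells at opposite poles of the A-P axis (each cell is pulled
to the side opposite its birth position) and the *symmetric* model
places both wells on the same side, so the cells compete for it.

The inverse temperature beta, the well width sigma and the repulsion
strength rho are free model parameters; the defaults here were fixed
once by the calibration sweep in ``scripts/calibrate_sim.py`` so that a
single particle is captured by its well well inside the step budget
and ensemble medians of the final-axis readouts are stable across
seeds, and they are recorded in every run manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import trajectory as traj
from .config import RunConfig

__all__ = [
    "SimConfig",
    "SimState",
    "SimTrajectory",
    "circular_distance",
    "repulsion_energy",
    "well_energy",
    "hamiltonian",
    "metropolis_step",
    "run_simulation",
    "run_ensemble",
    "run_single_particle",
    "boltzmann_lattice_density",
    "make_asymmetric_config",
    "make_symmetric_config",
    "relative_well_depth",
    "sweep_replicates",
    "sim_pair_record",
]

#: reference well depth used throughout the model comparisons
REFERENCE_DEPTH = 50.0


@dataclass
class SimConfig:
    """Model parameters; angles in degrees, energies dimensionless."""

    rho: float = 1.0  # repulsion strength
    omega1: float = REFERENCE_DEPTH  # well depths (>= 0)
    omega2: float = 0.0
    mu1: float = 0.0  # well centers
    mu2: float = 180.0
    sigma: float = 140.0  # well width
    d_int: float = 180.0  # max interaction distance
    step_deg: float = 0.25  # lattice interval
    beta: float = 0.25  # inverse temperature
    n_steps: int = 1_000_000
    breaking_steps: int = 10_000  # wells off before this step
    init_mean: float = 180.0  # initial pair-axis angle distribution
    init_sd: float = 50.0
    init_mode: str = "axis"  # "axis": diametrically opposed pair; "independent"
    record_every: int = 4_000  # frame-recording stride
    radius_um: float = 4.0  # circle radius for Cartesian readouts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_deg <= 0 or self.sigma <= 0:
            raise ValueError("step_deg and sigma must be > 0")
        if not 0 < self.d_int <= 180:
            raise ValueError("d_int must lie in (0, 180]")
        if not self.n_steps > self.breaking_steps >= 0:
            raise ValueError("need n_steps > breaking_steps >= 0")
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("well depths are nonnegative")
        if self.init_mode not in ("axis", "independent"):
            raise ValueError("init_mode must be 'axis' or 'independent'")

    def snap(self, theta) -> np.ndarray | float:
        """Snap angles to the step lattice on [0, 360)."""
        out = (np.round(np.asarray(theta, dtype=float) / self.step_deg) * self.step_deg) % 360.0
        return out if np.ndim(theta) else float(out)


def circular_distance(a, b):
    """Shortest angular separation in [0, 180] degrees."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    out = np.minimum(d, 360.0 - d)
    return out if (np.ndim(a) or np.ndim(b)) else float(out)


def repulsion_energy(theta1, theta2, config: SimConfig):
    """Soft-sphere repulsion (d / dist)**12; infinite at coincidence."""
    dist = circular_distance(theta1, theta2)
    with np.errstate(divide="ignore", over="ignore"):
        out = np.where(dist > 0, (config.d_int / np.maximum(dist, 1e-300)) ** 12, np.inf)
    return out if np.ndim(dist) else float(out)


def well_energy(theta, mu, sigma):
    """Gaussian attractor well, minimum -1 at theta = mu."""
    d = circular_distance(theta, mu)
    out = -np.exp(-(d**2) / (2.0 * sigma**2))
    return out if np.ndim(out) else float(out)


def hamiltonian(theta1, theta2, config: SimConfig, wells_active: bool = True):
    """Total energy; the wells contribute only once switched on."""
    h = config.rho * repulsion_energy(theta1, theta2, config)
    if wells_active:
        h = h + config.omega1 * well_energy(theta1, config.mu1, config.sigma)
        h = h + config.omega2 * well_energy(theta2, config.mu2, config.sigma)
    return h


@dataclass
class SimState:
    theta1: float
    theta2: float
    energy: float
    wells_active: bool = True
    accepted: bool = True


def metropolis_step(state: SimState, config: SimConfig, rng: np.random.Generator) -> SimState:
    """One update: pick a cell uniformly, propose +-one lattice step,
    accept with probability min(1, exp(-beta dH)); rejected proposals
    leave the cell in place."""
    which = int(rng.integers(0, 2))
    direction = 1.0 if rng.integers(0, 2) else -1.0
    t1, t2 = state.theta1, state.theta2
    if which == 0:
        t1 = (t1 + direction * config.step_deg) % 360.0
    else:
        t2 = (t2 + direction * config.step_deg) % 360.0
    new_e = hamiltonian(t1, t2, config, state.wells_active)
    de = new_e - state.energy
    if de <= 0 or rng.random() < math.exp(-config.beta * min(de, 700.0 / max(config.beta, 1e-12))):
        return SimState(t1, t2, new_e, state.wells_active, accepted=True)
    return replace(state, accepted=False)


@dataclass
class SimTrajectory:
    """Recorded frames of one simulation replicate."""

    config: SimConfig
    steps: np.ndarray  # recorded step indices
    theta1: np.ndarray
    theta2: np.ndarray
    energy: np.ndarray
    acceptance_rate: float

    @property
    def final_angle_deviation(self) -> float:
        """First-quadrant deviation of the final inter-cell axis (deg)."""
        return final_axis_deviation(self.theta1[-1], self.theta2[-1])

    def pair_record(self, frame_interval_s: float = 200.0) -> "traj.CellPairRecord":
        return sim_pair_record(self, frame_interval_s)


def final_axis_deviation(theta1, theta2):
    """Fold the chord direction between the two circle positions into
    [0, 90] against the A-P axis."""
    t1 = np.radians(np.asarray(theta1, dtype=float))
    t2 = np.radians(np.asarray(theta2, dtype=float))
    vx = np.cos(t2) - np.cos(t1)
    vy = np.sin(t2) - np.sin(t1)
    out = np.degrees(np.arctan2(np.abs(vy), np.abs(vx)))
    return out if np.ndim(out) else float(out)


def _initial_angles(config: SimConfig, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    if config.init_mode == "axis":
        phi = rng.normal(config.init_mean, config.init_sd, size=n)
        t1 = config.snap(phi)
        t2 = (t1 + 180.0) % 360.0
    else:
        t1 = config.snap(rng.normal(config.init_mean, config.init_sd, size=n))
        t2 = config.snap(rng.normal(config.init_mean, config.init_sd, size=n))
        # avoid coincident starts on the lattice
        t2 = np.where(t1 == t2, (t2 + config.step_deg) % 360.0, t2)
    return t1, t2


def run_simulation(config: SimConfig, record_every: int | None = None) -> SimTrajectory:
    """Run one replicate; identical seeds give bit-identical trajectories."""
    out = run_ensemble(config, n_reps=1, seed=config.seed, record_every=record_every)
    return SimTrajectory(
        config=config,
        steps=out["steps"],
        theta1=out["theta1"][0],
        theta2=out["theta2"][0],
        energy=out["energy"][0],
        acceptance_rate=float(out["acceptance_rate"][0]),
    )


def _ensemble_block(t1, t2, which, direction, uni, params, active0, active1, accepted,
                    rec1, rec2, rec_e, frame_base, stride, frame_offset):
    """Advance all replicates through one block of steps (numpy fallback).

    ``active0``/``active1`` bracket the wells-on switch inside the block.
    """
    rho, omega1, omega2, mu1, mu2, sig2, d_int, step_deg, beta, breaking = params
    nb, n_reps = which.shape

    def rep_energy(a, b):
        d = np.abs(a - b) % 360.0
        d = np.minimum(d, 360.0 - d)
        with np.errstate(divide="ignore"):
            return np.where(d > 0, rho * (d_int / np.maximum(d, 1e-300)) ** 12, np.inf)

    def well(theta, mu, omega):
        d = np.abs(theta - mu) % 360.0
        d = np.minimum(d, 360.0 - d)
        return -omega * np.exp(-(d * d) / sig2)

    active = active0
    rep_e = rep_energy(t1, t2)
    w1 = well(t1, mu1, omega1) if active else np.zeros_like(t1)
    w2 = well(t2, mu2, omega2) if active else np.zeros_like(t2)
    frame_idx = frame_offset
    for i in range(nb):
        global_step = frame_base + i
        if not active and global_step >= breaking:
            active = True
            w1 = well(t1, mu1, omega1)
            w2 = well(t2, mu2, omega2)
        move = direction[i] * step_deg
        first = which[i] == 0
        p = np.where(first, t1 + move, t2 + move) % 360.0
        other = np.where(first, t2, t1)
        new_rep = rep_energy(p, other)
        if active:
            new_w = np.where(first, well(p, mu1, omega1), well(p, mu2, omega2))
            old_w = np.where(first, w1, w2)
        else:
            new_w = old_w = 0.0
        de = (new_rep - rep_e) + (new_w - old_w)
        with np.errstate(over="ignore", invalid="ignore"):
            acc = (de <= 0) | (uni[i] < np.exp(-beta * np.where(np.isfinite(de), de, np.inf)))
        upd1 = first & acc
        upd2 = (~first) & acc
        t1 = np.where(upd1, p, t1)
        t2 = np.where(upd2, p, t2)
        rep_e = np.where(acc, new_rep, rep_e)
        if active:
            w1 = np.where(upd1, new_w, w1)
            w2 = np.where(upd2, new_w, w2)
        accepted += acc
        if (global_step + 1) % stride == 0:
            rec1[:, frame_idx] = t1
            rec2[:, frame_idx] = t2
            rec_e[:, frame_idx] = rep_e + w1 + w2
            frame_idx += 1
    return t1, t2, frame_idx


try:  # compiled kernel: same update rule, scalar loops
    import numba

    @numba.njit(cache=True)
    def _ensemble_block_nb(t1, t2, which, direction, uni, params, accepted,
                           rec1, rec2, rec_e, frame_base, stride, frame_offset):
        rho, omega1, omega2, mu1, mu2, sig2, d_int, step_deg, beta, breaking = (
            params[0], params[1], params[2], params[3], params[4],
            params[5], params[6], params[7], params[8], params[9],
        )
        nb, n_reps = which.shape
        frame_idx = frame_offset
        for i in range(nb):
            global_step = frame_base + i
            active = global_step >= breaking
            for r in range(n_reps):
                a, b = t1[r], t2[r]
                if which[i, r] == 0:
                    p = (a + direction[i, r] * step_deg) % 360.0
                    q = b
                    mu, om = mu1, omega1
                    old = a
                else:
                    p = (b + direction[i, r] * step_deg) % 360.0
                    q = a
                    mu, om = mu2, omega2
                    old = b
                d_old = abs(old - q) % 360.0
                if d_old > 180.0:
                    d_old = 360.0 - d_old
                d_new = abs(p - q) % 360.0
                if d_new > 180.0:
                    d_new = 360.0 - d_new
                if d_new <= 0.0:
                    continue  # overlap proposal: infinite energy, rejected
                de = rho * ((d_int / d_new) ** 12 - (d_int / d_old) ** 12)
                if active and om > 0.0:
                    dm_old = abs(old - mu) % 360.0
                    if dm_old > 180.0:
                        dm_old = 360.0 - dm_old
                    dm_new = abs(p - mu) % 360.0
                    if dm_new > 180.0:
                        dm_new = 360.0 - dm_new
                    de += om * (
                        np.exp(-(dm_old * dm_old) / sig2) - np.exp(-(dm_new * dm_new) / sig2)
                    )
                if de <= 0.0 or uni[i, r] < np.exp(-beta * de):
                    if which[i, r] == 0:
                        t1[r] = p
                    else:
                        t2[r] = p
                    accepted[r] += 1.0
            if (global_step + 1) % stride == 0:
                for r in range(n_reps):
                    a, b = t1[r], t2[r]
                    d = abs(a - b) % 360.0
                    if d > 180.0:
                        d = 360.0 - d
                    e = rho * (d_int / d) ** 12 if d > 0 else np.inf
                    if active:
                        d1 = abs(a - mu1) % 360.0
                        if d1 > 180.0:
                            d1 = 360.0 - d1
                        d2 = abs(b - mu2) % 360.0
                        if d2 > 180.0:
                            d2 = 360.0 - d2
                        e += -omega1 * np.exp(-(d1 * d1) / sig2) - omega2 * np.exp(
                            -(d2 * d2) / sig2
                        )
                    rec1[r, frame_idx] = a
                    rec2[r, frame_idx] = b
                    rec_e[r, frame_idx] = e
                frame_idx += 1
        return frame_idx

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def run_ensemble(
    config: SimConfig,
    n_reps: int,
    seed: int | None = None,
    record_every: int | None = None,
) -> dict:
    """Ensemble of independent replicates of the same model.

    Returns recorded frames ``theta1``/``theta2`` of shape
    (n_reps, n_frames), per-frame total energy, per-replicate acceptance
    rates, and the recorded step indices.  The update rule is identical
    with and without the compiled kernel; results depend only on the
    seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    stride = int(record_every or config.record_every)
    n_steps = int(config.n_steps)
    rec_steps = np.arange(0, n_steps + 1, stride)
    t1, t2 = _initial_angles(config, rng, n_reps)
    t1, t2 = t1.astype(float), t2.astype(float)

    n_frames = len(rec_steps)
    rec1 = np.empty((n_reps, n_frames))
    rec2 = np.empty((n_reps, n_frames))
    rec_e = np.empty((n_reps, n_frames))
    accepted = np.zeros(n_reps)
    active0 = config.breaking_steps == 0
    rec1[:, 0] = t1
    rec2[:, 0] = t2
    rec_e[:, 0] = hamiltonian(t1, t2, config, active0)

    params = np.array(
        [
            config.rho,
            config.omega1,
            config.omega2,
            config.mu1,
            config.mu2,
            2.0 * config.sigma**2,
            config.d_int,
            config.step_deg,
            config.beta,
            float(config.breaking_steps),
        ]
    )
    block = 50_000
    step = 0
    frame_idx = 1
    while step < n_steps:
        nb = min(block, n_steps - step)
        which = rng.integers(0, 2, size=(nb, n_reps)).astype(np.int8)
        direction = (rng.integers(0, 2, size=(nb, n_reps)) * 2.0 - 1.0)
        uni = rng.random(size=(nb, n_reps))
        if _HAVE_NUMBA:
            frame_idx = _ensemble_block_nb(
                t1, t2, which, direction, uni, params, accepted,
                rec1, rec2, rec_e, step, stride, frame_idx,
            )
        else:
            a0 = step >= config.breaking_steps or active0
            a1 = step + nb > config.breaking_steps or active0
            t1, t2, frame_idx = _ensemble_block(
                t1, t2, which, direction, uni, params, a0, a1, accepted,
                rec1, rec2, rec_e, step, stride, frame_idx,
            )
        step += nb

    return {
        "steps": rec_steps,
        "theta1": rec1,
        "theta2": rec2,
        "energy": rec_e,
        "acceptance_rate": accepted / n_steps,
        "final_theta1": t1.copy(),
        "final_theta2": t2.copy(),
    }


def run_single_particle(
    omega: float,
    mu: float,
    sigma: float,
    beta: float,
    n_steps: int,
    n_walkers: int = 1,
    step_deg: float = 0.25,
    burn_in: int = 0,
    seed: int = 0,
    init: float | None = None,
) -> np.ndarray:
    """Metropolis chain of one particle in one Gaussian well.

    Returns the post-burn-in positions, shape (n_walkers, n_steps).
    Used for detailed-balance checks and for calibrating beta.
    """
    rng = np.random.default_rng(seed)
    theta = np.full(n_walkers, (mu if init is None else init) % 360.0)
    theta = (np.round(theta / step_deg) * step_deg) % 360.0
    sig2 = 2.0 * sigma**2

    def energy(t):
        d = circular_distance(t, mu)
        return -omega * np.exp(-(d**2) / sig2)

    e = energy(theta)
    total = burn_in + n_steps
    out = np.empty((n_walkers, n_steps))
    direction = rng.integers(0, 2, size=(total, n_walkers)) * 2.0 - 1.0
    uni = rng.random(size=(total, n_walkers))
    for i in range(total):
        prop = (theta + direction[i] * step_deg) % 360.0
        pe = energy(prop)
        de = pe - e
        acc = (de <= 0) | (uni[i] < np.exp(-beta * de))
        theta = np.where(acc, prop, theta)
        e = np.where(acc, pe, e)
        if i >= burn_in:
            out[:, i - burn_in] = theta
    return out


def boltzmann_lattice_density(
    omega: float, mu: float, sigma: float, beta: float, step_deg: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized Boltzmann weights exp(-beta omega V) on the lattice."""
    lattice = np.arange(0.0, 360.0, step_deg)
    w = np.exp(-beta * omega * well_energy(lattice, mu, sigma))
    return lattice, w / w.sum()


def relative_well_depth(config: SimConfig) -> float:
    """Ratio of the shallower to the deeper well depth."""
    hi = max(config.omega1, config.omega2)
    if hi == 0:
        return 0.0
    return min(config.omega1, config.omega2) / hi


def make_asymmetric_config(**overrides) -> SimConfig:
    """Wells at opposite poles of the A-P axis (relative depth 0 by
    default: only one cell is actively pulled; the other follows through
    the exclusion)."""
    defaults = dict(omega1=REFERENCE_DEPTH, omega2=0.0, mu1=0.0, mu2=180.0)
    defaults.update(overrides)
    return SimConfig(**defaults)


def make_symmetric_config(**overrides) -> SimConfig:
    """Both wells on the same side (same center): the cells compete.
    Default depths 50 and 20 (relative depth 0.4)."""
    defaults = dict(omega1=REFERENCE_DEPTH, omega2=20.0, mu1=180.0, mu2=180.0)
    defaults.update(overrides)
    return SimConfig(**defaults)


def sim_pair_record(
    trajectory: SimTrajectory, frame_interval_s: float = 200.0
) -> "traj.CellPairRecord":
    """Convert recorded frames to Cartesian sibling tracks so that the
    empirical pipeline (angle series, logistic fit, noise) applies."""
    r = trajectory.config.radius_um
    t1 = np.radians(trajectory.theta1)
    t2 = np.radians(trajectory.theta2)
    xy1 = r * np.column_stack([np.cos(t1), np.sin(t1)])
    xy2 = r * np.column_stack([np.cos(t2), np.sin(t2)])
    frames = np.arange(len(trajectory.steps))
    return traj.CellPairRecord(
        pair_id=f"sim-{trajectory.config.seed}",
        genotype="synthetic",
        frames=frames,
        times_min=frames * frame_interval_s / 60.0,
        xy1=xy1,
        xy2=xy2,
    )


def _ensemble_readouts(out: dict, config: SimConfig, run_config: RunConfig) -> pd.DataFrame:
    """Final-axis deviation and trajectory noise per replicate."""
    n_reps = out["theta1"].shape[0]
    rows = []
    r = config.radius_um
    for i in range(n_reps):
        t1 = np.radians(out["theta1"][i])
        t2 = np.radians(out["theta2"][i])
        pair = traj.CellPairRecord(
            pair_id=f"rep{i}",
            genotype="synthetic",
            frames=np.arange(len(out["steps"])),
            times_min=np.arange(len(out["steps"]), dtype=float),
            xy1=r * np.column_stack([np.cos(t1), np.sin(t1)]),
            xy2=r * np.column_stack([np.cos(t2), np.sin(t2)]),
        )
        noise = traj.trajectory_noise(traj.center_pair(pair), run_config)
        rows.append(
            {
                "replicate": i,
                "final_angle_deviation": final_axis_deviation(
                    out["final_theta1"][i], out["final_theta2"][i]
                ),
                "noise": noise.value,
                "noise_excluded": noise.excluded,
            }
        )
    return pd.DataFrame(rows)


def sweep_replicates(
    template: SimConfig,
    n_reps: int,
    depth_ratios,
    models=("asymmetric", "symmetric"),
    seed: int = 0,
    run_config: RunConfig | None = None,
) -> pd.DataFrame:
    """Replicate sweep over model type and relative well depth.

    The deeper (reference) well is fixed at 50; the second well's depth
    is ``ratio * 50``.  For each condition the distribution of final
    first-quadrant axis deviations and of trajectory noise (both
    computed with the empirical pipeline on the recorded frames) is
    summarized over ``n_reps`` independently seeded replicates.
    """
    run_config = run_config or RunConfig()
    rows = []
    factories = {"asymmetric": make_asymmetric_config, "symmetric": make_symmetric_config}
    base = {
        f: getattr(template, f)
        for f in ("rho", "sigma", "d_int", "step_deg", "beta", "n_steps",
                  "breaking_steps", "init_mean", "init_sd", "init_mode",
                  "record_every", "radius_um")
    }
    for m, model in enumerate(models):
        for k, ratio in enumerate(depth_ratios):
            cfg = factories[model](
                **base, omega2=float(ratio) * REFERENCE_DEPTH, seed=seed
            )
            sub_seed = (seed + 7919 * m + 104729 * k) % (2**31 - 1)
            out = run_ensemble(cfg, n_reps=n_reps, seed=sub_seed)
            reads = _ensemble_readouts(out, cfg, run_config)
            ok_noise = reads.loc[~reads["noise_excluded"], "noise"]
            rows.append(
                {
                    "model": model,
                    "relative_well_depth": float(ratio),
                    "n_reps": n_reps,
                    "median_final_angle": float(reads["final_angle_deviation"].median()),
                    "q1_final_angle": float(reads["final_angle_deviation"].quantile(0.25)),
                    "q3_final_angle": float(reads["final_angle_deviation"].quantile(0.75)),
                    "median_noise": float(ok_noise.median()) if len(ok_noise) else np.nan,
                    "n_noise_excluded": int(reads["noise_excluded"].sum()),
                }
            )
    return pd.DataFrame(rows)
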