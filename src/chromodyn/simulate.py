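"""Ground-truth trajectory generators for validating the estimators.

Motion models
-------------
``brownian``
    Independent Gaussian increments, variance ``2 D dt`` per axis.
``fbm``
    Fractional Brownian motion with exact-covariance fractional Gaussian
    increments (Davies-Harte circulant embedding, Cholesky fallback for
    short paths), Hurst ``H = alpha / 2``; the per-axis one-step increment
    variance is ``2 D dt`` so the lag-l MSD is ``2 dim D dt l**alpha``.
    ``D`` is therefore the *apparent* (lag-1) diffusion coefficient.
``confined_ou``
    Ornstein-Uhlenbeck motion around a fixed centre, parameterized by the
    stationary positional SD per axis and the relaxation time (exact
    discretization).
``directed``
    Brownian motion plus a constant velocity.
``switching``
    Continuous-time Markov chain over sub-specs with exponential holding
    times; each frame carries its ground-truth state label.

Localization noise is added per frame (optionally z-anisotropic);
photobleaching truncates tracks by a geometric draw; a detection-gap
probability (optionally displacement-dependent, emulating motion-blur loss
of fast molecules) splits tracks the way a frame-to-frame linker would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ScenarioError, SpecError
from .trajio import Trajectory

SCENARIOS = ("stage1_20ms", "stage2_500ms", "timelapse", "locus2d")


@dataclass
class MotionSpec:
    kind: str
    d: float = 1.0  # µm²/s (apparent, lag-1)
    alpha: float = 1.0  # anomalous exponent, (0, 2]
    confinement_sd: float = 0.05  # µm, OU stationary SD per axis
    relax_time: float = 0.1  # s, OU relaxation time
    velocity: np.ndarray | None = None  # µm/s, for 'directed'
    switch_rates: np.ndarray | None = None  # (k, k) transition rates, s^-1
    states: list["MotionSpec"] | None = None  # sub-specs for 'switching'
    label: str = ""
    dim: int = 3
    dt: float = 0.02
    n_frames: int = 100

    def __post_init__(self) -> None:
        if self.kind not in ("brownian", "fbm", "confined_ou", "directed", "switching"):
            raise SpecError(f"unknown motion kind {self.kind!r}")
        if not (0 < self.alpha <= 2):
            raise SpecError("alpha must be in (0, 2]")
        if self.dt <= 0:
            raise SpecError("dt must be > 0")
        if self.kind == "switching":
            if not self.states or self.switch_rates is None:
                raise SpecError("switching needs states and switch_rates")
            if np.any(np.asarray(self.switch_rates) < 0):
                raise SpecError("rates must be >= 0")
            dims = {s.dim for s in self.states}
            if dims != {self.dim}:
                raise SpecError(f"inconsistent dims among sub-specs: {dims}")


@dataclass
class NoiseSpec:
    loc_sd: float | np.ndarray = 0.0  # µm; scalar or per-axis (z-anisotropic)
    bleach_rate: float = 0.0  # per exposure; survival exp(-rate)
    gap_p: float = 0.0  # per-frame detection-gap probability
    gap_blur_threshold: float = np.inf  # µm; gaps apply above this step size

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.loc_sd) < 0):
            raise SpecError("localization SD must be >= 0")
        if not (0 <= self.gap_p <= 1):
            raise SpecError("gap probability must be in [0, 1]")


def fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Standard fractional Gaussian noise (unit one-step variance).

    Exact covariance via Davies-Harte circulant embedding; falls back to a
    Cholesky factorization when the embedding is not nonnegative-definite
    (short paths / extreme Hurst values).
    """
    if hurst == 0.5:
        return rng.standard_normal(n)
    k = np.arange(n + 1)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma[: n + 1], gamma[n - 1 : 0 : -1]])
    m = len(row)  # 2n
    ev = np.fft.fft(row).real
    if np.min(ev) >= -1e-8 * np.max(ev):
        ev = np.clip(ev, 0.0, None)
        # Hermitian-symmetric complex Gaussian spectrum
        v = np.empty(m, dtype=complex)
        v[0] = np.sqrt(ev[0] / m) * rng.standard_normal()
        v[n] = np.sqrt(ev[n] / m) * rng.standard_normal()
        half = np.arange(1, n)
        re = rng.standard_normal(n - 1)
        im = rng.standard_normal(n - 1)
        v[half] = np.sqrt(ev[half] / (2 * m)) * (re + 1j * im)
        v[m - half] = np.conj(v[half])
        return np.fft.fft(v).real[:n]
    # Cholesky fallback on the exact Toeplitz covariance
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    cov = gamma[idx]
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return L @ rng.standard_normal(n)


def _increments(spec: MotionSpec, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Per-axis displacement increments, shape (n_steps, dim)."""
    sd = np.sqrt(2.0 * spec.d * spec.dt)
    if spec.kind == "brownian":
        return rng.standard_normal((n_steps, spec.dim)) * sd
    if spec.kind == "directed":
        v = np.asarray(spec.velocity, dtype=float)
        if v.shape != (spec.dim,):
            raise SpecError("velocity must match dim")
        return rng.standard_normal((n_steps, spec.dim)) * sd + v * spec.dt
    if spec.kind == "fbm":
        h = spec.alpha / 2.0
        return np.column_stack([fgn(n_steps, h, rng) * sd for _ in range(spec.dim)])
    raise SpecError(spec.kind)  # pragma: no cover


def _simulate_positions(
    spec: MotionSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """True positions (n_frames, dim) and per-frame state labels."""
    n = spec.n_frames
    if spec.kind == "confined_ou":
        a = np.exp(-spec.dt / spec.relax_time)
        s = spec.confinement_sd
        x = np.empty((n, spec.dim))
        x[0] = rng.standard_normal(spec.dim) * s  # stationary start
        noise_sd = s * np.sqrt(1 - a * a)
        eps = rng.standard_normal((n - 1, spec.dim)) * noise_sd
        for t in range(1, n):
            x[t] = a * x[t - 1] + eps[t - 1]
        labels = np.full(n, spec.label or spec.kind, dtype=object)
        return x, labels
    if spec.kind == "switching":
        return _simulate_switching(spec, rng)
    inc = _increments(spec, n - 1, rng)
    x = np.vstack([np.zeros(spec.dim), np.cumsum(inc, axis=0)])
    labels = np.full(n, spec.label or spec.kind, dtype=object)
    return x, labels


def _simulate_switching(
    spec: MotionSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    q = np.asarray(spec.switch_rates, dtype=float)
    k = len(spec.states)
    if q.shape != (k, k):
        raise SpecError("switch_rates must be (k, k) for k states")
    exit_rates = q.sum(axis=1) - np.diag(q)
    state = int(rng.integers(k))
    n = spec.n_frames
    t_total = (n - 1) * spec.dt
    # continuous-time state path, then sampled onto the frame grid
    times, states_seq = [0.0], [state]
    t = 0.0
    while True:
        r = exit_rates[state]
        if r <= 0:
            break
        t += rng.exponential(1.0 / r)
        if t >= t_total:
            break
        p = q[state].copy()
        p[state] = 0.0
        p = p / p.sum()
        state = int(rng.choice(k, p=p))
        times.append(t)
        states_seq.append(state)
    frame_t = np.arange(n) * spec.dt
    seg = np.searchsorted(times, frame_t, side="right") - 1
    frame_state = np.asarray(states_seq, dtype=int)[seg]

    # the increment of step t -> t+1 follows the state at time t*dt; runs of
    # equal-state steps share exact within-run covariance (fBM memory resets
    # at switches)
    step_state = frame_state[:-1]
    inc = np.empty((n - 1, spec.dim))
    i = 0
    while i < n - 1:
        j = i
        while j < n - 1 and step_state[j] == step_state[i]:
            j += 1
        sub = spec.states[step_state[i]]
        run = j - i
        if sub.kind == "confined_ou":
            # molecule binds where it is: OU relative to the run-entry point
            a = np.exp(-spec.dt / sub.relax_time)
            noise_sd = sub.confinement_sd * np.sqrt(1 - a * a)
            y = np.zeros((run + 1, spec.dim))
            eps = rng.standard_normal((run, spec.dim)) * noise_sd
            for tt in range(1, run + 1):
                y[tt] = a * y[tt - 1] + eps[tt - 1]
            inc[i:j] = np.diff(y, axis=0)
        else:
            sub_spec = MotionSpec(
                kind=sub.kind, d=sub.d, alpha=sub.alpha, velocity=sub.velocity,
                label=sub.label, dim=spec.dim, dt=spec.dt, n_frames=run + 1,
            )
            inc[i:j] = _increments(sub_spec, run, rng)
        i = j
    x = np.vstack([np.zeros(spec.dim), np.cumsum(inc, axis=0)])
    names = np.asarray(
        [s.label or f"state{ix}" for ix, s in enumerate(spec.states)], dtype=object
    )
    return x, names[frame_state]


def simulate(
    motion: MotionSpec,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator = 0,
    traj_id: str = "sim0",
) -> list[tuple[Trajectory, np.ndarray]]:
    """Simulate one molecule; returns [(trajectory, frame labels), ...].

    Usually a single element; detection gaps split the track into the
    consecutive-frame segments a linker would recover (segments shorter
    than two frames are dropped, as in real linking).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = noise or NoiseSpec()
    x, labels = _simulate_positions(motion, rng)
    n = len(x)

    if noise.bleach_rate > 0:
        p_surv = np.exp(-noise.bleach_rate)
        n_obs = int(rng.geometric(1.0 - p_surv))
        n = min(n, n_obs)
        x, labels = x[:n], labels[:n]
    if n < 2:
        return []

    obs = x + rng.standard_normal(x.shape) * np.broadcast_to(
        np.asarray(noise.loc_sd, dtype=float), (motion.dim,)
    )

    keep = np.ones(n, dtype=bool)
    if noise.gap_p > 0:
        if np.isfinite(noise.gap_blur_threshold):
            # motion-blur emulation: only frames preceded by a large true
            # displacement risk being lost
            step = np.linalg.norm(np.diff(x, axis=0), axis=1)
            risky = np.concatenate([[False], step > noise.gap_blur_threshold])
            p_gap = np.where(risky, noise.gap_p, 0.0)
        else:
            p_gap = np.full(n, noise.gap_p)
            p_gap[0] = 0.0
        keep = rng.random(n) >= p_gap

    out: list[tuple[Trajectory, np.ndarray]] = []
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        return out
    splits = np.split(idx, np.flatnonzero(np.diff(idx) != 1) + 1)
    for si, seg in enumerate(splits):
        if len(seg) < 2:
            continue
        out.append(
            (
                Trajectory(
                    id=f"{traj_id}" if len(splits) == 1 else f"{traj_id}.{si}",
                    dt=motion.dt,
                    frames=np.arange(seg[0], seg[0] + len(seg)),
                    xyz=obs[seg],
                ),
                labels[seg],
            )
        )
    return out


# ---------------------------------------------------------------------------
# benchmark scenarios
# ---------------------------------------------------------------------------

@dataclass
class Benchmark:
    """A labelled synthetic dataset emulating one imaging regime."""

    scenario: str
    dt: float
    dim: int
    trajectories: list[Trajectory]
    labels: dict[str, np.ndarray]  # traj id -> per-frame true state
    truth: dict = field(default_factory=dict)


# imaging-regime constants: localization precision (µm) of the 20 ms and
# 500 ms experiments, and the 2-state / 3-state mobility scales
LOC_SD_20MS = 0.060
LOC_SD_500MS = 0.034
STAGE1_PARAMS = {
    "free": dict(kind="brownian", d=1.3, alpha=1.0),
    "bound": dict(kind="fbm", d=0.43, alpha=0.5),
}
STAGE1_BOUND_FRACTION = 0.55
STAGE2_PARAMS = {
    "S": dict(kind="fbm", d=0.006, alpha=0.59),
    "F1": dict(kind="fbm", d=0.018, alpha=0.60),
    "F2": dict(kind="fbm", d=0.018, alpha=0.89, drift_speed=0.2),
}
STAGE2_PROPORTIONS = {"S": 0.67, "F1": 0.26, "F2": 0.07}
TIMELAPSE_TAUS = (0.5, 2.5, 8.0, 32.0)


def make_benchmark_suite(
    scenario: str,
    seed: int = 0,
    n_tracks: int = 500,
    n_frames: int = 31,
) -> Benchmark:
    """Deterministic labelled datasets for end-to-end validation.

    ``stage1_20ms``: 20 ms exposure mixture of freely diffusing
    (Brownian, D_app 1.3 µm²/s) and chromatin-bound (fBM, alpha 0.5,
    D_app 0.43 µm²/s) molecules with 60 nm localization noise.

    ``stage2_500ms``: 500 ms exposure chromatin-bound molecules in three
    substates -- S (alpha 0.59, D_app 0.006), F1 (alpha 0.60, D_app 0.018)
    and F2 (alpha 0.89, D_app 0.018 plus 0.02 µm/s directed drift) at
    proportions 0.67 / 0.26 / 0.07 -- with 34 nm noise.

    ``timelapse``: geometric track lengths over the lapse ladder
    {0.5, 2.5, 8, 32} s.

    ``locus2d``: 2D enhancer-locus tracks with the stage-2 substate mix.
    """
    if scenario not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {scenario!r}; options: {SCENARIOS}")
    rng = np.random.default_rng(seed)
    if scenario == "stage1_20ms":
        return _stage1(rng, n_tracks, n_frames)
    if scenario == "stage2_500ms":
        return _stage2(rng, n_tracks, n_frames, dim=3)
    if scenario == "locus2d":
        return _stage2(rng, n_tracks, n_frames, dim=2, name="locus2d")
    # timelapse: track-length-only benchmark
    from .kinetics import simulate_timelapse

    truth = dict(k_off=0.01, k_bleach=0.5, t_int=0.5)
    conds = simulate_timelapse(
        truth["k_off"], truth["k_bleach"], truth["t_int"],
        list(TIMELAPSE_TAUS), n_tracks, seed=int(rng.integers(2**31)),
    )
    return Benchmark(
        scenario="timelapse", dt=0.5, dim=3, trajectories=[], labels={},
        truth={**truth, "conditions": conds},
    )


def _stage1(rng: np.random.Generator, n_tracks: int, n_frames: int) -> Benchmark:
    dt = 0.02
    noise = NoiseSpec(loc_sd=LOC_SD_20MS)
    trajs, labels = [], {}
    n_bound = int(round(STAGE1_BOUND_FRACTION * n_tracks))
    kinds = ["bound"] * n_bound + ["free"] * (n_tracks - n_bound)
    for i, k in enumerate(kinds):
        p = STAGE1_PARAMS[k]
        spec = MotionSpec(
            kind=p["kind"], d=p["d"], alpha=p["alpha"],
            label="confined" if k == "bound" else "unconfined",
            dim=3, dt=dt, n_frames=n_frames,
        )
        for t, lab in simulate(spec, noise, rng, traj_id=f"s1_{i:04d}"):
            trajs.append(t)
            labels[t.id] = lab
    return Benchmark(
        "stage1_20ms", dt, 3, trajs, labels,
        truth=dict(params=STAGE1_PARAMS, bound_fraction=STAGE1_BOUND_FRACTION),
    )


def _stage2(
    rng: np.random.Generator, n_tracks: int, n_frames: int, dim: int = 3,
    name: str = "stage2_500ms",
) -> Benchmark:
    dt = 0.5
    noise = NoiseSpec(loc_sd=LOC_SD_500MS)
    states = list(STAGE2_PROPORTIONS)
    probs = np.array([STAGE2_PROPORTIONS[s] for s in states])
    counts = np.floor(probs * n_tracks).astype(int)
    counts[0] += n_tracks - counts.sum()  # exact proportions up to rounding
    trajs, labels = [], {}
    i = 0
    for s_name, cnt in zip(states, counts):
        p = STAGE2_PARAMS[s_name]
        for _ in range(cnt):
            vel = None
            kind = p["kind"]
            if "drift_speed" in p:
                u = rng.standard_normal(dim)
                vel = p["drift_speed"] * u / np.linalg.norm(u)
                kind = "fbm"
            spec = MotionSpec(
                kind=kind, d=p["d"], alpha=p["alpha"], label=s_name,
                dim=dim, dt=dt, n_frames=n_frames,
            )
            for t, lab in simulate(spec, noise, rng, traj_id=f"s2_{i:04d}"):
                if vel is not None:
                    t.xyz = t.xyz + np.outer(np.arange(t.n) * dt, vel)
                trajs.append(t)
                labels[t.id] = lab
            i += 1
    return Benchmark(
        name, dt, dim, trajs, labels,
        truth=dict(params=STAGE2_PARAMS, proportions=dict(STAGE2_PROPORTIONS)),
    )
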