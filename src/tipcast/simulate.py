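"""Ramped stochastic simulation, recovery-rate series and training sampling.

A simulation ramps one coefficient (the forcing parameter mu) linearly in
time while integrating the system with forward Euler (deterministic) or
Euler-Maruyama (white or AR(1) "red" additive noise).  The tipping label of
a noisy path is *not* its own escape point: it is the parameter value at
which the recovery rate lambda of the noise-free twin first crosses zero,
which carries the rate-induced delay past the static bifurcation.  Premature
noise-induced escapes are therefore deliberately mislabeled relative to the
realized path -- the label tracks loss of stability of the quasi-static
attractor, not the stochastic exit.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy.signal import lfilter

from . import _kernels as K
from .syslib import BifurcationRecord, PolySystem

__all__ = [
    "RampSpec",
    "NoiseSpec",
    "Trajectory",
    "SampledSeries",
    "gen_red_noise",
    "simulate_ramp",
    "recovery_rate_series",
    "locate_tipping",
    "irregular_sample",
    "make_training_set",
    "simulate_record",
]

#: training-corpus white-noise amplitude: triangular(lo, mode, hi)
TRAIN_SIGMA_TRIANGLE = (0.0075, 0.01, 0.0125)
#: default red-noise stationary amplitude (matches the white scale)
RED_STATIONARY_SD = 0.01
#: default duration (time units) of the slowest training ramp; the base
#: ramp rate of a system is |mu_static - mu0| * (1 + margin) / this.  200
#: time units (2e4 Euler steps) matches the pre-tipping segment geometry of
#: the benchmark systems' printed ramp rates.
BASE_RAMP_DURATION = 200.0
#: fraction of the ramp span simulated beyond the static bifurcation
#: (rate-delayed crossings overshoot the static value by up to ~25% of the
#: span at the fastest ratios)
TERMINAL_MARGIN = 0.5

DIVERGENCE_BOUND = 1e6


@dataclasses.dataclass(frozen=True)
class RampSpec:
    mu0: float
    rate: float
    direction: int
    mu_terminal: float

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if (self.mu_terminal - self.mu0) * self.direction <= 0:
            raise ValueError("mu_terminal must lie beyond mu0 in the ramp direction")

    @property
    def rate_signed(self) -> float:
        return self.rate * self.direction


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    kind: str = "white"  # {"white", "red", "none"}
    sigma: float = 0.01
    phi: float = 0.5
    red_stationary_sd: float = RED_STATIONARY_SD

    def __post_init__(self):
        if self.kind not in ("white", "red", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0 or self.red_stationary_sd < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not -1.0 < self.phi < 1.0:
            raise ValueError("|phi| must be < 1")


@dataclasses.dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n, dim)
    mu_values: np.ndarray
    dt: float
    noise: NoiseSpec
    ramp: RampSpec
    diverged: bool = False

    def __post_init__(self):
        n = len(self.times)
        if not (len(self.states) == len(self.mu_values) == n):
            raise ValueError("times/states/mu_values must have equal lengths")


@dataclasses.dataclass
class SampledSeries:
    times: np.ndarray
    values: np.ndarray
    mu_values: np.ndarray
    mu_c: float
    bif_type: str = ""
    noise_kind: str = "white"
    rate: float = 0.0
    system_id: str = ""
    seeds: dict = dataclasses.field(default_factory=dict)

    @property
    def relative_distance(self) -> float:
        mu0, mu_end = self.mu_values[0], self.mu_values[-1]
        return (self.mu_c - mu_end) / (mu_end - mu0)


def gen_red_noise(phi: float, stationary_sd: float, n: int,
                  rng_seed) -> np.ndarray:
    """AR(1) series eta_{t+1} = phi eta_t + innovation, innovation sd
    = stationary_sd * sqrt(1 - phi^2), eta_0 from the stationary law."""
    if not -1.0 < phi < 1.0:
        raise ValueError("|phi| must be < 1")
    if stationary_sd < 0:
        raise ValueError("stationary_sd must be >= 0")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    e = np.empty(n)
    e[0] = rng.normal(0.0, stationary_sd)
    e[1:] = rng.normal(0.0, stationary_sd * np.sqrt(1.0 - phi * phi), n - 1)
    return lfilter([1.0], [1.0, -phi], e)


def draw_noise_increments(noise: NoiseSpec, dim: int, n: int, dt: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-step additive increments, shape (dim, n).

    white: sigma * sqrt(dt) * N(0,1); red: per-coordinate AR(1) stream with
    stationary sd = red_stationary_sd * sqrt(dt); none: zeros.
    """
    if noise.kind == "none" or n == 0:
        return np.zeros((dim, n))
    if noise.kind == "white":
        return noise.sigma * np.sqrt(dt) * rng.standard_normal((dim, n))
    sd = noise.red_stationary_sd * np.sqrt(dt)
    return np.vstack([gen_red_noise(noise.phi, sd, n, rng) for _ in range(dim)])


def simulate_ramp(field: Callable, x0: Sequence[float], ramp: RampSpec,
                  noise: NoiseSpec, dt: float = 0.01, burn_in: float = 100.0,
                  rng_seed=0, divergence_bound: float = DIVERGENCE_BOUND
                  ) -> Trajectory:
    """Euler / Euler-Maruyama integration under a linear parameter ramp.

    ``field(state, mu) -> array`` is an arbitrary Python callable (the heavy
    internal paths use compiled kernels instead).  mu is held at ramp.mu0
    during the burn-in (noise applied, portion discarded), then ramps
    linearly until ramp.mu_terminal.  Divergence (state norm beyond the
    bound) truncates the trajectory and sets ``diverged``.
    """
    x0 = np.asarray(x0, float)
    if not np.isfinite(x0).all():
        raise ValueError("x0 must be finite")
    dim = x0.size
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    n_burn = int(round(burn_in / dt))
    n_ramp = int(np.ceil((ramp.mu_terminal - ramp.mu0) / (ramp.rate_signed * dt)))
    incr = draw_noise_increments(noise, dim, n_burn + n_ramp, dt, rng)

    s = x0.copy()
    for j in range(n_burn):
        s = s + np.asarray(field(s, ramp.mu0), float) * dt + incr[:, j]

    states = np.empty((n_ramp, dim))
    mus = np.empty(n_ramp)
    mu = ramp.mu0
    diverged = False
    done = 0
    for i in range(n_ramp):
        s = s + np.asarray(field(s, mu), float) * dt + incr[:, n_burn + i]
        mu = ramp.mu0 + ramp.rate_signed * dt * (i + 1)
        states[i] = s
        mus[i] = mu
        done = i + 1
        if not np.isfinite(s).all() or np.abs(s).max() > divergence_bound:
            diverged = True
            break
    times = dt * np.arange(1, done + 1)
    return Trajectory(times=times, states=states[:done], mu_values=mus[:done],
                      dt=dt, noise=noise, ramp=ramp, diverged=diverged)


def recovery_rate_series(jacobian_fn: Callable, traj: Trajectory,
                         stride: int = 1) -> np.ndarray:
    """lambda_i = max real part of eigvals(jacobian_fn(state_i, mu_i)) for
    every ``stride``-th retained step; truncates at the first non-finite
    state."""
    lams = []
    for s, mu in zip(traj.states[::stride], traj.mu_values[::stride]):
        if not np.isfinite(s).all():
            break
        J = np.atleast_2d(np.asarray(jacobian_fn(s, mu), float))
        lams.append(np.linalg.eigvals(J).real.max())
    return np.asarray(lams)


def locate_tipping(lambda_series, mu_series):
    """Parameter value at the first negative-to-nonnegative crossing of
    lambda, linearly interpolated; None if lambda never crosses."""
    lam = np.asarray(lambda_series, float)
    mu = np.asarray(mu_series, float)
    if lam.size == 0 or mu.size == 0:
        raise ValueError("empty input")
    if lam.size != mu.size:
        raise ValueError("lambda and mu series must have equal lengths")
    neg = lam < 0
    pos = lam >= 0
    idx = np.nonzero(neg[:-1] & pos[1:])[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    if lam[i + 1] == lam[i]:
        return float(mu[i + 1])
    w = (0.0 - lam[i]) / (lam[i + 1] - lam[i])
    return float(mu[i] + w * (mu[i + 1] - mu[i]))


# -- irregular sampling ------------------------------------------------------

LS_RANGE = (505, 1000)          # inclusive integer range of ls
N_KEEP = 500                    # points kept per instance
REL_DIST_RANGE = (0.01, 2.0)    # allowed (mu_c - mu_end) / (mu_end - mu_0)


def _sample_indices(n_pre: int, rng: np.random.Generator) -> np.ndarray:
    ls = int(rng.integers(LS_RANGE[0], LS_RANGE[1] + 1))
    idx = np.sort(rng.choice(n_pre, size=ls, replace=False))
    return idx[:N_KEEP]


def irregular_sample_arrays(times, values, mu_values, mu_c, direction,
                            rng, max_tries: int = 200, meta=None
                            ) -> SampledSeries | None:
    """Core of :func:`irregular_sample` operating on plain arrays."""
    pre = (mu_values - mu_c) * direction < 0
    n_pre = int(np.count_nonzero(pre))
    if n_pre < LS_RANGE[1]:
        raise ValueError(
            f"pre-tipping segment has {n_pre} < {LS_RANGE[1]} points; "
            "simulate with a denser grid or slower ramp")
    t = times[:n_pre]
    v = values[:n_pre]
    m = mu_values[:n_pre]
    for _ in range(max_tries):
        idx = _sample_indices(n_pre, rng)
        mu_end = m[idx[-1]]
        mu0 = m[idx[0]]
        rel = (mu_c - mu_end) / (mu_end - mu0)
        if REL_DIST_RANGE[0] <= rel <= REL_DIST_RANGE[1]:
            meta = meta or {}
            return SampledSeries(times=t[idx], values=v[idx], mu_values=m[idx],
                                 mu_c=float(mu_c), **meta)
    return None


def irregular_sample(traj: Trajectory, mu_c: float, observed_index: int,
                     rng_seed) -> SampledSeries:
    """Draw ls ~ U{505..1000} strictly increasing sample times from the
    pre-tipping segment, keep the first 500, and resample until the relative
    distance of the tipping point lies in [0.01, 2]."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    out = irregular_sample_arrays(
        traj.times, traj.states[:, observed_index], traj.mu_values, mu_c,
        traj.ramp.direction, rng,
        meta={"noise_kind": traj.noise.kind, "rate": traj.ramp.rate})
    if out is None:
        raise RuntimeError("could not satisfy the relative-distance window")
    return out


# -- training-set assembly ---------------------------------------------------

def _training_noise(rng: np.random.Generator, kind: str) -> NoiseSpec:
    if kind == "white":
        lo, mode, hi = TRAIN_SIGMA_TRIANGLE
        return NoiseSpec(kind="white", sigma=float(rng.triangular(lo, mode, hi)))
    phi = float(rng.uniform(-1.0, 1.0))
    return NoiseSpec(kind="red", phi=phi, red_stationary_sd=RED_STATIONARY_SD)


def simulate_record(system: PolySystem, record: BifurcationRecord,
                    rate: float, noise: NoiseSpec, rng: np.random.Generator,
                    dt: float = 0.01, burn_in: float = 100.0,
                    lam_stride: int = 5) -> SampledSeries | None:
    """One labeled training instance from a (system, bifurcation) record.

    Runs the noise-free twin to locate the rate-delayed tipping point mu_c
    (lambda crossing along the trajectory), then the noisy path up to mu_c,
    and irregularly samples it.  Returns None when no crossing is found or
    the sampler cannot satisfy the relative-distance window (discards).
    """
    c = system.coeffs
    mu0 = c[record.varied_index]
    direction = record.direction
    span = abs(record.mu_static - mu0)
    if span <= 0:
        return None
    mu_term = record.mu_static + direction * TERMINAL_MARGIN * span
    x0, y0 = record_start_state(system, record)
    if K.poly_lambda(system.a_coeffs, system.b_coeffs, x0, y0) >= 0:
        return None  # starting state is not on a stable branch
    burn_steps = int(round(burn_in / dt))

    mus, lams, status = K.ramp_poly_lambda(
        system.a_coeffs, system.b_coeffs, record.varied_index, x0, y0,
        mu0, rate * direction, mu_term, dt, lam_stride, DIVERGENCE_BOUND,
        burn_steps)
    if len(mus) < 2:
        return None
    mu_c = locate_tipping(lams, mus)
    if mu_c is None:
        return None

    n_ramp = int(np.ceil((mu_c - mu0) / (rate * direction * dt)))
    incr = draw_noise_increments(noise, 2, burn_steps + n_ramp, dt, rng)
    obs, n_done, status = K.ramp_poly_noisy(
        system.a_coeffs, system.b_coeffs, record.varied_index, x0, y0,
        mu0, rate * direction, mu_c, dt, incr, DIVERGENCE_BOUND, burn_steps)
    times = dt * np.arange(1, n_done + 1)
    mu_vals = mu0 + rate * direction * dt * np.arange(1, n_done + 1)
    try:
        return irregular_sample_arrays(
            times, obs, mu_vals, mu_c, direction, rng,
            meta={"bif_type": record.bif_type, "noise_kind": noise.kind,
                  "rate": rate, "system_id": record.system_id,
                  "seeds": {"varied_index": record.varied_index,
                            "direction": record.direction,
                            "mu_static": record.mu_static}})
    except ValueError:
        return None


def record_start_state(system: PolySystem, record: BifurcationRecord):
    """Stable-equilibrium starting state at the record's original parameter
    value, on the branch the bifurcation was detected on.

    Uses the record's stored starting equilibrium when available (Newton
    polished); otherwise falls back to re-settling from the
    bifurcation-point state."""
    if record.eq_start is not None:
        x, y, ok = K.newton_poly(system.a_coeffs, system.b_coeffs,
                                 record.eq_start.state[0],
                                 record.eq_start.state[1], 1e-10, 60)
        if ok:
            return x, y
    x, y, _ = K.settle_poly(system.a_coeffs, system.b_coeffs,
                            record.eq_at_bif.state[0],
                            record.eq_at_bif.state[1], 0.01, 5000, np.inf,
                            DIVERGENCE_BOUND)
    x, y, ok = K.newton_poly(system.a_coeffs, system.b_coeffs, x, y, 1e-10, 60)
    if not ok:
        x, y = record.eq_at_bif.state
    return x, y


def make_training_set(library, rng_seed, rates_per_system: int = 5,
                      n_instances: int | None = None,
                      base_ramp_duration: float = BASE_RAMP_DURATION,
                      noise_kinds=("white", "red"), dt: float = 0.01
                      ) -> list[SampledSeries]:
    """Labeled training instances from a bifurcation library.

    Per visit of a (system, record) pair: a base rate spanning the distance
    from the original coefficient value to the static bifurcation in
    ``base_ramp_duration`` time units, ``rates_per_system`` distinct ratio
    multipliers drawn from {1..10}, one noisy simulation (with noise-free
    twin for the label) per rate.  Simulations without a lambda crossing or
    failing the relative-distance window are discarded.  When
    ``n_instances`` is given, the library is cycled with fresh noise
    realizations until the target is met.
    """
    if not library:
        return []
    rng = np.random.default_rng(rng_seed)
    out: list[SampledSeries] = []
    target = n_instances if n_instances is not None else len(library) * rates_per_system
    guard = 0
    while len(out) < target:
        for system, record in library:
            mu0 = system.coeffs[record.varied_index]
            span = abs(record.mu_static - mu0)
            if span <= 0:
                continue
            base_rate = span * (1.0 + TERMINAL_MARGIN) / base_ramp_duration
            ratios = rng.choice(np.arange(1, 11), size=rates_per_system,
                                replace=False)
            for ratio in ratios:
                kind = noise_kinds[int(rng.integers(len(noise_kinds)))]
                noise = _training_noise(rng, kind)
                inst = simulate_record(system, record, base_rate * float(ratio),
                                       noise, rng, dt=dt)
                if inst is not None:
                    out.append(inst)
                if len(out) >= target:
                    return out
            guard += 1
        if n_instances is None:
            break
        if guard > 100 * len(library) * max(1, target):
            raise RuntimeError("training-set generation is not converging")
    return out
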