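"""The eight named benchmark systems and the evaluation protocol.

Each model carries its printed constants, ramp specification, noise kind and
an analytic Jacobian; the ground-truth tipping point of a configuration is
the parameter value at the first negative-to-positive crossing of the
recovery rate (max real part of the Jacobian eigenvalues) along the
noise-free ramped trajectory, which includes the rate-induced delay beyond
the static bifurcation.

Rate conventions.  The ecological and climate systems (five ramp rates
each) specify the parameter increment *per Euler step*; their effective
per-unit-time rates are the printed values divided by the step size.  The
two hysteresis systems specify their single rate per unit time literally.
Both conventions were validated against the models' published tipping
locations and are stored here as effective per-unit-time rates.

The ocean energy-balance model is reconstructed as
dT/dt = (-e rho T^4 + u I0 (1 - a + b T) / 4) / c with I0 = 7.1944e8, the
value (ten times the printed figure) for which a fold exists near the
published location; it and the TRIFFID model are calibration cases, not
reference targets.  TRIFFID's recovery rate uses the Jacobian of the
unfloored field, P (1 - 2V) - G, which reproduces the published negative-P
crossing; the floored variant is available behind a switch.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from numba import njit

from . import _kernels as K
from .preprocess import inference_instance, relative_error, to_regular_grid
from .simulate import (NoiseSpec, SampledSeries, draw_noise_increments,
                       locate_tipping)
from . import baselines as BL

__all__ = [
    "NamedModel",
    "EvaluationTable",
    "MODEL_NAMES",
    "get_model",
    "ground_truth_tipping",
    "generate_test_set",
    "run_benchmark",
    "hysteresis_experiment",
]

MODEL_NAMES = ("may_harvest", "food_chain3", "rosenzweig_macarthur",
               "ocean_energy_balance", "mpt_glacial", "triffid_vegetation",
               "arousal_sleepwake", "sprott_b")

DIVERGENCE_BOUND = 1e6


# ---------------------------------------------------------------------------
# vector fields and analytic Jacobians
# ---------------------------------------------------------------------------

@njit(cache=True)
def _may_field(s, mu, out):
    x = s[0]
    out[0] = x * (1.0 - x) - mu * x * x / (0.01 + x * x)


@njit(cache=True)
def _may_jac(s, mu, J):
    x = s[0]
    d = 0.01 + x * x
    J[0, 0] = 1.0 - 2.0 * x - mu * 2.0 * x * 0.01 / (d * d)


@njit(cache=True)
def _food_field(s, mu, out):
    r, c, p = s[0], s[1], s[2]
    out[0] = r * (1.0 - r / mu) - 0.4 * 2.009 * c * r / (r + 0.16129)
    out[1] = 0.4 * c * (2.009 * r / (r + 0.16129) - 1.0) \
        - 0.08 * 2.876 * p * c / (c + 0.5)
    out[2] = 0.08 * p * (2.876 * c / (c + 0.5) - 1.0)


@njit(cache=True)
def _food_jac(s, mu, J):
    r, c, p = s[0], s[1], s[2]
    xc, yc, xp, yp, r0, c0 = 0.4, 2.009, 0.08, 2.876, 0.16129, 0.5
    J[0, 0] = 1.0 - 2.0 * r / mu - xc * yc * c * r0 / ((r + r0) ** 2)
    J[0, 1] = -xc * yc * r / (r + r0)
    J[0, 2] = 0.0
    J[1, 0] = xc * c * yc * r0 / ((r + r0) ** 2)
    J[1, 1] = xc * (yc * r / (r + r0) - 1.0) - xp * yp * p * c0 / ((c + c0) ** 2)
    J[1, 2] = -xp * yp * c / (c + c0)
    J[2, 0] = 0.0
    J[2, 1] = xp * p * yp * c0 / ((c + c0) ** 2)
    J[2, 2] = xp * (yp * c / (c + c0) - 1.0)


@njit(cache=True)
def _rm_field(s, mu, out):
    # mu = attack rate a; g=4, k=1.7, e=0.5, h=0.15, m=2
    x, y = s[0], s[1]
    den = 1.0 + mu * 0.15 * x
    out[0] = 4.0 * x * (1.0 - x / 1.7) - mu * x * y / den
    out[1] = 0.5 * mu * x * y / den - 2.0 * y


@njit(cache=True)
def _rm_jac(s, mu, J):
    x, y = s[0], s[1]
    h = 0.15
    den = 1.0 + mu * h * x
    dfr = mu * y / (den * den)          # d/dx of a x y/(1+ahx) = a y / den^2
    J[0, 0] = 4.0 * (1.0 - 2.0 * x / 1.7) - dfr
    J[0, 1] = -mu * x / den
    J[1, 0] = 0.5 * dfr
    J[1, 1] = 0.5 * mu * x / den - 2.0


def _make_ocean(i0: float):
    e, rho, c, a, b = 0.69, 0.03, 1e8, 2.8, 0.009

    @njit(cache=False)
    def field(s, mu, out):
        T = s[0]
        out[0] = (-e * rho * T ** 4 + 0.25 * mu * i0 * (1.0 - a + b * T)) / c

    @njit(cache=False)
    def jac(s, mu, J):
        T = s[0]
        J[0, 0] = (-4.0 * e * rho * T ** 3 + 0.25 * mu * i0 * b) / c

    return field, jac


@njit(cache=True)
def _mpt_field(s, mu, out):
    # p=1, q=1.2, s=0.8; mu = u
    x, y, z = s[0], s[1], s[2]
    out[0] = -x - y
    out[1] = -1.0 * z + mu * y + 0.8 * z * z - y * z * z
    out[2] = -1.2 * (x + z)


@njit(cache=True)
def _mpt_jac(s, mu, J):
    x, y, z = s[0], s[1], s[2]
    J[0, 0] = -1.0; J[0, 1] = -1.0; J[0, 2] = 0.0
    J[1, 0] = 0.0
    J[1, 1] = mu - z * z
    J[1, 2] = -1.0 + 1.6 * z - 2.0 * y * z
    J[2, 0] = -1.2; J[2, 1] = 0.0; J[2, 2] = -1.2


@njit(cache=True)
def _triffid_field(s, mu, out):
    # mu = productivity P; G = 0.004; V* = max(V, 0.1) in the growth term
    V = s[0]
    Vs = V if V >= 0.1 else 0.1
    out[0] = mu * Vs * (1.0 - V) - 0.004 * V


@njit(cache=True)
def _triffid_jac_unfloored(s, mu, J):
    V = s[0]
    J[0, 0] = mu * (1.0 - 2.0 * V) - 0.004


@njit(cache=True)
def _triffid_jac_floored(s, mu, J):
    V = s[0]
    if V >= 0.1:
        J[0, 0] = mu * (1.0 - 2.0 * V) - 0.004
    else:
        J[0, 0] = -0.1 * mu - 0.004


@njit(cache=True)
def _arousal_field(s, mu, out):
    # mu = D; Qmax=100, theta=10, sigma'=3, vmaQa=1, vvm=vmv=-1.9, tau=10
    Vv, Vm = s[0], s[1]
    Qm = 100.0 / (1.0 + np.exp(-(Vm - 10.0) / 3.0))
    Qv = 100.0 / (1.0 + np.exp(-(Vv - 10.0) / 3.0))
    out[0] = (-Vv - 1.9 * Qm + mu) / 10.0
    out[1] = (-Vm + 1.0 - 1.9 * Qv) / 10.0


@njit(cache=True)
def _arousal_jac(s, mu, J):
    Vv, Vm = s[0], s[1]
    em = np.exp(-(Vm - 10.0) / 3.0)
    ev = np.exp(-(Vv - 10.0) / 3.0)
    dQm = 100.0 * em / (3.0 * (1.0 + em) ** 2)
    dQv = 100.0 * ev / (3.0 * (1.0 + ev) ** 2)
    J[0, 0] = -0.1
    J[0, 1] = -0.19 * dQm
    J[1, 0] = -0.19 * dQv
    J[1, 1] = -0.1


@njit(cache=True)
def _sprott_field(s, mu, out):
    # mu = excitation phase k; a=8, b=2.89, beta=5
    x, y, z = s[0], s[1], s[2]
    out[0] = 8.0 * (y - x)
    out[1] = x * z + 5.0 * np.cos(mu)
    out[2] = 2.89 - x * y


@njit(cache=True)
def _sprott_jac(s, mu, J):
    x, y, z = s[0], s[1], s[2]
    J[0, 0] = -8.0; J[0, 1] = 8.0; J[0, 2] = 0.0
    J[1, 0] = z; J[1, 1] = 0.0; J[1, 2] = x
    J[2, 0] = -y; J[2, 1] = -x; J[2, 2] = 0.0


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NamedModel:
    name: str
    dimension: int
    field: object                     # jitted field(state, mu, out)
    jac: object                       # jitted jac(state, mu, J)
    fixed_params: dict
    ramp_param: str
    bif_type: str
    noise_kind: str                   # "white" or "red"
    dt: float
    observed_index: int
    directions: tuple                 # (+1,), (-1,) or (+1, -1)
    initial_values: dict              # direction -> tuple of mu starting values
    rates: dict                       # direction -> tuple of effective rates
    mu_terminal: dict                 # direction -> ramp stop value
    settle_state: dict                # direction -> ndarray initial state
    settle_time: float = 200.0

    def noise_spec(self, rng: np.random.Generator) -> NoiseSpec:
        if self.noise_kind == "white":
            return NoiseSpec(kind="white", sigma=0.01)
        return NoiseSpec(kind="red", phi=float(rng.uniform(-1.0, 1.0)),
                         red_stationary_sd=0.01)


def _per_step(rates, dt):
    """Printed per-step rates -> effective per-unit-time rates."""
    return tuple(r / dt for r in rates)


def get_model(name: str, triffid_jacobian: str = "unfloored",
              ocean_i0: float = 7.1944e8) -> NamedModel:
    dt = 0.01
    if name == "may_harvest":
        return NamedModel(
            name=name, dimension=1, field=_may_field, jac=_may_jac,
            fixed_params={"r": 1.0, "k": 1.0, "s": 0.1}, ramp_param="h",
            bif_type="fold", noise_kind="white", dt=dt, observed_index=0,
            directions=(1,),
            initial_values={1: tuple(np.round(np.linspace(0.0, 0.2, 11), 3))},
            rates={1: _per_step((1e-5, 2e-5, 3e-5, 4e-5, 5e-5), dt)},
            mu_terminal={1: 0.36}, settle_state={1: np.array([0.8])})
    if name == "food_chain3":
        return NamedModel(
            name=name, dimension=3, field=_food_field, jac=_food_jac,
            fixed_params={"xc": 0.4, "yc": 2.009, "xp": 0.08, "yp": 2.876,
                          "r0": 0.16129, "c0": 0.5}, ramp_param="k",
            bif_type="hopf", noise_kind="white", dt=dt, observed_index=0,
            directions=(1,),
            initial_values={1: tuple(np.round(np.linspace(0.20, 0.40, 11), 3))},
            rates={1: _per_step((1e-5, 2e-5, 3e-5, 4e-5, 5e-5), dt)},
            mu_terminal={1: 0.60}, settle_state={1: np.array([0.8, 0.2, 0.2])},
            settle_time=500.0)
    if name == "rosenzweig_macarthur":
        return NamedModel(
            name=name, dimension=2, field=_rm_field, jac=_rm_jac,
            fixed_params={"g": 4.0, "k": 1.7, "e": 0.5, "h": 0.15, "m": 2.0},
            ramp_param="a", bif_type="transcritical", noise_kind="white",
            dt=dt, observed_index=0, directions=(1,),
            initial_values={1: tuple(np.round(np.linspace(0.0, 5.0, 11), 2))},
            rates={1: _per_step((1e-4, 2e-4, 3e-4, 4e-4, 5e-4), dt)},
            mu_terminal={1: 7.1}, settle_state={1: np.array([1.7, 0.05])})
    if name == "ocean_energy_balance":
        field, jac = _make_ocean(ocean_i0)
        return NamedModel(
            name=name, dimension=1, field=field, jac=jac,
            fixed_params={"e": 0.69, "rho": 0.03, "I0": ocean_i0, "c": 1e8,
                          "a": 2.8, "b": 0.009}, ramp_param="u",
            bif_type="fold", noise_kind="red", dt=1.0, observed_index=0,
            directions=(-1,),
            initial_values={-1: tuple(np.round(np.linspace(1.4, 1.2, 11), 3))},
            rates={-1: (5e-7, 6e-7, 7e-7, 8e-7, 9e-7)},
            mu_terminal={-1: 0.75}, settle_state={-1: np.array([350.0])},
            settle_time=2000.0)
    if name == "mpt_glacial":
        return NamedModel(
            name=name, dimension=3, field=_mpt_field, jac=_mpt_jac,
            fixed_params={"p": 1.0, "q": 1.2, "s": 0.8}, ramp_param="u",
            bif_type="hopf", noise_kind="red", dt=dt, observed_index=0,
            directions=(1,),
            initial_values={1: tuple(np.round(np.linspace(0.0, 0.3, 11), 3))},
            rates={1: _per_step((1e-5, 2e-5, 3e-5, 4e-5, 5e-5), dt)},
            mu_terminal={1: 0.45}, settle_state={1: np.array([0.0, 0.1, 0.0])})
    if name == "triffid_vegetation":
        jac = _triffid_jac_unfloored if triffid_jacobian == "unfloored" \
            else _triffid_jac_floored
        return NamedModel(
            name=name, dimension=1, field=_triffid_field, jac=jac,
            fixed_params={"G": 0.004}, ramp_param="P",
            bif_type="transcritical", noise_kind="red", dt=dt,
            observed_index=0, directions=(-1,),
            initial_values={-1: tuple(np.round(np.linspace(0.90, 0.10, 11), 3))},
            rates={-1: _per_step((1e-5, 2e-5, 3e-5, 4e-5, 5e-5), dt)},
            mu_terminal={-1: -0.05}, settle_state={-1: np.array([0.95])})
    if name == "arousal_sleepwake":
        return NamedModel(
            name=name, dimension=2, field=_arousal_field, jac=_arousal_jac,
            fixed_params={"Qmax": 100.0, "theta": 10.0, "sigma": 3.0,
                          "vmaQa": 1.0, "vvm": -1.9, "vmv": -1.9,
                          "tau": 10.0}, ramp_param="D", bif_type="fold",
            noise_kind="white", dt=dt, observed_index=0, directions=(1, -1),
            initial_values={1: tuple(np.round(np.linspace(0.1, 1.1, 11), 2)),
                            -1: tuple(np.round(np.linspace(1.9, 0.9, 11), 2))},
            rates={1: (1.0 / 7200.0,), -1: (1.0 / 7200.0,)},
            mu_terminal={1: 1.6, -1: 0.5},
            settle_state={1: np.array([0.0, 0.0]),
                          -1: np.array([-7.0, 0.4])},
            settle_time=500.0)
    if name == "sprott_b":
        pi = np.pi
        return NamedModel(
            name=name, dimension=3, field=_sprott_field, jac=_sprott_jac,
            fixed_params={"a": 8.0, "b": 2.89, "beta": 5.0}, ramp_param="k",
            bif_type="hopf", noise_kind="white", dt=dt, observed_index=0,
            directions=(1, -1),
            initial_values={1: tuple(np.round(np.linspace(1.0, 1.4, 11), 3) * pi),
                            -1: tuple(np.round(np.linspace(2.0, 1.6, 11), 3) * pi)},
            rates={1: (pi * 1e-3,), -1: (pi * 1e-3,)},
            mu_terminal={1: 1.8 * pi, -1: 1.2 * pi},
            settle_state={1: np.array([1.7, 1.7, 2.94]),
                          -1: np.array([-1.7, -1.7, 2.94])})
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


# ---------------------------------------------------------------------------
# ground truth and test-set generation
# ---------------------------------------------------------------------------

def _settled_state(model: NamedModel, mu0: float, direction: int) -> np.ndarray:
    """Quasi-static attractor at mu0, tracked adiabatically along the
    experiment's branch.

    The state first settles at the direction's base initial parameter value,
    then (for other starting values) is carried to mu0 by a noise-free ramp
    and re-settled.  Direct settling at mu0 could land on the wrong attractor
    of a hysteretic system.
    """
    n_steps = int(round(model.settle_time / model.dt))
    base = model.initial_values[direction][0]
    s, _ = K.settle_named(model.field, model.settle_state[direction], base,
                          model.dt, n_steps, 1e-8, DIVERGENCE_BOUND)
    if mu0 != base:
        # carry at the direction's slowest experiment rate: the state at mu0
        # is then the state of the actual experiment passing through mu0
        carry_rate = min(model.rates[direction])
        s, _ = K.ramp_named_state(model.field, s, base,
                                  carry_rate * np.sign(mu0 - base), mu0,
                                  model.dt, DIVERGENCE_BOUND)
        # no re-settling here: the carried state is the quasi-static attractor
        # state of the experiment itself; relaxing it again near a fold can
        # push starts close to the bifurcation off their (narrowing) basin
    return s


def ground_truth_tipping(model: NamedModel, initial_value: float, rate: float,
                         direction: int, lam_stride: int = 5) -> float | None:
    """Noise-free ramped integration; parameter value at the first
    negative-to-positive crossing of the trajectory-evaluated recovery rate
    (linearly interpolated).  None if lambda never crosses before the
    terminal parameter value."""
    s = _settled_state(model, initial_value, direction)
    mus, lams, _ = K.ramp_named_lambda(
        model.field, model.jac, s, initial_value, rate * direction,
        model.mu_terminal[direction], model.dt, lam_stride, DIVERGENCE_BOUND, 3)
    if len(mus) < 2:
        return None
    return locate_tipping(lams, mus)


def _test_sample(times, values, mu_values, mu_c, direction, rng,
                 sampling: str, n_points_range, max_tries: int = 200):
    """Test-set sampling: ls ~ U{505..1000} points over the pre-tipping
    segment, truncated to a length drawn from ``n_points_range``; the
    resulting relative distance is constrained to [0.01, 2]."""
    pre = (mu_values - mu_c) * direction < 0
    n_pre = int(np.count_nonzero(pre))
    if n_pre < 1000:
        raise ValueError("pre-tipping segment shorter than 1000 points")
    for _ in range(max_tries):
        ls = int(rng.integers(505, 1001))
        L = int(rng.integers(n_points_range[0], n_points_range[1] + 1))
        if L > ls:
            continue
        if sampling == "irregular":
            idx = np.sort(rng.choice(n_pre, size=ls, replace=False))[:L]
        else:
            idx = np.unique(np.round(np.linspace(0, n_pre - 1, ls))
                            .astype(int))[:L]
        mu_end = mu_values[idx[-1]]
        mu0 = mu_values[idx[0]]
        rel = (mu_c - mu_end) / (mu_end - mu0)
        if 0.01 <= rel <= 2.0:
            return idx
    return None


def generate_test_set(model: NamedModel, sampling: str = "irregular",
                      n_points_range=(250, 500), replicates: int = 10,
                      rng_seed=0, direction: int = 1, initial_values=None,
                      rates=None, burn_in: float = 100.0
                      ) -> list[SampledSeries]:
    """The evaluation grid: per (initial value, rate), ``replicates`` noisy
    simulations sampled down to labeled test series.

    Every instance is tagged with the noise-free mu_c of its own
    (initial value, rate) configuration.
    """
    if sampling not in ("regular", "irregular"):
        raise ValueError("sampling must be 'regular' or 'irregular'")
    rng = np.random.default_rng(rng_seed)
    initial_values = model.initial_values[direction] \
        if initial_values is None else initial_values
    rates = model.rates[direction] if rates is None else rates
    burn_steps = int(round(burn_in / model.dt))
    out = []
    for mu0 in initial_values:
        s0 = _settled_state(model, mu0, direction)
        for rate in rates:
            mu_c = ground_truth_tipping(model, mu0, rate, direction)
            if mu_c is None:
                continue
            n_ramp = int(np.ceil(abs(mu_c - mu0) / (rate * model.dt)))
            for rep in range(replicates):
                noise = model.noise_spec(rng)
                incr = draw_noise_increments(noise, model.dimension,
                                             burn_steps + n_ramp, model.dt, rng)
                obs, nd, _ = K.ramp_named_noisy(
                    model.field, s0, mu0, rate * direction, mu_c, model.dt,
                    incr, model.observed_index, DIVERGENCE_BOUND, burn_steps)
                t = model.dt * np.arange(1, nd + 1)
                mv = mu0 + rate * direction * model.dt * np.arange(1, nd + 1)
                idx = _test_sample(t, obs, mv, mu_c, direction, rng, sampling,
                                   n_points_range)
                if idx is None:
                    continue
                out.append(SampledSeries(
                    times=t[idx], values=obs[idx], mu_values=mv[idx],
                    mu_c=float(mu_c), bif_type=model.bif_type,
                    noise_kind=noise.kind, rate=rate, system_id=model.name,
                    seeds={"initial_value": float(mu0), "rate": float(rate),
                           "replicate": rep, "direction": direction}))
    return out


# ---------------------------------------------------------------------------
# method evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvaluationTable:
    rows: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Mean epsilon with 5th/95th percentiles per
        (model, initial_value, method); missing predictions excluded."""
        g = self.rows.dropna(subset=["epsilon"]).groupby(
            ["model", "initial_value", "method"])["epsilon"]
        return g.agg(mean_eps="mean",
                     p5=lambda v: np.percentile(v, 5),
                     p95=lambda v: np.percentile(v, 95),
                     n="count").reset_index()


BASELINE_METHODS = ("degenerate_fingerprinting", "bb", "dev")
DL_METHODS = ("dl", "lstm_ablation")


def _baseline_mu_hat(method: str, series: SampledSeries,
                     window_frac: float = 0.5) -> float | None:
    n = len(series.values)
    v = to_regular_grid(series.times, series.values, n)
    m = to_regular_grid(series.times, series.mu_values, n)
    dt_reg = (series.times[-1] - series.times[0]) / (n - 1)
    step = max(1, n // 100)
    try:
        if method == "degenerate_fingerprinting":
            ind = BL.degenerate_fingerprinting(v, window_frac, mu_values=m,
                                               step=step)
        elif method == "bb":
            ind = BL.bb_lambda(v, dt_reg, window_frac, mu_values=m, step=step)
        elif method == "dev":
            ind = BL.dev_series(v, mu_values=m, window_frac=window_frac,
                                step=step)
        else:
            raise ValueError(f"unknown baseline {method!r}")
        return BL.extrapolate_crossing(ind, beyond=series.mu_values[-1]).mu_hat
    except ValueError:
        return None


def run_benchmark(methods, test_set, ensemble=None) -> EvaluationTable:
    """Evaluate methods on a test set; per instance, mu_hat and epsilon.

    ``methods``: names from {"dl", "lstm_ablation", "degenerate_fingerprinting",
    "bb", "dev"} or (name, callable) pairs where callable(series) -> mu_hat.
    ``ensemble``: a TrainedEnsemble (serves "dl") or a dict name->ensemble.
    Baseline non-predictions are recorded with epsilon = NaN.
    """
    from .predictor import predict_tipping  # local import to avoid cycle
    ens_map = {}
    if ensemble is not None:
        ens_map = dict(ensemble) if isinstance(ensemble, dict) \
            else {"dl": ensemble}
    rows = []
    for method in methods:
        if isinstance(method, tuple):
            name, fn = method
        else:
            name, fn = method, None
            if name in DL_METHODS:
                if name not in ens_map:
                    raise ValueError(f"method {name!r} needs a trained ensemble")
            elif name not in BASELINE_METHODS:
                raise ValueError(f"unknown method {name!r}")
        for s in test_set:
            if fn is not None:
                mu_hat = fn(s)
            elif name in DL_METHODS:
                inst = inference_instance(s.values, s.mu_values)
                mu_hat = predict_tipping(ens_map[name], inst)
            else:
                mu_hat = _baseline_mu_hat(name, s)
            eps = relative_error(mu_hat, s.mu_c, s.mu_values[-1]) \
                if mu_hat is not None else np.nan
            rows.append({
                "model": s.system_id,
                "initial_value": s.seeds.get("initial_value", np.nan),
                "rate": s.rate,
                "replicate": s.seeds.get("replicate", -1),
                "method": name,
                "mu_hat": mu_hat if mu_hat is not None else np.nan,
                "mu_c": s.mu_c,
                "epsilon": eps,
            })
    return EvaluationTable(rows=pd.DataFrame(rows))


def hysteresis_experiment(model: NamedModel, ensemble, rng_seed=0,
                          n_points: int = 400, burn_in: float = 100.0) -> dict:
    """Direction-resolved predictions for a hysteretic system.

    For each ramp direction and initial parameter value: one noisy
    simulation, a ``n_points``-point irregular sample, the ensemble
    prediction and its relative error against that direction's ground
    truth.  Returns per-direction mean epsilon and the min/max predicted
    tipping values.
    """
    from .predictor import predict_tipping
    if set(model.directions) != {1, -1}:
        raise ValueError("hysteresis experiment needs a two-direction model")
    rng = np.random.default_rng(rng_seed)
    out = {}
    for direction in (1, -1):
        rate = model.rates[direction][0]
        preds, errs, mu_cs = [], [], []
        for mu0 in model.initial_values[direction]:
            test = generate_test_set(
                model, sampling="irregular",
                n_points_range=(n_points, n_points), replicates=1,
                rng_seed=rng.integers(2**31 - 1), direction=direction,
                initial_values=(mu0,), rates=(rate,), burn_in=burn_in)
            if not test:
                continue
            s = test[0]
            inst = inference_instance(s.values, s.mu_values)
            mu_hat = predict_tipping(ensemble, inst)
            preds.append(mu_hat)
            mu_cs.append(s.mu_c)
            errs.append(relative_error(mu_hat, s.mu_c, s.mu_values[-1]))
        out[direction] = {
            "mean_eps": float(np.mean(errs)) if errs else np.nan,
            "pred_min": float(np.min(preds)) if preds else np.nan,
            "pred_max": float(np.max(preds)) if preds else np.nan,
            "predictions": preds,
            "ground_truths": mu_cs,
        }
    return out
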