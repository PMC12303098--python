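"""Competing early-warning estimators and indicator extrapolation.

Three sliding-window indicators anticipate a bifurcation from a regularly
sampled record:

* degenerate fingerprinting: lag-1 autocorrelation of the leading principal
  component (for a single observed variable, of the series itself), which
  approaches 1 at a bifurcation as the system's relaxation slows;
* the BB estimator: under AR(1) ("red") driving noise the observed series
  is AR(2) -- x_{t+1} = (a + phi) x_t - a phi x_{t-1} + eps -- so jointly
  fitting both roots separates the system's discrete-time multiplier a from
  the noise coefficient phi and removes the red-noise bias of the naive
  lag-1 estimate; the indicator is lambda = ln(a)/dt with critical value 0;
* DEV: locally weighted linear one-step maps fitted in a time-delay
  embedding of the observed variable; the modulus of the dominant eigenvalue
  of the fitted companion matrix approaches 1 at a bifurcation.

An indicator series is extrapolated to its critical value by both a linear
and a quadratic least-squares fit in the forcing parameter; the candidate
from the fit with the larger in-sample R^2 is selected (both are reported).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "IndicatorSeries",
    "ExtrapolationResult",
    "degenerate_fingerprinting",
    "bb_lambda",
    "dev_series",
    "extrapolate_crossing",
]

MIN_WINDOW = 30


@dataclasses.dataclass
class IndicatorSeries:
    window_centers: np.ndarray
    indicator_values: np.ndarray
    kind: str                      # {"ac1", "bb_lambda", "dev_modulus"}
    critical_value: float
    window_frac: float

    def __post_init__(self):
        if len(self.window_centers) != len(self.indicator_values):
            raise ValueError("centers and values must have equal lengths")


@dataclasses.dataclass
class ExtrapolationResult:
    mu_hat: float | None           # selected estimate (None: no crossing)
    selected: str | None           # "linear" or "quadratic"
    candidates: dict               # fit -> {"mu": float|None, "r2": float}


def _window_starts(n: int, w: int, step: int) -> np.ndarray:
    return np.arange(0, n - w + 1, step)


def _detrend_linear(x: np.ndarray) -> np.ndarray:
    t = np.arange(len(x), dtype=float)
    c = np.polyfit(t, x, 1)
    return x - np.polyval(c, t)


def _resolve_centers(mu_values, n, starts, w):
    if mu_values is None:
        mu_values = np.arange(n, dtype=float)
    mu_values = np.asarray(mu_values, float)
    return np.array([mu_values[s:s + w].mean() for s in starts])


def degenerate_fingerprinting(series_matrix, window_frac: float = 0.5,
                              mu_values=None, step: int = 1
                              ) -> IndicatorSeries:
    """Lag-1 autocorrelation of the leading principal component per window.

    ``series_matrix``: (n,) single variable or (n, k) with one column per
    variable.  Each window is linearly detrended per variable before the
    PCA projection.
    """
    X = np.asarray(series_matrix, float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    w = int(round(window_frac * n))
    if w < MIN_WINDOW:
        raise ValueError(f"window of {w} < {MIN_WINDOW} points")
    starts = _window_starts(n, w, step)
    vals = np.empty(len(starts))
    for j, s in enumerate(starts):
        Wd = np.column_stack([_detrend_linear(X[s:s + w, k])
                              for k in range(X.shape[1])])
        if X.shape[1] == 1:
            proj = Wd[:, 0]
        else:
            # leading principal component of the window
            _, _, vt = np.linalg.svd(Wd - Wd.mean(0), full_matrices=False)
            proj = Wd @ vt[0]
        v0 = proj[:-1]
        v1 = proj[1:]
        denom = v0.std() * v1.std()
        vals[j] = np.mean((v0 - v0.mean()) * (v1 - v1.mean())) / denom \
            if denom > 0 else np.nan
    centers = _resolve_centers(mu_values, n, starts, w)
    return IndicatorSeries(centers, vals, "ac1", 1.0, window_frac)


def _yule_walker_ar2(x: np.ndarray):
    x = x - x.mean()
    c0 = np.mean(x * x)
    if c0 == 0:
        return np.nan, np.nan
    r1 = np.mean(x[:-1] * x[1:]) / c0
    r2 = np.mean(x[:-2] * x[2:]) / c0
    den = 1.0 - r1 * r1
    if den <= 0:
        return np.nan, np.nan
    phi1 = r1 * (1.0 - r2) / den
    phi2 = (r2 - r1 * r1) / den
    return phi1, phi2


def bb_lambda(series, dt: float, window_frac: float = 0.5, mu_values=None,
              step: int = 1) -> IndicatorSeries:
    """Red-noise-unbiased restoring-rate estimate per sliding window.

    Fits an AR(2) by Yule-Walker on the linearly detrended window; its
    characteristic roots are the system multiplier a and the driving-noise
    coefficient phi.  The larger root is taken as the system mode (the mode
    that approaches 1 under critical slowing down) and converted to a
    continuous rate lambda = ln(a)/dt.  When sampling noise drives the
    discriminant negative (the two roots merge), the repeated root phi1/2 of
    the nearest real-rooted AR(2) is used.
    """
    x = np.asarray(series, float)
    n = len(x)
    w = int(round(window_frac * n))
    if w < MIN_WINDOW + 2:
        raise ValueError(f"window of {w} points is too short for lag-2 moments")
    starts = _window_starts(n, w, step)
    vals = np.empty(len(starts))
    for j, s in enumerate(starts):
        seg = _detrend_linear(x[s:s + w])
        phi1, phi2 = _yule_walker_ar2(seg)
        a = np.nan
        if np.isfinite(phi1):
            disc = phi1 * phi1 + 4.0 * phi2
            a = 0.5 * (phi1 + np.sqrt(disc)) if disc >= 0 else 0.5 * phi1
        vals[j] = np.log(a) / dt if np.isfinite(a) and a > 0 else np.nan
    centers = _resolve_centers(mu_values, n, starts, w)
    return IndicatorSeries(centers, vals, "bb_lambda", 0.0, window_frac)


def naive_lambda(series, dt: float, window_frac: float = 0.5, mu_values=None,
                 step: int = 1) -> IndicatorSeries:
    """Naive lag-1-autocorrelation-derived restoring rate (for comparison
    against :func:`bb_lambda`; biased under red driving noise)."""
    x = np.asarray(series, float)
    n = len(x)
    w = int(round(window_frac * n))
    starts = _window_starts(n, w, step)
    vals = np.empty(len(starts))
    for j, s in enumerate(starts):
        seg = _detrend_linear(x[s:s + w])
        c0 = np.mean(seg * seg)
        r1 = np.mean(seg[:-1] * seg[1:]) / c0 if c0 > 0 else np.nan
        vals[j] = np.log(r1) / dt if np.isfinite(r1) and r1 > 0 else np.nan
    centers = _resolve_centers(mu_values, n, starts, w)
    return IndicatorSeries(centers, vals, "bb_lambda", 0.0, window_frac)


def _delay_embed(x: np.ndarray, E: int, tau: int):
    """Rows (x_t, x_{t-tau}, ..., x_{t-(E-1)tau}) and the one-step targets."""
    n = len(x)
    t0 = (E - 1) * tau
    rows = np.column_stack([x[t0 - k * tau: n - 1 - k * tau] for k in range(E)])
    target = x[t0 + 1: n]
    return rows, target


def dev_series(series, embed_dim: int = 3, embed_lag: int = 1,
               theta: float = 0.0, window_frac: float = 0.5, mu_values=None,
               step: int = 1) -> IndicatorSeries:
    """Dominant-eigenvalue modulus of locally weighted linear one-step maps
    in a time-delay embedding, per sliding window.

    theta = 0 degenerates to one global linear map per window; theta > 0
    weights library points by exp(-theta * distance / mean distance) around
    each target point (S-map) and the indicator averages the per-point
    dominant eigenvalue moduli.
    """
    x = np.asarray(series, float)
    if np.std(x) == 0:
        raise ValueError("constant series has no dynamics to embed")
    n = len(x)
    w = int(round(window_frac * n))
    if w <= embed_dim * embed_lag + 10:
        raise ValueError("window too short for the requested embedding")
    starts = _window_starts(n, w, step)
    vals = np.empty(len(starts))
    E = embed_dim
    for j, s in enumerate(starts):
        seg = _detrend_linear(x[s:s + w])
        rows, target = _delay_embed(seg, E, embed_lag)
        A = np.column_stack([rows, np.ones(len(rows))])
        if theta == 0.0:
            coef, *_ = np.linalg.lstsq(A, target, rcond=None)
            vals[j] = _companion_modulus(coef[:E])
        else:
            dists = np.linalg.norm(rows[:, None, :] - rows[None, :, :], axis=2)
            dbar = dists.mean()
            mods = []
            for i in range(len(rows)):
                wgt = np.exp(-theta * dists[i] / dbar)
                Aw = A * wgt[:, None]
                coef, *_ = np.linalg.lstsq(Aw, target * wgt, rcond=None)
                mods.append(_companion_modulus(coef[:E]))
            vals[j] = float(np.mean(mods))
    centers = _resolve_centers(mu_values, n, starts, w)
    return IndicatorSeries(centers, vals, "dev_modulus", 1.0, window_frac)


def _companion_modulus(coef: np.ndarray) -> float:
    E = len(coef)
    if E == 1:
        return abs(float(coef[0]))
    C = np.zeros((E, E))
    C[0] = coef
    C[1:, :-1] = np.eye(E - 1)
    return float(np.abs(np.linalg.eigvals(C)).max())


# -- extrapolation to the critical value -------------------------------------

def _crossing_of_poly(coef, crit: float, mu_last: float, direction: int,
                      mu_limit: float | None = None):
    """Nearest real root of poly(mu) = crit beyond mu_last in the ramp
    direction (optionally capped at mu_limit)."""
    c = np.array(coef, float)
    c[-1] -= crit
    roots = np.roots(c)
    real = roots[np.abs(roots.imag) < 1e-9].real
    ahead = real[(real - mu_last) * direction > 0]
    if mu_limit is not None:
        ahead = ahead[(mu_limit - ahead) * direction >= 0]
    if len(ahead) == 0:
        return None
    return float(ahead[np.argmin(np.abs(ahead - mu_last))])


def extrapolate_crossing(ind: IndicatorSeries,
                         max_extrapolation: float = 20.0,
                         beyond: float | None = None) -> ExtrapolationResult:
    """Linear and quadratic extrapolation of an indicator to its critical
    value; the fit with the larger R^2 provides the selected estimate.

    ``beyond`` is where the crossing search starts (default: the last window
    center; callers that know the end of the observed record pass it so a
    "prediction" can never fall inside the data).  ``max_extrapolation``
    caps the search at that multiple of the observed parameter range beyond
    the start (wild extrapolations are treated as non-predictions, mirroring
    how severely deviating estimates are left out of comparisons).
    """
    ok = np.isfinite(ind.indicator_values)
    mu = np.asarray(ind.window_centers, float)[ok]
    y = np.asarray(ind.indicator_values, float)[ok]
    if len(mu) < 3:
        raise ValueError("need at least 3 indicator points")
    direction = 1 if mu[-1] >= mu[0] else -1
    start = mu[-1] if beyond is None else float(beyond)
    span = abs(mu[-1] - mu[0])
    mu_limit = start + direction * max_extrapolation * span if span > 0 else None
    sst = np.sum((y - y.mean()) ** 2)
    candidates = {}
    best = (None, -np.inf, None)
    for name, deg in (("linear", 1), ("quadratic", 2)):
        coef = np.polyfit(mu, y, deg)
        resid = y - np.polyval(coef, mu)
        r2 = 1.0 - np.sum(resid ** 2) / sst if sst > 0 else 0.0
        cross = _crossing_of_poly(coef, ind.critical_value, start, direction,
                                  mu_limit)
        candidates[name] = {"mu": cross, "r2": float(r2)}
        if cross is not None and r2 > best[1]:
            best = (cross, r2, name)
    return ExtrapolationResult(mu_hat=best[0], selected=best[2],
                               candidates=candidates)
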