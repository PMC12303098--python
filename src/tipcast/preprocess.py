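"""Detrending, padding, normalization and the relative-error metric.

The predictor consumes fixed-shape 2 x 500 instances: a residual channel
(observed values minus a Lowess smooth) and a forcing-parameter channel.
Variable-length records are left-padded with exact zeros; the zero prefix
acts as a "missing" token and is excluded from every normalization:

* residuals: divided by the mean absolute value of the unpadded part;
* parameters: affinely mapped so the unpadded part runs from 0 to 1
  (regardless of ramp direction);
* label: label_norm = 1 + (mu_c - mu_end) / (mu_end - mu0_eff), constrained
  upstream to [1.01, 3], where mu0_eff / mu_end are the first and last
  unpadded parameter values.

Pipeline order is detrend -> zero-pad -> normalize.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "NormalizedInstance",
    "lowess_detrend",
    "zero_pad",
    "normalize_instance",
    "denormalize_prediction",
    "relative_error",
    "to_regular_grid",
    "training_instance",
    "inference_instance",
    "save_instance",
    "load_instance",
]

N_TOTAL = 500          # fixed instance length
MAX_PAD = 250          # maximal zeroed prefix
LABEL_RANGE = (1.01, 3.0)
LOWESS_SPAN = 0.2
LOWESS_ITERS = 1       # robustness iterations of the local linear fits


@dataclasses.dataclass
class NormalizedInstance:
    residual_channel: np.ndarray
    param_channel: np.ndarray
    pad_len: int
    label_norm: float | None
    meta: dict = dataclasses.field(default_factory=dict)

    def as_input(self) -> np.ndarray:
        """The 2 x 500 array fed to the predictor."""
        return np.stack([self.residual_channel, self.param_channel])


def lowess_detrend(values, span: float = LOWESS_SPAN) -> np.ndarray:
    """Residuals of a locally weighted linear regression smooth.

    The regression abscissa is the index position, mirroring how the
    fixed-length architecture treats the samples as a sequence.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    v = np.asarray(values, float)
    if v.size < 10:
        raise ValueError("need at least 10 points to detrend")
    x = np.arange(v.size, dtype=float)
    smooth = lowess(v, x, frac=span, it=LOWESS_ITERS, return_sorted=False)
    return v - smooth


def zero_pad(residuals, params, pad_len: int):
    """Replace the first ``pad_len`` entries of both channels by exact zeros."""
    r = np.asarray(residuals, float)
    p = np.asarray(params, float)
    if r.shape != (N_TOTAL,) or p.shape != (N_TOTAL,):
        raise ValueError(f"channels must have length {N_TOTAL}")
    if not 0 <= pad_len <= MAX_PAD:
        raise ValueError(f"pad_len must lie in [0, {MAX_PAD}]")
    r = r.copy()
    p = p.copy()
    r[:pad_len] = 0.0
    p[:pad_len] = 0.0
    return r, p


def normalize_instance(residuals, params, mu_c: float | None,
                       pad_len: int, meta: dict | None = None
                       ) -> NormalizedInstance:
    """Normalize zero-padded channels and (when mu_c is given) the label."""
    r = np.asarray(residuals, float).copy()
    p = np.asarray(params, float).copy()
    if r.shape != (N_TOTAL,) or p.shape != (N_TOTAL,):
        raise ValueError(f"channels must have length {N_TOTAL}")
    live_r = r[pad_len:]
    live_p = p[pad_len:]
    mu0_eff = float(live_p[0])
    mu_end = float(live_p[-1])
    if mu_end == mu0_eff:
        raise ValueError("degenerate ramp: mu_end equals mu0_eff")
    scale = np.abs(live_r).mean()
    if scale == 0.0:
        raise ValueError("residual channel is identically zero on the live part")
    r[pad_len:] = live_r / scale
    p[pad_len:] = (live_p - mu0_eff) / (mu_end - mu0_eff)
    label = None
    if mu_c is not None:
        label = 1.0 + (mu_c - mu_end) / (mu_end - mu0_eff)
    m = dict(meta or {})
    m.setdefault("mu0_eff", mu0_eff)
    m.setdefault("mu_end", mu_end)
    return NormalizedInstance(residual_channel=r, param_channel=p,
                              pad_len=int(pad_len), label_norm=label, meta=m)


def denormalize_prediction(label_norm_hat: float, mu0_eff: float,
                           mu_end: float) -> float:
    """Exact inverse of the label normalization."""
    if mu_end == mu0_eff:
        raise ValueError("degenerate ramp: mu_end equals mu0_eff")
    return mu_end + (label_norm_hat - 1.0) * (mu_end - mu0_eff)


def relative_error(mu_hat: float, mu_c: float, mu_end: float) -> float:
    """epsilon = |mu_hat - mu_c| / |mu_end - mu_c|."""
    denom = abs(mu_end - mu_c)
    if denom == 0.0:
        raise ValueError("mu_end equals mu_c")
    return abs(mu_hat - mu_c) / denom


def to_regular_grid(times, values, n_out: int) -> np.ndarray:
    """Linear interpolation onto n_out equidistant times spanning the record."""
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    grid = np.linspace(t[0], t[-1], n_out)
    return np.interp(grid, t, v)


# -- full preprocessing pipeline --------------------------------------------

def _embed(series: np.ndarray, length: int) -> tuple[np.ndarray, int]:
    """Right-align a series of length <= N_TOTAL into a zero-filled buffer."""
    pad = N_TOTAL - length
    out = np.zeros(N_TOTAL)
    out[pad:] = series
    return out, pad


def training_instance(values, mu_values, mu_c: float,
                      rng: np.random.Generator, span: float = LOWESS_SPAN,
                      meta: dict | None = None, max_tries: int = 50
                      ) -> NormalizedInstance | None:
    """Detrend, draw a zero prefix from U{0..250}, normalize.

    The prefix shortens the visible ramp and therefore raises label_norm; a
    draw pushing the label outside [1.01, 3] is retried, falling back to no
    padding.  Returns None only when even the unpadded label escapes the
    range (the upstream relative-distance window normally prevents this).
    """
    v = np.asarray(values, float)
    p = np.asarray(mu_values, float)
    if v.shape != (N_TOTAL,):
        raise ValueError(f"training series must have length {N_TOTAL}")
    resid = lowess_detrend(v, span)
    for _ in range(max_tries):
        pad = int(rng.integers(0, MAX_PAD + 1))
        r, q = zero_pad(resid, p, pad)
        inst = normalize_instance(r, q, mu_c, pad, meta=meta)
        if LABEL_RANGE[0] <= inst.label_norm <= LABEL_RANGE[1]:
            return inst
    r, q = zero_pad(resid, p, 0)
    inst = normalize_instance(r, q, mu_c, 0, meta=meta)
    if LABEL_RANGE[0] <= inst.label_norm <= LABEL_RANGE[1]:
        return inst
    return None


def inference_instance(values, mu_values, mu_c: float | None = None,
                       span: float = LOWESS_SPAN, meta: dict | None = None
                       ) -> NormalizedInstance:
    """Preprocess a (possibly shorter than 500 points) record for prediction:
    detrend, left-pad to length 500, normalize."""
    v = np.asarray(values, float)
    p = np.asarray(mu_values, float)
    if not 10 <= v.size <= N_TOTAL:
        raise ValueError(f"record length must lie in [10, {N_TOTAL}]")
    resid = lowess_detrend(v, span)
    r, pad = _embed(resid, v.size)
    q, _ = _embed(p, p.size)
    return normalize_instance(r, q, mu_c, pad, meta=meta)


# -- serialization (bit-exact round-trip) ------------------------------------

def save_instance(inst: NormalizedInstance, path) -> None:
    with open(path, "w") as fh:
        meta = {"pad_len": inst.pad_len, "label_norm": inst.label_norm,
                "meta": inst.meta}
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("residual,param\n")
        for r, p in zip(inst.residual_channel, inst.param_channel):
            fh.write(f"{float(r)!r},{float(p)!r}\n")


def load_instance(path) -> NormalizedInstance:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise ValueError("missing metadata header")
        meta = json.loads(header[2:])
        fh.readline()  # column header
        rows = [line.strip().split(",") for line in fh if line.strip()]
    r = np.array([float(a) for a, _ in rows])
    p = np.array([float(b) for _, b in rows])
    return NormalizedInstance(residual_channel=r, param_channel=p,
                              pad_len=meta["pad_len"],
                              label_norm=meta["label_norm"], meta=meta["meta"])
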