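"""Library of random two-dimensional polynomial systems and their bifurcations.

The training corpus is built from random cubic polynomial vector fields

    dx/dt = sum_i a_i p_i(x, y),   dy/dt = sum_i b_i p_i(x, y),

with p = (1, x, y, x^2, xy, y^2, x^3, x^2 y, x y^2, y^3).  Coefficients are
standard normal, half of the twenty are zeroed at random, and the eight cubic
coefficients are forced nonpositive so that generic trajectories stay bounded.
For each system that settles onto a stable equilibrium, the equilibrium branch
is continued in every nonzero coefficient (both directions) by pseudo-arclength
continuation with Newton correction; the first sign change of the recovery rate
lambda (max real part of the Jacobian eigenvalues) along the branch marks a
codimension-one bifurcation, classified as

* hopf          -- the crossing eigenvalues form a complex pair,
* fold          -- a real eigenvalue crosses zero and the branch folds back
                   in the parameter,
* transcritical -- a real eigenvalue crosses zero and the branch continues.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np
from scipy import optimize

from . import _kernels as K

__all__ = [
    "PolySystem",
    "Equilibrium",
    "BranchPoint",
    "BifurcationRecord",
    "sample_polysystem",
    "eval_field",
    "eval_jacobian",
    "settle_to_equilibrium",
    "continue_branch",
    "detect_bifurcation",
    "build_library",
    "library_to_jsonl",
    "library_from_jsonl",
]

#: monomial basis order used throughout
MONOMIALS = ("1", "x", "y", "x2", "xy", "y2", "x3", "x2y", "xy2", "y3")
_CUBIC = (6, 7, 8, 9)

#: divergence guard for settling and continuation (cubic damping keeps
#: genuine attractors well inside this)
DIVERGENCE_BOUND = 1e6

#: threshold on |Im| of the crossing eigenvalues that separates a Hopf
#: crossing from a real-eigenvalue crossing
IM_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class PolySystem:
    """A random 2-D cubic polynomial vector field."""

    a_coeffs: np.ndarray
    b_coeffs: np.ndarray
    id: str = ""
    rng_seed: int = -1

    def __post_init__(self):
        object.__setattr__(self, "a_coeffs", np.asarray(self.a_coeffs, float))
        object.__setattr__(self, "b_coeffs", np.asarray(self.b_coeffs, float))
        if self.a_coeffs.shape != (10,) or self.b_coeffs.shape != (10,):
            raise ValueError("coefficient vectors must have length 10")
        if not (np.isfinite(self.a_coeffs).all() and np.isfinite(self.b_coeffs).all()):
            raise ValueError("coefficients must be finite")

    @property
    def coeffs(self) -> np.ndarray:
        """The concatenated 20-vector (a, b)."""
        return np.concatenate([self.a_coeffs, self.b_coeffs])

    def with_coeff(self, varied_index: int, value: float) -> "PolySystem":
        c = self.coeffs
        c[varied_index] = value
        return PolySystem(c[:10], c[10:], id=self.id, rng_seed=self.rng_seed)


@dataclasses.dataclass(frozen=True)
class Equilibrium:
    state: tuple
    coefficient_context: np.ndarray
    residual_norm: float


@dataclasses.dataclass(frozen=True)
class BranchPoint:
    mu: float
    equilibrium: Equilibrium
    eigenvalues: tuple

    @property
    def lam(self) -> float:
        return max(e.real for e in self.eigenvalues)


@dataclasses.dataclass(frozen=True)
class BifurcationRecord:
    system_id: str
    varied_index: int
    direction: int
    bif_type: str
    mu_static: float
    eq_at_bif: Equilibrium
    #: equilibrium at the original parameter value on the detected branch
    #: (provenance: where a ramp toward this bifurcation starts)
    eq_start: Equilibrium | None = None


def sample_polysystem(rng_seed: int) -> PolySystem:
    """Draw a random polynomial system.

    Twenty standard-normal coefficients; a uniformly random subset of exactly
    ten is zeroed; the eight cubic coefficients are then replaced by minus
    their absolute value (zeros stay zero).
    """
    rng = np.random.default_rng(rng_seed)
    c = rng.standard_normal(20)
    zero = rng.choice(20, size=10, replace=False)
    c[zero] = 0.0
    for base in (0, 10):
        for i in _CUBIC:
            c[base + i] = -abs(c[base + i])
    return PolySystem(c[:10], c[10:], id=f"sys-{rng_seed}", rng_seed=rng_seed)


def eval_field(sys: PolySystem, state: Sequence[float]) -> tuple:
    x, y = float(state[0]), float(state[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("state must be finite")
    return K.poly_rhs(sys.a_coeffs, sys.b_coeffs, x, y)


def eval_jacobian(sys: PolySystem, state: Sequence[float]) -> np.ndarray:
    x, y = float(state[0]), float(state[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("state must be finite")
    j11, j12, j21, j22 = K.poly_jac(sys.a_coeffs, sys.b_coeffs, x, y)
    return np.array([[j11, j12], [j21, j22]])


def settle_to_equilibrium(sys: PolySystem, init_state: Sequence[float],
                          n_steps: int = 10_000, dt: float = 0.01,
                          tol: float = 1e-8) -> Equilibrium | None:
    """Forward-Euler integrate; converged iff the final 10 states differ by
    less than ``tol`` coordinate-wise.  The converged state is polished by a
    Newton root solve.  Returns None when not converged (incl. divergence).
    """
    if dt <= 0 or n_steps < 10:
        raise ValueError("need dt > 0 and n_steps >= 10")
    x, y, status = K.settle_poly(sys.a_coeffs, sys.b_coeffs,
                                 float(init_state[0]), float(init_state[1]),
                                 dt, n_steps, tol, DIVERGENCE_BOUND)
    if status != K.OK:
        return None
    x, y, ok = K.newton_poly(sys.a_coeffs, sys.b_coeffs, x, y, 1e-12, 50)
    if not ok:
        return None
    fx, fy = K.poly_rhs(sys.a_coeffs, sys.b_coeffs, x, y)
    return Equilibrium(state=(x, y), coefficient_context=sys.coeffs,
                       residual_norm=float(np.hypot(fx, fy)))


def continue_branch(sys: PolySystem, start: Equilibrium, varied_index: int,
                    direction: int, mu_step: float = 0.02,
                    mu_span: float = 4.0, max_pts: int = 2000,
                    n_past: int = 5) -> list[BranchPoint]:
    """Pseudo-arclength continuation of the equilibrium branch in the given
    coefficient; Newton-corrected points with their Jacobian eigenvalues."""
    if sys.coeffs[varied_index] == 0.0:
        raise ValueError("varied_index must name a nonzero coefficient")
    arrs = K.continue_branch_poly(
        sys.a_coeffs, sys.b_coeffs, start.state[0], start.state[1],
        varied_index, float(direction), mu_step, mu_span, max_pts, n_past,
        DIVERGENCE_BOUND, 1e-10, mu_step / 64.0)
    mus, xs, ys, re1, im1, re2, im2, n, status = arrs
    pts = []
    for i in range(n):
        ctx = sys.coeffs
        ctx[varied_index] = mus[i]
        fx, fy = K.poly_rhs(ctx[:10], ctx[10:], xs[i], ys[i])
        eq = Equilibrium(state=(xs[i], ys[i]), coefficient_context=ctx,
                         residual_norm=float(np.hypot(fx, fy)))
        eigs = (complex(re1[i], im1[i]), complex(re2[i], im2[i]))
        pts.append(BranchPoint(mu=float(mus[i]), equilibrium=eq, eigenvalues=eigs))
    return pts


# -- classification helpers --------------------------------------------------

def _classify_arrays(mus, xs, ys, re1, im1, im_tol=IM_TOL):
    """Locate the first lambda sign change and classify it.

    Returns (kind, i) with i the index before the crossing, or (None, -1).
    """
    lam = re1
    n = len(mus)
    for i in range(n - 1):
        if lam[i] < 0.0 <= lam[i + 1]:
            if abs(im1[i]) > im_tol and abs(im1[i + 1]) > im_tol:
                return "hopf", i
            # fold iff the parameter progression reverses near the crossing
            lo = max(0, i - 3)
            hi = min(n - 1, i + 4)
            dmu = np.diff(mus[lo:hi + 1])
            if len(dmu) >= 2 and (np.sign(dmu[:-1]) * np.sign(dmu[1:]) < 0).any():
                return "fold", i
            if abs(mus[i + 1] - mus[i]) < 1e-12:
                return None, -1  # degenerate crossing, unusable
            return "transcritical", i
    return None, -1


def _newton_lambda_at(coeffs, varied_index, mu, seed_state):
    c = coeffs.copy()
    c[varied_index] = mu
    x, y, ok = K.newton_poly(c[:10], c[10:], seed_state[0], seed_state[1],
                             1e-12, 60)
    if not ok:
        return None, seed_state
    return K.poly_lambda(c[:10], c[10:], x, y), (x, y)


def _refine_bisect(coeffs, varied_index, mu_lo, mu_hi, state_lo, tol=1e-8):
    """Bisection on mu for the lambda zero along a branch that is a graph
    over mu near the crossing (Hopf / transcritical)."""
    lam_lo, st = _newton_lambda_at(coeffs, varied_index, mu_lo, state_lo)
    if lam_lo is None:
        return 0.5 * (mu_lo + mu_hi), state_lo
    seed = st
    for _ in range(80):
        mid = 0.5 * (mu_lo + mu_hi)
        lam_mid, st = _newton_lambda_at(coeffs, varied_index, mid, seed)
        if lam_mid is None:
            break
        seed = st
        if lam_mid * lam_lo <= 0.0 and lam_mid != 0.0:
            mu_hi = mid
        else:
            mu_lo, lam_lo = mid, lam_mid
        if abs(mu_hi - mu_lo) < tol:
            break
    return 0.5 * (mu_lo + mu_hi), seed


def _refine_fold(coeffs, varied_index, mu_guess, state_guess):
    """Newton on the extended system (f1, f2, det J) = 0 in (x, y, mu)."""
    def ext(u):
        c = coeffs.copy()
        c[varied_index] = u[2]
        f1, f2 = K.poly_rhs(c[:10], c[10:], u[0], u[1])
        j11, j12, j21, j22 = K.poly_jac(c[:10], c[10:], u[0], u[1])
        return [f1, f2, j11 * j22 - j12 * j21]

    sol = optimize.root(ext, [state_guess[0], state_guess[1], mu_guess],
                        method="hybr", tol=1e-12)
    if sol.success:
        return float(sol.x[2]), (float(sol.x[0]), float(sol.x[1]))
    return float(mu_guess), state_guess


def detect_bifurcation(branch: list[BranchPoint], system_id: str = "",
                       im_tol: float = IM_TOL,
                       refine_tol: float = 1e-8) -> BifurcationRecord | None:
    """Find and classify the first recovery-rate sign change along a branch.

    Returns None when lambda keeps its sign or the branch is too short to
    bracket a crossing.
    """
    if len(branch) < 2:
        return None
    mus = np.array([p.mu for p in branch])
    xs = np.array([p.equilibrium.state[0] for p in branch])
    ys = np.array([p.equilibrium.state[1] for p in branch])
    re1 = np.array([max(e.real for e in p.eigenvalues) for p in branch])
    im1 = np.array([max(p.eigenvalues, key=lambda e: e.real).imag for p in branch])

    kind, i = _classify_arrays(mus, xs, ys, re1, im1, im_tol)
    if kind is None:
        return None

    # recover the varied coefficient from the stored contexts
    c0 = branch[0].equilibrium.coefficient_context
    c1 = branch[-1].equilibrium.coefficient_context
    diff = np.nonzero(c0 != c1)[0]
    if len(diff) != 1:
        raise ValueError("branch points do not share a single varied coefficient")
    varied_index = int(diff[0])
    direction = 1 if mus[min(i + 1, len(mus) - 1)] >= mus[0] else -1

    coeffs = c0.copy()
    if kind == "fold":
        mu_static, st = _refine_fold(coeffs, varied_index,
                                     0.5 * (mus[i] + mus[i + 1]),
                                     (xs[i], ys[i]))
    else:
        mu_static, st = _refine_bisect(coeffs, varied_index, mus[i], mus[i + 1],
                                       (xs[i], ys[i]), tol=refine_tol)
    c = coeffs.copy()
    c[varied_index] = mu_static
    fx, fy = K.poly_rhs(c[:10], c[10:], st[0], st[1])
    eq = Equilibrium(state=(st[0], st[1]), coefficient_context=c,
                     residual_norm=float(np.hypot(fx, fy)))
    return BifurcationRecord(system_id=system_id, varied_index=varied_index,
                             direction=direction, bif_type=kind,
                             mu_static=float(mu_static), eq_at_bif=eq,
                             eq_start=branch[0].equilibrium)


# -- library assembly --------------------------------------------------------

def find_bifurcations(sys: PolySystem, eq: Equilibrium, mu_step: float = 0.02,
                      mu_span: float = 4.0) -> list[BifurcationRecord]:
    """All bifurcations found by continuing every nonzero coefficient in basis
    order, both directions, taking the first crossing per branch."""
    out = []
    coeffs = sys.coeffs
    for idx in range(20):
        if coeffs[idx] == 0.0:
            continue
        for direction in (1, -1):
            try:
                branch = continue_branch(sys, eq, idx, direction,
                                         mu_step=mu_step, mu_span=mu_span)
                rec = detect_bifurcation(branch, system_id=sys.id)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if rec is not None:
                out.append(rec)
    return out


def build_library(n_fold: int, n_hopf: int, n_trans: int, rng_seed: int,
                  mu_step: float = 0.02, mu_span: float = 4.0,
                  max_attempts: int = 200_000):
    """Sample systems until each bifurcation-type quota is met.

    Returns a list of (PolySystem, BifurcationRecord).  Systems that do not
    settle onto an equilibrium are discarded; every detected bifurcation of a
    system may contribute (provenance is kept via ``system_id``).  If the
    attempt cap is exceeded, the partial library is returned with a warning.
    """
    quotas = {"fold": n_fold, "hopf": n_hopf, "transcritical": n_trans}
    if any(v < 0 for v in quotas.values()):
        raise ValueError("quotas must be >= 0")
    counts = {k: 0 for k in quotas}
    library: list[tuple[PolySystem, BifurcationRecord]] = []
    ss = np.random.SeedSequence(rng_seed)
    master = np.random.default_rng(ss)
    attempt = 0
    while any(counts[k] < quotas[k] for k in quotas) and attempt < max_attempts:
        attempt += 1
        sys_seed = int(master.integers(0, 2**31 - 1))
        system = sample_polysystem(sys_seed)
        init = np.random.default_rng(sys_seed + 1).uniform(-1.0, 1.0, size=2)
        eq = settle_to_equilibrium(system, init)
        if eq is None:
            continue
        for rec in find_bifurcations(system, eq, mu_step=mu_step, mu_span=mu_span):
            if counts[rec.bif_type] < quotas[rec.bif_type]:
                counts[rec.bif_type] += 1
                library.append((system, rec))
        # leave the loop as soon as all quotas are met
    if any(counts[k] < quotas[k] for k in quotas):
        warnings.warn(f"attempt cap {max_attempts} exceeded; partial library "
                      f"with counts {counts}")
    return library


# -- serialization -----------------------------------------------------------

def library_to_jsonl(library, path) -> None:
    with open(path, "w") as fh:
        for system, rec in library:
            obj = {
                "system_id": system.id,
                "rng_seed": system.rng_seed,
                "a_coeffs": system.a_coeffs.tolist(),
                "b_coeffs": system.b_coeffs.tolist(),
                "varied_index": rec.varied_index,
                "direction": rec.direction,
                "bif_type": rec.bif_type,
                "mu_static": rec.mu_static,
                "eq_state": list(rec.eq_at_bif.state),
                "eq_start_state": list(rec.eq_start.state)
                if rec.eq_start is not None else None,
            }
            fh.write(json.dumps(obj) + "\n")


def library_from_jsonl(path):
    library = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            system = PolySystem(np.array(obj["a_coeffs"]), np.array(obj["b_coeffs"]),
                                id=obj["system_id"], rng_seed=obj["rng_seed"])
            c = system.coeffs
            c[obj["varied_index"]] = obj["mu_static"]
            fx, fy = K.poly_rhs(c[:10], c[10:], *obj["eq_state"])
            eq = Equilibrium(state=tuple(obj["eq_state"]), coefficient_context=c,
                             residual_norm=float(np.hypot(fx, fy)))
            eq_start = None
            if obj.get("eq_start_state") is not None:
                sx, sy = obj["eq_start_state"]
                fx, fy = K.poly_rhs(system.a_coeffs, system.b_coeffs, sx, sy)
                eq_start = Equilibrium(state=(sx, sy),
                                       coefficient_context=system.coeffs,
                                       residual_norm=float(np.hypot(fx, fy)))
            rec = BifurcationRecord(system_id=obj["system_id"],
                                    varied_index=obj["varied_index"],
                                    direction=obj["direction"],
                                    bif_type=obj["bif_type"],
                                    mu_static=obj["mu_static"], eq_at_bif=eq,
                                    eq_start=eq_start)
            library.append((system, rec))
    return library
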