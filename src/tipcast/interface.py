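"""File formats, run configuration, logging and the seeded fixture bundle.

Columnar records are plain text with header ``time,state,param`` plus an
optional JSON sidecar (``<path>.json``) holding the label and provenance.
All randomness in a run flows from a single master seed through
``numpy.random.SeedSequence`` spawning, so every stage is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np

from . import syslib
from .simulate import SampledSeries, make_training_set
from .preprocess import training_instance

__all__ = [
    "RunConfig",
    "read_series",
    "write_series",
    "make_fixtures",
    "get_logger",
    "SeriesFormatError",
]

log = logging.getLogger("tipcast")


def get_logger(level: str = "INFO") -> logging.Logger:
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
    log.setLevel(level.upper())
    return log


class SeriesFormatError(ValueError):
    """Malformed columnar series file (message names the offending line)."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_STAGES = ("library", "corpus", "preprocess", "train", "benchmark", "fixtures")


@dataclasses.dataclass
class RunConfig:
    master_seed: int = 0
    n_fold: int = 40
    n_hopf: int = 40
    n_trans: int = 40
    n_instances: int = 3000
    noise_kinds: tuple = ("white", "red")
    output_dir: str = "tipcast-out"
    log_level: str = "INFO"
    model: dict = dataclasses.field(default_factory=dict)  # ModelConfig overrides

    def stage_seed(self, stage: str) -> int:
        """Derived per-stage seed: a pure function of the master seed."""
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        child = np.random.SeedSequence(self.master_seed).spawn(len(_STAGES))
        return int(child[_STAGES.index(stage)].generate_state(1)[0] % (2**31 - 1))

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["noise_kinds"] = list(self.noise_kinds)
        pathlib.Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(pathlib.Path(path).read_text())
        d["noise_kinds"] = tuple(d.get("noise_kinds", ("white", "red")))
        return cls(**d)


# ---------------------------------------------------------------------------
# columnar series I/O
# ---------------------------------------------------------------------------

def write_series(series: SampledSeries, path) -> None:
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        fh.write("time,state,param\n")
        for t, v, m in zip(series.times, series.values, series.mu_values):
            fh.write(f"{float(t)!r},{float(v)!r},{float(m)!r}\n")
    sidecar = {
        "mu_c": series.mu_c,
        "bif_type": series.bif_type,
        "noise_kind": series.noise_kind,
        "rate": series.rate,
        "system_id": series.system_id,
        "seeds": {k: (v if not isinstance(v, np.generic) else v.item())
                  for k, v in series.seeds.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_series(path):
    """Parse a ``time,state,param`` file (strictly increasing times enforced);
    returns (times, values, mu_values, meta) with meta from the JSON sidecar
    when present."""
    path = pathlib.Path(path)
    times, values, mus = [], [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "time,state,param":
            raise SeriesFormatError(f"{path}:1: expected header 'time,state,param'")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != 3:
                raise SeriesFormatError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
            try:
                t, v, m = (float(p) for p in parts)
            except ValueError as exc:
                raise SeriesFormatError(f"{path}:{ln}: non-numeric cell ({exc})")
            if times and t <= times[-1]:
                raise SeriesFormatError(f"{path}:{ln}: times not strictly increasing")
            times.append(t)
            values.append(v)
            mus.append(m)
    if not times:
        raise SeriesFormatError(f"{path}: no data rows")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return np.array(times), np.array(values), np.array(mus), meta


# ---------------------------------------------------------------------------
# canonical normal-form systems (used by analytic tests and fixtures)
# ---------------------------------------------------------------------------

def normal_form_systems() -> dict:
    """The three analytic systems whose bifurcation locations are known in
    closed form: fold (dx = a1 - x^2), transcritical (dx = a2 x - x^2) and
    a rotational Hopf (dx = a2 x - y - x r^2, dy = x - y r^2), each with
    the crossing at parameter value 0."""
    def mk(a, b, name):
        A = np.zeros(10)
        B = np.zeros(10)
        for k, v in a.items():
            A[k] = v
        for k, v in b.items():
            B[k] = v
        return syslib.PolySystem(A, B, id=name)

    return {
        "fold": (mk({0: 1.0, 3: -1.0}, {2: -1.0}, "nf-fold"), 0, -1),
        "transcritical": (mk({1: -1.0, 3: -1.0}, {2: -1.0}, "nf-transcritical"), 1, 1),
        "hopf": (mk({1: -1.0, 2: -1.0, 6: -1.0, 8: -1.0},
                    {1: 1.0, 7: -1.0, 9: -1.0}, "nf-hopf"), 1, 1),
    }


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def make_fixtures(master_seed: int, benchmark_models=("may_harvest",
                                                      "arousal_sleepwake")
                  ) -> dict:
    """Deterministic fixture bundle for tests and examples.

    Contains a 6-record mini-library (2 per bifurcation type), a 60-instance
    mini training corpus with normalized instances, a handful of benchmark
    test series at each listed model's slowest rate, and the canonical
    normal-form systems.  Everything derives from ``master_seed``.
    """
    from . import benchmark as BM  # deferred: compiles jitted models lazily

    cfg = RunConfig(master_seed=master_seed)
    lib = syslib.build_library(2, 2, 2, rng_seed=cfg.stage_seed("library"))
    corpus = make_training_set(lib, rng_seed=cfg.stage_seed("corpus"),
                               n_instances=60)
    rng = np.random.default_rng(cfg.stage_seed("preprocess"))
    instances = []
    for s in corpus:
        inst = training_instance(s.values, s.mu_values, s.mu_c, rng,
                                 meta={"bif_type": s.bif_type})
        if inst is not None:
            instances.append(inst)
    bench = {}
    for name in benchmark_models:
        model = BM.get_model(name)
        d = model.directions[0]
        bench[name] = BM.generate_test_set(
            model, replicates=5, rng_seed=cfg.stage_seed("benchmark"),
            direction=d, initial_values=(model.initial_values[d][-1],),
            rates=(model.rates[d][0],))
    return {
        "config": cfg,
        "library": lib,
        "corpus": corpus,
        "instances": instances,
        "benchmark": bench,
        "normal_forms": normal_form_systems(),
    }
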