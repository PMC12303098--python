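"""The CNN-LSTM tipping-point regressor: training, ensembling, persistence.

The network maps a normalized 2 x 500 instance (residual channel, parameter
channel) to the normalized tipping location label_norm in [1.01, 3].  A
two-row convolution kernel of width d scans both channels jointly -- d plays
the role of the delay-embedding dimension, so d > 2m is required to resolve
an m-dimensional system -- followed by local max pooling, an LSTM over the
pooled feature sequence, and a dense scalar head.  The ablation drops the
convolution/pooling stage and feeds the two raw channels to the LSTM.

Training minimizes MSE between predicted and true normalized labels; an
ensemble of independently seeded networks is trained and predictions are
averaged, then clipped to the label range and denormalized to parameter
units.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import numpy as np

from ._nn import Adam, CNNLSTM, DTYPE
from .preprocess import (LABEL_RANGE, N_TOTAL, NormalizedInstance,
                         denormalize_prediction)

__all__ = [
    "ModelConfig",
    "TrainedEnsemble",
    "build_model",
    "train",
    "train_ensemble",
    "predict_norm",
    "predict_tipping",
    "save_ensemble",
    "load_ensemble",
]


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters.  Full-scale defaults mirror the training protocol of
    300,000 instances / 200 epochs / ensemble of ten; reduced configurations
    are constructed explicitly where desk-scale runs are wanted."""

    kernel_len_d: int = 10
    n_filters: int = 50
    pool_size: int = 2
    lstm_units: int = 64
    learning_rate: float = 5e-4
    batch_size: int = 64
    epochs: int = 200
    ensemble_size: int = 10
    split: tuple = (0.95, 0.04, 0.01)
    seed: int = 0
    ablation_no_cnn: bool = False

    def __post_init__(self):
        if self.kernel_len_d < 3:
            raise ValueError("kernel_len_d must be >= 3")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


#: a configuration sized for single-CPU runs (several thousand instances)
DESK_CONFIG = ModelConfig(n_filters=24, pool_size=4, lstm_units=24,
                          learning_rate=2e-3, batch_size=256, epochs=20,
                          ensemble_size=3)


@dataclasses.dataclass
class EnsembleMember:
    model: CNNLSTM
    config: ModelConfig
    seed: int
    history: dict


@dataclasses.dataclass
class TrainedEnsemble:
    members: list
    corpus_fingerprint: str = ""

    @property
    def training_history(self):
        return [m.history for m in self.members]


def build_model(config: ModelConfig, seed: int | None = None) -> CNNLSTM:
    return CNNLSTM(kernel_len=config.kernel_len_d, n_filters=config.n_filters,
                   pool_size=config.pool_size, lstm_units=config.lstm_units,
                   use_cnn=not config.ablation_no_cnn,
                   seed=config.seed if seed is None else seed,
                   n_input=N_TOTAL)


def _dataset_arrays(dataset):
    X = np.stack([inst.as_input() for inst in dataset]).astype(DTYPE)
    y = np.array([inst.label_norm for inst in dataset], DTYPE)
    if np.any(np.isnan(y)):
        raise ValueError("training requires labeled instances")
    return X, y


def _fingerprint(X, y) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X[:64]).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    h.update(str(X.shape).encode())
    return h.hexdigest()[:16]


def train(network: CNNLSTM, dataset, config: ModelConfig,
          seed: int | None = None) -> EnsembleMember:
    """Train one network on the labeled dataset with a seeded split/shuffle.

    The dataset is split train/validation/test by the config fractions; MSE
    is minimized with Adam; per-epoch train and validation losses are
    recorded.
    """
    X, y = _dataset_arrays(dataset)
    n = len(y)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(config.split[0] * n)
    n_val = int(config.split[1] * n)
    if n_train == 0:
        raise ValueError("empty training split")
    tr = order[:n_train]
    va = order[n_train:n_train + n_val]
    opt = Adam(network.params, lr=config.learning_rate)
    hist = {"train": [], "val": []}
    for _ in range(config.epochs):
        perm = rng.permutation(n_train)
        ep_loss = 0.0
        nb = 0
        for k in range(0, n_train, config.batch_size):
            idx = tr[perm[k:k + config.batch_size]]
            loss, grads = network.loss_and_grads(X[idx], y[idx])
            opt.step(network.params, grads)
            ep_loss += loss
            nb += 1
        hist["train"].append(ep_loss / max(nb, 1))
        if len(va):
            pv = network.forward(X[va])
            hist["val"].append(float(np.mean((pv - y[va]) ** 2)))
    return EnsembleMember(model=network, config=config, seed=seed, history=hist)


def train_ensemble(dataset, config: ModelConfig) -> TrainedEnsemble:
    """Train ``config.ensemble_size`` independently seeded members."""
    X, y = _dataset_arrays(dataset)
    members = []
    for k in range(config.ensemble_size):
        net = build_model(config, seed=config.seed + 1000 * k)
        members.append(train(net, dataset, config, seed=config.seed + 1000 * k))
    return TrainedEnsemble(members=members, corpus_fingerprint=_fingerprint(X, y))


def predict_norm(ensemble: TrainedEnsemble, instances,
                 batch_size: int = 512) -> np.ndarray:
    """Member-averaged normalized predictions, clipped to the label range."""
    if isinstance(instances, NormalizedInstance):
        instances = [instances]
    X = np.stack([inst.as_input() for inst in instances]).astype(DTYPE)
    preds = np.zeros(len(instances))
    for m in ensemble.members:
        out = np.concatenate([m.model.forward(X[k:k + batch_size])
                              for k in range(0, len(X), batch_size)])
        preds += out
    preds /= len(ensemble.members)
    return np.clip(preds, LABEL_RANGE[0], LABEL_RANGE[1])


def predict_tipping(ensemble: TrainedEnsemble, instance: NormalizedInstance
                    ) -> float:
    """Predicted tipping point in original parameter units."""
    meta = instance.meta
    if "mu0_eff" not in meta or "mu_end" not in meta:
        raise ValueError("instance meta lacks mu0_eff/mu_end")
    ln = float(predict_norm(ensemble, instance)[0])
    return denormalize_prediction(ln, meta["mu0_eff"], meta["mu_end"])


# -- persistence -------------------------------------------------------------

def save_ensemble(ensemble: TrainedEnsemble, path) -> None:
    """Self-describing directory: config JSON + one weights blob per member."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "corpus_fingerprint": ensemble.corpus_fingerprint,
        "members": [{"seed": m.seed, "config": dataclasses.asdict(m.config),
                     "history": m.history} for m in ensemble.members],
    }
    (path / "config.json").write_text(json.dumps(meta, indent=1))
    for k, m in enumerate(ensemble.members):
        np.savez(path / f"member{k}.npz", **m.model.get_weights())


def load_ensemble(path) -> TrainedEnsemble:
    path = pathlib.Path(path)
    meta = json.loads((path / "config.json").read_text())
    members = []
    for k, mm in enumerate(meta["members"]):
        cfg_d = mm["config"]
        cfg_d["split"] = tuple(cfg_d["split"])
        cfg = ModelConfig(**cfg_d)
        net = build_model(cfg, seed=mm["seed"])
        with np.load(path / f"member{k}.npz") as z:
            net.set_weights({k2: z[k2] for k2 in z.files})
        members.append(EnsembleMember(model=net, config=cfg, seed=mm["seed"],
                                      history=mm["history"]))
    return TrainedEnsemble(members=members,
                           corpus_fingerprint=meta["corpus_fingerprint"])
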