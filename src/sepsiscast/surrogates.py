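"""The four surrogate network families and their training contracts.

Architectures (hidden widths scale with ``width_scale``; defaults are the
full-size networks and give the closed-form parameter counts):

lstm_predictor (one per cytokine, 296,301 parameters)
    5×11 input → three 100-unit LSTM layers (first two return sequences,
    the third its final state) → dense 300 → dense 200 → scalar.
    Loss: MAE. No dropout layer in the printed stack; an optional
    1% Monte-Carlo dropout before the first dense layer can be enabled
    to build forecast ensembles (an interpretation, see docs).
mlp_predictor (one per cytokine, 5,764,501 parameters)
    dense 1000 applied per time step (5×11 → 5×1000) → flatten to 5000 →
    dense 1000 → 1% permanent dropout → dense 500 → dense 500 → scalar.
    Loss: MSE.
health_regressor (2,494,801 parameters)
    11 → dense 1500 → dense 1500 → dense 150 → scalar. Loss: MSE.
deficit_only_mlp (178,951 parameters)
    5 past deficits → dense 1000 → 1% permanent dropout → dense 150 →
    dense 150 → scalar. Loss: MSE.

"Permanent" dropout means the layer stays active at inference when a
stochastic prediction is requested, which is what turns one trained
network into a Monte-Carlo ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .abm import N_CYTOKINES
from .windows import WINDOW_LEN, NormStats, WindowSet

__all__ = ["NetSpec", "BuildConfig", "OptConfig", "SurrogateModel",
    "build", "train", "predict", "predict_stochastic", "count_parameters",
    "KINDS", "REQUIRED_LOSS"]

KINDS = ("lstm_predictor", "mlp_predictor", "health_regressor",
         "deficit_only_mlp")

#: loss function mandated for each family
REQUIRED_LOSS = {
    "lstm_predictor": "MAE",
    "mlp_predictor": "MSE",
    "health_regressor": "MSE",
    "deficit_only_mlp": "MSE",
}

_FULL_WIDTHS = {
    "lstm_predictor": (100, 100, 100, 300, 200),
    "mlp_predictor": (1000, 1000, 500, 500),
    "health_regressor": (1500, 1500, 150),
    "deficit_only_mlp": (1000, 150, 150),
}

_INPUT_SHAPE = {
    "lstm_predictor": (WINDOW_LEN, N_CYTOKINES),
    "mlp_predictor": (WINDOW_LEN, N_CYTOKINES),
    "health_regressor": (N_CYTOKINES,),
    "deficit_only_mlp": (WINDOW_LEN,),
}


class ConfigurationError(ValueError):
    """Unknown kind or inconsistent model configuration."""


class ContractError(ValueError):
    """Data shapes or loss selection violate the model's contract."""


class NotTrainedError(RuntimeError):
    """Prediction requested from an untrained, non-stub model."""


@dataclass(frozen=True)
class BuildConfig:
    """Construction options for :func:`build`.

    ``width_scale`` multiplies every hidden width (1.0 = the published
    architecture); ``lstm_mc_dropout`` inserts the 1% dropout layer into
    the LSTM stack so that family can also produce forecast ensembles.
    """

    width_scale: float = 1.0
    dropout_rate: float = 0.01
    seed: int = 0
    lstm_mc_dropout: bool = False


@dataclass(frozen=True)
class OptConfig:
    """Adam/early-stopping hyperparameters (customary defaults)."""

    lr: float = 1e-3
    epochs: int = 200
    batch_size: int = 128
    patience: int = 10
    min_delta_frac: float = 1e-4
    seed: int = 0


@dataclass(frozen=True)
class NetSpec:
    kind: str
    layer_sizes: tuple
    dropout_rate: float
    dropout_permanent: bool
    loss: str
    input_shape: tuple
    output_shape: tuple = (1,)

    def to_dict(self):
        return asdict(self)


@dataclass
class SurrogateModel:
    """A trainable predictive network plus its bookkeeping.

    ``channel`` names which cytokine a predictor forecasts (index 0..10);
    it is ignored for the regressor and deficit-only families.
    """

    spec: NetSpec
    net: nn.Sequential
    trained: bool = False
    is_stub: bool = False
    channel: int | None = None
    loss_history: dict = field(default_factory=dict)
    norm_stats: NormStats | None = None

    def n_params(self) -> int:
        return self.net.n_params()


def _scaled(widths, scale):
    return tuple(max(1, int(round(w * scale))) for w in widths)


def _make_layers(kind: str, w: tuple, p: float, lstm_mc_dropout: bool,
                 rng: np.random.Generator):
    """Layer stack for a family at explicit hidden widths ``w``."""
    if kind == "lstm_predictor":
        layers = [
            nn.LSTM(N_CYTOKINES, w[0], True, rng=rng),
            nn.LSTM(w[0], w[1], True, rng=rng),
            nn.LSTM(w[1], w[2], False, rng=rng),
        ]
        if lstm_mc_dropout:
            layers.append(nn.Dropout(p))
        layers += [
            nn.Dense(w[2], w[3], "relu", rng=rng),
            nn.Dense(w[3], w[4], "relu", rng=rng),
            nn.Dense(w[4], 1, "linear", rng=rng),
        ]
        dropout_rate = p if lstm_mc_dropout else 0.0
    elif kind == "mlp_predictor":
        layers = [
            nn.TimeDistributedDense(N_CYTOKINES, w[0], "relu", rng=rng),
            nn.Flatten(),
            nn.Dense(WINDOW_LEN * w[0], w[1], "relu", rng=rng),
            nn.Dropout(p),
            nn.Dense(w[1], w[2], "relu", rng=rng),
            nn.Dense(w[2], w[3], "relu", rng=rng),
            nn.Dense(w[3], 1, "linear", rng=rng),
        ]
        dropout_rate = p
    elif kind == "health_regressor":
        layers = [
            nn.Dense(N_CYTOKINES, w[0], "relu", rng=rng),
            nn.Dense(w[0], w[1], "relu", rng=rng),
            nn.Dense(w[1], w[2], "relu", rng=rng),
            nn.Dense(w[2], 1, "linear", rng=rng),
        ]
        dropout_rate = 0.0
    else:  # deficit_only_mlp
        layers = [
            nn.Dense(WINDOW_LEN, w[0], "relu", rng=rng),
            nn.Dropout(p),
            nn.Dense(w[0], w[1], "relu", rng=rng),
            nn.Dense(w[1], w[2], "relu", rng=rng),
            nn.Dense(w[2], 1, "linear", rng=rng),
        ]
        dropout_rate = p
    return layers, dropout_rate


def build(kind: str, config: BuildConfig = BuildConfig(),
          channel: int | None = None) -> SurrogateModel:
    """Construct an untrained surrogate network of the given family."""
    if kind not in KINDS:
        raise ConfigurationError(
            f"unknown kind {kind!r}; expected one of {KINDS}")
    rng = np.random.default_rng(config.seed)
    w = _scaled(_FULL_WIDTHS[kind], config.width_scale)
    layers, dropout_rate = _make_layers(
        kind, w, config.dropout_rate, config.lstm_mc_dropout, rng)
    spec = NetSpec(
        kind=kind,
        layer_sizes=w,
        dropout_rate=dropout_rate,
        dropout_permanent=dropout_rate > 0,
        loss=REQUIRED_LOSS[kind],
        input_shape=_INPUT_SHAPE[kind],
    )
    return SurrogateModel(spec=spec, net=nn.Sequential(layers),
                          channel=channel)


def count_parameters(model: SurrogateModel) -> int:
    """Total trainable parameter count (weights plus biases)."""
    return model.n_params()


def _training_arrays(model: SurrogateModel, ws: WindowSet):
    """Standardized (X, y) pairs appropriate to the model family."""
    stats = ws.norm_stats
    if stats is None:
        raise ContractError("WindowSet has no norm_stats")
    kind = model.spec.kind
    if kind in ("lstm_predictor", "mlp_predictor"):
        if model.channel is None:
            raise ContractError(f"{kind} requires a target channel (0..10)")
        X = stats.standardize_cyto(ws.inputs)
        y = stats.standardize_cyto(ws.labels_next_profile)[:, model.channel]
    elif kind == "health_regressor":
        X = stats.standardize_cyto(ws.inputs[:, -1, :])
        y = stats.standardize_deficit(ws.labels_deficit)
    else:  # deficit_only_mlp
        X = stats.standardize_deficit(ws.deficit_inputs)
        y = stats.standardize_deficit(ws.labels_next_deficit)
    expected = _INPUT_SHAPE[kind]
    if X.shape[1:] != expected:
        raise ContractError(
            f"{kind} expects input shape (N, {expected}); got {X.shape}")
    return X, y


def train(model: SurrogateModel, train_windows: WindowSet,
          val_windows: WindowSet | None = None,
          opt: OptConfig = OptConfig()) -> SurrogateModel:
    """Train a surrogate on standardized window pairs, in place.

    The loss is fixed per family (MAE for the LSTM predictor, MSE for the
    rest); training runs until the early-stopping rule fires and the best
    validation weights are restored. Deterministic given ``opt.seed``.
    """
    X, y = _training_arrays(model, train_windows)
    if val_windows is not None and len(val_windows):
        Xv, yv = _training_arrays(model, val_windows)
    else:
        Xv = yv = None
    history = model.net.fit(
        X, y, Xv, yv,
        loss=model.spec.loss,
        epochs=opt.epochs,
        batch_size=opt.batch_size,
        lr=opt.lr,
        seed=opt.seed,
        patience=opt.patience,
        min_delta_frac=opt.min_delta_frac,
    )
    model.loss_history = history
    model.trained = True
    model.norm_stats = train_windows.norm_stats
    return model


def _check_ready(model: SurrogateModel):
    if not model.trained and not model.is_stub:
        raise NotTrainedError(
            f"model of kind {model.spec.kind!r} is not trained")


def predict(model: SurrogateModel, inputs: np.ndarray) -> np.ndarray:
    """Deterministic prediction (dropout disabled), standardized units."""
    _check_ready(model)
    return model.net.forward(np.asarray(inputs, dtype=float))[:, 0]


def predict_stochastic(model: SurrogateModel, inputs: np.ndarray,
                       sample_seed) -> np.ndarray:
    """Prediction with the permanent dropout layer active.

    ``sample_seed`` may be an integer or a ``numpy.random.Generator``;
    each row of the batch receives an independent dropout mask, so a
    batch of repeated inputs is a Monte-Carlo ensemble. With a zero
    dropout rate this coincides exactly with :func:`predict`.
    """
    _check_ready(model)
    rng = (sample_seed if isinstance(sample_seed, np.random.Generator)
           else np.random.default_rng(sample_seed))
    return model.net.forward(np.asarray(inputs, dtype=float), rng=rng)[:, 0]


def save_model(model: SurrogateModel, path) -> None:
    """Persist spec, weights, norm_stats and loss history (.npz + .json)."""
    import json
    from pathlib import Path
    path = Path(path)
    weights = {f"w{i:03d}": p for i, p in enumerate(model.net.params())}
    np.savez(path.with_suffix(".npz"), **weights)
    meta = {
        "spec": model.spec.to_dict(),
        "channel": model.channel,
        "trained": model.trained,
        "loss_history": model.loss_history,
        "norm_stats": (model.norm_stats.to_dict()
                       if model.norm_stats is not None else None),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_model(path) -> SurrogateModel:
    import json
    from pathlib import Path
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    sd = meta["spec"]
    spec = NetSpec(kind=sd["kind"], layer_sizes=tuple(sd["layer_sizes"]),
                   dropout_rate=sd["dropout_rate"],
                   dropout_permanent=sd["dropout_permanent"],
                   loss=sd["loss"], input_shape=tuple(sd["input_shape"]),
                   output_shape=tuple(sd["output_shape"]))
    lstm_mc = spec.kind == "lstm_predictor" and spec.dropout_rate > 0
    layers, _ = _make_layers(spec.kind, spec.layer_sizes,
                             spec.dropout_rate or 0.01, lstm_mc,
                             np.random.default_rng(0))
    net = nn.Sequential(layers)
    with np.load(path.with_suffix(".npz")) as fh:
        net.set_weights([fh[k] for k in sorted(fh.files)])
    return SurrogateModel(
        spec=spec, net=net, trained=meta["trained"],
        channel=meta["channel"], loss_history=meta["loss_history"],
        norm_stats=(NormStats.from_dict(meta["norm_stats"])
                    if meta["norm_stats"] else None))


def flatten_width(model: SurrogateModel) -> int | None:
    """Length of the flattened intermediate vector (mlp_predictor only)."""
    for i, layer in enumerate(model.net.layers):
        if isinstance(layer, nn.Flatten):
            prev = model.net.layers[i - 1]
            return WINDOW_LEN * prev.n_out
    return None
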