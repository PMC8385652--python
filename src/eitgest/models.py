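"""Classifier architectures: baseline MLPs, CNNs, and dual-input fusion models.

Every architecture is described declaratively by a :class:`ModelSpec` and
materialized by :func:`build_model`. The named presets cover:

* **MLP 1 / MLP 2** (and ``Unreg`` variants without dropout) — the baseline
  fully-connected classifiers on flat frames;
* **CNN 1 / CNN 2** — single-input convolutional classifiers on the N x N
  matrix view, built from conv blocks (3 x 3 convolution, batch norm, ReLU),
  with dilation on the later blocks to widen the receptive field;
* **MLP 3 / MLP 4** (``... dual`` variants) — dual-input fully-connected
  models taking (measurement, reference) pairs, fused early (input
  concatenation) or late (independent branches, then concatenation);
* the **dual-input CNN template family** (``CNN 3 L`` ... ``CNN 9 E D-50``) —
  derived from one template: per branch ``num_convs`` conv blocks with
  ``filters_1``/``dropout_1``, fusion by channel concatenation (early fusion
  concatenates the two input tensors instead), one post-fusion conv block
  with ``filters_2``/``dropout_2``, flatten, softmax classifier. Late-fusion
  branches are structurally identical but do not share weights.

Training uses categorical cross-entropy with Adam and records the per-epoch
test accuracy; the headline metric of a run is the best test accuracy over
epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .frames import GestureDataset, N_GESTURES, dataset_to_tensors
from .results import EvalResult
from .schedule import MeasurementSchedule


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Declarative architecture description."""

    name: str
    family: str  # mlp | cnn | dual_mlp | dual_cnn
    fusion: str = "none"  # none | early | late
    hidden_layers: tuple[int, ...] = ()  # MLP widths
    hidden_dropout: tuple[float, ...] = ()  # dropout rate after each hidden layer
    filters: tuple[int, ...] = ()  # single-input CNN: filters per block
    block_dropout: tuple[float, ...] = ()  # single-input CNN: dropout per block
    dilation: tuple[int, ...] = ()  # single-input CNN: dilation per block
    filters_1: int = 0  # dual CNN template
    filters_2: int = 0
    dropout_1: float = 0.0
    dropout_2: float = 0.0
    num_convs: int = 0
    dilation_rate: int = 1
    n_classes: int = N_GESTURES
    # late-fusion MLPs: number of hidden layers after the fusion point
    post_fusion_layers: int = 0

    def __post_init__(self):
        if self.family.startswith("dual") and self.fusion not in ("early", "late"):
            raise ValueError(f"{self.name}: dual-input families require early or late fusion")
        if not self.family.startswith("dual") and self.fusion != "none":
            raise ValueError(f"{self.name}: fusion is only meaningful for dual-input families")

    @property
    def dual_input(self) -> bool:
        return self.family.startswith("dual")

    @property
    def convolutional(self) -> bool:
        return self.family in ("cnn", "dual_cnn")


def _dual_cnn(name: str, fusion: str, f1: int, f2: int, d1: float, d2: float,
              num_convs: int, dilation_rate: int) -> ModelSpec:
    return ModelSpec(name=name, family="dual_cnn", fusion=fusion,
                     filters_1=f1, filters_2=f2, dropout_1=d1, dropout_2=d2,
                     num_convs=num_convs, dilation_rate=dilation_rate)


#: The dual-input CNN grid: (fusion, filters_1, filters_2, dropout_1,
#: dropout_2, num_convs, dilation_rate) per named variant.
_DUAL_CNN_GRID: dict[str, tuple] = {
    "CNN 3 L": ("late", 64, 64, 0.0, 0.0, 3, 3),
    "CNN 3 L D-25": ("late", 64, 64, 0.25, 0.25, 3, 3),
    "CNN 3 L D-50": ("late", 64, 64, 0.50, 0.50, 3, 3),
    "CNN 4 L": ("late", 64, 64, 0.0, 0.0, 1, 2),
    "CNN 5 L": ("late", 32, 32, 0.0, 0.0, 3, 3),
    "CNN 6 L": ("late", 64, 64, 0.0, 0.0, 1, 1),
    "CNN 6 L D-25": ("late", 64, 64, 0.25, 0.25, 1, 1),
    "CNN 6 L D-50": ("late", 64, 64, 0.50, 0.50, 1, 1),
    "CNN 6 E": ("early", 64, 64, 0.0, 0.0, 1, 3),
    "CNN 6 E D-25": ("early", 64, 64, 0.25, 0.25, 1, 3),
    "CNN 6 E D-50": ("early", 64, 64, 0.50, 0.50, 1, 3),
    "CNN 7 L": ("late", 64, 64, 0.0, 0.0, 2, 2),
    "CNN 8 E": ("early", 64, 64, 0.0, 0.0, 1, 2),
    "CNN 8 E D-25": ("early", 64, 64, 0.25, 0.25, 1, 2),
    "CNN 8 E D-50": ("early", 64, 64, 0.50, 0.50, 1, 2),
    "CNN 9 E": ("early", 128, 128, 0.0, 0.0, 1, 2),
    "CNN 9 E D-25": ("early", 128, 128, 0.25, 0.25, 1, 2),
    "CNN 9 E D-50": ("early", 128, 128, 0.50, 0.50, 1, 2),
}


def _presets() -> dict[str, ModelSpec]:
    p: dict[str, ModelSpec] = {}
    p["MLP 1"] = ModelSpec("MLP 1", "mlp", hidden_layers=(128, 128),
                           hidden_dropout=(0.5, 0.5))
    p["MLP 1 Unreg"] = ModelSpec("MLP 1 Unreg", "mlp", hidden_layers=(128, 128),
                                 hidden_dropout=(0.0, 0.0))
    p["MLP 2"] = ModelSpec("MLP 2", "mlp", hidden_layers=(256, 128, 64),
                           hidden_dropout=(0.5, 0.5, 0.0))
    p["MLP 2 Unreg"] = ModelSpec("MLP 2 Unreg", "mlp", hidden_layers=(256, 128, 64),
                                 hidden_dropout=(0.0, 0.0, 0.0))
    # CNN 1: four 64-filter blocks, 25% dropout after each, dilation 3 on
    # every block but the first
    p["CNN 1"] = ModelSpec("CNN 1", "cnn", filters=(64, 64, 64, 64),
                           block_dropout=(0.25,) * 4, dilation=(1, 3, 3, 3))
    # CNN 2: three 64-filter blocks, no dropout, dilation 2 on the last only
    p["CNN 2"] = ModelSpec("CNN 2", "cnn", filters=(64, 64, 64),
                           block_dropout=(0.0,) * 3, dilation=(1, 1, 2))
    # MLP 3: three hidden 128-neuron layers; monolithic (early-fused) input
    p["MLP 3"] = ModelSpec("MLP 3", "dual_mlp", fusion="early",
                           hidden_layers=(128, 128, 128),
                           hidden_dropout=(0.0,) * 3)
    # MLP 3 dual: first two layers duplicated per branch, fusion, then the
    # last hidden layer and the classifier
    p["MLP 3 dual"] = ModelSpec("MLP 3 dual", "dual_mlp", fusion="late",
                                hidden_layers=(128, 128, 128),
                                hidden_dropout=(0.0,) * 3, post_fusion_layers=1)
    # MLP 4: monolithic input on the MLP 2 architecture
    p["MLP 4"] = ModelSpec("MLP 4", "dual_mlp", fusion="early",
                           hidden_layers=(256, 128, 64),
                           hidden_dropout=(0.5, 0.5, 0.0))
    # MLP 4 dual: all three hidden layers duplicated, fusion, classifier
    p["MLP 4 dual"] = ModelSpec("MLP 4 dual", "dual_mlp", fusion="late",
                                hidden_layers=(256, 128, 64),
                                hidden_dropout=(0.5, 0.5, 0.0), post_fusion_layers=0)
    for name, row in _DUAL_CNN_GRID.items():
        p[name] = _dual_cnn(name, *row)
    return p


PRESETS: dict[str, ModelSpec] = _presets()


def preset(name: str) -> ModelSpec:
    """Look up a named architecture preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _mlp_stack(widths, dropouts, n_in, rng) -> tuple[list[nn.Layer], int]:
    layers: list[nn.Layer] = []
    for w, dr in zip(widths, dropouts):
        layers.append(nn.Dense(n_in, w, rng))
        layers.append(nn.ReLU())
        if dr > 0:
            layers.append(nn.Dropout(dr, rng))
        n_in = w
    return layers, n_in


def _conv_block(n_in, filters, dilation, dropout, rng) -> tuple[list[nn.Layer], int]:
    layers: list[nn.Layer] = [
        nn.Conv2D(n_in, filters, rng, dilation=dilation),
        nn.BatchNorm(filters),
        nn.ReLU(),
    ]
    if dropout > 0:
        layers.append(nn.Dropout(dropout, rng))
    return layers, filters


def build_model(spec: ModelSpec, schedule: MeasurementSchedule, seed: int = 0) -> nn.Network:
    """Instantiate a trainable network for ``spec``.

    MLP families take flat frames (``N (N - 3)`` values); CNN families take
    the ``N x N x 1`` matrix view (``x 2`` stacked for early fusion). All
    networks end in a 12-way softmax classification layer.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_electrodes
    d = schedule.n_measurements

    if spec.family == "mlp":
        layers, width = _mlp_stack(spec.hidden_layers, spec.hidden_dropout, d, rng)
        layers.append(nn.Dense(width, spec.n_classes, rng))
        return nn.Sequential(layers)

    if spec.family == "cnn":
        layers: list[nn.Layer] = []
        ch = 1
        for f, dil, dr in zip(spec.filters, spec.dilation, spec.block_dropout):
            block, ch = _conv_block(ch, f, dil, dr, rng)
            layers.extend(block)
        layers.append(nn.Flatten())
        layers.append(nn.Dense(n * n * ch, spec.n_classes, rng))
        return nn.Sequential(layers)

    if spec.family == "dual_mlp":
        if spec.fusion == "early":
            head, width = _mlp_stack(spec.hidden_layers, spec.hidden_dropout, 2 * d, rng)
            head.append(nn.Dense(width, spec.n_classes, rng))
            return nn.DualNetwork(nn.Sequential([]), nn.Sequential([]), nn.Sequential(head))
        k = len(spec.hidden_layers) - spec.post_fusion_layers
        branch_widths = spec.hidden_layers[:k]
        branch_drop = spec.hidden_dropout[:k]
        branches = []
        for _ in range(2):
            layers, width = _mlp_stack(branch_widths, branch_drop, d, rng)
            branches.append(nn.Sequential(layers))
        head_layers, width = _mlp_stack(
            spec.hidden_layers[k:], spec.hidden_dropout[k:], 2 * width, rng
        )
        head_layers.append(nn.Dense(width, spec.n_classes, rng))
        return nn.DualNetwork(branches[0], branches[1], nn.Sequential(head_layers))

    if spec.family == "dual_cnn":
        def stage(n_in):
            layers: list[nn.Layer] = []
            ch = n_in
            for _ in range(spec.num_convs):
                block, ch = _conv_block(ch, spec.filters_1, spec.dilation_rate,
                                        spec.dropout_1, rng)
                layers.extend(block)
            return layers, ch

        if spec.fusion == "early":
            pre, ch = stage(2)
            head = pre
        else:
            layers_a, ch = stage(1)
            layers_b, _ = stage(1)
            ba, bb = nn.Sequential(layers_a), nn.Sequential(layers_b)
            head = []
            ch = 2 * ch
        post, ch = _conv_block(ch, spec.filters_2, spec.dilation_rate, spec.dropout_2, rng)
        head = head + post + [nn.Flatten(), nn.Dense(n * n * ch, spec.n_classes, rng)]
        if spec.fusion == "early":
            return nn.DualNetwork(nn.Sequential([]), nn.Sequential([]), nn.Sequential(head))
        return nn.DualNetwork(ba, bb, nn.Sequential(head))

    raise ValueError(f"unknown model family {spec.family!r}")


# ---------------------------------------------------------------------------
# input preparation
# ---------------------------------------------------------------------------

def prepare_inputs(spec: ModelSpec, ds: GestureDataset,
                   references: np.ndarray | None = None):
    """Arrange a dataset (and optional reference vectors) as model input."""
    if spec.dual_input and references is None:
        raise ValueError(f"{spec.name} is dual-input and needs reference frames")
    if spec.convolutional:
        x = dataset_to_tensors(ds)[..., None]
        if spec.dual_input:
            from .frames import values_to_matrix  # local import to avoid cycle at module load

            n, c = ds.schedule.n_electrodes, ds.schedule.cycle_length
            r = np.zeros((len(ds), n, n))
            r[:, :, :c] = references.reshape(len(ds), n, c)
            return (x, r[..., None])
        return x
    if spec.dual_input:
        return (ds.values, references)
    return ds.values


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam on categorical cross-entropy."""

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def train(
    model: nn.Network,
    train_x,
    train_y: np.ndarray,
    test_x,
    test_y: np.ndarray,
    config: TrainConfig,
    model_name: str = "",
    split: str = "",
    calibration: str = "none",
) -> EvalResult:
    """Train ``model`` and record the per-epoch test trajectory.

    ``train_x``/``test_x`` are arrays, or (measurement, reference) tuples for
    dual-input models. Labels are integers 0..11.
    """
    n_train = train_x[0].shape[0] if isinstance(train_x, tuple) else train_x.shape[0]
    n_test = test_x[0].shape[0] if isinstance(test_x, tuple) else test_x.shape[0]
    if n_train == 0 or n_test == 0:
        raise ValueError("train and test sets must be non-empty")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    result = EvalResult(model=model_name, split=split, calibration=calibration,
                        seed=config.seed)

    def batch(x, idx):
        return tuple(a[idx] for a in x) if isinstance(x, tuple) else x[idx]

    for _ in range(config.epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for lo in range(0, n_train, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            logits = model.forward(batch(train_x, idx), train=True)
            loss, grad = nn.softmax_cross_entropy(logits, train_y[idx])
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        result.train_loss.append(epoch_loss / n_train)

        logits = model.predict_logits(test_x)
        loss, _ = nn.softmax_cross_entropy(logits, test_y)
        result.test_loss.append(loss)
        result.test_accuracy.append(nn.accuracy(logits, test_y))
    return result


# ---------------------------------------------------------------------------
# reference SVM hook
# ---------------------------------------------------------------------------

def svm_baseline(kernel: str = "rbf", degree: int = 3):
    """Thin scikit-learn SVC hook for the classical baselines.

    ``kernel`` in {linear, rbf, poly}; ``degree`` applies to the polynomial
    kernel (the customary grid uses degrees 2, 3, and 6). All other
    parameters stay at library defaults.
    """
    from sklearn.svm import SVC

    if kernel not in ("linear", "rbf", "poly"):
        raise ValueError(f"unsupported kernel {kernel!r}")
    return SVC(kernel=kernel, degree=degree)
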