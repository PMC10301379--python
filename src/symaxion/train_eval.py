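"""Subject-dependent training and evaluation.

A single subject's epochs are split 7:3 (stratified by class), the classifier
is trained with plain SGD and cross-entropy for a fixed number of epochs with
multiplicative learning-rate decay, and performance is reported as accuracy,
macro recall and macro F1 (percent) together with the confusion matrix (rows
are true classes, columns predicted).  The module also provides the feature-
combination ablation, classical baselines on flattened fused features, and
the per-band/per-class mean-DE topography export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import fusion as fusion_mod
from .autodiff import SGD, cross_entropy
from .features import (
    DEFAULT_BANDS,
    BandSpec,
    EpochSet,
    FeatureStack,
    bandpass,
    de_stack,
    differential_entropy,
    normalize,
    oef_stack,
    qsm_stack,
    ssm_stack,
)
from .model import ModelConfig, MultiAxisClassifier
from .montage import ElectrodeLayout, build_default_layout

logger = logging.getLogger("symaxion")


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    """Optimisation settings (SGD, lr 0.01 with 1% per-epoch decay, 30 epochs)."""

    optimizer: str = "sgd"
    learning_rate: float = 0.01
    momentum: float = 0.9
    lr_decay: float = 0.01
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 30
    split_ratio: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must lie in (0, 1)")
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0 or self.lr_decay < 0:
            raise ValueError("hyperparameters must be positive")
        if self.optimizer.lower() != "sgd":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class EvalReport:
    accuracy: float  # percent
    macro_recall: float  # percent
    macro_f1: float  # percent
    confusion: np.ndarray  # counts, rows = true
    class_names: tuple[str, ...]
    n_test: int

    @property
    def normalized_confusion(self) -> np.ndarray:
        row_sums = self.confusion.sum(axis=1, keepdims=True)
        return self.confusion / np.maximum(row_sums, 1)


def split(labels: np.ndarray, config: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    """Stratified, seed-reproducible train/test index split."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 epochs to split")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=config.split_ratio,
        stratify=labels,
        random_state=config.seed,
        shuffle=True,
    )
    return np.sort(train_idx), np.sort(test_idx)


def extract_feature_stacks(
    epochs: EpochSet,
    layout: ElectrodeLayout | None = None,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    kinds: tuple[str, ...] = fusion_mod.FUSION_ORDER,
    normalized: bool = True,
) -> dict[str, FeatureStack]:
    """Compute the requested symmetric feature stacks (normalised by default)."""
    if layout is None:
        layout = build_default_layout()
    stacks: dict[str, FeatureStack] = {}
    need_oef = any(k.endswith("OEF") for k in kinds)
    need_de = any(k.endswith("DE") for k in kinds) or "DE" in kinds
    base: dict[str, FeatureStack] = {}
    if need_oef:
        base["OEF"] = oef_stack(epochs, layout)
    if need_de:
        base["DE"] = de_stack(epochs, bands, layout)
    for kind in kinds:
        if kind in ("OEF", "DE"):
            stacks[kind] = base[kind]
        elif kind.startswith("SSM_"):
            stacks[kind] = ssm_stack(base[kind[4:]])
        elif kind.startswith("QSM_"):
            stacks[kind] = qsm_stack(base[kind[4:]])
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
    if normalized:
        stacks = {k: normalize(s) for k, s in stacks.items()}
    return stacks


def prepare_fused(
    epochs: EpochSet,
    layout: ElectrodeLayout | None = None,
    kinds: tuple[str, ...] = fusion_mod.FUSION_ORDER,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    target_depth: int = fusion_mod.TARGET_DEPTH,
    spatial_size: int = fusion_mod.SPATIAL_SIZE,
) -> np.ndarray:
    """Epochs -> fused network input (n, target_depth * len(kinds), S, S)."""
    stacks = extract_feature_stacks(epochs, layout, bands, kinds)
    return fusion_mod.prepare(stacks, kinds, target_depth, spatial_size)


def train(
    x_train: np.ndarray,
    y_train: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[MultiAxisClassifier, list[float]]:
    """Train the classifier; returns the model and the per-epoch loss history."""
    x_train = np.asarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train)
    model = MultiAxisClassifier(model_config, seed=train_config.seed)
    opt = SGD(
        model.parameters(),
        train_config.learning_rate,
        train_config.weight_decay,
        train_config.momentum,
    )
    rng = np.random.default_rng(train_config.seed)
    history: list[float] = []
    for epoch in range(train_config.epochs):
        opt.lr = train_config.learning_rate * (1.0 - train_config.lr_decay) ** epoch
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), train_config.batch_size):
            batch = order[start : start + train_config.batch_size]
            opt.zero_grad()
            loss = cross_entropy(model.forward(x_train[batch]), y_train[batch])
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}: model={model_config}, train={train_config}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        logger.info("epoch %d/%d  lr=%.4g  loss=%.4f", epoch + 1, train_config.epochs, opt.lr, history[-1])
    return model, history


def evaluate(
    model: MultiAxisClassifier,
    x_test: np.ndarray,
    y_test: np.ndarray,
    class_names: tuple[str, ...],
) -> EvalReport:
    """Accuracy, macro recall, macro F1 (all %) and the confusion matrix."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(np.asarray(x_test, dtype=np.float32))
    return report_from_predictions(y_test, pred, class_names)


def report_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, class_names: tuple[str, ...]
) -> EvalReport:
    labels = np.arange(len(class_names))
    cm = sk_confusion(y_true, y_pred, labels=labels)
    accuracy = 100.0 * np.trace(cm) / cm.sum()
    recalls = np.diag(cm) / np.maximum(cm.sum(axis=1), 1)
    precisions = np.diag(cm) / np.maximum(cm.sum(axis=0), 1)
    f1 = np.where(
        precisions + recalls > 0, 2 * precisions * recalls / np.maximum(precisions + recalls, 1e-12), 0.0
    )
    return EvalReport(
        accuracy=float(accuracy),
        macro_recall=float(100.0 * recalls.mean()),
        macro_f1=float(100.0 * f1.mean()),
        confusion=cm,
        class_names=tuple(class_names),
        n_test=int(cm.sum()),
    )


def run_experiment(
    epochs: EpochSet,
    model_config: ModelConfig,
    train_config: TrainConfig,
    kinds: tuple[str, ...] = fusion_mod.FUSION_ORDER,
    layout: ElectrodeLayout | None = None,
    fused: np.ndarray | None = None,
) -> tuple[EvalReport, list[float]]:
    """Features -> fusion -> split -> train -> evaluate, in one call."""
    if fused is None:
        fused = prepare_fused(epochs, layout, kinds, spatial_size=model_config.spatial)
    train_idx, test_idx = split(epochs.labels, train_config)
    model, history = train(fused[train_idx], epochs.labels[train_idx], model_config, train_config)
    report = evaluate(model, fused[test_idx], epochs.labels[test_idx], epochs.class_names)
    return report, history


def run_ablation(
    subsets: list[tuple[str, ...]],
    epochs: EpochSet,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seeds: tuple[int, ...] = (0,),
    layout: ElectrodeLayout | None = None,
) -> pd.DataFrame:
    """Mean test accuracy per feature-kind subset (Table-5-style comparison).

    Feature stacks are extracted once; each subset reuses its slices of the
    fused tensor.  One row per subset with the per-seed accuracies and mean.
    """
    if any(len(s) == 0 for s in subsets):
        raise ValueError("empty feature subset")
    if layout is None:
        layout = build_default_layout()
    all_kinds = tuple(dict.fromkeys(k for s in subsets for k in s))
    stacks = extract_feature_stacks(epochs, layout, kinds=all_kinds)
    prepared = {
        k: fusion_mod.prepare({k: stacks[k]}, (k,), spatial_size=model_config.spatial)
        for k in all_kinds
    }
    rows = []
    for subset in subsets:
        fused = np.concatenate([prepared[k] for k in subset], axis=1)
        accs = []
        for seed in seeds:
            mc = ModelConfig(**{**model_config.__dict__, "in_depth": fused.shape[1]})
            tc = TrainConfig(**{**train_config.__dict__, "seed": seed})
            report, _ = run_experiment(epochs, mc, tc, kinds=subset, layout=layout, fused=fused)
            accs.append(report.accuracy)
        rows.append(
            {
                "combination": "+".join(subset),
                "n_kinds": len(subset),
                "mean_accuracy": float(np.mean(accs)),
                "std_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "accuracies": accs,
            }
        )
    return pd.DataFrame(rows)


def run_baselines(
    fused: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Classical baselines on flattened fused features, on the identical split."""
    x = np.asarray(fused, dtype=np.float32).reshape(len(fused), -1)
    y = np.asarray(labels)
    models = {
        "SVM (Linear)": SVC(kernel="linear", random_state=seed),
        "GNB (Default)": GaussianNB(),
        "KNN (N = 5)": KNeighborsClassifier(n_neighbors=5),
    }
    rows = []
    for name, clf in models.items():
        clf.fit(x[train_idx], y[train_idx])
        acc = 100.0 * float(np.mean(clf.predict(x[test_idx]) == y[test_idx]))
        rows.append({"model": name, "accuracy": acc, "n_test": len(test_idx)})
    return pd.DataFrame(rows)


def band_topography(
    epochs: EpochSet,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    layout: ElectrodeLayout | None = None,
    by_class: bool = True,
) -> pd.DataFrame:
    """Mean DE per electrode, band and (optionally) class, as a tidy table."""
    if layout is None:
        layout = build_default_layout()
    groups = (
        [(cls, epochs.labels == ci) for ci, cls in enumerate(epochs.class_names)]
        if by_class
        else [("all", np.ones(epochs.n_epochs, dtype=bool))]
    )
    rows = []
    for band in bands:
        de = differential_entropy(bandpass(epochs, band).data)  # epochs x channels
        for cls, sel in groups:
            mean_de = de[sel].mean(axis=0)
            for ch, val in zip(layout.names, mean_de):
                rows.append({"class": cls, "band": band.name, "channel": ch, "mean_de": float(val)})
    return pd.DataFrame(rows)


def plot_topography(table: pd.DataFrame, layout: ElectrodeLayout | None = None, path=None):
    """Optional scalp-grid rendering of a band_topography table (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .montage import vector_to_grid

    if layout is None:
        layout = build_default_layout()
    classes = table["class"].unique()
    bands = table["band"].unique()
    fig, axes = plt.subplots(len(classes), len(bands), figsize=(3 * len(bands), 3 * len(classes)), squeeze=False)
    for i, cls in enumerate(classes):
        for j, band in enumerate(bands):
            sub = table[(table["class"] == cls) & (table["band"] == band)]
            vec = sub.set_index("channel").loc[list(layout.names), "mean_de"].to_numpy()
            axes[i][j].imshow(vector_to_grid(vec, layout), cmap="RdBu_r")
            axes[i][j].set_title(f"{cls} / {band}", fontsize=8)
            axes[i][j].axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
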