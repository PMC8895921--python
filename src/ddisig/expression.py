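"""Feature generation model: compound features -> 978-gene expression signature.

A two-branch dense network maps a Morgan fingerprint and a scaled property
vector to a predicted differential-expression signature over the 978
landmark genes.  Each branch passes through its own hidden layer; the two
latent representations are concatenated and projected to the 978-gene
output.  Training minimizes mean-squared error with decoupled L2 weight
decay, optional batch normalization on the branch activations, and a
cosine-annealed learning rate with warm restarts.  Model selection uses
k-fold cross-validation in which every compound is predicted exactly once
out-of-fold; the deployed model is then refit on the full reference set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold

from . import _autodiff as ad
from .chem import N_LANDMARK_GENES

__all__ = [
    "ExpressionModelConfig",
    "ExpressionModel",
    "mse_loss",
    "cosine_annealing_lr",
    "pearson_correlation",
    "per_compound_pearson",
    "train_expression_model",
    "predict_expression",
]


@dataclass
class ExpressionModelConfig:
    """Hyperparameters of the feature generation model.

    Widths follow the two-branch layout (fingerprint branch, property
    branch, merged output of 978).  The learning rate follows
    lr(t) = lr_min + (lr_max - lr_min)(1 + cos(pi (t mod T)/T))/2 per epoch.
    """

    n_fingerprint_bits: int = 2048
    n_properties: int = 100
    n_genes: int = N_LANDMARK_GENES
    fingerprint_width: int = 512
    property_width: int = 64
    l2: float = 1e-5
    batch_norm: bool = True
    epochs: int = 200
    batch_size: int = 64
    lr_max: float = 1e-3
    lr_min: float = 1e-5
    lr_period: int = 50
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_fingerprint_bits", "n_properties", "n_genes",
                     "fingerprint_width", "property_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lr_min > self.lr_max:
            raise ValueError("lr_min must be <= lr_max")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_period <= 0:
            raise ValueError("lr_period must be > 0")


def mse_loss(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Mean squared error averaged over every element of the batch."""
    y_pred = np.asarray(y_pred, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.float64)
    if y_pred.shape != y_true.shape:
        raise ValueError(f"shape mismatch: {y_pred.shape} vs {y_true.shape}")
    return float(np.mean((y_pred - y_true) ** 2))


def cosine_annealing_lr(step: int, config) -> float:
    """Cosine-annealed learning rate with warm restarts every ``lr_period`` steps.

    ``config`` is any object with ``lr_max``, ``lr_min`` and ``lr_period``
    attributes (both model configs qualify).
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    t = step % config.lr_period
    return config.lr_min + 0.5 * (config.lr_max - config.lr_min) * (
        1.0 + np.cos(np.pi * t / config.lr_period)
    )


def pearson_correlation(pred: np.ndarray, true: np.ndarray) -> float:
    """Product-moment correlation between two equal-length vectors."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    true = np.asarray(true, dtype=np.float64).ravel()
    if pred.shape != true.shape or pred.size < 2:
        raise ValueError("pearson_correlation needs two equal-length vectors (n >= 2)")
    if np.std(pred) == 0 or np.std(true) == 0:
        raise ValueError("pearson_correlation undefined for zero-variance input")
    return float(stats.pearsonr(pred, true).statistic)


def per_compound_pearson(pred: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Row-wise (per-compound, across genes) Pearson r for two matrices."""
    pred = np.atleast_2d(np.asarray(pred, dtype=np.float64))
    true = np.atleast_2d(np.asarray(true, dtype=np.float64))
    if pred.shape != true.shape:
        raise ValueError("shape mismatch")
    return np.array([pearson_correlation(p, t) for p, t in zip(pred, true)])


class _BatchNorm:
    """1-D batch normalization with running statistics for inference."""

    def __init__(self, width: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = ad.param(np.ones(width))
        self.beta = ad.param(np.zeros(width))
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: ad.Tensor, train: bool) -> ad.Tensor:
        if train:
            m = ad.mean(x, axis=0, keepdims=True)
            centered = x - m
            v = ad.mean(centered * centered, axis=0, keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * m.data.ravel()
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * v.data.ravel()
            )
            inv = ad.powc(v + self.eps, -0.5)
            return centered * inv * self.gamma + self.beta
        xn = (x - self.running_mean) * (1.0 / np.sqrt(self.running_var + self.eps))
        return xn * self.gamma + self.beta

    def params(self) -> list[ad.Tensor]:
        return [self.gamma, self.beta]


class ExpressionModel:
    """Two-branch dense network with a 978-gene linear output head."""

    def __init__(self, config: ExpressionModelConfig, rng: np.random.Generator):
        c = config
        self.config = c
        self.W_fp = ad.param((c.n_fingerprint_bits, c.fingerprint_width), rng=rng)
        self.b_fp = ad.param(np.zeros(c.fingerprint_width))
        self.W_pr = ad.param((c.n_properties, c.property_width), rng=rng)
        self.b_pr = ad.param(np.zeros(c.property_width))
        merged = c.fingerprint_width + c.property_width
        self.W_out = ad.param((merged, c.n_genes), rng=rng)
        self.b_out = ad.param(np.zeros(c.n_genes))
        self.bn_fp = _BatchNorm(c.fingerprint_width) if c.batch_norm else None
        self.bn_pr = _BatchNorm(c.property_width) if c.batch_norm else None

    def params(self) -> list[ad.Tensor]:
        ps = [self.W_fp, self.b_fp, self.W_pr, self.b_pr, self.W_out, self.b_out]
        if self.bn_fp is not None:
            ps += self.bn_fp.params() + self.bn_pr.params()
        return ps

    def forward(self, fp: np.ndarray, props: np.ndarray, train: bool = False) -> ad.Tensor:
        c = self.config
        fp = np.atleast_2d(np.asarray(fp, dtype=np.float64))
        props = np.atleast_2d(np.asarray(props, dtype=np.float64))
        if fp.shape[1] != c.n_fingerprint_bits:
            raise ValueError(
                f"fingerprint length {fp.shape[1]} != {c.n_fingerprint_bits}"
            )
        if props.shape[1] != c.n_properties:
            raise ValueError(f"property length {props.shape[1]} != {c.n_properties}")
        a = ad.matmul(ad.constant(fp), self.W_fp) + self.b_fp
        if self.bn_fp is not None:
            a = self.bn_fp(a, train)
        a = ad.relu(a)
        b = ad.matmul(ad.constant(props), self.W_pr) + self.b_pr
        if self.bn_pr is not None:
            b = self.bn_pr(b, train)
        b = ad.relu(b)
        merged = ad.concat([a, b], axis=1)
        return ad.matmul(merged, self.W_out) + self.b_out

    def predict(self, fp: np.ndarray, props: np.ndarray) -> np.ndarray:
        """Deterministic inference-mode prediction (running batch-norm stats)."""
        return self.forward(fp, props, train=False).data

    # ---- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {
            "W_fp": self.W_fp.data, "b_fp": self.b_fp.data,
            "W_pr": self.W_pr.data, "b_pr": self.b_pr.data,
            "W_out": self.W_out.data, "b_out": self.b_out.data,
        }
        if self.bn_fp is not None:
            arrays.update(
                bn_fp_gamma=self.bn_fp.gamma.data, bn_fp_beta=self.bn_fp.beta.data,
                bn_fp_mean=self.bn_fp.running_mean, bn_fp_var=self.bn_fp.running_var,
                bn_pr_gamma=self.bn_pr.gamma.data, bn_pr_beta=self.bn_pr.beta.data,
                bn_pr_mean=self.bn_pr.running_mean, bn_pr_var=self.bn_pr.running_var,
            )
        np.savez(directory / "expression_model.npz", **arrays)
        import json

        (directory / "config.json").write_text(json.dumps(vars(self.config), indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ExpressionModel":
        import json

        directory = Path(directory)
        config = ExpressionModelConfig(**json.loads((directory / "config.json").read_text()))
        model = cls(config, rng=np.random.default_rng(0))
        with np.load(directory / "expression_model.npz") as z:
            model.W_fp.data = z["W_fp"]; model.b_fp.data = z["b_fp"]
            model.W_pr.data = z["W_pr"]; model.b_pr.data = z["b_pr"]
            model.W_out.data = z["W_out"]; model.b_out.data = z["b_out"]
            if model.bn_fp is not None:
                model.bn_fp.gamma.data = z["bn_fp_gamma"]; model.bn_fp.beta.data = z["bn_fp_beta"]
                model.bn_fp.running_mean = z["bn_fp_mean"]; model.bn_fp.running_var = z["bn_fp_var"]
                model.bn_pr.gamma.data = z["bn_pr_gamma"]; model.bn_pr.beta.data = z["bn_pr_beta"]
                model.bn_pr.running_mean = z["bn_pr_mean"]; model.bn_pr.running_var = z["bn_pr_var"]
        return model


def _fit_one(
    model: ExpressionModel,
    fp: np.ndarray,
    props: np.ndarray,
    y: np.ndarray,
    config: ExpressionModelConfig,
    rng: np.random.Generator,
    eval_data: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> list[dict]:
    opt = ad.Adam(model.params(), lr=config.lr_max, weight_decay=config.l2)
    n = fp.shape[0]
    history = []
    for epoch in range(config.epochs):
        lr = cosine_annealing_lr(epoch, config)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = model.forward(fp[idx], props[idx], train=True)
            diff = pred - ad.constant(y[idx])
            loss = ad.mean(diff * diff)
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            epoch_loss += float(loss.data)
            n_batches += 1
        entry = {"epoch": epoch, "lr": float(lr), "loss": epoch_loss / max(n_batches, 1)}
        if eval_data is not None:
            efp, epr, ey = eval_data
            pred = model.predict(efp, epr)
            entry["pearson"] = float(np.mean(per_compound_pearson(pred, ey)))
        history.append(entry)
    return history


def train_expression_model(
    fingerprints: np.ndarray,
    properties: np.ndarray,
    signatures: np.ndarray,
    config: ExpressionModelConfig,
) -> tuple[ExpressionModel, dict]:
    """Cross-validated training, then a final refit on the full dataset.

    With ``config.folds >= 2``, every compound is predicted exactly once by
    the fold that held it out; the returned history carries the per-epoch
    loss curves of each fold, the out-of-fold predictions, and their mean
    per-compound Pearson r.  The returned model is refit on all compounds.
    """
    fp = np.asarray(fingerprints, dtype=np.float64)
    props = np.asarray(properties, dtype=np.float64)
    y = np.asarray(signatures, dtype=np.float64)
    if not (fp.shape[0] == props.shape[0] == y.shape[0]):
        raise ValueError("fingerprints, properties and signatures must align by row")
    for name, arr in (("fingerprints", fp), ("properties", props), ("signatures", y)):
        if np.isnan(arr).any():
            raise ValueError(f"NaN values in {name}; clean inputs before training")
    history: dict = {"folds": [], "final": []}
    if config.folds >= 2:
        if fp.shape[0] < config.folds:
            raise ValueError("need at least `folds` compounds for cross-validation")
        kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
        oof = np.zeros_like(y)
        for fold_id, (tr, te) in enumerate(kf.split(fp)):
            rng = np.random.default_rng([config.seed, fold_id])
            fold_model = ExpressionModel(config, rng=rng)
            fold_hist = _fit_one(
                fold_model, fp[tr], props[tr], y[tr], config, rng,
                eval_data=(fp[te], props[te], y[te]),
            )
            oof[te] = fold_model.predict(fp[te], props[te])
            history["folds"].append(fold_hist)
        r = per_compound_pearson(oof, y)
        history["oof_predictions"] = oof
        history["oof_pearson_per_compound"] = r
        history["oof_pearson_mean"] = float(np.mean(r))
    rng = np.random.default_rng([config.seed, config.folds])
    model = ExpressionModel(config, rng=rng)
    history["final"] = _fit_one(model, fp, props, y, config, rng)
    return model, history


def predict_expression(
    model: ExpressionModel,
    fingerprints: np.ndarray,
    properties: np.ndarray,
    gene_symbols: list[str] | None = None,
) -> np.ndarray:
    """Predict expression signatures; single vectors and batches agree row-wise."""
    return model.predict(fingerprints, properties)
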