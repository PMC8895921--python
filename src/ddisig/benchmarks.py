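"""Planted-world recovery benchmarks.

These are the package's standard self-checks: train each model on a
synthetic world whose generating structure matches the model's assumptions
and measure how well the planted signal is recovered.  The worlds are fixed
(500 compounds at noise 0.5 for the expression world; 60 drugs and 8 side
effects for the DDI world) and the model configurations below are the
package defaults for these problem sizes.  Both the test suite and the
reproduction script call into this module so they measure the same thing.
"""

from __future__ import annotations

import numpy as np

from .ddi import DDIModelConfig, predict_scores, train_ddi_model
from .evaluation import per_side_effect_report
from .expression import ExpressionModelConfig, train_expression_model
from .pipeline import prepare_split
from .synthetic import (
    DDIWorld,
    DDIWorldConfig,
    ExpressionWorldConfig,
    generate_ddi_world,
    generate_expression_world,
)
from .triplets import SplitSpec

__all__ = [
    "expression_recovery_config",
    "expression_recovery",
    "ddi_recovery_config",
    "ddi_recovery",
]

# Drug-holdout fraction for the unseen-drug regimes: 20% of drugs, so the
# both-unseen test set has enough pairs to estimate a ranking metric.
DRUG_HOLDOUT_FRACTION = 0.2


def expression_recovery_config(seed: int = 7) -> tuple[ExpressionWorldConfig, ExpressionModelConfig]:
    world_cfg = ExpressionWorldConfig(seed=seed)  # n=500, noise_sd=0.5, linear map
    model_cfg = ExpressionModelConfig(
        n_fingerprint_bits=world_cfg.n_fingerprint_bits,
        n_properties=world_cfg.n_properties,
        fingerprint_width=256,
        property_width=128,
        batch_norm=False,
        epochs=150,
        batch_size=64,
        lr_max=5e-3,
        lr_min=1e-4,
        lr_period=150,
        folds=3,
        seed=seed,
    )
    return world_cfg, model_cfg


def expression_recovery(seed: int = 7, noise_sd: float | None = None) -> dict:
    """Train the feature generator on the planted linear world.

    Returns the cross-validated out-of-fold mean per-compound Pearson r
    between predicted and true signatures.
    """
    world_cfg, model_cfg = expression_recovery_config(seed)
    if noise_sd is not None:
        world_cfg.noise_sd = noise_sd
    world = generate_expression_world(world_cfg)
    _, history = train_expression_model(
        world.fingerprints, world.properties, world.signatures, model_cfg
    )
    return {
        "oof_pearson_mean": history["oof_pearson_mean"],
        "n_compounds": world_cfg.n_compounds,
        "noise_sd": world_cfg.noise_sd,
    }


def ddi_recovery_config(seed: int = 7) -> tuple[DDIWorldConfig, DDIModelConfig]:
    world_cfg = DDIWorldConfig(seed=seed)  # 60 drugs, 8 side effects, 20% positive
    model_cfg = DDIModelConfig(
        hidden_width=256,
        reduced_width=64,
        embedding_width=32,
        epochs=40,
        lr_period=40,
        seed=seed,
    )
    return world_cfg, model_cfg


def ddi_recovery(
    seed: int = 7,
    regime: str = "unseen_interaction",
    gates_open: bool = False,
    head: str = "transe",
    world: DDIWorld | None = None,
) -> dict:
    """Train the DDI scorer on the planted world and evaluate one regime.

    Returns the per-side-effect macro metrics on the held-out test set.
    Pass ``gates_open=True`` or ``head="mlp"`` for the two ablations.
    A pre-generated world may be passed to share it across calls.
    """
    world_cfg, model_cfg = ddi_recovery_config(seed)
    model_cfg.gates_open = gates_open
    model_cfg.head = head
    if world is None:
        world = generate_ddi_world(world_cfg)
    spec = SplitSpec(
        regime=regime, seed=seed, drug_holdout_fraction=DRUG_HOLDOUT_FRACTION
    )
    train_ds, val_ds, test_ds = prepare_split(world.dataset, spec)
    model, history = train_ddi_model(train_ds, world.expressions, model_cfg)
    scores = predict_scores(model, test_ds, world.expressions)
    val_scores = predict_scores(model, val_ds, world.expressions)
    _, macro = per_side_effect_report(
        scores, test_ds, threshold_scores=val_scores, threshold_dataset=val_ds
    )
    macro.update(
        regime=regime,
        n_train=len(train_ds),
        n_test=len(test_ds),
        final_loss=history["loss"][-1],
        train_pos_mean_score=history["train_pos_mean_score"],
        train_neg_mean_score=history["train_neg_mean_score"],
    )
    return macro
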