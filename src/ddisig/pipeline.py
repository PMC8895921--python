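"""End-to-end orchestration: data -> splits -> training -> scores -> metrics.

A run is described by a flat YAML/dict config.  Inputs are either synthetic
world sections (``expression_world``, ``ddi_world``) or paths to triplet and
expression TSVs.  Every stage writes its artifacts under the output
directory and the manifest records seeds, dataset sizes and SHA-256 digests
of the written files, so identical configs reproduce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ddi import DDIModelConfig, predict_scores, train_ddi_model
from .evaluation import per_side_effect_report
from .expression import ExpressionModelConfig, train_expression_model
from .io import write_expression_tsv
from .synthetic import (
    DDIWorldConfig,
    ExpressionWorldConfig,
    generate_ddi_world,
    generate_expression_world,
)
from .triplets import (
    SplitSpec,
    TripletDataset,
    read_triplets,
    sample_negatives,
    split_unseen_drugs,
    split_unseen_interactions,
    write_triplets,
)

__all__ = ["validate_config", "run_pipeline", "prepare_split"]

log = logging.getLogger("ddisig")

_KNOWN_KEYS = {
    "seed", "out_dir", "log_level", "expression_world", "ddi_world",
    "triplets_path", "expressions_path", "split", "expression_model",
    "ddi_model", "evaluation",
}


def validate_config(config: dict) -> list[str]:
    """Schema and cross-field checks; returns all findings at once."""
    errors: list[str] = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    for key in config:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown config key: {key!r}")
    if "seed" in config and not isinstance(config["seed"], int):
        errors.append("seed must be an integer")
    for section, cls in (
        ("expression_world", ExpressionWorldConfig),
        ("ddi_world", DDIWorldConfig),
        ("expression_model", ExpressionModelConfig),
        ("ddi_model", DDIModelConfig),
        ("split", SplitSpec),
    ):
        if section in config:
            try:
                cls(**config[section])
            except (TypeError, ValueError) as exc:
                errors.append(f"{section}: {exc}")
    em = config.get("expression_model", {})
    ew = config.get("expression_world", {})
    if em and ew:
        n_props = ew.get("n_properties", ExpressionWorldConfig().n_properties)
        if em.get("n_properties", n_props) > n_props:
            errors.append("expression_model.n_properties exceeds world properties")
    if "triplets_path" in config and not Path(config["triplets_path"]).exists():
        errors.append(f"triplets_path does not exist: {config['triplets_path']}")
    if "expressions_path" in config and not Path(config["expressions_path"]).exists():
        errors.append(f"expressions_path does not exist: {config['expressions_path']}")
    return errors


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def prepare_split(
    dataset: TripletDataset, spec: SplitSpec
) -> tuple[TripletDataset, TripletDataset, TripletDataset]:
    """Split positives per regime and attach exclusive 1:1 negatives to each set."""
    if spec.regime == "unseen_interaction":
        train_p, val_p, test_p = split_unseen_interactions(dataset, spec)
    else:
        train_p, val_p, test_p = split_unseen_drugs(dataset, spec)
    all_pos = dataset.keys()
    vocab = dataset.drugs
    taken: set = set()
    out = []
    for part, ds in enumerate((train_p, val_p, test_p)):
        negs = sample_negatives(
            ds,
            seed=int(np.random.default_rng([spec.seed, part]).integers(2**31)),
            vocabulary=vocab,
            known_positives=all_pos,
            exclude=taken,
        )
        taken |= negs.keys()
        out.append(ds.merge(negs))
    return out[0], out[1], out[2]


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the manifest."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "ddisig_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    logging.basicConfig(level=config.get("log_level", "INFO"))
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}, "artifacts": {}}

    # ---- expression stage (optional) ------------------------------------
    if "expression_world" in config or "expression_model" in config:
        ew_cfg = ExpressionWorldConfig(**{"seed": seed, **config.get("expression_world", {})})
        world = generate_expression_world(ew_cfg)
        log.info("expression world: %d compounds, noise_sd=%.2f", ew_cfg.n_compounds, ew_cfg.noise_sd)
        em_kwargs = {
            "n_fingerprint_bits": ew_cfg.n_fingerprint_bits,
            "n_properties": ew_cfg.n_properties,
            "n_genes": ew_cfg.n_genes,
            "seed": seed,
        }
        em_kwargs.update(config.get("expression_model", {}))
        em_cfg = ExpressionModelConfig(**em_kwargs)
        model, history = train_expression_model(
            world.fingerprints, world.properties, world.signatures, em_cfg
        )
        model.save(out / "expression_model")
        sig_path = out / "signatures.tsv"
        write_expression_tsv(sig_path, world.signatures_frame())
        manifest["stages"]["expression"] = {
            "n_compounds": ew_cfg.n_compounds,
            "oof_pearson_mean": history.get("oof_pearson_mean"),
            "final_loss": history["final"][-1]["loss"],
        }
        manifest["artifacts"]["signatures.tsv"] = _digest(sig_path)

    # ---- DDI stage -------------------------------------------------------
    if "ddi_world" in config or "triplets_path" in config:
        if "triplets_path" in config:
            dataset = read_triplets(config["triplets_path"])
            from .io import read_expression_tsv

            expressions = read_expression_tsv(config["expressions_path"])
        else:
            dw_cfg = DDIWorldConfig(**{"seed": seed, **config.get("ddi_world", {})})
            dworld = generate_ddi_world(dw_cfg)
            dataset = dworld.dataset
            expressions = dworld.expressions
        log.info(
            "DDI dataset: %d positives, %d drugs, %d side effects",
            len(dataset), len(dataset.drugs), len(dataset.side_effects),
        )
        spec = SplitSpec(**{"seed": seed, **config.get("split", {})})
        train_ds, val_ds, test_ds = prepare_split(dataset, spec)
        for name, ds in (("train", train_ds), ("val", val_ds), ("test", test_ds)):
            path = out / f"{name}_triplets.tsv"
            write_triplets(path, ds)
            manifest["artifacts"][path.name] = _digest(path)
        dm_cfg = DDIModelConfig(**{"seed": seed, **config.get("ddi_model", {})})
        model, history = train_ddi_model(train_ds, expressions, dm_cfg)
        model.save(out / "ddi_model")
        scores = predict_scores(model, test_ds, expressions)
        val_scores = predict_scores(model, val_ds, expressions) if len(val_ds) else None
        score_path = out / "scores.tsv"
        score_frame = test_ds.frame.copy()
        score_frame["score"] = scores
        score_frame.to_csv(score_path, sep="\t", index=False)
        manifest["artifacts"]["scores.tsv"] = _digest(score_path)
        rows, macro = per_side_effect_report(
            scores, test_ds,
            threshold_scores=val_scores,
            threshold_dataset=val_ds if val_scores is not None else None,
        )
        report = pd.DataFrame([asdict(r) for r in rows])
        report_path = out / "per_side_effect_metrics.tsv"
        report.to_csv(report_path, sep="\t", index=False)
        manifest["artifacts"][report_path.name] = _digest(report_path)
        manifest["stages"]["ddi"] = {
            "regime": spec.regime,
            "n_train": len(train_ds),
            "n_val": len(val_ds),
            "n_test": len(test_ds),
            "final_loss": history["loss"][-1],
            "macro": macro,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
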