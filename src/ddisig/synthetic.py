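"""Synthetic worlds with the statistical structure the models assume.

Two generators make every stage testable without any external download:

* an expression world — compound features (Bernoulli fingerprint bits,
  uniform properties) pushed through a planted linear or shallow-nonlinear
  map to 978-gene signatures with additive Gaussian noise; and
* a DDI world — drug latents drawn in a low-dimensional space, per-side-
  effect translating-embedding parameters (r, M_rh, M_rt), true symmetric
  two-direction scores for every unordered drug pair, and positive labels
  assigned to the lowest-scoring quantile of pairs per side effect.  Drug
  expression signatures are a fixed linear embedding of the latents, so a
  model consuming expressions can in principle recover the planted ranking.

Both are deterministic under their seed.  The ground truth is returned
alongside the data so tests can use planted-parameter oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import N_LANDMARK_GENES
from .io import default_gene_symbols
from .triplets import TripletDataset

__all__ = [
    "ExpressionWorldConfig",
    "ExpressionWorld",
    "DDIWorldConfig",
    "DDIWorld",
    "generate_expression_world",
    "generate_ddi_world",
]


@dataclass
class ExpressionWorldConfig:
    """Conditions of the planted feature -> expression world."""

    n_compounds: int = 500
    n_fingerprint_bits: int = 128
    n_properties: int = 50
    map_type: str = "linear"  # linear | shallow-nonlinear
    noise_sd: float = 0.5     # expression units (z-score-like)
    fingerprint_density: float = 0.1
    n_genes: int = N_LANDMARK_GENES
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_fingerprint_bits", "n_properties", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.map_type not in ("linear", "shallow-nonlinear"):
            raise ValueError(f"unknown map_type {self.map_type!r}")


@dataclass
class ExpressionWorld:
    config: ExpressionWorldConfig
    compound_ids: list[str]
    fingerprints: np.ndarray  # (n, bits) in {0,1}
    properties: np.ndarray    # (n, props) in [0,1]
    signatures: np.ndarray    # (n, n_genes)
    gene_symbols: list[str]
    map_weights: dict = field(repr=False, default_factory=dict)

    def apply_map(self, fingerprints: np.ndarray, properties: np.ndarray) -> np.ndarray:
        """Noise-free planted map applied to arbitrary features."""
        w = self.map_weights
        lin = fingerprints @ w["W_fp"] + properties @ w["W_pr"]
        if self.config.map_type == "linear":
            return lin
        return np.tanh(lin @ w["W_mix"]) @ w["W_out"]

    def signatures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.signatures,
            index=pd.Index(self.compound_ids, name="compound_id"),
            columns=self.gene_symbols,
        )


def generate_expression_world(config: ExpressionWorldConfig) -> ExpressionWorld:
    rng = np.random.default_rng(config.seed)
    c = config
    fp = (rng.random((c.n_compounds, c.n_fingerprint_bits)) < c.fingerprint_density)
    fp = fp.astype(np.float64)
    props = rng.random((c.n_compounds, c.n_properties))
    weights: dict = {
        "W_fp": rng.normal(0.0, 1.0, (c.n_fingerprint_bits, c.n_genes)),
        "W_pr": rng.normal(0.0, 1.0, (c.n_properties, c.n_genes)),
    }
    if c.map_type == "shallow-nonlinear":
        hidden = 32
        weights["W_fp"] = rng.normal(0.0, 1.0, (c.n_fingerprint_bits, hidden))
        weights["W_pr"] = rng.normal(0.0, 1.0, (c.n_properties, hidden))
        weights["W_mix"] = np.eye(hidden)
        weights["W_out"] = rng.normal(0.0, 1.0, (hidden, c.n_genes))
    world = ExpressionWorld(
        config=c,
        compound_ids=[f"C{i:04d}" for i in range(c.n_compounds)],
        fingerprints=fp,
        properties=props,
        signatures=np.empty(0),
        gene_symbols=default_gene_symbols(c.n_genes),
        map_weights=weights,
    )
    clean = world.apply_map(fp, props)
    world.signatures = clean + rng.normal(0.0, c.noise_sd, clean.shape)
    return world


@dataclass
class DDIWorldConfig:
    """Conditions of the planted translating-embedding DDI world."""

    n_drugs: int = 60
    n_side_effects: int = 8
    latent_width: int = 8
    embedding_width: int = 8
    positive_fraction: float = 0.2
    label_noise: float = 0.0
    n_genes: int = N_LANDMARK_GENES
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_drugs < 4:
            raise ValueError("n_drugs must be >= 4")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0,1)")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must be in [0,1)")


@dataclass
class DDIWorld:
    config: DDIWorldConfig
    drugs: list[str]
    latents: np.ndarray            # (n_drugs, L) planted entity vectors
    expressions: pd.DataFrame      # drugs x genes, a linear embedding of latents
    relation_r: np.ndarray         # (R, E)
    relation_M_rh: np.ndarray      # (R, E, L)
    relation_M_rt: np.ndarray      # (R, E, L)
    dataset: TripletDataset        # positive triplets (label 1)
    side_effects: list[str] = field(default_factory=list)

    def true_score(self, drug_i: str, drug_j: str, side_effect: str) -> float:
        """Planted-parameter score of a triplet (the generating oracle)."""
        di = self.drugs.index(drug_i)
        dj = self.drugs.index(drug_j)
        k = self.side_effects.index(side_effect)
        h, t = self.latents[di], self.latents[dj]
        r = self.relation_r[k]
        Mh, Mt = self.relation_M_rh[k], self.relation_M_rt[k]
        return float(
            np.linalg.norm(Mh @ h + r - Mt @ t) + np.linalg.norm(Mh @ t + r - Mt @ h)
        )


def generate_ddi_world(config: DDIWorldConfig) -> DDIWorld:
    c = config
    rng = np.random.default_rng(c.seed)
    drugs = [f"D{i:03d}" for i in range(c.n_drugs)]
    side_effects = [f"SE{k:02d}" for k in range(c.n_side_effects)]
    latents = rng.normal(0.0, 1.0, (c.n_drugs, c.latent_width))
    r = rng.normal(0.0, 1.0, (c.n_side_effects, c.embedding_width))
    M_rh = rng.normal(0.0, 1.0 / np.sqrt(c.latent_width),
                      (c.n_side_effects, c.embedding_width, c.latent_width))
    M_rt = rng.normal(0.0, 1.0 / np.sqrt(c.latent_width),
                      (c.n_side_effects, c.embedding_width, c.latent_width))
    W_embed = rng.normal(0.0, 1.0, (c.latent_width, c.n_genes)) / np.sqrt(c.latent_width)
    expressions = pd.DataFrame(
        latents @ W_embed,
        index=pd.Index(drugs, name="compound_id"),
        columns=default_gene_symbols(c.n_genes),
    )
    ia, ja = np.triu_indices(c.n_drugs, k=1)
    # vectorized two-direction scores for all unordered pairs x side effects
    h = latents[ia]  # (P, L)
    t = latents[ja]
    fwd = np.einsum("rel,pl->pre", M_rh, h) + r[None, :, :] - np.einsum("rel,pl->pre", M_rt, t)
    bwd = np.einsum("rel,pl->pre", M_rh, t) + r[None, :, :] - np.einsum("rel,pl->pre", M_rt, h)
    scores = np.linalg.norm(fwd, axis=2) + np.linalg.norm(bwd, axis=2)  # (P, R)
    n_pairs = len(ia)
    n_pos = int(round(c.positive_fraction * n_pairs))
    if n_pos < 1:
        raise ValueError("positive_fraction yields no positives for a side effect")
    rows = []
    for k, eff in enumerate(side_effects):
        order = np.argsort(scores[:, k], kind="stable")
        positive = np.zeros(n_pairs, dtype=bool)
        positive[order[:n_pos]] = True
        if c.label_noise > 0:
            flips = rng.random(n_pairs) < c.label_noise
            positive ^= flips
        for p in np.flatnonzero(positive):
            rows.append((drugs[ia[p]], drugs[ja[p]], eff, 1))
    dataset = TripletDataset(
        pd.DataFrame(rows, columns=["drug_i", "drug_j", "side_effect", "label"])
    )
    return DDIWorld(
        config=c,
        drugs=drugs,
        latents=latents,
        expressions=expressions,
        relation_r=r,
        relation_M_rh=M_rh,
        relation_M_rt=M_rt,
        dataset=dataset,
        side_effects=side_effects,
    )
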