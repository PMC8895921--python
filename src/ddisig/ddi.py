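"""Pair-conditional gated DDI scorer with translating side-effect embeddings.

Each drug enters as its 978-gene expression signature and is encoded by a
shared dense layer into a latent h of width H (H = 978 by default so gate
entries stay gene-indexed).  Co-administration is modeled with a gated
linear unit: the pair context [h_self ; h_partner] is projected through a
shared weight and squashed by a sigmoid into a gate g in (0,1)^H, and the
gated latent h (*) g is reduced by a second shared layer to width D.  A side
effect r is a relation in a translating-embedding space: with projection
matrices M_rh, M_rt and relation vector r, the triplet score is

    S(i, j, r) = || M_rh z_i + r - M_rt z_j ||_2 + || M_rh z_j + r - M_rt z_i ||_2

which is exactly symmetric under pair reversal (drug pairs carry no
direction).  Lower scores mean a more plausible interaction.  Training uses
a margin ranking loss between matched positive and negative triplets.

Two ablation hooks mirror the architecture study: ``gates_open`` forces
g = 1 (no co-administration gating) and ``head="mlp"`` replaces the
translating-embedding scorer with a plain feed-forward head on the reduced
latents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _autodiff as ad
from .chem import N_LANDMARK_GENES
from .triplets import TripletDataset

__all__ = [
    "DDIModelConfig",
    "DDIModel",
    "SideEffectSpace",
    "glu_gate",
    "triplet_score",
    "margin_loss",
    "encode_drug",
    "coadminister",
    "train_ddi_model",
    "predict_scores",
    "gene_attention",
    "top_k_genes",
    "pair_latent",
]


@dataclass
class DDIModelConfig:
    """Hyperparameters of the DDI prediction model."""

    n_genes: int = N_LANDMARK_GENES
    hidden_width: int = N_LANDMARK_GENES  # H; = n_genes keeps gates gene-indexed
    reduced_width: int = 128              # D
    embedding_width: int = 64             # E
    margin: float = 1.0
    epochs: int = 60
    batch_size: int = 1024
    lr_max: float = 1e-3
    lr_min: float = 1e-5
    lr_period: int = 60
    l2: float = 0.0
    seed: int = 0
    aggregate_margin_loss: bool = False  # the per-relation aggregate hinge variant
    gates_open: bool = False             # ablation: force every gate to 1
    head: str = "transe"                 # "transe" | "mlp" (ablation head)
    mlp_hidden: int = 64

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        for name in ("n_genes", "hidden_width", "reduced_width", "embedding_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.head not in ("transe", "mlp"):
            raise ValueError("head must be 'transe' or 'mlp'")


@dataclass
class SideEffectSpace:
    """Relation parameters of one side effect: r plus projections M_rh, M_rt."""

    side_effect: str
    r: np.ndarray      # (E,)
    M_rh: np.ndarray   # (E, D)
    M_rt: np.ndarray   # (E, D)


def glu_gate(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Gated linear unit: elementwise A * sigmoid(B)."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    with np.errstate(over="ignore"):
        return A / (1.0 + np.exp(-B))


def triplet_score(z_h: np.ndarray, z_t: np.ndarray, se: SideEffectSpace) -> float:
    """Symmetric two-direction translating-embedding distance of a triplet."""
    z_h = np.asarray(z_h, dtype=np.float64)
    z_t = np.asarray(z_t, dtype=np.float64)
    if se.M_rh.shape[1] != z_h.shape[-1] or se.M_rt.shape[1] != z_t.shape[-1]:
        raise ValueError("latent width does not match the side-effect projections")
    fwd = np.linalg.norm(se.M_rh @ z_h + se.r - se.M_rt @ z_t)
    bwd = np.linalg.norm(se.M_rh @ z_t + se.r - se.M_rt @ z_h)
    return float(fwd + bwd)


def margin_loss(
    pos_scores: np.ndarray,
    neg_scores: np.ndarray,
    margin: float,
    aggregate: bool = False,
) -> float:
    """Margin ranking loss between positive and negative triplet scores.

    Default: matched per-pair hinge, mean of max(0, S_pos - S_neg + margin)
    over positions (positives and negatives must align 1:1).  With
    ``aggregate=True``, the per-relation aggregate variant is computed
    instead: max(0, sum(S_pos) - sum(S_neg) + margin).
    """
    if margin <= 0:
        raise ValueError("margin must be > 0")
    pos = np.atleast_1d(np.asarray(pos_scores, dtype=np.float64))
    neg = np.atleast_1d(np.asarray(neg_scores, dtype=np.float64))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("score lists must be non-empty")
    if aggregate:
        return float(max(0.0, pos.sum() - neg.sum() + margin))
    if pos.shape != neg.shape:
        raise ValueError("matched-pair margin loss needs aligned pos/neg lists")
    return float(np.mean(np.maximum(0.0, pos - neg + margin)))


class DDIModel:
    """Gated encoder + per-side-effect translating-embedding scorer."""

    def __init__(self, config: DDIModelConfig, side_effects: list[str], rng: np.random.Generator):
        c = config
        self.config = c
        self.side_effects = list(side_effects)
        self._se_index = {se: k for k, se in enumerate(self.side_effects)}
        R = len(self.side_effects)
        H, D, E = c.hidden_width, c.reduced_width, c.embedding_width
        self.W1 = ad.param((c.n_genes, H), rng=rng)
        self.b1 = ad.param(np.zeros(H))
        # the two halves of the shared pair-concat gate weight W_g [self ; partner]
        self.Wg_self = ad.param((H, H), rng=rng)
        self.Wg_partner = ad.param((H, H), rng=rng)
        self.bg = ad.param(np.zeros(H))
        self.Wr = ad.param((H, D), rng=rng)
        self.br = ad.param(np.zeros(D))
        self.r_emb = ad.param((R, E), rng=rng)
        self.M_rh = ad.param((R, E, D), rng=rng)
        self.M_rt = ad.param((R, E, D), rng=rng)
        if c.head == "mlp":
            self.W_m1 = ad.param((2 * D + E, c.mlp_hidden), rng=rng)
            self.b_m1 = ad.param(np.zeros(c.mlp_hidden))
            self.w_m2 = ad.param((c.mlp_hidden, 1), rng=rng)
            self.b_m2 = ad.param(np.zeros(1))

    def params(self) -> list[ad.Tensor]:
        ps = [self.W1, self.b1, self.Wg_self, self.Wg_partner, self.bg,
              self.Wr, self.br, self.r_emb, self.M_rh, self.M_rt]
        if self.config.head == "mlp":
            ps += [self.W_m1, self.b_m1, self.w_m2, self.b_m2]
        return ps

    # ---- differentiable building blocks ---------------------------------

    def _encode_all(self, X: np.ndarray) -> ad.Tensor:
        """Shared first layer over a drug expression matrix (n_drugs, 978)."""
        if X.shape[1] != self.config.n_genes:
            raise ValueError(f"expression width {X.shape[1]} != {self.config.n_genes}")
        return ad.relu(ad.matmul(ad.constant(X), self.W1) + self.b1)

    def _gated_reduced(
        self,
        h_all: ad.Tensor,
        a_self: ad.Tensor,
        a_partner: ad.Tensor,
        self_idx: np.ndarray,
        partner_idx: np.ndarray,
    ) -> tuple[ad.Tensor, ad.Tensor]:
        """Return (z, g) of the self drug gated by its partner."""
        h_self = ad.gather(h_all, self_idx)
        if self.config.gates_open:
            u = h_self
            g = ad.constant(np.ones_like(h_self.data))
        else:
            logits = ad.gather(a_self, self_idx) + ad.gather(a_partner, partner_idx) + self.bg
            g = ad.sigmoid(logits)
            u = h_self * g
        z = ad.matmul(u, self.Wr) + self.br
        return z, g

    def _score_batch(
        self,
        X: np.ndarray,
        i_idx: np.ndarray,
        j_idx: np.ndarray,
        se_idx: np.ndarray,
    ) -> ad.Tensor:
        """Differentiable scores of a triplet batch against expressions X."""
        h_all = self._encode_all(X)
        if self.config.gates_open:
            a_self = a_partner = h_all  # unused placeholders
        else:
            a_self = ad.matmul(h_all, self.Wg_self)
            a_partner = ad.matmul(h_all, self.Wg_partner)
        z_i, _ = self._gated_reduced(h_all, a_self, a_partner, i_idx, j_idx)
        z_j, _ = self._gated_reduced(h_all, a_self, a_partner, j_idx, i_idx)
        if self.config.head == "mlp":
            e = ad.gather(self.r_emb, se_idx)
            s_ij = self._mlp_head(z_i, z_j, e)
            s_ji = self._mlp_head(z_j, z_i, e)
            return (s_ij + s_ji) * 0.5
        Mh = ad.gather(self.M_rh, se_idx)
        Mt = ad.gather(self.M_rt, se_idx)
        rv = ad.gather(self.r_emb, se_idx)
        fwd = ad.l2norm_rows(ad.bmv(Mh, z_i) + rv - ad.bmv(Mt, z_j))
        bwd = ad.l2norm_rows(ad.bmv(Mh, z_j) + rv - ad.bmv(Mt, z_i))
        return fwd + bwd

    def _mlp_head(self, z_a: ad.Tensor, z_b: ad.Tensor, e: ad.Tensor) -> ad.Tensor:
        x = ad.concat([z_a, z_b, e], axis=1)
        hid = ad.relu(ad.matmul(x, self.W_m1) + self.b_m1)
        out = ad.matmul(hid, self.w_m2) + self.b_m2
        return _squeeze(out)

    # ---- inference -------------------------------------------------------

    def side_effect_space(self, side_effect: str) -> SideEffectSpace:
        k = self._se_lookup(side_effect)
        return SideEffectSpace(
            side_effect=side_effect,
            r=self.r_emb.data[k].copy(),
            M_rh=self.M_rh.data[k].copy(),
            M_rt=self.M_rt.data[k].copy(),
        )

    def _se_lookup(self, side_effect: str) -> int:
        if side_effect not in self._se_index:
            raise KeyError(
                f"unknown side effect {side_effect!r}: side effects are closed-world"
            )
        return self._se_index[side_effect]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        np.savez(directory / "ddi_model.npz", **arrays)
        meta = {"config": vars(self.config), "side_effects": self.side_effects}
        (directory / "ddi_model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "DDIModel":
        directory = Path(directory)
        meta = json.loads((directory / "ddi_model.json").read_text())
        config = DDIModelConfig(**meta["config"])
        model = cls(config, meta["side_effects"], rng=np.random.default_rng(0))
        with np.load(directory / "ddi_model.npz") as z:
            for i, p in enumerate(model.params()):
                p.data = z[f"p{i}"]
        return model


def _squeeze(t: ad.Tensor) -> ad.Tensor:
    """(B,1) -> (B,) view inside the graph."""
    out = ad.Tensor(t.data[:, 0], requires_grad=t.requires_grad, parents=(t,))

    def bwd(g: np.ndarray) -> None:
        if t.requires_grad:
            t._accum(g[:, None])

    out._backward = bwd
    return out


# ---- functional surface ---------------------------------------------------


def encode_drug(expression: np.ndarray, model: DDIModel) -> np.ndarray:
    """Partner-independent drug latent from the shared first layer."""
    x = np.atleast_2d(np.asarray(expression, dtype=np.float64))
    h = model._encode_all(x).data
    return h[0] if np.asarray(expression).ndim == 1 else h


def coadminister(
    h_i: np.ndarray, h_j: np.ndarray, model: DDIModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pair-conditional gating and reduction: returns (z_i, z_j, g_i, g_j).

    Gates use the shared self-first pair weight, so swapping the arguments
    swaps the outputs bitwise.
    """
    h_i = np.asarray(h_i, dtype=np.float64)
    h_j = np.asarray(h_j, dtype=np.float64)
    H = model.config.hidden_width
    if h_i.shape != (H,) or h_j.shape != (H,):
        raise ValueError(f"latents must have width {H}")
    c = model.config

    def one(self_h: np.ndarray, partner_h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if c.gates_open:
            g = np.ones(H)
            u = self_h
        else:
            logits = (
                self_h @ model.Wg_self.data
                + partner_h @ model.Wg_partner.data
                + model.bg.data
            )
            with np.errstate(over="ignore"):
                g = 1.0 / (1.0 + np.exp(-logits))
            u = self_h * g
        z = u @ model.Wr.data + model.br.data
        return z, g

    z_i, g_i = one(h_i, h_j)
    z_j, g_j = one(h_j, h_i)
    return z_i, z_j, g_i, g_j


def _drug_matrix(
    drugs: list[str], expressions: pd.DataFrame, n_genes: int
) -> np.ndarray:
    missing = [d for d in drugs if d not in expressions.index]
    if missing:
        raise KeyError(f"drugs without expression features: {missing}")
    X = expressions.loc[drugs].to_numpy(dtype=np.float64)
    if X.shape[1] != n_genes:
        raise ValueError(f"expression width {X.shape[1]} != {n_genes}")
    return X


def _paired_arrays(
    ds: TripletDataset, drug_index: dict[str, int], se_index: dict[str, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Align positives with negatives of the same side effect, by position.

    Returns (pos_i, pos_j, neg_i, neg_j, se_idx); if a side effect has
    unequal counts the shorter list is cycled.
    """
    pi, pj, ni, nj, se = [], [], [], [], []
    f = ds.frame
    for eff, grp in f.groupby("side_effect", sort=True):
        pos = grp[grp["label"] == 1]
        neg = grp[grp["label"] == 0]
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError(
                f"side effect {eff!r} lacks positives or negatives for training"
            )
        n = max(len(pos), len(neg))
        pos_rows = pos.iloc[np.arange(n) % len(pos)]
        neg_rows = neg.iloc[np.arange(n) % len(neg)]
        pi += [drug_index[d] for d in pos_rows["drug_i"]]
        pj += [drug_index[d] for d in pos_rows["drug_j"]]
        ni += [drug_index[d] for d in neg_rows["drug_i"]]
        nj += [drug_index[d] for d in neg_rows["drug_j"]]
        se += [se_index[eff]] * n
    return tuple(np.asarray(a, dtype=np.intp) for a in (pi, pj, ni, nj, se))  # type: ignore[return-value]


def train_ddi_model(
    dataset: TripletDataset,
    expressions: pd.DataFrame,
    config: DDIModelConfig,
) -> tuple[DDIModel, dict]:
    """Train the gated translating-embedding scorer on labeled triplets.

    ``expressions`` is a compounds x genes DataFrame covering every drug in
    the dataset.  The returned history holds the per-epoch mean margin loss
    and the final train-set mean positive/negative scores.  Fully
    reproducible for a fixed config seed.
    """
    from .expression import cosine_annealing_lr

    drugs = dataset.drugs
    drug_index = {d: k for k, d in enumerate(drugs)}
    X = _drug_matrix(drugs, expressions, config.n_genes)
    if np.isnan(X).any():
        raise ValueError("expression features contain NaN")
    side_effects = dataset.side_effects
    rng = np.random.default_rng(config.seed)
    model = DDIModel(config, side_effects, rng=rng)
    pos_i, pos_j, neg_i, neg_j, se_idx = _paired_arrays(
        dataset, drug_index, model._se_index
    )
    n = len(se_idx)
    opt = ad.Adam(model.params(), lr=config.lr_max, weight_decay=config.l2)
    history: dict = {"loss": []}
    for epoch in range(config.epochs):
        lr = cosine_annealing_lr(epoch, config)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            b = order[start : start + config.batch_size]
            s_pos = model._score_batch(X, pos_i[b], pos_j[b], se_idx[b])
            s_neg = model._score_batch(X, neg_i[b], neg_j[b], se_idx[b])
            if config.aggregate_margin_loss:
                loss = _aggregate_hinge(s_pos, s_neg, se_idx[b], config.margin)
            else:
                loss = ad.mean(ad.relu(s_pos - s_neg + config.margin))
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            epoch_loss += float(loss.data)
            n_batches += 1
        history["loss"].append(epoch_loss / max(n_batches, 1))
    s_pos = model._score_batch(X, pos_i, pos_j, se_idx).data
    s_neg = model._score_batch(X, neg_i, neg_j, se_idx).data
    history["train_pos_mean_score"] = float(np.mean(s_pos))
    history["train_neg_mean_score"] = float(np.mean(s_neg))
    return model, history


def _aggregate_hinge(
    s_pos: ad.Tensor, s_neg: ad.Tensor, se_idx: np.ndarray, margin: float
) -> ad.Tensor:
    """Per-relation aggregate hinge: sum_r max(0, sum S+ - sum S- + margin)."""
    terms: list[ad.Tensor] = []
    for k in np.unique(se_idx):
        mask = ad.constant((se_idx == k).astype(np.float64))
        diff = ad.total(s_pos * mask) - ad.total(s_neg * mask) + margin
        terms.append(ad.relu(diff))
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / len(terms))


def predict_scores(
    model: DDIModel,
    triplets: TripletDataset | pd.DataFrame,
    expressions: pd.DataFrame,
) -> np.ndarray:
    """Score triplets (lower = more likely interacting); exact pair symmetry.

    Drugs are open-world: any drug with an expression signature can be
    scored, trained on or not.  Side effects are closed-world and must have
    been seen in training.
    """
    frame = triplets.frame if isinstance(triplets, TripletDataset) else triplets
    drugs = sorted(set(frame["drug_i"]) | set(frame["drug_j"]))
    drug_index = {d: k for k, d in enumerate(drugs)}
    X = _drug_matrix(drugs, expressions, model.config.n_genes)
    i_idx = np.asarray([drug_index[d] for d in frame["drug_i"]], dtype=np.intp)
    j_idx = np.asarray([drug_index[d] for d in frame["drug_j"]], dtype=np.intp)
    se_idx = np.asarray(
        [model._se_lookup(se) for se in frame["side_effect"]], dtype=np.intp
    )
    return model._score_batch(X, i_idx, j_idx, se_idx).data.copy()


def gene_attention(
    model: DDIModel,
    expression_i: np.ndarray,
    expression_j: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene gate values (g_i, g_j) of a drug pair, each of length H.

    Requires the gate width to equal the gene width so entries align to
    landmark genes.
    """
    if model.config.hidden_width != model.config.n_genes:
        raise ValueError("gene attention requires hidden_width == n_genes")
    h_i = encode_drug(expression_i, model)
    h_j = encode_drug(expression_j, model)
    _, _, g_i, g_j = coadminister(h_i, h_j, model)
    return g_i, g_j


def top_k_genes(attention: np.ndarray, gene_symbols: list[str], k: int = 100) -> list[str]:
    """The k genes with the highest gate values, ties broken by gene order."""
    attention = np.asarray(attention, dtype=np.float64)
    if len(gene_symbols) != attention.size:
        raise ValueError("gene_symbols must align with the attention vector")
    if k > attention.size:
        raise ValueError(f"k={k} exceeds the number of genes {attention.size}")
    order = np.argsort(-attention, kind="stable")
    return [gene_symbols[i] for i in order[:k]]


def pair_latent(
    model: DDIModel,
    expression_i: np.ndarray,
    expression_j: np.ndarray,
) -> np.ndarray:
    """Gated pre-reduction representation h_i (*) g_i of drug i in context j."""
    h_i = encode_drug(expression_i, model)
    h_j = encode_drug(expression_j, model)
    _, _, g_i, _ = coadminister(h_i, h_j, model)
    return h_i * g_i
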