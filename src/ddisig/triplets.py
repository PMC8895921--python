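"""Triplet datasets: I/O, evaluation splits, negative sampling, augmentation.

The unit of supervision is the triplet (drug_i, drug_j, side_effect, label)
with unordered pair semantics: (a, b) and (b, a) are the same record.
Internally pairs are stored in canonical sorted order.

Three split regimes mirror the evaluation protocol for polypharmacy
side-effect prediction:

* ``unseen_interaction`` — 90:10 split of triplets; every drug may appear in
  training, but no test (pair, side effect) does.
* ``one_unseen`` — a drug subset is held out; test triplets contain exactly
  one held-out drug.
* ``both_unseen`` — test triplets contain two held-out drugs.

Validation is 1% of the training set in all regimes.  Negatives are sampled
per positive (d_i, d_j, r) by redrawing the partner drug, at a 1:1 ratio,
and are kept exclusive across splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Triplet",
    "TripletDataset",
    "SplitSpec",
    "read_triplets",
    "write_triplets",
    "split_unseen_interactions",
    "split_unseen_drugs",
    "sample_negatives",
    "add_reversed_pairs",
    "filter_side_effects",
]

_COLUMNS = ["drug_i", "drug_j", "side_effect", "label"]


@dataclass(frozen=True)
class Triplet:
    drug_i: str
    drug_j: str
    side_effect: str
    label: int  # 1 = positive interaction, 0 = negative

    def key(self) -> tuple[str, str, str]:
        """Unordered-pair identity (canonical drug order + side effect)."""
        a, b = sorted((self.drug_i, self.drug_j))
        return (a, b, self.side_effect)


def _canonical_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["drug_i"] = out["drug_i"].astype(str)
    out["drug_j"] = out["drug_j"].astype(str)
    out["side_effect"] = out["side_effect"].astype(str)
    out["label"] = out["label"].astype(int)
    swap = out["drug_i"] > out["drug_j"]
    out.loc[swap, ["drug_i", "drug_j"]] = out.loc[swap, ["drug_j", "drug_i"]].values
    return out[_COLUMNS].reset_index(drop=True)


@dataclass(eq=False)
class TripletDataset:
    """A deduplicated set of unordered triplets with a drug vocabulary."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_COLUMNS))

    def __post_init__(self) -> None:
        df = _canonical_frame(self.frame)
        if (df["drug_i"] == df["drug_j"]).any():
            bad = df[df["drug_i"] == df["drug_j"]].iloc[0]
            raise ValueError(f"self-pair triplet not allowed: {bad['drug_i']}")
        n_before = len(df)
        df = df.drop_duplicates(subset=_COLUMNS).reset_index(drop=True)
        if len(df) < n_before:
            warnings.warn(
                f"collapsed {n_before - len(df)} duplicate unordered triplet(s)",
                stacklevel=2,
            )
        conflict = df.duplicated(subset=["drug_i", "drug_j", "side_effect"], keep=False)
        if conflict.any():
            key = df[conflict].iloc[0]
            raise ValueError(
                "triplet labeled both positive and negative: "
                f"({key['drug_i']}, {key['drug_j']}, {key['side_effect']})"
            )
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TripletDataset):
            return NotImplemented
        return self.keys_with_labels() == other.keys_with_labels()

    def keys(self) -> set[tuple[str, str, str]]:
        return set(zip(self.frame["drug_i"], self.frame["drug_j"], self.frame["side_effect"]))

    def keys_with_labels(self) -> set[tuple[str, str, str, int]]:
        return set(
            zip(
                self.frame["drug_i"],
                self.frame["drug_j"],
                self.frame["side_effect"],
                self.frame["label"],
            )
        )

    @property
    def drugs(self) -> list[str]:
        return sorted(set(self.frame["drug_i"]) | set(self.frame["drug_j"]))

    @property
    def side_effects(self) -> list[str]:
        return sorted(self.frame["side_effect"].unique())

    def positives(self) -> "TripletDataset":
        return TripletDataset(self.frame[self.frame["label"] == 1])

    def negatives(self) -> "TripletDataset":
        return TripletDataset(self.frame[self.frame["label"] == 0])

    def subset(self, mask: np.ndarray) -> "TripletDataset":
        return TripletDataset(self.frame[np.asarray(mask, dtype=bool)])

    def merge(self, other: "TripletDataset") -> "TripletDataset":
        return TripletDataset(pd.concat([self.frame, other.frame], ignore_index=True))

    def triplets(self) -> list[Triplet]:
        return [
            Triplet(r.drug_i, r.drug_j, r.side_effect, int(r.label))
            for r in self.frame.itertuples(index=False)
        ]


def read_triplets(path: str | Path) -> TripletDataset:
    """Read a triplet TSV (header drug_i, drug_j, side_effect, label)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad = df[_COLUMNS].isna().any(axis=1)
    if bad.any():
        # +2: one for the header row, one for 1-based numbering
        line = int(np.flatnonzero(bad.values)[0]) + 2
        raise ValueError(f"{path}: malformed row at line {line}")
    try:
        df["label"] = df["label"].astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer label: {exc}") from exc
    return TripletDataset(df)


def write_triplets(path: str | Path, ds: TripletDataset) -> None:
    ds.frame.to_csv(Path(path), sep="\t", index=False)


@dataclass
class SplitSpec:
    """Parameters of one evaluation split."""

    regime: str = "unseen_interaction"  # unseen_interaction | one_unseen | both_unseen
    test_fraction: float = 0.1
    val_fraction: float = 0.01  # fraction *of the training set*
    drug_holdout_fraction: float = 0.1  # used by the unseen-drug regimes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("unseen_interaction", "one_unseen", "both_unseen"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0,1)")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0,1)")


def split_unseen_interactions(
    ds: TripletDataset, spec: SplitSpec
) -> tuple[TripletDataset, TripletDataset, TripletDataset]:
    """Split triplets ~9:1 into train/test, then carve 1% of train as validation."""
    if spec.regime != "unseen_interaction":
        raise ValueError("spec.regime must be 'unseen_interaction'")
    n = len(ds)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_test = int(round(spec.test_fraction * n))
    n_val = int(round(spec.val_fraction * (n - n_test)))
    if n_test < 1 or n_val < 1 or n - n_test - n_val < 1:
        raise ValueError(f"dataset of {n} triplets too small for the requested split")
    test_idx = order[:n_test]
    val_idx = order[n_test : n_test + n_val]
    train_idx = order[n_test + n_val :]
    f = ds.frame
    return (
        TripletDataset(f.iloc[train_idx]),
        TripletDataset(f.iloc[val_idx]),
        TripletDataset(f.iloc[test_idx]),
    )


def split_unseen_drugs(
    ds: TripletDataset, spec: SplitSpec
) -> tuple[TripletDataset, TripletDataset, TripletDataset]:
    """Hold out a drug subset; test triplets touch one or two held-out drugs.

    ``one_unseen``: test = triplets with exactly one held-out drug;
    ``both_unseen``: test = triplets with both drugs held out.  Training
    never contains a held-out drug.
    """
    if spec.regime not in ("one_unseen", "both_unseen"):
        raise ValueError("spec.regime must be 'one_unseen' or 'both_unseen'")
    rng = np.random.default_rng(spec.seed)
    drugs = np.asarray(ds.drugs)
    n_held = int(round(spec.drug_holdout_fraction * len(drugs)))
    held = set(rng.choice(drugs, size=n_held, replace=False)) if n_held else set()
    if not held:
        warnings.warn("drug holdout fraction yields no held-out drugs; test is empty")
    f = ds.frame
    n_unseen = f["drug_i"].isin(held).astype(int) + f["drug_j"].isin(held).astype(int)
    train_pool = f[n_unseen == 0]
    want = 1 if spec.regime == "one_unseen" else 2
    test = f[n_unseen == want]
    n_val = int(round(spec.val_fraction * len(train_pool)))
    order = rng.permutation(len(train_pool))
    val = train_pool.iloc[order[:n_val]]
    train = train_pool.iloc[order[n_val:]]
    train_ds = TripletDataset(train)
    missing = set(ds.side_effects) - {
        se for se in train_ds.frame.loc[train_ds.frame["label"] == 1, "side_effect"]
    }
    if missing:
        warnings.warn(
            f"side effect(s) without training positives after drug holdout: {sorted(missing)}"
        )
    return train_ds, TripletDataset(val), TripletDataset(test)


def sample_negatives(
    positives: TripletDataset,
    seed: int = 0,
    vocabulary: Iterable[str] | None = None,
    known_positives: set[tuple[str, str, str]] | None = None,
    exclude: set[tuple[str, str, str]] | None = None,
    max_attempts: int = 200,
) -> TripletDataset:
    """Sample one negative per positive by redrawing the partner drug.

    For each positive (d_i, d_j, r), keep one end of the (unordered) pair
    and draw a replacement partner d' uniformly from the vocabulary such
    that d' differs from the kept drug and (kept, d', r) is not a known
    positive nor in ``exclude`` (negatives already claimed by another split)
    nor already sampled here.  The kept end is re-chosen at random per
    attempt so a drug saturated with positives does not block sampling.
    Returns negatives aligned 1:1 with the positives, in order.
    """
    vocab = sorted(vocabulary) if vocabulary is not None else positives.drugs
    if len(vocab) <= 2:
        raise ValueError("drug vocabulary must be larger than 2")
    pos_keys = known_positives if known_positives is not None else positives.keys()
    taken: set[tuple[str, str, str]] = set(exclude) if exclude else set()
    rng = np.random.default_rng(seed)
    vocab_arr = np.asarray(vocab)
    rows = []
    for rec in positives.frame.itertuples(index=False):
        if rec.label != 1:
            raise ValueError("sample_negatives expects a positives-only dataset")
        found = False
        for _ in range(max_attempts):
            kept = rec.drug_i if rng.random() < 0.5 else rec.drug_j
            dj = str(vocab_arr[rng.integers(len(vocab_arr))])
            if dj == kept:
                continue
            a, b = sorted((kept, dj))
            key = (a, b, rec.side_effect)
            if key in pos_keys or key in taken:
                continue
            taken.add(key)
            rows.append((a, b, rec.side_effect, 0))
            found = True
            break
        if not found:
            # rejection sampling exhausted: enumerate the feasible candidates
            cands = []
            for kept in (rec.drug_i, rec.drug_j):
                for dj in vocab:
                    if dj == kept:
                        continue
                    a, b = sorted((kept, dj))
                    key = (a, b, rec.side_effect)
                    if key not in pos_keys and key not in taken:
                        cands.append(key)
            if not cands:
                raise RuntimeError(
                    f"could not sample a negative for ({rec.drug_i}, "
                    f"{rec.drug_j}, {rec.side_effect}): vocabulary saturated"
                )
            cands.sort()
            key = cands[rng.integers(len(cands))]
            taken.add(key)
            rows.append((key[0], key[1], key[2], 0))
    return TripletDataset(pd.DataFrame(rows, columns=_COLUMNS))


def add_reversed_pairs(ds: TripletDataset) -> pd.DataFrame:
    """Ordered training view: every record emitted in both drug orders.

    Returns a DataFrame (not a dataset: datasets are unordered) with 2n rows
    for n records; applying the function to its own output is idempotent
    because the input is reduced to unordered records first.
    """
    fwd = ds.frame.copy()
    rev = fwd.rename(columns={"drug_i": "drug_j", "drug_j": "drug_i"})[_COLUMNS]
    return pd.concat([fwd, rev], ignore_index=True)


def filter_side_effects(ds: TripletDataset, min_pairs: int = 500) -> TripletDataset:
    """Drop side effects observed with fewer than ``min_pairs`` positive drug pairs."""
    pos = ds.frame[ds.frame["label"] == 1]
    counts = pos.groupby("side_effect")[["drug_i", "drug_j"]].apply(
        lambda g: len(g.drop_duplicates())
    )
    keep = set(counts[counts >= min_pairs].index)
    return TripletDataset(ds.frame[ds.frame["side_effect"].isin(keep)])
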