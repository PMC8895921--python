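"""Compound featurization and expression-signature selection.

Turns compound tables (id + SMILES) into the fixed-length inputs the
expression generator consumes: Morgan fingerprint bits plus a scaled vector
of 2-D physicochemical descriptors, with random-forest feature selection
against the expression matrix and [0, 1] min-max scaling anchored on a
reference compound set.  Also houses the signature-strength rule used to
pick one representative differential-expression signature per compound out
of multiple experimental conditions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from sklearn.ensemble import RandomForestRegressor

RDLogger.DisableLog("rdApp.*")

N_LANDMARK_GENES = 978

__all__ = [
    "N_LANDMARK_GENES",
    "CompoundRecord",
    "FeatureScaler",
    "FeatureSelector",
    "SignatureCollection",
    "canonicalize_smiles",
    "compute_fingerprint",
    "list_descriptor_sets",
    "compute_properties",
    "descriptor_names",
    "drop_missing_properties",
    "select_top_properties",
    "fit_scaler",
    "apply_scaler",
    "signature_strength",
    "select_representative_signature",
    "featurize_compounds",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass
class CompoundRecord:
    """A featurized compound: canonical SMILES, fingerprint bits, scaled properties."""

    compound_id: str
    smiles: str
    fingerprint: np.ndarray
    properties: np.ndarray


def _mol(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical SMILES form; idempotent, equivalence-class stable."""
    return Chem.MolToSmiles(_mol(smiles))


def compute_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Morgan (circular) fingerprint as a 0/1 uint8 vector of length ``n_bits``."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits <= 0:
        raise ValueError("n_bits must be > 0")
    mol = _mol(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = 1
    return arr


# Descriptor providers.  "rdkit2d" is the full built-in 2-D descriptor table;
# "rdkit2d-minimal" is a fast deterministic subset used in tests.
_MINIMAL_DESCRIPTORS = [
    "MolWt",
    "HeavyAtomCount",
    "MolLogP",
    "TPSA",
    "NumHDonors",
    "NumHAcceptors",
    "NumRotatableBonds",
    "RingCount",
    "FractionCSP3",
    "NumAromaticRings",
]


def list_descriptor_sets() -> list[str]:
    return ["rdkit2d", "rdkit2d-minimal"]


def descriptor_names(descriptor_set: str = "rdkit2d") -> list[str]:
    if descriptor_set == "rdkit2d":
        return [name for name, _ in Descriptors.descList]
    if descriptor_set == "rdkit2d-minimal":
        return list(_MINIMAL_DESCRIPTORS)
    raise ValueError(
        f"unknown descriptor_set {descriptor_set!r}; choose from {list_descriptor_sets()}"
    )


def compute_properties(smiles: str, descriptor_set: str = "rdkit2d") -> np.ndarray:
    """Fixed-length descriptor vector; undefined descriptors are NaN, never 0.

    The vector is ordered as :func:`descriptor_names`; callers remove missing
    values across a compound set with :func:`drop_missing_properties`.
    """
    names = descriptor_names(descriptor_set)
    mol = _mol(smiles)
    lookup = dict(Descriptors.descList)
    out = np.empty(len(names), dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, name in enumerate(names):
            try:
                val = float(lookup[name](mol))
            except Exception:
                val = np.nan
            out[i] = val
    return out


def drop_missing_properties(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop every column containing a NaN anywhere; return (reduced, kept indices)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D compounds x properties matrix")
    keep = ~np.isnan(matrix).any(axis=0)
    if not keep.any():
        raise ValueError("every property column contains a missing value")
    kept = np.flatnonzero(keep)
    return matrix[:, kept], kept


@dataclass
class FeatureSelector:
    """Random-forest importance ranking over candidate properties."""

    importances: np.ndarray
    selected: np.ndarray  # ordered top-k column indices

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64)[:, self.selected]

    def to_json(self) -> str:
        return json.dumps(
            {
                "importances": self.importances.tolist(),
                "selected": self.selected.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSelector":
        d = json.loads(text)
        return cls(
            importances=np.asarray(d["importances"], dtype=np.float64),
            selected=np.asarray(d["selected"], dtype=np.intp),
        )


def select_top_properties(
    X: np.ndarray,
    Y: np.ndarray,
    k: int = 100,
    seed: int = 0,
    n_estimators: int = 100,
) -> FeatureSelector:
    """Select the top-``k`` properties by random-forest importance.

    A multi-target forest regresses the expression matrix ``Y`` on the
    property matrix ``X``; impurity importances therefore average over gene
    targets.  Ties are broken by ascending column index, so the selection is
    deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have aligned rows")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds number of properties {X.shape[1]}")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("X and Y must be NaN-free (drop_missing_properties first)")
    forest = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(X, Y)
    imp = forest.feature_importances_
    order = np.argsort(-imp, kind="stable")  # stable => ties by ascending index
    return FeatureSelector(importances=imp, selected=order[:k])


@dataclass
class FeatureScaler:
    """Per-feature min-max scaler anchored on a reference compound set.

    Non-reference values falling outside the reference range are clipped to
    [0, 1] so the model input domain stays closed.  Constant features map to
    zero (with a warning at fit time).
    """

    minimum: np.ndarray
    maximum: np.ndarray
    feature_types: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "minimum": self.minimum.tolist(),
                "maximum": self.maximum.tolist(),
                "feature_types": self.feature_types,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureScaler":
        d = json.loads(text)
        return cls(
            minimum=np.asarray(d["minimum"], dtype=np.float64),
            maximum=np.asarray(d["maximum"], dtype=np.float64),
            feature_types=list(d.get("feature_types", [])),
        )

    def inverse(self, X_scaled: np.ndarray) -> np.ndarray:
        """Undo the affine map (valid for in-range, non-constant features)."""
        span = self.maximum - self.minimum
        return np.asarray(X_scaled, dtype=np.float64) * span + self.minimum


def fit_scaler(X_reference: np.ndarray, feature_types: list[str] | None = None) -> FeatureScaler:
    X = np.asarray(X_reference, dtype=np.float64)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    n_const = int(np.sum(hi == lo))
    if n_const:
        warnings.warn(
            f"{n_const} constant feature(s) in the reference set map to 0 after scaling",
            stacklevel=2,
        )
    return FeatureScaler(minimum=lo, maximum=hi, feature_types=feature_types or [])


def apply_scaler(X: np.ndarray, scaler: FeatureScaler) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    span = scaler.maximum - scaler.minimum
    safe = np.where(span > 0, span, 1.0)
    scaled = (X - scaler.minimum) / safe
    scaled = np.where(span > 0, scaled, 0.0)
    return np.clip(scaled, 0.0, 1.0)


# ---- expression-signature selection --------------------------------------


@dataclass
class SignatureCollection:
    """Candidate differential-expression signatures for one compound."""

    compound_id: str
    signatures: list[np.ndarray]


def signature_strength(signature: np.ndarray, z_threshold: float = 2.0) -> int:
    """Number of landmark genes with |differential expression| >= threshold."""
    sig = np.asarray(signature, dtype=np.float64)
    if sig.shape != (N_LANDMARK_GENES,):
        raise ValueError(
            f"expected a length-{N_LANDMARK_GENES} signature, got shape {sig.shape}"
        )
    return int(np.sum(np.abs(sig) >= z_threshold))


def select_representative_signature(
    collection: SignatureCollection, z_threshold: float = 2.0
) -> np.ndarray:
    """The candidate with maximal signature strength; ties go to the earliest."""
    if not collection.signatures:
        raise ValueError(f"no candidate signatures for {collection.compound_id}")
    strengths = [signature_strength(s, z_threshold) for s in collection.signatures]
    return np.asarray(collection.signatures[int(np.argmax(strengths))], dtype=np.float64)


# ---- end-to-end featurization --------------------------------------------


def featurize_compounds(
    compounds: pd.DataFrame,
    radius: int = 2,
    n_bits: int = 2048,
    descriptor_set: str = "rdkit2d",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Canonicalize, fingerprint and compute raw descriptors for a compound table.

    ``compounds`` needs columns ``compound_id`` and ``smiles``.  Returns
    (fingerprint DataFrame, raw property DataFrame), both indexed by
    compound_id; properties may contain NaN and are not yet selected/scaled.
    """
    for col in ("compound_id", "smiles"):
        if col not in compounds.columns:
            raise ValueError(f"compound table missing column {col!r}")
    names = descriptor_names(descriptor_set)
    fps, props, ids = [], [], []
    for row in compounds.itertuples(index=False):
        smiles = canonicalize_smiles(row.smiles)
        fps.append(compute_fingerprint(smiles, radius=radius, n_bits=n_bits))
        props.append(compute_properties(smiles, descriptor_set))
        ids.append(str(row.compound_id))
    fp_df = pd.DataFrame(
        np.asarray(fps), index=pd.Index(ids, name="compound_id"),
        columns=[f"fp_{i}" for i in range(n_bits)],
    )
    prop_df = pd.DataFrame(
        np.asarray(props), index=pd.Index(ids, name="compound_id"), columns=names
    )
    return fp_df, prop_df
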