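import numpy as np
import pandas as pd
import pytest

from ddisig import (
    DDIModel,
    DDIModelConfig,
    DDIWorldConfig,
    TripletDataset,
    generate_ddi_world,
)


@pytest.fixture(scope="session")
def tiny_world():
    """A small planted DDI world shared by fast unit tests."""
    return generate_ddi_world(
        DDIWorldConfig(n_drugs=20, n_side_effects=4, latent_width=4,
                       embedding_width=4, positive_fraction=0.25, seed=11)
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_world):
    """An untrained small DDI model over the tiny world's side effects."""
    cfg = DDIModelConfig(n_genes=978, hidden_width=32, reduced_width=8,
                         embedding_width=4, seed=3)
    return DDIModel(cfg, tiny_world.side_effects, rng=np.random.default_rng(3))


@pytest.fixture()
def thousand_triplets():
    """A deterministic 1000-triplet positive dataset over 40 drugs, 5 side effects."""
    rng = np.random.default_rng(42)
    drugs = [f"D{i:02d}" for i in range(40)]
    rows = set()
    while len(rows) < 1000:
        i, j = rng.choice(40, size=2, replace=False)
        se = f"SE{rng.integers(5)}"
        a, b = sorted((drugs[i], drugs[j]))
        rows.add((a, b, se))
    frame = pd.DataFrame(
        [(a, b, se, 1) for a, b, se in sorted(rows)],
        columns=["drug_i", "drug_j", "side_effect", "label"],
    )
    return TripletDataset(frame)
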