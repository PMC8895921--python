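"""Gated encoder, translating-embedding score, margin loss, interpretability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ortho_group

from ddisig import (
    DDIModel,
    DDIModelConfig,
    SideEffectSpace,
    coadminister,
    encode_drug,
    gene_attention,
    glu_gate,
    margin_loss,
    pair_latent,
    predict_scores,
    top_k_genes,
    train_ddi_model,
    triplet_score,
)
from ddisig.pipeline import prepare_split
from ddisig.triplets import SplitSpec


class TestGLU:
    def test_zero_gate_logits_halve_the_payload(self):
        np.testing.assert_allclose(
            glu_gate(np.array([2.0, -4.0]), np.zeros(2)), [1.0, -2.0]
        )

    def test_saturated_gate_passes_payload_through(self):
        A = np.array([1.5, -2.5])
        np.testing.assert_allclose(glu_gate(A, np.full(2, 50.0)), A, atol=1e-12)

    def test_log3_logit_gives_three_quarters(self):
        out = glu_gate(np.ones(2), np.full(2, np.log(3.0)))
        np.testing.assert_allclose(out, [0.75, 0.75])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            glu_gate(np.zeros(2), np.zeros(3))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_gate_never_amplifies(self, seed):
        rng = np.random.default_rng(seed)
        A, B = rng.normal(size=(2, 6)) * 10
        assert np.all(np.abs(glu_gate(A, B)) <= np.abs(A) + 1e-12)


class TestTripletScore:
    def test_coincident_points_score_zero(self):
        se = SideEffectSpace("s", np.zeros(3), np.eye(3), np.eye(3))
        z = np.array([1.0, 2.0, 3.0])
        assert triplet_score(z, z, se) == 0.0

    def test_worked_identity_projection_example(self):
        se = SideEffectSpace("s", np.array([1.0, 1.0]), np.eye(2), np.eye(2))
        assert triplet_score(np.array([1.0, 0.0]), np.array([0.0, 1.0]), se) == 4.0

    def test_exactly_symmetric_in_drug_order(self):
        rng = np.random.default_rng(0)
        se = SideEffectSpace("s", rng.normal(size=4),
                             rng.normal(size=(4, 5)), rng.normal(size=(4, 5)))
        z1, z2 = rng.normal(size=(2, 5))
        assert triplet_score(z1, z2, se) == triplet_score(z2, z1, se)

    def test_invariant_under_orthogonal_rotation_of_embedding_space(self):
        rng = np.random.default_rng(1)
        E = 4
        se = SideEffectSpace("s", rng.normal(size=E),
                             rng.normal(size=(E, 5)), rng.normal(size=(E, 5)))
        z1, z2 = rng.normal(size=(2, 5))
        base = triplet_score(z1, z2, se)
        for seed in range(3):
            Q = ortho_group.rvs(E, random_state=seed)
            rotated = SideEffectSpace("s", Q @ se.r, Q @ se.M_rh, Q @ se.M_rt)
            assert triplet_score(z1, z2, rotated) == pytest.approx(base, rel=1e-12)

    def test_shape_mismatch_raises(self):
        se = SideEffectSpace("s", np.zeros(2), np.eye(2), np.eye(2))
        with pytest.raises(ValueError):
            triplet_score(np.zeros(3), np.zeros(3), se)


class TestMarginLoss:
    @pytest.mark.parametrize(
        "pos,neg,margin,expected",
        [(1.0, 3.0, 1.0, 0.0), (2.0, 2.0, 0.7, 0.7), (3.0, 1.0, 1.0, 3.0)],
    )
    def test_hinge_values(self, pos, neg, margin, expected):
        assert margin_loss([pos], [neg], margin) == pytest.approx(expected)

    def test_aggregate_variant_sums_before_the_hinge(self):
        # sum(pos)=4, sum(neg)=7 -> max(0, 4-7+1) = 0; and 7-4+1 = 4 reversed
        assert margin_loss([1, 3], [3, 4], 1.0, aggregate=True) == 0.0
        assert margin_loss([3, 4], [1, 3], 1.0, aggregate=True) == 4.0

    def test_empty_lists_raise(self):
        with pytest.raises(ValueError):
            margin_loss([], [1.0], 1.0)

    def test_invalid_margin_raises(self):
        with pytest.raises(ValueError):
            margin_loss([1.0], [2.0], 0.0)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000), st.floats(0.01, 2.0))
    def test_monotone_in_scores(self, seed, bump):
        rng = np.random.default_rng(seed)
        pos, neg = rng.normal(size=(2, 5)) * 3
        base = margin_loss(pos, neg, 1.0)
        assert margin_loss(pos + bump, neg, 1.0) >= base
        assert margin_loss(pos, neg + bump, 1.0) <= base


class TestEncoderAndGates:
    def _h(self, model, rng):
        return encode_drug(rng.normal(size=978), model)

    def test_encode_deterministic_and_partner_free(self, tiny_model):
        rng = np.random.default_rng(0)
        x = rng.normal(size=978)
        np.testing.assert_array_equal(encode_drug(x, tiny_model), encode_drug(x, tiny_model))

    def test_zero_parameters_give_zero_latent(self, tiny_world):
        cfg = DDIModelConfig(hidden_width=16, reduced_width=4, embedding_width=4)
        model = DDIModel(cfg, tiny_world.side_effects, rng=np.random.default_rng(0))
        model.W1.data[:] = 0.0
        model.b1.data[:] = 0.0
        np.testing.assert_array_equal(encode_drug(np.ones(978), model), np.zeros(16))

    def test_coadminister_swaps_outputs_bitwise(self, tiny_model):
        rng = np.random.default_rng(1)
        h_i, h_j = self._h(tiny_model, rng), self._h(tiny_model, rng)
        z_i, z_j, g_i, g_j = coadminister(h_i, h_j, tiny_model)
        z_j2, z_i2, g_j2, g_i2 = coadminister(h_j, h_i, tiny_model)
        np.testing.assert_array_equal(z_i, z_i2)
        np.testing.assert_array_equal(z_j, z_j2)
        np.testing.assert_array_equal(g_i, g_i2)
        np.testing.assert_array_equal(g_j, g_j2)

    def test_gates_lie_strictly_inside_unit_interval(self, tiny_model):
        rng = np.random.default_rng(2)
        _, _, g_i, g_j = coadminister(self._h(tiny_model, rng), self._h(tiny_model, rng), tiny_model)
        for g in (g_i, g_j):
            assert np.all(g > 0) and np.all(g < 1)

    def test_gate_is_pair_conditional(self, tiny_model):
        rng = np.random.default_rng(3)
        h_i = self._h(tiny_model, rng)
        _, _, g_with_j, _ = coadminister(h_i, self._h(tiny_model, rng), tiny_model)
        _, _, g_with_l, _ = coadminister(h_i, self._h(tiny_model, rng), tiny_model)
        assert not np.allclose(g_with_j, g_with_l)


class TestTrainingAndPrediction:
    @pytest.fixture(scope="class")
    def trained(self, tiny_world):
        spec = SplitSpec(regime="unseen_interaction", seed=5, val_fraction=0.05)
        train_ds, val_ds, test_ds = prepare_split(tiny_world.dataset, spec)
        cfg = DDIModelConfig(hidden_width=64, reduced_width=16, embedding_width=8,
                             epochs=15, batch_size=256, lr_period=15, seed=5)
        model, history = train_ddi_model(train_ds, tiny_world.expressions, cfg)
        return model, history, train_ds, test_ds, tiny_world

    def test_loss_history_recorded_and_positive_scores_lower(self, trained):
        model, history, *_ = trained
        assert len(history["loss"]) == model.config.epochs
        assert history["train_pos_mean_score"] < history["train_neg_mean_score"]

    def test_same_seed_identical_history(self, tiny_world):
        spec = SplitSpec(regime="unseen_interaction", seed=5, val_fraction=0.05)
        train_ds, *_ = prepare_split(tiny_world.dataset, spec)
        cfg = DDIModelConfig(hidden_width=32, reduced_width=8, embedding_width=4,
                             epochs=3, lr_period=3, seed=9)
        _, h1 = train_ddi_model(train_ds, tiny_world.expressions, cfg)
        _, h2 = train_ddi_model(train_ds, tiny_world.expressions, cfg)
        assert h1["loss"] == h2["loss"]

    def test_margin_loss_bookkeeping_matches_scored_triplets(self, trained):
        model, _, train_ds, _, world = trained
        pos = train_ds.positives()
        neg = train_ds.negatives()
        n = min(len(pos), len(neg), 50)
        # restrict to one side effect so positives and negatives are matched
        se = pos.side_effects[0]
        pos_f = pos.frame[pos.frame.side_effect == se].head(n)
        neg_f = neg.frame[neg.frame.side_effect == se].head(len(pos_f))
        from ddisig.triplets import TripletDataset

        s_pos = predict_scores(model, TripletDataset(pos_f), world.expressions)
        s_neg = predict_scores(model, TripletDataset(neg_f), world.expressions)
        expected = float(np.mean(np.maximum(0, s_pos - s_neg + model.config.margin)))
        assert margin_loss(s_pos, s_neg, model.config.margin) == pytest.approx(expected)

    def test_reversed_pair_scores_identical(self, trained):
        model, _, _, test_ds, world = trained
        fwd = test_ds.frame.head(20)
        rev = fwd.rename(columns={"drug_i": "drug_j", "drug_j": "drug_i"})
        s_fwd = predict_scores(model, fwd, world.expressions)
        s_rev = predict_scores(model, rev, world.expressions)
        np.testing.assert_array_equal(s_fwd, s_rev)

    def test_unseen_drug_with_features_gets_finite_score(self, trained):
        import pandas as pd

        model, _, _, _, world = trained
        rng = np.random.default_rng(0)
        expr = pd.concat([
            world.expressions,
            pd.DataFrame(rng.normal(size=(1, 978)), index=["NEWDRUG"],
                         columns=world.expressions.columns),
        ])
        frame = pd.DataFrame({
            "drug_i": ["NEWDRUG"], "drug_j": [world.drugs[0]],
            "side_effect": [world.side_effects[0]], "label": [0],
        })
        s = predict_scores(model, frame, expr)
        assert np.isfinite(s).all()

    def test_unknown_side_effect_rejected(self, trained):
        import pandas as pd

        model, _, _, _, world = trained
        frame = pd.DataFrame({
            "drug_i": [world.drugs[0]], "drug_j": [world.drugs[1]],
            "side_effect": ["NOT_A_SE"], "label": [0],
        })
        with pytest.raises(KeyError, match="closed-world"):
            predict_scores(model, frame, world.expressions)

    def test_batch_and_single_scoring_agree(self, trained):
        model, _, _, test_ds, world = trained
        batch = predict_scores(model, test_ds.frame.head(10), world.expressions)
        singles = [
            predict_scores(model, test_ds.frame.iloc[[k]], world.expressions)[0]
            for k in range(10)
        ]
        np.testing.assert_allclose(singles, batch, atol=1e-9)

    def test_missing_drug_features_error_lists_ids(self, tiny_world):
        cfg = DDIModelConfig(hidden_width=16, reduced_width=4, embedding_width=4, epochs=1)
        expr = tiny_world.expressions.drop(index=tiny_world.drugs[0])
        with pytest.raises(KeyError, match=tiny_world.drugs[0]):
            train_ddi_model(tiny_world.dataset, expr, cfg)

    def test_save_load_roundtrip(self, trained, tmp_path):
        model, _, _, test_ds, world = trained
        model.save(tmp_path / "m")
        back = DDIModel.load(tmp_path / "m")
        a = predict_scores(model, test_ds.frame.head(5), world.expressions)
        b = predict_scores(back, test_ds.frame.head(5), world.expressions)
        np.testing.assert_array_equal(a, b)

    def test_aggregate_margin_variant_trains(self, tiny_world):
        spec = SplitSpec(regime="unseen_interaction", seed=5, val_fraction=0.05)
        train_ds, *_ = prepare_split(tiny_world.dataset, spec)
        cfg = DDIModelConfig(hidden_width=16, reduced_width=4, embedding_width=4,
                             epochs=2, lr_period=2, seed=1, aggregate_margin_loss=True)
        _, history = train_ddi_model(train_ds, tiny_world.expressions, cfg)
        assert len(history["loss"]) == 2


class TestInterpretability:
    @pytest.fixture(scope="class")
    def gene_model(self, tiny_world):
        cfg = DDIModelConfig(reduced_width=8, embedding_width=4, seed=2)  # H = 978
        return DDIModel(cfg, tiny_world.side_effects, rng=np.random.default_rng(2))

    def test_attention_is_gene_indexed_and_bounded(self, gene_model):
        rng = np.random.default_rng(0)
        g_i, g_j = gene_attention(gene_model, rng.normal(size=978), rng.normal(size=978))
        assert g_i.shape == g_j.shape == (978,)
        assert np.all((g_i > 0) & (g_i < 1))

    def test_attention_depends_on_partner(self, gene_model):
        rng = np.random.default_rng(1)
        x_i, x_j, x_l = rng.normal(size=(3, 978))
        g_with_j, _ = gene_attention(gene_model, x_i, x_j)
        g_with_l, _ = gene_attention(gene_model, x_i, x_l)
        assert not np.allclose(g_with_j, g_with_l)

    def test_narrow_hidden_width_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="hidden_width"):
            gene_attention(tiny_model, np.zeros(978), np.zeros(978))

    def test_top_k_selects_highest_attended_genes(self):
        genes = [f"G{i:04d}" for i in range(978)]
        att = np.zeros(978)
        att[[5, 100, 700]] = [0.9, 0.8, 0.95]
        assert top_k_genes(att, genes, 3) == ["G0700", "G0005", "G0100"]
        assert len(top_k_genes(att, genes, 100)) == 100
        assert sorted(top_k_genes(att, genes, 978)) == genes
        with pytest.raises(ValueError):
            top_k_genes(att, genes, 979)

    def test_pair_latent_varies_with_partner(self, gene_model):
        rng = np.random.default_rng(3)
        x_i, x_j, x_l = rng.normal(size=(3, 978))
        assert not np.allclose(
            pair_latent(gene_model, x_i, x_j), pair_latent(gene_model, x_i, x_l)
        )

    def test_pair_latent_is_half_hidden_when_gate_logits_vanish(self, tiny_world):
        cfg = DDIModelConfig(reduced_width=8, embedding_width=4, seed=4)
        model = DDIModel(cfg, tiny_world.side_effects, rng=np.random.default_rng(4))
        model.Wg_self.data[:] = 0.0
        model.Wg_partner.data[:] = 0.0
        model.bg.data[:] = 0.0
        x = np.random.default_rng(5).normal(size=978)
        h = encode_drug(x, model)
        np.testing.assert_allclose(pair_latent(model, x, x), h / 2.0)

    def test_open_gates_reduce_to_ungated_translating_scorer(self, tiny_world):
        cfg = DDIModelConfig(hidden_width=32, reduced_width=8, embedding_width=4,
                             seed=6, gates_open=True)
        model = DDIModel(cfg, tiny_world.side_effects, rng=np.random.default_rng(6))
        import pandas as pd

        frame = pd.DataFrame({
            "drug_i": [tiny_world.drugs[0]], "drug_j": [tiny_world.drugs[1]],
            "side_effect": [tiny_world.side_effects[0]], "label": [0],
        })
        s = predict_scores(model, frame, tiny_world.expressions)[0]
        h1 = encode_drug(tiny_world.expressions.iloc[0].to_numpy(), model)
        h2 = encode_drug(tiny_world.expressions.iloc[1].to_numpy(), model)
        z1 = h1 @ model.Wr.data + model.br.data
        z2 = h2 @ model.Wr.data + model.br.data
        se = model.side_effect_space(tiny_world.side_effects[0])
        assert s == pytest.approx(triplet_score(z1, z2, se), rel=1e-12)
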