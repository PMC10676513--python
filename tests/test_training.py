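"""Margin loss, rough embeddings, negative sampling, and two-stage training."""

import numpy as np
import pytest

from termalign import (
    AlignmentModel,
    Projection,
    encode_name,
    make_test_encoder,
    margin_loss,
    rough_embeddings,
    sample_negatives,
)
from termalign import training as tr
from termalign.synth import SynthConfig, generate_pair


def small_model(seed=0, **kw):
    defaults = dict(rng_seed=seed, d_enc=64, d_proj=16, hidden=8)
    defaults.update(kw)
    return AlignmentModel.build(**defaults)


class TestMarginLoss:
    def test_worked_hinge_value(self):
        assert margin_loss(0.2, [0.5], 1.0) == pytest.approx(0.7)

    def test_inactive_when_separated(self):
        assert margin_loss(0.2, [1.5, 2.0, 1.2], 1.0) == 0.0

    def test_equal_distances_give_gamma(self):
        assert margin_loss(0.4, [0.4], 1.0) == pytest.approx(1.0)

    def test_nonnegative_and_zero_iff_separated(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            gamma = float(rng.uniform(0.1, 2.0))
            d_pos = float(rng.uniform(0, 3))
            d_negs = rng.uniform(0, 5, size=4).tolist()
            loss = margin_loss(d_pos, d_negs, gamma)
            assert loss >= 0.0
            separated = all(d >= d_pos + gamma for d in d_negs)
            assert (loss == 0.0) == separated

    def test_nonpositive_margin_rejected(self):
        with pytest.raises(Exception, match="margin"):
            margin_loss(0.1, [0.2], 0.0)


class TestRoughEmbeddings:
    def test_equals_encode_name_per_concept(self):
        pair = generate_pair(SynthConfig(n_concepts=10, rng_seed=1))
        enc = make_test_encoder(dim=64, rng_seed=0)
        proj = Projection.init(64, 16, np.random.default_rng(0))
        rough = rough_embeddings(pair.source, enc, proj)
        assert len(rough) == 10
        for cid, vec in rough.items():
            assert vec.shape == (16,)
            np.testing.assert_array_equal(
                vec, encode_name(enc, proj, pair.source.concepts[cid])
            )


class TestSampleNegatives:
    def _pool(self, n, seed=2):
        rng = np.random.default_rng(seed)
        return {f"T{i:03d}": rng.normal(size=8) for i in range(n)}

    def test_five_from_fifty_excludes_gold(self):
        pool = self._pool(60)
        q = np.zeros(8)
        out = sample_negatives("e", pool, m=5, p=50, rng=np.random.default_rng(0),
                               gold_id="T005", query_vec=q)
        assert len(out) == 5 and len(set(out)) == 5
        assert "T005" not in out

    def test_tiny_target_base_returns_all_non_gold(self):
        pool = self._pool(6)
        out = sample_negatives("e", pool, m=5, p=50, rng=np.random.default_rng(1),
                               gold_id="T000", query_vec=np.zeros(8))
        assert sorted(out) == [f"T{i:03d}" for i in range(1, 6)]

    def test_deterministic_given_rng_seed(self):
        pool = self._pool(40)
        a = sample_negatives("e", pool, m=5, p=20, rng=np.random.default_rng(9),
                             gold_id="T001", query_vec=np.ones(8))
        b = sample_negatives("e", pool, m=5, p=20, rng=np.random.default_rng(9),
                             gold_id="T001", query_vec=np.ones(8))
        assert a == b

    def test_samples_come_from_nearest_pool(self):
        # Pool members are the p nearest by l2; far-away ids never appear.
        pool = {f"N{i}": np.full(4, float(i)) for i in range(30)}
        out = sample_negatives("e", pool, m=3, p=5, rng=np.random.default_rng(3),
                               gold_id="N0", query_vec=np.zeros(4))
        assert set(out) <= {"N1", "N2", "N3", "N4", "N5"}

    def test_too_few_candidates_rejected(self):
        pool = self._pool(3)
        with pytest.raises(Exception, match="negative candidates"):
            sample_negatives("e", pool, m=5, p=50, rng=np.random.default_rng(0),
                             gold_id="T000", query_vec=np.zeros(8))


class TestTrain:
    def test_stage1_loss_decreases_on_separable_toy(self):
        pair = generate_pair(SynthConfig(n_concepts=50, rng_seed=3))
        cfg = tr.TrainingConfig(
            epochs=5, rng_seed=3, learning_rate=0.005,
            negatives_per_positive=5, candidate_pool=5,  # fixed negatives
        )
        trained = tr.train(pair.source, pair.target, pair.gold, cfg, model=small_model(3))
        losses = [r["loss"] for r in trained.log if r["stage"] == 1]
        assert len(losses) == 5
        assert losses[-1] <= losses[0]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_zero_loss_leaves_parameters_unchanged(self):
        pair = generate_pair(SynthConfig(n_concepts=30, rng_seed=4))
        model = small_model(4)
        # find the initial separation and pick a margin below it
        probe_cfg = tr.TrainingConfig(epochs=1, rng_seed=4, learning_rate=0.0)
        probe = tr.train(pair.source, pair.target, pair.gold, probe_cfg, model=small_model(4))
        assert probe.log[0]["loss"] >= 0.0
        # identical names make d_pos = 0; any margin below the smallest
        # negative distance keeps every hinge inactive
        w_before = model.projection.weight.copy()
        cfg = tr.TrainingConfig(epochs=3, rng_seed=4, margin=1e-9)
        trained = tr.train(pair.source, pair.target, pair.gold, cfg, model=model)
        losses = [r["loss"] for r in trained.log if r["stage"] == 1]
        assert all(l == 0.0 for l in losses)
        np.testing.assert_array_equal(trained.model.projection.weight, w_before)

    def test_training_reproducible(self):
        pair = generate_pair(SynthConfig(n_concepts=40, p_synonym=0.4, rng_seed=5))
        cfg = tr.TrainingConfig(epochs=4, rng_seed=5)
        a = tr.train(pair.source, pair.target, pair.gold, cfg, model=small_model(5))
        b = tr.train(pair.source, pair.target, pair.gold, cfg, model=small_model(5))
        fa = [r["loss"] for r in a.log if "loss" in r]
        fb = [r["loss"] for r in b.log if "loss" in r]
        np.testing.assert_allclose(fa, fb, atol=1e-6)

    def test_training_improves_over_untrained_model(self):
        from termalign import evaluation as ev

        pair = generate_pair(SynthConfig(n_concepts=100, p_synonym=0.3, rng_seed=6))
        cfg = tr.TrainingConfig(epochs=10, rng_seed=6)
        seeds = tr.split_seeds(pair.gold, cfg.train_fraction, cfg.seed_cap, cfg.rng_seed)
        val = seeds.validation
        queries = [s for s, _ in val]
        gold = dict(val)
        untrained = small_model(6, d_enc=256, d_proj=64)
        r0 = ev.rank_all(untrained, pair.source, pair.target, queries, pair.target.ids())
        h0 = ev.hits_at_k(r0, gold, 1)
        trained = tr.train(pair.source, pair.target, seeds, cfg,
                           model=small_model(6, d_enc=256, d_proj=64))
        h1 = trained.log[-1]["validation_hits_at_1"]
        assert h1 > h0

    def test_empty_train_split_rejected(self):
        pair = generate_pair(SynthConfig(n_concepts=10, rng_seed=7))
        from termalign import AlignmentSeeds

        labeled = AlignmentSeeds(
            pairs=pair.gold.pairs, labels=["validation"] * len(pair.gold.pairs)
        )
        with pytest.raises(Exception, match="empty training split"):
            tr.train(pair.source, pair.target, labeled,
                     tr.TrainingConfig(epochs=1), model=small_model())

    def test_config_validation(self):
        with pytest.raises(Exception, match="margin"):
            tr.TrainingConfig(margin=0.0)
        with pytest.raises(Exception, match="candidate_pool"):
            tr.TrainingConfig(negatives_per_positive=10, candidate_pool=5)
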