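import math

import numpy as np
import pytest

from phositec import cspred, nn
from phositec.cspred import ClassifierConfig, LabeledSite
from phositec.msio import PhosSiteID


def pairwise_auroc(labels, scores):
    """O(n^2) concordance oracle with 0.5 credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestFuseEmbeddings:
    def test_dimensions(self):
        rng = np.random.default_rng(0)
        align = nn.Linear(1024, 1152, rng)
        both = cspred.fuse_embeddings(rng.normal(size=1024), rng.normal(size=128), align)
        only = cspred.fuse_embeddings(rng.normal(size=1024), None, align)
        assert both.shape == (1152,) and only.shape == (1152,)

    def test_zero_alignment_linearity(self):
        align = nn.Linear(8, 10, np.random.default_rng(0))
        align.weight.data[:] = 0.0
        out = cspred.fuse_embeddings(np.zeros(8), None, align)
        assert np.array_equal(out, np.zeros(10))

    def test_wrong_dimension_errors(self):
        align = nn.Linear(8, 10, np.random.default_rng(0))
        with pytest.raises(ValueError):
            cspred.fuse_embeddings(np.zeros(7), None, align)

    def test_classifier_widths_halve(self):
        cfg = ClassifierConfig(seq_dim=1024, ms_dim=128)
        assert cfg.widths == [1152, 576, 288, 144, 1]


class TestLossWeights:
    def sites(self):
        return [
            LabeledSite(PhosSiteID("P1", "S", 10), 1, in_aloop=True),
            LabeledSite(PhosSiteID("P1", "T", 90), 0, in_aloop=False),
        ]

    def test_assignment(self):
        inl, outl = cspred.assign_loss_weights(self.sites(), 4.0)
        assert inl.weight == 1.0 and outl.weight == 4.0

    def test_unweighted(self):
        assert all(s.weight == 1.0 for s in cspred.assign_loss_weights(self.sites(), 1.0))

    def test_invalid_weight(self):
        with pytest.raises(ValueError):
            cspred.assign_loss_weights(self.sites(), 0.5)


class TestWeightedBce:
    def test_ln2_at_zero_logit(self):
        assert cspred.weighted_bce([0.0], [1.0], [1.0]) == pytest.approx(math.log(2))

    def test_linear_in_weights(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.integers(0, 2, 6).astype(float)
        w = rng.uniform(1, 3, 6)
        assert cspred.weighted_bce(x, y, 2 * w) == pytest.approx(
            2 * cspred.weighted_bce(x, y, w)
        )

    def test_saturation(self):
        assert cspred.weighted_bce([20.0], [1.0], [1.0]) < 1e-8

    def test_all_ones_equals_unweighted(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=9), rng.integers(0, 2, 9).astype(float)
        assert cspred.weighted_bce(x, y, np.ones(9)) == pytest.approx(
            cspred.weighted_bce(x, y), abs=1e-12
        )

    def test_monotone_in_out_weight(self):
        # a batch holding an out-of-A-loop error: larger w_out -> larger loss
        x = np.array([0.0, 2.0])
        y = np.array([1.0, 1.0])
        losses = [
            cspred.weighted_bce(x, y, np.array([w, 1.0])) for w in (1, 2, 4, 8, 16)
        ]
        assert all(a < b for a, b in zip(losses, losses[1:]))

    def test_nonfinite_logits_error(self):
        with pytest.raises(ValueError):
            cspred.weighted_bce([float("inf")], [1.0], [1.0])

    def test_tensor_loss_agrees_with_reference(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=8), rng.integers(0, 2, 8).astype(float)
        w = rng.uniform(1, 5, 8)
        t = cspred._bce_loss_tensor(nn.Tensor(x), y, w).item()
        assert t == pytest.approx(cspred.weighted_bce(x, y, w), abs=1e-12)


class TestUndersampleRounds:
    def test_disjoint_and_exhausting(self):
        rng = np.random.default_rng(0)
        rounds = cspred.undersample_rounds(list("abc"), list(range(90)), 10, 3, rng)
        negs = [set(n) for _, n in rounds]
        assert all(len(n) == 30 for n in negs)
        assert negs[0] | negs[1] | negs[2] == set(range(90))
        assert not (negs[0] & negs[1] or negs[0] & negs[2] or negs[1] & negs[2])

    def test_single_round(self):
        rng = np.random.default_rng(0)
        (pos, neg), = cspred.undersample_rounds(list("abc"), list(range(90)), 10, 1, rng)
        assert len(neg) == 30 and pos == list("abc")

    def test_short_pool_remainder_policy(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="short"):
            rounds = cspred.undersample_rounds(list("abc"), list(range(50)), 10, 3, rng)
        assert [len(n) for _, n in rounds] == [30, 20, 0]

    def test_empty_positives_error(self):
        with pytest.raises(ValueError):
            cspred.undersample_rounds([], [1], 10, 3, np.random.default_rng(0))


class TestComputeMetrics:
    def test_worked_example(self):
        m = cspred.compute_metrics([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert m["auroc"] == pytest.approx(0.75)

    def test_perfect_separation(self):
        m = cspred.compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert m["auroc"] == 1.0 and m["mcc"] == 1.0

    def test_f1_half(self):
        # TP=1, FP=1, FN=1 -> precision = recall = 0.5
        m = cspred.compute_metrics([1, 0, 1, 0], [0.9, 0.9, 0.1, 0.1])
        assert m["f1"] == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            cspred.compute_metrics([1, 1], [0.5, 0.6])

    def test_auroc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if len(set(y.tolist())) < 2:
                continue
            s = np.round(rng.random(n), 2)  # rounding induces ties
            assert cspred.compute_metrics(y, s)["auroc"] == pytest.approx(
                pairwise_auroc(y, s), abs=1e-12
            )


class TestSelectHighConfidence:
    def test_printed_count(self):
        rng = np.random.default_rng(0)
        scores = {f"P{i:05d}:S10": float(rng.random()) for i in range(5428)}
        assert len(cspred.select_high_confidence(scores, 0.05)) == 272

    def test_ceiling(self):
        scores = {f"P{i}:S10": float(i) for i in range(10)}
        assert len(cspred.select_high_confidence(scores, 0.05)) == 1

    def test_tie_break_lexicographic(self):
        scores = {"B:S1": 1.0, "A:S1": 1.0, "C:S1": 0.5}
        assert cspred.select_high_confidence(scores, 1 / 3) == ["A:S1"]

    def test_empty(self):
        assert cspred.select_high_confidence({}, 0.05) == []


class TestTraining:
    def test_separable_classes_and_determinism(self):
        rng = np.random.default_rng(0)
        n = 120
        y = rng.permutation(np.r_[np.ones(20), np.zeros(100)]).astype(int)
        seq = rng.normal(size=(n, 32)) + np.where(y == 1, 3.0, 0.0)[:, None]
        ms = rng.normal(size=(n, 8)) + np.where(y == 1, 3.0, 0.0)[:, None]
        has = np.ones(n, bool)
        sites = [
            LabeledSite(PhosSiteID(f"P{i:03d}", "S", 10), int(y[i]), in_aloop=bool(i % 2))
            for i in range(n)
        ]
        cfg = ClassifierConfig(seq_dim=32, ms_dim=8, max_epochs=30, patience=6)
        proto = cspred.TrainingProtocol(rounds=2, neg_pos_ratio=2, cv_folds=3, seed=1)
        r1 = cspred.train_cspred(seq, ms, has, sites, proto, cfg)
        assert r1["auroc_mean"] > 0.9
        r2 = cspred.train_cspred(seq, ms, has, sites, proto, cfg)
        assert [m["auroc"] for m in r1["rounds"]] == [m["auroc"] for m in r2["rounds"]]
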