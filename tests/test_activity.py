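import numpy as np
import pytest

from phositec import activity
from phositec.activity import DownshiftConfig
from phositec.msio import NormalizedPhosMatrix, PhosSiteID


def brute_force_es(ranked, gene_set, p=1.0):
    """Independent running-sum walk, written as a plain loop."""
    hits = [(s in gene_set) for s, _ in ranked]
    n, nh = len(ranked), sum(hits)
    denom = sum(abs(v) ** p for (s, v), h in zip(ranked, hits) if h)
    running, best = 0.0, 0.0
    for (s, v), h in zip(ranked, hits):
        if h:
            running += (abs(v) ** p) / denom
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


def make_matrix(vals, sites=None):
    vals = np.asarray(vals, float)
    if sites is None:
        sites = [PhosSiteID(f"P{i:04d}", "S", 10) for i in range(vals.shape[0])]
    samples = [f"s{j}" for j in range(vals.shape[1])]
    return NormalizedPhosMatrix(sites, samples, vals)


class TestSplitByDetection:
    def test_partition(self):
        m = make_matrix([[0, 0.2, 0.9, 0]])
        phos, non = activity.split_by_site_detection(m, m.sites[0])
        assert (phos, non) == (["s1", "s2"], ["s0", "s3"])

    def test_degenerate_groups(self):
        m = make_matrix([[0, 0], [0.3, 0.4]])
        assert activity.split_by_site_detection(m, m.sites[0])[0] == []
        assert activity.split_by_site_detection(m, m.sites[1])[1] == []

    def test_absent_site_errors(self):
        m = make_matrix([[0.1]])
        with pytest.raises(KeyError):
            activity.split_by_site_detection(m, PhosSiteID("X1", "S", 1))


class TestRankByFoldChange:
    def test_ordering_and_antisymmetry(self):
        m = make_matrix([[0.4, 0.4, 0.1, 0.1], [0.2, 0.2, 0.2, 0.2]])
        groups = (["s0", "s1"], ["s2", "s3"])
        ranked = activity.rank_by_foldchange(m, groups)
        assert ranked[0][0] == m.sites[0]
        assert ranked[0][1] == pytest.approx(2.0, abs=1e-4)
        assert ranked[1][1] == pytest.approx(0.0, abs=1e-12)
        flipped = activity.rank_by_foldchange(m, (groups[1], groups[0]))
        assert flipped[-1][0] == m.sites[0]
        assert flipped[-1][1] == pytest.approx(-ranked[0][1])

    def test_empty_group_errors(self):
        m = make_matrix([[0.1, 0.2]])
        with pytest.raises(ValueError):
            activity.rank_by_foldchange(m, ([], ["s0", "s1"]))


class TestEnrichmentScore:
    def sites(self, n):
        return [PhosSiteID(f"P{i:04d}", "S", 10) for i in range(n)]

    def test_top_singleton_unweighted(self):
        s = self.sites(3)
        ranked = list(zip(s, [3.0, 2.0, 1.0]))
        es, walk = activity.enrichment_score(ranked, {s[0]}, weight_p=0)
        assert es == pytest.approx(1.0)
        assert walk == pytest.approx([1.0, 0.5, 0.0])

    def test_bottom_singleton_unweighted(self):
        s = self.sites(3)
        ranked = list(zip(s, [3.0, 2.0, 1.0]))
        es, _ = activity.enrichment_score(ranked, {s[2]}, weight_p=0)
        assert es == pytest.approx(-1.0)

    def test_degenerate_sets_error(self):
        s = self.sites(3)
        ranked = list(zip(s, [3.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            activity.enrichment_score(ranked, set(s))
        with pytest.raises(ValueError):
            activity.enrichment_score(ranked, {PhosSiteID("Z1", "S", 1)})

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            s = self.sites(n)
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = list(zip(s, scores))
            k = int(rng.integers(1, n))
            gene_set = {s[i] for i in rng.choice(n, size=k, replace=False)}
            p = float(rng.choice([0.0, 1.0, 2.0]))
            es, _ = activity.enrichment_score(ranked, gene_set, p)
            assert es == pytest.approx(brute_force_es(ranked, gene_set, p), abs=1e-12)

    def test_reversal_antisymmetry_p0(self):
        rng = np.random.default_rng(1)
        s = self.sites(12)
        scores = np.sort(rng.normal(size=12))[::-1]
        gene_set = {s[i] for i in (0, 3, 7)}
        es_fwd, _ = activity.enrichment_score(list(zip(s, scores)), gene_set, 0)
        es_rev, _ = activity.enrichment_score(
            list(zip(s[::-1], scores[::-1])), gene_set, 0
        )
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    def test_es_bounded(self):
        rng = np.random.default_rng(2)
        s = self.sites(20)
        for _ in range(20):
            scores = rng.normal(size=20)
            order = np.argsort(-scores)
            ranked = [(s[i], scores[i]) for i in order]
            gene_set = {s[i] for i in rng.choice(20, size=5, replace=False)}
            es, _ = activity.enrichment_score(ranked, gene_set)
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12


class TestNormalizedEnrichment:
    def make_ranked(self, n=200, planted=20, seed=0):
        rng = np.random.default_rng(seed)
        sites = [PhosSiteID(f"P{i:04d}", "S", 10) for i in range(n)]
        scores = np.sort(rng.normal(size=n))[::-1]
        gene_set = set(sites[:planted])  # concentrated at the top
        return list(zip(sites, scores)), gene_set, sites

    def test_planted_set_scores_high(self):
        passed = 0
        for seed in range(5):
            ranked, gene_set, _ = self.make_ranked(seed=seed)
            res = activity.normalized_enrichment(
                ranked, gene_set, permutations=500, rng=np.random.default_rng(seed)
            )
            passed += res.nes > 1.5
        assert passed >= 4

    def test_random_set_near_null(self):
        ranked, _, sites = self.make_ranked(seed=3)
        rng = np.random.default_rng(3)
        nes = []
        for _ in range(20):
            random_set = {sites[i] for i in rng.choice(200, size=20, replace=False)}
            res = activity.normalized_enrichment(
                ranked, random_set, permutations=200, rng=rng
            )
            nes.append(abs(res.nes))
        assert np.median(nes) < 1.5

    def test_seeded_determinism(self):
        ranked, gene_set, _ = self.make_ranked(seed=4)
        a = activity.normalized_enrichment(
            ranked, gene_set, 200, np.random.default_rng(9)
        )
        b = activity.normalized_enrichment(
            ranked, gene_set, 200, np.random.default_rng(9)
        )
        assert a.nes == b.nes

    def test_invariant_to_monotone_rescaling_at_p0(self):
        ranked, gene_set, _ = self.make_ranked(seed=5)
        rescaled = [(s, 10 * v + 3) for s, v in ranked]
        a = activity.normalized_enrichment(
            ranked, gene_set, 200, np.random.default_rng(1), weight_p=0
        )
        b = activity.normalized_enrichment(
            rescaled, gene_set, 200, np.random.default_rng(1), weight_p=0
        )
        assert a.nes == pytest.approx(b.nes, abs=1e-12)


class TestDownshiftImpute:
    def test_constant_observed(self):
        x = np.array([2.0, 2.0, 2.0, np.nan])
        out = activity.downshift_impute(x, rng=np.random.default_rng(0))
        assert out[3] == pytest.approx(2.0)

    def test_large_sample_moments(self):
        rng = np.random.default_rng(1)
        n = 25000
        x = np.r_[rng.normal(10.0, 2.0, size=n), np.full(10000, np.nan)]
        out = activity.downshift_impute(x, rng=np.random.default_rng(2))
        obs = x[~np.isnan(x)]
        mu0, sd0 = obs.mean(), obs.std(ddof=1)
        imputed = out[np.isnan(x)]
        tol = 3 * (0.5 * sd0) / np.sqrt(len(imputed))
        assert abs(imputed.mean() - (mu0 - 0.5 * sd0)) < tol
        assert imputed.std(ddof=1) == pytest.approx(0.5 * sd0, rel=0.05)

    def test_rejects_excess_missingness(self):
        x = np.r_[np.ones(4), np.full(6, np.nan)]
        with pytest.raises(ValueError, match="rejected"):
            activity.downshift_impute(x)

    def test_lambda_positive_required(self):
        with pytest.raises(ValueError):
            DownshiftConfig(lam=0.0)


class TestBhAdjust:
    def test_known_example(self):
        adj = activity.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert np.all(activity.bh_adjust([0.5, 0.001]) <= 1.0)
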