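"""Feature statistics: oracles for t, Fisher, permutation and BH."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from cyanihgt import (
    GeneRecord,
    Lineage,
    benjamini_hochberg,
    exon_class_test,
    exon_count_test,
    expression_compare,
    gc_compare,
    go_enrichment,
)
from cyanihgt.stats import permutation_rank_sum


def gene(i, *, gc=40.0, exons=2, cpm=100.0, hgt=False, go=()):
    return GeneRecord(
        gene_id=f"g{i}", species="sp", lineage=Lineage.GALDIERIA,
        gc_percent=gc, exon_count=exons, cpm=cpm, is_hgt=hgt,
        og_id=f"OG{i}", go_terms=frozenset(go),
    )


def records(hgt_values, native_values, attr):
    out = []
    for i, v in enumerate(hgt_values):
        out.append(gene(i, hgt=True, **{attr: v}))
    for i, v in enumerate(native_values):
        out.append(gene(1000 + i, hgt=False, **{attr: v}))
    return out


class TestGcCompare:
    def test_identical_samples_degenerate(self):
        res = gc_compare(records([40, 40], [40, 40], "gc"))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_closed_form_welch_oracle(self):
        x = [38.2, 40.1, 41.5, 39.9]
        y = [39.0, 39.4, 40.8, 42.2]
        res = gc_compare(records(x, y, "gc"))
        # independent Welch computation from the textbook formulas
        mx, my = np.mean(x), np.mean(y)
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        se2 = vx / len(x) + vy / len(y)
        t = (mx - my) / math.sqrt(se2)
        df = se2**2 / (
            (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
        )
        p = 2 * sps.t.sf(abs(t), df)
        assert res.statistic == pytest.approx(t)
        assert res.p_value == pytest.approx(p)
        assert res.effect == pytest.approx(mx - my)

    def test_pooled_variance_flag(self):
        x, y = [38.0, 40.0, 41.0], [39.0, 41.0, 43.0, 44.0]
        res = gc_compare(records(x, y, "gc"), pooled_variance=True)
        t, p = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(float(t))

    def test_requires_two_per_class(self):
        with pytest.raises(ValueError):
            gc_compare(records([40.0], [39.0, 39.5], "gc"))


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration with
    exact integer arithmetic."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def weight(k):  # tables with first cell k and the same margins
        if k < max(0, c1 - r2) or k > min(r1, c1):
            return 0
        return math.comb(r1, k) * math.comb(r2, c1 - k)
    total = math.comb(n, c1)
    obs = weight(a)
    p = sum(w for k in range(0, min(r1, c1) + 1)
            if (w := weight(k)) <= obs) / total
    return p


class TestExonClassTest:
    def test_balanced_table_gives_p_one(self):
        res = exon_class_test(
            records([1] * 5 + [2] * 5, [1] * 5 + [2] * 5, "exons")
        )
        assert res.p_value == 1.0

    def test_two_sided_p_matches_enumeration(self):
        res = exon_class_test(
            records([1] * 8 + [2] * 2, [1] * 2 + [2] * 8, "exons")
        )
        assert res.p_value == pytest.approx(
            fisher_enumeration_oracle([[8, 2], [2, 8]])
        )

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning):
            res = exon_class_test(records([1, 1], [1, 1], "exons"))
        assert res.p_value == 1.0

    def test_effect_is_single_exon_proportion_difference(self):
        res = exon_class_test(
            records([1, 1, 1, 2], [1, 2, 2, 2], "exons")
        )
        assert res.effect == pytest.approx(0.75 - 0.25)


class TestExonCountTest:
    def test_small_sample_p_matches_exhaustive_label_enumeration(self):
        x = np.array([1.0, 2.0, 2.0, 5.0, 3.0])
        y = np.array([3.0, 4.0, 6.0, 4.0, 7.0])
        stat, p = permutation_rank_sum(x, y, rng=0)
        # independent oracle: every C(10, 5) assignment of labels
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        mu = ranks.sum() / 2
        obs = ranks[:5].sum()
        null = [
            sum(ranks[list(idx)])
            for idx in itertools.combinations(range(10), 5)
        ]
        oracle = np.mean([abs(s - mu) >= abs(obs - mu) - 1e-9 for s in null])
        assert p == pytest.approx(float(oracle))

    def test_planted_shift_is_detected(self):
        rng = np.random.default_rng(1)
        hgt = 1 + rng.poisson(0.3, size=60)
        native = 1 + rng.poisson(1.6, size=400)
        res = exon_count_test(records(hgt, native, "exons"), rng=2)
        assert res.p_value <= 0.05
        assert res.effect < 0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        recs = records(1 + rng.poisson(1.0, 40), 1 + rng.poisson(1.0, 40), "exons")
        a = exon_count_test(recs, rng=123)
        b = exon_count_test(recs, rng=123)
        assert a.p_value == b.p_value


class TestExpressionCompare:
    def test_means_match_hand_arithmetic(self):
        res = expression_compare(
            records([10.0, 20.0, 60.0], [30.0, 30.0, 60.0], "cpm")
        )
        assert res.extra["mean_hgt_cpm"] == pytest.approx(30.0)
        assert res.extra["mean_native_cpm"] == pytest.approx(40.0)
        assert res.effect == pytest.approx(-10.0)

    def test_equal_distributions_not_significant(self):
        rng = np.random.default_rng(2)
        v = rng.lognormal(4, 1, size=200)
        res = expression_compare(records(v[:50], v[50:], "cpm"))
        assert res.p_value > 0.05

    def test_all_zero_cpm_is_an_error(self):
        with pytest.raises(ValueError):
            expression_compare(records([0.0, 0.0], [0.0, 0.0], "cpm"))


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.05]).tolist() == [0.05]

    def test_step_up_collapses_evenly_spaced(self):
        out = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_matches_formula_oracle_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.random(size=int(rng.integers(1, 40)))
            ours = benjamini_hochberg(p)
            # brute-force step-up formula
            order = np.argsort(p)
            m = len(p)
            oracle = np.empty(m)
            for rank_pos, idx in enumerate(order, start=1):
                later = [
                    p[order[j]] * m / (j + 1)
                    for j in range(rank_pos - 1, m)
                ]
                oracle[idx] = min(1.0, min(later))
            assert np.allclose(ours, oracle)
            assert np.allclose(ours, multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(9)
        p = np.sort(rng.random(30))
        adj = benjamini_hochberg(p)
        assert np.all(np.diff(adj) >= -1e-12)


class TestGoEnrichment:
    def _records(self):
        out = []
        for i in range(20):  # HGT genes: all carry GO:A, none GO:B
            out.append(gene(i, hgt=True, go=("GO:A", f"GO:rand{i % 5}")))
        for i in range(200):
            out.append(gene(100 + i, hgt=False, go=("GO:B", f"GO:rand{i % 5}")))
        return out

    def test_extreme_association_has_smallest_p(self):
        results = go_enrichment(self._records())
        assert min(results, key=lambda t: results[t].p_value) == "GO:A"
        assert results["GO:A"].p_adjusted <= 0.05

    def test_rare_terms_excluded(self):
        recs = self._records() + [gene(999, hgt=True, go=("GO:once",))]
        results = go_enrichment(recs, min_occurrence=2)
        assert "GO:once" not in results

    def test_adjusted_matches_independent_step_up(self):
        results = go_enrichment(self._records())
        raw = {t: r.p_value for t, r in results.items()}
        terms = sorted(raw)
        oracle = benjamini_hochberg([raw[t] for t in terms])
        for t, adj in zip(terms, oracle):
            assert results[t].p_adjusted == pytest.approx(adj)

    def test_no_passing_terms_warns(self):
        with pytest.warns(UserWarning):
            out = go_enrichment([gene(0, hgt=True, go=("GO:x",)),
                                 gene(1, hgt=False)])
        assert out == {}
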