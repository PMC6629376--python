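"""Native-vs-HGT comparative statistics.

Horizontally acquired genes initially carry the donor genome's signature:
a shifted GC content, no spliceosomal introns (hence single-exon models),
and — if the transfer is recent — high identity to extant prokaryotic
relatives.  This module tests each signature on per-gene feature records:

* GC content: two-sided two-sample t-test (Welch by default),
* single- vs multi-exon composition: Fisher's exact test on the 2x2 table,
* exons per gene: Wilcoxon-Mann-Whitney with a label-permutation null,
* transcript abundance (CPM): rank-sum test (no shift expected),
* GO-term enrichment: per-term Fisher tests with Benjamini-Hochberg
  correction across terms.

Fisher, t and rank-sum machinery comes from :mod:`scipy.stats`; the
Benjamini-Hochberg step-up and the permutation null are implemented here
and are cross-checked against independent oracles in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .records import GeneRecord, StatResult

logger = logging.getLogger(__name__)


def _split(genes: Sequence[GeneRecord]) -> tuple[list[GeneRecord], list[GeneRecord]]:
    hgt = [g for g in genes if g.is_hgt]
    native = [g for g in genes if not g.is_hgt]
    return hgt, native


# ----------------------------------------------------------------------
# GC content
# ----------------------------------------------------------------------

def gc_compare(genes: Sequence[GeneRecord], pooled_variance: bool = False) -> StatResult:
    """Two-sided two-sample t-test on GC%, HGT vs native.

    Welch's unequal-variance form is the default; set ``pooled_variance``
    for the classical pooled form.  Effect is mean(HGT) - mean(native).
    """
    hgt, native = _split(genes)
    if len(hgt) < 2 or len(native) < 2:
        raise ValueError("gc_compare requires >=2 genes in each class")
    x = np.array([g.gc_percent for g in hgt])
    y = np.array([g.gc_percent for g in native])
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        # degenerate: identical constant samples
        return StatResult("t-test", 0.0, 1.0, len(x), len(y), 0.0)
    t, p = sps.ttest_ind(x, y, equal_var=pooled_variance)
    return StatResult(
        method="t-test" if pooled_variance else "welch-t",
        statistic=float(t),
        p_value=float(p),
        n1=len(x),
        n2=len(y),
        effect=float(x.mean() - y.mean()),
    )


# ----------------------------------------------------------------------
# exon structure
# ----------------------------------------------------------------------

def exon_class_test(genes: Sequence[GeneRecord]) -> StatResult:
    """Fisher's exact test on single- vs multi-exon composition.

    Table: [[HGT-single, HGT-multi], [native-single, native-multi]];
    effect is the difference in single-exon proportions (HGT - native).
    A zero margin yields p = 1 with a warning.
    """
    hgt, native = _split(genes)
    table = np.array(
        [
            [sum(g.exon_count == 1 for g in hgt), sum(g.exon_count > 1 for g in hgt)],
            [
                sum(g.exon_count == 1 for g in native),
                sum(g.exon_count > 1 for g in native),
            ],
        ]
    )
    n1, n2 = int(table[0].sum()), int(table[1].sum())
    if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        warnings.warn("degenerate 2x2 margin; Fisher p set to 1", stacklevel=2)
        odds, p = np.nan, 1.0
    else:
        odds, p = sps.fisher_exact(table, alternative="two-sided")
    effect = (table[0, 0] / n1 if n1 else 0.0) - (table[1, 0] / n2 if n2 else 0.0)
    return StatResult(
        method="fisher-exact",
        statistic=float(odds),
        p_value=float(p),
        n1=n1,
        n2=n2,
        effect=float(effect),
        extra={"table": table.tolist()},
    )


def rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Wilcoxon rank-sum statistic: sum of ranks of *x* in the pooled sample
    (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    return float(ranks[: len(x)].sum())


def permutation_rank_sum(
    x: np.ndarray,
    y: np.ndarray,
    n_resamples: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Two-sided label-permutation p-value for the rank-sum statistic.

    Returns ``(statistic, p)``.  When the pooled sample admits at most
    20 000 distinct label assignments the null is enumerated exhaustively
    (exact p); otherwise *n_resamples* random label shuffles are used with
    the add-one estimator ``(1 + #{|T*-mu| >= |T-mu|}) / (1 + n_resamples)``,
    which is valid and seed-reproducible.
    """
    import math as _math
    from itertools import combinations

    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    observed = ranks[:n1].sum()
    n = len(pooled)
    mu = ranks.sum() * n1 / n
    if _math.comb(n, n1) <= 20_000:
        null = np.array(
            [ranks[list(idx)].sum() for idx in combinations(range(n), n1)]
        )
        p = float((np.abs(null - mu) >= np.abs(observed - mu) - 1e-9).mean())
        return float(observed), p
    rng = np.random.default_rng(rng)
    tiled = np.tile(ranks, (n_resamples, 1))
    permuted = rng.permuted(tiled, axis=1)
    null = permuted[:, :n1].sum(axis=1)
    extreme = np.abs(null - mu) >= np.abs(observed - mu) - 1e-9
    p = (1 + int(extreme.sum())) / (1 + n_resamples)
    return float(observed), float(p)


def exon_count_test(
    genes: Sequence[GeneRecord],
    n_bootstrap: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> StatResult:
    """Rank-sum comparison of exons per gene with a resampled null.

    The permutation scheme shuffles class labels ``n_bootstrap`` times; the
    exact large-sample rank-sum p is reported alongside in ``extra``.
    Effect is the difference in mean exons per gene (HGT - native).
    """
    hgt, native = _split(genes)
    if len(hgt) < 2 or len(native) < 2:
        raise ValueError("exon_count_test requires >=2 genes in each class")
    x = np.array([g.exon_count for g in hgt], dtype=float)
    y = np.array([g.exon_count for g in native], dtype=float)
    statistic, p_perm = permutation_rank_sum(x, y, n_bootstrap, rng)
    _, p_exact = sps.mannwhitneyu(x, y, alternative="two-sided")
    return StatResult(
        method="rank-sum-permutation",
        statistic=statistic,
        p_value=p_perm,
        n1=len(x),
        n2=len(y),
        effect=float(x.mean() - y.mean()),
        extra={"p_rank_sum": float(p_exact)},
    )


# ----------------------------------------------------------------------
# expression
# ----------------------------------------------------------------------

def expression_compare(genes: Sequence[GeneRecord]) -> StatResult:
    """Rank-sum test on CPM, HGT vs native, with class means reported."""
    hgt, native = _split(genes)
    if len(hgt) < 1 or len(native) < 1:
        raise ValueError("expression_compare requires genes in both classes")
    x = np.array([g.cpm for g in hgt])
    y = np.array([g.cpm for g in native])
    if x.max(initial=0.0) == 0.0 and y.max(initial=0.0) == 0.0:
        raise ValueError("all CPM values are zero")
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return StatResult(
        method="rank-sum",
        statistic=float(u),
        p_value=float(p),
        n1=len(x),
        n2=len(y),
        effect=float(x.mean() - y.mean()),
        extra={"mean_hgt_cpm": float(x.mean()), "mean_native_cpm": float(y.mean())},
    )


# ----------------------------------------------------------------------
# multiple testing
# ----------------------------------------------------------------------

def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    ``adj[i] = min_{j >= i} ( p_(j) * m / j )`` over the sorted p-values,
    clipped at 1 and mapped back to the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ----------------------------------------------------------------------
# GO enrichment
# ----------------------------------------------------------------------

def go_enrichment(
    genes: Sequence[GeneRecord], min_occurrence: int = 2
) -> dict[str, StatResult]:
    """Per-GO-term Fisher enrichment of HGT vs native genes.

    Terms occurring fewer than *min_occurrence* times among HGT genes are
    excluded; Benjamini-Hochberg adjustment runs across all tested terms.
    Returns an ordered mapping term -> result (ascending adjusted p).
    """
    hgt, native = _split(genes)
    term_counts: dict[str, int] = {}
    for g in hgt:
        for t in g.go_terms:
            term_counts[t] = term_counts.get(t, 0) + 1
    tested = sorted(t for t, c in term_counts.items() if c >= min_occurrence)
    if not tested:
        warnings.warn("no GO term passes min_occurrence; empty result",
                      stacklevel=2)
        return {}
    results: dict[str, StatResult] = {}
    n_hgt, n_native = len(hgt), len(native)
    for term in tested:
        a = sum(term in g.go_terms for g in hgt)
        b = n_hgt - a
        c = sum(term in g.go_terms for g in native)
        d = n_native - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        effect = a / n_hgt - (c / n_native if n_native else 0.0)
        results[term] = StatResult(
            method="fisher-exact",
            statistic=float(odds),
            p_value=float(p),
            n1=n_hgt,
            n2=n_native,
            effect=float(effect),
            extra={"table": [[a, b], [c, d]]},
        )
    adjusted = benjamini_hochberg([results[t].p_value for t in tested])
    for term, adj in zip(tested, adjusted):
        results[term].p_adjusted = float(adj)
    return dict(
        sorted(results.items(), key=lambda kv: (kv[1].p_adjusted, kv[0]))
    )


# ----------------------------------------------------------------------
# per-species driver
# ----------------------------------------------------------------------

def per_species_suite(
    genes: Sequence[GeneRecord],
    n_bootstrap: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> dict[str, dict[str, StatResult]]:
    """Run GC, exon-class, exon-count and expression comparisons for every
    species with at least two genes in each class; under-sampled species
    are skipped with a log line."""
    rng = np.random.default_rng(rng)
    out: dict[str, dict[str, StatResult]] = {}
    for species in sorted({g.species for g in genes}):
        sub = [g for g in genes if g.species == species]
        hgt, native = _split(sub)
        if len(hgt) < 2 or len(native) < 2:
            logger.info("species %s: too few genes per class; skipped", species)
            continue
        out[species] = {
            "gc": gc_compare(sub),
            "exon_class": exon_class_test(sub),
            "exon_count": exon_count_test(sub, n_bootstrap, rng),
            "expression": expression_compare(sub),
        }
    return out
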