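"""Percent-identity (PID) analyses and trend statistics.

Covers four result families: per-orthogroup PID aggregates (within the
focal group and toward the non-eukaryotic donors), the ">70 % PID means
artifact" rule audit, Kendall correlation between within-group and
to-donor PID, and the cumulative-effects suite (rank-sum comparisons and
the Jonckheere-Terpstra ordered trend over orthogroup size).

Pairwise PID is computed from a global protein alignment
(:class:`Bio.Align.PairwiseAligner`, BLOSUM62) as identical positions over
aligned columns with both residues present (gap columns excluded from the
denominator).  The Jonckheere-Terpstra statistic and its permutation null,
and the small-sample permutation p for Kendall's tau, are implemented here.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats as sps

from .records import OGSummary, StatResult
from .stats import benjamini_hochberg

HGT_CATEGORIES = frozenset(
    {"shared", "galdieria_only", "cyanidioschyzon_only", "multiple_hgt", "uncertain"}
)
NATIVE_CATEGORY = "native_with_prok"
EGT_PHYLA = frozenset({"Cyanobacteria", "Chlamydiae", "Proteobacteria"})


# ----------------------------------------------------------------------
# pairwise percent identity
# ----------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def pairwise_pid(seq_a: str, seq_b: str) -> float:
    """Percent identity between two protein sequences under a global
    BLOSUM62 alignment; denominator = aligned residue-residue columns."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    identical = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        aligned_cols += a1 - a0
        for i, j in zip(range(a0, a1), range(b0, b1)):
            identical += seq_a[i] == seq_b[j]
    if aligned_cols == 0:
        return 0.0
    return 100.0 * identical / aligned_cols


# ----------------------------------------------------------------------
# per-orthogroup summary
# ----------------------------------------------------------------------

def _agg(values: Sequence[float]) -> tuple[float, float, float]:
    return (float(np.mean(values)), float(min(values)), float(max(values)))


def og_pid_summary(
    og_id: str,
    sequences: Mapping[str, str],
    focal_ids: set[str],
    donor_ids: set[str],
    category: str,
    galdieria_strain_of: Mapping[str, str] | None = None,
    pid_fn=pairwise_pid,
) -> OGSummary:
    """Aggregate PID statistics for one orthogroup.

    ``pid_within`` covers all focal-focal pairs, ``pid_to_donor`` all
    focal-donor pairs; ``max_candidate_pid`` is the highest PID any single
    focal candidate reaches toward any donor (the 70 %-rule quantity).
    ``og_size`` counts distinct *Galdieria* strains among the focal members
    (via *galdieria_strain_of*, mapping member id -> strain name).
    """
    if not focal_ids:
        raise ValueError(f"{og_id}: no focal members")
    focal = sorted(focal_ids & sequences.keys())
    donors = sorted(donor_ids & sequences.keys())
    within = [
        pid_fn(sequences[a], sequences[b])
        for a, b in itertools.combinations(focal, 2)
    ]
    to_donor: dict[str, list[float]] = {f: [] for f in focal}
    for f in focal:
        for d in donors:
            to_donor[f].append(pid_fn(sequences[f], sequences[d]))
    donor_pids = [p for pids in to_donor.values() for p in pids]
    strains = (
        {galdieria_strain_of[f] for f in focal if f in galdieria_strain_of}
        if galdieria_strain_of
        else set()
    )
    return OGSummary(
        og_id=og_id,
        category=category,
        og_size=len(strains),
        pid_within=_agg(within) if within else None,
        pid_to_donor=_agg(donor_pids) if donor_pids else None,
        max_candidate_pid=(
            max(max(p) for p in to_donor.values() if p) if donor_pids else None
        ),
    )


# ----------------------------------------------------------------------
# seventy percent rule
# ----------------------------------------------------------------------

@dataclass(slots=True)
class SeventyRuleAudit:
    """Partition of orthogroups around the PID artifact threshold."""

    threshold: float
    hgt_over: list[str]
    native_over: list[str]
    under: list[str]
    egt_attributable: list[str]  # native_over with donor phyla in the EGT set
    n_hgt_total: int
    n_native_total: int

    @property
    def hgt_over_percent(self) -> float:
        return 100.0 * len(self.hgt_over) / self.n_hgt_total if self.n_hgt_total else 0.0

    @property
    def native_over_percent(self) -> float:
        return (
            100.0 * len(self.native_over) / self.n_native_total
            if self.n_native_total
            else 0.0
        )


def seventy_rule_audit(
    summaries: Sequence[OGSummary], threshold: float = 70.0
) -> SeventyRuleAudit:
    """Audit which orthogroups contain an individual candidate whose PID to
    a donor strictly exceeds *threshold* (boundary values stay under)."""
    hgt_over, native_over, under, egt = [], [], [], []
    n_hgt = n_native = 0
    for s in summaries:
        is_hgt = s.category in HGT_CATEGORIES
        if is_hgt:
            n_hgt += 1
        elif s.category == NATIVE_CATEGORY:
            n_native += 1
        else:
            continue
        over = s.max_candidate_pid is not None and s.max_candidate_pid > threshold
        if not over:
            under.append(s.og_id)
        elif is_hgt:
            hgt_over.append(s.og_id)
        else:
            native_over.append(s.og_id)
            if s.donor_phyla & EGT_PHYLA:
                egt.append(s.og_id)
    return SeventyRuleAudit(
        threshold=threshold,
        hgt_over=sorted(hgt_over),
        native_over=sorted(native_over),
        under=sorted(under),
        egt_attributable=sorted(egt),
        n_hgt_total=n_hgt,
        n_native_total=n_native,
    )


# ----------------------------------------------------------------------
# Kendall correlation
# ----------------------------------------------------------------------

def kendall_trend(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Kendall's tau-b between within-group PID and to-donor PID.

    The p-value is exact (full permutation enumeration) for n <= 8 and the
    tie-corrected normal approximation above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("kendall_trend needs paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("tau undefined for a constant vector")
    tau, p_asym = sps.kendalltau(x, y)
    n = x.size
    if math.factorial(n) <= 100_000:
        observed = abs(tau)
        count = total = 0
        for perm in itertools.permutations(range(n)):
            t, _ = sps.kendalltau(x, y[list(perm)])
            total += 1
            if abs(t) >= observed - 1e-12:
                count += 1
        p = count / total
        method = "kendall-tau-exact"
    else:
        p = float(p_asym)
        method = "kendall-tau"
    return StatResult(
        method=method,
        statistic=float(tau),
        p_value=float(p),
        n1=n,
        n2=n,
        effect=float(tau),
    )


# ----------------------------------------------------------------------
# Jonckheere-Terpstra
# ----------------------------------------------------------------------

def jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """JT = sum over ordered group pairs (i < j) of
    #(x_i < x_j) + 0.5 #(x_i = x_j)."""
    total = 0.0
    for gi, gj in itertools.combinations(groups, 2):
        diff = gj[None, :] - gi[:, None]
        total += float((diff > 0).sum()) + 0.5 * float((diff == 0).sum())
    return total


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]],
    direction: str = "increasing",
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> StatResult:
    """Jonckheere-Terpstra test for an ordered trend across groups.

    ``direction='increasing'`` tests for values growing along the supplied
    group order; ``'decreasing'`` reverses the order.  The one-sided
    p-value comes from exhaustive enumeration of label permutations when
    the pooled sample admits at most 100 000 permutations, otherwise from
    *n_perm* seeded random permutations (add-one estimator).  A two-sided
    p is reported in ``extra``.
    """
    if len(groups) < 3:
        raise ValueError("jonckheere_terpstra needs >= 3 ordered groups")
    if direction not in {"increasing", "decreasing"}:
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if direction == "decreasing":
        arrays = arrays[::-1]
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    pooled = np.concatenate(arrays)
    n = pooled.size
    observed = jt_statistic(arrays)
    # null mean: half of all cross-pair comparisons
    mu = sum(si * sj for si, sj in itertools.combinations(sizes, 2)) / 2.0

    def regroup(values: np.ndarray) -> list[np.ndarray]:
        return [values[bounds[k]: bounds[k + 1]] for k in range(len(sizes))]

    if math.factorial(n) <= 100_000:
        stats = np.array(
            [
                jt_statistic(regroup(pooled[list(perm)]))
                for perm in itertools.permutations(range(n))
            ]
        )
        p_one = float((stats >= observed - 1e-9).mean())
        p_two = float((np.abs(stats - mu) >= abs(observed - mu) - 1e-9).mean())
        method = "jonckheere-terpstra-exact"
    else:
        gen = np.random.default_rng(rng)
        perms = gen.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
        stats = np.zeros(n_perm)
        for k, l in itertools.combinations(range(len(sizes)), 2):
            gi = perms[:, bounds[k]: bounds[k + 1]]
            gj = perms[:, bounds[l]: bounds[l + 1]]
            diff = gj[:, None, :] - gi[:, :, None]
            stats += (diff > 0).sum(axis=(1, 2)) + 0.5 * (diff == 0).sum(axis=(1, 2))
        p_one = (1 + int((stats >= observed - 1e-9).sum())) / (1 + n_perm)
        p_two = (
            1 + int((np.abs(stats - mu) >= abs(observed - mu) - 1e-9).sum())
        ) / (1 + n_perm)
        method = "jonckheere-terpstra-permutation"
    return StatResult(
        method=method,
        statistic=observed,
        p_value=float(p_one),
        n1=n,
        n2=len(sizes),
        effect=float(observed - mu),
        extra={"p_two_sided": float(p_two), "null_mean": mu},
    )


# ----------------------------------------------------------------------
# cumulative effects
# ----------------------------------------------------------------------

@dataclass(slots=True)
class CumulativeEffectsReport:
    global_donor_pid: StatResult | None = None
    jt_by_class: dict = field(default_factory=dict)
    per_size: dict = field(default_factory=dict)
    three_way: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def _donor_means(summaries: Sequence[OGSummary]) -> np.ndarray:
    return np.array(
        [s.pid_to_donor[0] for s in summaries if s.pid_to_donor is not None]
    )


def cumulative_effects_suite(
    summaries: Sequence[OGSummary],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> CumulativeEffectsReport:
    """Run the cumulative-effects test battery on orthogroup summaries.

    (a) global HGT-vs-native rank-sum test on mean donor PID;
    (b) Jonckheere-Terpstra trend of donor PID over orthogroup size within
        each class (direction: decreasing PID with increasing size);
    (c) per-size pairwise HGT-vs-native rank-sum tests, BH-adjusted;
    (d) three-way comparison of donor PID between shared,
        *Galdieria*-exclusive and *Cyanidioschyzon*-exclusive orthogroups,
        pairwise rank-sum with BH.
    Empty classes skip their tests with a note in ``skipped``.
    """
    rng = np.random.default_rng(rng)
    report = CumulativeEffectsReport()
    hgt = [s for s in summaries if s.category in HGT_CATEGORIES]
    native = [s for s in summaries if s.category == NATIVE_CATEGORY]

    hgt_pid = _donor_means(hgt)
    native_pid = _donor_means(native)
    if hgt_pid.size and native_pid.size:
        u, p = sps.mannwhitneyu(hgt_pid, native_pid, alternative="two-sided")
        report.global_donor_pid = StatResult(
            method="rank-sum",
            statistic=float(u),
            p_value=float(p),
            n1=hgt_pid.size,
            n2=native_pid.size,
            effect=float(hgt_pid.mean() - native_pid.mean()),
        )
    else:
        report.skipped.append("global_donor_pid: empty class")

    for label, subset in (("hgt", hgt), ("native", native)):
        by_size: dict[int, list[float]] = {}
        for s in subset:
            if s.pid_to_donor is not None and s.og_size >= 1:
                by_size.setdefault(s.og_size, []).append(s.pid_to_donor[0])
        sizes = sorted(k for k, v in by_size.items() if v)
        if len(sizes) >= 3:
            report.jt_by_class[label] = jonckheere_terpstra(
                [by_size[k] for k in sizes],
                direction="decreasing",
                n_perm=n_perm,
                rng=rng,
            )
        else:
            report.skipped.append(f"jt[{label}]: fewer than 3 occupied sizes")

    sizes_h = {s.og_size for s in hgt if s.pid_to_donor is not None}
    sizes_n = {s.og_size for s in native if s.pid_to_donor is not None}
    raw: dict[int, StatResult] = {}
    for size in sorted(sizes_h & sizes_n):
        a = np.array(
            [s.pid_to_donor[0] for s in hgt
             if s.og_size == size and s.pid_to_donor is not None]
        )
        b = np.array(
            [s.pid_to_donor[0] for s in native
             if s.og_size == size and s.pid_to_donor is not None]
        )
        if a.size < 2 or b.size < 2:
            continue
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        raw[size] = StatResult(
            "rank-sum", float(u), float(p), a.size, b.size,
            float(a.mean() - b.mean()),
        )
    if raw:
        adj = benjamini_hochberg([raw[k].p_value for k in sorted(raw)])
        for size, a_ in zip(sorted(raw), adj):
            raw[size].p_adjusted = float(a_)
    report.per_size = raw

    groups = {
        label: _donor_means([s for s in hgt if s.category == label])
        for label in ("shared", "galdieria_only", "cyanidioschyzon_only")
    }
    pairs = [
        (a, b)
        for a, b in itertools.combinations(groups, 2)
        if groups[a].size >= 2 and groups[b].size >= 2
    ]
    three: dict[tuple[str, str], StatResult] = {}
    for a, b in pairs:
        u, p = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        three[(a, b)] = StatResult(
            "rank-sum", float(u), float(p), groups[a].size, groups[b].size,
            float(groups[a].mean() - groups[b].mean()),
        )
    if three:
        adj = benjamini_hochberg([three[k].p_value for k in sorted(three)])
        for key, a_ in zip(sorted(three), adj):
            three[key].p_adjusted = float(a_)
    elif not pairs:
        report.skipped.append("three_way: insufficient categories")
    report.three_way = three
    return report
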