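"""PID computation, the 70 % rule, Kendall and Jonckheere-Terpstra."""

import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from cyanihgt import (
    OGSummary,
    jonckheere_terpstra,
    jt_statistic,
    kendall_trend,
    og_pid_summary,
    pairwise_pid,
    seventy_rule_audit,
)


# ----------------------------------------------------------------------
# pairwise PID
# ----------------------------------------------------------------------

def nw_score_oracle(a, b, open_gap=-11.0, extend_gap=-1.0):
    """Independent affine-gap Needleman-Wunsch optimal score (Gotoh)."""
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    neg = -1e9
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_gap + extend_gap * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = open_gap + extend_gap * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + s
            X[i][j] = max(M[i - 1][j] + open_gap, X[i - 1][j] + extend_gap,
                          Y[i - 1][j] + open_gap)
            Y[i][j] = max(M[i][j - 1] + open_gap, Y[i][j - 1] + extend_gap,
                          X[i][j - 1] + open_gap)
    return max(M[n][m], X[n][m], Y[n][m])


AA = "ACDEFGHIKLMNPQRSTVWY"


class TestPairwisePid:
    def test_identity(self):
        seq = "MKVLITGAGSGIGLAVAKEL"
        assert pairwise_pid(seq, seq) == 100.0

    def test_three_of_four(self):
        assert pairwise_pid("AAAA", "AAAT") == 75.0

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            pairwise_pid("", "AAAA")

    def test_substitution_only_pairs_match_hamming(self):
        # same length, few scattered substitutions: the optimal global
        # alignment is the identity alignment, so PID = 1 - mismatches/len
        rng = np.random.default_rng(21)
        for _ in range(5):
            a = "".join(rng.choice(list(AA), size=60))
            b = list(a)
            pos = rng.choice(60, size=6, replace=False)
            for p in pos:
                b[p] = AA[(AA.index(b[p]) + 1) % 20]
            pid = pairwise_pid(a, "".join(b))
            assert pid == pytest.approx(100.0 * 54 / 60)

    def test_aligner_score_matches_dp_oracle(self):
        from cyanihgt.pid import _ALIGNER

        rng = np.random.default_rng(22)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(10, 30))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(10, 30))))
            assert _ALIGNER.score(a, b) == pytest.approx(nw_score_oracle(a, b))


class TestOgPidSummary:
    def test_identical_focal_pair_with_half_identity_donor(self):
        seqs = {
            "f1": "MKVLITGAGSGIGLAVAKEL",
            "f2": "MKVLITGAGSGIGLAVAKEL",
            "d1": "MKVLITGAGSWPYHWHWHWH",  # 50% identical to focal
        }
        s = og_pid_summary("OG1", seqs, {"f1", "f2"}, {"d1"}, "shared")
        assert s.pid_within == (100.0, 100.0, 100.0)
        assert s.pid_to_donor[0] == pytest.approx(50.0, abs=6.0)
        assert s.max_candidate_pid == s.pid_to_donor[2]

    def test_all_pairs_averaged_matches_enumeration(self):
        # stub PID function: value encodes the pair, so the aggregation
        # (all 6 focal-donor pairs, all 3 focal-focal pairs) is checkable
        table = {}
        ids = ["f1", "f2", "f3", "d1", "d2"]
        rng = np.random.default_rng(5)
        for x, y in itertools.combinations(ids, 2):
            table[frozenset((x, y))] = float(rng.uniform(20, 90))
        fake = lambda a, b: table[frozenset((a, b))]
        seqs = {i: i for i in ids}
        s = og_pid_summary(
            "OG2", seqs, {"f1", "f2", "f3"}, {"d1", "d2"}, "galdieria_only",
            pid_fn=fake,
        )
        within = [table[frozenset(p)] for p in
                  itertools.combinations(["f1", "f2", "f3"], 2)]
        donor = [table[frozenset((f, d))]
                 for f in ["f1", "f2", "f3"] for d in ["d1", "d2"]]
        assert s.pid_within[0] == pytest.approx(np.mean(within))
        assert s.pid_to_donor[0] == pytest.approx(np.mean(donor))
        assert s.max_candidate_pid == pytest.approx(
            max(max(table[frozenset((f, d))] for d in ["d1", "d2"])
                for f in ["f1", "f2", "f3"])
        )

    def test_og_size_counts_galdieria_strains(self):
        seqs = {"f1": "MKVL", "f2": "MKVL", "f3": "MKVL"}
        s = og_pid_summary(
            "OG3", seqs, set(seqs), set(), "galdieria_only",
            galdieria_strain_of={"f1": "S1", "f2": "S1", "f3": "S2"},
        )
        assert s.og_size == 2
        assert s.pid_to_donor is None


def summary(og_id, category, max_pid, phyla=("Firmicutes",)):
    return OGSummary(
        og_id=og_id, category=category, og_size=3,
        pid_to_donor=(min(max_pid, 50.0), 20.0, max(max_pid, 50.0)),
        max_candidate_pid=max_pid, donor_phyla=frozenset(phyla),
    )


class TestSeventyRule:
    def test_boundary_is_strict(self):
        audit = seventy_rule_audit([summary("a", "shared", 69.9),
                                    summary("b", "shared", 70.0)])
        assert audit.hgt_over == []
        assert len(audit.under) == 2

    def test_five_of_ninety_six(self):
        over = [75.56, 75.76, 80.00, 72.37, 71.17]
        ogs = [summary(f"h{i}", "galdieria_only", v)
               for i, v in enumerate(over)]
        ogs += [summary(f"u{i}", "galdieria_only", 40.0) for i in range(91)]
        audit = seventy_rule_audit(ogs)
        assert len(audit.hgt_over) == 5
        assert audit.n_hgt_total == 96
        assert round(audit.hgt_over_percent, 1) == 5.2

    def test_threshold_hundred_flags_nothing(self):
        ogs = [summary(f"h{i}", "shared", 99.0) for i in range(5)]
        audit = seventy_rule_audit(ogs, threshold=100.0)
        assert audit.hgt_over == []

    def test_egt_attribution_by_phylum(self):
        ogs = [
            summary("n1", "native_with_prok", 80.0, ("Cyanobacteria",)),
            summary("n2", "native_with_prok", 80.0, ("Bacteroidetes",)),
        ]
        audit = seventy_rule_audit(ogs)
        assert audit.egt_attributable == ["n1"]
        assert sorted(audit.native_over) == ["n1", "n2"]


class TestKendall:
    def test_perfect_concordance(self):
        res = kendall_trend([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_discordance(self):
        res = kendall_trend([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert res.statistic == pytest.approx(-1.0)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError):
            kendall_trend([1, 1, 1], [1, 2, 3])

    def test_exact_p_matches_enumeration_with_tie(self):
        from scipy import stats as sps

        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 5.0]  # one tie in y
        res = kendall_trend(x, y)
        tau_obs = abs(sps.kendalltau(x, y).statistic)
        count = 0
        perms = list(itertools.permutations(y))
        for perm in perms:
            t = sps.kendalltau(x, perm).statistic
            if abs(t) >= tau_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / len(perms))


class TestJonckheereTerpstra:
    def test_maximal_ordering(self):
        res = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == 12.0
        # 8 of the 720 pooled orderings reach the maximum: the three group
        # value-sets are forced, each permutable internally (2!^3)
        assert res.p_value == pytest.approx(8 / 720)

    def test_all_equal_gives_null_mean_and_p_one(self):
        res = jonckheere_terpstra([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert res.statistic == res.extra["null_mean"] == 6.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_exhaustive_oracle_on_random_data(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            groups = [rng.integers(0, 6, size=2).tolist(),
                      rng.integers(0, 6, size=3).tolist(),
                      rng.integers(0, 6, size=2).tolist()]
            res = jonckheere_terpstra(groups)
            pooled = [v for g in groups for v in g]
            sizes = [len(g) for g in groups]
            obs = jt_statistic([np.array(g, float) for g in groups])
            count = total = 0
            for perm in itertools.permutations(pooled):
                arrs, k = [], 0
                for s in sizes:
                    arrs.append(np.array(perm[k:k + s], float))
                    k += s
                total += 1
                if jt_statistic(arrs) >= obs - 1e-9:
                    count += 1
            assert res.p_value == pytest.approx(count / total)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(32)
        groups = [rng.normal(size=4).tolist() for _ in range(3)]
        a = jonckheere_terpstra(groups, n_perm=200, rng=1)
        b = jonckheere_terpstra(
            [[math.exp(v) for v in g] for g in groups], n_perm=200, rng=1
        )
        assert a.statistic == b.statistic

    def test_direction_reverses_statistic(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        inc = jonckheere_terpstra(groups, "increasing")
        dec = jonckheere_terpstra(groups, "decreasing")
        assert inc.statistic == 12.0 and dec.statistic == 0.0

    def test_sign_agrees_with_tau_on_two_group_collapse(self):
        rng = np.random.default_rng(33)
        for _ in range(5):
            g1 = rng.normal(0, 1, 4)
            g2 = rng.normal(1.0, 1, 4)
            g3 = rng.normal(2.0, 1, 4)
            res = jonckheere_terpstra([g1.tolist(), g2.tolist(), g3.tolist()],
                                      n_perm=200, rng=0)
            from scipy import stats as sps
            x = [0] * 4 + [1] * 4 + [2] * 4
            tau = sps.kendalltau(x, np.concatenate([g1, g2, g3])).statistic
            assert np.sign(res.effect) == np.sign(tau)

    def test_fewer_than_three_groups_is_an_error(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1, 2], [3, 4]])
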