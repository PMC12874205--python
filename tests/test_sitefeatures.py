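import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fucostoich.ingest import AnnotationMap, ProteinDB
from fucostoich.quantify import GlycopeptideKey, StoichiometryEstimate
from fucostoich.sitefeatures import (
    aligned_window,
    aromatic_count,
    gravy,
    group_summary,
    isoelectric_point,
    mann_whitney,
    motif_scores,
    quartile_groups,
    relative_position,
    significance_stars,
    thirteen_mer,
)


def _estimate(stoich, i=0, accession="P1", site=None):
    return StoichiometryEstimate(
        key=GlycopeptideKey(f"PEP{i}NGSK", accession, site or (10 + i)),
        stoichiometry=stoich, raw_ratio=stoich, mean_ratio=stoich,
        replicate_ratios=np.array([stoich] * 3), cv=0.0, n_psms=1,
    )


class TestWindows:
    @pytest.fixture
    def db(self):
        db = ProteinDB()
        db.add("X13", "ABCDEFNHIJKLM")  # length 13, N at site 7
        db.add("LONG", "ACDEFGHIKLMNPQRSTVWY")
        return db

    def test_exact_fit_returns_whole_protein(self, db):
        assert thirteen_mer(db, "X13", 7) == "ABCDEFNHIJKLM"

    def test_left_truncation(self, db):
        assert thirteen_mer(db, "X13", 1) == "ABCDEFN"

    def test_right_truncation(self, db):
        assert thirteen_mer(db, "X13", 13) == "NHIJKLM"

    def test_out_of_range_errors(self, db):
        with pytest.raises(ValueError):
            thirteen_mer(db, "X13", 14)

    def test_aligned_window_pads_missing_positions(self, db):
        w = aligned_window(db, "X13", 2)
        assert len(w) == 13
        assert w == "-----ABCDEFNH"
        assert w[6] == "B"  # site residue at center


class TestGravyAromatic:
    def test_polyalanine(self):
        assert gravy("AAAA") == pytest.approx(1.8)

    def test_nst_mean(self):
        assert gravy("NST") == pytest.approx((-3.5 - 0.8 - 0.7) / 3)

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
           st.randoms())
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariance(self, seq, rnd):
        shuffled = list(seq)
        rnd.shuffle(shuffled)
        assert gravy("".join(shuffled)) == pytest.approx(gravy(seq))

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            gravy("AAB")

    @pytest.mark.parametrize(
        "seq,count", [("NFSWTYA", 3), ("AAAA", 0), ("FWYFWY", 6)]
    )
    def test_aromatic_counts(self, seq, count):
        assert aromatic_count(seq) == count

    def test_histidine_optional(self):
        assert aromatic_count("HHH") == 0
        assert aromatic_count("HHH", aromatic=frozenset("FWYH")) == 3


class TestIsoelectricPoint:
    def test_charge_is_zero_at_pi(self):
        from fucostoich.sitefeatures import _net_charge
        from fucostoich.constants import EMBOSS_PKA

        for seq in ("GNDKRST", "KKKK", "DDEE", "ACDEFGHIKLMNPQRSTVWY"):
            pi = isoelectric_point(seq)
            assert abs(_net_charge(seq, pi, EMBOSS_PKA)) < 1e-3

    def test_basic_peptide_above_acidic(self):
        assert isoelectric_point("KKKKAA") > isoelectric_point("DDDDAA")

    def test_glycine_is_terminal_pka_midpoint(self):
        # no ionizable side chains: pI = (8.6 + 3.6) / 2 for the EMBOSS set
        assert isoelectric_point("G") == pytest.approx(6.1, abs=1e-3)


class TestQuartiles:
    def test_eight_sites_split_evenly(self):
        ests = [_estimate(s / 10, i) for i, s in enumerate([3, 1, 7, 5, 8, 2, 6, 4])]
        labels, tied = quartile_groups(ests)
        by_group = {}
        for e in ests:
            by_group.setdefault(labels[e.key], []).append(e.stoichiometry)
        assert {g: len(v) for g, v in by_group.items()} == {
            "P1": 2, "P2": 2, "P3": 2, "P4": 2}
        assert max(by_group["P1"]) < min(by_group["P4"])
        assert not tied

    def test_remainder_rule_ten_sites(self):
        ests = [_estimate(i / 10, i) for i in range(10)]
        labels, _ = quartile_groups(ests)
        sizes = {g: sum(1 for v in labels.values() if v == g) for g in
                 ("P1", "P2", "P3", "P4")}
        assert sizes == {"P1": 3, "P2": 3, "P3": 2, "P4": 2}

    def test_boundary_ties_flagged(self):
        values = [0.1, 0.5, 0.5, 0.5, 0.7, 0.8, 0.9, 1.0]
        ests = [_estimate(v, i) for i, v in enumerate(values)]
        labels, tied = quartile_groups(ests)
        assert tied  # the 0.5 block straddles the P1/P2 boundary
        assert all(ests[i].key in tied for i in (1, 2, 3))

    def test_fewer_than_four_errors(self):
        with pytest.raises(ValueError, match="at least 4"):
            quartile_groups([_estimate(0.5, i) for i in range(3)])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_partition_exhaustive_and_balanced(self, values):
        ests = [_estimate(v, i) for i, v in enumerate(values)]
        labels, _ = quartile_groups(ests)
        assert set(labels) == {e.key for e in ests}
        sizes = [sum(1 for v in labels.values() if v == f"P{g}") for g in range(1, 5)]
        assert max(sizes) - min(sizes) <= 1
        assert sizes == sorted(sizes, reverse=True)


def exact_mw_p(a, b):
    """Full enumeration of all rank assignments (no ties)."""
    pooled = sorted(a + b)
    n1, n2 = len(a), len(b)
    ranks_a = [pooled.index(x) + 1 for x in a]
    u_obs = sum(ranks_a) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestMannWhitney:
    def test_identical_groups(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == 4.5  # n1*n2/2
        assert p == 1.0

    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 rankings as extreme

    def test_swap_antisymmetry(self):
        a, b = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0]
        u_ab, p_ab = mann_whitney(a, b)
        u_ba, p_ba = mann_whitney(b, a)
        assert u_ab + u_ba == len(a) * len(b)
        assert p_ab == pytest.approx(p_ba)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 6)
                                       for n2 in range(n1, 6) if n1 + n2 <= 10])
    def test_exact_mode_matches_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(3):
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = list(vals[:n1]), list(vals[n1:])
            u, p = mann_whitney(a, b)
            assert p == pytest.approx(exact_mw_p(a, b), abs=1e-12)

    def test_stars_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.00004) == "****"
        assert significance_stars(0.2) == "ns"


def _binom_tail_ge(k, n, q):
    return sum(math.comb(n, i) * q**i * (1 - q) ** (n - i) for i in range(k, n + 1))


class TestMotifScores:
    def _random_windows(self, rng, n):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        out = []
        for _ in range(n):
            w = rng.choice(aas, size=13)
            w[6] = "N"
            out.append("".join(w))
        return out

    def test_null_case_bounded(self):
        rng = np.random.default_rng(0)
        windows = self._random_windows(rng, 300)
        m = motif_scores(windows, windows)
        # log10(2) holds exactly when k = n*q; the pseudocount perturbs q
        # by O(10/N) per cell, hence the small allowance
        assert np.abs(m.scores.to_numpy()).max() <= math.log10(2) + 0.05

    def test_score_matches_direct_binomial_tail(self):
        # foreground all-W at +1 against a background where W is rare
        rng = np.random.default_rng(1)
        background = self._random_windows(rng, 200)
        fg = ["AAAAAANWSAAAA"] * 10
        m = motif_scores(fg, background)
        bg_counts = m.background_counts
        n, k = 10, 10
        q = (bg_counts.loc[1, "W"] + 0.5) / (bg_counts.loc[1].sum() + 10.0)
        expected = -math.log10(_binom_tail_ge(k, n, q))
        assert m.scores.loc[1, "W"] == pytest.approx(expected, rel=1e-9)
        assert expected > 10  # strong over-representation

    def test_absent_residue_scores_negative(self):
        rng = np.random.default_rng(2)
        background = self._random_windows(rng, 200)
        fg = ["AAAAAANGSAAAA"] * 20  # L never appears in the foreground
        m = motif_scores(fg, background)
        assert m.scores.loc[-3, "L"] < 0

    def test_truncated_windows_reduce_position_count(self):
        fg = ["---AAANGSAAAA", "AAAAAANGSAAAA"]
        m = motif_scores(fg, fg)
        assert m.foreground_counts.loc[-6].sum() == 1
        assert m.foreground_counts.loc[1].sum() == 2

    def test_empty_foreground_errors(self):
        with pytest.raises(ValueError):
            motif_scores([], ["AAAAAANGSAAAA"])


class TestRelativePosition:
    def test_examples(self):
        assert relative_position(1, 100) == pytest.approx(0.01)
        assert relative_position(100, 100) == 1.0

    def test_monotone_in_site(self):
        vals = [relative_position(s, 50) for s in range(1, 51)]
        assert vals == sorted(vals)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            relative_position(0, 10)


class TestGroupSummary:
    def _annotated(self, values_by_label, category="disorder"):
        estimates, amap = [], AnnotationMap()
        i = 0
        for label, values in values_by_label.items():
            for v in values:
                e = _estimate(v, i)
                estimates.append(e)
                amap.add(e.key.accession, e.key.site, category, label)
                i += 1
        return estimates, amap

    def test_single_label_no_tests(self):
        ests, amap = self._annotated({"ordered": [0.2, 0.4, 0.6]})
        summary, pairwise = group_summary(ests, amap, "disorder")
        assert len(summary) == 1
        assert len(pairwise) == 0

    def test_shifted_groups_sign_and_consistency(self):
        ests, amap = self._annotated(
            {"ordered": [0.1, 0.2, 0.25, 0.3], "disordered": [0.7, 0.8, 0.85, 0.9]}
        )
        summary, pairwise = group_summary(ests, amap, "disorder")
        means = dict(zip(summary["label"], summary["mean"]))
        assert means["disordered"] > means["ordered"]
        u_direct, p_direct = mann_whitney(
            [0.7, 0.8, 0.85, 0.9], [0.1, 0.2, 0.25, 0.3]
        )
        row = pairwise.iloc[0]
        assert row["p"] == pytest.approx(p_direct)

    def test_missing_category_errors(self):
        ests, amap = self._annotated({"ordered": [0.2, 0.4]})
        with pytest.raises(ValueError, match="compartment"):
            group_summary(ests, amap, "compartment")
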