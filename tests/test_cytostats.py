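"""Cytogenetic statistics: symmetry index, test battery, summaries."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sstats

import satellitome as st
from satellitome.cytostats import (
    LocationRecord,
    mann_whitney,
    parse_regions,
    read_location_table,
    shared_cluster_table,
    summarize_rul,
    symmetry_index,
)
from satellitome.datasets import (
    a_pattern_records,
    load_a_patterns,
    load_b_locations,
    load_satellitome_catalog,
)
from satellitome.errors import (
    InvalidParameterError,
    UndefinedCorrelationError,
)


def _rec(sat, regions, b="B1", pattern="c"):
    return LocationRecord(satellite=sat, species="sp", chromosome=b, pattern=pattern,
                          regions=parse_regions(regions))


class TestLocationRecords:
    def test_region_parsing(self):
        r = parse_regions("pe;p:i;p:t;q:i")
        assert r["pe"] == {"pe"} and r["p"] == {"i", "t"} and r["q"] == {"i"}
        assert parse_regions("-") == {}

    def test_invalid_tokens_rejected(self):
        with pytest.raises(InvalidParameterError):
            _rec("x", "p:z")
        with pytest.raises(InvalidParameterError):
            LocationRecord(satellite="x", species="s", chromosome="B", pattern="nc",
                           regions=parse_regions("p:t"))

    def test_terminal_and_distal_count_as_matching_arm_ends(self):
        assert _rec("x", "p:t;q:d").is_symmetric is True

    def test_pericentromeric_only_excluded_from_symmetry(self):
        assert _rec("x", "pe").is_symmetric is None


class TestSymmetryIndex:
    def test_single_one_armed_satellite_gives_zero(self):
        rec = symmetry_index([_rec("a", "p:t")])
        assert rec.si == 0.0 and rec.n_noncentromeric == 1

    def test_all_symmetric_gives_one(self):
        rec = symmetry_index([_rec("a", "p:t;q:t"), _rec("b", "p:i;q:i"), _rec("c", "pe")])
        assert rec.si == 1.0
        assert rec.n_noncentromeric == 2  # pe-only satellite excluded

    def test_no_noncentromeric_satellites_undefined(self):
        rec = symmetry_index([_rec("a", "pe")])
        assert rec.si is None

    def test_arm_relabelling_invariance(self):
        def swap(regions):
            return ";".join(
                tok.replace("p:", "Q:").replace("q:", "p:").replace("Q:", "q:")
                for tok in regions.split(";")
            )

        originals = ["p:t;q:i", "p:i;q:i", "q:t", "pe;p:t;q:t"]
        si1 = symmetry_index([_rec(f"s{i}", r) for i, r in enumerate(originals)]).si
        si2 = symmetry_index([_rec(f"s{i}", swap(r)) for i, r in enumerate(originals)]).si
        assert si1 == si2

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(InvalidParameterError):
            symmetry_index([_rec("a", "p:t", b="B1"), _rec("b", "p:t", b="B2")])


def _brute_force_mw(x, y):
    """Exhaustive two-sided Mann-Whitney P over all group assignments."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(assign):
        xs = [pooled[i] for i in assign]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(assign)]
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        return u

    obs = u_of(tuple(range(n)))
    center = n * len(y) / 2
    total = 0
    extreme = 0
    for assign in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(u_of(assign) - center) >= abs(obs - center) - 1e-12:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_identical_multisets(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.value == 9 / 2
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3], [4, 5, 6]),
            ([1, 5, 3], [2, 2, 7, 9]),
            ([1, 1, 2], [1, 3]),  # ties across groups
            ([2, 2, 2, 4], [2, 3]),
        ],
    )
    def test_exact_p_matches_brute_force_enumeration(self, x, y):
        res = mann_whitney(x, y)
        assert res.p_value == pytest.approx(_brute_force_mw(x, y), abs=1e-9)

    def test_no_tie_case_matches_scipy_exact(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8).tolist()
        y = rng.normal(1.0, size=6).tolist()
        res = mann_whitney(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            mann_whitney([], [1.0])


def _brute_force_fisher(table):
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def pmf(x):
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-7))


class TestFisherExact:
    def test_uniform_table_p_one(self):
        assert st.fisher_exact_2x2([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [[[3, 1], [1, 3]], [[5, 0], [1, 4]], [[2, 7], [8, 2]], [[4, 4], [3, 5]]],
    )
    def test_two_sided_matches_direct_enumeration(self, table):
        res = st.fisher_exact_2x2(table)
        assert res.p_value == pytest.approx(_brute_force_fisher(table), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidParameterError):
            st.fisher_exact_2x2([[0, 0], [1, 2]])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert st.spearman(x, x).value == pytest.approx(1.0)
        assert st.spearman(x, list(reversed(x))).value == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            st.spearman([1, 1, 1], [1, 2, 3])

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        res = st.spearman(x, y)
        ref = sstats.spearmanr(x, y)
        assert res.value == pytest.approx(ref.statistic, abs=1e-12)


class TestLevene:
    def test_hand_computed_two_group_formula(self):
        x = [1.0, 4.0, 7.0]
        y = [2.0, 2.5, 3.0]
        zx = [abs(v - np.mean(x)) for v in x]
        zy = [abs(v - np.mean(y)) for v in y]
        zbar = np.mean(zx + zy)
        num = (len(x) * (np.mean(zx) - zbar) ** 2 + len(y) * (np.mean(zy) - zbar) ** 2) / 1
        den = (sum((v - np.mean(zx)) ** 2 for v in zx) + sum((v - np.mean(zy)) ** 2 for v in zy)) / 4
        res = st.levene(x, y)
        assert res.value == pytest.approx(num / den, rel=1e-12)
        assert res.aux["df"] == (1, 4)

    def test_identical_spread_gives_zero(self):
        assert st.levene([1, 2, 3], [11, 12, 13]).value == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(InvalidParameterError):
            st.levene([5, 5], [5, 5])


class TestShapiroWilk:
    def test_normal_quantiles_high_w(self):
        q = sstats.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        assert st.shapiro_wilk(q).value > 0.99

    def test_two_point_mixture_rejected_as_normal(self):
        x = np.array([0.0] * 30 + [10.0] * 15)
        assert st.shapiro_wilk(x).p_value < 0.05

    def test_small_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            st.shapiro_wilk([1.0, 2.0])


class TestReferenceTables:
    """Statistics over the packaged satellitome of Astyanax paranae."""

    def test_symmetry_indices_of_the_three_b_chromosomes(self):
        records = load_b_locations()
        by_b = {}
        for b in ("BpM", "BfMa", "BbM"):
            by_b[b] = symmetry_index([r for r in records if r.chromosome == b])
        assert by_b["BpM"].si == 1.0
        assert by_b["BbM"].si == 1.0
        assert by_b["BfMa"].n_noncentromeric == 11
        assert by_b["BfMa"].n_symmetric == 5
        assert round(by_b["BfMa"].si, 2) == 0.45

    def test_clustered_vs_nonclustered_rul(self):
        catalog = load_satellitome_catalog().rename(columns={"name": "name"})
        patterns = a_pattern_records("A. paranae")
        summary = summarize_rul(catalog.rename(columns={}), patterns)
        assert summary["clustered"]["n"] == 30
        assert summary["non_clustered"]["n"] == 5
        assert summary["clustered"]["median"] == 77.5
        assert summary["non_clustered"]["median"] == 21
        assert summary["clustered"]["variance"] == pytest.approx(6448.3, abs=0.05)
        assert summary["non_clustered"]["variance"] == pytest.approx(1423.5, abs=0.05)
        assert summary["satellitome_median_rul"] == 59
        assert summary["n_rul_below_100"] == 33

    def test_mann_whitney_u_between_patterns(self):
        catalog = load_satellitome_catalog()
        rul = dict(zip(catalog["name"], catalog["rul"]))
        patterns = a_pattern_records("A. paranae")
        clustered = [rul[r.satellite] for r in patterns if r.pattern == "c"]
        nc = [rul[r.satellite] for r in patterns if r.pattern == "nc"]
        res = mann_whitney(clustered, nc)
        assert res.value == 26
        assert res.p_value < 0.05

    def test_levene_between_patterns(self):
        catalog = load_satellitome_catalog()
        rul = dict(zip(catalog["name"], catalog["rul"]))
        patterns = a_pattern_records("A. paranae")
        clustered = [rul[r.satellite] for r in patterns if r.pattern == "c"]
        nc = [rul[r.satellite] for r in patterns if r.pattern == "nc"]
        res = st.levene(clustered, nc)
        assert round(res.value, 1) == 2.5
        assert res.aux["df"] == (1, 33)
        assert res.p_value == pytest.approx(0.124, abs=0.005)

    def test_spearman_rul_vs_at(self):
        catalog = load_satellitome_catalog()
        res = st.spearman(catalog["rul"], catalog["at_percent"])
        # printed value 0.34 reflects unprinted input precision; the
        # transcribed table gives 0.33
        assert abs(res.value - 0.34) <= 0.015
        assert res.p_value < 0.05

    def test_shapiro_wilk_at_content_is_normal(self):
        catalog = load_satellitome_catalog()
        res = st.shapiro_wilk(catalog["at_percent"])
        assert abs(res.value - 0.978) <= 0.002
        assert res.p_value > 0.05
        # RUL, abundance and divergence are far from normal
        for col in ("rul", "abundance_0b", "divergence_0b"):
            assert st.shapiro_wilk(catalog[col]).p_value < 0.05

    def test_shared_cluster_contingency_table(self):
        table = shared_cluster_table(load_a_patterns(), load_b_locations())
        assert table.tolist() == [[26, 4], [12, 6]]

    def test_location_table_roundtrip(self):
        records = load_b_locations()
        assert sum(1 for r in records if r.pattern == "t") == 3
        assert all(r.pattern in {"c", "t"} for r in records)

    def test_statistics_report_collects_the_battery(self):
        from satellitome.cytostats import format_report, statistics_report

        report = statistics_report(
            load_satellitome_catalog(),
            a_pattern_records("A. paranae"),
            load_b_locations(),
            load_a_patterns(),
        )
        by_name = report.set_index("statistic")
        assert by_name.loc["Mann-Whitney U, RUL c vs nc", "value"] == 26
        assert round(by_name.loc["symmetry index (BfMa)", "value"], 2) == 0.45
        assert round(by_name.loc["Fisher exact, shared clusters A vs B", "p_value"], 4) == 0.1007
        text = format_report(report)
        assert "median RUL (satellitome): 59" in text
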