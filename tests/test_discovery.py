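"""Mining: sampling, clustering, tandem detection, subtraction, iteration."""

import numpy as np
import pytest

import satellitome as st
from satellitome._seq import encode, rotate
from satellitome.catalog import MinedMonomer
from satellitome.discovery import detect_tandem, subtract_reads
from satellitome.errors import SamplingError


def _array_reads(monomer, n_copies, n_reads, seed, read_len=101, divergence=0.0):
    """Reads drawn purely from a tandem array of the monomer."""
    spec = st.FamilySpec(
        label="s", rul=len(monomer), copies_0b=n_copies, intra_divergence=divergence
    )
    # plant into a background just big enough, then sample only array reads
    pair = st.plant_families([spec], max(3 * n_copies * len(monomer), 20_000), 0.0, seed=seed)
    truth = pair.truth["s"]
    tag, s, e, _ = truth.intervals[0]
    array = pair.seq_0b[s:e]
    lib = st.simulate_reads(array, n_reads, read_len=read_len, insert_mean=min(300, len(array)), seed=seed + 1)
    return truth.monomer, lib


class TestSampleReads:
    def test_full_sample_is_the_library(self):
        g = st.build_monomer(3_000, 0.5, seed=0)
        lib = st.simulate_reads(g, 100, seed=1)
        sample = st.sample_reads(lib, 100, seed=2)
        assert np.array_equal(sample.r1, lib.r1)

    def test_oversampling_rejected(self):
        g = st.build_monomer(3_000, 0.5, seed=0)
        lib = st.simulate_reads(g, 100, seed=1)
        with pytest.raises(SamplingError):
            st.sample_reads(lib, 101, seed=2)

    def test_doubling_schedule(self, combined_library, mined_four_families):
        log = mined_four_families.log
        for i, row in enumerate(log):
            want = 1_000 * 2**i
            assert row.sample_pairs == min(want, 20_000)


class TestClusterReads:
    def test_single_tandem_array_single_cluster(self):
        mono, lib = _array_reads(st.build_monomer(40, 0.5, seed=3), 120, 300, seed=10)
        clusters = st.cluster_reads(lib.reads())
        assert len(clusters) == 1
        assert clusters[0].size == 600  # every repeat-derived read

    def test_two_unrelated_families_two_clusters(self):
        _, lib_a = _array_reads(st.build_monomer(40, 0.5, seed=4), 120, 150, seed=11)
        _, lib_b = _array_reads(st.build_monomer(63, 0.5, seed=5), 80, 150, seed=12)
        reads = np.concatenate([lib_a.reads(), lib_b.reads()])
        clusters = st.cluster_reads(reads)
        assert len(clusters) == 2
        sizes = sorted(c.size for c in clusters)
        assert sizes == [300, 300]

    def test_low_coverage_background_gives_no_clusters(self):
        # < 1x coverage: unique reads rarely share 5 k-mers
        g = st.build_monomer(500_000, 0.5, seed=6)
        lib = st.simulate_reads(g, 1_000, seed=13)  # ~0.4x
        clusters = st.cluster_reads(lib.reads())
        assert clusters == []

    def test_empty_read_set(self):
        assert st.cluster_reads(np.empty((0, 101), dtype=np.uint8)) == []


class TestDetectTandem:
    def test_error_free_short_period_recovered(self):
        base = st.build_monomer(51, 0.5, seed=7)
        # 51 > (101-1)//2 would use assembly; use 40 for the vote path
        mono, lib = _array_reads(st.build_monomer(40, 0.5, seed=8), 150, 400, seed=14)
        [cluster] = st.cluster_reads(lib.reads())
        m = detect_tandem(cluster)
        assert m is not None
        assert m.period == 40
        assert st.rotational_identity(m.consensus, mono) == 100.0

    def test_divergent_monomer_consensus_close_to_ancestor(self):
        mono, lib = _array_reads(st.build_monomer(21, 0.5, seed=9), 300, 400, seed=15, divergence=0.05)
        [cluster] = st.cluster_reads(lib.reads())
        m = detect_tandem(cluster)
        assert m is not None and m.period == 21
        # <= 2 mismatches from the planted ancestor
        assert st.rotational_identity(m.consensus, mono) >= 100 * (21 - 2) / 21

    def test_long_period_via_assembly(self):
        mono, lib = _array_reads(st.build_monomer(178, 0.5, seed=10), 40, 400, seed=16, divergence=0.02)
        [cluster] = st.cluster_reads(lib.reads())
        m = detect_tandem(cluster)
        assert m is not None and m.period == 178
        assert st.rotational_identity(m.consensus, mono) >= 97.0

    def test_unique_sequence_cluster_yields_none(self):
        # force a cluster from high-coverage unique sequence
        g = st.build_monomer(2_000, 0.5, seed=11)
        lib = st.simulate_reads(g, 300, seed=17)  # ~30x of unique sequence
        clusters = st.cluster_reads(lib.reads())
        assert clusters  # deep coverage chains the background into components
        assert all(detect_tandem(c) is None for c in clusters)

    def test_rotation_invariance_of_canonical_consensus(self):
        base = st.build_monomer(33, 0.5, seed=12)
        results = set()
        for rot in (0, 7, 20):
            array = rotate(base, rot) * 80
            lib = st.simulate_reads(array, 250, insert_mean=300, seed=18 + rot)
            [cluster] = st.cluster_reads(lib.reads())
            m = detect_tandem(cluster)
            assert m is not None and m.period == 33
            results.add(m.consensus)
        assert len(results) == 1  # same canonical monomer from any rotation

    @pytest.mark.parametrize("period", [9, 14, 20, 25])
    def test_period_matches_brute_force_oracle(self, period):
        """On toy arrays the detected period equals the brute-force winner
        over all candidate periods by exact string self-comparison."""
        mono = st.build_monomer(period, 0.5, seed=period)
        array = mono * (2_000 // period)
        lib = st.simulate_reads(array, 120, insert_mean=250, seed=period)
        [cluster] = st.cluster_reads(lib.reads())
        m = detect_tandem(cluster)

        def brute_force_period(s):
            best_p, best_score = None, 0.0
            for p in range(5, len(s) // 2):
                score = sum(a == b for a, b in zip(s, s[p:])) / (len(s) - p)
                if score >= 0.99 and (best_p is None or p < best_p):
                    best_p = p
                    best_score = score
            return best_p

        assert m is not None
        assert m.period == brute_force_period(array) == period


class TestSubtractReads:
    def test_planted_family_removed_background_kept(self, four_family_scenario):
        spec = st.FamilySpec(label="s", rul=50, copies_0b=100, intra_divergence=0.0)
        pair = st.plant_families([spec], 100_000, 0.0, seed=19)
        lib = st.simulate_reads(pair.seq_0b, 10_000, seed=20)
        mono = MinedMonomer(pair.truth["s"].monomer, 50, 1)
        kept, removed = subtract_reads(lib, [mono])
        # truth fraction 5%: a pair is removed when either mate overlaps the
        # array by >= half a read, so the removed fraction tracks 2x5% minus
        # pair correlation; bound it by the truth-based window
        frac = removed / 10_000
        assert 0.04 <= frac <= 0.13
        assert kept.n_pairs + removed == 10_000
        # remaining reads do not match the monomer at the homology criterion
        masker = st.Masker([("s", mono.consensus)], min_identity=0.8, min_len=50)
        assert not masker.matches(kept.r1).any()

    def test_empty_catalog_identity(self):
        g = st.build_monomer(5_000, 0.5, seed=13)
        lib = st.simulate_reads(g, 100, seed=21)
        kept, removed = subtract_reads(lib, [])
        assert removed == 0 and kept is lib


class TestMineSatellitome:
    def test_recovers_planted_families(self, four_family_scenario, mined_four_families):
        _, pair = four_family_scenario
        result = mined_four_families
        best = {}
        for m in result.monomers:
            for row in pair.truth:
                ident = st.rotational_identity(m.consensus, row.monomer)
                if ident >= 95 and m.period == row.rul:
                    best[row.label] = ident
        assert set(best) == {"famA", "famB", "famC", "famR"}
        assert result.log[-1].new_monomers == 0  # termination logged

    def test_monotone_catalog_and_subtraction_safety(self, mined_four_families):
        # iterations only ever add monomers; the log never shows a shrink
        seen = 0
        for row in mined_four_families.log:
            assert row.new_monomers >= 0
            seen += row.new_monomers
        assert seen == len(mined_four_families.monomers)

    def test_repeat_free_genome_yields_empty_catalog(self):
        g = st.build_monomer(400_000, 0.5, seed=14)
        lib = st.simulate_reads(g, 4_000, seed=22)
        result = st.mine_satellitome(lib, st.MineConfig(start_pairs=1_000, max_iterations=3, seed=1))
        assert result.monomers == []
        assert result.log[0].new_monomers == 0
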