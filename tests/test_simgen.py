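"""Simulator: monomer generation, planting, read simulation, ground truth."""

import numpy as np
import pytest

import satellitome as st
from satellitome._seq import revcomp
from satellitome.errors import CapacityError, InvalidParameterError
from satellitome.simgen import derive_at_identity, mutate


class TestBuildMonomer:
    def test_at_frac_one_forces_at_alphabet(self):
        m = st.build_monomer(6, 1.0, seed=3)
        assert len(m) == 6
        assert set(m) <= {"A", "T"}

    def test_zero_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            st.build_monomer(0, 0.5, seed=1)

    def test_deterministic_given_seed(self):
        assert st.build_monomer(51, 0.5, seed=9) == st.build_monomer(51, 0.5, seed=9)

    def test_mean_at_fraction_matches_target(self):
        # Monte-Carlo check of the generator's own law
        target = 0.549
        fracs = [
            (m.count("A") + m.count("T")) / 51
            for m in (st.build_monomer(51, target, seed=s) for s in range(3000))
        ]
        assert abs(np.mean(fracs) - target) < 0.02


class TestFamilySpec:
    def test_rul_bounds_enforced(self):
        with pytest.raises(InvalidParameterError):
            st.FamilySpec(label="x", rul=5, copies_0b=1)

    def test_b_restricted_requires_no_a_copies(self):
        with pytest.raises(InvalidParameterError):
            st.FamilySpec(label="x", rul=20, copies_0b=3, copies_b=5, b_restricted=True)

    def test_partner_identity_range(self):
        with pytest.raises(InvalidParameterError):
            st.FamilySpec(label="x", rul=20, copies_0b=1, superfamily_partner="y", partner_identity=0.9)


class TestPlantFamilies:
    def test_truth_fraction_exact_without_mutation(self):
        spec = st.FamilySpec(label="s", rul=50, copies_0b=100, intra_divergence=0.0)
        pair = st.plant_families([spec], 100_000, 0.0, seed=4)
        assert len(pair.seq_0b) == 100_000
        assert pair.seq_1b == pair.seq_0b  # f = 0: no B segment
        assert pair.truth["s"].fraction_0b == pytest.approx(100 * 50 / 100_000)
        # the planted array is literally present as >= 2 consecutive copies
        mono = pair.truth["s"].monomer
        assert (mono + mono) in pair.seq_0b

    def test_b_restricted_family_absent_from_0b(self):
        spec = st.FamilySpec(label="b", rul=30, copies_b=200, b_restricted=True)
        pair = st.plant_families([spec], 120_000, 0.08, seed=5)
        mono = pair.truth["b"].monomer
        dimer = mono + mono
        assert dimer in pair.b_segment
        assert dimer not in pair.seq_0b and revcomp(dimer) not in pair.seq_0b

    def test_length_dilution_factor_haploid(self):
        # an A-only family is diluted by exactly 1/(1+f) on haploid strings
        spec = st.FamilySpec(label="s", rul=50, copies_0b=100, intra_divergence=0.0)
        pair = st.plant_families([spec], 100_000, 0.08, seed=6)
        t = pair.truth["s"]
        assert t.fraction_1b / t.fraction_0b == pytest.approx(1 / 1.08)

    def test_diploid_equivalent_dilution_factor(self):
        spec = st.FamilySpec(label="s", rul=50, copies_0b=100, intra_divergence=0.0)
        pair = st.plant_families([spec], 100_000, 0.08, seed=6)
        r = pair.truth.expected_read_fraction("s", "1B", diploid_equivalent=True)
        r0 = pair.truth.expected_read_fraction("s", "0B")
        assert r / r0 == pytest.approx(1 / 1.04)

    def test_b_segment_length_invariant(self):
        spec = st.FamilySpec(label="s", rul=50, copies_0b=10)
        pair = st.plant_families([spec], 99_990, 0.08, seed=7)
        assert pair.seq_1b.startswith(pair.seq_0b)
        assert len(pair.seq_1b) - len(pair.seq_0b) == round(0.08 * 99_990)

    def test_capacity_error_names_family(self):
        spec = st.FamilySpec(label="huge", rul=100, copies_0b=200)
        with pytest.raises(CapacityError, match="huge"):
            st.plant_families([spec], 10_000, 0.0, seed=1)

    def test_duplicate_labels_rejected(self):
        spec = st.FamilySpec(label="a", rul=20, copies_0b=2)
        with pytest.raises(InvalidParameterError):
            st.plant_families([spec, spec], 50_000, 0.0, seed=1)


class TestVariantsAndPartners:
    def test_mutate_rate_matches_multiple_hit_expectation(self):
        rng = np.random.default_rng(0)
        base = st.build_monomer(500, 0.5, seed=1)
        muts = [sum(a != b for a, b in zip(base, mutate(base, 0.1, rng))) / 500 for _ in range(50)]
        # Poisson hits, uniform target base: realised mismatch fraction
        expected = 0.75 * (1 - np.exp(-4 * 0.1 / 3))
        assert abs(np.mean(muts) - expected) < 0.01

    def test_derive_at_identity_hits_target(self):
        rng = np.random.default_rng(1)
        base = st.build_monomer(200, 0.5, seed=2)
        d = derive_at_identity(base, 0.65, rng)
        ident = st.rotational_identity(base, d)
        assert 63.0 <= ident <= 72.0  # gapped alignment can only raise it slightly


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self):
        g = st.build_monomer(2_000, 0.5, seed=8)
        lib = st.simulate_reads(g, 200, read_len=50, insert_mean=150, error_rate=0.0, seed=1)
        for s in lib.sequences():
            assert s in g or revcomp(s) in g

    def test_observed_error_rate(self):
        g = st.build_monomer(5_000, 0.5, seed=9)
        lib = st.simulate_reads(g, 100_000, error_rate=0.01, seed=2)
        clean = st.simulate_reads(g, 100_000, error_rate=0.0, seed=2)
        mism = (lib.reads() != clean.reads()).mean()
        # substituting to a different base always changes the letter
        assert abs(mism - 0.01) < 0.001

    def test_fastq_byte_identical_given_seed(self, tmp_path):
        g = st.build_monomer(2_000, 0.5, seed=10)
        paths = []
        for tag in ("a", "b"):
            lib = st.simulate_reads(g, 50, error_rate=0.01, seed=77, label="x")
            p1, p2 = tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq"
            lib.to_fastq(p1, p2)
            paths.append((p1.read_bytes(), p2.read_bytes()))
        assert paths[0] == paths[1]

    def test_invalid_parameters(self):
        g = st.build_monomer(1_000, 0.5, seed=1)
        with pytest.raises(InvalidParameterError):
            st.simulate_reads(g, 0)
        with pytest.raises(InvalidParameterError):
            st.simulate_reads(g, 10, read_len=101, insert_mean=50)


def test_read_fraction_conservation(four_family_scenario):
    """Error-free reads hit a planted family at its truth fraction (+-3 s.e.)."""
    specs, _ = four_family_scenario
    spec = st.FamilySpec(label="s", rul=51, copies_0b=120, intra_divergence=0.0)
    pair = st.plant_families([spec], 60_000, 0.0, seed=21)
    lib = st.simulate_reads(pair.seq_0b, 40_000, error_rate=0.0, seed=3)
    masker = st.Masker([("s", pair.truth["s"].monomer)], min_identity=0.95, min_len=30)
    frac = masker.matches(lib.reads()).mean()
    p = pair.truth["s"].fraction_0b
    se = np.sqrt(p * (1 - p) / (2 * 40_000))
    # full-read matching misses boundary reads; allow that one-sided bias
    assert p - 0.25 * p <= frac <= p + 3 * se
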