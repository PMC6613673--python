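"""Tests of the synthetic cfDNA generator: genetics and count noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nipthmm.simulate import (
    CONDITIONS,
    EUPLOIDY,
    MATERNAL_TRISOMY,
    PATERNAL_TRISOMY,
    Haplotype,
    SimulationConfig,
    draw_counts,
    form_fetus,
    recombine,
    simulate_cohort,
    simulate_parent,
    simulate_sample,
    write_samples_tsv,
    _negative_binomial,
    _simulate_genotypes,
)


class TestParentSimulation:
    def test_zero_maf_is_monomorphic(self):
        cfg = SimulationConfig(n_loci=500, maf=0.0)
        h1, h2 = simulate_parent(cfg, np.random.default_rng(0))
        assert not h1.alleles.any() and not h2.alleles.any()

    @pytest.mark.parametrize("maf,expected", [(0.5, 0.5), (0.2, 0.32)])
    def test_heterozygote_fraction_matches_hardy_weinberg(self, maf, expected):
        # closed form: P(het) = 2 m (1 - m)
        cfg = SimulationConfig(n_loci=100_000, maf=maf)
        h1, h2 = simulate_parent(cfg, np.random.default_rng(1))
        het = (h1.alleles != h2.alleles).mean()
        assert het == pytest.approx(expected, abs=0.01)

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError, match="maf"):
            SimulationConfig(maf=0.7)


class TestRecombination:
    @given(seed=st.integers(0, 10_000), mode=st.sampled_from(["suffix", "subset"]))
    @settings(max_examples=50, deadline=None)
    def test_per_locus_allele_multiset_conserved(self, seed, mode):
        rng = np.random.default_rng(seed)
        h1 = Haplotype(rng.integers(0, 2, 50, dtype=np.int8))
        h2 = Haplotype(rng.integers(0, 2, 50, dtype=np.int8))
        r1, r2 = recombine(h1, h2, rng, mode=mode)
        np.testing.assert_array_equal(
            r1.alleles + r2.alleles, h1.alleles + h2.alleles
        )

    def test_suffix_mode_is_single_breakpoint(self):
        h1 = Haplotype(np.zeros(100, dtype=np.int8))
        h2 = Haplotype(np.ones(100, dtype=np.int8))
        r1, _ = recombine(h1, h2, np.random.default_rng(3), mode="suffix")
        # r1 is all-0 then all-1 (or degenerate): at most one change point
        assert np.abs(np.diff(r1.alleles.astype(int))).sum() <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            recombine(
                Haplotype(np.zeros(5, dtype=np.int8)),
                Haplotype(np.zeros(6, dtype=np.int8)),
                np.random.default_rng(0),
            )


class TestFetusFormation:
    def _parents(self, rng, n=200):
        cfg = SimulationConfig(n_loci=n)
        mother = recombine(*simulate_parent(cfg, rng), rng)
        father = recombine(*simulate_parent(cfg, rng), rng)
        return mother, father

    @pytest.mark.parametrize(
        "condition,n_mat,n_pat",
        [(EUPLOIDY, 1, 1), (MATERNAL_TRISOMY, 2, 1), (PATERNAL_TRISOMY, 1, 2)],
    )
    def test_origin_cardinality(self, condition, n_mat, n_pat):
        rng = np.random.default_rng(5)
        fetus = form_fetus(*self._parents(rng), condition, rng)
        assert fetus.origins.count("maternal") == n_mat
        assert fetus.origins.count("paternal") == n_pat
        assert fetus.ploidy == n_mat + n_pat

    def test_maternal_mi_trisomy_transmits_both_maternal_alleles(self):
        # at a maternally heterozygous locus the fetus carries {A, B} from
        # the mother (meiosis-I heterodisomy survives recombination)
        rng = np.random.default_rng(6)
        mother, father = self._parents(rng)
        fetus = form_fetus(mother, father, MATERNAL_TRISOMY, rng)
        m_dosage = mother[0].alleles + mother[1].alleles
        maternal_fetal = fetus.haplotypes[0].alleles + fetus.haplotypes[1].alleles
        np.testing.assert_array_equal(maternal_fetal, m_dosage)

    def test_paternal_trisomy_het_rate_given_mother_homozygous(self):
        # enumeration oracle: fetus = 1 maternal + 2 paternal alleles;
        # given mother hom, P(fetus het) = 1 - 0.5^2 = 0.75 at MAF 0.5
        m_b, f_b, f_total = _simulate_genotypes(
            20, 1000, 0.5, PATERNAL_TRISOMY, np.random.default_rng(8)
        )
        hom = m_b != 1
        het = (f_b > 0) & (f_b < f_total)
        assert het[hom].mean() == pytest.approx(0.75, abs=0.02)

    def test_unknown_condition_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="condition"):
            form_fetus(*self._parents(rng), "tetrasomy", rng)


class TestCounts:
    def test_negative_binomial_moments(self):
        rng = np.random.default_rng(9)
        draws = _negative_binomial(np.full(100_000, 500.0), 3.0, rng)
        assert draws.mean() == pytest.approx(500, rel=0.02)
        assert draws.var() / draws.mean() == pytest.approx(3.0, rel=0.05)

    def test_zero_mean_is_deterministic_zero(self):
        rng = np.random.default_rng(0)
        assert (_negative_binomial(np.zeros(100), 3.0, rng) == 0).all()

    def test_trisomic_locus_expected_total(self):
        # E[total] = RD * (1 + FF/2) = 1050 at RD 1000, FF 0.10
        cfg = SimulationConfig(read_depth=1000, fetal_fraction=0.10)
        rng = np.random.default_rng(10)
        totals = [
            draw_counts("AB", "AAB", cfg, rng).total for _ in range(20_000)
        ]
        assert np.mean(totals) == pytest.approx(1050, rel=0.01)

    def test_genotype_validation(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="2 alleles"):
            draw_counts("AAB", "AB", cfg, rng)
        with pytest.raises(ValueError, match="alphabet"):
            draw_counts("AC", "AB", cfg, rng)


class TestSampleSimulation:
    def test_euploid_sample_has_diploid_fetal_genotypes(self):
        s = simulate_sample(SimulationConfig(condition=EUPLOIDY, seed=1))
        assert (s.studied.f_total == 2).all()

    @pytest.mark.parametrize("condition", CONDITIONS)
    def test_reference_chromosome_always_euploid(self, condition):
        s = simulate_sample(SimulationConfig(condition=condition, seed=2))
        assert (s.reference.f_total == 2).all()

    def test_fixed_seed_is_bit_identical(self):
        cfg = SimulationConfig(condition=MATERNAL_TRISOMY, seed=42)
        a, b = simulate_sample(cfg), simulate_sample(cfg)
        np.testing.assert_array_equal(a.studied.count_a, b.studied.count_a)
        np.testing.assert_array_equal(a.reference.count_b, b.reference.count_b)

    def test_trisomy_to_euploid_depth_ratio(self):
        # mean trisomic total / mean euploid total -> 1 + FF/2
        ff = 0.12
        cfg = SimulationConfig(
            read_depth=2000, fetal_fraction=ff, condition=MATERNAL_TRISOMY, n_loci=2000
        )
        cohort = simulate_cohort(cfg, 10, np.random.default_rng(3))
        ratio = cohort.studied.total.mean() / cohort.reference.total.mean()
        assert ratio == pytest.approx(1 + ff / 2, rel=0.01)


class TestTsvWriter:
    def test_round_trip_row_count_and_gzip(self, tmp_path):
        import pandas as pd

        cfg = SimulationConfig(n_loci=20, condition=PATERNAL_TRISOMY)
        cohort = simulate_cohort(cfg, 3, np.random.default_rng(0))
        path = tmp_path / "samples.tsv.gz"
        write_samples_tsv(cohort, path, seed=0)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 3 * 2 * 20  # samples x roles x loci
        assert set(df["chromosome_role"]) == {"studied", "reference"}
        ref = df[df["chromosome_role"] == "reference"]
        assert (ref["condition"] == EUPLOIDY).all()
        assert set(ref["fetal_genotype"].str.len()) == {2}
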