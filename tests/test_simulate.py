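"""Breeding-simulator behaviour: allele sampling, funnel crosses,
inbreeding, genotyping noise and phenotype construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ccqg
from ccqg.errors import InvalidArgumentError
from ccqg.genmap import GeneticMap

from oracles import two_locus_pedigree_prob_diff


def _two_marker_founders(d_cm=5.0):
    gm = GeneticMap(
        pd.DataFrame(
            {
                "marker": ["a", "b"],
                "chrom": ["1", "1"],
                "bp": [1, int(d_cm * 2e6)],
                "cM": [0.0, d_cm],
            }
        ),
        {"1": d_cm},
    )
    return ccqg.FounderHaplotypes(gm, np.zeros((8, 2), dtype=np.uint8))


class TestSimulateFounders:
    def test_empty_marker_set_is_valid(self):
        f = ccqg.simulate_founders([0, 0], [50.0, 60.0], seed=1)
        assert f.n_markers == 0
        assert f.alleles.shape == (8, 0)

    def test_allele_frequency_matches_binomial(self):
        f = ccqg.simulate_founders([10_000], [100.0], allele_freq=0.5, seed=2)
        n = f.alleles.size
        frac = f.alleles.mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_same_seed_is_byte_identical(self):
        a = ccqg.simulate_founders([100], [50.0], seed=7)
        b = ccqg.simulate_founders([100], [50.0], seed=7)
        assert np.array_equal(a.alleles, b.alleles)
        assert a.gmap.markers.equals(b.gmap.markers)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_markers_per_chr=[-1], chr_lengths_cM=[50.0]),
            dict(n_markers_per_chr=[10], chr_lengths_cM=[0.0]),
            dict(n_markers_per_chr=[10], chr_lengths_cM=[50.0], allele_freq=0.0),
            dict(n_markers_per_chr=[], chr_lengths_cM=[]),
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            ccqg.simulate_founders(**kwargs)


class TestBreeding:
    def test_zero_length_chromosome_single_founder_segment(self):
        gm = GeneticMap(
            pd.DataFrame(
                {"marker": ["m"], "chrom": ["1"], "bp": [1], "cM": [0.0]}
            ),
            {"1": 0.0},
        )
        f = ccqg.FounderHaplotypes(gm, np.zeros((8, 1), dtype=np.uint8))
        mos = ccqg.breed_cc_line(f, seed=3)
        assert len(mos.hap1["1"]) == 1
        assert len(mos.hap2["1"]) == 1

    def test_invalid_funnel_rejected(self, small_founders):
        with pytest.raises(InvalidArgumentError):
            ccqg.breed_cc_line(small_founders, funnel=(0,) * 8, seed=1)

    def test_founder_shares_sum_to_one(self, small_panel):
        mosaics, _ = small_panel
        for mos in mosaics:
            assert mos.founder_shares().sum() == pytest.approx(1.0)

    def test_determinism(self, small_founders):
        a = ccqg.breed_cc_line(small_founders, seed=11)
        b = ccqg.breed_cc_line(small_founders, seed=11)
        assert a.hap1 == b.hap1 and a.hap2 == b.hap2

    def test_heterozygosity_non_increasing_in_inbreeding(self):
        f = ccqg.simulate_founders([2] * 3, [50.0] * 3, seed=21)
        means = []
        for gens in (0, 3, 8, 20):
            mos = ccqg.breed_cc_panel(f, 40, n_inbreeding_gens=gens, seed=22)
            means.append(np.mean([m.heterozygous_fraction() for m in mos]))
        assert all(a >= b for a, b in zip(means, means[1:]))
        assert means[-1] < 0.05  # near-inbred at F20-equivalent

    def test_junctions_match_two_locus_pedigree_oracle(self):
        """The segment simulator's probability of a founder switch across a
        5 cM gap agrees with an independent locus-based pedigree
        simulation (and with the eight-way sib-mating RIL limit
        7r/(1+6r))."""
        d = 5.0
        n_oracle, n_sim = 3000, 1500
        oracle = two_locus_pedigree_prob_diff(
            d, 20, n_oracle, np.random.default_rng(3)
        )
        f = _two_marker_founders(d)
        mosaics = ccqg.breed_cc_panel(f, n_sim, n_inbreeding_gens=20, seed=9)
        labels = np.stack([m.founder_labels(f.gmap)[0] for m in mosaics])
        sim = float((labels[:, 0] != labels[:, 1]).mean())
        se = np.sqrt(
            oracle * (1 - oracle) / n_oracle + sim * (1 - sim) / n_sim
        )
        assert abs(sim - oracle) < 3 * se
        r = (1 - np.exp(-d / 50)) / 2
        assert abs(sim - 7 * r / (1 + 6 * r)) < 0.05

    def test_balanced_funnels_balance_positions(self):
        funnels = ccqg.balanced_funnels(80, seed=5)
        counts = np.zeros((8, 8), dtype=int)
        for fun in funnels:
            for pos, founder in enumerate(fun):
                counts[founder, pos] += 1
        assert (counts == 10).all()


class TestGenotyping:
    def test_noiseless_calls_equal_haplotype_sum(self, small_founders, small_panel):
        mosaics, _ = small_panel
        mos = mosaics[0]
        calls = ccqg.genotype_line(mos, small_founders, 0.0, 0.0, seed=1)
        labels = mos.founder_labels(small_founders.gmap)
        idx = np.arange(small_founders.n_markers)
        expected = (
            small_founders.alleles[labels[0], idx]
            + small_founders.alleles[labels[1], idx]
        )
        assert np.array_equal(calls, expected.astype(np.int8))

    def test_missing_rate_one_blanks_everything(self, small_founders, small_panel):
        mosaics, _ = small_panel
        calls = ccqg.genotype_line(mosaics[0], small_founders, 0.0, 1.0, seed=2)
        assert (calls == -1).all()

    def test_error_rate_within_binomial_bounds(self):
        f = ccqg.simulate_founders([4000], [100.0], seed=31)
        mos = ccqg.breed_cc_line(f, seed=32)
        clean = ccqg.genotype_line(mos, f, 0.0, 0.0, seed=33)
        noisy = ccqg.genotype_line(mos, f, 0.05, 0.0, seed=33)
        frac = (clean != noisy).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 4000)

    def test_map_mismatch_rejected(self, small_founders):
        other = ccqg.simulate_founders([40, 40], [60.0, 60.0], seed=34)
        mos = ccqg.breed_cc_line(other, seed=35)
        with pytest.raises(ccqg.errors.InconsistentInputError):
            ccqg.genotype_line(mos, small_founders)


class TestPhenotypes:
    def test_all_variance_off_gives_identical_animals(self, small_panel):
        mosaics, _ = small_panel
        spec = ccqg.QtlSpec(sigma_g2=0.0, sigma_e2=0.0, intercept=3.0)
        ph = ccqg.simulate_phenotypes(mosaics, None, spec, n_per_line=4, seed=1)
        assert np.allclose(ph["trait"], 3.0)
        assert ph.attrs["true_h2"] == 0.0

    def test_pure_genetic_variance_means_no_within_line_spread(self, small_panel):
        mosaics, truth = small_panel
        K = ccqg.kinship_from_descent(truth)
        spec = ccqg.QtlSpec(sigma_g2=2.0, sigma_e2=0.0)
        ph = ccqg.simulate_phenotypes(mosaics, K, spec, n_per_line=4, seed=2)
        within = ph.groupby("line")["trait"].var(ddof=1)
        assert np.allclose(within.fillna(0.0), 0.0)
        an = ccqg.anova_broad_h2(
            ph["trait"].to_numpy(), ph["line"].to_numpy()
        )
        assert an.H2 == pytest.approx(1.0)

    def test_variance_decomposition_matches_components(self):
        # identity kinship isolates the between/within-line split
        f = ccqg.simulate_founders([2], [50.0], seed=41)
        mosaics = ccqg.breed_cc_panel(f, 100, seed=42)
        K = ccqg.KinshipMatrix(
            tuple(m.line_id for m in mosaics), np.eye(100)
        )
        spec = ccqg.QtlSpec(sigma_g2=2.0, sigma_e2=1.0)
        ph = ccqg.simulate_phenotypes(mosaics, K, spec, n_per_line=5, seed=43)
        an = ccqg.anova_broad_h2(ph["trait"].to_numpy(), ph["line"].to_numpy())
        assert an.vg == pytest.approx(2.0, abs=0.6)
        assert an.ve == pytest.approx(1.0, abs=0.2)

    def test_psd_check(self, small_panel):
        mosaics, _ = small_panel
        bad = np.eye(len(mosaics))
        bad[0, 1] = bad[1, 0] = 2.0  # indefinite
        spec = ccqg.QtlSpec(sigma_g2=1.0, sigma_e2=1.0)
        with pytest.raises(InvalidArgumentError):
            ccqg.simulate_phenotypes(mosaics, bad, spec, seed=1)

    def test_qtl_effect_shifts_lines_carrying_the_allele(self, small_panel):
        mosaics, _ = small_panel
        effects = (5.0, 0, 0, 0, 0, 0, 0, 0)
        spec = ccqg.QtlSpec(
            qtls=(ccqg.QtlEffect("1", 25.0, effects),),
            sigma_g2=0.0,
            sigma_e2=0.0,
        )
        ph = ccqg.simulate_phenotypes(mosaics, None, spec, n_per_line=2, seed=3)
        means = ph.groupby("line")["trait"].mean()
        for mos in mosaics:
            f1, f2 = mos.founder_at("1", 25.0)
            expected = 0.5 * (effects[f1] + effects[f2])
            assert means[mos.line_id] == pytest.approx(expected)


@given(st.integers(0, 2**31 - 1))
def test_mosaic_segments_always_tile(seed):
    """Any bred mosaic tiles each chromosome without gaps or overlaps
    (the MosaicGenome constructor enforces tiling and founder range)."""
    f = _two_marker_founders(40.0)
    mos = ccqg.breed_cc_line(f, n_inbreeding_gens=2, seed=seed)
    assert mos.founder_shares().sum() == pytest.approx(1.0)
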