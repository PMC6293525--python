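"""Kinship construction and both heritability estimators."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

import ccqg
from ccqg.errors import InvalidArgumentError
from ccqg.herit import KinshipMatrix, _profile_negll
from ccqg.hmm import DescentProbabilities
from ccqg.genmap import GeneticMap

from oracles import regular_founders, true_sharing_fraction


def _probs_from_p(p):
    n = p.shape[1]
    cm = np.linspace(0, 10 * (n - 1), n)
    gm = GeneticMap(
        pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(n)],
                "chrom": "1",
                "bp": (cm * 2e6).astype(np.int64) + 1 + np.arange(n),
                "cM": cm,
            }
        )
    )
    return DescentProbabilities(
        tuple(f"L{i}" for i in range(p.shape[0])),
        gm.intervals,
        p,
        ccqg.CC_FOUNDERS,
    )


class TestKinship:
    def test_identical_one_hot_lines_share_everything(self):
        p = np.zeros((2, 5, 8))
        p[:, :, 2] = 1.0
        K = ccqg.kinship_from_descent(_probs_from_p(p))
        assert np.allclose(K.values, 1.0)

    def test_uniform_probabilities_give_one_eighth(self):
        p = np.full((3, 4, 8), 1 / 8)
        K = ccqg.kinship_from_descent(_probs_from_p(p))
        assert np.allclose(K.values, 1 / 8)

    def test_self_kinship_dominates_on_one_hot_probs(self, small_panel):
        _, truth = small_panel
        # collapse to one-hot (haploid consensus) probabilities
        p = np.zeros_like(truth.p)
        np.put_along_axis(
            p, truth.p.argmax(axis=2)[:, :, None], 1.0, axis=2
        )
        K = ccqg.kinship_from_descent(
            DescentProbabilities(
                truth.line_ids, truth.intervals, p, truth.founders
            )
        ).values
        assert np.allclose(np.diag(K), 1.0)
        for i in range(K.shape[0]):
            assert K[i, i] >= K[i].max() - 1e-12

    def test_symmetric_and_psd(self, small_panel):
        _, truth = small_panel
        K = ccqg.kinship_from_descent(truth)
        assert np.allclose(K.values, K.values.T)
        K.check_psd()
        assert np.linalg.eigvalsh(K.values).min() > -1e-8

    def test_matches_true_genome_sharing(self):
        """Kinship from descent probabilities equals the cM-weighted
        fraction of genome with identical founder labels, measured on a
        dense grid directly from the segment mosaics."""
        f = regular_founders([400] * 3, [60.0] * 3, seed=201)
        mosaics = ccqg.breed_cc_panel(f, 8, n_inbreeding_gens=25, seed=202)
        K = ccqg.kinship_from_descent(
            ccqg.descent_from_truth(mosaics, f.gmap)
        ).values
        for i in range(4):
            for j in range(i, 8):
                oracle = true_sharing_fraction(mosaics[i], mosaics[j], 0.2)
                assert abs(K[i, j] - oracle) < 0.02

    def test_rescaled_unit_mean_diagonal(self, small_panel):
        _, truth = small_panel
        K = ccqg.kinship_from_descent(truth).rescaled()
        assert np.trace(K.values) / len(K.line_ids) == pytest.approx(1.0)


class TestVarianceComponents:
    def test_optimum_beats_grid_envelope(self, small_panel):
        mosaics, truth = small_panel
        K = ccqg.kinship_from_descent(truth)
        spec = ccqg.QtlSpec(sigma_g2=1.0, sigma_e2=1.0)
        ph = ccqg.simulate_phenotypes(mosaics, K, spec, n_per_line=5, seed=210)
        y, lines = ph["trait"].to_numpy(), ph["line"].to_numpy()
        vc = ccqg.fit_variance_components(y, lines, K)
        idx = {l: i for i, l in enumerate(K.line_ids)}
        li = np.array([idx[l] for l in lines])
        s, U = np.linalg.eigh(K.values[np.ix_(li, li)])
        s = np.clip(s, 0, None)
        yt, xt = U.T @ y, U.T @ np.ones(len(y))
        for h in np.linspace(0, 0.999, 21):
            nll, _, _ = _profile_negll(h, s, yt, xt, len(y), False)
            assert -vc.loglik <= nll + 1e-6

    def test_matches_bruteforce_2d_grid(self):
        """Profile-ML h2 agrees with a dense direct search over
        (h2, total variance) using explicit Cholesky likelihoods."""
        rng = np.random.default_rng(5)
        f = ccqg.simulate_founders([40] * 4, [60.0] * 4, seed=51)
        for inst in range(3):
            nl = int(rng.integers(15, 30))
            mosaics = ccqg.breed_cc_panel(f, nl, seed=600 + inst)
            K = ccqg.kinship_from_descent(
                ccqg.descent_from_truth(mosaics, f.gmap)
            )
            spec = ccqg.QtlSpec(sigma_g2=float(rng.uniform(0, 3)), sigma_e2=1.0)
            ph = ccqg.simulate_phenotypes(
                mosaics, K, spec, n_per_line=5, seed=700 + inst
            )
            y, lines = ph["trait"].to_numpy(), ph["line"].to_numpy()
            vc = ccqg.fit_variance_components(y, lines, K)
            idx = {l: i for i, l in enumerate(K.line_ids)}
            A = K.values[np.ix_(
                [idx[l] for l in lines], [idx[l] for l in lines]
            )]
            n = len(y)
            one = np.ones(n)
            best = (None, -np.inf)
            for h in np.linspace(0, 0.995, 200):
                for sp2 in np.geomspace(0.05, 20, 60):
                    V = sp2 * (h * A + (1 - h) * np.eye(n))
                    c = linalg.cho_factor(V)
                    vi1 = linalg.cho_solve(c, one)
                    beta = (vi1 @ y) / (vi1 @ one)
                    r = y - beta
                    ll = -0.5 * (
                        n * np.log(2 * np.pi)
                        + 2 * np.log(np.diag(c[0])).sum()
                        + r @ linalg.cho_solve(c, r)
                    )
                    if ll > best[1]:
                        best = (h, ll)
            assert abs(vc.h2 - best[0]) < 0.02

    def test_heritability_monotone_in_genetic_variance(self):
        f = ccqg.simulate_founders([40] * 4, [60.0] * 4, seed=220)
        mosaics = ccqg.breed_cc_panel(f, 60, seed=221)
        K = ccqg.kinship_from_descent(ccqg.descent_from_truth(mosaics, f.gmap))
        narrow, broad = [], []
        for i, sg2 in enumerate((0.25, 1.0, 4.0)):
            spec = ccqg.QtlSpec(sigma_g2=sg2, sigma_e2=1.0)
            ph = ccqg.simulate_phenotypes(
                mosaics, K, spec, n_per_line=5, seed=230 + i
            )
            y, lines = ph["trait"].to_numpy(), ph["line"].to_numpy()
            narrow.append(ccqg.fit_variance_components(y, lines, K).h2)
            broad.append(ccqg.anova_broad_h2(y, lines).H2)
        assert narrow == sorted(narrow)
        assert broad == sorted(broad)

    def test_constant_trait_rejected(self, small_panel):
        _, truth = small_panel
        K = ccqg.kinship_from_descent(truth)
        lines = list(K.line_ids) * 3
        with pytest.raises(InvalidArgumentError):
            ccqg.fit_variance_components(np.ones(len(lines)), lines, K)

    def test_non_psd_kinship_rejected(self):
        ids = ("L1", "L2")
        K = KinshipMatrix(ids, np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(InvalidArgumentError):
            ccqg.fit_variance_components(
                np.array([1.0, 2.0, 3.0, 4.0]),
                ["L1", "L1", "L2", "L2"],
                K,
            )

    def test_reml_flag_runs(self, small_panel):
        mosaics, truth = small_panel
        K = ccqg.kinship_from_descent(truth)
        spec = ccqg.QtlSpec(sigma_g2=1.0, sigma_e2=1.0)
        ph = ccqg.simulate_phenotypes(mosaics, K, spec, n_per_line=5, seed=240)
        vc = ccqg.fit_variance_components(
            ph["trait"].to_numpy(), ph["line"].to_numpy(), K, reml=True
        )
        assert vc.method == "REML" and 0 <= vc.h2 <= 1


class TestAnovaH2:
    def test_hand_computed_toy(self):
        """Lines {1,3} and {5,7}: MSb=16, MSw=2, n=2, Vg=7, Ve=2, H2=7/9."""
        y = np.array([1.0, 3.0, 5.0, 7.0])
        lines = ["A", "A", "B", "B"]
        an = ccqg.anova_broad_h2(y, lines)
        assert an.ms_between == pytest.approx(16.0)
        assert an.ms_within == pytest.approx(2.0)
        assert an.n_bar == pytest.approx(2.0)
        assert an.vg == pytest.approx(7.0)
        assert an.ve == pytest.approx(2.0)
        assert an.H2 == pytest.approx(7.0 / 9.0)
        assert an.F == pytest.approx(8.0)
        assert an.p_value == pytest.approx(float(stats.f.sf(8.0, 1, 2)))

    def test_zero_within_line_variance_gives_full_heritability(self):
        an = ccqg.anova_broad_h2(
            np.array([1.0, 1.0, 4.0, 4.0, 9.0, 9.0]),
            ["A", "A", "B", "B", "C", "C"],
        )
        assert an.H2 == pytest.approx(1.0)

    def test_identical_animals_clamp_to_zero(self):
        an = ccqg.anova_broad_h2(
            np.full(6, 2.0), ["A", "A", "B", "B", "C", "C"]
        )
        assert an.H2 == 0.0

    def test_negative_vg_clamped_and_flagged(self):
        # strong within-line spread, equal line means
        y = np.array([0.0, 10.0, 0.0, 10.0, 0.0, 10.0, 0.0, 10.0])
        an = ccqg.anova_broad_h2(y, ["A", "A", "B", "B", "C", "C", "D", "D"])
        assert an.clamped and an.vg == 0.0 and an.H2 == 0.0

    def test_single_line_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ccqg.anova_broad_h2(np.array([1.0, 2.0]), ["A", "A"])
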