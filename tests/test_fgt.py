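"""Responsive-fraction (FGT1+) statistic: moment fits, null exceedance
probabilities, and the binomial tail p-value, checked against independent
oracles (hand arithmetic, pmf summation, Monte Carlo)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stressstates.fgt import (
    FgtError,
    NBControlModel,
    exceedance_prob,
    fgt_test,
    fgt_screen,
    fit_nb_mom,
    summarize_thresholds,
)
import scipy.sparse as sp

from stressstates.matrix import CountMatrix


def binom_tail_oracle(n: int, pi: float, k: int) -> float:
    """P(Binom(n, pi) >= k) by direct pmf summation."""
    return sum(
        math.comb(n, j) * pi**j * (1 - pi) ** (n - j) for j in range(k, n + 1)
    )


class TestFitNbMom:
    def test_hand_example_overdispersed(self):
        m = fit_nb_mom([2, 4, 6, 8])
        assert m.family == "NB"
        assert m.m == 5.0
        assert m.v == pytest.approx(20 / 3)
        assert m.r == pytest.approx(15.0)
        assert m.p == pytest.approx(0.75)

    def test_hand_example_sparse(self):
        m = fit_nb_mom([0, 0, 0, 10])
        assert m.m == 2.5
        assert m.v == pytest.approx(25.0)
        assert m.r == pytest.approx(2.5**2 / 22.5)
        assert m.p == pytest.approx(0.1)

    def test_constant_control_is_degenerate(self):
        m = fit_nb_mom([5, 5, 5, 5])
        assert m.family == "degenerate"
        assert m.m == 5.0

    def test_underdispersed_falls_back_to_poisson(self):
        m = fit_nb_mom([4, 5, 6, 5])  # v = 2/3 < m = 5
        assert m.family == "Poisson"

    @pytest.mark.parametrize("bad", [[3.0], [-1, 2, 3]])
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(FgtError):
            fit_nb_mom(bad)


class TestExceedanceProb:
    def test_poisson_tail_matches_pmf_summation(self):
        model = NBControlModel(5.0, 5.0, "Poisson")
        expected = 1.0 - sum(
            math.exp(-5) * 5**j / math.factorial(j) for j in range(11)
        )
        assert exceedance_prob(model, 10) == pytest.approx(expected, abs=1e-12)
        assert exceedance_prob(model, 10) == pytest.approx(0.01370, abs=5e-5)

    def test_nb_tail_matches_pmf_summation(self):
        model = fit_nb_mom([2, 4, 6, 8])
        # NB(r=15, p=0.75) pmf summed to the threshold
        total = sum(
            math.comb(j + 14, j) * 0.75**15 * 0.25**j for j in range(11)
        )
        assert exceedance_prob(model, 10) == pytest.approx(1 - total, abs=1e-12)

    def test_threshold_zero_counts_any_expression(self):
        model = fit_nb_mom([2, 4, 6, 8])
        assert exceedance_prob(model, 0) == pytest.approx(
            1 - stats.nbinom.pmf(0, 15, 0.75)
        )

    def test_degenerate_is_indicator(self):
        model = NBControlModel(5.0, 0.0, "degenerate")
        assert exceedance_prob(model, 10) == 0.0
        assert exceedance_prob(model, 4) == 1.0


class TestFgtTest:
    def test_identical_constant_vectors_give_p_one(self):
        r = fgt_test([4, 4, 4], [4, 4, 4, 4])
        assert r.k_exceed == 0 and r.f0 == 0.0 and r.p_value == 1.0

    def test_hand_example_against_enumeration_and_mc(self):
        r = fgt_test([1, 11, 12, 3], [2, 4, 6, 8])
        assert r.threshold == 10.0
        assert r.k_exceed == 2 and r.f0 == 0.5
        assert r.p_value == pytest.approx(
            binom_tail_oracle(4, r.pi0, 2), abs=1e-12
        )
        # Monte-Carlo check of the null exceedance probability itself
        rng = np.random.default_rng(0)
        draws = rng.negative_binomial(15, 0.75, size=10**6)
        pi_mc = (draws > 10).mean()
        se = math.sqrt(pi_mc * (1 - pi_mc) / 10**6)
        assert r.pi0 == pytest.approx(pi_mc, abs=3 * se)

    def test_all_zero_control_is_unscorable(self):
        r = fgt_test([0, 3, 5], [0, 0, 0])
        assert r.threshold == 0.0
        assert math.isnan(r.p_value)
        assert r.f0 == pytest.approx(2 / 3)

    def test_monotone_in_exceedances(self):
        """More exceeding cells => smaller p, all else fixed."""
        control = [2, 4, 6, 8]
        ps = []
        for k in range(5):
            treated = [11] * k + [1] * (4 - k)
            ps.append(fgt_test(treated, control).p_value)
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_downregulation_mirror(self):
        r = fgt_test([0, 0, 1, 9], [4, 8, 6, 6], downregulation=True)
        assert r.threshold == pytest.approx(3.0)
        assert r.k_exceed == 3  # values strictly below 3
        assert 0 < r.p_value <= 1


class TestFgtScreen:
    @staticmethod
    def _count_matrix(control, treated):
        values = np.vstack([control, treated])
        n_c, n_t = control.shape[0], treated.shape[0]
        meta = pd.DataFrame(
            {"chemical": ["DMSO"] * n_c + ["drugA"] * n_t,
             "conc": [0.0] * n_c + [1.0] * n_t},
            index=pd.Index([f"c{i}" for i in range(n_c + n_t)], name="cell_id"),
        )
        genes = pd.Index([f"g{j}" for j in range(values.shape[1])])
        return CountMatrix(sp.csr_matrix(values), meta, genes)

    def test_matches_single_gene_tests(self):
        """The screen reduces to per-gene tests on the raw counts."""
        rng = np.random.default_rng(5)
        control = rng.negative_binomial(5, 0.4, size=(40, 6))
        treated = rng.negative_binomial(5, 0.3, size=(30, 6))
        cm = self._count_matrix(control, treated)
        table, _ = fgt_screen(cm, alpha=0.1)
        for j in range(6):
            single = fgt_test(treated[:, j], control[:, j])
            row = table[table.gene == f"g{j}"].iloc[0]
            assert row.f0 == single.f0
            assert row.p == pytest.approx(single.p_value, abs=1e-12)
            assert row.pi0 == pytest.approx(single.pi0, abs=1e-12)

    def test_target_depth_rescales_cells(self):
        control = np.array([[4, 4], [2, 2], [6, 6]])
        treated = np.array([[10, 10], [4, 4]])
        cm = self._count_matrix(control, treated)
        raw_table, _ = fgt_screen(cm)
        norm_table, _ = fgt_screen(cm, target_depth=8.0)
        # after rescaling every cell is [4, 4]: nothing exceeds 2x the mean
        assert (norm_table.k_exceed == 0).all()
        assert raw_table.k_exceed.sum() > 0

    def test_missing_control_raises(self):
        cm = self._count_matrix(np.ones((3, 2), dtype=int), np.ones((2, 2), dtype=int))
        cm.cell_meta["chemical"] = "drugA"
        with pytest.raises(FgtError):
            fgt_screen(cm)

    def test_threshold_summary_hand_tally(self):
        table = pd.DataFrame(
            {
                "chemical": ["a"] * 3,
                "conc": [1.0] * 3,
                "f0": [0.06, 0.15, 0.5],
                "p": [0.05, 0.5, 0.01],
            }
        )
        s = summarize_thresholds(table, alpha=0.1).iloc[0]
        # gene 2 is not significant; genes 1 and 3 pass 0.05, only gene 3
        # passes 0.1 and 0.2
        assert s["n_significant"] == 2
        assert s["fgt_gt_0.05"] == 2
        assert s["fgt_gt_0.1"] == 1
        assert s["fgt_gt_0.2"] == 1


class TestNullCalibration:
    def test_null_pvalues_not_anticonservative(self):
        """Treated drawn from the control law => empirical CDF of p at any
        cutoff stays near or below the cutoff.

        The plug-in null needs the control moments estimated well, so the
        control population is large (2,000 cells), as in screens where a
        shared vehicle pool dwarfs each treatment group.
        """
        from stressstates.fgt import _vectorized_fgt

        rng = np.random.default_rng(42)
        n_genes = 1000
        mu = rng.lognormal(np.log(5), 0.8, n_genes)
        r = 5.0
        control = rng.negative_binomial(r, r / (r + mu), size=(2000, n_genes))
        treated = rng.negative_binomial(r, r / (r + mu), size=(300, n_genes))
        ps = _vectorized_fgt(treated.astype(float), control.astype(float), 1.0)[
            "p"
        ].to_numpy()
        for t in (0.01, 0.05, 0.1, 0.2):
            se = math.sqrt(t * (1 - t) / n_genes)
            assert (ps < t).mean() <= t + 3 * se + 0.01

    def test_power_increases_with_fraction_and_effect(self):
        """Mean f0 over simulated genes rises with responsive fraction and
        with effect size."""
        rng = np.random.default_rng(7)
        r, mu, n = 20.0, 10.0, 200

        def mean_f0(frac, l2fc, n_genes=60):
            out = []
            for _ in range(n_genes):
                control = rng.negative_binomial(r, r / (r + mu), n)
                resp = rng.random(n) < frac
                means = np.where(resp, mu * 2.0**l2fc, mu)
                treated = rng.negative_binomial(r, r / (r + means))
                out.append(fgt_test(treated, control).f0)
            return np.mean(out)

        assert mean_f0(0.2, 2) < mean_f0(0.5, 2) < mean_f0(0.8, 2)
        assert mean_f0(0.5, 0.5) < mean_f0(0.5, 2)
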