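"""Control standardisation, Z200 selection, generalized Jaccard scoring and
two-way ANOVA effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stressstates.connectivity import (
    ConnectivityError,
    ScoreTensor,
    Z200,
    anova_effects,
    gj_score,
    score_cells,
    select_z200,
    standardize_to_control,
)
from stressstates.matrix import NormMatrix
from stressstates.signatures import SignatureLibrary


def _norm(values, chemicals, concs):
    n, g = values.shape
    return NormMatrix(
        values,
        pd.DataFrame(
            {"chemical": chemicals, "conc": concs},
            index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
        ),
        pd.Index([f"g{j}" for j in range(g)]),
        normalized=True,
        logged=True,
    )


class TestStandardize:
    def test_control_cells_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        values = rng.normal(3, 2, size=(40, 10))
        nm = _norm(values, ["DMSO"] * 30 + ["a"] * 10, [0.0] * 30 + [1.0] * 10)
        zm = standardize_to_control(nm)
        ctrl = zm.z[:30]
        np.testing.assert_allclose(ctrl.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(ctrl.std(0, ddof=1), 1, rtol=1e-12)

    def test_hand_example_with_ddof1(self):
        values = np.array([[1.0], [3.0], [4.0]])
        nm = _norm(values, ["DMSO", "DMSO", "a"], [0.0, 0.0, 1.0])
        zm = standardize_to_control(nm)
        assert zm.z[2, 0] == pytest.approx(np.sqrt(2))

    def test_constant_control_gene_excluded(self):
        values = np.array([[1.0, 5.0], [1.0, 6.0], [9.0, 7.0]])
        nm = _norm(values, ["DMSO", "DMSO", "a"], [0.0, 0.0, 1.0])
        zm = standardize_to_control(nm)
        assert zm.excluded_genes == ["g0"]
        assert list(zm.gene_ids) == ["g1"]


class TestSelectZ200:
    def test_small_row_keeps_all_signed_genes(self):
        z200 = select_z200([1.0, -2.0, 0.0, 3.0], ["a", "b", "c", "d"], n=200)
        assert set(z200.up) == {"a", "d"}
        assert set(z200.down) == {"b"}

    def test_all_zero_row_gives_empty_sets(self):
        z200 = select_z200([0.0, 0.0], ["a", "b"], n=200)
        assert not z200.up and not z200.down

    def test_truncation_keeps_largest(self):
        rng = np.random.default_rng(3)
        z = rng.normal(2, 1, 250).clip(min=0.01)
        genes = [f"g{i:03d}" for i in range(250)]
        z200 = select_z200(z, genes, n=200)
        assert len(z200.up) == 200
        kept = np.sort(list(z200.up.values()))
        assert kept[0] >= np.sort(z)[::-1][199]


class TestGjScore:
    def test_perfect_concordance(self):
        z = Z200({"A": 1.0, "B": 0.5}, {})
        assert gj_score(z, ["A", "B"]) == 1.0

    def test_hand_example_cancellation(self):
        z = Z200({"A": 1.0, "B": 0.5}, {"C": -1.0})
        assert gj_score(z, ["A", "C", "D"]) == 0.0

    def test_hand_example_discordant(self):
        z = Z200({"A": 1.0}, {"B": -1.0})
        assert gj_score(z, ["B"]) == -0.5

    def test_empty_signature_rejected(self):
        with pytest.raises(ConnectivityError):
            gj_score(Z200({"A": 1.0}, {}), [])

    def test_swap_up_down_negates_for_unsigned_signature(self):
        z = Z200({"A": 1.0, "B": 0.5}, {"C": -2.0})
        swapped = Z200({"C": 2.0}, {"A": -1.0, "B": -0.5})
        sig = ["A", "C", "E"]
        assert gj_score(swapped, sig) == -gj_score(z, sig)

    def test_brute_force_oracle_small_universes(self):
        """Every signed configuration over a <= 5-element universe matches an
        element-by-element counting oracle."""
        universe = ["a", "b", "c", "d", "e"]
        # each element: 0 absent from cell, 1 in U, 2 in D; and 0 absent
        # from signature, 1 in S+, 2 in S-
        count = 0
        for cell_states in itertools.product((0, 1, 2), repeat=4):
            for sig_states in itertools.product((0, 1, 2), repeat=4):
                if all(s == 0 for s in sig_states):
                    continue
                up = {u: 1.0 for u, s in zip(universe, cell_states) if s == 1}
                down = {u: -1.0 for u, s in zip(universe, cell_states) if s == 2}
                sig = [u for u, s in zip(universe, sig_states) if s]
                signs = {
                    u: (1.0 if s == 1 else -1.0)
                    for u, s in zip(universe, sig_states)
                    if s
                }
                num = denom = 0
                for u, cs, ss in zip(universe, cell_states, sig_states):
                    if cs or ss:
                        denom += 1
                    if cs and ss:
                        num += 1 if cs == ss else -1
                expected = num / denom
                got = gj_score(Z200(up, down), sig, signs)
                assert got == pytest.approx(expected, abs=1e-12)
                assert -1.0 <= got <= 1.0
                count += 1
        assert count == 81 * 80

    @given(st.integers(0, 3**6 - 1), st.integers(0, 3**6 - 1))
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_bounds_on_random_instances(self, cell_code, sig_code):
        universe = [f"u{i}" for i in range(6)]
        cs = [(cell_code // 3**i) % 3 for i in range(6)]
        ss = [(sig_code // 3**i) % 3 for i in range(6)]
        if not any(ss):
            return
        up = {u: 1.0 for u, s in zip(universe, cs) if s == 1}
        down = {u: -1.0 for u, s in zip(universe, cs) if s == 2}
        sig = [u for u, s in zip(universe, ss) if s]
        signs = {u: 1.0 if s == 1 else -1.0 for u, s in zip(universe, ss) if s}
        assert -1.0 <= gj_score(Z200(up, down), sig, signs) <= 1.0


class TestScoreCells:
    def test_planted_activation_separates_pathways(self):
        """Cells whose top genes are exactly one signature score ~1 on it and
        near 0 on the others; control scores standardise to mean 0."""
        rng = np.random.default_rng(4)
        n_genes = 400
        lib = SignatureLibrary(
            {
                "UPR": [f"g{j}" for j in range(0, 50)],
                "OSR": [f"g{j}" for j in range(50, 100)],
            },
            sizes=(50,),
        )
        n_ctrl, n_resp = 60, 40
        values = rng.normal(0, 1, size=(n_ctrl + n_resp, n_genes))
        values[n_ctrl:, :50] += 6.0  # activate UPR genes only
        nm = _norm(
            values,
            ["DMSO"] * n_ctrl + ["drug"] * n_resp,
            [0.0] * n_ctrl + [1.0] * n_resp,
        )
        zm = standardize_to_control(nm)
        st_ = score_cells(zm, lib, sizes=(50,))
        z = st_.z_frame(50)
        treated = z.iloc[n_ctrl:]
        assert treated["UPR"].mean() > 3
        assert abs(treated["OSR"].mean()) < 1
        np.testing.assert_allclose(z.iloc[:n_ctrl].mean(0), 0, atol=1e-9)

    def test_duplicate_cell_scores_identically(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, size=(10, 50))
        values[9] = values[8]
        lib = SignatureLibrary({"S": [f"g{j}" for j in range(10)]}, sizes=(10,))
        nm = _norm(values, ["DMSO"] * 8 + ["d", "d"], [0.0] * 8 + [1.0, 1.0])
        st_ = score_cells(standardize_to_control(nm), lib, sizes=(10,))
        assert st_.raw[8, 0, 0] == st_.raw[9, 0, 0]

    def test_disjoint_signature_warns_and_is_nan(self, caplog):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, size=(6, 20))
        lib = SignatureLibrary({"S": ["absent1", "absent2"]}, sizes=(2,))
        nm = _norm(values, ["DMSO"] * 4 + ["d", "d"], [0.0] * 4 + [1.0, 1.0])
        st_ = score_cells(standardize_to_control(nm), lib, sizes=(2,))
        assert np.isnan(st_.raw).all()


class TestAnovaEffects:
    @staticmethod
    def _tensor(z_values, concs, sizes=(50, 100)):
        """One pathway, len(concs) cells x len(sizes) observations."""
        n = len(concs)
        z = np.asarray(z_values, dtype=float).reshape(n, 1, len(sizes))
        meta = pd.DataFrame(
            {
                "chemical": ["DMSO" if c == 0 else "drug" for c in concs],
                "conc": concs,
            },
            index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
        )
        return ScoreTensor(z.copy(), z, meta, ("SRP",), tuple(sizes))

    def test_constant_response_zero_eta(self):
        t = self._tensor(np.ones((4, 2)), [0.0, 0.0, 1.0, 2.0])
        out = anova_effects(t)
        assert (out.eta_squared == 0).all()
        assert (out.slope == 0).all()

    def test_pure_conc_effect_eta_one(self):
        concs = [0.0, 0.0, 1.0, 2.0]
        z = np.repeat(np.array(concs)[:, None], 2, axis=1) * 3.0
        out = anova_effects(self._tensor(z, concs)).set_index("factor")
        assert out.loc["conc", "eta_squared"] == pytest.approx(1.0)
        assert out.loc["length", "eta_squared"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["conc", "slope"] == pytest.approx(3.0)

    def test_matches_normal_equations_oracle(self):
        """Sequential sums of squares and slopes match an explicit
        least-squares computation on an 8-observation design."""
        concs = [0.0, 0.0, 1.0, 5.0]
        sizes = (50, 100)
        rng = np.random.default_rng(7)
        z = rng.normal(0, 1, size=(4, 2)) + np.array(concs)[:, None] * 0.5
        out = anova_effects(self._tensor(z, concs, sizes)).set_index("factor")

        # oracle: explicit projections
        y = z.ravel()
        c = np.repeat(concs, 2)
        l = np.tile(sizes, 4).astype(float)
        X0 = np.ones((8, 1))
        X1 = np.column_stack([np.ones(8), c])
        X2 = np.column_stack([np.ones(8), c, l])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return ((y - X @ beta) ** 2).sum()

        ss_total = ((y - y.mean()) ** 2).sum()
        ss_conc = rss(X0) - rss(X1)
        ss_len = rss(X1) - rss(X2)
        beta_full = np.linalg.lstsq(X2, y, rcond=None)[0]

        assert out.loc["conc", "eta_squared"] == pytest.approx(
            ss_conc / ss_total, abs=1e-10
        )
        assert out.loc["length", "eta_squared"] == pytest.approx(
            ss_len / ss_total, abs=1e-10
        )
        assert out.loc["conc", "slope"] == pytest.approx(beta_full[1], abs=1e-10)
        assert out.loc["length", "slope"] == pytest.approx(beta_full[2], abs=1e-10)
        assert out.eta_squared.sum() <= 1.0 + 1e-12

    def test_eta_invariant_to_affine_response_rescaling(self):
        concs = [0.0, 0.0, 1.0, 2.0, 4.0, 8.0]
        rng = np.random.default_rng(8)
        z = rng.normal(0, 1, size=(6, 2)) + np.array(concs)[:, None]
        a = anova_effects(self._tensor(z, concs)).set_index("factor")
        b = anova_effects(self._tensor(5 * z + 2, concs)).set_index("factor")
        pd.testing.assert_series_equal(
            a.eta_squared, b.eta_squared, atol=1e-10, rtol=0
        )
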