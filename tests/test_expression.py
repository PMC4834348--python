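"""Thresholding, binarization, GPR state mapping and differential statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gbmflux as gf
from gbmflux.expression import (
    GBM_MARKER_GENES,
    UNMAPPED,
    ExpressionError,
    collapse_probes,
)


def matrix(data, label="test"):
    return gf.ExpressionMatrix(pd.DataFrame(data).T.rename(
        columns=lambda c: f"s{c}"), dataset_label=label)


def simple_matrix(values_by_gene):
    df = pd.DataFrame(values_by_gene).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return gf.ExpressionMatrix(df)


class TestThreshold:
    def test_half_of_mean(self):
        m = simple_matrix({"g": [2.0, 4.0, 6.0]})
        assert gf.compute_threshold(m, 0.5) == pytest.approx(2.0)

    def test_fraction_one_is_grand_mean(self):
        m = simple_matrix({"g1": [1.0, 3.0], "g2": [5.0, 7.0]})
        assert gf.compute_threshold(m, 1.0) == pytest.approx(4.0)

    def test_third_of_mean_on_random_matrix(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, size=(1000, 10))
        m = gf.ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(1000)],
            columns=[f"s{j}" for j in range(10)]))
        assert gf.compute_threshold(m, 1 / 3) == pytest.approx(vals.mean() / 3)
        assert gf.compute_threshold(m, 1 / 3) == pytest.approx(0.5 / 3, abs=0.01)

    def test_empty_matrix_rejected(self):
        m = gf.ExpressionMatrix(pd.DataFrame())
        with pytest.raises(ExpressionError):
            gf.compute_threshold(m, 0.5)

    def test_marker_panel_is_the_six_gbm_genes(self):
        assert tuple(GBM_MARKER_GENES) == ("HK2", "PKM2", "GLS", "ACLY",
                                           "ACC", "FASN")

    def test_validation_passes_when_markers_above(self):
        m = simple_matrix({g: [10.0, 10.0] for g in GBM_MARKER_GENES})
        rep = gf.validate_threshold(m, 5.0)
        assert rep.valid and not rep.offending

    def test_validation_flags_offending_marker(self):
        data = {g: [10.0, 10.0] for g in GBM_MARKER_GENES}
        data["HK2"] = [4.0, 4.0]
        rep = gf.validate_threshold(simple_matrix(data), 5.0)
        assert not rep.valid
        assert rep.offending == ["HK2"]

    def test_absent_markers_are_warnings_not_failures(self):
        m = simple_matrix({"HK2": [10.0, 10.0]})
        rep = gf.validate_threshold(m, 5.0)
        assert rep.valid
        assert set(rep.absent_markers) == set(GBM_MARKER_GENES) - {"HK2"}


class TestBinarize:
    def test_above_threshold_is_on(self):
        st = gf.binarize(simple_matrix({"g": [6.0, 6.0]}), 2.0)
        assert st["g"] == 1

    def test_boundary_mean_equal_threshold_is_off(self):
        st = gf.binarize(simple_matrix({"g": [2.0, 2.0]}), 2.0)
        assert st["g"] == 0

    def test_fraction_on_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        m = gf.ExpressionMatrix(pd.DataFrame(
            rng.lognormal(4, 1, size=(200, 8)),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(8)]))
        fracs = [gf.binarize(m, t).fraction_on()
                 for t in np.linspace(0, 200, 30)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestReactionStates:
    def test_or_rule(self, toy_branch_net):
        st = gf.BinaryExpressionState({"g2": 0, "g3": 1})
        rs = gf.reaction_states(toy_branch_net, st)
        assert rs["R2"] == 0 and rs["R3"] == 1
        assert rs["R1"] == UNMAPPED and rs["R4"] == UNMAPPED

    def test_missing_gene_policy(self):
        net = gf.MetabolicNetwork()
        net.add_metabolite(gf.Metabolite("A"))
        net.add_reaction(gf.Reaction("R", {"A": 1.0},
                                     gpr=gf.parse_gpr("g1 and g2")))
        on = gf.reaction_states(net, gf.BinaryExpressionState({"g1": 1}))
        off = gf.reaction_states(net, gf.BinaryExpressionState({"g1": 1}),
                                 missing_policy="off")
        assert on["R"] == 1 and off["R"] == 0

    def test_matches_bruteforce_boolean_oracle(self):
        rng = np.random.default_rng(11)
        genes = ["g1", "g2", "g3", "g4"]
        for trial in range(25):
            a, b, c, d = rng.permutation(genes)
            o = [" and ", " or "]
            rule = f"({a}{rng.choice(o)}{b}){rng.choice(o)}({c}{rng.choice(o)}{d})"
            net = gf.MetabolicNetwork()
            net.add_metabolite(gf.Metabolite("A"))
            net.add_reaction(gf.Reaction("R", {"A": 1.0}, gpr=gf.parse_gpr(rule)))
            for bits in itertools.product([0, 1], repeat=4):
                env = dict(zip(genes, bits))
                expected = int(eval(rule, {}, {k: bool(v) for k, v in env.items()}))
                rs = gf.reaction_states(net, gf.BinaryExpressionState(env))
                assert rs["R"] == expected

    def test_monotone_in_gene_states(self, toy_net):
        """Flipping any gene 0 -> 1 never flips a reaction 1 -> 0."""
        rng = np.random.default_rng(13)
        genes = sorted(toy_net.genes)
        for _ in range(20):
            base = {g: int(rng.random() < 0.5) for g in genes}
            rs0 = gf.reaction_states(toy_net, gf.BinaryExpressionState(base))
            flip = rng.choice([g for g in genes if base[g] == 0] or genes)
            up = dict(base, **{flip: 1})
            rs1 = gf.reaction_states(toy_net, gf.BinaryExpressionState(up))
            for rid, s0 in rs0.items():
                if s0 == 1:
                    assert rs1[rid] == 1


class TestDifferentialStats:
    def test_closed_form_pooled_t(self):
        case = simple_matrix({"g": [4.0, 5.0, 6.0]})
        control = simple_matrix({"g": [1.0, 2.0, 3.0]})
        st = gf.differential_stats(case, control)
        assert st.table.at["g", "t_statistic"] == pytest.approx(3.674, abs=1e-3)
        assert st.table.at["g", "p_value"] == pytest.approx(0.0214, abs=2e-4)
        assert st.table.at["g", "fold_change"] == pytest.approx(2.5)

    def test_identical_groups(self):
        m = simple_matrix({"g": [2.0, 3.0, 4.0]})
        st = gf.differential_stats(m, m)
        assert st.table.at["g", "fold_change"] == pytest.approx(1.0)
        assert st.table.at["g", "p_value"] == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        m = simple_matrix({"g": [5.0, 5.0]})
        st = gf.differential_stats(m, m)
        assert st.table.at["g", "p_value"] == 1.0

    def test_zero_variance_unequal_means_uses_floor(self):
        st = gf.differential_stats(simple_matrix({"g": [5.0, 5.0]}),
                                   simple_matrix({"g": [1.0, 1.0]}))
        assert st.table.at["g", "p_value"] < 1e-6

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        a = simple_matrix({"g": rng.normal(10, 1, 5).tolist()})
        b = simple_matrix({"g": rng.normal(12, 1, 5).tolist()})
        ab = gf.differential_stats(a, b).table
        ba = gf.differential_stats(b, a).table
        assert ab.at["g", "t_statistic"] == pytest.approx(-ba.at["g", "t_statistic"])
        assert ab.at["g", "fold_change"] == pytest.approx(
            1 / ba.at["g", "fold_change"])

    def test_matches_independent_t_on_random_fixtures(self):
        """100 random fixtures against scipy's independent pooled-t path."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(2, 8, 2)
            x = rng.lognormal(3, 0.5, n1)
            y = rng.lognormal(3, 0.5, n2)
            st = gf.differential_stats(
                simple_matrix({"g": x.tolist()}), simple_matrix({"g": y.tolist()}))
            t_ref, p_ref = sps.ttest_ind(x, y, equal_var=True)
            assert st.table.at["g", "t_statistic"] == pytest.approx(t_ref, abs=1e-10)
            assert st.table.at["g", "p_value"] == pytest.approx(p_ref, abs=1e-10)


class TestProbeCollapse:
    def test_max_mean_policy(self):
        df = pd.DataFrame({"s1": [1.0, 10.0, 3.0], "s2": [2.0, 12.0, 3.0]},
                          index=["p1", "p2", "p3"])
        sym = pd.Series(["GENEA", "GENEA", "GENEB"], index=df.index)
        out = collapse_probes(df, sym)
        assert out.loc["GENEA", "s1"] == 10.0
        assert out.shape == (2, 2)


class TestSensitivity:
    def test_zero_delta_is_identity(self):
        rep = gf.threshold_sensitivity(lambda t: {"R": t * 0 + 1.0}, 10.0,
                                       delta=0.0)
        assert rep.max_abs_flux_change == 0.0

    def test_stable_band_reports_zero_change(self, toy_branch_net):
        def run(thr):
            st = gf.BinaryExpressionState({"g2": int(5.0 > thr),
                                           "g3": int(50.0 > thr)})
            rs = gf.reaction_states(toy_branch_net, st)
            ctx = gf.gimme(toy_branch_net, rs, rmf_fraction=0.9)
            return gf.dual_objective_fba(ctx.network).fluxes

        rep = gf.threshold_sensitivity(run, 20.0, delta=0.05)
        assert rep.max_abs_flux_change == pytest.approx(0.0, abs=1e-9)
        assert not rep.failures

    def test_straddling_threshold_localizes_change(self, toy_branch_net):
        """A gene mean just below (1+delta)*threshold flips only its own
        reaction's flux."""
        def run(thr):
            st = gf.BinaryExpressionState({"g2": int(20.5 > thr),
                                           "g3": int(50.0 > thr)})
            rs = gf.reaction_states(toy_branch_net, st)
            ctx = gf.gimme(toy_branch_net, rs, rmf_fraction=0.9)
            return gf.dual_objective_fba(ctx.network).fluxes

        rep = gf.threshold_sensitivity(run, 20.0, delta=0.05)
        assert rep.max_abs_flux_change > 0
        changed = set(rep.per_reaction[rep.per_reaction["max_change"] > 1e-9].index)
        # rerouting is confined to the branch governed by the straddled gene
        assert "R2" in changed
        assert "R1" not in changed and "R4" not in changed
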