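"""Network data model, GPR parsing, stoichiometric assembly and SBML/JSON I/O."""

import itertools

import numpy as np
import pytest

import gbmflux as gf
from gbmflux.network import (
    GPRSyntaxError,
    NetworkError,
    check_steady_state,
    read_json,
    read_sbml,
    write_json,
    write_sbml,
)


class TestGPR:
    @pytest.mark.parametrize("rule,states,expected", [
        ("(g1 and g2) or g3", {"g1": 1, "g2": 0, "g3": 1}, 1),
        ("g1 and g2", {"g1": 1, "g2": 0}, 0),
        ("g1 or g2", {"g1": 0, "g2": 1}, 1),
        ("g1 AND (g2 OR g3)", {"g1": 1, "g2": 0, "g3": 1}, 1),
    ])
    def test_evaluation_examples(self, rule, states, expected):
        assert gf.parse_gpr(rule).evaluate(states) == expected

    def test_truth_table_oracle(self):
        """Tree evaluation equals direct boolean evaluation of the expression
        over all assignments, for a panel of random 3-gene rules."""
        rng = np.random.default_rng(0)
        genes = ["g1", "g2", "g3"]
        ops = [" and ", " or "]
        for _ in range(50):
            a, b, c = rng.permutation(genes)
            o1, o2 = rng.choice(ops, 2)
            if rng.random() < 0.5:
                rule = f"({a}{o1}{b}){o2}{c}"
                pyexpr = f"({a}{o1}{b}){o2}{c}"
            else:
                rule = f"{a}{o1}({b}{o2}{c})"
                pyexpr = f"{a}{o1}({b}{o2}{c})"
            tree = gf.parse_gpr(rule)
            for bits in itertools.product([0, 1], repeat=3):
                env = dict(zip(genes, bits))
                expected = int(eval(pyexpr, {}, {k: bool(v) for k, v in env.items()}))
                assert tree.evaluate(env) == expected

    def test_missing_gene_defaults_to_expressed(self):
        assert gf.parse_gpr("g1 and g2").evaluate({"g1": 1}) == 1
        assert gf.parse_gpr("g1 and g2").evaluate({"g1": 1}, missing=0) == 0

    @pytest.mark.parametrize("rule", ["(g1 and g2", "g1 and", "and g2",
                                      "g1 g2", "g1 and or g2"])
    def test_syntax_errors_carry_position(self, rule):
        with pytest.raises(GPRSyntaxError) as exc:
            gf.parse_gpr(rule)
        assert "position" in str(exc.value)

    def test_roundtrip_to_string(self):
        tree = gf.parse_gpr("(g1 and g2) or g3 or (g4 and g5)")
        assert gf.parse_gpr(tree.to_string()).to_string() == tree.to_string()

    def test_random_rules_roundtrip_and_evaluate_consistently(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        genes = st.sampled_from(["g1", "g2", "g3", "g4"])
        rules = st.recursive(
            genes.map(lambda g: g),
            lambda kids: st.tuples(kids, st.sampled_from(["and", "or"]),
                                   kids).map(lambda t: f"({t[0]} {t[1]} {t[2]})"),
            max_leaves=8)

        @settings(max_examples=60, derandomize=True, deadline=None)
        @given(rule=rules, bits=st.tuples(*[st.integers(0, 1)] * 4))
        def check(rule, bits):
            env = dict(zip(["g1", "g2", "g3", "g4"], bits))
            tree = gf.parse_gpr(rule)
            back = gf.parse_gpr(tree.to_string())
            assert back.evaluate(env) == tree.evaluate(env)
            expected = int(eval(rule, {}, {k: bool(v) for k, v in env.items()}))
            assert tree.evaluate(env) == expected

        check()


class TestInvariants:
    def test_bounds_order_enforced(self):
        r = gf.Reaction("r", {"A": -1.0}, lower_bound=2.0, upper_bound=1.0)
        with pytest.raises(NetworkError, match="lower_bound"):
            r.validate()

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(NetworkError, match="empty"):
            gf.Reaction("r", {}).validate()

    def test_exchange_single_entry(self):
        r = gf.Reaction("r", {"A": -1.0, "B": 1.0}, is_exchange=True)
        with pytest.raises(NetworkError, match="exactly one"):
            r.validate()

    def test_duplicate_reaction_id(self, toy_lin):
        with pytest.raises(NetworkError, match="R_up"):
            toy_lin.add_reaction(gf.Reaction("R_up", {"A": -1.0}))

    def test_unknown_metabolite_rejected(self, toy_lin):
        with pytest.raises(NetworkError, match="nonexistent"):
            toy_lin.add_reaction(gf.Reaction("R_x", {"nonexistent": 1.0}))


class TestStoichiometricMatrix:
    def test_toy_lin_readback(self, toy_lin):
        S = gf.stoichiometric_matrix(toy_lin, sparse=False)
        assert S.shape == (3, 3)
        i = {m: k for k, m in enumerate(toy_lin.metabolite_ids)}
        j = {r: k for k, r in enumerate(toy_lin.reaction_ids)}
        assert S[i["A"], j["R_up"]] == -1.0
        assert S[i["A"], j["R_conv"]] == -1.0
        assert S[i["B"], j["R_conv"]] == 1.0
        assert S[i["B"], j["R_out"]] == -1.0

    def test_isolated_metabolite_row_retained(self, toy_lin):
        S = gf.stoichiometric_matrix(toy_lin, sparse=False)
        i = toy_lin.metabolite_ids.index("C")
        assert np.all(S[i] == 0)

    def test_fba_solution_in_null_space(self, toy_lin):
        fd = gf.fba(toy_lin)
        S = gf.stoichiometric_matrix(toy_lin)
        v = np.array([fd.fluxes[r] for r in toy_lin.reaction_ids])
        assert np.abs(S @ v).max() <= 1e-6


class TestSBML:
    def test_roundtrip_identity(self, toy_net, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(toy_net, path)
        back = read_sbml(path)
        assert toy_net.equal_under_canonical_ordering(back)
        assert back.objective_reaction == toy_net.objective_reaction
        assert back.genes == toy_net.genes

    def test_default_bounds_applied(self, tmp_path):
        """Reactions without declared bounds: irreversible [0, 1000],
        reversible [-1000, 1000]."""
        sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
 <model id="m">
  <listOfCompartments><compartment id="e" name="extracellular"/></listOfCompartments>
  <listOfSpecies>
   <species id="A" compartment="e"/><species id="B" compartment="e"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="r_irr" reversible="false">
    <listOfReactants><speciesReference species="A"/></listOfReactants>
    <listOfProducts><speciesReference species="B"/></listOfProducts>
   </reaction>
   <reaction id="r_rev" reversible="true">
    <listOfReactants><speciesReference species="A"/></listOfReactants>
    <listOfProducts><speciesReference species="B"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>"""
        p = tmp_path / "m.xml"
        p.write_text(sbml)
        net = read_sbml(p)
        assert (net.reaction("r_irr").lower_bound,
                net.reaction("r_irr").upper_bound) == (0.0, 1000.0)
        assert (net.reaction("r_rev").lower_bound,
                net.reaction("r_rev").upper_bound) == (-1000.0, 1000.0)

    def test_duplicate_reaction_id_rejected(self, tmp_path):
        sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
 <model id="m">
  <listOfCompartments><compartment id="e"/></listOfCompartments>
  <listOfSpecies><species id="A" compartment="e"/></listOfSpecies>
  <listOfReactions>
   <reaction id="dup"><listOfReactants><speciesReference species="A"/></listOfReactants></reaction>
   <reaction id="dup"><listOfReactants><speciesReference species="A"/></listOfReactants></reaction>
  </listOfReactions>
 </model>
</sbml>"""
        p = tmp_path / "dup.xml"
        p.write_text(sbml)
        with pytest.raises(NetworkError, match="dup"):
            read_sbml(p)

    def test_malformed_xml_names_line(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<sbml><model><unclosed></model></sbml>")
        with pytest.raises(NetworkError, match="line"):
            read_sbml(p)


class TestJSON:
    def test_roundtrip(self, toy_net, tmp_path):
        path = tmp_path / "toy.json"
        write_json(toy_net, path)
        back = read_json(path)
        assert toy_net.equal_under_canonical_ordering(back)
        assert back.objective_reaction == toy_net.objective_reaction


def test_solver_outputs_satisfy_feasibility_invariant(constrained_net):
    """|S v| <= 1e-6 and bounds to 1e-9 for every solver output."""
    fd = gf.dual_objective_fba(constrained_net)
    resid, bviol = check_steady_state(constrained_net, fd.fluxes)
    assert resid <= 1e-6
    assert bviol <= 1e-9
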