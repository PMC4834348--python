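"""FBA and Euclidean-norm minimization against independent oracles.

The LP is checked against exhaustive vertex enumeration (basic feasible
solutions of the small polytopes) and against an independent COBRA/GLPK
solve; the QP against closed-form Lagrange solutions.
"""

import itertools

import numpy as np
import pytest

import gbmflux as gf
from gbmflux.optimize import INFEASIBLE, OPTIMAL, min_norm_fluxes


def enumerate_vertices(net, extra_rows=None):
    """Brute-force vertex enumeration oracle for small networks.

    Vertices of {v : A v = b, lb <= v <= ub} are found by fixing
    (n - rank(A)) variables at a bound in all combinations and solving the
    resulting square system; infeasible or unbounded combinations are
    discarded.
    """
    S = net.stoichiometric_matrix(sparse=False)
    b = np.zeros(S.shape[0])
    if extra_rows:
        for coeffs, rhs in extra_rows:
            row = np.zeros(S.shape[1])
            for rid, c in coeffs.items():
                row[net.reaction_index(rid)] = c
            S = np.vstack([S, row])
            b = np.append(b, rhs)
    lb, ub = net.bounds_arrays()
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    n_fix = n - rank
    vertices = []
    for idx in itertools.combinations(range(n), n_fix):
        for bounds in itertools.product(*[(lb[j], ub[j]) for j in idx]):
            A = S.copy()
            rhs = b.copy()
            for j, val in zip(idx, bounds):
                row = np.zeros(n)
                row[j] = 1.0
                A = np.vstack([A, row])
                rhs = np.append(rhs, val)
            try:
                v, res, rk, _ = np.linalg.lstsq(A, rhs, rcond=None)
            except np.linalg.LinAlgError:
                continue
            if rk < n:
                continue
            if np.abs(A @ v - rhs).max() > 1e-8:
                continue
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
                vertices.append(v)
    return vertices


class TestFBA:
    def test_linear_path_bottleneck(self, toy_lin):
        fd = gf.fba(toy_lin)
        assert fd.status == OPTIMAL
        assert fd.objective_value == pytest.approx(10.0, abs=1e-9)
        assert fd["R_up"] == pytest.approx(-10.0, abs=1e-9)

    def test_inverted_bounds_infeasible(self, toy_lin):
        net = toy_lin.copy()
        net.reaction("R_conv").lower_bound = 5.0
        net.reaction("R_conv").upper_bound = 2.0
        assert gf.fba(net).status == INFEASIBLE

    def test_vertex_enumeration_oracle_on_branch(self, toy_branch_net):
        verts = enumerate_vertices(toy_branch_net)
        assert verts, "oracle found no vertices"
        j = toy_branch_net.reaction_index("R4")
        oracle_opt = max(v[j] for v in verts)
        fd = gf.fba(toy_branch_net)
        assert fd.objective_value == pytest.approx(oracle_opt, abs=1e-8)

    def test_random_feasible_points_never_beat_optimum(self, toy_branch_net):
        """Any feasible point (from LPs with random objectives) scores no
        higher than the FBA optimum."""
        opt = gf.fba(toy_branch_net).objective_value
        rng = np.random.default_rng(1)
        j = toy_branch_net.reaction_index("R4")
        for _ in range(20):
            c = rng.normal(size=len(toy_branch_net.reactions))
            from scipy.optimize import linprog

            S = toy_branch_net.stoichiometric_matrix()
            lb, ub = toy_branch_net.bounds_arrays()
            res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=np.column_stack([lb, ub]), method="highs")
            assert res.status == 0
            assert res.x[j] <= opt + 1e-6

    def test_bound_scaling_homogeneity(self, toy_branch_net):
        """Scaling all bounds by k scales the optimum by k."""
        opt = gf.fba(toy_branch_net).objective_value
        scaled = toy_branch_net.copy()
        for r in scaled.reactions:
            r.lower_bound *= 2.5
            r.upper_bound *= 2.5
        assert gf.fba(scaled).objective_value == pytest.approx(2.5 * opt, rel=1e-9)

    def test_agrees_with_cobra_on_toy_brain(self, constrained_net):
        """Independent oracle: the same model solved through COBRA/GLPK."""
        cobra = pytest.importorskip("cobra")
        m = cobra.Model("toy")
        mets = {mm.id: cobra.Metabolite(mm.id) for mm in constrained_net.metabolites}
        rxns = []
        for r in constrained_net.reactions:
            cr = cobra.Reaction(r.id)
            cr.lower_bound, cr.upper_bound = r.lower_bound, r.upper_bound
            rxns.append(cr)
        m.add_reactions(rxns)
        for r in constrained_net.reactions:
            m.reactions.get_by_id(r.id).add_metabolites(
                {mets[k]: v for k, v in r.stoichiometry.items()})
        m.objective = constrained_net.objective_reaction
        sol = m.optimize()
        ours = gf.fba(constrained_net)
        assert sol.status == "optimal"
        assert ours.objective_value == pytest.approx(sol.objective_value, abs=1e-6)


class TestMinNorm:
    def test_symmetric_paths_split_evenly(self, toy_branch_net):
        fd = gf.fba(toy_branch_net)
        mn = min_norm_fluxes(toy_branch_net, objective_value=fd.objective_value)
        assert mn["R2"] == pytest.approx(5.0, abs=1e-8)
        assert mn["R3"] == pytest.approx(5.0, abs=1e-8)

    def test_lagrange_closed_form_two_path(self):
        """min v1^2 + 2 v2^2 s.t. v1 + v2 = 10 -> v1 = 20/3, v2 = 10/3."""
        net = gf.toy_two_path()
        fd = gf.fba(net)
        mn = min_norm_fluxes(net, objective_value=fd.objective_value)
        assert mn["P1"] == pytest.approx(20 / 3, abs=1e-8)
        assert mn["P2a"] == pytest.approx(10 / 3, abs=1e-8)
        assert mn["P2b"] == pytest.approx(10 / 3, abs=1e-8)

    def test_uniqueness_on_rerun(self, toy_branch_net):
        fd = gf.fba(toy_branch_net)
        a = min_norm_fluxes(toy_branch_net, objective_value=fd.objective_value)
        b = min_norm_fluxes(toy_branch_net, objective_value=fd.objective_value)
        for rid in a.fluxes:
            assert a[rid] == b[rid]

    def test_norm_not_above_plain_fba(self, constrained_net):
        fd = gf.fba(constrained_net)
        mn = min_norm_fluxes(constrained_net, objective_value=fd.objective_value)
        internal = constrained_net.internal_ids()
        norm_fba = sum(fd[r] ** 2 for r in internal)
        norm_mn = sum(mn[r] ** 2 for r in internal)
        assert norm_mn <= norm_fba + 1e-6

    def test_kkt_stationarity_against_generic_qp(self):
        """The minimizer satisfies KKT of the equality-constrained QP: the
        weighted flux vector is orthogonal to the feasible null space."""
        net = gf.toy_two_path()
        fd = gf.fba(net)
        mn = min_norm_fluxes(net, objective_value=fd.objective_value)
        v = np.array([mn[r.id] for r in net.reactions])
        w = np.array([0.0 if r.is_exchange else 1.0 for r in net.reactions])
        S = net.stoichiometric_matrix(sparse=False)
        j = net.reaction_index("R_out")
        row = np.zeros(len(net.reactions))
        row[j] = 1.0
        A = np.vstack([S, row])
        from scipy.linalg import null_space

        N = null_space(A)
        grad = w * v
        assert np.abs(N.T @ grad).max() <= 1e-7


class TestDualObjective:
    def test_unique_path_equals_plain_fba(self, toy_lin):
        fba_fd = gf.fba(toy_lin)
        dual = gf.dual_objective_fba(toy_lin)
        assert dual.objective_value == pytest.approx(fba_fd.objective_value)
        for rid in fba_fd.fluxes:
            assert dual[rid] == pytest.approx(fba_fd[rid], abs=1e-8)

    def test_composition_on_branch(self, toy_branch_net):
        dual = gf.dual_objective_fba(toy_branch_net)
        assert dual.objective_value == pytest.approx(10.0, abs=1e-8)
        assert dual["R2"] == pytest.approx(5.0, abs=1e-7)

    def test_infeasible_status_propagates(self, toy_lin):
        net = toy_lin.copy()
        net.reaction("R_conv").lower_bound = 5.0
        net.reaction("R_conv").upper_bound = 2.0
        assert gf.dual_objective_fba(net).status == INFEASIBLE
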