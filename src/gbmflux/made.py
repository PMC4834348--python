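"""MADE: two-condition metabolic adjustment by differential expression.

MADE replaces the arbitrary binarization threshold of GIMME with the
statistically significant expression *changes* between two conditions.  Per
gene the desired transition is: increase if fold change > 1 and p < alpha,
decrease if fold change < 1 and p < alpha, otherwise constant.  A MILP picks
binary gene states in control and case maximizing the significance-weighted
number of matched transitions (weight w_g = 1 - p_g), subject to each
condition's model remaining functional: gene states propagate through the
GPR rules (AND/OR linearized over binaries) to reaction on/off indicators,
off reactions carry zero flux, and growth must reach a stated fraction of
the unconstrained optimum in both conditions.

The MILP is solved with HiGHS through :func:`scipy.optimize.milp`.  Ties in
the primary objective are broken toward the fewest control-to-case state
flips via a small secondary penalty, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .network import MetabolicNetwork
from .optimize import (
    OPTIMAL,
    FluxDistribution,
    SolverError,
    SolverSettings,
    fba,
    min_norm_fluxes,
)

INCREASE, DECREASE, CONSTANT = "increase", "decrease", "constant"

#: weight of the flip-minimizing tie-break; small enough to never trade
#: against the significance-weighted agreement objective
TIE_BREAK_EPS = 1e-7


class MadeError(RuntimeError):
    pass


@dataclass
class MadeResult:
    gene_states: dict  # gene -> (state_control, state_case)
    desired: dict      # gene -> transition
    matched: dict      # gene -> bool (significant genes only)
    matched_changes: int
    total_weighted_agreement: float
    control_flux: FluxDistribution
    case_flux: FluxDistribution

    def write_gene_states_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("gene\tstate_control\tstate_case\tdesired_transition\tmatched\n")
            for g in sorted(self.gene_states):
                s0, s1 = self.gene_states[g]
                fh.write(f"{g}\t{s0}\t{s1}\t{self.desired.get(g, CONSTANT)}"
                         f"\t{self.matched.get(g, '')}\n")


def desired_transitions(stats, alpha, genes=None):
    """Per-gene desired transition and weight w = 1 - p."""
    desired, weights = {}, {}
    table = stats.table
    for g in (genes if genes is not None else table.index):
        if g not in table.index:
            desired[g], weights[g] = CONSTANT, 0.0
            continue
        fc = table.at[g, "fold_change"]
        p = table.at[g, "p_value"]
        if p < alpha and fc > 1:
            desired[g] = INCREASE
        elif p < alpha and fc < 1:
            desired[g] = DECREASE
        else:
            desired[g] = CONSTANT
        weights[g] = 1.0 - float(p)
    return desired, weights


class _Milp:
    """Incrementally assembled sparse MILP (rows of A with lo <= A x <= hi)."""

    def __init__(self):
        self.ncols = 0
        self.c = []
        self.lb = []
        self.ub = []
        self.integrality = []
        self.rows = []  # (coeff dict, lo, hi)

    def var(self, lo, hi, integer=False, cost=0.0):
        j = self.ncols
        self.ncols += 1
        self.c.append(cost)
        self.lb.append(lo)
        self.ub.append(hi)
        self.integrality.append(1 if integer else 0)
        return j

    def row(self, coeffs, lo, hi):
        self.rows.append((coeffs, lo, hi))

    def solve(self):
        data, ri, ci = [], [], []
        lo = np.empty(len(self.rows))
        hi = np.empty(len(self.rows))
        for i, (coeffs, l, h) in enumerate(self.rows):
            lo[i], hi[i] = l, h
            for j, a in coeffs.items():
                ri.append(i)
                ci.append(j)
                data.append(a)
        A = sp.csr_matrix((data, (ri, ci)), shape=(len(self.rows), self.ncols))
        res = milp(
            c=np.array(self.c),
            constraints=LinearConstraint(A, lo, hi),
            bounds=Bounds(np.array(self.lb), np.array(self.ub)),
            integrality=np.array(self.integrality),
            options={"mip_rel_gap": 0.0},
        )
        return res


def _gpr_indicator(m, tree, gene_var):
    """Binary variable equal to the boolean value of the GPR subtree."""
    if tree.node == "GENE":
        return gene_var[tree.gene_id]
    kids = [_gpr_indicator(m, c, gene_var) for c in tree.children]
    y = m.var(0, 1, integer=True)
    n = len(kids)
    if tree.node == "AND":
        for k in kids:
            m.row({y: 1.0, k: -1.0}, -np.inf, 0.0)          # y <= k
        m.row({y: 1.0, **{k: -1.0 for k in kids}}, 1 - n, np.inf)  # y >= sum-(n-1)
    else:  # OR
        for k in kids:
            m.row({y: 1.0, k: -1.0}, 0.0, np.inf)           # y >= k
        m.row({y: 1.0, **{k: -1.0 for k in kids}}, -np.inf, 0.0)   # y <= sum
    return y


def made_two_condition(net, stats, alpha=0.05, functionality_id=None,
                       fraction=0.3, post_norm=False,
                       settings=SolverSettings()):
    """Two-condition MADE; returns gene states and both flux distributions.

    ``fraction`` is the functionality fraction each condition's model must
    retain relative to the unconstrained FBA optimum.  ``post_norm=True``
    additionally applies the Euclidean-norm secondary objective to each
    condition's flux at its achieved growth (off reactions held closed) —
    off by default because MADE's native output is the MILP flux itself.
    """
    functionality_id = functionality_id or net.objective_reaction
    if functionality_id is None:
        raise MadeError("no functionality reaction given")
    if not 0 < alpha < 1:
        raise MadeError("alpha must be in (0, 1)")
    model_genes = sorted(net.genes)
    covered = [g for g in model_genes if g in set(stats.genes)]
    if not covered:
        raise MadeError("statistics cover no model gene")
    desired, weights = desired_transitions(stats, alpha, model_genes)

    base = fba(net, functionality_id, settings=settings)
    if base.status != OPTIMAL:
        raise MadeError("functionality infeasible on the full network")
    required = fraction * base.objective_value

    m = _Milp()
    n = len(net.reactions)
    lb, ub = net.bounds_arrays()
    S = net.stoichiometric_matrix().tocoo()
    cm = net.coupling_matrix()

    v_vars, gene_vars = [], []
    for cond in range(2):
        v = [m.var(lb[j], ub[j]) for j in range(n)]
        v_vars.append(v)
        gv = {g: m.var(0, 1, integer=True) for g in model_genes}
        gene_vars.append(gv)
        met_rows = {}
        for i, j, a in zip(S.row, S.col, S.data):
            met_rows.setdefault(i, {})[v[j]] = a
        for coeffs in met_rows.values():
            m.row(coeffs, 0.0, 0.0)
        if cm is not None:
            A, lo, hi = cm
            for i in range(A.shape[0]):
                coeffs = {v[j]: A[i, j] for j in range(n) if A[i, j] != 0}
                m.row(coeffs, lo[i], hi[i])
        jf = net.reaction_index(functionality_id)
        m.row({v[jf]: 1.0}, required, np.inf)
        for j, r in enumerate(net.reactions):
            if r.gpr is None:
                continue
            y = _gpr_indicator(m, r.gpr, gv)
            # off reaction carries no flux: lb*y <= v <= ub*y
            m.row({v[j]: 1.0, y: -ub[j]}, -np.inf, 0.0)
            m.row({v[j]: 1.0, y: -lb[j]}, 0.0, np.inf)

    # Significant genes enter the primary objective (weight 1 - p); genes with
    # no significant change are handled by the flip-minimizing tie-break alone,
    # which keeps them constant whenever feasible.  This keeps the agreement
    # score monotone under tightening alpha: shrinking the significant set can
    # only drop non-negative terms from the objective.
    match_vars, flip_vars = {}, {}
    for g in model_genes:
        x0, x1 = gene_vars[0][g], gene_vars[1][g]
        d = m.var(0, 1, cost=TIE_BREAK_EPS)  # d >= |x1 - x0| (minimized)
        m.row({d: 1.0, x1: -1.0, x0: 1.0}, 0.0, np.inf)
        m.row({d: 1.0, x0: -1.0, x1: 1.0}, 0.0, np.inf)
        flip_vars[g] = d
        if desired[g] == CONSTANT:
            continue
        mv = m.var(0, 1, cost=-weights[g])  # maximize weighted agreement
        if desired[g] == INCREASE:       # matched iff x0=0 and x1=1
            m.row({mv: 1.0, x1: -1.0}, -np.inf, 0.0)
            m.row({mv: 1.0, x0: 1.0}, -np.inf, 1.0)
        else:                            # matched iff x0=1 and x1=0
            m.row({mv: 1.0, x0: -1.0}, -np.inf, 0.0)
            m.row({mv: 1.0, x1: 1.0}, -np.inf, 1.0)
        match_vars[g] = mv

    res = m.solve()
    if res.status == 2 or (res.status != 0 and res.x is None):
        raise MadeError(
            "MADE MILP infeasible — the functionality constraint "
            f"v_{functionality_id} >= {required:.6g} cannot be met"
        )
    if res.x is None:
        raise SolverError(f"MILP solver failure: {res.message}")
    x = res.x

    gene_states = {g: (int(round(x[gene_vars[0][g]])),
                       int(round(x[gene_vars[1][g]])))
                   for g in model_genes}
    matched = {g: bool(round(x[match_vars[g]])) for g in match_vars}
    agreement = float(sum(weights[g] * x[mv] for g, mv in match_vars.items()))
    n_matched = sum(matched.values())

    fluxes = []
    for cond in range(2):
        vd = {r.id: float(x[v_vars[cond][j]])
              for j, r in enumerate(net.reactions)}
        fd = FluxDistribution(fluxes=vd,
                              objective_value=vd[functionality_id],
                              status=OPTIMAL)
        if post_norm:
            fd = _post_norm(net, gene_states, cond, fd, functionality_id, settings)
        fluxes.append(fd)
    if all(s0 == s1 for s0, s1 in gene_states.values()):
        # identical gene states mean identical condition models; report one
        # representative flux vector for both
        fluxes[1] = fluxes[0]

    return MadeResult(
        gene_states=gene_states, desired=desired, matched=matched,
        matched_changes=int(n_matched), total_weighted_agreement=agreement,
        control_flux=fluxes[0], case_flux=fluxes[1],
    )


def _post_norm(net, gene_states, cond, fd, functionality_id, settings):
    """Optional norm-minimization at the achieved growth, off reactions closed."""
    states = {g: s[cond] for g, s in gene_states.items()}
    extra = {}
    for r in net.reactions:
        if r.gpr is not None and r.gpr.evaluate(states, missing=1) == 0:
            extra[r.id] = (0.0, 0.0)
    try:
        return min_norm_fluxes(net, functionality_id, fd.objective_value,
                               extra_bounds=extra, settings=settings)
    except SolverError:
        return fd
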