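"""GIMME: context-specific model extraction from binarized expression.

GIMME removes reactions whose genes fall below the expression threshold, but
adds a removed reaction back whenever the model would otherwise fail to
achieve a required metabolic functionality (here: biomass growth at a stated
fraction of its optimum).  Both steps are realized by a single LP: flux
through below-threshold ("state 0") reactions is penalized subject to steady
state, bounds, and the functionality constraint; state-0 reactions whose
penalized flux is zero are removed, the rest are logged as added back.  The
LP objective value is the inconsistency score between data and function.

Reversible reactions are split into two non-negative variables inside the LP
so that |v| is linear; the network itself keeps signed variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .constraints import apply_constraint_set
from .expression import (
    GBM_MARKER_GENES,
    UNMAPPED,
    binarize,
    compute_threshold,
    reaction_states,
    validate_threshold,
)
from .network import MetabolicNetwork
from .optimize import OPTIMAL, SolverError, SolverSettings, dual_objective_fba, fba

ZERO_FLUX_TOL = 1e-9


class GimmeError(RuntimeError):
    pass


@dataclass
class ContextModel:
    """A pruned context-specific network plus its extraction ledger."""

    network: MetabolicNetwork
    removed_reactions: list = field(default_factory=list)
    added_back: list = field(default_factory=list)
    inconsistency_score: float = 0.0
    rmf_fraction: float = 0.9
    threshold: float = float("nan")

    def removal_ledger_rows(self, states, weights):
        rows = []
        for rid in self.removed_reactions:
            rows.append((rid, 0, weights.get(rid, 1.0), "removed",
                         "below threshold, zero flux in penalized optimum"))
        for rid in self.added_back:
            rows.append((rid, 0, weights.get(rid, 1.0), "kept",
                         "added back: required for functionality"))
        return rows

    def write_removal_ledger(self, path, states=None, weights=None):
        with open(path, "w") as fh:
            fh.write("reaction_id\tstate\tpenalty\tdecision\treason\n")
            for row in self.removal_ledger_rows(states or {}, weights or {}):
                fh.write("\t".join(str(x) for x in row) + "\n")


def gimme(net, rxn_states, rxn_weights=None, functionality_id=None,
          rmf_fraction=0.9, settings=SolverSettings()):
    """Run GIMME on a network with precomputed reaction states.

    ``rxn_states`` maps reaction id to 0, 1 or "unmapped"; only state-0
    reactions are penalized (uniform weight 1 by default — binarized data
    carries no graded distance from the threshold).  The pruned model is
    guaranteed to attain at least ``rmf_fraction`` times the original optimum
    of the functionality reaction.
    """
    functionality_id = functionality_id or net.objective_reaction
    if functionality_id is None:
        raise GimmeError("no functionality reaction given")
    base = fba(net, functionality_id, settings=settings)
    if base.status != OPTIMAL or base.objective_value <= ZERO_FLUX_TOL:
        raise GimmeError("required functionality blocked (optimum is zero "
                         "or infeasible) — GIMME needs a growing model")
    required = rmf_fraction * base.objective_value

    penalized = [rid for rid, s in rxn_states.items()
                 if s == 0 and net.has_reaction(rid)]
    weights = {rid: 1.0 for rid in penalized}
    if rxn_weights:
        weights.update({k: v for k, v in rxn_weights.items() if k in weights})

    v = _penalized_lp(net, weights, functionality_id, required)

    removed, added_back = [], []
    for rid in penalized:
        if abs(v[rid]) < ZERO_FLUX_TOL:
            removed.append(rid)
        else:
            added_back.append(rid)
    score = sum(weights[rid] * abs(v[rid]) for rid in penalized)

    pruned = net.copy()
    pruned.remove_reactions(removed)
    verify = fba(pruned, functionality_id, settings=settings)
    if verify.status != OPTIMAL or verify.objective_value < required - 1e-6:
        raise GimmeError(
            "pruned model fails to attain the functionality bound "
            f"({verify.objective_value} < {required})"
        )
    return ContextModel(
        network=pruned, removed_reactions=sorted(removed),
        added_back=sorted(added_back), inconsistency_score=float(score),
        rmf_fraction=rmf_fraction,
    )


def _penalized_lp(net, weights, functionality_id, required):
    """min sum w_i |v_i| s.t. S v = 0, bounds, coupling, v_func >= required.

    Solved with reversible reactions split into forward/backward parts.
    """
    n = len(net.reactions)
    lb, ub = net.bounds_arrays()
    S = net.stoichiometric_matrix()
    # v = p - m with p in [max(0,lb), max(0,ub)], m in [max(0,-ub), max(0,-lb)]
    p_lo, p_hi = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    m_lo, m_hi = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    A_eq_rows = [sp.hstack([S, -S])]
    b_eq = [np.zeros(S.shape[0])]
    A_ub_rows, b_ub = [], []
    cm = net.coupling_matrix()
    if cm is not None:
        A, lo, hi = cm
        Afull = np.hstack([A, -A])
        eq = np.isclose(lo, hi)
        if eq.any():
            A_eq_rows.append(sp.csr_matrix(Afull[eq]))
            b_eq.append(lo[eq])
        if (~eq).any():
            A_ub_rows.append(np.vstack([Afull[~eq], -Afull[~eq]]))
            b_ub.append(np.concatenate([hi[~eq], -lo[~eq]]))
    jf = net.reaction_index(functionality_id)
    row = np.zeros(2 * n)
    row[jf], row[n + jf] = -1.0, 1.0  # -(p - m) <= -required
    A_ub_rows.append(row.reshape(1, -1))
    b_ub.append(np.array([-required]))

    c = np.zeros(2 * n)
    for rid, w in weights.items():
        j = net.reaction_index(rid)
        c[j] += w
        c[n + j] += w
    res = linprog(
        c,
        A_eq=sp.vstack(A_eq_rows, format="csr"),
        b_eq=np.concatenate(b_eq),
        A_ub=np.vstack(A_ub_rows) if A_ub_rows else None,
        b_ub=np.concatenate(b_ub) if b_ub else None,
        bounds=np.column_stack([
            np.concatenate([p_lo, m_lo]), np.concatenate([p_hi, m_hi]),
        ]),
        method="highs",
    )
    if res.status == 2:
        raise GimmeError("GIMME LP infeasible")
    if res.status != 0:
        raise SolverError(f"GIMME LP failed: {res.message}")
    v = res.x[:n] - res.x[n:]
    return {r.id: float(v[j]) for j, r in enumerate(net.reactions)}


@dataclass
class GimmePipelineResult:
    context: ContextModel
    flux: "FluxDistribution"
    threshold: float
    states: dict
    reaction_state_map: dict


def gimme_pipeline(net, expr, fraction, markers=GBM_MARKER_GENES,
                   constraints=None, rmf_fraction=0.9,
                   missing_policy="expressed", settings=SolverSettings()):
    """Full GIMME path: threshold -> binarize -> reaction states -> GIMME ->
    flux-phase constraints -> dual-objective FBA on the pruned model.

    Expression is first restricted to genes present in the model (the
    threshold is a fraction of the mean over model-mappable genes); the
    threshold is validated against the GBM marker panel before use.
    """
    model_expr = expr.subset(net.genes)
    if not model_expr.genes:
        model_expr = expr
    threshold = compute_threshold(model_expr, fraction)
    report = validate_threshold(model_expr, threshold, markers)
    if not report.valid:
        raise GimmeError(
            "threshold exceeds expression of GBM marker genes: "
            + ", ".join(report.offending)
        )
    states = binarize(model_expr, threshold)
    gimme_net = (apply_constraint_set(net, constraints, "gimme")
                 if constraints is not None else net)
    rs = reaction_states(gimme_net, states, missing_policy)
    ctx = gimme(gimme_net, rs, functionality_id=gimme_net.objective_reaction,
                rmf_fraction=rmf_fraction, settings=settings)
    ctx.threshold = threshold
    flux_net = (apply_constraint_set(ctx.network, constraints, "flux")
                if constraints is not None else ctx.network)
    fd = dual_objective_fba(flux_net, settings=settings)
    if fd.status != OPTIMAL:
        raise GimmeError(f"flux-phase FBA {fd.status} on the pruned model")
    return GimmePipelineResult(context=ctx, flux=fd, threshold=threshold,
                               states=states.states, reaction_state_map=rs)
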