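"""Uniform sampling of the growth-constrained flux polytope.

Instead of a single optimal flux vector, the steady-state solution space
with growth restricted to a band — between a fraction of the optimum
(default 80%) and the optimum itself — is characterized by uniform samples.
The polytope {v : S v = 0, coupling rows, lb <= v <= ub, growth in band} is
parameterized on a null-space basis of the equality system (bound-fixed
variables are pinned by extra rows, so every basis direction is genuinely
free), and explored by coordinate hit-and-run: at each step a random basis
coordinate defines a chord through the current point, and the next point is
drawn uniformly from the feasible segment of that chord.

Runs are deterministic for a fixed seed.  A split-chain ratio (first half
vs second half of the chain, pooled vs within variance) is reported per
reaction as a convergence diagnostic; it is reported, not enforced.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .optimize import OPTIMAL, SolverError, dual_objective_fba, fba


class SamplerError(RuntimeError):
    pass


@dataclass
class FluxSample:
    points: np.ndarray            # n_samples x n_reactions
    reaction_ids: list
    growth_band: tuple
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def mean(self):
        return dict(zip(self.reaction_ids, self.points.mean(axis=0)))

    def sd(self):
        return dict(zip(self.reaction_ids, self.points.std(axis=0, ddof=1)))

    def column(self, rxn_id):
        return self.points[:, self.reaction_ids.index(rxn_id)]

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("\t".join(self.reaction_ids) + "\n")
            np.savetxt(fh, self.points, delimiter="\t", fmt="%.10g")

    def write_diagnostics(self, path):
        with open(path, "w") as fh:
            json.dump(self.diagnostics, fh, indent=1)


def sample_fluxes(net, growth_fraction_low=0.8, n_samples=1000, seed=0,
                  thinning=100, warmup=100, objective_id=None):
    """Coordinate hit-and-run over the growth-banded flux polytope.

    The chain starts from the dual-objective FBA solution (warm start on the
    optimal face) and records every ``thinning``-th step after ``warmup``
    discarded recorded points' worth of steps.  Identical seeds give
    identical output.
    """
    objective_id = objective_id or net.objective_reaction
    opt = fba(net, objective_id)
    if opt.status != OPTIMAL:
        raise SamplerError(f"network {opt.status}; cannot sample")
    if opt.objective_value <= 0:
        raise SamplerError("growth optimum is zero; the band is degenerate")
    band = (growth_fraction_low * opt.objective_value, opt.objective_value)

    n = len(net.reactions)
    lb, ub = net.bounds_arrays()
    j_obj = net.reaction_index(objective_id)
    lb[j_obj] = max(lb[j_obj], band[0])
    ub[j_obj] = min(ub[j_obj], band[1] + 1e-9)

    start = dual_objective_fba(net, objective_id)
    v0 = np.array([start.fluxes[r.id] for r in net.reactions])
    v0 = np.clip(v0, lb, ub)

    A = net.stoichiometric_matrix().toarray()
    cm = net.coupling_matrix()
    if cm is not None:
        Ac, lo, hi = cm
        eq = np.isclose(lo, hi)
        if not eq.all():
            raise SamplerError("ranged coupling rows are not supported here")
        A = np.vstack([A, Ac])
    # pin bound-fixed variables so null-space directions are all free
    fixed = np.isclose(lb, ub, atol=1e-12)
    if fixed.any():
        E = np.zeros((int(fixed.sum()), n))
        for k, j in enumerate(np.where(fixed)[0]):
            E[k, j] = 1.0
            v0[j] = lb[j]
        A = np.vstack([A, E])
    N = null_space(A)
    ids = [r.id for r in net.reactions]

    if N.shape[1] == 0:
        warnings.warn("polytope is a single point; returning it", stacklevel=2)
        pts = v0.reshape(1, -1)
        return FluxSample(points=pts, reaction_ids=ids, growth_band=band,
                          seed=seed, diagnostics=_diagnostics(pts, ids))

    rng = np.random.default_rng(seed)
    v = v0.copy()
    pts = np.empty((n_samples, n))
    k = N.shape[1]
    total_steps = (n_samples + warmup) * thinning
    recorded = 0
    step = 0
    eps = 1e-12
    while recorded < n_samples and step < total_steps + n_samples * thinning:
        d = N[:, rng.integers(k)]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = np.where(d > eps, (lb - v) / d,
                            np.where(d < -eps, (ub - v) / d, -np.inf))
            t_hi = np.where(d > eps, (ub - v) / d,
                            np.where(d < -eps, (lb - v) / d, np.inf))
        tmin = np.max(t_lo)
        tmax = np.min(t_hi)
        step += 1
        if tmax - tmin > eps:
            v = v + rng.uniform(tmin, tmax) * d
            v = np.clip(v, lb, ub)
        if step % thinning == 0:
            if step // thinning > warmup:
                pts[recorded] = v
                recorded += 1
    if recorded < n_samples:
        pts = pts[:recorded]
    return FluxSample(points=pts, reaction_ids=ids, growth_band=band,
                      seed=seed, diagnostics=_diagnostics(pts, ids))


def _diagnostics(points, ids, threshold=1.1):
    """Per-reaction mean/sd and split-chain convergence ratio.

    The ratio compares pooled variance of two half-chains against the mean
    within-half variance (a two-chain potential-scale-reduction analogue);
    values near 1 indicate a stationary chain.
    """
    m = points.shape[0]
    out = {"n_samples": int(m), "per_reaction": {}, "max_split_chain_ratio": None,
           "split_chain_threshold": threshold}
    if m < 4:
        return out
    half = m // 2
    a, b = points[:half], points[half:2 * half]
    ratios = []
    for j, rid in enumerate(ids):
        mu, sd = float(points[:, j].mean()), float(points[:, j].std(ddof=1))
        wa, wb = a[:, j].var(ddof=1), b[:, j].var(ddof=1)
        W = 0.5 * (wa + wb)
        B = half * ((a[:, j].mean() - mu) ** 2 + (b[:, j].mean() - mu) ** 2)
        if W > 1e-16:
            r = float(np.sqrt((W * (half - 1) / half + B / half) / W))
        else:
            r = 1.0
        ratios.append(r)
        out["per_reaction"][rid] = {"mean": mu, "sd": sd, "split_chain_ratio": r}
    out["max_split_chain_ratio"] = float(max(ratios))
    return out
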