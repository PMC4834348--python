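"""Data model for multi-cell-type metabolic networks.

A :class:`MetabolicNetwork` holds metabolites, reactions with bounds and
gene-protein-reaction (GPR) rules, and assembles the stoichiometric matrix S
used by every solver in the package.  Networks describe metabolism *in and
between* two brain cell types (astrocytes and neurons) plus an extracellular
compartment, following the layout of two-cell-type brain reconstructions.

Sign convention for exchange reactions: uptake is a negative flux, secretion a
positive flux.  Reversible reactions are kept as single signed variables;
splitting into forward/backward parts happens only inside the GIMME LP.
"""

from __future__ import annotations

import copy as _copy
import json
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

COMPARTMENTS = ("astrocyte", "neuron", "extracellular")
CELL_TYPES = ("astrocyte", "neuron", "exchange", "inter-cell")

#: default bounds applied when an SBML file does not declare any
DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)
DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)


class NetworkError(ValueError):
    """Raised when a network invariant is violated."""


class GPRSyntaxError(ValueError):
    """Raised on malformed GPR rules; carries the offending position."""

    def __init__(self, message, position):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRTree:
    """Boolean gene-protein-reaction rule.

    ``AND`` encodes complex subunits (all genes required), ``OR`` isozymes
    (any gene suffices).  Evaluation uses AND=min / OR=max so that the same
    tree works for 0/1 states and for graded expression values.
    """

    node: str  # "GENE" | "AND" | "OR"
    gene_id: str = ""
    children: tuple = ()

    def __post_init__(self):
        if self.node == "GENE":
            if not self.gene_id or self.children:
                raise NetworkError("GENE nodes carry a gene_id and no children")
        elif self.node in ("AND", "OR"):
            if len(self.children) < 2:
                raise NetworkError(f"{self.node} nodes need >=2 children")
        else:
            raise NetworkError(f"unknown GPR node type {self.node!r}")

    def genes(self):
        """Set of all gene ids referenced by the rule."""
        if self.node == "GENE":
            return {self.gene_id}
        out = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, states, missing=1):
        """Evaluate with AND=min, OR=max.

        ``states`` maps gene id to a value; genes absent from the mapping get
        ``missing`` (default 1: absence of evidence keeps a reaction).
        """
        if self.node == "GENE":
            return states.get(self.gene_id, missing)
        vals = [c.evaluate(states, missing) for c in self.children]
        return min(vals) if self.node == "AND" else max(vals)

    def to_string(self):
        if self.node == "GENE":
            return self.gene_id
        sep = f" {self.node.lower()} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.node != "GENE":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-:]+)")


def _tokenize(rule):
    tokens, pos = [], 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if not m:
            raise GPRSyntaxError(f"unexpected character {rule[pos]!r}", pos)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule):
    """Parse a GPR string like ``"(g1 and g2) or g3"`` into a :class:`GPRTree`.

    Keywords ``and``/``or`` are case-insensitive; anything else alphanumeric is
    a gene symbol.  Returns ``None`` for an empty rule.
    """
    if rule is None or not rule.strip():
        return None
    tokens = _tokenize(rule)
    tree, idx = _parse_or(tokens, 0)
    if idx != len(tokens):
        raise GPRSyntaxError(f"dangling token {tokens[idx][0]!r}", tokens[idx][1])
    return tree


def _flatten(op, children):
    flat = []
    for c in children:
        if c.node == op:
            flat.extend(c.children)
        else:
            flat.append(c)
    if len(flat) == 1:
        return flat[0]
    return GPRTree(op, children=tuple(flat))


def _parse_or(tokens, idx):
    left, idx = _parse_and(tokens, idx)
    parts = [left]
    while idx < len(tokens) and tokens[idx][0].lower() == "or":
        nxt, idx = _parse_and(tokens, idx + 1)
        parts.append(nxt)
    return _flatten("OR", parts), idx


def _parse_and(tokens, idx):
    left, idx = _parse_atom(tokens, idx)
    parts = [left]
    while idx < len(tokens) and tokens[idx][0].lower() == "and":
        nxt, idx = _parse_atom(tokens, idx + 1)
        parts.append(nxt)
    return _flatten("AND", parts), idx


def _parse_atom(tokens, idx):
    if idx >= len(tokens):
        pos = tokens[-1][1] if tokens else 0
        raise GPRSyntaxError("dangling operator", pos)
    tok, pos = tokens[idx]
    if tok == "(":
        tree, idx = _parse_or(tokens, idx + 1)
        if idx >= len(tokens) or tokens[idx][0] != ")":
            raise GPRSyntaxError("unbalanced parentheses", pos)
        return tree, idx + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GPRSyntaxError(f"unexpected token {tok!r}", pos)
    return GPRTree("GENE", gene_id=tok), idx + 1


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "extracellular"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise NetworkError(
                f"metabolite {self.id}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )


@dataclass
class Reaction:
    """A reaction with signed stoichiometry over metabolite ids.

    Flux units are mmol/gDW/h (the growth drain is in 1/h).  ``cell_type``
    tags where the reaction operates; ``is_exchange`` marks boundary reactions
    (exactly one non-zero stoichiometric entry, uptake negative).
    """

    id: str
    stoichiometry: dict = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GPRTree | None = None
    subsystem: str = ""
    cell_type: str = "astrocyte"
    is_exchange: bool = False

    def validate(self):
        if self.lower_bound > self.upper_bound:
            raise NetworkError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id}: empty stoichiometry")
        nz = [c for c in self.stoichiometry.values() if c != 0]
        if self.is_exchange and len(nz) != 1:
            raise NetworkError(
                f"exchange reaction {self.id} must have exactly one non-zero "
                f"stoichiometric entry, has {len(nz)}"
            )
        if self.cell_type not in CELL_TYPES:
            raise NetworkError(
                f"reaction {self.id}: cell_type {self.cell_type!r} not in {CELL_TYPES}"
            )

    @property
    def reversible(self):
        return self.lower_bound < 0

    def genes(self):
        return self.gpr.genes() if self.gpr is not None else set()


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class CouplingConstraint:
    """Extra linear row over fluxes: lb <= sum(coeff_r * v_r) <= ub.

    Used for ratio constraints between cell types (e.g. 94/6 uptake coupling)
    without touching the stoichiometric entries of exchange reactions.
    """

    name: str
    coefficients: dict
    lb: float = 0.0
    ub: float = 0.0


class MetabolicNetwork:
    """Container for metabolites, reactions and optional coupling rows."""

    def __init__(self, id="network", metabolites=(), reactions=(),
                 objective_reaction=None, coupling_constraints=()):
        self.id = id
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self.coupling_constraints: list[CouplingConstraint] = list(coupling_constraints)
        self.objective_reaction = objective_reaction
        self._met_index: dict[str, int] = {}
        self._rxn_index: dict[str, int] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction ------------------------------------------------------

    def add_metabolite(self, met):
        if met.id in self._met_index:
            raise NetworkError(f"duplicate metabolite id {met.id!r}")
        self._met_index[met.id] = len(self.metabolites)
        self.metabolites.append(met)

    def add_reaction(self, rxn):
        if rxn.id in self._rxn_index:
            raise NetworkError(f"duplicate reaction id {rxn.id!r}")
        rxn.validate()
        missing = [m for m in rxn.stoichiometry if m not in self._met_index]
        if missing:
            raise NetworkError(
                f"reaction {rxn.id}: unknown metabolites {sorted(missing)}"
            )
        self._rxn_index[rxn.id] = len(self.reactions)
        self.reactions.append(rxn)

    def remove_reactions(self, ids):
        drop = set(ids)
        unknown = drop - set(self._rxn_index)
        if unknown:
            raise NetworkError(f"cannot remove unknown reactions {sorted(unknown)}")
        self.reactions = [r for r in self.reactions if r.id not in drop]
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if self.objective_reaction in drop:
            self.objective_reaction = None

    def copy(self):
        return _copy.deepcopy(self)

    # -- lookups -----------------------------------------------------------

    @property
    def genes(self):
        out = set()
        for r in self.reactions:
            out |= r.genes()
        return out

    def reaction(self, rxn_id) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise NetworkError(f"unknown reaction {rxn_id!r}") from None

    def metabolite(self, met_id) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise NetworkError(f"unknown metabolite {met_id!r}") from None

    def has_reaction(self, rxn_id):
        return rxn_id in self._rxn_index

    def reaction_index(self, rxn_id):
        return self._rxn_index[rxn_id]

    @property
    def reaction_ids(self):
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self):
        return [m.id for m in self.metabolites]

    def exchange_ids(self):
        return [r.id for r in self.reactions if r.is_exchange]

    def internal_ids(self):
        """Non-exchange reactions: the set whose Euclidean norm is minimized."""
        return [r.id for r in self.reactions if not r.is_exchange]

    def validate(self):
        for r in self.reactions:
            r.validate()
        for cc in self.coupling_constraints:
            for rid in cc.coefficients:
                if rid not in self._rxn_index:
                    raise NetworkError(
                        f"coupling constraint {cc.name}: unknown reaction {rid!r}"
                    )

    # -- assembly ----------------------------------------------------------

    def stoichiometric_matrix(self, sparse=True):
        """S with one row per metabolite, one column per reaction."""
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                rows.append(self._met_index[met_id])
                cols.append(j)
                vals.append(float(coef))
        S = sp.coo_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        ).tocsr()
        return S if sparse else S.toarray()

    def bounds_arrays(self):
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def coupling_matrix(self):
        """(A, lb, ub) for the extra coupling rows, or None if there are none."""
        if not self.coupling_constraints:
            return None
        A = np.zeros((len(self.coupling_constraints), len(self.reactions)))
        lo = np.zeros(len(self.coupling_constraints))
        hi = np.zeros(len(self.coupling_constraints))
        for i, cc in enumerate(self.coupling_constraints):
            for rid, coef in cc.coefficients.items():
                A[i, self._rxn_index[rid]] = coef
            lo[i], hi[i] = cc.lb, cc.ub
        return A, lo, hi

    def set_coupling(self, cc: CouplingConstraint):
        """Add or replace (by name) a coupling row — keeps application idempotent."""
        self.coupling_constraints = [
            c for c in self.coupling_constraints if c.name != cc.name
        ]
        self.coupling_constraints.append(cc)

    # -- comparison --------------------------------------------------------

    def equal_under_canonical_ordering(self, other, tol=1e-9):
        """Structural equality ignoring declaration order."""
        if sorted(self.metabolite_ids) != sorted(other.metabolite_ids):
            return False
        if sorted(self.reaction_ids) != sorted(other.reaction_ids):
            return False
        for m in self.metabolites:
            if other.metabolite(m.id).compartment != m.compartment:
                return False
        for r in self.reactions:
            o = other.reaction(r.id)
            if abs(r.lower_bound - o.lower_bound) > tol:
                return False
            if abs(r.upper_bound - o.upper_bound) > tol:
                return False
            if set(r.stoichiometry) != set(o.stoichiometry):
                return False
            for k, v in r.stoichiometry.items():
                if abs(v - o.stoichiometry[k]) > tol:
                    return False
            g1 = r.gpr.to_string() if r.gpr else ""
            g2 = o.gpr.to_string() if o.gpr else ""
            if g1 != g2:
                return False
        return True


def stoichiometric_matrix(net, sparse=True):
    """Module-level alias for :meth:`MetabolicNetwork.stoichiometric_matrix`."""
    return net.stoichiometric_matrix(sparse=sparse)


def check_steady_state(net, fluxes, s_tol=1e-6, bound_tol=1e-9):
    """Verify |S v| <= s_tol and lb - bound_tol <= v <= ub + bound_tol.

    Returns (max |S v|, max bound violation); raises nothing — callers decide.
    """
    v = np.array([fluxes[r.id] for r in net.reactions], dtype=float)
    S = net.stoichiometric_matrix()
    resid = np.abs(S @ v).max() if len(net.metabolites) else 0.0
    lb, ub = net.bounds_arrays()
    bviol = max(float(np.max(lb - v, initial=0.0)), float(np.max(v - ub, initial=0.0)))
    return float(resid), bviol


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

def to_json_dict(net):
    return {
        "id": net.id,
        "objective_reaction": net.objective_reaction,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in net.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string() if r.gpr else "",
                "subsystem": r.subsystem,
                "cell_type": r.cell_type,
                "is_exchange": r.is_exchange,
            }
            for r in net.reactions
        ],
        "coupling_constraints": [
            {"name": c.name, "coefficients": dict(c.coefficients),
             "lb": c.lb, "ub": c.ub}
            for c in net.coupling_constraints
        ],
    }


def write_json(net, path):
    with open(path, "w") as fh:
        json.dump(to_json_dict(net), fh, indent=1, sort_keys=True)


def from_json_dict(d):
    net = MetabolicNetwork(id=d.get("id", "network"))
    for m in d["metabolites"]:
        net.add_metabolite(Metabolite(m["id"], m.get("name", ""), m["compartment"]))
    for r in d["reactions"]:
        net.add_reaction(Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            gpr=parse_gpr(r.get("gpr", "")),
            subsystem=r.get("subsystem", ""),
            cell_type=r.get("cell_type", "astrocyte"),
            is_exchange=bool(r.get("is_exchange", False)),
        ))
    for c in d.get("coupling_constraints", []):
        net.set_coupling(CouplingConstraint(
            c["name"], {k: float(v) for k, v in c["coefficients"].items()},
            float(c["lb"]), float(c["ub"]),
        ))
    net.objective_reaction = d.get("objective_reaction")
    return net


def read_json(path):
    with open(path) as fh:
        return from_json_dict(json.load(fh))


# ---------------------------------------------------------------------------
# SBML I/O (Level 3 + fbc v2 on write; L3/fbc and L2-with-notes on read)
# ---------------------------------------------------------------------------

_SBML_COMP = {"astrocyte": "a", "neuron": "n", "extracellular": "e"}
_SBML_COMP_INV = {v: k for k, v in _SBML_COMP.items()}


def _notes_string(rxn):
    body = (
        f"<p>SUBSYSTEM: {rxn.subsystem}</p>"
        f"<p>CELL_TYPE: {rxn.cell_type}</p>"
        f"<p>IS_EXCHANGE: {str(rxn.is_exchange).lower()}</p>"
    )
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


def write_sbml(net, path):
    """Write SBML Level 3 Version 1 with the fbc v2 package."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(re.sub(r"[^A-Za-z0-9_]", "_", net.id))
    mplug = model.getPlugin("fbc")
    mplug.setStrict(False)

    used_comps = {m.compartment for m in net.metabolites}
    for comp in COMPARTMENTS:
        if comp in used_comps:
            c = model.createCompartment()
            c.setId(_SBML_COMP[comp])
            c.setName(comp)
            c.setConstant(True)

    for m in net.metabolites:
        s = model.createSpecies()
        s.setId(m.id)
        s.setName(m.name or m.id)
        s.setCompartment(_SBML_COMP[m.compartment])
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    for g in sorted(net.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_gene_sid(g))
        gp.setLabel(g)

    bounds_seen = {}

    def bound_param(value):
        key = float(value)
        if key not in bounds_seen:
            p = model.createParameter()
            p.setId(f"fb_{len(bounds_seen)}")
            p.setValue(key)
            p.setConstant(True)
            bounds_seen[key] = p.getId()
        return bounds_seen[key]

    for r in net.reactions:
        rx = model.createReaction()
        rx.setId(r.id)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        rx.setNotes(_notes_string(r), True)
        for met_id, coef in r.stoichiometry.items():
            if coef < 0:
                sr = rx.createReactant()
            else:
                sr = rx.createProduct()
            sr.setSpecies(met_id)
            sr.setStoichiometry(abs(float(coef)))
            sr.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if r.gpr is not None:
            ga = rplug.createGeneProductAssociation()
            ga.setAssociation(_gpr_to_fbc_string(r.gpr), True)

    if net.objective_reaction:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(net.objective_reaction)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _gene_sid(gene):
    sid = re.sub(r"[^A-Za-z0-9_]", "_", gene)
    if not re.match(r"[A-Za-z_]", sid):
        sid = "G_" + sid
    return "gp_" + sid


def _gpr_to_fbc_string(tree):
    if tree.node == "GENE":
        return _gene_sid(tree.gene_id)
    sep = " and " if tree.node == "AND" else " or "
    return "(" + sep.join(_gpr_to_fbc_string(c) for c in tree.children) + ")"


def read_sbml(path):
    """Read SBML into a :class:`MetabolicNetwork`.

    Accepts Level 3 with fbc bounds/GPRs, or Level 2 with notes-encoded
    ``LOWER_BOUND``/``UPPER_BOUND``/``GENE_ASSOCIATION``.  Reactions lacking
    any declared bound get the documented defaults: [0, 1000] if declared
    irreversible, [-1000, 1000] if reversible.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise NetworkError(
                f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
            )
    model = doc.getModel()
    if model is None:
        raise NetworkError(f"no model found in {path}")

    comp_map = {}
    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        name = (c.getName() or "").lower()
        if name in COMPARTMENTS:
            comp_map[c.getId()] = name
        elif c.getId() in _SBML_COMP_INV:
            comp_map[c.getId()] = _SBML_COMP_INV[c.getId()]
        else:
            comp_map[c.getId()] = "extracellular"

    net = MetabolicNetwork(id=model.getId() or "network")
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        net.add_metabolite(Metabolite(
            s.getId(), s.getName() or s.getId(),
            comp_map.get(s.getCompartment(), "extracellular"),
        ))

    mplug = model.getPlugin("fbc")
    gene_labels = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    objective_rxn = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_rxn = obj.getFluxObjective(0).getReaction()

    params = {}
    for i in range(model.getNumParameters()):
        p = model.getParameter(i)
        params[p.getId()] = p.getValue()

    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        rid = rx.getId()
        if net.has_reaction(rid):
            raise NetworkError(f"duplicate reaction id {rid!r} in {path}")
        stoich = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}

        notes = rx.getNotesString() if rx.isSetNotes() else ""
        meta = dict(re.findall(r"<p>\s*([A-Z_]+)\s*:\s*(.*?)\s*</p>", notes))

        lb = ub = None
        rplug = rx.getPlugin("fbc")
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                pid = rplug.getLowerFluxBound()
                if pid not in params:
                    raise NetworkError(
                        f"reaction {rid}: unresolvable lower bound parameter {pid!r}"
                    )
                lb = params[pid]
            if rplug.isSetUpperFluxBound():
                pid = rplug.getUpperFluxBound()
                if pid not in params:
                    raise NetworkError(
                        f"reaction {rid}: unresolvable upper bound parameter {pid!r}"
                    )
                ub = params[pid]
        if lb is None and "LOWER_BOUND" in meta:
            lb = float(meta["LOWER_BOUND"])
        if ub is None and "UPPER_BOUND" in meta:
            ub = float(meta["UPPER_BOUND"])
        # L2 kinetic-law parameter style
        if (lb is None or ub is None) and rx.isSetKineticLaw():
            kl = rx.getKineticLaw()
            for j in range(kl.getNumParameters()):
                p = kl.getParameter(j)
                if p.getId() == "LOWER_BOUND" and lb is None:
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND" and ub is None:
                    ub = p.getValue()
        if lb is None or ub is None:
            dflt = (DEFAULT_REVERSIBLE_BOUNDS if rx.getReversible()
                    else DEFAULT_IRREVERSIBLE_BOUNDS)
            lb = dflt[0] if lb is None else lb
            ub = dflt[1] if ub is None else ub

        gpr = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            assoc = rplug.getGeneProductAssociation().getAssociation()
            gpr = _fbc_assoc_to_tree(assoc, gene_labels)
        elif "GENE_ASSOCIATION" in meta and meta["GENE_ASSOCIATION"]:
            gpr = parse_gpr(meta["GENE_ASSOCIATION"])

        nz = [c for c in stoich.values() if c != 0]
        is_exchange = meta.get("IS_EXCHANGE", "").lower() == "true" or (
            "IS_EXCHANGE" not in meta and len(nz) == 1
        )
        cell_type = meta.get("CELL_TYPE", "")
        if cell_type not in CELL_TYPES:
            cell_type = "exchange" if is_exchange else "astrocyte"

        net.add_reaction(Reaction(
            id=rid, stoichiometry=stoich, lower_bound=float(lb),
            upper_bound=float(ub), gpr=gpr,
            subsystem=meta.get("SUBSYSTEM", ""),
            cell_type=cell_type, is_exchange=is_exchange,
        ))

    net.objective_reaction = objective_rxn
    return net


def _fbc_assoc_to_tree(assoc, gene_labels):
    import libsbml

    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        gid = assoc.getGeneProduct()
        return GPRTree("GENE", gene_id=gene_labels.get(gid, gid))
    if isinstance(assoc, libsbml.FbcAnd):
        kids = [_fbc_assoc_to_tree(assoc.getAssociation(i), gene_labels)
                for i in range(assoc.getNumAssociations())]
        return _flatten("AND", kids)
    if isinstance(assoc, libsbml.FbcOr):
        kids = [_fbc_assoc_to_tree(assoc.getAssociation(i), gene_labels)
                for i in range(assoc.getNumAssociations())]
        return _flatten("OR", kids)
    raise NetworkError(f"unsupported GPR association node {type(assoc)}")
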