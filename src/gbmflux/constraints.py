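"""GBM physiological constraints.

Encodes the constraint protocol used to make a two-cell-type brain network
behave like glioblastoma tissue:

* reactions absent or silenced in GBM are closed (glutamine exchange from
  astrocyte to neuron, glutamine release, glycogen uptake, ketone-body
  metabolism);
* the NH3 exchange, uptake-only in healthy brain, is made reversible so
  ammonia can be released;
* glucose, glutamine and oxygen uptake are constrained by measured GBM flux
  values (0.852, 0.080 and 0.272 mmol/gDW/h), distributed between astrocyte
  and neuron as 94% / 6%;
* every amino-acid uptake other than glutamine is capped at one tenth of the
  glutamine uptake.

Constraints are applied in two phases.  In the *gimme* phase (model
extraction) only the 94/6 astrocyte/neuron ratio of the uptakes is imposed,
as a coupling row, with no absolute magnitudes.  In the *flux* phase (flux
computation) the per-cell magnitudes are set on the bounds; ``uptake_mode``
selects whether magnitudes are equalities ("fixed to the measured value",
the published protocol) or capacities (upper bounds on uptake).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .network import CouplingConstraint, MetabolicNetwork, NetworkError


class ConstraintError(ValueError):
    pass


@dataclass
class UptakeConstraint:
    """A substrate uptake split between the two cell types.

    ``astro_rxn``/``neuron_rxn`` are the per-cell uptake reactions;
    ``metabolite`` the extracellular species whose consumption is constrained
    (the magnitude refers to metabolite consumption in mmol/gDW/h, so
    reactions consuming the substrate with |stoichiometry| != 1 are scaled).
    """

    substrate: str
    astro_rxn: str
    neuron_rxn: str
    magnitude: float
    metabolite: str = ""


@dataclass
class ConstraintSet:
    zero_reactions: list = field(default_factory=list)
    reversibility_overrides: dict = field(default_factory=dict)  # rxn -> (lb, ub)
    fixed_uptakes: list = field(default_factory=list)  # list[UptakeConstraint]
    cell_split: dict = field(default_factory=lambda: {"astrocyte": 0.94,
                                                      "neuron": 0.06})
    amino_acid_cap_fraction: float = 0.1
    amino_acid_subsystem: str = "amino acid uptake"
    amino_acid_reactions: list = field(default_factory=list)  # explicit override
    uptake_mode: str = "equality"  # "equality" | "capacity"

    def validate(self):
        s = sum(self.cell_split.values())
        if abs(s - 1.0) > 1e-9:
            raise ConstraintError(f"cell split sums to {s}, expected 1")
        for up in self.fixed_uptakes:
            if up.magnitude < 0:
                raise ConstraintError(
                    f"uptake magnitude for {up.substrate} must be >= 0"
                )
        if self.uptake_mode not in ("equality", "capacity"):
            raise ConstraintError(f"unknown uptake_mode {self.uptake_mode!r}")

    def glutamine_magnitude(self):
        for up in self.fixed_uptakes:
            if up.substrate == "glutamine":
                return up.magnitude
        return None

    # -- YAML --------------------------------------------------------------

    def to_yaml(self, path):
        d = {
            "zero_reactions": list(self.zero_reactions),
            "reversibility_overrides": {
                k: list(v) for k, v in self.reversibility_overrides.items()
            },
            "fixed_uptakes": [
                {"substrate": u.substrate, "astro_rxn": u.astro_rxn,
                 "neuron_rxn": u.neuron_rxn, "magnitude": u.magnitude,
                 "metabolite": u.metabolite}
                for u in self.fixed_uptakes
            ],
            "cell_split": dict(self.cell_split),
            "amino_acid_cap_fraction": self.amino_acid_cap_fraction,
            "amino_acid_subsystem": self.amino_acid_subsystem,
            "amino_acid_reactions": list(self.amino_acid_reactions),
            "uptake_mode": self.uptake_mode,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            zero_reactions=d.get("zero_reactions", []),
            reversibility_overrides={
                k: tuple(v) for k, v in d.get("reversibility_overrides", {}).items()
            },
            fixed_uptakes=[UptakeConstraint(**u) for u in d.get("fixed_uptakes", [])],
            cell_split=d.get("cell_split", {"astrocyte": 0.94, "neuron": 0.06}),
            amino_acid_cap_fraction=float(d.get("amino_acid_cap_fraction", 0.1)),
            amino_acid_subsystem=d.get("amino_acid_subsystem", "amino acid uptake"),
            amino_acid_reactions=d.get("amino_acid_reactions", []),
            uptake_mode=d.get("uptake_mode", "equality"),
        )


#: measured GBM uptake rates, mmol/gDW/h
GBM_GLUCOSE_UPTAKE = 0.852
GBM_GLUTAMINE_UPTAKE = 0.080
GBM_OXYGEN_UPTAKE = 0.272


def default_gbm_constraints():
    """The published GBM constraint protocol on the full brain reconstruction.

    Reaction ids follow that reconstruction: r_95 (astrocyte-to-neuron
    glutamine exchange), r_580 (glutamine release), r_575 (glycogen uptake),
    r_608/r_609 (ketone-body metabolism) are closed; r_607 (NH3 exchange)
    becomes reversible; glucose enters through the per-cell exchanges
    r_596/r_597.  The per-cell glutamine and oxygen exchange ids are not part
    of the main-text protocol and must be supplied when applying this set to
    the full reconstruction.
    """
    return ConstraintSet(
        zero_reactions=["r_95", "r_580", "r_575", "r_608", "r_609"],
        reversibility_overrides={"r_607": (-1000.0, 1000.0)},
        fixed_uptakes=[
            UptakeConstraint("glucose", "r_596", "r_597", GBM_GLUCOSE_UPTAKE),
            UptakeConstraint("glutamine", "", "", GBM_GLUTAMINE_UPTAKE),
            UptakeConstraint("oxygen", "", "", GBM_OXYGEN_UPTAKE),
        ],
        cell_split={"astrocyte": 0.94, "neuron": 0.06},
        amino_acid_cap_fraction=0.1,
        uptake_mode="equality",
    )


def _uptake_direction(net, rxn_id, metabolite):
    """(+1, coef) if uptake is positive flux, (-1, coef) for exchange uptake."""
    rxn = net.reaction(rxn_id)
    met = metabolite
    if not met:
        # single-substrate reactions: use the unique consumed extracellular species
        consumed = [m for m, c in rxn.stoichiometry.items() if c < 0]
        if len(consumed) != 1:
            raise ConstraintError(
                f"cannot infer constrained metabolite for {rxn_id}; set "
                "UptakeConstraint.metabolite"
            )
        met = consumed[0]
    if met not in rxn.stoichiometry:
        raise ConstraintError(f"{rxn_id} does not involve {met}")
    coef = abs(rxn.stoichiometry[met])
    sign = -1.0 if rxn.is_exchange else 1.0
    return sign, coef


def apply_constraint_set(net: MetabolicNetwork, cs: ConstraintSet, phase):
    """Return a new network with the constraint set applied.

    ``phase="gimme"``: zeroed reactions, reversibility overrides and 94/6
    ratio coupling rows only.  ``phase="flux"``: additionally the per-cell
    uptake magnitudes and amino-acid caps.  Application is idempotent.
    """
    if phase not in ("gimme", "flux"):
        raise ConstraintError(f"unknown phase {phase!r}")
    cs.validate()
    out = net.copy()

    for rid in cs.zero_reactions:
        if not out.has_reaction(rid):
            raise NetworkError(f"constraint refers to unknown reaction {rid!r}")
        r = out.reaction(rid)
        r.lower_bound = 0.0
        r.upper_bound = 0.0
    for rid, (lo, hi) in cs.reversibility_overrides.items():
        if not out.has_reaction(rid):
            raise NetworkError(f"constraint refers to unknown reaction {rid!r}")
        r = out.reaction(rid)
        r.lower_bound = float(lo)
        r.upper_bound = float(hi)

    wa = cs.cell_split.get("astrocyte", 0.0)
    wn = cs.cell_split.get("neuron", 0.0)

    for up in cs.fixed_uptakes:
        if not up.astro_rxn or not up.neuron_rxn:
            continue  # ids not resolvable on this network; documented in the set
        for rid in (up.astro_rxn, up.neuron_rxn):
            if not out.has_reaction(rid):
                raise NetworkError(
                    f"uptake constraint {up.substrate}: unknown reaction {rid!r}"
                )
        if phase == "gimme":
            # ratio row: wn * v_astro - wa * v_neuron = 0
            out.set_coupling(CouplingConstraint(
                name=f"ratio_{up.substrate}",
                coefficients={up.astro_rxn: wn, up.neuron_rxn: -wa},
                lb=0.0, ub=0.0,
            ))
        else:
            for rid, w in ((up.astro_rxn, wa), (up.neuron_rxn, wn)):
                sign, coef = _uptake_direction(out, rid, up.metabolite)
                v = sign * w * up.magnitude / coef
                r = out.reaction(rid)
                if cs.uptake_mode == "equality":
                    r.lower_bound = r.upper_bound = v
                else:  # capacity: uptake magnitude bounded above, not forced
                    if sign < 0:
                        r.lower_bound, r.upper_bound = v, max(r.upper_bound, 0.0)
                    else:
                        r.lower_bound, r.upper_bound = 0.0, v

    if phase == "flux":
        _apply_amino_acid_caps(out, cs)
    out.validate()
    return out


def _apply_amino_acid_caps(net, cs):
    gln = cs.glutamine_magnitude()
    if gln is None or cs.amino_acid_cap_fraction <= 0:
        return
    targets = set(cs.amino_acid_reactions)
    if not targets and cs.amino_acid_subsystem:
        targets = {r.id for r in net.reactions
                   if r.subsystem == cs.amino_acid_subsystem}
    for rid in sorted(targets):
        r = net.reaction(rid)
        if r.cell_type == "astrocyte":
            share = cs.cell_split.get("astrocyte", 1.0)
        elif r.cell_type == "neuron":
            share = cs.cell_split.get("neuron", 1.0)
        else:
            share = 1.0
        cap = cs.amino_acid_cap_fraction * gln * share
        if r.is_exchange:
            r.lower_bound = -cap
            r.upper_bound = max(r.upper_bound, 0.0)
        else:
            r.lower_bound = 0.0
            r.upper_bound = cap
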