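"""Biomass growth reaction from macromolecular composition.

Tumour proliferation is modelled by a biomass pseudo-reaction draining
precursor metabolites in proportion to the macromolecular composition of the
parent tissue.  For glioblastoma the parent tissue is brain white matter:
54.9% lipid and 39.5% protein by mass, with the residual 5.6% assigned to a
configurable "other" pool (carbohydrate/nucleotide precursors by default).
Astrocytes and neurons contribute in proportion to their abundance in white
matter, 94% and 6%.

The stoichiometric coefficient of precursor p in cell c is

    cell_weight[c] * macro_fraction * sub_fraction / molar_mass   [mmol/g biomass]

so that the total consumed mass over the covered fractions is 1 g per g of
biomass.  The reaction produces one unit of a biomass pseudo-metabolite that
is drained by a growth exchange; the flux of that drain is the growth rate
in 1/h.  An optional ATP maintenance coefficient (mmol ATP per g biomass,
default 0) adds a growth-associated energy demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .network import MetabolicNetwork, Metabolite, NetworkError, Reaction

BIOMASS_METABOLITE = "biomass"
BIOMASS_REACTION = "BIOMASS"
GROWTH_EXCHANGE = "EX_biomass"


class BiomassError(ValueError):
    pass


@dataclass
class BiomassComposition:
    """Macromolecular composition of the growing tissue.

    ``macro_fractions``: mass fraction (g/g) per pool (lipid, protein, other).
    ``sub_fractions``: per pool, mass fractions of individual precursors within
    the pool (g/g of the pool; e.g. the amino-acid composition of the protein
    pool), each summing to 1.
    ``precursor_molar_masses``: g/mmol per precursor.
    ``cell_weights``: contribution of each cell type, summing to 1.
    ``atp_maintenance``: mmol ATP consumed per g biomass (default 0).
    """

    macro_fractions: dict = field(default_factory=dict)
    sub_fractions: dict = field(default_factory=dict)
    precursor_molar_masses: dict = field(default_factory=dict)
    cell_weights: dict = field(default_factory=dict)
    atp_maintenance: float = 0.0

    def validate(self):
        total = sum(self.macro_fractions.values())
        if total > 1 + 1e-9:
            raise BiomassError(f"macro fractions sum to {total} > 1")
        for pool, subs in self.sub_fractions.items():
            s = sum(subs.values())
            if abs(s - 1.0) > 1e-6:
                raise BiomassError(
                    f"sub-fractions of pool {pool!r} sum to {s}, expected 1"
                )
        wsum = sum(self.cell_weights.values())
        if abs(wsum - 1.0) > 1e-9:
            raise BiomassError(f"cell weights sum to {wsum}, expected 1")
        if self.atp_maintenance < 0:
            raise BiomassError("atp_maintenance must be >= 0")

    def precursor_fractions(self):
        """Flatten to precursor -> overall mass fraction of biomass (g/g)."""
        out = {}
        for pool, frac in self.macro_fractions.items():
            subs = self.sub_fractions.get(pool, {pool: 1.0})
            for precursor, sub in subs.items():
                out[precursor] = out.get(precursor, 0.0) + frac * sub
        return out

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            macro_fractions=d.get("macro_fractions", {}),
            sub_fractions=d.get("sub_fractions", {}),
            precursor_molar_masses=d.get("precursor_molar_masses", {}),
            cell_weights=d.get("cell_weights", {}),
            atp_maintenance=float(d.get("atp_maintenance", 0.0)),
        )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump({
                "macro_fractions": dict(self.macro_fractions),
                "sub_fractions": {k: dict(v) for k, v in self.sub_fractions.items()},
                "precursor_molar_masses": dict(self.precursor_molar_masses),
                "cell_weights": dict(self.cell_weights),
                "atp_maintenance": self.atp_maintenance,
            }, fh)


#: white-matter composition: lipid 54.9%, protein 39.5%, residual 5.6% "other"
WHITE_MATTER_MACRO_FRACTIONS = {"lipid": 0.549, "protein": 0.395, "other": 0.056}
#: glia/neuron abundance in white matter
WHITE_MATTER_CELL_WEIGHTS = {"astrocyte": 0.94, "neuron": 0.06}


def build_biomass_reaction(comp: BiomassComposition, precursor_map,
                           atp_map=None, reaction_id=BIOMASS_REACTION):
    """Assemble the biomass reaction.

    ``precursor_map`` maps precursor name -> {cell_type: metabolite_id}; every
    precursor with non-zero overall fraction must be mapped in every weighted
    cell type.  ``atp_map`` maps cell_type -> ATP metabolite id and is required
    only when ``atp_maintenance`` > 0.
    """
    comp.validate()
    fractions = comp.precursor_fractions()
    if not any(f > 0 for f in fractions.values()):
        raise BiomassError("all biomass fractions are zero (empty biomass)")
    stoich = {}
    for precursor, frac in fractions.items():
        if frac == 0:
            continue
        if precursor not in comp.precursor_molar_masses:
            raise BiomassError(f"no molar mass for precursor {precursor!r}")
        mm = comp.precursor_molar_masses[precursor]
        if mm <= 0:
            raise BiomassError(f"molar mass of {precursor!r} must be > 0")
        mapping = precursor_map.get(precursor, {})
        for cell, weight in comp.cell_weights.items():
            if weight == 0:
                continue
            if cell not in mapping:
                raise BiomassError(
                    f"precursor {precursor!r} has no mapped metabolite in "
                    f"cell type {cell!r}"
                )
            met = mapping[cell]
            stoich[met] = stoich.get(met, 0.0) - weight * frac / mm
    if comp.atp_maintenance > 0:
        if not atp_map:
            raise BiomassError("atp_maintenance > 0 requires an atp_map")
        for cell, weight in comp.cell_weights.items():
            if weight == 0:
                continue
            if cell not in atp_map:
                raise BiomassError(f"no ATP metabolite mapped for {cell!r}")
            met = atp_map[cell]
            stoich[met] = stoich.get(met, 0.0) - weight * comp.atp_maintenance
    stoich[BIOMASS_METABOLITE] = 1.0
    return Reaction(
        id=reaction_id, stoichiometry=stoich, lower_bound=0.0,
        upper_bound=1000.0, subsystem="biomass", cell_type="inter-cell",
    )


def covered_mass(comp: BiomassComposition, reaction: Reaction,
                 precursor_map):
    """Mass-conservation check: sum over precursor coefficients x molar mass.

    Returns total consumed precursor mass in g per g biomass (ATP maintenance
    excluded); equals the covered mass fraction to 1e-6 by construction.
    """
    met_to_mass = {}
    for precursor, mapping in precursor_map.items():
        for met in mapping.values():
            met_to_mass[met] = comp.precursor_molar_masses[precursor]
    total = 0.0
    for met, coef in reaction.stoichiometry.items():
        if met in met_to_mass and coef < 0:
            total += -coef * met_to_mass[met]
    return total


def attach_growth(net: MetabolicNetwork, bio: Reaction,
                  growth_id=GROWTH_EXCHANGE):
    """Attach a biomass reaction plus its growth drain; returns a new network.

    The growth exchange becomes the FBA objective (growth rate in 1/h).
    """
    if net.has_reaction(bio.id) or net.has_reaction(growth_id):
        raise NetworkError(
            f"biomass ids {bio.id!r}/{growth_id!r} collide with the network "
            "(already attached?)"
        )
    out = net.copy()
    if BIOMASS_METABOLITE not in out.metabolite_ids:
        out.add_metabolite(Metabolite(BIOMASS_METABOLITE, "biomass pseudo-metabolite",
                                      "extracellular"))
    out.add_reaction(bio)
    out.add_reaction(Reaction(
        id=growth_id, stoichiometry={BIOMASS_METABOLITE: -1.0},
        lower_bound=0.0, upper_bound=1000.0, subsystem="biomass",
        cell_type="exchange", is_exchange=True,
    ))
    out.objective_reaction = growth_id
    return out
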