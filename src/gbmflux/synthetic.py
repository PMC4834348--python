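"""Synthetic study system: a toy two-cell-type brain network and
subtype-structured expression matrices.

The toy network carries astrocytic and neuronal copies of the pathways that
dominate GBM metabolic rewiring — glycolysis, the lactate branch, the
pyruvate dehydrogenase / carboxylase split, a lumped TCA cycle with an
anaplerotic entry at alpha-ketoglutarate, oxidative and (implicitly, via a
reversible return) non-oxidative pentose phosphate flux, glutamine uptake
with glutaminolysis, a fatty-acid precursor drain, oxidative-phosphorylation
ATP production (with separate cytosolic and mitochondrial NADH pools so that
full oxidation is the oxygen-efficient route), and a biomass sink built from
white-matter composition.  Every reaction carries a GPR with a real gene
symbol, including the GBM marker panel (HK2, PKM2, GLS, ACLY, ACC, FASN),
so the expression pipeline runs unchanged on toy and real data.

The expression simulator draws log-normally perturbed intensities around a
baseline, with multiplicative mean shifts on pathway gene groups per sample
group — the structure of subtype-clustered microarray data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomass import (
    BiomassComposition,
    WHITE_MATTER_CELL_WEIGHTS,
    WHITE_MATTER_MACRO_FRACTIONS,
    attach_growth,
    build_biomass_reaction,
)
from .constraints import (
    GBM_GLUCOSE_UPTAKE,
    GBM_GLUTAMINE_UPTAKE,
    GBM_OXYGEN_UPTAKE,
    ConstraintSet,
    UptakeConstraint,
)
from .expression import ExpressionMatrix
from .network import MetabolicNetwork, Metabolite, Reaction, parse_gpr
from .report import ReactionGroup

CELLS = (("a", "astrocyte"), ("n", "neuron"))

#: pathway membership of the toy genes (shared between cell types)
TOY_GENE_GROUPS = {
    "glycolysis": ["HK2", "PKM2"],
    "lactate": ["LDHA"],
    "pdh": ["PDHA1"],
    "tca": ["CS", "OGDH"],
    "pyruvate_carboxylase": ["PC"],
    "malic_enzyme": ["ME1"],
    "oxphos": ["NDUFS1", "GPD2"],
    "ppp": ["G6PD", "TKT"],
    "glutaminolysis": ["GLS", "GLUD1"],
    "lipid": ["ACLY", "ACC", "FASN"],
}


@dataclass
class ToyNetworkParams:
    include_neuron: bool = True
    uptake_bounds: dict = field(default_factory=lambda: {
        # loose physiological capacities (mmol/gDW/h); the GBM constraint set
        # tightens these to the measured values
        "glucose": 10.0, "glutamine": 1.0, "oxygen": 5.0,
    })
    atp_per_glycolysis: int = 2   # ATP per glucose through glycolysis
    atp_per_tca: int = 1          # substrate-level ATP per TCA turn
    #: lumped ATP demand per g biomass (growth-associated plus tissue
    #: maintenance); large enough that proliferation is energy-limited,
    #: which is what makes oxidative vs glycolytic routing consequential
    atp_maintenance: float = 100.0

    def validate(self):
        for k, v in self.uptake_bounds.items():
            if v <= 0:
                raise ValueError(f"uptake bound {k} must be > 0")


#: precursor molar masses, g/mmol (palmitate-like lipid precursor, glutamate
#: as the amino-acid proxy, ribose-5-phosphate as the nucleotide/other pool)
TOY_MOLAR_MASSES = {"lipid": 0.256, "glutamate": 0.147, "r5p": 0.230}


def toy_biomass_composition(atp_maintenance=100.0):
    return BiomassComposition(
        macro_fractions=dict(WHITE_MATTER_MACRO_FRACTIONS),
        sub_fractions={
            "lipid": {"lipid": 1.0},
            "protein": {"glutamate": 1.0},
            "other": {"r5p": 1.0},
        },
        precursor_molar_masses=dict(TOY_MOLAR_MASSES),
        cell_weights=dict(WHITE_MATTER_CELL_WEIGHTS),
        atp_maintenance=atp_maintenance,
    )


def toy_brain_network(params: ToyNetworkParams | None = None, with_biomass=True):
    """Build the toy two-cell-type brain network (40 reactions by default)."""
    p = params or ToyNetworkParams()
    p.validate()
    net = MetabolicNetwork(id="toy_brain")

    for mid in ("glc_e", "gln_e", "o2_e", "lac_e", "nh3_e"):
        net.add_metabolite(Metabolite(mid, compartment="extracellular"))
    cells = CELLS if p.include_neuron else CELLS[:1]
    for suffix, comp in cells:
        for mid in ("g6p", "pyr", "accoa", "oaa", "akg", "r5p", "glu",
                    "lipid", "atp", "nadh_c", "nadh_m", "nadph"):
            net.add_metabolite(Metabolite(f"{mid}_{suffix}", compartment=comp))

    ag = p.atp_per_glycolysis
    at = p.atp_per_tca

    def rxn(rid, stoich, gpr, subsystem, cell, lb=0.0, ub=1000.0):
        net.add_reaction(Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            gpr=parse_gpr(gpr), subsystem=subsystem, cell_type=cell,
        ))

    for suffix, comp in cells:
        s = suffix
        glc_cap = p.uptake_bounds["glucose"]
        gln_cap = p.uptake_bounds["glutamine"]
        o2_cap = p.uptake_bounds["oxygen"]
        # glycolysis
        rxn(f"HEX_{s}", {"glc_e": -1, f"g6p_{s}": 1}, "HK2",
            "glycolysis", comp, ub=glc_cap)
        rxn(f"PYK_{s}", {f"g6p_{s}": -1, f"pyr_{s}": 2, f"atp_{s}": ag,
                         f"nadh_c_{s}": 2}, "PKM2", "glycolysis", comp)
        # lactate branch
        rxn(f"LDH_{s}", {f"pyr_{s}": -1, f"nadh_c_{s}": -1, "lac_e": 1},
            "LDHA", "lactate branch", comp)
        # pyruvate branch point
        rxn(f"PDH_{s}", {f"pyr_{s}": -1, f"accoa_{s}": 1, f"nadh_m_{s}": 1},
            "PDHA1", "pyruvate dehydrogenase", comp)
        rxn(f"PC_{s}", {f"pyr_{s}": -1, f"atp_{s}": -1, f"oaa_{s}": 1},
            "PC", "pyruvate carboxylase", comp)
        # lumped TCA: citrate synthase leg and the oxidative turn back to OAA
        rxn(f"CS_{s}", {f"accoa_{s}": -1, f"oaa_{s}": -1, f"akg_{s}": 1,
                        f"nadh_m_{s}": 2}, "CS", "tca cycle", comp)
        rxn(f"AKGDH_{s}", {f"akg_{s}": -1, f"oaa_{s}": 1, f"nadh_m_{s}": 2,
                           f"atp_{s}": at}, "OGDH", "tca cycle", comp)
        rxn(f"ME_{s}", {f"oaa_{s}": -1, f"pyr_{s}": 1, f"nadph_{s}": 1},
            "ME1", "malic enzyme", comp)
        # oxidative phosphorylation; cytosolic NADH enters via a shuttle with
        # a lower P/O yield than mitochondrial NADH
        rxn(f"OXPC_{s}", {f"nadh_c_{s}": -1, "o2_e": -0.5, f"atp_{s}": 1.5},
            "GPD2 and NDUFS1", "oxidative phosphorylation", comp,
            ub=2 * o2_cap)
        rxn(f"OXPM_{s}", {f"nadh_m_{s}": -1, "o2_e": -0.5, f"atp_{s}": 2.5},
            "NDUFS1", "oxidative phosphorylation", comp, ub=2 * o2_cap)
        # pentose phosphate pathway: the oxidative arm is lumped with the
        # non-oxidative carbon return (net NADPH source), while the
        # isomerase branch drains carbon into the nucleotide precursor pool
        rxn(f"G6PD_{s}", {f"g6p_{s}": -1, f"nadph_{s}": 2},
            "G6PD", "oxidative ppp", comp)
        rxn(f"RPI_{s}", {f"g6p_{s}": -1, f"r5p_{s}": 1},
            "TKT", "nonoxidative ppp", comp)
        # glutamine uptake + glutaminase, and anaplerotic glutamate dehydrogenase
        rxn(f"GLS_{s}", {"gln_e": -1, f"glu_{s}": 1, "nh3_e": 1},
            "GLS", "glutaminolysis", comp, ub=gln_cap)
        rxn(f"GDH_{s}", {f"glu_{s}": -1, f"akg_{s}": 1, "nh3_e": 1,
                         f"nadph_{s}": 1}, "GLUD1", "glutaminolysis", comp)
        # fatty-acid precursor drain
        rxn(f"FASYN_{s}", {f"accoa_{s}": -1, f"nadph_{s}": -2, f"atp_{s}": -1,
                           f"lipid_{s}": 1}, "ACLY and ACC and FASN",
            "lipid synthesis", comp)
        # ATP hydrolysis sink (non-growth maintenance; no gene)
        rxn(f"ATPM_{s}", {f"atp_{s}": -1}, "", "maintenance", comp)

    if p.include_neuron:
        # astrocyte-to-neuron glutamate hand-off (glutamate/glutamine cycle
        # analogue; closed under GBM constraints)
        net.add_reaction(Reaction(
            id="GLUtr_an", stoichiometry={"glu_a": -1, "glu_n": 1},
            lower_bound=0.0, upper_bound=1000.0, subsystem="intercellular",
            cell_type="inter-cell",
        ))

    def exch(rid, met, lb, ub, subsystem="exchange"):
        net.add_reaction(Reaction(
            id=rid, stoichiometry={met: -1.0}, lower_bound=lb, upper_bound=ub,
            subsystem=subsystem, cell_type="exchange", is_exchange=True,
        ))

    exch("EX_glc", "glc_e", -p.uptake_bounds["glucose"], 0.0)
    exch("EX_gln", "gln_e", -p.uptake_bounds["glutamine"], 0.0)
    exch("EX_o2", "o2_e", -p.uptake_bounds["oxygen"], 0.0)
    exch("EX_lac", "lac_e", 0.0, 1000.0)
    # ammonia has no metabolic sink in the toy, so its exchange is reversible
    # from the start (the constraint protocol's reversibility override keeps
    # the same bounds; on the full reconstruction it flips uptake-only to
    # reversible)
    exch("EX_nh3", "nh3_e", -1000.0, 1000.0)

    if with_biomass:
        comp = toy_biomass_composition(p.atp_maintenance)
        if not p.include_neuron:
            comp.cell_weights = {"astrocyte": 1.0}
        pm = {
            "lipid": {c: f"lipid_{sfx}" for sfx, c in cells},
            "glutamate": {c: f"glu_{sfx}" for sfx, c in cells},
            "r5p": {c: f"r5p_{sfx}" for sfx, c in cells},
        }
        am = {c: f"atp_{sfx}" for sfx, c in cells}
        bio = build_biomass_reaction(comp, pm, atp_map=am)
        net = attach_growth(net, bio)
    return net


def toy_gbm_constraints(uptake_mode="capacity"):
    """The GBM constraint protocol expressed on toy reaction ids.

    Uptake magnitudes are the measured GBM values; by default they act as
    capacities (upper bounds) so that expression, not the medium, decides
    how much carbon each context actually draws (see docs/methods.md).
    Oxygen is shared between the two oxphos routes within each cell, so its
    total capacity is set on the exchange rather than split per reaction.
    """
    cs = ConstraintSet(
        zero_reactions=["GLUtr_an"],
        reversibility_overrides={
            "EX_nh3": (-1000.0, 1000.0),
            "EX_o2": (-GBM_OXYGEN_UPTAKE, 0.0),
        },
        fixed_uptakes=[
            UptakeConstraint("glucose", "HEX_a", "HEX_n",
                             GBM_GLUCOSE_UPTAKE, metabolite="glc_e"),
            UptakeConstraint("glutamine", "GLS_a", "GLS_n",
                             GBM_GLUTAMINE_UPTAKE, metabolite="gln_e"),
        ],
        cell_split={"astrocyte": 0.94, "neuron": 0.06},
        amino_acid_cap_fraction=0.1,
        amino_acid_subsystem="amino acid uptake",
        uptake_mode=uptake_mode,
    )
    return cs


#: astrocyte reaction -> neuron counterpart, for phenotype aggregation
def toy_cell_pairing():
    pairs = {}
    for rid in ("HEX", "PYK", "LDH", "PDH", "PC", "CS", "AKGDH", "ME",
                "OXPC", "OXPM", "G6PD", "RPI", "GLS", "GDH", "FASYN", "ATPM"):
        pairs[f"{rid}_a"] = f"{rid}_n"
    return pairs


def toy_report_groups():
    """Key-flux groups of the full reconstruction mapped onto toy ids."""
    return [
        ReactionGroup("lactate_production", "sum", ["LDH_a", "LDH_n"],
                      reference_value=1.336,
                      reference_source="DeBerardinis et al. 2007"),
        ReactionGroup("glucose_uptake", "sum", ["HEX_a", "HEX_n"], uptake=True),
        ReactionGroup("pyruvate_carboxylase", "sum", ["PC_a", "PC_n"]),
        ReactionGroup("pyruvate_carboxylase_ratio", "ratio",
                      numerator="pyruvate_carboxylase",
                      denominator="glucose_uptake",
                      reference_range=(0.0, 0.227),
                      reference_source="Portais et al. 1993"),
        ReactionGroup("oxidative_ppp", "sum", ["G6PD_a", "G6PD_n"]),
        ReactionGroup("nonoxidative_ppp", "sum", ["RPI_a", "RPI_n"],
                      reference_source="increase vs healthy brain"),
        ReactionGroup("oxidative_ppp_ratio", "ratio",
                      numerator="oxidative_ppp", denominator="glucose_uptake",
                      reference_value=0.060,
                      reference_source="DeBerardinis et al. 2007"),
        ReactionGroup("tca_citrate_synthase", "sum", ["CS_a", "CS_n"]),
        ReactionGroup("pyruvate_dehydrogenase", "sum", ["PDH_a", "PDH_n"]),
        ReactionGroup("anaplerosis", "sum", ["GDH_a", "GDH_n"],
                      reference_range=(0.039, 0.078),
                      reference_source="Portais et al. 1993"),
        ReactionGroup("anaplerosis_to_cs_ratio", "ratio",
                      numerator="anaplerosis",
                      denominator="tca_citrate_synthase",
                      reference_range=(0.940, 1.800),
                      reference_source="Maher et al. 2012"),
        ReactionGroup("lipid_precursor", "sum", ["FASYN_a", "FASYN_n"]),
        ReactionGroup("malic_enzyme", "sum", ["ME_a", "ME_n"]),
        ReactionGroup("nh3_release", "sum", ["EX_nh3"],
                      reference_value=0.023,
                      reference_source="DeBerardinis et al. 2007"),
        ReactionGroup("growth_rate", "sum", ["EX_biomass"],
                      reference_range=(0.0006, 0.0095),
                      reference_source="experimental doubling times"),
    ]


# ---------------------------------------------------------------------------
# Small analytic fixtures
# ---------------------------------------------------------------------------

def toy_linear(uptake=10.0):
    """TOY-LIN: uptake of A (bound 10) -> conversion -> secretion of B.

    Three metabolites (C is deliberately isolated: its all-zero row must be
    retained in S), three reactions; the FBA optimum equals the uptake bound.
    """
    net = MetabolicNetwork(id="toy_lin")
    for mid in ("A", "B", "C"):
        net.add_metabolite(Metabolite(mid, compartment="extracellular"))
    net.add_reaction(Reaction("R_up", {"A": -1.0}, -uptake, 0.0,
                              cell_type="exchange", is_exchange=True))
    net.add_reaction(Reaction("R_conv", {"A": -1.0, "B": 1.0}, 0.0, 1000.0,
                              gpr=parse_gpr("g1"), cell_type="astrocyte"))
    net.add_reaction(Reaction("R_out", {"B": -1.0}, 0.0, 1000.0,
                              cell_type="exchange", is_exchange=True))
    net.objective_reaction = "R_out"
    return net


def toy_branch(uptake=10.0):
    """TOY-BRANCH: two parallel one-reaction paths A -> B under genes g2, g3."""
    net = MetabolicNetwork(id="toy_branch")
    for mid in ("A", "B"):
        net.add_metabolite(Metabolite(mid, compartment="extracellular"))
    net.add_reaction(Reaction("R1", {"A": -1.0}, -uptake, 0.0,
                              cell_type="exchange", is_exchange=True))
    net.add_reaction(Reaction("R2", {"A": -1.0, "B": 1.0}, 0.0, 1000.0,
                              gpr=parse_gpr("g2"), cell_type="astrocyte"))
    net.add_reaction(Reaction("R3", {"A": -1.0, "B": 1.0}, 0.0, 1000.0,
                              gpr=parse_gpr("g3"), cell_type="astrocyte"))
    net.add_reaction(Reaction("R4", {"B": -1.0}, 0.0, 1000.0,
                              cell_type="exchange", is_exchange=True))
    net.objective_reaction = "R4"
    return net


def toy_two_path(total=10.0):
    """Min-norm fixture: path P1 (one reaction) vs P2 (two reactions).

    With the drain fixed at ``total``, minimizing v1^2 + 2 v2^2 subject to
    v1 + v2 = total gives v1 = 2/3 total, v2 = 1/3 total.
    """
    net = MetabolicNetwork(id="toy_two_path")
    for mid in ("A", "M", "B"):
        net.add_metabolite(Metabolite(mid, compartment="extracellular"))
    net.add_reaction(Reaction("R_up", {"A": -1.0}, -total, 0.0,
                              cell_type="exchange", is_exchange=True))
    net.add_reaction(Reaction("P1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0,
                              cell_type="astrocyte"))
    net.add_reaction(Reaction("P2a", {"A": -1.0, "M": 1.0}, 0.0, 1000.0,
                              cell_type="astrocyte"))
    net.add_reaction(Reaction("P2b", {"M": -1.0, "B": 1.0}, 0.0, 1000.0,
                              cell_type="astrocyte"))
    net.add_reaction(Reaction("R_out", {"B": -1.0}, 0.0, 1000.0,
                              cell_type="exchange", is_exchange=True))
    net.objective_reaction = "R_out"
    return net


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimParams:
    n_samples_per_group: int = 20
    baseline_mean: float = 100.0
    noise_sd: float = 0.25  # sd of the log-normal multiplicative noise
    #: group -> {gene set name or gene id -> multiplicative shift}
    group_shifts: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self, known_sets, known_genes):
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if self.baseline_mean <= 0 or self.noise_sd <= 0:
            raise ValueError("baseline_mean and noise_sd must be positive")
        for grp, shifts in self.group_shifts.items():
            for key, shift in shifts.items():
                if shift <= 0:
                    raise ValueError(f"shift for {key} in {grp} must be > 0")
                if key not in known_sets and key not in known_genes:
                    raise ValueError(f"unknown gene or gene set {key!r} "
                                     f"in group {grp!r}")


#: mean shifts emulating the GBM expression programme against a normal-brain
#: control: glycolysis/lactate/glutaminolysis/lipid genes up; citrate
#: synthase and pyruvate carboxylase down (the TCA entry points — the
#: alpha-ketoglutarate-to-OAA span stays expressed so glutamine-fed
#: anaplerosis can run); LDHA low in the control (healthy brain relies on
#: oxidative metabolism, not lactate export)
WARBURG_SHIFTS = {
    "control": {"lactate": 0.2},
    "case": {
        "glycolysis": 2.0, "lactate": 2.0, "ppp": 2.0, "lipid": 2.0,
        "glutaminolysis": 2.0, "CS": 0.25, "pyruvate_carboxylase": 0.25,
    },
}


def warburg_sim_params(seed=0, n_samples_per_group=20, noise_sd=0.25):
    return ExpressionSimParams(
        n_samples_per_group=n_samples_per_group, noise_sd=noise_sd,
        group_shifts={g: dict(s) for g, s in WARBURG_SHIFTS.items()}, seed=seed,
    )


def synth_expression(net, params: ExpressionSimParams, gene_sets=None):
    """Simulate one expression matrix per group.

    values = baseline * shift * exp(N(0, noise_sd)); deterministic per seed.
    Returns (dict group -> ExpressionMatrix, truth dict gene -> group -> shift).
    """
    gene_sets = gene_sets if gene_sets is not None else TOY_GENE_GROUPS
    genes = sorted(net.genes)
    params.validate(set(gene_sets), set(genes))
    for name, members in gene_sets.items():
        unknown = set(members) - set(genes)
        if unknown:
            raise ValueError(f"gene set {name!r} contains genes absent from "
                             f"the network: {sorted(unknown)}")
    rng = np.random.default_rng(params.seed)
    matrices, truth = {}, {g: {} for g in genes}
    for group in sorted(params.group_shifts):
        shifts = params.group_shifts[group]
        shift_per_gene = {g: 1.0 for g in genes}
        for key, shift in shifts.items():
            members = gene_sets.get(key, [key])
            for g in members:
                shift_per_gene[g] *= shift
        n = params.n_samples_per_group
        noise = rng.normal(0.0, params.noise_sd, size=(len(genes), n))
        vals = np.array([
            params.baseline_mean * shift_per_gene[g] for g in genes
        ]).reshape(-1, 1) * np.exp(noise)
        cols = [f"{group}_{i + 1}" for i in range(n)]
        matrices[group] = ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=cols),
            dataset_label=f"synthetic:{group}",
        )
        for g in genes:
            truth[g][group] = shift_per_gene[g]
    return matrices, truth
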