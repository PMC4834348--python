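"""Key-flux aggregation and reporting.

Because the network carries an astrocytic and a neuronal copy of each core
pathway, phenotype evaluation first sums each astrocytic flux with its
neuronal counterpart, then computes named pathway fluxes (sums over reaction
groups) and flux ratios, rendered next to literature reference values.
Fluxes are reported to 3 decimals, growth rates to 4; uptake magnitudes are
reported as positive numbers.  Ratios are recomputed exactly from the
reported component fluxes; a zero denominator yields an undefined (None)
ratio, never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .optimize import FluxDistribution


class ReportError(ValueError):
    pass


@dataclass
class ReactionGroup:
    """A named flux quantity: a sum of reactions or a ratio of two groups."""

    name: str
    kind: str = "sum"  # "sum" | "ratio"
    member_ids: list = field(default_factory=list)
    numerator: str = ""
    denominator: str = ""
    uptake: bool = False  # report |value| (uptake magnitudes are positive)
    reference_value: float | None = None
    reference_range: tuple | None = None
    reference_source: str = ""

    def validate(self, by_name):
        if self.kind == "sum":
            if not self.member_ids:
                raise ReportError(f"group {self.name}: no member reactions")
        elif self.kind == "ratio":
            for ref in (self.numerator, self.denominator):
                if ref not in by_name:
                    raise ReportError(
                        f"ratio group {self.name} references unknown group {ref!r}"
                    )
        else:
            raise ReportError(f"group {self.name}: unknown kind {self.kind!r}")


def aggregate_cell_fluxes(v: FluxDistribution, pairing):
    """Sum astrocytic fluxes with their neuronal counterparts.

    ``pairing`` maps astrocytic reaction id -> neuronal reaction id; the
    aggregate is stored under the astrocytic id, the neuronal entry is
    dropped, unpaired reactions pass through unchanged.
    """
    for a, n in pairing.items():
        if a not in v.fluxes or n not in v.fluxes:
            missing = [x for x in (a, n) if x not in v.fluxes]
            raise ReportError(f"pairing refers to unknown reactions {missing}")
    out = dict(v.fluxes)
    for a, n in pairing.items():
        out[a] = out[a] + out.pop(n)
    return FluxDistribution(fluxes=out, objective_value=v.objective_value,
                            status=v.status)


@dataclass
class KeyFluxReport:
    model_label: str
    rows: list = field(default_factory=list)
    # each row: dict(name, kind, value, reference_value, reference_range, source)

    def value(self, name):
        for r in self.rows:
            if r["name"] == name:
                return r["value"]
        raise KeyError(name)

    def to_tsv(self, path=None):
        lines = ["name\tkind\tvalue\treference\tsource"]
        for r in self.rows:
            ref = ""
            if r["reference_value"] is not None:
                ref = f"{r['reference_value']}"
            elif r["reference_range"] is not None:
                lo, hi = r["reference_range"]
                ref = f"{lo}-{hi}"
            val = "undefined" if r["value"] is None else f"{r['value']}"
            lines.append(f"{r['name']}\t{r['kind']}\t{val}\t{ref}\t{r['source']}")
        text = "\n".join(lines) + "\n"
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_markdown(self):
        lines = [f"### Key fluxes — {self.model_label}", "",
                 "| quantity | value | reference | source |",
                 "|---|---|---|---|"]
        for r in self.rows:
            ref = ""
            if r["reference_value"] is not None:
                ref = f"{r['reference_value']}"
            elif r["reference_range"] is not None:
                ref = f"{r['reference_range'][0]}–{r['reference_range'][1]}"
            val = "undefined" if r["value"] is None else f"{r['value']}"
            lines.append(f"| {r['name']} | {val} | {ref} | {r['source']} |")
        return "\n".join(lines) + "\n"


def key_flux_report(v: FluxDistribution, groups, model_label="model",
                    growth_group="growth_rate", flux_decimals=3,
                    growth_decimals=4):
    """Compute all group sums and ratios from a flux distribution."""
    by_name = {g.name: g for g in groups}
    for g in groups:
        g.validate(by_name)
    sums = {}
    for g in groups:
        if g.kind != "sum":
            continue
        # reactions pruned from a context model or folded into their
        # astrocytic counterpart by aggregation carry zero flux
        total = sum(v.fluxes.get(rid, 0.0) for rid in g.member_ids)
        if g.uptake:
            total = abs(total)
        sums[g.name] = total
    rows = []
    for g in groups:
        decimals = growth_decimals if g.name == growth_group else flux_decimals
        if g.kind == "sum":
            value = round(sums[g.name], decimals)
        else:
            num = sums.get(g.name) if g.name in sums else None
            num = sums[g.numerator]
            den = sums[g.denominator]
            value = None if den == 0 else round(num / den, decimals)
        rows.append({
            "name": g.name, "kind": g.kind, "value": value,
            "reference_value": g.reference_value,
            "reference_range": g.reference_range,
            "source": g.reference_source,
        })
    return KeyFluxReport(model_label=model_label, rows=rows)


def _groups_from_yaml_dict(d):
    groups = []
    for g in d["groups"]:
        rr = g.get("reference_range")
        groups.append(ReactionGroup(
            name=g["name"], kind=g.get("kind", "sum"),
            member_ids=list(g.get("member_ids", [])),
            numerator=g.get("numerator", ""),
            denominator=g.get("denominator", ""),
            uptake=bool(g.get("uptake", False)),
            reference_value=g.get("reference_value"),
            reference_range=tuple(rr) if rr else None,
            reference_source=g.get("reference_source", ""),
        ))
    return groups


def default_table1_groups():
    """Key-flux definitions for the full brain reconstruction (r_*/e_* ids)."""
    text = resources.files("gbmflux.data").joinpath("table1_groups.yaml").read_text()
    return _groups_from_yaml_dict(yaml.safe_load(text))


def load_groups_yaml(path):
    with open(path) as fh:
        return _groups_from_yaml_dict(yaml.safe_load(fh))
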