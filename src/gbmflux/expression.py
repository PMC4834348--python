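"""Transcriptome ingestion, binarization and two-condition statistics.

The flow mirrors how microarray data drives context-specific model
extraction: a gene-by-sample intensity matrix is reduced to per-gene means,
a threshold is chosen as a *fraction of the grand mean* of the dataset, the
choice is validated against a panel of genes known to be upregulated in GBM
(the threshold must not exceed their expression), genes are binarized
(1 = highly expressed), and reaction on/off states are obtained by
propagating gene states through GPR rules with AND=min / OR=max.

For the two-condition MADE path, per-gene fold changes and classical
pooled-variance Student's t p-values are computed case vs control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

#: genes known to be upregulated in GBM (glucose, glutamine, lipid metabolism);
#: a valid binarization threshold must not exceed their expression levels
GBM_MARKER_GENES = ("HK2", "PKM2", "GLS", "ACLY", "ACC", "FASN")

UNMAPPED = "unmapped"


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene-by-sample non-negative intensity matrix."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    dataset_label: str = ""

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ExpressionError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("expression intensities must be non-negative")

    @property
    def genes(self):
        return list(self.values.index)

    @property
    def samples(self):
        return list(self.values.columns)

    def gene_means(self):
        return self.values.mean(axis=1)

    def grand_mean(self):
        if self.values.size == 0:
            raise ExpressionError("empty expression matrix")
        return float(self.values.to_numpy().mean())

    def subset(self, genes):
        """Restrict to the given genes (e.g. genes mappable to a model)."""
        keep = [g for g in self.genes if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.dataset_label)

    def to_tsv(self, path):
        self.values.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path, dataset_label="", probe_column=None,
                        collapse="max_mean"):
    """Read a tab-delimited gene-by-sample matrix with a header row.

    If ``probe_column`` names a column holding gene symbols (probe-level
    files), multiple probes per symbol are collapsed; the default policy
    keeps the probe with the highest mean intensity.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if probe_column is not None:
        sym = df[probe_column]
        df = df.drop(columns=[probe_column])
        df = collapse_probes(df, sym, policy=collapse)
    df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        df = df.dropna(axis=0, how="any")
    return ExpressionMatrix(df, dataset_label or str(path))


def collapse_probes(df, symbols, policy="max_mean"):
    """Collapse a probe-level matrix to gene level.

    ``max_mean`` (default) keeps, per gene symbol, the probe with the highest
    mean; ``mean`` averages all probes of a symbol.
    """
    if policy == "max_mean":
        means = df.mean(axis=1)
        order = means.sort_values(ascending=False).index
        df2 = df.loc[order]
        sym2 = symbols.loc[order]
        keep = ~sym2.duplicated()
        out = df2.loc[keep]
        out.index = sym2.loc[keep]
        return out
    if policy == "mean":
        return df.groupby(symbols).mean()
    raise ExpressionError(f"unknown probe collapse policy {policy!r}")


@dataclass
class BinaryExpressionState:
    states: dict = field(default_factory=dict)  # gene -> 0/1
    threshold_used: float = float("nan")

    def __getitem__(self, gene):
        return self.states[gene]

    def fraction_on(self):
        if not self.states:
            return float("nan")
        return sum(self.states.values()) / len(self.states)


def compute_threshold(expr: ExpressionMatrix, fraction: float) -> float:
    """``fraction`` times the grand mean of all values in the matrix.

    The fractions used in practice are 1/2, 1/1 and 1/3 of the dataset mean,
    chosen per dataset so that the marker-gene criterion below holds.
    """
    if fraction <= 0:
        raise ExpressionError("threshold fraction must be > 0")
    return fraction * expr.grand_mean()


@dataclass
class ThresholdReport:
    valid: bool
    offending: list
    absent_markers: list
    threshold: float


def validate_threshold(expr, threshold, marker_genes=GBM_MARKER_GENES):
    """Check that no marker gene's mean expression falls below the threshold."""
    means = expr.gene_means()
    offending, absent = [], []
    for g in marker_genes:
        if g not in means.index:
            absent.append(g)
        elif means[g] <= threshold:
            offending.append(g)
    return ThresholdReport(valid=not offending, offending=offending,
                           absent_markers=absent, threshold=threshold)


def binarize(expr, threshold):
    """Gene state 1 iff its mean across the dataset's samples exceeds the
    threshold (strict inequality), else 0."""
    if not math.isfinite(threshold):
        raise ExpressionError("threshold must be finite")
    means = expr.gene_means()
    states = {g: (1 if means[g] > threshold else 0) for g in expr.genes}
    return BinaryExpressionState(states=states, threshold_used=float(threshold))


def reaction_states(net, states: BinaryExpressionState, missing_policy="expressed"):
    """Map gene states to reaction on/off via GPR (AND=min, OR=max).

    Reactions without a GPR are ``"unmapped"`` and never penalized.  Genes in
    the model but absent from the data are treated as expressed by default
    (``missing_policy="expressed"``); ``"off"`` treats them as 0.
    """
    missing = 1 if missing_policy == "expressed" else 0
    out = {}
    for r in net.reactions:
        if r.gpr is None:
            out[r.id] = UNMAPPED
        else:
            out[r.id] = int(r.gpr.evaluate(states.states, missing=missing))
    return out


# ---------------------------------------------------------------------------
# Differential statistics (MADE inputs)
# ---------------------------------------------------------------------------

@dataclass
class GeneStatistics:
    """Per-gene fold change (case/control) and pooled-t p-value."""

    table: pd.DataFrame  # columns: fold_change, log2_fold_change, t_statistic, p_value

    @property
    def genes(self):
        return list(self.table.index)

    def significant(self, alpha):
        return self.table[self.table["p_value"] < alpha]


_VARIANCE_FLOOR = 1e-12


def differential_stats(case: ExpressionMatrix, control: ExpressionMatrix):
    """Two-sample pooled-variance Student's t and fold changes per gene.

    Fold change is mean(case)/mean(control).  When the pooled variance is
    exactly zero, p is 1 if the means agree and otherwise computed with a
    variance floor of 1e-12.
    """
    genes = [g for g in case.genes if g in set(control.genes)]
    if not genes:
        raise ExpressionError("case and control share no genes")
    rows = {}
    for g in genes:
        x = case.values.loc[g].to_numpy(dtype=float)
        y = control.values.loc[g].to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ExpressionError(f"gene {g}: need >=2 samples per group")
        mx, my = x.mean(), y.mean()
        df = len(x) + len(y) - 2
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
        if sp2 <= 0:
            if mx == my:
                t, p = 0.0, 1.0
            else:
                se = math.sqrt(_VARIANCE_FLOOR * (1 / len(x) + 1 / len(y)))
                t = (mx - my) / se
                p = 2 * _sps.t.sf(abs(t), df)
        else:
            se = math.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
            t = (mx - my) / se
            p = 2 * _sps.t.sf(abs(t), df)
        fc = mx / my if my != 0 else float("inf")
        rows[g] = {
            "fold_change": fc,
            "log2_fold_change": math.log2(fc) if 0 < fc < math.inf else float("nan"),
            "t_statistic": t,
            "p_value": float(min(max(p, 0.0), 1.0)),
        }
    return GeneStatistics(pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# Threshold sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityReport:
    max_abs_flux_change: float
    per_reaction: pd.DataFrame  # columns: low, base, high, max_change
    failures: list


def threshold_sensitivity(run, threshold, delta=0.05):
    """Rerun a deterministic pipeline closure at (1 +/- delta) x threshold.

    ``run`` maps a threshold to a flux dict (reaction -> flux).  Reports the
    maximum and per-reaction absolute flux difference against the baseline;
    an infeasible rerun is recorded in ``failures`` rather than raised.
    """
    base = run(threshold)
    results, failures = {}, []
    for label, thr in (("low", (1 - delta) * threshold),
                       ("high", (1 + delta) * threshold)):
        try:
            results[label] = run(thr)
        except Exception as exc:  # noqa: BLE001 - recorded, not raised
            failures.append((label, thr, str(exc)))
            results[label] = None
    all_ids = set(base)
    for res in results.values():
        if res is not None:
            all_ids |= set(res)
    rows = {}
    for rid in sorted(all_ids):
        v = base.get(rid, 0.0)  # a pruned reaction carries zero flux
        lo = results["low"].get(rid, 0.0) if results["low"] is not None else v
        hi = results["high"].get(rid, 0.0) if results["high"] is not None else v
        rows[rid] = {
            "low": lo, "base": v, "high": hi,
            "max_change": max(abs(lo - v), abs(hi - v)),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    max_change = float(table["max_change"].max()) if len(table) else 0.0
    return SensitivityReport(max_abs_flux_change=max_change,
                             per_reaction=table, failures=failures)
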