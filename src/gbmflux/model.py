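"""Model/Results interface over the context-specific modelling pipelines.

Mirrors the fit-and-summarize idiom of statistical modelling packages: a
model object is built from a metabolic network plus expression data, its
``fit()`` runs the integration algorithm and returns a results object
carrying the flux estimates, the extraction ledger and a ``summary()``
table of key fluxes against literature reference values.

``GIMME`` binarizes one condition's expression against a fraction-of-mean
threshold and extracts a pruned context model; ``MADE`` contrasts a case
against a control condition through fold changes and t-test p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constraints import ConstraintSet
from .expression import GBM_MARKER_GENES, ExpressionMatrix, differential_stats
from .gimme import GimmePipelineResult, gimme_pipeline
from .made import MadeResult, made_two_condition
from .network import MetabolicNetwork
from .optimize import FluxDistribution, SolverSettings
from .report import ReactionGroup, aggregate_cell_fluxes, key_flux_report
from .sampler import FluxSample, sample_fluxes


@dataclass
class _SummaryMixin:
    def _summary(self, flux, label):
        v = flux
        if self.pairing:
            v = aggregate_cell_fluxes(v, {a: n for a, n in self.pairing.items()
                                          if a in v.fluxes and n in v.fluxes})
        return key_flux_report(v, self.groups, model_label=label)


class GIMME:
    """GIMME model: one network + one expression condition.

    Parameters
    ----------
    network : MetabolicNetwork
        Growth-enabled network (objective_reaction set).
    expression : ExpressionMatrix
        Condition-specific intensities (gene x sample).
    threshold_fraction : float
        Binarization threshold as a fraction of the dataset grand mean over
        model-mappable genes (1/2, 1/1 or 1/3 in the published protocol).
    constraints : ConstraintSet, optional
        Physiological constraint protocol (ratio rows during extraction,
        uptake magnitudes during flux computation).
    rmf_fraction : float
        Fraction of the growth optimum the context model must retain.
    """

    def __init__(self, network: MetabolicNetwork, expression: ExpressionMatrix,
                 threshold_fraction=0.5, constraints: ConstraintSet = None,
                 rmf_fraction=0.9, markers=GBM_MARKER_GENES,
                 groups=(), pairing=None, settings=SolverSettings()):
        self.network = network
        self.expression = expression
        self.threshold_fraction = threshold_fraction
        self.constraints = constraints
        self.rmf_fraction = rmf_fraction
        self.markers = markers
        self.groups = list(groups)
        self.pairing = dict(pairing or {})
        self.settings = settings

    def fit(self) -> "GIMMEResults":
        res = gimme_pipeline(
            self.network, self.expression, self.threshold_fraction,
            markers=self.markers, constraints=self.constraints,
            rmf_fraction=self.rmf_fraction, settings=self.settings,
        )
        return GIMMEResults(model=self, pipeline=res)


@dataclass
class GIMMEResults(_SummaryMixin):
    model: GIMME
    pipeline: GimmePipelineResult

    @property
    def flux(self) -> FluxDistribution:
        return self.pipeline.flux

    @property
    def growth_rate(self):
        return self.flux.objective_value

    @property
    def context_network(self):
        return self.pipeline.context.network

    @property
    def removed_reactions(self):
        return self.pipeline.context.removed_reactions

    @property
    def inconsistency_score(self):
        return self.pipeline.context.inconsistency_score

    @property
    def groups(self):
        return self.model.groups

    @property
    def pairing(self):
        return self.model.pairing

    def summary(self, label=None):
        label = label or (self.model.expression.dataset_label or "GIMME model")
        return self._summary(self.flux, label)

    def sample(self, growth_fraction_low=0.8, n_samples=1000, seed=0,
               thinning=100) -> FluxSample:
        """Uniformly sample the context model's growth-banded flux space."""
        from .constraints import apply_constraint_set

        net = self.context_network
        if self.model.constraints is not None:
            net = apply_constraint_set(net, self.model.constraints, "flux")
        return sample_fluxes(net, growth_fraction_low=growth_fraction_low,
                             n_samples=n_samples, seed=seed, thinning=thinning)


class MADE:
    """MADE model: one network + case and control expression conditions."""

    def __init__(self, network: MetabolicNetwork, case: ExpressionMatrix,
                 control: ExpressionMatrix, alpha=0.05,
                 constraints: ConstraintSet = None, functionality_fraction=0.3,
                 post_norm=False, groups=(), pairing=None,
                 settings=SolverSettings()):
        self.network = network
        self.case = case
        self.control = control
        self.alpha = alpha
        self.constraints = constraints
        self.functionality_fraction = functionality_fraction
        self.post_norm = post_norm
        self.groups = list(groups)
        self.pairing = dict(pairing or {})
        self.settings = settings

    def fit(self) -> "MADEResults":
        from .constraints import apply_constraint_set

        stats = differential_stats(self.case, self.control)
        net = self.network
        if self.constraints is not None:
            net = apply_constraint_set(net, self.constraints, "gimme")
            net = apply_constraint_set(net, self.constraints, "flux")
        res = made_two_condition(
            net, stats, alpha=self.alpha,
            functionality_id=net.objective_reaction,
            fraction=self.functionality_fraction, post_norm=self.post_norm,
            settings=self.settings,
        )
        return MADEResults(model=self, stats=stats, result=res)


@dataclass
class MADEResults(_SummaryMixin):
    model: MADE
    stats: "GeneStatistics"
    result: MadeResult

    @property
    def case_flux(self):
        return self.result.case_flux

    @property
    def control_flux(self):
        return self.result.control_flux

    @property
    def growth_rate(self):
        return self.case_flux.objective_value

    @property
    def gene_states(self):
        return self.result.gene_states

    @property
    def groups(self):
        return self.model.groups

    @property
    def pairing(self):
        return self.model.pairing

    def summary(self, condition="case", label=None):
        flux = self.case_flux if condition == "case" else self.control_flux
        label = label or f"MADE model ({condition})"
        return self._summary(flux, label)
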