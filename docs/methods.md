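# Methods

## Model

Metabolism of brain tumour tissue is described by a stoichiometric network
over three compartments — astrocyte, neuron, extracellular — with reactions
tagged by cell type (astrocytic, neuronal, exchange, inter-cell).  Steady
state `S·v = 0` with flux bounds defines the feasible set; fluxes are in
mmol/gDW/h and the growth drain in 1/h.  Exchange fluxes follow the uptake-
negative convention, and uptake magnitudes are reported as positive numbers.
Reversible reactions are single signed variables everywhere except inside
the GIMME LP, where they are split into non-negative forward/backward parts
so that |v| is linear.

### Biomass

Growth is a pseudo-reaction draining precursors in proportion to tissue
composition.  The default composition is brain white matter — lipid 0.549,
protein 0.395 g/g, with the unspecified residual 0.056 assigned to a
configurable "other" pool (carbohydrate/nucleotide precursors by default) —
weighted by cell-type abundance (astrocyte 0.94, neuron 0.06).  Coefficients
are `weight × macro_fraction × sub_fraction / molar_mass`, so covered mass
closes to 1 g per g biomass (checked to 1e-6).  An ATP maintenance
coefficient (mmol ATP per g biomass) is configurable and defaults to **0**
in the builder; the toy network sets it to 100 (below).

### Dual-objective flux distributions

FBA optima of genome-scale models are degenerate.  The package's uniform
alternate-optima policy is: maximize growth (LP, HiGHS), then minimize
`Σ v_i²` over internal (non-exchange) fluxes at the fixed optimum (convex
QP).  Internal includes inter-cell transport reactions; exchanges and the
growth drain are excluded so the norm does not fight fixed uptakes.  The QP
is solved by `trust-constr` started from a growth-clamped LP solution, with
the growth clamp implemented as an equality band of ±1e-6 for robustness.
A final polish solves the KKT system of the active-set equality problem
directly (least squares), pinning the objective at its exact LP optimum;
this removes the O(slack) bias of the clamping band and reproduces
closed-form solutions to machine precision on the analytic fixtures.  The
polish is only accepted if it is feasible and does not blow up the norm.

## Transcriptome integration

Expression matrices are gene×sample intensity tables (probe-level files are
collapsed per symbol, keeping the max-mean probe by default).  Thresholds
are a *fraction of the grand mean* of the dataset restricted to
model-mappable genes; per-gene summaries for binarization are means across
the dataset's samples (the alternative — binarize per sample, then vote —
is not used, so each dataset yields exactly one context model).  A threshold
is rejected if it exceeds the mean expression of any present GBM marker
gene (HK2, PKM2, GLS, ACLY, ACC, FASN).  Gene state 1 requires mean strictly
above the threshold.  Reaction states come from GPR evaluation with AND=min,
OR=max; reactions without GPR are unmapped and never penalized; model genes
absent from the array count as expressed (configurable) — absence of
evidence does not delete reactions.

### GIMME

One LP minimizes `Σ w_i·|v_i|` over state-0 reactions (uniform weights 1;
binarized data carries no graded distance to the threshold) subject to
steady state, bounds, coupling rows, and growth ≥ `rmf_fraction` × optimum
(default 0.9, the common convention).  State-0 reactions with |v| < 1e-9 in
the minimizer are removed; the rest are logged as added back.  The LP
objective value is the inconsistency score.  The pruned model is re-solved
to verify the functionality bound.

### MADE

Desired transitions per gene: increase if fold change > 1 and p < α,
decrease if fold change < 1 and p < α, else constant; weights w = 1 − p.
A MILP chooses binary gene states in control and case, propagated through
linearized GPRs to reaction indicators with flux coupling
`lb_r·y ≤ v_r ≤ ub_r·y` (the reaction's own bounds serve as the big-M
constants — the tightest valid choice), and growth ≥ `fraction` × optimum
(default 0.3) in each condition.  The primary objective maximizes weighted
agreement over the *significant* genes only; genes with no significant
change are governed by a small secondary penalty (1e-7 per flip) that keeps
states constant whenever feasible and breaks ties reproducibly.  Restricting
the objective to significant genes makes the agreement score provably
monotone under tightening α (shrinking the significant set can only drop
non-negative terms), which the original all-genes objective does not
guarantee.  When the optimal states are identical in both conditions the
control flux vector is reported for both, since the condition models
coincide.  No norm-minimization step is applied to MADE fluxes by default
(its native output is the MILP flux vector); `post_norm=True` adds it for
comparison.

Differential statistics are classical pooled-variance two-sided Student's t
per gene with fold change = mean(case)/mean(control); a zero pooled variance
yields p = 1 for equal means and otherwise a variance floor of 1e-12.

## GBM constraint protocol

Two-phase application.  Extraction phase: zeroed reactions, reversibility
overrides, and the astrocyte/neuron 94/6 *ratio* of glucose, glutamine and
oxygen uptake as coupling rows (no absolute magnitudes).  Flux phase:
per-cell uptake magnitudes on the bounds and the amino-acid cap (every
amino-acid uptake other than glutamine ≤ 0.1 × the glutamine uptake,
applied against the per-cell glutamine share for cell-tagged reactions).
Magnitudes refer to metabolite consumption, so reactions consuming the
substrate with |stoichiometry| ≠ 1 are scaled accordingly.

`uptake_mode` selects equalities (`lb = ub`, the published protocol for the
full reconstruction, and the default) or capacities (upper bounds on uptake
magnitude).  The toy constraint set uses capacities: when glucose *and*
oxygen are both fixed as equalities in a small redox-closed network, every
extra TCA turn produces NADH that the oxygen-capped respiratory chain
cannot absorb and that must leave as lactate, so lactate and TCA flux rise
and fall together and no expression state can produce the
high-lactate/low-TCA contrast.  Treating the measured uptakes as capacities
lets expression decide how much substrate each context actually draws,
which is the behaviour the comparison between a tumour-like and a
control-like expression state needs.

## Synthetic study system

`toy_brain_network()` builds a 40-reaction, 17-gene network with astrocytic
and neuronal copies of: glycolysis (2 ATP + 2 cytosolic NADH per glucose),
lactate dehydrogenase exporting lactate, the pyruvate
dehydrogenase/carboxylase split, a lumped TCA cycle in two legs (citrate
synthase leg and an α-KG→OAA leg with substrate-level ATP), a malic-enzyme
valve OAA→pyruvate + NADPH, oxidative phosphorylation with separate
cytosolic (P/O 1.5, shuttle) and mitochondrial (P/O 2.5) NADH pools,
oxidative PPP as a net NADPH source plus an isomerase branch draining
ribose-5-phosphate, glutaminase-coupled glutamine uptake and glutamate
dehydrogenase anaplerosis, a fatty-acid precursor drain, ATP maintenance
sinks, an astrocyte→neuron glutamate hand-off, and exchanges for glucose,
glutamine, oxygen, lactate, NH₃ and biomass.  Default uptake capacities are
loose (glucose 10, glutamine 1, oxygen 5 mmol/gDW/h); the GBM constraint
set tightens them to the measured values.  The biomass ATP coefficient is
100 mmol/gDW — a lumped growth-plus-tissue-maintenance demand chosen so
that proliferation is energy-limited, which is what makes the oxidative vs
glycolytic routing decision consequential (the separate NADH pools make
full oxidation the oxygen-efficient route, so an oxygen-limited
lactate-blocked model prefers the TCA cycle).  The toy is deliberately not
elementally balanced (CO₂ and water are not tracked); it conserves the
carbon/redox/energy couplings that drive the phenotype.

`synth_expression()` draws intensities `baseline × shift × exp(N(0, σ))` —
log-normal noise around a positive baseline (default 100, σ = 0.25, n = 20
samples per group), with multiplicative mean shifts on pathway gene groups.
The Warburg preset shifts glycolysis/lactate/PPP/lipid/glutaminolysis genes
×2 and citrate synthase + pyruvate carboxylase ×0.25 in the case, and LDHA
×0.2 in the control (healthy brain relies on oxidative metabolism).  These
sizes emulate subtype-clustered microarray contrasts; they produce
essentially deterministic binarization at the ×0.5-mean threshold (≥5σ
margins on gene means), so pipeline outcomes are stable across seeds.

What the toy does *not* emulate: probe-level array structure, normalization
artefacts, correlated noise between genes, isozyme-rich GPRs, and the
hundreds of pathways of the full reconstruction.  Passing tests therefore
demonstrate algorithmic correctness and the recoverability of the rerouting
phenotype under the stated conditions, not quantitative agreement with any
real tumour.

## Sampling

Coordinate hit-and-run on a null-space basis of the equality system (S,
coupling rows, and pinning rows for bound-fixed variables, so every basis
direction is free), warm-started from the dual-objective solution, with the
growth drain bounded to [0.8, 1.0] × optimum.  Default thinning 100; chains
are deterministic per seed.  A split-chain ratio (pooled vs within variance
of the two half-chains) is reported per reaction with threshold 1.1 —
reported, not enforced.  Degenerate (single-point) polytopes return the
point with a warning.

## Reporting

Astrocytic fluxes are summed with neuronal counterparts before phenotype
evaluation.  Key-flux groups are sums of reaction sets or ratios of two
groups; ratios are recomputed from the reported component values, a zero
denominator yields "undefined", fluxes print at 3 decimals and growth at 4.
Literature reference values attached to groups are rendered as context only
— no automatic pass/fail verdict is made against them.  For the full
reconstruction, note that published growth rates appear both as 0.0057 1/h
(subtype table) and 0.057 1/h (text, same dataset); both are carried in the
metadata without silent correction.

## Numerical choices and limitations

LP/QP/MILP tolerances: steady-state residual ≤ 1e-6, bound violation
≤ 1e-9, zero-flux threshold 1e-9 for GIMME removal, MILP gap 0, MADE
tie-break 1e-7.  Problem sizes used by the test-suite and the acceptance
script (toy networks of ≤ 40 reactions, 10⁴ samples, 200 statistical
replicates) were chosen as the smallest sizes at which every property is
sharply testable.  Known limitations: GIMME uses a single LP
(remove-then-verify) rather than iterative re-insertion, which matches the
remove/add-back semantics but may differ from iterative variants on
networks with interacting low-expression routes; MADE supports exactly two
conditions; the sampler requires equality coupling rows; no
flux-variability analysis, gap-filling or thermodynamic constraints.
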