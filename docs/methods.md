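# Methods

## Screen model

A well's raw fluorescence is modelled as multiplicative:

```
raw = baseline × plate_effect × gene_effect × drug_interaction × noise
```

with lognormal plate effects and noise (viability readings are positive and
right-skewed; a multiplicative model keeps every downstream ratio
scale-free). The drug interaction applies only to a true sensitizer gene in
the drug arm. Knockdown efficacy `e ∈ [0,1]` attenuates the planted
interaction factor `f` linearly: the effective multiplier is `1 + e(f − 1)`,
so a fully efficient siRNA realizes `f` exactly and an inert one realizes 1.
This interpolation is a modelling choice; any monotone attenuation with the
same endpoints would serve, and the deconvolution logic depends only on the
endpoints.

Plate effects hit *every* well on a plate, including the GL2 control wells.
That is deliberate: it is exactly the disturbance the per-plate GL2-median
normalization must cancel, and the scale-invariance tests check that
property (multiplying any plate by any constant changes no SI, p-value or
hit call).

Layout: one vehicle/drug plate pair per drug, replicate wells for each gene
within a plate (default 3 per gene × condition; the replicate count is a
parameter because screen layouts vary), and 5 GL2 wells per plate by
default. Vehicle and drug plates are linked by an explicit `plate_pair`
column; when absent, plates are paired in sorted order within each drug arm,
and the explicit column always wins.

### Sensitization index and testing

Replicate normalized viabilities are summarized per arm by the arithmetic
mean before the SI ratio is taken (a geometric-mean flag exists; on
log-scale data the two orderings differ only slightly and the arithmetic
mean matches per-well-normalization-then-summarize practice). The drug
effect is tested per unit by OLS of log2 normalized viability on an arm
indicator — identical to a pooled-variance two-sample t-test — and, by
default, residual variances are moderated across units by an empirical-Bayes
scaled-F prior fitted by moments on the log scale (the moderated t gains the
prior degrees of freedom). With only a handful of replicates per arm,
moderation is what makes the per-gene test usable; a `moderate=False` flag
gives plain OLS. Two-sided p-values are used: directionality is enforced by
the separate SI < 0.85 biological gate, so the dual criterion is
`SI < 0.85 AND BH-FDR < 0.15`, both inequalities strict, FDR computed
screen-wide within each drug. Deconvolution validates a gene when ≥ 2 of its
4 individual siRNAs independently pass the dual criterion; for the
drug-specificity re-screen the two siRNAs with lowest SI for the anchor drug
are selected ("best two"), a defensible reading where the selection rule is
not otherwise fixed.

Numerical edge cases: a unit with zero residual variance gets p = 0 if the
arm means differ and p = 1 otherwise; variances below 1e−20 and effects
below 1e−10 (float-epsilon residue of the log/divide round trip) are snapped
to zero so the degenerate branch is itself scale-invariant; units with fewer
than two replicates per arm get p = 1 and a `low_replicates` flag rather
than being dropped.

## Expression model

The simulator draws per-gene baselines N(7, 1.5²) on the log2 scale,
applies planted shifts (constant across all knockdown samples) and
coordinated cytoband shifts, and adds i.i.d. N(0, σ²) residuals; control
samples sit at the baseline. Defaults emulate a 22,011-gene × 16-sample
design (14 knockdowns + 2 controls), residual σ = 0.3.

Per-sample log2FC subtracts the *mean of the controls*; with 2 controls this
shared baseline contributes variance σ²/2 to every fold change of a gene,
which dominates the uncertainty of the per-gene mean log2FC (sd ≈ 0.23 at
σ = 0.3). Parameter recovery is therefore assessed as bias — the
seed-averaged estimate against the planted truth — rather than per-seed
absolute error, which no estimator could push below that floor. The
universal-change rule is inclusive at the threshold (log2FC ≤ −1.0 in every
knockdown counts); the report tier (mean < −1.5) and near-threshold rule
(consistent sign, |mean| ≥ 0.85, primary cutoff missed) are strict/inclusive
as written. The near-threshold cutoff of 0.85 is a reporting convenience
chosen to capture consistently regulated genes just under the primary
threshold without flagging plain noise; it is not a discovery criterion.

The pooled-variance t (df = n_kd + n_con − 2) deliberately pools the tiny
control group with the knockdowns. The gene-set statistic is the rank sum of
a set's t-statistics against all other genes'; small untied sets (≤ 10
members in a universe of ≤ 200 measured genes) get an exact permutation p by
dynamic-programming enumeration of the rank-sum distribution — in the far
tail the normal approximation is off by orders of magnitude — while
genome-scale problems use the normal approximation with tie and continuity
corrections. Regions (cytoband major bands) and curated pathways are
Bonferroni-corrected as separate families since they are reported
separately. Cytoband parsing accepts `19q13.1`, range labels (`6p25-p24`
resolves to its first band) and X/Y bands; unparseable labels are logged and
excluded rather than fatal.

## What the simulators do and do not emulate

They reproduce the statistical structure the pipeline must cope with —
multiplicative plate/gene/drug effects, lognormal measurement noise,
variable siRNA efficacy, planted consensus genes and region-level shifts —
with known truth. They do not emulate probe-level microarray processing
(matrices are consumed already normalized and gene-summarized),
dose–response behaviour, spatial within-plate artifacts (edge effects), or
correlated gene–gene expression structure. Passing tests therefore
demonstrate correctness of the scoring and inference machinery under the
declared noise model, not robustness to artifacts the model excludes.

## Problem sizes and determinism

The acceptance computations use 100 simulated screens (53 genes, 3
replicates) and 100 simulated expression matrices at full 22,011 × 16 size —
sizes at which the Monte-Carlo margins quoted in the tests are meaningful
while a full run stays around a minute. Every stochastic routine takes an
explicit seed (generators refuse to run without one) and identical seeds
give bit-identical outputs; pipeline runs write a JSON manifest (inputs,
thresholds, flags, seed, version) whose checksum is embedded as a comment
line in every output table.

## Known limitations

- The screen arm validates knockdown *phenotypically* only; qPCR-style
  confirmation of target knockdown is outside computational scope and noted
  in provenance.
- FDR control is screen-wide per drug; within-plate correction is not
  offered.
- The empirical-Bayes prior assumes exchangeable residual variances across
  genes (no mean–variance trend fitting).
- B-score/SSMD normalizations and instrument-native export formats are not
  implemented; input is the long-format CSV described in the README.
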