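# Methods

This note records the models, numerical choices and design decisions
behind `cgimeth`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Biomarker-selection cascade

The cascade operates on CGI-aggregated Illumina-450k-style β values
(methylated / total signal, in [0, 1]) with tumour/normal group labels
and a discovery/validation cohort split.

**Gates and strictness.** Stage 1 retains CGIs whose mean normal β is
*strictly below* 0.25. Stage 2 requires β > 0.45 (strict) in at least
75 % of tumours (inclusive) and β > 0.25 (strict) in not more than 25 %
of normals (inclusive). The AUC gate requires AUC *strictly above* 0.95
in both cohorts. Strict-vs-inclusive choices follow the cascade's verbal
definitions literally ("lower than", "at least", "not more than"); the
boundary cases are pinned by unit tests. By default stages 1–2 are
evaluated on the discovery cohort only (`stage_cohort_policy=
'discovery_only'`), because the original selection was driven by the
discovery arrays with the validation cohort confirming AUC; requiring
both cohorts (`'both_cohorts_intersect'`) is available since the
published description does not settle which convention was used.

**AUC.** The Mann–Whitney form — the fraction of (tumour, normal) pairs
with tumour β above normal β, ties counted ½ — computed from midranks.
This equals the trapezoidal area under the empirical ROC curve, is exact
under ties, and is invariant to strictly monotone transforms of the
scores. Direction is fixed with tumour as case; an AUC below 0.5 is
reported as-is, never auto-flipped. No multiple-testing correction is
applied: the gate is an AUC threshold, not a p-value.

**Missing values.** β may be missing; means, prevalence fractions and
AUC all use present values only (pairwise deletion). A CGI missing more
than 20 % of its entries (configurable) is marked not computable and
fails the cascade with a recorded reason rather than being silently
dropped. A group left with zero present values likewise fails.

**Flag semantics.** `pass_auc` is evaluated on the survivors of stages
1–2 (the cascade's ROC step runs on the filtered set), so
`selected = pass_stage1 & pass_stage2 & pass_auc` and the selected set is
nested within the stage-2 and stage-1 survivor sets by construction.

## MethyLight calling

Each (sample, specimen, target) assay is a Ct triplicate with a 50-cycle
protocol cap; non-amplifying replicates arrive as "Undetermined" and are
never converted to a numeric Ct. The replicate mean uses amplified
replicates only, and a target counts as *detected* when at least 2 of 3
replicates amplified (configurable quorum; the underlying protocol gives
no explicit rule, so the quorum is this package's construction, chosen to
reject single-replicate artifacts without demanding perfect triplicates).

The paired-tissue rule — hypermethylated if ΔCt = C̄t(normal) −
C̄t(tumour) > 2, hypomethylated if ΔCt < −2, both strict — is applied to
Alu-normalized mean Ct by default. The published description states the
rule on mean Ct while also stating that Alu normalizes DNA input; since
raw cross-specimen Ct differences are confounded by input amount, the
normalized form is the default and raw mode sits behind
`normalize_ct_to_alu = False`. The rule is invariant to adding a common
constant to both normalized Cts, which is exactly the invariance Alu
normalization is meant to confer. A tumour target that never amplifies
while its Alu control does is *undetectable methylation*; a failed Alu
control makes the sample *invalid*, since no methylation signal cannot be
distinguished from no DNA. The degenerate case of a normal specimen with
no detectable methylation but a methylation-positive tumour is called
hypermethylated (a gain over zero background).

Stool samples get a binary call: methylated iff both target and Alu are
detected.

## ddPCR quantification

Replicate wells are pooled by exact integer summation ("merged well");
the estimator depends only on the pooled counts, so k identical wells
yield the single-well estimate. With negative fraction p̂ = n⁻/n and
droplet volume V_d, λ̂ = −ln p̂ and concentration = λ̂/V_d. V_d defaults
to 0.85 nL (8.5 × 10⁻⁴ µL), the QX200 droplet-generator convention; every
quantification is parameterized by it.

Two interval methods: the delta method, SE(λ̂) = √((1 − p̂)/(n·p̂)),
normal interval clipped at 0; and an exact route that computes a
Clopper–Pearson binomial interval on p_neg and maps it through
−ln(·)/V_d (monotone decreasing, so bounds swap). `auto` (default) uses
the exact interval when fewer than 10 positive or 10 negative droplets
were observed — where the normal approximation fails — and the delta
method otherwise. Edge cases: zero positives → concentration 0 with a
one-sided upper bound; zero negatives (saturated) → flagged, NaN point
estimate, one-sided lower bound only — never a silent infinity. Detection
requires ≥ 3 positive droplets in the merged well (common ddPCR practice;
the source protocol reports calls without stating a rule), configurable.

## Expression statistics

ΔCt = gene mean Ct − TFRC mean Ct per specimen; ΔΔCt = ΔCt(tumour) −
ΔCt(normal) per matched pair; fold change 2^(−ΔΔCt). Group inference runs
Welch's t-test on ΔCt values (not on fold changes, whose ratio
distribution is skewed): t = (x̄₁ − x̄₂)/√(s₁²/n₁ + s₂²/n₂) with
Satterthwaite degrees of freedom and a two-sided p from the t
distribution. Zero-variance corner cases are flagged degenerate (t = 0,
p = 1 for equal means; p = 0 otherwise). Regulation calls use α = 0.05 —
the weakest significance tier the source figures annotate — with
direction read from the group means (higher tumour ΔCt, or lower tumour
band ratio, = downregulated); no correction across the four genes is
applied, matching the source analysis. Protein bands are normalized
lane-wise to NaK-ATPase and duplicates averaged per sample before
testing; samples lacking lysate for a target are recorded by omission and
excluded.

Per-pair fold changes are reported alongside the group test (the default
aggregation); the group-level test never runs on the ratios themselves.

## Synthetic-data generator

The generator's defaults define the study conditions; they are not tuned
per experiment.

**Methylation.** β ~ Beta(mean, precision κ = 500), i.e. SD ≈ 0.022 at
mean 0.5 — tightly dispersed, deliberately *well separated* so that
parameter recovery is an implementation check, not a power study. Of 74
CGIs, 24 true biomarkers (normal mean 0.10, tumour mean 0.50: the planted
effect straddles the 0.45 prevalence gate with margin), 20 stage-1 decoys
(normal mean 0.35), 18 stage-2 decoys (tumour mean 0.35), and 12
AUC decoys: tumour mean 0.50, but a fixed 25 % subset of normals at
β ≈ 0.60 (the rest at 0.08), which keeps the normal mean at ≈ 0.21 and
the high-normal fraction exactly at the inclusive 25 % boundary while
capping the AUC near 0.75 in both cohorts. The counts reproduce the
74 → 36 → 24 cascade narrowing. Cohort sizes: 18/4 discovery, 100/40
validation. `beta_precision = inf` gives point masses for degenerate
exact-recovery tests.

**Patients.** Ten patients; each carries a per-target tumour methylated
concentration, lognormal around 75 copies/µL (log₁₀ SD 0.4). The tissue
specimen sees it scaled by specimen purity — 1.0 (six patients), 0.1 (two
low-purity patients, landing at ΔCt ≈ 1, i.e. not differentially
methylated), or 0.0 (two specimens that missed the tumour, giving
undetectable methylation) — reflecting the histopathological explanation
that discordant tissue calls track tumour-cell content. The matched
normal carries a 1/20 background, so a pure specimen gives ΔCt ≈ log₂ 20
≈ 4.3. Stool sees the *patient's* concentration (not the specimen's)
diluted 1/50; one designated patient sheds no tumour DNA into stool
(both assays negative, as observed for one study patient).

**qPCR.** Each replicate first draws its template-molecule count from
Poisson(concentration × input volume × efficiency); zero molecules — or a
response beyond the 50-cycle cap — is "Undetermined"; otherwise
Ct = 40 − log₂(molecules) + N(0, 0.3²) (slope 1 cycle per doubling).
MethyLight efficiency is 1.0 in tissue but 0.12 in stool, modelling the
PCR inhibitors in stool DNA that degrade bulk qPCR but not partitioned
ddPCR — this single knob produces the MethyLight-miss / ddPCR-hit regime
at realistic stool concentrations. Alu is simulated as an abundant,
methylation-independent reaction (Ct ≈ 20).

**ddPCR.** Per well, droplet count ~ Poisson(20 000); positives ~
Binomial(n, 1 − e^(−c·V_d)) with c the in-reaction concentration (5 µL
sample into a 20 µL reaction); three wells per assay.

**Expression/protein.** Gene ΔCt baseline 6 cycles with biological SD 0.5
across samples; planted ΔΔCt of 2.0 (GRIA4), 1.5 (VIPR2, SPOCK1) and 3.0
(SLC6A3 — the largest effect, as observed). Protein tumour/normal ratios
0.30/0.80/0.40/0.25 with lognormal biological (SD 0.25) and measurement
(SD 0.15) noise; VIPR2's mild effect under this variability is typically
non-significant at the protein level, mirroring the study's outcome.

**What passing does not show.** The generator draws well-separated,
unit-variance-free Beta β values without probe-level structure, batch
effects, cell-type composition or tumour-purity continua; qPCR noise is
homoscedastic Gaussian on the cycle scale; droplet classification is
error-free (no "rain"). Green tests therefore demonstrate correctness of
the estimators and decision rules under their stated models — not
clinical performance of the biomarkers on real arrays or real stool.

## Problem sizes

Statistical checks use 20 seeds for cascade recovery and assay-ordering
runs, 10⁴ simulations for estimator bias and Welch type-I calibration
(lognormal σ = 0.25 null), 5 × 10³ for CI coverage, 10⁵ for the
parametric-bootstrap CI cross-check, and 200/1000 random instances for
the AUC brute-force and antisymmetry checks — sizes at which the
Monte-Carlo standard error is comfortably inside each asserted tolerance.

## Known limitations

* No probe→CGI aggregation: β matrices arrive CGI-level; how the original
  arrays were aggregated is not recorded in the source description.
* No PMR (percent-methylated-reference) quantification; the
  fully-methylated control is treated as a reaction control only.
* ddPCR copies are not back-calculated to copies per ng of input DNA.
* The stool MethyLight "methylated vs undetectable" boundary is the
  detection quorum, a package construction; no published numeric rule
  exists for it.
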