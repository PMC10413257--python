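# Methods

## Scope and model of the data

`luxuptake` re-implements, as a tested pipeline, the analysis used to
dissect how constitutive overexpression of a master phosphate-starvation
regulator (a Myb-type transcription factor, PSR1 in *Chlamydomonas
reinhardtii*) rewires the transcriptome and drives luxury phosphate
uptake in batch culture. The experimental design it models is: one
untransformed control line plus a strong and a weak overexpressor,
sampled at culture days 2, 3 and 6 in biological triplicate for RNA-seq,
with daily physiology (biomass dry weight, medium PO4-P "PE", biomass P
"PI", medium Mg, medium NH4-N) over 7 days; and a published
phosphate-starvation reference experiment with two timepoints ("early",
"late") in wild-type and regulator-null (*psr1-1*) backgrounds, available
only as fold changes without adjusted p-values.

## Expression quantification

Expression is RPKM: count / (gene length in kb) / (total assigned reads
in millions). The per-sample total is metadata of the count matrix — all
assigned reads, not the column sum of whichever gene subset is loaded —
so RPKM and CPM are stable under gene filtering. Gene lengths come from
a two-column TSV or from GFF3, where a gene's length is the union
(merged intervals) of its exons; a plain per-transcript sum would
double-count alternatively spliced regions.

Transgene- and endogenous-specific expression (e.g. a reporter CDS vs
the native gene's UTRs) is quantified by exact bidirectional substring
matching of reads against fragment sequences on both strands. This
replaces a per-sample BLAST database + `blastn` step: for error-free
reads exact matching is equivalent, deterministic and dependency-free.
Reads matching several fragments are counted for all and flagged rather
than resolved. Fragment RPKM uses the fragment's own length.

## Differential expression stand-in

The original analysis used DESeq2; here the classifier only consumes
per-contrast FC and adjusted p-values, so the package provides a simple,
fully documented stand-in and an importer for external tables. Fold
change is the ratio of group-mean CPM plus a pseudocount (default 0.5
CPM, which bounds FC on zero counts); the p-value is a two-sided Welch
t-test on log2(CPM + pseudocount) with Benjamini–Hochberg adjustment
within each contrast. This satisfies FC(A,B)·FC(B,A) = 1 at fixed
pseudocount. The stand-in performs no dispersion shrinkage, independent
filtering or median-ratio normalisation: on data where a large,
direction-biased fraction of the library shifts, CPM fold changes absorb
a composition bias that DESeq2's size factors would remove. On real
data, importing DESeq2 output restores full fidelity; the synthetic
generator avoids the bias by construction (below).

## Gene classification

A gene enters the overexpression-responsive set iff, for at least one
transgenic line at at least one day, FC > 2 or FC < 0.5 (strict). Its
direction is the sign of the greatest-|log2FC| change across all
(line, day) cells; exact ties resolve toward the earlier day, then the
stronger line (the published analysis never met a tie; the rule is for
determinism only). Venn letters record membership: A = strong line,
B = weak line, C/D = |FC| > 2 in the reference wild-type early/late
contrast. Classes pool sectors: I = ABC/D, II = A or AC/D,
III = B or BC/D, IV = AB. Genes absent from the reference get
C = D = false.

Ectopic / regulator-independent calls use the mutant-background
reference. ΔFC between backgrounds is a fold ratio,
max(FCwt, FCmut)/min(FCwt, FCmut): a difference of FCs has no scale-free
meaning. Each gene is called once, anchored at the contrast with the
larger mutant |log2FC| (the published tables carry one call per gene but
do not say which contrast anchors it). Ectopic: mutant-significant and
wild-type either non-significant or ΔFC > 2. Independent: ΔFC < 2, same
direction, significant in both. A gene meeting both is resolved as
independent, the stricter concordant condition.

`pca_reassign` mimics a manual step in the source analysis where a
handful of genes were relabelled after inspecting the FC-profile PCA
biplot. The stand-in is nearest-centroid-with-margin: a gene moves to
class k only if k's centroid (first two PCs) is more than 20% closer
(default margin 0.2) than its own class's centroid; classes with under
3 members contribute no centroid. The end-to-end report computes and
exports the PCA but applies reassignment only when configured
(`apply_pca_reassign`), because automatic reassignment is unreliable
where it matters most: Classes I and IV differ only by reference
membership, which the FC-profile PCA cannot see, and a class containing
both induced and repressed genes has a centroid between its two lobes.
The operation is intended for interactive use with a chosen margin, as
in the original analysis.

## Correlation and ordination

Profiles are per-gene vectors on an ordered (line, day) axis: six points
(2 transgenic lines × 3 days of mean log2FC) or nine points (3 lines ×
3 days of replicate-mean RPKM normalized per gene to its maximum).
Physiology covariates (PE, PI, N) are aligned on the same axis. Pearson
r uses the standard product-moment formula with a two-sided t test on
n−2 df; zero-variance vectors yield an undefined (flagged) r, never 0.
PCA is the SVD of the centered gene × axis matrix (genes are
observations); variables are not scaled to unit variance by default
because log2FC and normalized RPKM are already comparable across axis
points (configurable). Components are oriented so each one's
largest-magnitude loading is positive, making signs reproducible.

## Batch-culture kinetics

* µ = ln(y1/y0)/(t1−t0) over the log-phase window, default days 1–4.
* Doubling time = ln 2/µ.
* Biomass productivity Bp = (Bc_final − Bc_initial)/t with t = 7 d.
* R_max: daily removal computed as concentration(d−1) − concentration(d)
  — previous minus current, so a declining nutrient gives a positive
  rate — maximised over days and converted to mM/day with element molar
  masses P 30.97, Mg 24.31, N 14.01 g/mol. PO4-P and NH4-N
  concentrations are element-mass based, as the assays report.
* Nutrient consumption V = (CN0 − CN1)/(Bc1 − Bc0) over the window, in
  mg nutrient per g dw. The source prints this expression as a product,
  but its stated units (mg g⁻¹ dw) force the division; the division is
  implemented.
* Uptake rate k: three modes are exposed because the source's verbal
  definition (V/µ) carries units mg g⁻¹ d, while its results table
  reports mmol g dw⁻¹ d⁻¹. Default `times_mu` (V·µ) is the only form
  with amount · g dw⁻¹ · d⁻¹ units and equals the steady-state specific
  uptake rate during balanced exponential growth; `paper` (V/µ) and
  `per_day` (V/Δt) are available. No claim is made about which the
  original authors computed.

## Synthetic data generator

The generator is first-class, tested code that defines the study
conditions for every end-to-end check.

Counts: 2,000 genes × (3 lines × 3 days × 3 replicates), negative
binomial with overdispersion φ = 0.05 (variance m + φm²), falling back
to Poisson below φ = 1e-8. Per-gene baselines are lognormal (σ = 1)
around 80% of the mean library size (10⁶) divided by the gene count;
the remaining ~20% of each library stands for unannotated reads, and the
per-sample totals recorded as metadata are the true library sizes
(jittered ±5% lognormally). Because totals are true library sizes, CPM
ratios are unbiased by the planted regulation; this is the generator's
stand-in for the size-factor normalisation a full DE engine would do.

Regulation: genes are assigned to classes with default fractions
I 0.06, II 0.20, III 0.12, IV 0.06, null 0.56 and direction up with
probability 0.7 (the published responsive set skews ~2.5:1 up). A
regulated gene's |log2FC| is the configured effect (default 2.5)
jittered ×exp(N(0, 0.1)), constant across days within an affected line,
scaled by line strength (strong 1.0, weak 0.8) except for Class IV,
which responds equally in both lines — matching the observed lack of
dose dependence of that class. Class I/IV affect both lines, II only the
strong, III only the weak; Class I and half of II/III genes are planted
into the wild-type reference (early, late or both, |log2FC| 1.5–2), the
reference direction agreeing with the overexpression direction 80% of
the time. Constant-across-days effects mean the generator does not
emulate the day-3 expression peaks seen in the real data; the
classification scheme consumes only per-line maxima over days, so
recovery results are unaffected, but temporal-peak analyses would need a
richer profile model.

Mutant-background planting: 25% of in-reference regulated genes are
independent (mutant log2FC = wild type ± U(0.35)), a further 15% ectopic
(amplified by >2-fold ratio or flipped); 25% of out-of-reference
regulated genes are ectopic (mutant-only significant). All other
in-reference genes are silent in the mutant — i.e. regulator-dependent —
so non-planted genes cannot satisfy either call by construction.

Physiology: logistic biomass y(t) = K/(1 + ((K−y0)/y0)e^(−µt)) sampled
at integer days, y0 = 0.001 g dw/L, K = 3 g dw/L, per-line µ of
1.44/1.33/1.42 d⁻¹ (control/strong/weak, mirroring the published
growth-rate range). Daily P removal is Monod-like,
uptake_scale · biomass · PE/(PE + Km) with Km = 5 mg/L and per-line
uptake scales 12/80/35 mg P g dw⁻¹ d⁻¹ (control partial removal; strong
line complete early removal, luxury-uptake scale). Mg falls at the P
molar rate divided by the configured P:Mg ratio (default 2.5, inside the
published 2–3 molar band), so the realised R_max ratio recovers the
parameter exactly when no floor is hit. Biomass P (% dw) is cumulative
medium P loss divided by biomass — mass conservation holds to machine
precision and is asserted per line per day. PI starts at 0% (no baseline
cellular P is modelled). With these defaults the daily-sampled logistic
is close enough to exponential over days 1–4 that the log-phase
estimator recovers µ within ~2.5%; the stated tolerance is 5%.

Reads/fragments: four random fragments (reporter CDS 300 nt, native CDS
400 nt, 5'/3' UTRs 150 nt), validated pairwise non-substring on either
strand; fixed-length 75 nt reads drawn uniformly, half
reverse-complemented, each verified to match only its source fragment,
so exact-match counting must reproduce the planted depths exactly.
Sequencing error and base qualities are out of scope (the counter is
exact-match).

Everything is driven by `numpy.random.default_rng` seeded per stage from
the configured seed; identical config + seed gives byte-identical
outputs.

## What the synthetic tests do and do not show

Passing recovery tests show the set algebra, thresholds and calculators
are implemented correctly and that the whole chain is consistent under
the stated noise model. They do not show the CPM/Welch stand-in matches
DESeq2 on real data (no shrinkage, no composition correction, n = 3
t-tests are underpowered for small effects), nor that real biology is as
separable as the planted effects (|log2FC| ≥ ~2 against φ = 0.05 noise
is an easy detection problem by design — the point is correctness of the
logic, not power).

## Numerical choices

Strict inequalities at every cutoff (FC > 2, p-adj < 0.05), matching the
published phrasing; ties in ranked lists break by gene id;
Welch t on identical groups yields NaN, mapped to p = 1; genes with
all-zero profiles are dropped (with a warning) before max-normalisation;
fold-change tables reject non-positive FC at parse time with the line
number. Problem sizes in tests (300-gene bundles for structural tests,
the full 2,000-gene bundle for recovery) keep the whole suite in a few
seconds.

## Known limitations

Only day-matched transgenic-vs-control contrasts are produced (the
handling of starter-culture d0 samples in the source DE analysis is
unspecified). GO/functional-role annotation, curation of donut
categories and ANOVA across lines are out of scope. The ectopic /
independent anchor-contrast choice and the ΔFC-as-ratio reading are
documented interpretations of an underspecified published rule; both are
configurable.
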