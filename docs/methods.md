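# Methods

This note documents the models and procedures implemented in `enhancerkit`,
the assumptions behind them, the choices made where the design was open, and
what the synthetic-data tests do and do not establish about real data.

## Coordinate and overlap conventions

All coordinates are 0-based half-open (BED). "Overlap" always means at
least one shared base, so abutting half-open intervals do not overlap;
merging is a coverage union and therefore joins touching intervals. Strand
is ignored for all enhancer arithmetic (histone marks are unstranded) and
used only to orient gene TSSs. Paired-end fragments are represented as
single intervals; a pair counts once, consistent with scaling to one
million total paired fragments. A fragment overlapping two regions is
counted in both — per-region counts are treated as independent, since the
procedure never sums counts across regions.

## Enhancer definition

The co-occupancy rule keeps merged H3K27ac regions supported by ≥ 2 of the
4 samples (any two samples; the rule does not require one per condition)
that overlap a ≥ 2-supported merged H3K4me1 region by ≥ 1 bp. The retained
footprint is the H3K27ac region, because all downstream quantification is
H3K27ac-based; H3K4me1 only gates membership. Exclusion of promoters
(TSS ± 1000 bp), exons and H3K4me3 peaks is by ≥ 1 bp overlap.

## Differential enrichment model

Enrichment is `log2((Count_ChIP + 1)/(Count_input + 1))` on per-million
scaled counts; the +1 pseudocounts keep the score finite at empty regions.
Columns are quantile-normalized (reference distribution = per-rank means of
the sorted columns; ties receive the mean of their ranks' reference
values). The treated-vs-control test is a per-enhancer two-group linear
model with empirical-Bayes variance shrinkage: residual variance s² with
d = n₁ + n₂ − 2 df, posterior s̃² = (d₀s₀² + ds²)/(d₀ + d), moderated
t = logFC/(s̃·√(1/n₁ + 1/n₂)) referred to Student t with d + d₀ df. The
prior (d₀, s₀²) is estimated by moment matching on log s² via
digamma/trigamma inversion; a non-positive moment estimate of the excess
variance falls back to d₀ = ∞ (one shared variance, normal reference).
d₀ = 0 reduces exactly to the pooled-variance two-sample t (verified to
10 decimals against an independent implementation), and the estimated fit
was cross-checked during development against a reference empirical-Bayes
implementation on a frozen matrix (agreement ~1e-9 in t and p).

Classes: up if logFC ≥ 1 and BH q < 0.05, down mirrored; the unaffected
background is |linear fold| ≤ 1.05 (the lowest-difference band used as a
contrast set); everything else is "other". "Fold change ≥ 2" is read as a
difference of ≥ 1 in quantile-normalized log2 enrichment — a
ratio-of-log-scores reading would be ill-defined near zero. The de-novo
thresholds (treated > 1.5 with control < 1.1, and the mirror) are applied
to the log2 enrichment, the quantity defined immediately before them;
`scale="linear"` applies them to the linear ratio instead for users who
read "ChIP enrichment signals" as unlogged. Enhancers with an undefined
statistic (zero variance at d₀ = 0) are excluded from BH and labeled
"other".

## Super-enhancers

Stitching chains enhancers whose end-to-start gap is ≤ 12,500 bp. No
TSS-exclusion is applied during stitching: the input catalog is already
promoter-filtered, and BRD4-peak mode runs the same way for symmetry.
Signal is background-subtracted rpm over the stitched span, replicates
averaged after per-million scaling, floored at 0; a missing input track
falls back to unsubtracted ChIP rpm with a logged warning. The rank-curve
cutoff scales ranks and signals to [0, 1] and takes argmax(x − y), the
point where a slope-1 line is tangent below the convex hull of the curve;
ties break to the highest-signal index, which yields conservatively few SEs
on flat curves, and a completely flat vector yields zero SEs. SE means
signal strictly above the cutoff signal.

Differential SEs are evaluated on the union of SE spans from the two
conditions with overlapping spans merged and signals recomputed on the
merged span, so each locus is classified exactly once. Fold change uses an
ε = 0.1 rpm pseudo-signal (configurable) to avoid division by zero;
gained ⇔ fc ≥ 2, lost ⇔ fc ≤ 0.5. Swapping conditions maps gained ↔ lost
exactly, with fc → 1/fc up to the small ε asymmetry.

## Expression integration

"A.U." is TMM-scaled counts per million. The source analysis never defines
its arbitrary unit; TMM-CPM is the natural edgeR-normalized unit and makes
the 100 A.U. floor library-size-free. The TMM implementation follows the
standard recipe (30% log-ratio trim, 5% A trim, inverse-variance weights,
reference column by 75th-percentile proximity to the mean, factors centered
to geometric mean 1) and reproduces a reference implementation to ~1e-9 on
a frozen matrix. The DE rule is coverage ≥ 10 in either sample and linear
fold ≥ 1.5 in either direction, with no significance test — the integrated
expression data are a two-sample design without replicates, so a test is
not possible; "coverage" is taken as normalized A.U. (the rule is then
scale-free).

Gene assignment uses two deliberately different rules, as in the source
procedure: differential enhancers link to every DE gene with TSS within
± 250 kb of the enhancer boundaries (many-to-many); SEs and TEs map to the
single closest expressed gene (> 100 A.U. in either condition) with TSS
within ± 50 kb of the region center. The gene side of the ± 50 kb rule is
the TSS (consistent with the ± 250 kb rule; whole-gene-body distance is the
other defensible reading). Distance ties break to the lexicographically
lower gene_id, making the mapping deterministic. Genes claimed by both an
SE and a TE keep only the SE link; expressed genes with no region within
the window are "no_enhancer" genes. Contribution summaries report
100·(ΣA.U._trt − ΣA.U._ctrl)/ΣA.U._ctrl over SE-associated genes and
per-SE-class contributions in percentage points of the same denominator,
which therefore sum exactly to the total. The up/down gene partition uses
|log2 fc| > 1.

## lncRNA–enhancer overlap test

The statistic is the number of enhancers overlapping ≥ 1 lncRNA (the
lncRNA-side count is also reported). The null re-places *both* sets each
simulation, preserving observed element lengths — the stricter, standard
null; elements of a set may overlap each other (independent placement).
Each element picks a chromosome with probability proportional to its valid
start positions (L_c − a + 1) and a uniform start within it. The empirical
p is the add-one estimator (1 + exceedances)/(1 + n_sims), never zero; with
10,000 simulations the smallest attainable p is 1/10001 < 10⁻⁴.
Implementation: lncRNA placements are merged into a coverage union and
enhancer membership against the sorted disjoint union is two binary
searches, giving ~6 ms per simulation at 42,076 + 466 elements.

## qPCR formulas

2^−ΔΔCt with ΔCt = Ct_target − Ct_reference per condition; percent input is
100·2^−(Ct_ChIP − Ct_100%input) with Ct_100%input = Ct_input −
log2(1/input_fraction), the dilution correction for the fraction of
chromatin saved as input (default 10%; the correction is switchable since
published percent-input values do not always state whether it was applied).
Amplification efficiency is fixed at 2 — the formulas assume perfect
doubling and no efficiency calibration is offered, to stay faithful to the
stated quantification.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes on a
toy genome (default 2 × 50 Mb — large enough for ± 250 kb windows and
12.5 kb stitching without edge effects, small enough for seconds-scale
tests):

* **Placement.** Elements occupy random slots separated by ≥ 15 kb (above
  the stitch gap), so singleton enhancers never stitch together; cluster
  constituents sit 2–8 kb apart. Genes linked to an enhancer are placed
  5–40 kb downstream so that neither their exons nor their promoter windows
  touch the enhancer.
* **Counts.** Every track receives uniform genome-wide background at
  `background_rate` expected fragments per 2 kb of region (default 20);
  ChIP tracks add Poisson (default) or negative-binomial signal fragments
  at active enhancers. Signal magnitudes are solved per region so the
  expected enrichment hits planted targets at unit library scaling: active
  enhancers sit at the enrichment implied by `signal_rate` (default 63
  fragments, ≈ 2.0 log2 units over a 20-fragment background), "up"
  enhancers gain exactly `effect_size` log2 units in the treated condition,
  and de-novo enhancers idle at 0.5 (below the 1.1 threshold) when off with
  their active state `effect_size` higher. Because the realized library
  size of a ChIP track includes its signal fragments, realized absolute
  enrichments sit slightly (~0.2 log2 units) below the planted targets
  while planted *differences* are preserved; the classification margins
  absorb this.
* **Inputs.** One input track per ChIP replicate. With a shared
  per-condition input, input noise would be common within groups but
  independent between them, entering the contrast without entering the
  residual — the moderated t would be anticonservative by construction.
  Per-replicate inputs keep the null test calibrated (verified: rejection
  at α = 0.05 within 0.05 ± 0.02).
* **Peaks.** Every planted enhancer gets boundary-jittered peaks in both
  replicates of each condition where it is active (so the ≥ 2-of-4 rule
  retains it; de-novo elements are active in one condition only), H3K4me1
  peaks in all samples, plus spurious single-sample peaks the support rule
  must discard and decoy co-occupied regions that only the promoter/exon/
  H3K4me3 filters can remove.
* **Expression.** Baselines are log-normal (median 300 counts); genes
  linked to up/down enhancers or gained/lost clusters shift by
  ± `expr_effect` log2 units (default 1.0, i.e. planted fold 2 ≥ the 1.5 DE
  threshold); counts are gamma-Poisson with dispersion 0.05.
* **lncRNAs.** A configured fraction (default 0.3) is planted overlapping a
  random enhancer; the rest are uniform.

Everything derives from one seeded numpy Generator; a fixed seed reproduces
the experiment bit for bit.

What the generator does **not** model: sequence content, mappability and
GC structure, peak-caller artifacts, correlated background (fragment
clumping), chromatin-state autocorrelation along the genome, antibody
efficiency differences between marks, and multi-condition designs beyond
2 × 2. Passing recovery tests therefore demonstrates that the pipeline's
logic and statistics behave as specified under the assumed noise model —
not that the thresholds are optimal for any particular real dataset.

## Problem sizes and numerical choices

The planted-recovery checks use 500 singleton enhancers over 5 seeds
(sensitivity/FDR of up-down calls), 5 × 5 clusters for SE recovery, 10,000
simulations at the published scale (42,076/466 elements on a
2,718,881,021 bp single-axis genome) for the overlap bound, and 1,000
replicate experiments at 1,200/300 elements on 40 Mb with 199-simulation
nulls for calibration — sizes chosen so each check's Monte-Carlo error is
small against its acceptance band while the whole suite runs in minutes.
The calibration configuration keeps the expected null overlap count around
20 so that the discreteness of the count statistic (tie mass at the
rejection boundary) costs at most ~1 percentage point of rejection rate.
Degenerate inputs are defined, not special-cased: empty interval sets
propagate as empty results; flat signal vectors yield zero SEs; zero
variance with d₀ = 0 yields a missing statistic excluded from BH; an empty
null distribution is an error.

## Known limitations

* The moderated test assumes approximately normal enrichment scores;
  at very low fragment counts (≪ 10 per region) the log2 scores are
  discrete and calibration degrades.
* TMM and the DE rule follow the two-sample integration design; replicated
  expression designs would warrant a proper count model (e.g. a negative
  binomial GLM), which is out of scope here.
* The overlap null is uniform placement — no GC/mappability matching or
  exclusion zones; observed significance against this null conflates
  enhancer-lncRNA association with any shared non-uniformity of the two
  sets along the genome.
* H3K4me1 fragment tracks are not simulated (peaks only): the differential
  machinery is mark-agnostic and H3K27ac drives every classification, so
  the H3K4me1 differential path is exercised through the same code on
  H3K27ac data.
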