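# Methods

This note documents the models, estimators, numerical choices and
known limitations of the package, in the order the analysis chain runs.

## Variant QC and LD pruning

Genotypes are stored as alternate-allele dosages (0/1/2, −1 missing)
in a dense samples × sites matrix; coordinates are 0-based half-open
internally, converted at the VCF/GFF3 boundary (both 1-based
inclusive).  Site filters: minor-allele frequency computed over
non-missing calls (default minimum 0.05), missing-call fraction
(default maximum 0.20), and — when per-site depth is recorded — mean
depth within [⅓×, 2×] of the genome-wide mean.  Sites with every call
missing are removed and counted.  The filter is idempotent.

LD pruning follows the 50-SNP / 10-SNP / r² > 0.2 sliding-window
convention.  The removal rule is deterministic: within each window,
pairs are scanned in left-to-right index order and the later site of
an offending pair is dropped.  Because removals can bring previously
distant sites into the same window, passes repeat until a fixpoint, so
the output set itself satisfies the within-window r² bound.  r² is the
squared Pearson correlation of dosages over pairwise-complete samples;
undefined correlations (constant dosage, <2 complete pairs) count as 0.

## SNP effect classification

Gene models (gene → mRNA → exon/CDS with phase) come from GFF3 via
`gffutils`.  Coding SNPs are translated through the standard nuclear
code with strand handling; classes are synonymous, nonsynonymous,
stop-gain, stop-lost, splice-site (first/last 2 intronic bases),
intronic, upstream/downstream (5 kb flanks, configurable) and
intergenic.  Non-coding exonic (UTR) positions are pooled with
intronic: both are genic and non-coding, and the class menu does not
distinguish them.  When several transcripts or genes overlap a site,
the most severe class wins (stop-gain > stop-lost > nonsynonymous >
splice-site > synonymous > intronic > upstream > downstream >
intergenic).  Transcripts whose phase-adjusted CDS length is not a
multiple of 3 are skipped with a warning and the site falls back to
the genic non-coding class.  A reference-allele mismatch against the
FASTA is logged, not fatal.

## Diversity, differentiation, LD decay

Per-site π is the unbiased pairwise-difference estimator
2j(m−j)/(m(m−1)); window π divides by the full window length in bp
(not callable sites), matching the per-bp convention of the common
windowed tools; windows with fewer than `min_sites` SNPs report NaN.
Heterozygosity is heterozygous-call count divided by a caller-supplied
genome length (assembly length by default; a callable-length
denominator is the caller's choice).

F_ST uses the Weir–Cockerham (1984) two-population variance
components computed from genotype counts (so heterozygote frequencies
enter through h̄), aggregated per window as Σa/Σ(a+b+c).  Raw values
are kept — slightly negative windows are meaningful for empirical
quantiles and are not clamped.  Sites where either sample has no
called individual, or n̄ ≤ 1, are excluded.

The LD decay curve bins pairwise r² by physical distance (100 bp bins,
500 kb maximum) after re-filtering sites within the target population
(MAF ≥ 0.05, missingness ≤ 0.2).  Binned means are smoothed with a
weighted isotonic *decreasing* fit (pool-adjacent-violators) before
the half-decay distance is read off, which prevents noise-induced
early crossings; the half-decay distance is the left edge of the first
bin at or below half of the smoothed maximum.

## ABBA-BABA and f4-ratio

Sites are polarized by the outgroup consensus: only sites where the
outgroup sample is fixed (among called copies) are used; the fixed
allele is ancestral.  Pattern sums are frequency-weighted:
ABBA = Σ(1−p1)p2p3, BABA = Σp1(1−p2)p3 over polarized derived
frequencies.  Significance uses a delete-one block jackknife over
fixed physical blocks (1 Mb default); fewer than 20 non-empty blocks
triggers a warning, not an error.  The f4-ratio splits the donor
population P3 into two halves (first/second half of its sample list,
or explicit subsets) and reports
f4(P1,P2;P3a,O) / f4(P1,P3b;P3a,O), the standard admixture-fraction
estimator.  Note that published f4-ratio values from other toolchains
may use different subset conventions; this package documents and fixes
one.

## Folded SFS and demographic inference

The observed spectrum is the joint minor-allele-count histogram over
complete-case sites (any missing call in a selected sample drops the
site), folded by total count; cells on the fold diagonal keep half of
the combined mass, so counts can be half-integers (the likelihood uses
Γ-function factorials).  No projection is implemented: sample sizes
are taken as given.

Expected spectra are computed by Monte-Carlo branch-length averaging:
a coalescent with recombination is simulated under the model (msprime),
and the branch-mode joint allele-frequency spectrum — the expected
density of mutations per unit mutation rate — is averaged along a
genome whose map length carries `n_reps` units (about one marginal
genealogy each).  The reference diploid size inside the simulator is
N₀ = ½, which makes one generation equal one time unit of 2N_ref
generations, so sizes (ν, units of N_ref), times (units of 2N_ref
generations) and migration rates (2N_ref × fraction replaced per
generation) pass through unscaled; the spectrum is divided by 4N₀ so
that E[observed] = θ·expected with θ = 4N_ref·μ·L.  Because the
ancestral-recombination-graph cost grows superlinearly with map
length, the requested length is simulated in 2 000-unit chunks whose
spectra are averaged (seeded; deterministic).  The estimator is
validated against the analytic single-population folded spectrum
(η_i ∝ 1/i + 1/(n−i), halved at n/2; for n = 4, normalized
(8/11, 3/11)).

The Poisson composite log-likelihood is Σ[o·ln(θe) − θe − ln o!] over
live cells, with θ profiled analytically (θ̂ = Σo/Σe, exact for the
Poisson model).  Monte-Carlo expectations can put exactly zero mass in
a rare cell; such cells are floored at 10⁻⁵ of the spectrum's total
mass so a single empty cell cannot dominate.

Fitting follows a multi-start protocol: 50 starts, each multiplying
the model defaults by independent log-uniform factors in [⅓, 3], each
run through bounded Nelder–Mead (log-parameter transform) for at most
20 simplex iterations at low Monte-Carlo precision (200 reps) with one
fixed simulation seed (common random numbers — the objective is a
deterministic function of the parameters).  The low-precision surface
both displaces and mis-ranks optima, so three safeguards follow: every
start's endpoint is re-evaluated once at higher precision before
winners are chosen; the best candidates (two by default) are refined
through a precision ladder of Nelder–Mead stages, each preceded by a
one-dimensional line search along the spectrum's soft scale direction
(all sizes and times multiplied by c, migration divided by c — the
near-ridge of SFS-only inference, anchored only by the fixed ancestral
size, along which simplex descent crawls); and the overall winner gets
a final polish stage.  The reported log-likelihood, θ̂ and AIC are
evaluated once at 8 000 reps so fits of different models are
comparable.  Even so, the likelihood surface is multimodal and the
optimizer can settle in a wrong basin on some seeds; the verification
suite therefore runs two independent protocol replicates and keeps the
better likelihood, and its measured recovery errors quantify exactly
this limitation.  AIC = 2k − 2ℓ with k counting simplex parameters plus one
for the profiled θ (the flagship secondary-contact model has k = 8).
Ranking is ascending AIC; ties break toward fewer parameters, then
model id.

The catalog has 17 named three-population scenarios in five families
(nested splits p3-first unless stated): divergence with continuous
gene flow (4 variants: adjacent symmetric, all-pairs, adjacent
asymmetric, free intermediate-ancestor size), ancient migration (3:
migration only in the older epochs, stopping at a fraction of the
recent split time), secondary contact (3: isolation after the splits,
migration restarting in the most recent fraction of T2 — fixed ½ for
the 7-parameter flagship, free in an 8-parameter variant), simultaneous
three-way split (4: no/all/adjacent/asymmetric migration), and hybrid
origin (3: the middle population founded by an admixture pulse between
the outer two, optionally with ongoing migration).  Nested split times
are parameterized as (T2, T1d = T1 − T2), both positive, so T1 ≥ T2 by
construction.  Physical conversion: N_ref = θ̂/(4μL); Ne_i = ν_i·N_ref;
T_years = 2·N_ref·T·g; a migration parameter M (= 2N_ref·m) corresponds
to M·ν_receiving/2 migrant individuals per generation.

Defaults μ = 3.75×10⁻⁸ per bp per generation, g = 15 years,
L = 370.75 Mb are the constants appropriate for hazelnut-scale woody
perennials and are caller-overridable.

Confidence intervals are available through an explicit parametric
bootstrap (`parametric_bootstrap`): Poisson spectra simulated from the
fitted model are refit and percentile bounds reported.  It is off in
every pipeline default — refitting ~100 replicates is expensive — and
the parametric (rather than nonparametric block-resampling) form was
chosen because the composite likelihood treats cells as independent
Poisson counts, which is exactly the resampling a parametric bootstrap
performs.

Which SNP set feeds which statistic: effect annotation, diversity,
FST, the SFS and the sweep scan all run on the full filtered set; LD
pruning exists for structure-type analyses (trees, PCA, admixture —
outside this package's scope) and both paths are exposed, with the
`filter` stage's `--ld-prune` flag off by default.

## Sweep scan and the three-metric caller

The cross-population scan is a deliberately simplified XP-CLR variant.
Genome-wide drift is summarized by ω, estimated robustly as
median[(p_obj − p_ref)²/(p_ref(1−p_ref))]/0.4549 (the median of a
scaled 1-df χ²), so loci under selection do not inflate the neutral
model.  At each grid point (100 bp default step) the ≤200 nearest SNPs
inside a 0.05 cM window enter; the neutral model is a truncated normal
for p_obj centred on p_ref with variance ω·p_ref(1−p_ref) plus
binomial sampling variance; the sweep model says each SNP hitchhiked
to fixation or loss (a symmetric boundary mixture whose width is the
sampling noise) with probability λ·w(d), w(d) = exp(−d/(0.05 cM/4)),
and λ is maximized over a fixed grid.  The score is 2·(max ℓ_sweep −
ℓ_neutral) ≥ 0.  The genetic map is uniform cM/Mb (default 1.0) unless
a map is supplied.  Grid scores are reduced to the 100 kb/10 kb window
grid by within-window maximum, so the three metrics (F_ST, ln π-ratio,
XP-CLR) are thresholded on one grid; each metric's cutoff is its
empirical 95th percentile (type-7); windows flagged by all three are
merged (overlap or zero gap) into regions, and genes overlapping a
region by ≥1 bp are the candidate positively selected genes.  This
scan omits the original XP-CLR's LD-based SNP down-weighting and is
validated by planted-sweep power and neutral false-positive rate, not
by score equality with the original program.

## Niche statistics

Environmental redundancy pruning scans variables in input order and
drops any with |Pearson r| > 0.75 against an already-retained variable
(constant variables are dropped with a warning).  Suitability surfaces
are compared after joint renormalization on the shared valid mask:
D = 1 − ½Σ|a−b| and I = 1 − ½Σ(√a−√b)², both clamped to [0,1] against
floating-point residue at the endpoints.  The identity test pools the
two occurrence sets, re-splits them at random preserving sample sizes,
and recomputes D and I under a pluggable suitability model; the
default is a Gaussian KDE in standardized environmental space.  The
one-sided p-value uses the +1 correction and can never be 0.  Because
the default suitability model is a KDE rather than a maximum-entropy
model, absolute D/I values are not comparable with MaxEnt-based
studies; inference rests on the permutation null, and the package's
checks are calibration-based.

## Synthetic data

The generators produce every input the chain consumes, each
deterministic under its seed and paired with its ground truth:
coalescent genotype panels under any catalog model (diploid samples,
finite sites; multi-hit sites dropped); planted hard sweeps that
resolve one haplotype from a donor in the target population —
preferring a rare haplotype, since selection acts on initially
uncommon variants — and fix it homozygously in a chosen fraction of
samples; toy annotated genomes (two-exon genes on alternating strands,
5.5 kb intergenic blocks) with a truth table of SNPs whose classes are
derived by direct construction; and niche fixtures with two smooth
environmental gradients and Gaussian occurrence clouds separated by a
controllable effect size.

What the simulations do *not* emulate: sequencing/genotyping error,
missing-data structure, reference bias, variable recombination and
mutation maps, selection other than the planted copy-paste sweep, and
spatial sampling structure in the niche fixtures.  Passing checks
demonstrate correctness of the estimators under the model, not
robustness to those real-data artifacts.

## Problem sizes used in the verification suite

The test suite and `scripts/acceptance.py` run on deliberately modest
problem sizes chosen as the smallest at which each property is
statistically decisive: diversity/LD checks on 1 Mb panels of 10
diploids (θ/site = 10⁻³); D-statistic null calibration on 40 trio
simulations of 4 Mb with 20 jackknife blocks of 200 kb; demographic
recovery on a (6,6,6)-copy folded SFS with 50 000 SNPs under a
secondary-contact history with ν = (1.5, 2.0, 0.8), T2 = 0.2,
T1 = 0.5 and M = (2.0, 1.5) — magnitudes matching realistic recent
three-taxon divergences, with a long inter-split epoch so the scale is
anchored — and family ranking with one representative model per family
over 5 seeds; sweep power on ten 10 Mb two-population panels with one
planted 50 kb sweep each, and the false-positive rate on 20 Mb of
neutral simulation; niche calibration over 40 seeded fixtures with 99
permutations each.

## Known limitations

* The Monte-Carlo expected SFS makes the composite likelihood noisy;
  the refinement ladder controls but does not eliminate the resulting
  parameter displacement.  Very weak migration or very recent splits
  remain hard to resolve at the default simulation sizes.
* The folded SFS carries no linkage information; some parameter
  combinations (size vs. time rescalings) are weakly identified, which
  is inherent to SFS-only inference.
* The sweep scan's hitchhiking mixture is a phenomenological stand-in
  for the full XP-CLR model; its scores are comparable within a scan
  (ranks, quantiles), not across datasets.
* Block-jackknife SEs assume many roughly exchangeable blocks; with
  fewer than ~20 blocks the Z-score is unstable (a warning is issued).
* `ld_decay` is quadratic in sites per window and intended for the
  pruned/filtered panels it receives in this chain, not for
  genome-scale dense panels.
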