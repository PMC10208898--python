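# hazelpop

Population-genomic inference for multi-population SNP resequencing
panels, built around the analysis chain used in hazelnut (*Corylus*)
population studies: variant QC and LD pruning, SNP effect annotation,
windowed diversity and differentiation, ABBA-BABA introgression tests,
folded-SFS demographic model selection, three-metric selective-sweep
calling, and niche-overlap statistics.  Every stage is exercised
end-to-end on seeded coalescent simulations, so the whole chain is
testable without any external download.

## Who it is for

Researchers analysing whole-genome resequencing data from a few
closely related populations or sibling species (plant or otherwise)
who want a single, scriptable toolkit covering the standard descriptive
statistics *and* the model-based inferences (demography, introgression,
sweeps), plus the synthetic-data generators needed to validate each
step against known ground truth.

## The statistics at the core

* **Nucleotide diversity.** Per-site π = 2j(m−j)/(m(m−1)) for j
  alternate alleles among m called copies; windows report
  Σπ / window-length (per-bp), on a 100 kb / 10 kb sliding grid.
* **Weir–Cockerham F<sub>ST</sub> (1984).** Per-site variance
  components a, b, c from diploid genotype counts; windows use the
  ratio of sums Σa / Σ(a+b+c).  Raw values are reported (no clamping)
  so empirical top-5% thresholds are undistorted.
* **LD decay.** r² = squared Pearson correlation of genotype dosages
  over pairwise-complete samples, binned by distance (100 bp bins up to
  500 kb), isotonic-smoothed; the half-decay distance is where the
  smoothed curve falls to max r²/2.
* **Patterson's D / f4-ratio.** With outgroup-polarized derived
  frequencies p1, p2, p3: ABBA = Σ(1−p1)p2p3, BABA = Σp1(1−p2)p3,
  D = (ABBA−BABA)/(ABBA+BABA), with a delete-one block jackknife
  (1 Mb blocks) giving SE, Z and p.  The f4-ratio
  f4(P1,P2;P3a,O)/f4(P1,P3b;P3a,O) estimates the admixture fraction.
* **Demography.** Joint folded SFS over 2–3 populations; expected
  spectra per unit θ by seeded coalescent branch-length averaging
  (msprime); Poisson composite likelihood with θ profiled analytically
  (θ̂ = Σobs/Σexp); 50-start Nelder–Mead with threefold log-uniform
  perturbation; AIC = 2k − 2ℓ model selection over a 17-model catalog
  in five families (divergence-with-gene-flow, ancient migration,
  secondary contact, simultaneous split, hybrid origin).  Physical
  units via N<sub>ref</sub> = θ/(4μL), with μ = 3.75×10⁻⁸ per bp per
  generation and g = 15 yr as defaults.
* **Sweep scan.** A simplified XP-CLR: at each grid point a hitchhiking
  model (each SNP fixes/losses with probability λ·w(d), decaying with
  genetic distance) is tested against truncated-normal drift with
  genome-wide variance scale ω; the top-5% windows of F<sub>ST</sub>,
  ln(π-ratio) and XP-CLR are intersected, and merged regions are mapped
  to genes.
* **Niche overlap.** Schoener's D = 1 − ½Σ|a−b| and Hellinger
  I = 1 − ½Σ(√a−√b)² on normalized suitability rasters, with a
  pooled-resplit permutation identity test.

## Worked example

Simulate a three-population secondary-contact panel, filter it, and
measure diversity and differentiation:

```bash
hazelpop simulate --model sc_adjacent_sym --samples p1:6,p2:6,p3:6 \
    --length 300000 --seed 5 --out runs/sim
hazelpop diversity --vcf runs/sim/panel.vcf --popmap runs/sim/popmap.tsv \
    --pop-a p1 --pop-b p2 --window 50000 --step 50000 --out runs/div
cat runs/div/diversity.summary.json
```

which prints (numbers from this exact seed):

```json
{
  "genome_fst": 0.2150347679007705,
  "mean_pi_a": 0.0010914692185220998,
  "mean_pi_b": 0.0012287760541525893
}
```

Read: the two sister populations carry per-bp diversity of ~1.1×10⁻³
and ~1.2×10⁻³ (the simulation's θ/site was 10⁻³ in the ancestral
population; both daughters are modestly larger under the default
secondary-contact parameters), and the genome-wide Weir–Cockerham
F<sub>ST</sub> between them is ≈0.22 — moderate differentiation,
consistent with the recent split followed by renewed gene flow that
generated the data.  The same run writes per-window BED tables
(`fst.bed`, `pi_p1.bed`, …) for scanning.

The library surface mirrors the CLI: `hazelpop.read_vcf`,
`filter_variants`, `ld_prune`, `classify_snp_effects`, `window_pi`,
`wc_fst`, `ld_decay`, `abba_baba`, `build_folded_sfs`, `fit_model`,
`select_model`, `xpclr_scan`, `intersect_sweeps`, `schoener_d`,
`identity_test`, and the generators in `hazelpop.simulate`.

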