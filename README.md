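# breakscape

Genome-instability analyses for AID-driven B-cell malignancies, built as a
tested, reusable pipeline that runs end to end on synthetic data with known
ground truth.

Activation-induced cytidine deaminase (AID) initiates somatic hypermutation
and class-switch recombination in B cells; its off-target activity leaves
characteristic genomic footprints — translocation breakpoints near active
chromatin, C-centred mutations biased toward the non-template strand of
transcribed genes, hotspot motifs (RGYW and relatives) and G-quadruplex-prone
sequence. `breakscape` packages the computations used to characterize these
footprints:

* **Sequence annotation** — IUPAC hotspot-motif scanning (`RGYW`, `GAGCT`,
  `GGGGW`, `GGGCT`), G-quadruplex annotation (≥ 4 runs of ≥ 3 G separated by
  loops of ≤ 7 nt, stringent, or ≤ 30 nt, relaxed), GC-content and
  motif-density tracks.
* **Breakpoint meta-analysis** — interval merging, breakend-centred signal
  meta-profiles against chromosome-preserving shuffled backgrounds, distance-
  to-nearest-feature tests (two-sided Wilcoxon rank-sum vs. a shuffle null)
  and relative-distance (reldist) χ² tests.
* **SHM strand asymmetry** — somatic filtering (variants unique to one tumor
  and absent from controls), mutated-cytidine strand assignment against a
  stranded gene model, exact binomial test of the non-template fraction
  *b = n_NT / (n_NT + n_T)* against 0.5, and directional stranded-signal
  profiles.
* **Junction microhomology** — breakend shift-ambiguity (left + right) at
  single-nucleotide-resolved junctions, with group histograms and Wilcoxon
  comparisons.
* **Mutational signatures** — 96-class pyrimidine-centred trinucleotide
  spectra, optionally restricted to region sets, fitted to a signature
  catalog by non-negative least squares: min‖c/Σc − wᵀP‖₂ s.t. w ≥ 0,
  weights normalized to Σw = 1.
* **DamID occupancy** — DpnI (GA^TC) fragment maps, midpoint read counting,
  CPM normalization, Dam-only background subtraction, PROMPT-region
  construction and Mood's-median enrichment tests.
* **Contact matrices** — iterative proportional fitting (matrix balancing,
  balanced = F·M·F) of single-chromosome contact matrices and interval-pair
  "box" quantification with pairwise Wilcoxon comparisons.
* **Synthetic data** — seeded generators for every input (genomes with
  planted motifs/G4s, transcription units, proximity-biased breakpoints,
  signature-mixture SNVs with transcriptional strand bias, DamID reads with
  planted enrichment, distance-decay contact matrices with planted boxes),
  each returning its ground truth.

Small-sample statistics (exact Wilcoxon rank-sum, Fisher 2×2, Mood's median,
exact binomial, Pearson χ², Bonferroni scaling) are implemented in
`breakscape.stats` and validated against full-enumeration oracles.

## Worked example

```python
from breakscape.simulate import (
    SynthConfig, generate_genome, generate_transcription_units,
    generate_breakpoints, generate_snvs_from_signatures, random_catalog,
)
from breakscape.breakpoints import proximity_null_test, pairs_to_intervals
from breakscape.shm import select_cytidine_mutations, assign_transcriptional_strand
from breakscape.signatures import trinucleotide_spectrum, fit_signature_exposures

cfg = SynthConfig(seed=42)
cfg.genome.n_chroms = 2
cfg.genome.chrom_length = 200_000
cfg.transcription.n_units = 20
cfg.transcription.max_length = 8_000
cfg.snv.n = 2_000

genome, _ = generate_genome(cfg)
genes = generate_transcription_units(cfg, genome)
pairs, _ = generate_breakpoints(cfg, genome, genes)    # biased, sigma = 1 kb

res = proximity_null_test(pairs_to_intervals(pairs), genes, genome,
                          n_draws=100, seed=42)
print(f"observed median distance: {res.observed_median:.0f} bp")
print(f"shuffled median distance: {res.null_median:.0f} bp")
print(f"Wilcoxon two-sided p:     {res.wilcoxon.p_value:.3g}")

catalog = random_catalog(3, seed=42)
per_sample, _ = generate_snvs_from_signatures(cfg, genome, catalog, genes)
variants = per_sample["sample1"]
bias = assign_transcriptional_strand(select_cytidine_mutations(variants), genes)
print(f"non-template bias:        {bias.bias:.3f}  (binomial p = {bias.binomial.p_value:.3g})")

fit = fit_signature_exposures(trinucleotide_spectrum(variants, genome), catalog)
for name, w in fit.as_dict().items():
    print(f"exposure {name}: {w:.3f}")
```

prints

```
observed median distance: 164 bp
shuffled median distance: 2930 bp
Wilcoxon two-sided p:     1.68e-08
non-template bias:        0.701  (binomial p = 2.57e-44)
exposure SBS_synth1: 0.589
exposure SBS_synth2: 0.311
exposure SBS_synth3: 0.099
```

Breakpoints generated with a 1-kb half-normal bias toward gene edges sit a
median 164 bp from the nearest gene, against ~2.9 kb for shuffled
coordinates — a strong proximity signal. The planted 0.7 non-template
mutation fraction and the (0.6, 0.3, 0.1) signature mixture are both
recovered.

## Command line

```bash
breakscape simulate --seed 4 --out-dir sim/       # full synthetic dataset
breakscape proximity  --config run.yaml           # distance/reldist tests
breakscape characterize --config run.yaml         # breakpoint meta-profiles
breakscape shm        --config run.yaml           # strand-asymmetry report
breakscape signatures --config run.yaml           # spectra + exposures
```

The YAML config lists input paths by role (`genome`, `breakpoints`,
`features:<name>`, `variants:<sample>`, ...), per-module parameters and a
seed; every output TSV carries a header with the version, config hash and
seed, so runs are reproducible byte for byte.

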