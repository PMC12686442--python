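# cmaflux

Chaperone-mediated autophagy (CMA) degrades individual proteins that carry a
KFERQ-like targeting motif, recognized by the chaperone HSC70 and
translocated into the lysosome through LAMP-2A. Loss of CMA has been linked
to degeneration of the retinal pigment epithelium in age-related macular
degeneration (AMD). `cmaflux` implements the computational arm of this kind
of study as a tested, reusable pipeline for people analyzing lysosomal-flux
proteomics and CMA transcriptional state:

* **Motif scanning** — classify every 5-residue window of a protein as a
  canonical, phosphorylation-generated or acetylation-generated KFERQ-like
  motif, and summarize motif-class abundance over whole proteomes with exact
  per-class 2×2 tests against a reference collection.
* **CMA transcriptional score** — a per-sample weighted, directed average of
  z-scored expression over a configurable CMA-network gene table
  (effectors, positive and negative modulators; LAMP2 carries weight 2 as
  the rate-limiting effector).
* **Substrate calling** — row-wise paired or Welch t-tests of control vs
  lysosomal-inhibitor (NH₄Cl + leupeptin, "N/L") protein quantifications,
  the substrate filter FC > 1.25 ∧ p < 0.01 ∧ motif⁺, and Jaccard overlap
  between substrate sets.
* **Set enrichment** — the weighted Kolmogorov–Smirnov running-sum
  enrichment score with gene-set permutation (NES, add-one-smoothed p), and
  hypergeometric over-representation analysis with BH correction, plus the
  Jaccard ≥ 0.25 enrichment-map edge filter.
* **Synthetic data** — seeded generators for motif-planted proteomes,
  network-shifted expression matrices, and paired N/L experiments with
  planted substrates, all with exact truth tables.

## The statistics at the core

A canonical KFERQ-like pentapeptide has a terminal glutamine anchor and four
remaining residues composed of 1–2 hydrophobic (F/I/L/V), 1–2 positive
(K/R) and exactly 1 negative (E/D) residue; a phosphorylatable S/T/Y can
supply the acidic charge (phosphorylation-generated) and an acetylated
terminal K can mimic the Q anchor (acetylation-generated). The rule table is
configurable.

The CMA score for sample *s* is

```
score_s = Σ_g d_g · w_g · z_{g,s} / Σ_g w_g
```

with direction `d_g ∈ {+1, −1}`, weight `w_g > 0` (LAMP2: 2), and `z_{g,s}`
the per-gene z-score of log2 expression across samples.

A putative CMA substrate is a protein that accumulates under lysosomal
blockade: linear fold change N/L vs control > 1.25, raw p < 0.01 (paired
t-test over donors by default), and ≥ 1 KFERQ-like motif. Overlap between
conditions is reported as the Jaccard index |A∩B|/|A∪B|.

## Worked example

```bash
cmaflux simulate nl --seed 3 --out sim/
cmaflux call-substrates --quant sim/quant.tsv --design sim/design.tsv \
    --motifs sim/motifs.tsv --scale log2 --out calls
# -> called 50 putative substrates (FC>1.25, p<0.01, motif+)
```

The simulated experiment plants 50 accumulating substrates among 500
proteins (fold change 2, noise SD 0.1 log2 units, 5 donors); the paired
caller recovers them. The numbered drivers under `analysis/` run the full
narrative on synthetic data — `01_simulate_inputs.py` through
`05_enrichment.py` — writing tables under `results/`. For example,
`analysis/04_call_substrates.py` prints:

```
healthy: 40 called; sensitivity 1.00, FDR 0.00 against planted truth
amd: 75 called; sensitivity 1.00, FDR 0.00 against planted truth
worked example (171 vs 328, 118 shared): Jaccard = 0.3097
```

i.e. both conditions' planted substrates are recovered exactly at this
signal-to-noise, and two substrate sets of 171 and 328 proteins sharing 118
members overlap with Jaccard index 0.3097.

`analysis/03_cma_score.py` scores the simulated expression matrix, where the
AMD-like group carries a 1 log2-unit shift against each network gene's
direction:

```
AMD_like: mean CMA score -0.728 +/- 0.070 (n=8)
healthy: mean CMA score +0.728 +/- 0.067 (n=8)
AMD_like - healthy difference -1.455, t = -14.94, p = 5.34e-10
```

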