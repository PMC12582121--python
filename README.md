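# ncrbp

Analysis pipeline for characterizing a **non-canonical RNA-binding protein
(ncRBP)** — a protein that binds RNA without a classical RNA-binding domain —
in leukaemia cells. The package re-implements, as tested and reusable code,
the computational stages of such a study: a pooled CRISPR dropout screen, CLIP
crosslink-site peak analysis, a target-stabilization eCDF statistic on
knockdown RNA-seq, translation-efficiency analysis of actively translated
(RNC-bound) mRNA, biophysical binding/mass-photometry/enzyme curve fitting,
and mRNA half-life estimation after transcriptional arrest. A seeded
synthetic-data generator emulates every input class, so the whole pipeline
runs and is testable without any external sequencing or plate-reader data.

It is written for computational biologists who want each of these building
blocks as a plain Python function with explicit contracts, and for method
developers who need a fully controlled simulation in which every injected
effect can be recovered.

## The statistics at the core

**Screen depletion score.** Guide counts are normalized per sample to reads
per 100,000 (count / total × 10⁵). For guide *g*,
log₂FC(g) = log₂((n₄ + c)/(n₂₀ + c)) with pseudocount c = 0.5 on
replicate-averaged normalized abundances, so depleted genes score positive;
the gene score is the unweighted mean over its guides. Hits require
≥ log₂ 5 (five-fold depletion) in an AML line, with counter-screen filters
(AML > δ, T-ALL < δ at δ = 1; both AML lines > 2.5).

**CLIP peaks.** Single-nucleotide crosslink sites on the same strand within
50 bp chain into one peak spanning [min, max+1); an isolated site is extended
symmetrically to 50 bp. Peaks are intersected across three metabolic
conditions (normal glucose, low glucose, galactose) by ≥ 1 bp same-strand
single-linkage overlap, annotated by the precedence
5′UTR > CDS > 3′UTR > intron > lncRNA > other ncRNA > intergenic, and
summarized as a length-scaled 5′UTR metagene coverage profile.

**Stabilization eCDF.** With per-gene knockdown log₂ fold changes L, target
set T (CLIP-bound genes) and background B (all quantified genes, plus a
seeded random non-target control), the statistic reports median(L_T),
median(L_B), the mean difference E[L_T] − E[L_B], and a two-sided Wilcoxon
rank-sum p (exact for min(n) ≤ 25 without ties). A negative shift of the
target eCDF is the signature that the protein stabilizes its bound
transcripts.

**Curve fits.** One-site isotherm r([P]) = r_free + (r_bound − r_free)·[P]/(K_D + [P])
(hyperbolic, or exact quadratic with probe depletion); 4-parameter logistic
competition; OLS contrast→mass calibration and seeded Gaussian-mixture EM for
mass-photometry events; decay A·e^(−λt) with half-life t½ = ln 2 / λ and the
control/knockdown fold reduction t½ᶜ/t½ᵏᵈ.

## Worked example

Run the all-synthetic demo end to end:

```bash
ncrbp simulate --seed 3 --out sim.yaml     # inspect/edit generator truth
cat > pipe.yaml <<'EOF'
sim:
  seed: 3
  n_genes: 120
  screen_depth: 200000
  n_transcripts: 80
  n_sites_per_sample: 150
  n_mass_events: 2000
out_dir: bundle
EOF
ncrbp run --config pipe.yaml
```

The bundle contains per-stage TSV/BED/JSON outputs plus `report.html`. With
the config above it prints:

* **Screen** — 6 depleted genes (≥ 5-fold), all 6 AML-specific in both
  counter-screens: exactly the 5% of genes the generator depleted 8-fold in
  the AML lines and not in the T-ALL line.
* **CLIP** — 387 per-condition peaks merging into 178 cross-condition
  clusters: 70 present in all three metabolic conditions, 65 in exactly two,
  43 in one; 49% of peaks annotate to 5′UTRs (generator truth: 60% 5′UTR
  placement before merging, with some multi-feature peaks resolved by
  precedence).
* **Stabilization** — median target LFC −0.177 vs −0.042 for all genes,
  mean difference −0.202, rank-sum p = 1.6 × 10⁻⁵ (n = 71 targets / 120
  genes): the injected −0.5 log₂ stabilization of CLIP-bound genes is
  detected, attenuated by averaging over conditions and sampling noise.
* **Assays** — K_D = 172.6 ± 4.5 nM (truth 167 nM); mass components
  38.4 and 148.2 kDa, weights 0.42/0.58 (truth 38.5/148.3, 0.4/0.6);
  half-lives 6.10 h (control) vs 1.98 h (knockdown), a 3.08 ± 0.20-fold
  reduction (truth: 3-fold).

Every table carries a provenance header (`config_hash`, `seed`, stage);
rerunning the same config reproduces the bundle byte for byte.

All functionality is also available as a library
(`ncrbp.screen`, `ncrbp.clip`, `ncrbp.stabilization`, `ncrbp.diffexpr`,
`ncrbp.biophysics`, `ncrbp.stability`, `ncrbp.synthetic`,
`ncrbp.workflow`) and as per-stage CLI subcommands (`ncrbp screen score`,
`ncrbp clip merge`, `ncrbp cdf`, `ncrbp fit binding`, `ncrbp decay fit`, …).

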