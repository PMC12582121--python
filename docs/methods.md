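# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical details a user would need to audit a result.

## Synthetic data model

All generators draw from named substreams of one integer seed (CRC32 of the
stage name mixed into a `SeedSequence`), so identical configurations produce
byte-identical outputs and any single stage can be regenerated in isolation.
With `noiseless=True` each generator emits its expected value instead of a
draw; expected counts may then be fractional, which is intentional — the
noiseless mode exists for exact estimator-recovery checks, not for emulating
a sequencer.

**Screen counts.** Each of ~`n_genes` genes gets 4 sgRNAs (the usual library
design) with log-normal latent abundances (σ = 0.5). Day-4 samples draw
multinomially from the library composition at the configured depth (default
1.6 M reads ≈ 400× coverage of a 4,000-guide library); day-20 samples draw
from the composition after multiplying depleted genes' abundances by
1/`depletion_fold` (default 1/8, comfortably past the 5-fold hit threshold)
in the AML lines only. Three cell lines are simulated (two AML, one T-ALL)
with two replicates per time point.

A compositional subtlety worth knowing: because day-20 shares are
renormalized to fixed depth, depleting one gene shifts *every* gene's
normalized abundance by a common factor Σpⱼfⱼ. A gene forced to an exact
k-fold drop therefore scores log₂ k plus a small library-composition offset;
the offset cancels exactly in contrasts between genes. The test suite checks
the exact log₂ 5 recovery as such a contrast, and checks that the absolute
offset is negligible at realistic library sizes. Real screens have the same
property; it is why screen analyses interpret scores relative to the
distribution bulk.

**Toy genome and crosslink sites.** ~50 transcripts per chromosome, both
strands, non-overlapping, 500 bp apart. 80% of transcripts are
protein-coding with 5′UTR (100–300 nt), CDS (600–1,500 nt, half split by one
200–800 nt intron) and 3′UTR (200–600 nt); 12% lncRNA and 8% other ncRNA
carry a single exon. Sites land in a 5′UTR with probability
`utr5_enrichment` (default 0.6, echoing the strong 5′UTR preference the CLIP
analysis is meant to detect) and otherwise length-weighted across the other
features. A master pool of positions is shared across the three metabolic
conditions with per-condition inclusion probability `site_sharing`
(default 0.6) and 90% per-replicate observation, producing the partial
cross-condition overlap the Venn analysis quantifies. Sequence motifs, UMI
structure and read-level artefacts are *not* modelled: passing tests show
the interval arithmetic and statistics are correct, not that upstream
crosslink calling would be.

**Expression counts.** Gene means are log-normal (median 200 reads,
σ_log = 1); counts are negative-binomial with a single shared dispersion α
(default 0.05; variance μ + αμ²), Poisson at α = 0. Knockdown samples
multiply target-gene means by 2^`stabilization_lfc` (default −0.5: targets
are *less* abundant after knockdown of their stabilizer). The RNC fraction
multiplies means by the translation efficiency (1 by default, shifted by
2^`te_lfc` for targets in the knockdown). Per-sample library sizes vary
uniformly ±30%. Three metabolic conditions × {control, knockdown} × 2
replicates. In the orchestrated pipeline the stabilized target set defaults
to the genes actually bound in the CLIP stage, keeping the simulation's
ground truth coherent end to end.

**Assay curves.** Titrations are 2-fold dilution series (12 points from
8 µM) through the one-site isotherm with additive Gaussian noise
(σ = 3 mP), in triplicate, probe at 2 nM; mass events draw from the
configured Gaussian mixture (defaults ~38.5 and ~148.3 kDa — monomer and
tetramer of a ~150 kDa homotetramer — with event-level sd 4–6 kDa typical of
mass photometry); decay series are hourly over 8 h, 4 replicates,
exp(−λt) × log-normal noise (10%), with default half-lives 6 h (control)
vs 2 h (knockdown), i.e. a 3-fold destabilization.

## Analysis choices

**Screen.** Pseudocount 0.5 on normalized abundances keeps scores finite for
guides lost by day 20; replicate averaging precedes the log-ratio and guide
averaging precedes the gene score (the gene score is the mean of guide
scores, not the score of summed counts). Orientation: day4/day20, so
depletion is positive. The AML-vs-T-ALL filter requires the focal lineage
above and the counter lineage below the same threshold (δ = 1); the
two-AML-line filter requires *both* lines above δ = 2.5, matching a
"> 2.5 each" selection box; both deltas and the 5-fold cut are parameters.

**CLIP.** "Proximity" for merging is 50 bp — the one distance the protocol
names — and is a flag (`--gap`); solo sites are extended symmetrically
(25 bp each side), again configurable. Coordinates are 0-based half-open
internally and BED on disk; GTF is converted on import. Cross-condition
overlap needs ≥ 1 bp on the same strand; no reciprocal-overlap fraction is
imposed. Annotation precedence puts 5′UTR first to avoid double counting
peaks that straddle feature boundaries; the metagene profile is unweighted
presence/absence per scaled-UTR bin (peak heights are not used). Note that
with merge gap g and solo width w, output peaks are guaranteed disjoint when
w ≤ g + 2; the defaults (50, 50) satisfy this.

**Differential expression.** A deliberately minimal, fully specified layer:
median-of-ratios size factors (reference = genes detected in every sample),
log2 fold changes of normalized means with pseudocount 0.5, Welch's t-test
on log2-normalized counts, Benjamini–Hochberg adjustment. Count-model
frameworks (dispersion shrinkage, GLM offsets, IHW weighting) are
intentionally not re-implemented: the downstream stabilization and TE
statistics consume only per-gene LFCs, and the size factors are
cross-checked in the tests against an independent reference implementation.
Samples from the three metabolic conditions are pooled by knockdown status
for the main contrast (the conditions cluster by knockdown, not by medium);
per-condition contrasts remain available. TE is the ratio of normalized RNC
to normalized total means (pseudocount 0.5 both); its test contrasts
per-replicate log₂ TE between knockdown and control — a replicate-level
contrast, not a count GLM, and labelled as such. qPCR relative expression is
2^−ΔΔCt against the reference gene (18S in the assay this emulates).

**Stabilization eCDF.** Background = all quantified genes; the random
non-target control (seeded, drawn uniformly from genes without a CLIP peak)
is reported as a second comparison, never substituted for the background.
Two-sided rank-sum by default (one-sided available); exact when
min(n) ≤ 25 with no ties, otherwise tie-corrected normal approximation.
"Mean LFC difference" is the difference of set means, reported alongside the
medians as the summary the eCDF plot is annotated with.

**Binding fits.** Hyperbolic one-site is the default because the probe
(2 nM) sits far below the Kd regime of interest (~10²–10³ nM); the quadratic
ligand-depletion model is available and agrees within 1% when probe ≤ Kd/50.
Kd is bounded positive; starting values come from the response range and the
half-maximal crossing; SE(Kd) from the covariance of the least-squares fit.
No Hill coefficient by default (one-site behaviour), optional for
exploration. EMSA quantification enters as a fraction-bound table
(densitometry is upstream and out of scope) and uses the same isotherm
machinery with plateaus near 0 and 1.

**Mass photometry.** Calibration is an OLS line from ≥ 2 standards
(defaults: BSA 66.5 kDa, thyroglobulin 660 kDa monomer masses, overridable).
Mixtures are fitted by EM with seeded k-means++ initialization, tolerance
1e−8 on the relative log-likelihood, 500 iterations max; k is chosen by BIC
over 1–4 when not given. Component means are reported ascending, and mass
shifts between two samples compare components matched by nearest mean.

**Decay.** Log-linear OLS of ln(abundance) on time is the primary estimator
(closed form, robust for strictly positive qPCR readouts); the nonlinear
exponential fit is a refinement and the automatic fallback when a zero
abundance appears. Replicates are normalized to their own t = 0 and pooled
into one joint fit. Non-decaying series are flagged with an infinite
half-life rather than a negative rate. A model-free time-to-50%
interpolation is reported alongside; the single-exponential value is
primary. The fold reduction t½(control)/t½(knockdown) carries a delta-method
SE. The no-arrest (DMSO) arm can be fitted with the same machinery to
quantify baseline drift.

## Problem sizes and determinism

Default test and acceptance problem sizes are chosen so the full suite runs
in well under a minute of compute per module on a single core: 10⁵–10⁶-read
screens over 100–1,000 genes, hundreds of crosslink sites, 2,000–3,300-gene
count matrices, 5,000–20,000 mass events, 1,000 decay simulations for the
coverage property. All stochastic tests fix seeds; property-based tests run
derandomized. The acceptance script derives every stream from its `--seed`
argument.

## Known limitations

* The DE layer's Welch-on-log test is anticonservative for very low counts
  compared to count GLMs; it exists to supply LFCs, not p-value calibration.
* Normalized screen scores carry the compositional offset discussed above;
  per-gene absolute scores are only as interpretable as in any pooled
  screen.
* The synthetic genome has no overlapping genes, no alternative isoforms and
  no intergenic binding, so the `intergenic` and multi-isoform annotation
  paths are exercised only by hand-built fixtures.
* Mixture fitting assumes Gaussian components; heavy-tailed contrast
  distributions from real instruments may need trimming first.
* TE significance uses replicate-level log-TE contrasts; with 2 replicates
  per fraction its power is limited, matching its role as an effect-size
  (not discovery) readout.
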