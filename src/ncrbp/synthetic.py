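"""Synthetic-data generators for every input class the pipeline consumes.

Each generator draws from a named substream of the single configuration
seed, so stages are individually reproducible and the whole bundle is
byte-identical for a fixed :class:`~ncrbp.config.SimConfig`.

Ground truth is injected explicitly (depletion folds, stabilization shifts,
binding constants, mixture components, decay constants) so that every
downstream estimator can be checked for parameter recovery. With
``noiseless=True`` the generators emit expected values instead of draws;
expected counts may then be fractional.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = [
    "gen_screen_counts",
    "gen_annotation_and_sites",
    "gen_expression_counts",
    "gen_assay_curves",
    "depleted_genes",
    "target_genes",
]

TIMEPOINTS = ("day4", "day20")


def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(1, n + 1)])


def depleted_genes(cfg: SimConfig) -> list[str]:
    """The genes flagged as depleted in the AML lineage (seeded choice)."""
    genes = _gene_ids(cfg.n_genes)
    n_dep = int(round(cfg.depleted_gene_fraction * cfg.n_genes))
    rng = cfg.rng("screen-depleted-set")
    return sorted(rng.choice(genes, size=n_dep, replace=False).tolist())


def gen_screen_counts(cfg: SimConfig) -> pd.DataFrame:
    """Simulate guide-level counts for a pooled dropout screen.

    A latent per-guide abundance is drawn once; day-4 counts sample the
    library composition, day-20 counts sample the composition after
    multiplicative depletion of the flagged genes (AML lines only) and of
    any ``forced_fold_changes``. Per-sample totals equal ``screen_depth``
    up to multinomial rounding.

    Returns a tidy frame: guide_id, gene_id, cell_line, timepoint,
    replicate, count.
    """
    if cfg.screen_depth <= 0:
        raise ValueError("screen_depth must be positive")
    rng = cfg.rng("screen")
    genes = _gene_ids(cfg.n_genes)
    depleted = set(depleted_genes(cfg))

    gene_col = np.repeat(genes, cfg.n_guides_per_gene)
    guide_col = np.array(
        [f"{g}_sg{j + 1}" for g in genes for j in range(cfg.n_guides_per_gene)]
    )
    n_guides = len(guide_col)
    abundance = rng.lognormal(mean=0.0, sigma=0.5, size=n_guides)

    frames = []
    for cell_line, lineage in cfg.cell_lines:
        factor = np.ones(n_guides)
        if lineage == "AML":
            is_dep = np.isin(gene_col, list(depleted))
            factor[is_dep] = 1.0 / cfg.depletion_fold
            for gid, fold in cfg.forced_fold_changes.items():
                factor[gene_col == gid] = 1.0 / fold
        p4 = abundance / abundance.sum()
        a20 = abundance * factor
        p20 = a20 / a20.sum()
        for timepoint, probs in (("day4", p4), ("day20", p20)):
            for rep in range(1, cfg.n_screen_replicates + 1):
                if cfg.noiseless:
                    counts = cfg.screen_depth * probs
                else:
                    counts = rng.multinomial(cfg.screen_depth, probs)
                frames.append(
                    pd.DataFrame(
                        {
                            "guide_id": guide_col,
                            "gene_id": gene_col,
                            "cell_line": cell_line,
                            "timepoint": timepoint,
                            "replicate": rep,
                            "count": counts,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# toy genome annotation and crosslink sites
# ---------------------------------------------------------------------------

_TRANSCRIPTS_PER_CHROM = 50
_INTERGENIC_GAP = 500


def gen_annotation_and_sites(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a toy stranded genome annotation and place crosslink sites on it.

    Transcripts are laid out non-overlapping, ~50 per chromosome, on both
    strands. Protein-coding transcripts get 5'UTR/CDS/3'UTR features (half
    also carry one intron); noncoding transcripts get a single exon feature.
    Crosslink sites land in 5'UTRs with probability ``utr5_enrichment`` and
    otherwise uniformly (length-weighted) across the remaining features. A
    master pool of binding positions is shared across the three metabolic
    conditions with per-condition inclusion probability ``site_sharing``,
    which produces the partial condition overlap the Venn analysis measures.
    """
    rng = cfg.rng("annotation")
    annot_rows = []
    cursor: dict[str, int] = {}
    for i in range(cfg.n_transcripts):
        chrom = f"chr{i // _TRANSCRIPTS_PER_CHROM + 1}"
        start = cursor.get(chrom, 0) + _INTERGENIC_GAP
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{i + 1:05d}"
        tx_id = f"T{i + 1:05d}"
        u = rng.random()
        biotype = "protein_coding" if u < 0.8 else ("lncRNA" if u < 0.92 else "other_ncRNA")
        if biotype == "protein_coding":
            lens = {
                "five_prime_utr": int(rng.integers(100, 300)),
                "CDS": int(rng.integers(600, 1500)),
                "three_prime_utr": int(rng.integers(200, 600)),
            }
            parts = [("five_prime_utr", lens["five_prime_utr"])]
            if rng.random() < 0.5:
                cds = lens["CDS"]
                parts += [
                    ("CDS", cds // 2),
                    ("intron", int(rng.integers(200, 800))),
                    ("CDS", cds - cds // 2),
                ]
            else:
                parts.append(("CDS", lens["CDS"]))
            parts.append(("three_prime_utr", lens["three_prime_utr"]))
            # genomic left-to-right order: 5'->3' on +, 3'->5' on -
            if strand == "-":
                parts = parts[::-1]
        else:
            parts = [("noncoding_exon", int(rng.integers(400, 2000)))]
        pos = start
        for feature, length in parts:
            annot_rows.append(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + length,
                    "strand": strand,
                    "feature": feature,
                    "gene_id": gene_id,
                    "transcript_id": tx_id,
                    "biotype": biotype,
                }
            )
            pos += length
        cursor[chrom] = pos
    annot = pd.DataFrame(annot_rows)
    _check_annotation(annot)

    sites = _place_sites(cfg, annot)
    return annot, sites


def _check_annotation(annot: pd.DataFrame) -> None:
    if (annot["end"] <= annot["start"]).any():
        raise ValueError("malformed feature interval (end <= start)")
    for tx, sub in annot.groupby("transcript_id"):
        s = sub.sort_values("start")
        if (s["start"].values[1:] < s["end"].values[:-1]).any():
            raise ValueError(f"overlapping features within transcript {tx}")


def _place_sites(cfg: SimConfig, annot: pd.DataFrame) -> pd.DataFrame:
    rng = cfg.rng("sites")
    cols = ["chrom", "pos", "strand", "condition", "replicate", "score"]
    if cfg.n_sites_per_sample == 0:
        return pd.DataFrame(columns=cols)

    utr5 = annot[annot["feature"] == "five_prime_utr"]
    other = annot[annot["feature"] != "five_prime_utr"]
    if len(utr5) == 0 and cfg.utr5_enrichment > 0:
        raise ValueError("annotation has no 5'UTR features to place sites in")

    share = cfg.site_sharing if cfg.site_sharing > 0 else 1.0
    n_master = max(1, int(round(cfg.n_sites_per_sample / share)))
    in_utr5 = rng.random(n_master) < cfg.utr5_enrichment

    def _sample_positions(pool: pd.DataFrame, n: int) -> pd.DataFrame:
        lengths = (pool["end"] - pool["start"]).to_numpy()
        idx = rng.choice(len(pool), size=n, p=lengths / lengths.sum())
        rows = pool.iloc[idx]
        offs = rng.integers(0, lengths[idx])
        return pd.DataFrame(
            {
                "chrom": rows["chrom"].to_numpy(),
                "pos": rows["start"].to_numpy() + offs,
                "strand": rows["strand"].to_numpy(),
            }
        )

    parts = []
    n_in = int(in_utr5.sum())
    if n_in:
        parts.append(_sample_positions(utr5, n_in))
    if n_master - n_in:
        parts.append(_sample_positions(other, n_master - n_in))
    master = pd.concat(parts, ignore_index=True).drop_duplicates(
        subset=["chrom", "pos", "strand"], ignore_index=True
    )

    frames = []
    for condition in cfg.conditions:
        keep = rng.random(len(master)) < cfg.site_sharing
        pool = master[keep]
        for rep in range(1, cfg.n_clip_replicates + 1):
            seen = pool[rng.random(len(pool)) < 0.9].copy()
            seen["condition"] = condition
            seen["replicate"] = rep
            seen["score"] = 1.0 + rng.poisson(2.0, size=len(seen))
            frames.append(seen)
    if not frames:
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    return out[cols]


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------


def target_genes(cfg: SimConfig) -> list[str]:
    """The stabilized target set (explicit in the config, or a seeded draw)."""
    if cfg.target_gene_ids is not None:
        return sorted(cfg.target_gene_ids)
    genes = _gene_ids(cfg.n_genes)
    n_t = int(round(cfg.target_gene_fraction * cfg.n_genes))
    rng = cfg.rng("expression-target-set")
    return sorted(rng.choice(genes, size=n_t, replace=False).tolist())


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2; Poisson at 0."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_expression_counts(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the knockdown/control gene x sample count matrix.

    Baseline means are log-normal across genes; genes in the target set
    have their knockdown mean shifted by ``stabilization_lfc`` (log2).
    With ``include_rnc`` an RNC (actively translated) fraction is emitted
    whose mean is the total-fraction mean times the translation efficiency;
    targets get a TE shift of ``te_lfc`` (log2) in the knockdown.

    Returns (counts, metadata): counts indexed by gene_id with one column
    per sample; metadata has columns sample, group, condition, fraction.
    """
    if cfg.nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    rng = cfg.rng("expression")
    genes = _gene_ids(cfg.n_genes)
    targets = np.isin(genes, target_genes(cfg))

    base = rng.lognormal(mean=np.log(cfg.expr_mean_reads), sigma=1.0, size=cfg.n_genes)
    kd_shift = np.where(targets, 2.0 ** cfg.stabilization_lfc, 1.0)
    te_shift = np.where(targets, 2.0 ** cfg.te_lfc, 1.0)

    fractions = ("total", "RNC") if cfg.include_rnc else ("total",)
    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    for condition in cfg.conditions:
        for group in ("control", "knockdown"):
            for fraction in fractions:
                for rep in range(1, cfg.n_expr_replicates + 1):
                    mu = base.copy()
                    if group == "knockdown":
                        mu = mu * kd_shift
                    if fraction == "RNC":
                        mu = mu * (te_shift if group == "knockdown" else 1.0)
                    libsize = 1.0 if cfg.noiseless else rng.uniform(0.7, 1.3)
                    mu = mu * libsize
                    sample = f"{group}_{condition}_{fraction}_r{rep}"
                    counts[sample] = mu if cfg.noiseless else _nb_draw(rng, mu, cfg.nb_dispersion)
                    meta_rows.append(
                        {"sample": sample, "group": group, "condition": condition, "fraction": fraction}
                    )
    mat = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(meta_rows)
    return mat, meta


# ---------------------------------------------------------------------------
# assay curves
# ---------------------------------------------------------------------------


def gen_assay_curves(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate binding titrations, mass-photometry events and decay series.

    * Titration: a 2-fold protein dilution series read out through the
      one-site isotherm r = r_free + (r_bound - r_free) * [P] / (Kd + [P])
      with additive Gaussian noise (mP), in triplicate.
    * Mass events: particle masses drawn from the configured Gaussian
      mixture.
    * Decay: relative abundance exp(-lambda t) under multiplicative
      log-normal noise, sampled hourly over 8 h per condition/replicate.
    """
    bt = cfg.binding_truth
    bt.validate()
    rng = cfg.rng("assays")

    conc = cfg.titration_top_nM / 2.0 ** np.arange(cfg.n_titration_points - 1, -1, -1)
    tit_rows = []
    for rep in range(1, 4):
        resp = bt.r_free + (bt.r_bound - bt.r_free) * conc / (bt.kd_nM + conc)
        if not cfg.noiseless:
            resp = resp + rng.normal(0.0, cfg.titration_noise_mP, size=conc.size)
        tit_rows.append(
            pd.DataFrame(
                {
                    "protein_conc_nM": conc,
                    "response_mP": resp,
                    "probe_conc_nM": bt.probe_conc_nM,
                    "replicate": rep,
                }
            )
        )
    titration = pd.concat(tit_rows, ignore_index=True)

    comps = cfg.mass_components
    if comps:
        weights = np.array([c.weight for c in comps])
        which = rng.choice(len(comps), size=cfg.n_mass_events, p=weights / weights.sum())
        means = np.array([c.mean_kDa for c in comps])[which]
        sds = np.array([c.sd_kDa for c in comps])[which]
        masses = means if cfg.noiseless else rng.normal(means, np.where(sds > 0, sds, 0.0))
        masses = np.where(sds == 0, means, masses)
    else:
        masses = np.array([])
    mass_events = pd.DataFrame({"mass_kDa": masses, "condition": "sample"})

    dec_rows = []
    times = np.asarray(cfg.decay_times_h, dtype=float)
    for condition, hl in cfg.decay_halflives_h.items():
        lam = np.log(2.0) / hl
        for rep in range(1, cfg.n_decay_replicates + 1):
            y = np.exp(-lam * times)
            if not cfg.noiseless:
                y = y * np.exp(rng.normal(0.0, cfg.decay_noise_sd, size=times.size))
            dec_rows.append(
                pd.DataFrame(
                    {
                        "time_h": times,
                        "rel_abundance": y,
                        "condition": condition,
                        "replicate": rep,
                        "gene": "GAPDH",
                    }
                )
            )
    decay = pd.concat(dec_rows, ignore_index=True)
    return titration, mass_events, decay
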