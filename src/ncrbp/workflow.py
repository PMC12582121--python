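"""End-to-end orchestration of the pipeline from a single YAML config.

Stages run in dependency order (screen -> CLIP -> DE/TE -> CDF; the
biophysical assays are independent), every output table carries a
provenance header (config hash, seed, stage), and identical configs
produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biophysics, clip, diffexpr, screen, stability, stabilization, synthetic
from .config import SimConfig
from .io import write_json, write_peaks_bed, write_sites_bed, write_table, write_annotation_gtf

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("screen", "clip", "diffexpr", "cdf", "assays")
_DEPS = {"cdf": ("clip", "diffexpr")}


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "ncrbp_out"
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    fold_threshold: float = 5.0
    primary_delta: float = 1.0
    secondary_delta: float = 2.5
    merge_gap: int = 50
    solo_width: int = 50
    n_bins: int = 50
    pseudocount: float = 0.5
    n_control_genes: int = 300

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) in config: {sorted(unknown)}")
        for par in ("fold_threshold", "primary_delta", "secondary_delta",
                    "merge_gap", "solo_width", "n_bins"):
            if getattr(self, par) <= 0:
                raise ValueError(f"{par} must be positive")
        for stage, deps in _DEPS.items():
            if self.stages.get(stage, False):
                missing = [d for d in deps if not self.stages.get(d, False)]
                if missing:
                    raise ValueError(
                        f"stage {stage!r} requires disabled stage(s): {missing}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; write the report bundle; return results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.config_hash(), "seed": config.sim.seed}
    results: dict = {}

    if config.stages.get("screen", False):
        results["screen"] = _run_screen(config, out, prov)
    if config.stages.get("clip", False):
        results["clip"] = _run_clip(config, out, prov)
    if config.stages.get("diffexpr", False):
        results["diffexpr"] = _run_diffexpr(config, out, prov, results)
    if config.stages.get("cdf", False):
        results["cdf"] = _run_cdf(config, out, prov, results)
    if config.stages.get("assays", False):
        results["assays"] = _run_assays(config, out, prov)

    _write_report(config, out, results)
    return results


def _run_screen(config: PipelineConfig, out: Path, prov: dict) -> dict:
    counts = synthetic.gen_screen_counts(config.sim)
    write_table(counts, out / "guide_counts.tsv", provenance=prov | {"stage": "screen"})
    scores = screen.gene_log2fc(screen.normalize_counts(counts), pseudocount=config.pseudocount)
    hits = screen.select_hits(
        scores,
        fold_threshold=config.fold_threshold,
        primary_delta=config.primary_delta,
        secondary_delta=config.secondary_delta,
    )
    write_table(scores, out / "screen_scores.tsv", provenance=prov | {"stage": "screen"})
    write_table(hits, out / "screen_hits.tsv", provenance=prov | {"stage": "screen"})
    return {"scores": scores, "hits": hits}


def _run_clip(config: PipelineConfig, out: Path, prov: dict) -> dict:
    annot, sites = synthetic.gen_annotation_and_sites(config.sim)
    write_annotation_gtf(annot, out / "annotation.gtf")
    write_sites_bed(sites, out / "crosslink_sites.bed", provenance=prov | {"stage": "clip"})
    peaksets = {
        cond: clip.merge_sites(
            sites[sites["condition"] == cond], config.merge_gap, config.solo_width
        )
        for cond in config.sim.conditions
    }
    all_peaks = pd.concat(peaksets.values(), ignore_index=True)
    write_peaks_bed(all_peaks, out / "peaks.bed", provenance=prov | {"stage": "clip"})
    venn = clip.condition_overlap(peaksets)
    write_json(venn, out / "venn.json", provenance=prov | {"stage": "clip"})
    labelled, dist = clip.annotate_peaks(peaksets[config.sim.conditions[0]], annot)
    write_table(dist, out / "feature_distribution.tsv", provenance=prov | {"stage": "clip"})
    profile = clip.metagene_profile(all_peaks, annot, n_bins=config.n_bins)
    write_table(
        pd.DataFrame({"bin": np.arange(1, config.n_bins + 1), "coverage": profile}),
        out / "metagene.tsv", provenance=prov | {"stage": "clip"},
    )
    return {"annot": annot, "sites": sites, "peaksets": peaksets, "all_peaks": all_peaks,
            "venn": venn, "distribution": dist, "metagene": profile, "labelled": labelled}


def _run_diffexpr(config: PipelineConfig, out: Path, prov: dict, results: dict) -> dict:
    sim = config.sim
    if "clip" in results and sim.target_gene_ids is None:
        # ground-truth coherence: the stabilized genes are the CLIP-bound ones
        bound = stabilization.crosslink_targets(
            results["clip"]["all_peaks"], results["clip"]["annot"]
        )
        if bound:
            sim = dataclasses.replace(sim, target_gene_ids=tuple(sorted(bound)))
    counts, meta = synthetic.gen_expression_counts(sim)
    write_table(counts, out / "expression_counts.tsv", provenance=prov | {"stage": "diffexpr"},
                index=True)
    write_table(meta, out / "sample_metadata.csv", sep=",", provenance=prov | {"stage": "diffexpr"})
    total = meta[meta["fraction"] == "total"]["sample"]
    de = diffexpr.differential_expression(counts[list(total)], meta[meta["fraction"] == "total"])
    write_table(de.reset_index(), out / "de_results.tsv", provenance=prov | {"stage": "diffexpr"})
    result = {"counts": counts, "meta": meta, "de": de}
    if config.sim.include_rnc:
        te = diffexpr.translation_efficiency(counts, meta)
        write_table(te.reset_index(), out / "te_results.tsv",
                    provenance=prov | {"stage": "diffexpr"})
        result["te"] = te
    return result


def _run_cdf(config: PipelineConfig, out: Path, prov: dict, results: dict) -> dict:
    annot = results["clip"]["annot"]
    all_peaks = results["clip"]["all_peaks"]
    de = results["diffexpr"]["de"]
    lfc = de["log2fc"]
    universe = set(lfc.index)
    targets = stabilization.crosslink_targets(all_peaks, annot) & universe
    if not targets:
        raise ValueError("no CLIP target genes with a quantified LFC")
    comparison, curves = stabilization.cdf_shift_test(lfc, targets, universe)
    n_ctrl = min(config.n_control_genes, len(universe - targets))
    control = stabilization.draw_control_set(universe, targets, n_ctrl, seed=config.sim.seed)
    ctrl_comparison, ctrl_curves = stabilization.cdf_shift_test(lfc, targets, control)
    write_json(
        {"targets_vs_all": dataclasses.asdict(comparison),
         "targets_vs_random_control": dataclasses.asdict(ctrl_comparison)},
        out / "cdf_comparison.json", provenance=prov | {"stage": "cdf"},
    )
    points = []
    for label, (x, y) in curves.items():
        points.append(pd.DataFrame({"set": label, "lfc": x, "ecdf": y}))
    write_table(pd.concat(points, ignore_index=True), out / "ecdf_points.tsv",
                provenance=prov | {"stage": "cdf"})
    return {"comparison": comparison, "control_comparison": ctrl_comparison,
            "curves": curves, "targets": targets, "control": control}


def _run_assays(config: PipelineConfig, out: Path, prov: dict) -> dict:
    titration, mass_events, decay = synthetic.gen_assay_curves(config.sim)
    write_table(titration, out / "titration.csv", sep=",", provenance=prov | {"stage": "assays"})
    write_table(mass_events, out / "mass_events.csv", sep=",",
                provenance=prov | {"stage": "assays"})
    write_table(decay, out / "decay.csv", sep=",", provenance=prov | {"stage": "assays"})

    binding = biophysics.fit_binding(titration)
    mixture = biophysics.fit_mass_mixture(
        mass_events["mass_kDa"].to_numpy(), seed=config.sim.seed
    )
    decay_fits = {
        cond: stability.fit_decay(decay[decay["condition"] == cond])
        for cond in decay["condition"].unique()
    }
    fits_payload: dict = {
        "binding": dataclasses.asdict(binding),
        "mass_mixture": {
            "means_kDa": mixture.means_kDa, "sds_kDa": mixture.sds_kDa,
            "weights": mixture.weights, "k": mixture.k,
        },
        "decay": {c: {k: v for k, v in dataclasses.asdict(f).items()}
                  for c, f in decay_fits.items()},
    }
    if {"control", "knockdown"} <= set(decay_fits):
        ratio, se = stability.halflife_ratio(decay_fits["control"], decay_fits["knockdown"])
        fits_payload["halflife_fold_reduction"] = {"ratio": ratio, "se": se}
    write_json(fits_payload, out / "fits.json", provenance=prov | {"stage": "assays"})
    return {"binding": binding, "mixture": mixture, "decay_fits": decay_fits,
            "fits_payload": fits_payload}


def _write_report(config: PipelineConfig, out: Path, results: dict) -> None:
    """Small self-contained HTML summary with the headline numbers."""
    figures = _render_figures(out, results)
    parts = [
        "<html><head><title>ncrbp report</title></head><body>",
        f"<h1>ncrbp pipeline report</h1>",
        f"<p>config hash {config.config_hash()}, seed {config.sim.seed}</p>",
    ]
    if "screen" in results:
        hits = results["screen"]["hits"]
        parts.append(
            f"<h2>Screen</h2><p>{int(hits['depleted'].sum())} depleted genes "
            f"(&ge; {config.fold_threshold}-fold), "
            f"{int(hits['aml_vs_tall'].sum())} AML-vs-T-ALL specific, "
            f"{int(hits['aml_line_specific'].sum())} depleted in both AML lines.</p>"
        )
    if "clip" in results:
        venn = results["clip"]["venn"]
        parts.append(
            "<h2>CLIP</h2><p>peaks per condition (total "
            f"{venn['n_peaks_total']}); condition overlap: {venn['three']} in all three, "
            f"{venn['exactly_two']} in exactly two, {venn['exactly_one']} in one "
            f"({venn['n_clusters']} merged clusters).</p>"
            + results["clip"]["distribution"].to_html(index=False)
        )
    if "cdf" in results:
        c = results["cdf"]["comparison"]
        parts.append(
            "<h2>Target stabilization</h2>"
            f"<p>median target LFC {c.median_target_lfc:.3f} vs background "
            f"{c.median_background_lfc:.3f}; mean LFC difference "
            f"{c.mean_lfc_difference:.3f}; rank-sum p = {c.p:.3g} "
            f"(n = {c.n_target} targets / {c.n_background} background).</p>"
        )
    if "assays" in results:
        b = results["assays"]["binding"]
        mix = results["assays"]["mixture"]
        parts.append(
            "<h2>Assays</h2>"
            f"<p>binding K<sub>D</sub> = {b.kd:.1f} nM (R&sup2; {b.r_squared:.3f}); "
            f"mass components {np.round(mix.means_kDa, 1).tolist()} kDa.</p>"
        )
        if "halflife_fold_reduction" in results["assays"]["fits_payload"]:
            r = results["assays"]["fits_payload"]["halflife_fold_reduction"]
            parts.append(f"<p>half-life fold reduction {r['ratio']:.2f} &plusmn; {r['se']:.2f}</p>")
    for fig in figures:
        parts.append(f'<img src="{fig}" width="420"/>')
    parts.append("</body></html>")
    (out / "report.html").write_text("\n".join(parts))


def _render_figures(out: Path, results: dict) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = []
    if "cdf" in results:
        fig, ax = plt.subplots(figsize=(4, 3))
        for label, (x, y) in results["cdf"]["curves"].items():
            ax.step(x, y, where="post", label=label)
        c = results["cdf"]["comparison"]
        ax.set_xlabel("log2 fold change (knockdown / control)")
        ax.set_ylabel("eCDF")
        ax.set_title(f"median {c.median_target_lfc:.2f} vs {c.median_background_lfc:.2f}, "
                     f"p = {c.p:.2g}", fontsize=8)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "ecdf.png", dpi=120)
        plt.close(fig)
        names.append("ecdf.png")
    if "clip" in results:
        fig, ax = plt.subplots(figsize=(4, 3))
        prof = results["clip"]["metagene"]
        ax.plot(np.linspace(0, 1, len(prof)), prof)
        ax.set_xlabel("scaled 5'UTR position (5'->3')")
        ax.set_ylabel("fraction of UTRs covered")
        fig.tight_layout()
        fig.savefig(out / "metagene.png", dpi=120)
        plt.close(fig)
        names.append("metagene.png")
    return names
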