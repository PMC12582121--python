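"""Crosslink-site peak construction, condition overlap, and annotation.

Single-nucleotide crosslink sites are merged into peaks by single-linkage
proximity clustering (solo sites are extended to a fixed width), peaks are
intersected across metabolic conditions for the Venn breakdown, assigned
to genomic feature categories by precedence, and summarized as a
5'UTR metagene coverage profile.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "merge_sites",
    "condition_overlap",
    "annotate_peaks",
    "metagene_profile",
    "CATEGORY_PRECEDENCE",
]

CATEGORY_PRECEDENCE = ("5UTR", "CDS", "3UTR", "intron", "lncRNA", "other_ncRNA", "intergenic")

_FEATURE_CATEGORY = {
    "five_prime_utr": "5UTR",
    "CDS": "CDS",
    "three_prime_utr": "3UTR",
    "intron": "intron",
}


def merge_sites(
    sites: pd.DataFrame, merge_gap: int = 50, solo_width: int = 50
) -> pd.DataFrame:
    """Merge crosslink sites into peaks.

    Distinct site positions on the same chromosome and strand (and, when a
    ``condition`` column is present, the same condition — replicates are
    pooled) are chained into one cluster whenever consecutive positions lie
    within ``merge_gap`` bp. A multi-site cluster spans [min pos, max pos + 1);
    a solo site is extended symmetrically to ``solo_width`` bp (clipped at
    the chromosome start). Output peaks are sorted and pairwise disjoint
    within each group.
    """
    if merge_gap <= 0 or solo_width <= 0:
        raise ValueError("merge_gap and solo_width must be positive")
    cols = ["chrom", "start", "end", "strand", "n_sites", "score"]
    keys = ["chrom", "strand"] + (["condition"] if "condition" in sites.columns else [])
    if len(sites) == 0:
        return pd.DataFrame(columns=keys[2:] + cols[:2] + cols[2:]).reindex(
            columns=cols + keys[2:]
        )
    if (sites["pos"] < 0).any():
        raise ValueError("negative site coordinate")
    if not sites["strand"].isin(["+", "-"]).all():
        raise ValueError("site with undefined strand")

    rows = []
    for key, sub in sites.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        pos_score = sub.groupby("pos")["score"].sum() if "score" in sub.columns else (
            sub.groupby("pos").size().astype(float)
        )
        positions = pos_score.index.to_numpy()
        scores = pos_score.to_numpy()
        breaks = np.where(np.diff(positions) > merge_gap)[0] + 1
        for chunk, schunk in zip(np.split(positions, breaks), np.split(scores, breaks)):
            if len(chunk) == 1:
                half = solo_width // 2
                start = max(0, int(chunk[0]) - half)
                end = int(chunk[0]) + (solo_width - half)
            else:
                start, end = int(chunk[0]), int(chunk[-1]) + 1
            rows.append(dict(zip(keys, key)) | {
                "start": start,
                "end": end,
                "n_sites": len(chunk),
                "score": float(schunk.sum()),
            })
    out = pd.DataFrame(rows)
    out = out.sort_values(keys + ["start"]).reset_index(drop=True)
    return out[[c for c in ["chrom", "start", "end", "strand", "condition", "n_sites", "score"] if c in out.columns]]


def _overlap_clusters(peaks: pd.DataFrame) -> np.ndarray:
    """Single-linkage cluster ids for >=1 bp same-strand overlap."""
    cluster = np.full(len(peaks), -1, dtype=int)
    cid = 0
    order = peaks.sort_values(["chrom", "strand", "start"]).index
    prev_key = None
    current_end = -1
    for idx in order:
        row = peaks.loc[idx]
        key = (row["chrom"], row["strand"])
        if key != prev_key or row["start"] >= current_end:
            cid += 1
            current_end = row["end"]
        else:
            current_end = max(current_end, row["end"])
        prev_key = key
        cluster[peaks.index.get_loc(idx)] = cid
    return cluster


def condition_overlap(peaksets: dict, strict: bool = True) -> dict:
    """Venn breakdown of peaks across conditions.

    Peaks from all conditions are clustered by single-linkage on >=1 bp
    same-strand overlap; each cluster is counted once, in the category
    matching the number of distinct conditions present in it. Also reports
    the number of clusters and the total per-condition peak count (the two
    ways of counting an experiment's peaks).
    """
    if strict and not 1 <= len(peaksets) <= 3:
        raise ValueError(f"expected 1-3 conditions, got {len(peaksets)}")
    if len(peaksets) == 0:
        raise ValueError("no conditions given")
    frames = []
    for cond, peaks in peaksets.items():
        if len(peaks):
            f = peaks[["chrom", "start", "end", "strand"]].copy()
            f["condition"] = cond
            frames.append(f)
    result = {"three": 0, "exactly_two": 0, "exactly_one": 0, "n_clusters": 0,
              "n_peaks_total": int(sum(len(p) for p in peaksets.values()))}
    if not frames:
        return result
    allp = pd.concat(frames, ignore_index=True)
    allp["cluster"] = _overlap_clusters(allp)
    n_cond = allp.groupby("cluster")["condition"].nunique()
    result["three"] = int((n_cond == 3).sum())
    result["exactly_two"] = int((n_cond == 2).sum())
    result["exactly_one"] = int((n_cond == 1).sum())
    result["n_clusters"] = int(n_cond.size)
    return result


def _feature_trees(annot: pd.DataFrame) -> dict:
    """(chrom, strand) -> IntervalTree of annotation rows."""
    if not annot["strand"].isin(["+", "-"]).all():
        raise ValueError("annotation with unknown strand")
    trees: dict = {}
    for (chrom, strand), sub in annot.groupby(["chrom", "strand"]):
        tree = IntervalTree()
        for row in sub.itertuples():
            if row.end > row.start:
                tree.addi(row.start, row.end, row)
        trees[(chrom, strand)] = tree
    return trees


def _peak_category(hits) -> str:
    cats = set()
    for iv in hits:
        row = iv.data
        if row.feature in _FEATURE_CATEGORY:
            cats.add(_FEATURE_CATEGORY[row.feature])
        elif row.biotype == "lncRNA":
            cats.add("lncRNA")
        else:
            cats.add("other_ncRNA")
    for cat in CATEGORY_PRECEDENCE:
        if cat in cats:
            return cat
    return "intergenic"


def annotate_peaks(
    peaks: pd.DataFrame, annot: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each peak one feature category and tabulate the distribution.

    Overlap requires the same strand and >=1 bp; when a peak touches
    several features the category is chosen by precedence
    5UTR > CDS > 3UTR > intron > lncRNA > other_ncRNA, and a peak touching
    nothing is intergenic. Returns (labelled peaks, distribution) where the
    distribution has one row per category with count and fraction
    (fractions sum to 1).
    """
    trees = _feature_trees(annot)
    labels = []
    for row in peaks.itertuples():
        tree = trees.get((row.chrom, row.strand))
        hits = tree.overlap(row.start, row.end) if tree is not None else ()
        labels.append(_peak_category(hits))
    labelled = peaks.copy()
    labelled["category"] = labels
    counts = labelled["category"].value_counts()
    dist = pd.DataFrame(
        {
            "category": CATEGORY_PRECEDENCE,
            "count": [int(counts.get(c, 0)) for c in CATEGORY_PRECEDENCE],
        }
    )
    total = dist["count"].sum()
    dist["fraction"] = dist["count"] / total if total else 0.0
    return labelled, dist


def metagene_profile(
    peaks: pd.DataFrame, annot: pd.DataFrame, n_bins: int = 50
) -> np.ndarray:
    """Mean peak coverage over length-scaled 5'UTRs.

    Each annotated 5'UTR is divided into ``n_bins`` equal slices in
    transcript orientation (bin 0 is the 5' end; minus-strand UTRs are
    reversed). A bin is covered when any same-strand peak overlaps it by a
    positive amount; the profile is the fraction of UTRs covered per bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    utrs = annot[annot["feature"] == "five_prime_utr"]
    if len(utrs) == 0:
        raise ValueError("annotation contains no 5'UTRs")

    peak_trees: dict = {}
    for (chrom, strand), sub in peaks.groupby(["chrom", "strand"]):
        tree = IntervalTree()
        for row in sub.itertuples():
            if row.end > row.start:
                tree.addi(row.start, row.end)
        peak_trees[(chrom, strand)] = tree

    profiles = []
    for row in utrs.itertuples():
        length = row.end - row.start
        if length <= 0:
            warnings.warn(f"zero-length 5'UTR skipped: {row.transcript_id}")
            continue
        tree = peak_trees.get((row.chrom, row.strand))
        covered = np.zeros(n_bins)
        if tree is not None:
            edges = row.start + length * np.arange(n_bins + 1) / n_bins
            for j in range(n_bins):
                if tree.overlap(edges[j], edges[j + 1]):
                    covered[j] = 1.0
        if row.strand == "-":
            covered = covered[::-1]
        profiles.append(covered)
    if not profiles:
        raise ValueError("no usable 5'UTRs")
    return np.mean(profiles, axis=0)
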