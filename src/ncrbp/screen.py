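"""Pooled CRISPR screen depletion scoring and hit selection.

Guide counts from day 4 and day 20 are normalized per sample to reads per
100,000, converted to guide-level log2 fold changes (day 4 over day 20, so
depleted genes score positive), averaged over replicates and then over a
gene's guides, and filtered with the depletion and counter-screen rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NORMALIZATION_SCALE",
    "normalize_counts",
    "gene_log2fc",
    "select_hits",
    "ScreenHit",
]

NORMALIZATION_SCALE = 100_000.0

_SAMPLE_KEYS = ["cell_line", "timepoint", "replicate"]


@dataclass
class ScreenHit:
    gene_id: str
    depleted: bool
    lineage_specific: dict
    core_fitness: bool


def normalize_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to reads per 100,000.

    normalized = count / sample_total * 100,000, so normalized values sum
    to exactly 100,000 within each (cell_line, timepoint, replicate)
    sample. Raises on an empty table or a sample with zero total reads.
    """
    if len(table) == 0:
        raise ValueError("empty guide count table")
    for col in ["guide_id", "gene_id", "count"] + _SAMPLE_KEYS:
        if col not in table.columns:
            raise ValueError(f"guide count table lacks column {col!r}")
    totals = table.groupby(_SAMPLE_KEYS)["count"].transform("sum")
    if (totals <= 0).any():
        bad = table.loc[totals <= 0, _SAMPLE_KEYS].drop_duplicates()
        raise ValueError(f"sample(s) with non-positive total reads: {bad.values.tolist()}")
    out = table.copy()
    out["normalized"] = out["count"] / totals * NORMALIZATION_SCALE
    return out


def gene_log2fc(normalized: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Gene-level depletion scores per cell line.

    Guide log2fc = log2((day4 + pc) / (day20 + pc)) on replicate-averaged
    normalized abundances; the gene score is the unweighted mean of its
    guide scores. Returns columns gene_id, cell_line, log2fc, n_guides.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if "normalized" not in normalized.columns:
        normalized = normalize_counts(normalized)
    wide = (
        normalized.groupby(["gene_id", "guide_id", "cell_line", "timepoint"])["normalized"]
        .mean()  # average over replicates first
        .unstack("timepoint")
    )
    for tp in ("day4", "day20"):
        if tp not in wide.columns:
            raise ValueError(f"missing timepoint {tp!r}")
    guide_lfc = np.log2((wide["day4"] + pseudocount) / (wide["day20"] + pseudocount))
    per_gene = guide_lfc.groupby(level=["gene_id", "cell_line"]).agg(["mean", "size"])
    out = per_gene.reset_index()
    out.columns = ["gene_id", "cell_line", "log2fc", "n_guides"]
    return out


def select_hits(
    scores: pd.DataFrame,
    fold_threshold: float = 5.0,
    primary_delta: float = 1.0,
    secondary_delta: float = 2.5,
    fitness_list: set | None = None,
    aml_lines: tuple = ("MOLM-13", "THP-1"),
    tall_lines: tuple = ("Jurkat",),
) -> pd.DataFrame:
    """Apply the depletion and counter-screen selection filters.

    A gene is *depleted* when its score reaches log2(fold_threshold) in at
    least one AML line. Lineage specificity contrasts the mean AML score
    against the mean T-ALL score at ``primary_delta`` (above threshold in
    the focal lineage, below the same threshold in the counter lineage)
    and the two AML lines against each other at ``secondary_delta``.
    ``fitness_list`` flags known weak core fitness genes.
    """
    fitness_list = fitness_list or set()
    cols = ["gene_id", "depleted", "aml_vs_tall", "aml_line_specific", "core_fitness"]
    if len(scores) == 0:
        return pd.DataFrame(columns=cols)
    wide = scores.pivot_table(index="gene_id", columns="cell_line", values="log2fc")
    present_aml = [c for c in aml_lines if c in wide.columns]
    if not present_aml:
        raise ValueError(f"no AML contrast line among {list(wide.columns)}")
    log2_fold = np.log2(fold_threshold)
    depleted = (wide[present_aml] >= log2_fold).any(axis=1)

    present_tall = [c for c in tall_lines if c in wide.columns]
    if present_tall:
        aml_score = wide[present_aml].mean(axis=1)
        tall_score = wide[present_tall].mean(axis=1)
        aml_vs_tall = (aml_score > primary_delta) & (tall_score < primary_delta)
    else:
        aml_vs_tall = pd.Series(False, index=wide.index)

    if len(present_aml) >= 2:
        a, b = present_aml[:2]
        aml_line_specific = (wide[a] > secondary_delta) & (wide[b] > secondary_delta)
    else:
        aml_line_specific = pd.Series(False, index=wide.index)

    out = pd.DataFrame(
        {
            "gene_id": wide.index,
            "depleted": depleted.values,
            "aml_vs_tall": (aml_vs_tall & depleted).values,
            "aml_line_specific": (aml_line_specific & depleted).values,
            "core_fitness": [g in fitness_list for g in wide.index],
        }
    )
    return out.reset_index(drop=True)[cols]
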