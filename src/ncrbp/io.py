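"""Readers and writers for the pipeline's on-disk formats.

Tables are TSV/CSV with ``#``-prefixed provenance comment lines (config
hash, seed, stage); crosslink sites and peaks are BED6; annotation is GTF
(1-based inclusive on disk, converted to 0-based half-open on import).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import gffutils

from . import __version__

__all__ = [
    "write_table",
    "read_table",
    "write_sites_bed",
    "read_sites_bed",
    "write_peaks_bed",
    "read_peaks_bed",
    "write_annotation_gtf",
    "read_annotation_gtf",
    "write_json",
]

_CODING_FEATURES = {"five_prime_utr", "CDS", "three_prime_utr", "intron"}


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    items = {"ncrbp_version": __version__, **provenance}
    return "".join(f"# {k}={v}\n" for k, v in items.items())


def write_table(df: pd.DataFrame, path, sep: str = "\t", provenance: dict | None = None,
                index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep=sep, index=index)


def read_table(path, sep: str = "\t", **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kwargs)


def write_sites_bed(sites: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Crosslink sites as BED6: name = condition:replicate, score = count."""
    bed = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"].astype(int),
            "end": sites["pos"].astype(int) + 1,
            "name": sites["condition"].astype(str) + ":" + sites["replicate"].astype(str),
            "score": sites["score"],
            "strand": sites["strand"],
        }
    )
    write_table(bed, path, provenance=provenance)


def read_sites_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"], header=0,
    )
    cond_rep = bed["name"].str.split(":", n=1, expand=True)
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "pos": bed["start"],
            "strand": bed["strand"],
            "condition": cond_rep[0],
            "replicate": cond_rep[1],
            "score": bed["score"],
        }
    )


def write_peaks_bed(peaks: pd.DataFrame, path, provenance: dict | None = None) -> None:
    name = peaks["condition"] if "condition" in peaks.columns else "peak"
    bed = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"].astype(int),
            "end": peaks["end"].astype(int),
            "name": name,
            "score": peaks["n_sites"],
            "strand": peaks["strand"],
        }
    )
    write_table(bed, path, provenance=provenance)


def read_peaks_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"], header=0,
    )
    out = bed.rename(columns={"name": "condition", "score": "n_sites"})
    return out[["chrom", "start", "end", "strand", "condition", "n_sites"]]


def write_annotation_gtf(annot: pd.DataFrame, path, source: str = "ncrbp") -> None:
    """Write feature intervals as GTF (converting to 1-based inclusive)."""
    with open(path, "w") as fh:
        for row in annot.itertuples():
            feature = "exon" if row.feature == "noncoding_exon" else row.feature
            attrs = (
                f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}"; '
                f'gene_biotype "{row.biotype}";'
            )
            fh.write(
                f"{row.chrom}\t{source}\t{feature}\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_annotation_gtf(path) -> pd.DataFrame:
    """Import a GTF into the internal 0-based half-open annotation frame."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features():
        if feat.featuretype in ("gene", "transcript"):
            continue
        biotype = feat.attributes.get("gene_biotype", ["protein_coding"])[0]
        feature = feat.featuretype
        if feature == "exon" and biotype != "protein_coding":
            feature = "noncoding_exon"
        if feature not in _CODING_FEATURES and feature != "noncoding_exon":
            continue
        rows.append(
            {
                "chrom": feat.seqid,
                "start": feat.start - 1,
                "end": feat.end,
                "strand": feat.strand,
                "feature": feature,
                "gene_id": feat.attributes.get("gene_id", ["?"])[0],
                "transcript_id": feat.attributes.get("transcript_id", ["?"])[0],
                "biotype": biotype,
            }
        )
    return pd.DataFrame(rows)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path, provenance: dict | None = None) -> None:
    payload = {"provenance": {"ncrbp_version": __version__, **(provenance or {})}, **obj} \
        if provenance else obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
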