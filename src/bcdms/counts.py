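"""Assemble per-sample barcode tallies into a modeling-ready count table.

Unobserved (barcode, sample) pairs are stored as explicit zeros, never as
missing values: the assay reads out expressed RNA, so the absence of a
mapped barcode from a sample is evidence of low expression, and dropping
such barcodes would discard exactly the strongest loss-of-function signal.
Sample offsets are the natural log of the summed counts of nonsense (stop)
barcodes, which are expected to be constant across conditions.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .mapping import variant_label

ANNOTATION_COLUMNS = ["barcode", "oligo_id", "position", "wt_aa", "alt_aa", "variant"]


def sample_columns(counts: pd.DataFrame) -> list[str]:
    extra = ANNOTATION_COLUMNS + ["subregion"]
    return [c for c in counts.columns if c not in extra]


def tally_expression(
    sample_barcodes: Mapping[str, Iterable[str]],
    vb_map: pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Count mapped-barcode occurrences per sample.

    ``sample_barcodes`` maps sample_id to an iterable of observed barcode
    sequences (one entry per read). Barcodes absent from the variant-barcode
    map are excluded from the table and reported in the QC dict as an
    unmapped fraction per sample. Every mapped barcode appears in every
    sample column, with explicit zeros where unobserved.
    """
    missing = set(sample_sheet["sample_id"]) - set(sample_barcodes)
    if missing:
        raise ValueError(f"samples without barcode data: {sorted(missing)}")

    mapped = set(vb_map["barcode"])
    table = vb_map[["barcode", "oligo_id", "position", "wt_aa", "alt_aa"]].copy()
    table["variant"] = [
        variant_label(w, p, a)
        for w, p, a in zip(vb_map["wt_aa"], vb_map["position"], vb_map["alt_aa"])
    ]
    index = pd.Index(table["barcode"])
    unmapped_fraction = {}
    for sid in sample_sheet["sample_id"]:
        seen = pd.Series(list(sample_barcodes[sid]), dtype=object)
        n_total = len(seen)
        if n_total == 0:
            raise ValueError(f"sample {sid!r} has no reads")
        vc = seen.value_counts()
        in_map = vc.index.isin(mapped)
        n_mapped = int(vc[in_map].sum())
        if n_mapped == 0:
            raise ValueError(f"sample {sid!r} has zero mapped reads")
        unmapped_fraction[sid] = 1.0 - n_mapped / n_total
        table[sid] = vc.reindex(index).fillna(0).astype(int).to_numpy()
    qc = {"unmapped_fraction": unmapped_fraction}
    return table, qc


def compute_offsets(counts: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Fill the sample sheet's offset column from stop-derived totals.

    gamma_m = ln(sum of counts over all nonsense barcodes in sample m),
    summed library-wide. Errors if any sample has zero stop counts.
    """
    stops = counts[counts["alt_aa"] == "*"]
    if stops.empty:
        raise ValueError("no nonsense (stop) barcodes in the count table")
    out = sample_sheet.copy()
    offsets = []
    for sid in out["sample_id"]:
        total = int(stops[sid].sum())
        if total <= 0:
            raise ValueError(f"sample {sid!r} has zero stop-barcode counts; offset undefined")
        offsets.append(np.log(total))
    out["offset"] = offsets
    return out


def qc_summaries(counts: pd.DataFrame, sample_sheet: pd.DataFrame) -> dict:
    """Library-level QC: coverage medians and replicate agreement.

    Reports the median count per barcode per sample, the median-of-medians
    barcodes per variant, and the mean Pearson correlation of log1p counts
    between replicate pairs within each condition.
    """
    scols = sample_columns(counts)
    median_reads = float(np.median(counts[scols].to_numpy()))

    per_variant = counts.groupby("variant")["barcode"].nunique()
    median_barcodes_per_variant = float(per_variant.median())

    corrs = []
    for _, grp in sample_sheet.groupby("condition"):
        sids = grp["sample_id"].tolist()
        for i in range(len(sids)):
            for j in range(i + 1, len(sids)):
                a = np.log1p(counts[sids[i]].to_numpy(float))
                b = np.log1p(counts[sids[j]].to_numpy(float))
                if a.std() > 0 and b.std() > 0:
                    corrs.append(float(np.corrcoef(a, b)[0, 1]))
    return {
        "median_reads_per_barcode_per_sample": median_reads,
        "median_barcodes_per_variant": median_barcodes_per_variant,
        "inter_replicate_log1p_correlation": float(np.mean(corrs)) if corrs else float("nan"),
        "n_barcodes": int(counts["barcode"].nunique()),
        "n_variants": int(counts["variant"].nunique()),
        "n_samples": len(scols),
    }


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    return counts


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "condition", "replicate"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    dup = sheet.duplicated(["condition", "replicate"])
    if dup.any():
        raise ValueError("duplicate (condition, replicate) pairs in sample sheet")
    return sheet
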