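"""Variant-barcode map construction and filtering.

A barcode is a 21-nt DNA tag linked to a single designed oligo (variant).
The map is built from merged plasmid-library reads: the first 21 nt of each
read are the barcode, the remainder is the variant insert, which is matched
exactly against the designed oligo dictionary. Oligo-barcode pairs are then
filtered on barcode length, read depth and purity in both sequencing
replicates before being accepted into the map.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from typing import Iterable, Iterator

import pandas as pd

BARCODE_LEN = 21

#: default filter thresholds; depth and purity are strict (>) comparisons
DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_PURITY = 0.75

DESIGN_COLUMNS = ["oligo_id", "position", "wt_aa", "alt_aa", "insert_seq", "subregion"]

MAP_COLUMNS = [
    "barcode",
    "oligo_id",
    "position",
    "wt_aa",
    "alt_aa",
    "depth_rep1",
    "depth_rep2",
    "purity_rep1",
    "purity_rep2",
]


def variant_label(wt_aa: str, position: int, alt_aa: str) -> str:
    """Human-readable variant name; synonymous entries are wild-type."""
    if alt_aa == wt_aa:
        return "WT"
    return f"{wt_aa}{int(position)}{alt_aa}"


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check the designed-oligo table invariants and return it unchanged.

    Requires unique oligo ids, non-empty inserts, and at most one record
    per (position, alt_aa).
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design.empty:
        raise ValueError("design table is empty")
    if design["oligo_id"].duplicated().any():
        dups = design.loc[design["oligo_id"].duplicated(), "oligo_id"].tolist()
        raise ValueError(f"duplicate oligo_id values: {dups[:5]}")
    if (design["insert_seq"].str.len() == 0).any():
        raise ValueError("empty insert_seq in design")
    key = design[["position", "alt_aa"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise ValueError("more than one oligo per (position, alt_aa)")
    return design


def read_design(path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, sep="\t"))


def write_design(design: pd.DataFrame, path) -> None:
    validate_design(design).to_csv(path, sep="\t", index=False)


def design_variant_labels(design: pd.DataFrame) -> pd.Series:
    """Variant label per design row (synonymous rows labelled WT)."""
    return design.apply(
        lambda r: variant_label(r["wt_aa"], r["position"], r["alt_aa"]), axis=1
    )


# ---------------------------------------------------------------------------
# read-level operations


def extract_barcode(read: str) -> tuple[str, str] | None:
    """Split a merged read into its 21-nt barcode prefix and the insert.

    Returns ``None`` for reads of 21 nt or shorter, which carry no insert
    and cannot be matched; callers count and skip them.
    """
    if len(read) <= BARCODE_LEN:
        return None
    return read[:BARCODE_LEN], read[BARCODE_LEN:]


class InsertIndex:
    """Exact-lookup index from insert sequence to oligo_id.

    Replaces unique alignment against the designed library: the library is a
    closed dictionary, so strict uniqueness is preserved by exact matching.
    An optional edit-distance-1 rescue is available but off by default.
    """

    def __init__(self, design: pd.DataFrame, rescue_one_mismatch: bool = False):
        validate_design(design)
        self._exact: dict[str, list[str]] = defaultdict(list)
        for oligo_id, seq in zip(design["oligo_id"], design["insert_seq"]):
            self._exact[seq].append(oligo_id)
        self.rescue_one_mismatch = rescue_one_mismatch

    def match(self, insert: str) -> str | None:
        """Return the unique matching oligo_id, or None.

        None covers unmatched inserts and, defensively, ambiguous ones
        (only possible with duplicate inserts, which the design forbids).
        """
        hits = self._exact.get(insert)
        if hits is not None:
            return hits[0] if len(hits) == 1 else None
        if self.rescue_one_mismatch:
            return self._rescue(insert)
        return None

    def _rescue(self, insert: str) -> str | None:
        found: set[str] = set()
        for base in "ACGT":
            for i in range(len(insert)):
                if insert[i] == base:
                    continue
                hits = self._exact.get(insert[:i] + base + insert[i + 1:])
                if hits:
                    found.update(hits)
        return found.pop() if len(found) == 1 else None


def match_insert(insert: str, design: pd.DataFrame) -> str | None:
    """One-shot exact match of an insert against the design (see InsertIndex)."""
    return InsertIndex(design).match(insert)


def compute_purity(pair_reads: int, barcode_total_reads: int) -> float:
    """Fraction of a barcode's reads supporting one oligo pairing."""
    if barcode_total_reads <= 0:
        raise ValueError("barcode_total_reads must be positive")
    if pair_reads < 0 or pair_reads > barcode_total_reads:
        raise ValueError("need 0 <= pair_reads <= barcode_total_reads")
    return pair_reads / barcode_total_reads


# ---------------------------------------------------------------------------
# per-replicate tallies


@dataclasses.dataclass
class PairStats:
    """Majority oligo-barcode pairing per barcode for one mapping replicate.

    ``table`` columns: barcode, oligo_id, pair_reads, barcode_total_reads,
    purity. ``n_short`` / ``n_unmatched`` count skipped reads;
    ``n_ambiguous`` counts barcodes whose top two oligos tied.
    """

    table: pd.DataFrame
    n_reads: int
    n_short: int
    n_unmatched: int
    n_ambiguous: int


def tally_pairs(
    reads: Iterable[str], design: pd.DataFrame, rescue_one_mismatch: bool = False
) -> PairStats:
    """Count oligo-barcode pairs in one replicate's merged reads.

    The barcode total counts every read carrying the barcode, matched or
    not, so purity reflects both chimeras and unmatchable inserts.
    """
    index = InsertIndex(design, rescue_one_mismatch=rescue_one_mismatch)
    pair_counts: Counter[tuple[str, str]] = Counter()
    totals: Counter[str] = Counter()
    n_reads = n_short = n_unmatched = 0
    for read in reads:
        n_reads += 1
        split = extract_barcode(read)
        if split is None:
            n_short += 1
            continue
        barcode, insert = split
        totals[barcode] += 1
        oligo = index.match(insert)
        if oligo is None:
            n_unmatched += 1
            continue
        pair_counts[(barcode, oligo)] += 1

    best: dict[str, tuple[str, int]] = {}
    ambiguous: set[str] = set()
    for (barcode, oligo), n in pair_counts.items():
        cur = best.get(barcode)
        if cur is None or n > cur[1]:
            best[barcode] = (oligo, n)
            ambiguous.discard(barcode)
        elif n == cur[1]:
            ambiguous.add(barcode)
    rows = [
        (bc, oligo, n, totals[bc], n / totals[bc])
        for bc, (oligo, n) in best.items()
        if bc not in ambiguous
    ]
    table = pd.DataFrame(
        rows,
        columns=["barcode", "oligo_id", "pair_reads", "barcode_total_reads", "purity"],
    )
    return PairStats(
        table=table,
        n_reads=n_reads,
        n_short=n_short,
        n_unmatched=n_unmatched,
        n_ambiguous=len(ambiguous),
    )


# ---------------------------------------------------------------------------
# filtering


def filter_map(
    stats_rep1: PairStats | pd.DataFrame,
    stats_rep2: PairStats | pd.DataFrame | None,
    design: pd.DataFrame,
    *,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_purity: float = DEFAULT_MIN_PURITY,
    allow_single_replicate: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Apply the length/depth/purity filter chain in both replicates.

    A pair survives iff, in each replicate: the barcode is exactly 21 nt,
    barcode_total_reads > min_depth, and purity > min_purity (both strict),
    and both replicates agree on the majority oligo. Returns the map table
    and a provenance dict with per-rule removal counts and the thresholds.
    """
    t1 = stats_rep1.table if isinstance(stats_rep1, PairStats) else stats_rep1
    if stats_rep2 is None:
        if not allow_single_replicate:
            raise ValueError(
                "two mapping replicates required; pass allow_single_replicate=True "
                "to override"
            )
        t2 = t1
    else:
        t2 = stats_rep2.table if isinstance(stats_rep2, PairStats) else stats_rep2

    merged = t1.merge(t2, on="barcode", how="outer", suffixes=("_rep1", "_rep2"))
    removed = {
        "absent_in_replicate": 0,
        "oligo_disagreement": 0,
        "barcode_length": 0,
        "depth": 0,
        "purity": 0,
    }

    present = merged["oligo_id_rep1"].notna() & merged["oligo_id_rep2"].notna()
    removed["absent_in_replicate"] = int((~present).sum())
    merged = merged[present]

    agree = merged["oligo_id_rep1"] == merged["oligo_id_rep2"]
    removed["oligo_disagreement"] = int((~agree).sum())
    merged = merged[agree]

    # the three paper rules; order irrelevant, counts attribute each removal
    # to every rule it violates
    good_len = merged["barcode"].str.len() == BARCODE_LEN
    good_depth = (merged["barcode_total_reads_rep1"] > min_depth) & (
        merged["barcode_total_reads_rep2"] > min_depth
    )
    good_purity = (merged["purity_rep1"] > min_purity) & (
        merged["purity_rep2"] > min_purity
    )
    removed["barcode_length"] = int((~good_len).sum())
    removed["depth"] = int((~good_depth).sum())
    removed["purity"] = int((~good_purity).sum())
    merged = merged[good_len & good_depth & good_purity]

    anno = design.set_index("oligo_id")[["position", "wt_aa", "alt_aa"]]
    out = pd.DataFrame(
        {
            "barcode": merged["barcode"].to_numpy(),
            "oligo_id": merged["oligo_id_rep1"].to_numpy(),
            "depth_rep1": merged["barcode_total_reads_rep1"].astype(int).to_numpy(),
            "depth_rep2": merged["barcode_total_reads_rep2"].astype(int).to_numpy(),
            "purity_rep1": merged["purity_rep1"].to_numpy(),
            "purity_rep2": merged["purity_rep2"].to_numpy(),
        }
    )
    out = out.join(anno, on="oligo_id")
    out = out[MAP_COLUMNS].sort_values("barcode").reset_index(drop=True)
    provenance = {
        "min_depth": min_depth,
        "min_purity": min_purity,
        "barcode_length": BARCODE_LEN,
        "removed": removed,
        "n_retained": len(out),
    }
    return out, provenance


def build_map(
    reads_rep1: Iterable[str],
    reads_rep2: Iterable[str],
    design: pd.DataFrame,
    **filter_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Tally both replicates and filter in one step."""
    s1 = tally_pairs(reads_rep1, design)
    s2 = tally_pairs(reads_rep2, design)
    vb_map, provenance = filter_map(s1, s2, design, **filter_kwargs)
    provenance["replicate_read_stats"] = [
        {
            "n_reads": s.n_reads,
            "n_short": s.n_short,
            "n_unmatched": s.n_unmatched,
            "n_ambiguous_barcodes": s.n_ambiguous,
        }
        for s in (s1, s2)
    ]
    return vb_map, provenance


def read_map(path) -> pd.DataFrame:
    vb_map = pd.read_csv(path, sep="\t")
    missing = [c for c in MAP_COLUMNS if c not in vb_map.columns]
    if missing:
        raise ValueError(f"variant-barcode map missing columns: {missing}")
    return vb_map


def write_map(vb_map: pd.DataFrame, path) -> None:
    vb_map.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ plumbing


def iter_fastq_seqs(path) -> Iterator[str]:
    """Yield read sequences from a (optionally gzipped) FASTQ file."""
    from Bio import SeqIO

    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield str(record.seq)
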