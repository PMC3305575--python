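"""Read-level processing: barcode demultiplexing and read filters.

The pipeline applies, in this order: barcode assignment of pooled reads to
samples, removal of PCR duplicates (reads sharing start and end mapping
coordinates, keeping the top-mapping-quality read per group), and expunging
of reads with mapping quality below 50.  The duplicate-then-mapq order is
load-bearing: removing low-mapq reads first could promote a lower-quality
duplicate to group representative.

Reads travel in a documented internal alignment dialect, a TSV with columns
read_id, tag (the sample barcode as sequenced), contig, start (1-based),
end, strand, mapq, bases, quals (Phred+33).  The leading read_id column
exists so duplicate-group ties can be broken deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sim import READ_COLUMNS


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read after demultiplexing."""

    sample: str
    contig: str
    start: int
    end: int
    strand: str
    mapq: int
    bases: str
    quals: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("read start after end")
        if len(self.bases) != self.end - self.start + 1 or len(self.bases) != len(self.quals):
            raise ValueError("bases/quals length must equal end - start + 1")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


class BarcodeManifest:
    """Sample -> barcode mapping with the separation guarantee.

    Barcodes must be unique, equal length, and pairwise Hamming distance
    > 2 * max_mismatch, which makes nearest-barcode assignment unambiguous.
    """

    def __init__(self, barcodes: dict[str, str], max_mismatch: int = 1):
        if not barcodes:
            raise ValueError("empty manifest")
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        lengths = {len(b) for b in barcodes.values()}
        if len(lengths) != 1:
            raise ValueError("barcodes must all have the same length")
        if len(set(barcodes.values())) != len(barcodes):
            raise ValueError("barcodes must be unique")
        items = sorted(barcodes.items())
        for i, (si, bi) in enumerate(items):
            for sj, bj in items[i + 1 :]:
                d = sum(a != b for a, b in zip(bi, bj))
                if d <= 2 * max_mismatch:
                    raise ValueError(
                        f"barcodes of {si} and {sj} are Hamming distance {d} apart; "
                        f"need > {2 * max_mismatch} for unambiguous assignment"
                    )
        self.samples = [s for s, _ in items]
        self.barcodes = dict(items)
        self.max_mismatch = max_mismatch
        self.length = lengths.pop()

    @classmethod
    def from_truth(cls, truth, max_mismatch: int = 1) -> "BarcodeManifest":
        return cls(dict(zip(truth.samples["sample"], truth.samples["barcode"])), max_mismatch)

    @classmethod
    def read(cls, path, max_mismatch: int = 1) -> "BarcodeManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["sample"], df["barcode"])), max_mismatch)

    def write(self, path) -> None:
        pd.DataFrame(
            {"sample": self.samples, "barcode": [self.barcodes[s] for s in self.samples]}
        ).to_csv(path, sep="\t", index=False)


def _tag_matrix(tags: pd.Series, length: int) -> np.ndarray:
    arr = np.frombuffer("".join(tags).encode(), dtype=np.uint8)
    return arr.reshape(len(tags), length)


def assign_barcodes(
    reads: pd.DataFrame, manifest: BarcodeManifest
) -> tuple[pd.DataFrame, int]:
    """Assign pooled reads to samples by nearest barcode within max_mismatch.

    Returns (reads with a ``sample`` column, unassigned count).  Reads whose
    tag is not within ``max_mismatch`` of any barcode are dropped from the
    returned frame and counted; assignment is a partition, so
    len(assigned) + unassigned == len(reads).
    """
    if reads.empty:
        out = reads.copy()
        out["sample"] = pd.Series(dtype=str)
        return out, 0
    if (reads["tag"].str.len() != manifest.length).any():
        raise ValueError("read tag length differs from manifest barcode length")
    tags = _tag_matrix(reads["tag"], manifest.length)
    codes = _tag_matrix(
        pd.Series([manifest.barcodes[s] for s in manifest.samples]), manifest.length
    )
    # (n_reads, n_samples) Hamming distances
    dist = (tags[:, None, :] != codes[None, :, :]).sum(axis=2)
    best = dist.argmin(axis=1)
    ok = dist[np.arange(len(reads)), best] <= manifest.max_mismatch
    out = reads.loc[ok].copy()
    out["sample"] = np.array(manifest.samples)[best[ok]]
    return out, int((~ok).sum())


def demux_report(assigned: pd.DataFrame, manifest: BarcodeManifest, unassigned: int) -> pd.DataFrame:
    counts = assigned.groupby("sample").size()
    rows = [{"sample": s, "n_assigned": int(counts.get(s, 0))} for s in manifest.samples]
    rows.append({"sample": "__unassigned__", "n_assigned": unassigned})
    return pd.DataFrame(rows)


def remove_duplicates(reads: pd.DataFrame, with_strand: bool = False) -> pd.DataFrame:
    """Keep one read per (contig, start, end) group: the top-mapq read.

    Mapq ties are broken by lexicographically smallest read_id, making the
    operation deterministic and idempotent.  Output is sorted by coordinates.
    Set ``with_strand`` to include strand in the duplicate key.
    """
    if reads.empty:
        return reads.copy()
    key = ["contig", "start", "end"] + (["strand"] if with_strand else [])
    ordered = reads.sort_values(
        key + ["mapq", "read_id"], ascending=[True] * len(key) + [False, True], kind="stable"
    )
    return ordered.drop_duplicates(subset=key, keep="first").reset_index(drop=True)


def filter_mapq(reads: pd.DataFrame, min_mapq: int = 50) -> pd.DataFrame:
    """Expunge reads with mapping quality below ``min_mapq`` (>= passes)."""
    return reads.loc[reads["mapq"] >= min_mapq].reset_index(drop=True)


def process_sample_reads(
    reads: pd.DataFrame, min_mapq: int = 50, with_strand_dups: bool = False
) -> pd.DataFrame:
    """Duplicate removal followed by the mapq filter (order is fixed)."""
    return filter_mapq(remove_duplicates(reads, with_strand_dups), min_mapq)


def write_reads(reads: pd.DataFrame, path) -> None:
    cols = [c for c in READ_COLUMNS if c in reads.columns]
    extra = [c for c in reads.columns if c not in cols]
    reads[cols + extra].to_csv(path, sep="\t", index=False)


def read_reads(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"read_id": str, "tag": str, "contig": str, "strand": str, "bases": str, "quals": str},
    )
    for col in ("start", "end", "mapq"):
        df[col] = df[col].astype(int)
    return df
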