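"""Variant consequence annotation against the panel's toy gene models.

SNVs falling in CDS are classified by translating the affected codon before
and after the substitution (reverse-complementing on minus-strand
transcripts): same amino acid -> synonymous, stop gained -> nonsense, other
-> missense.  Exonic non-CDS positions are UTR; anything else inside or
around a gene is reported as intronic (targets only cover genes and their
boundaries, so no intergenic class is distinguished).  Indels overlapping CDS
are frameshift unless their length is a multiple of 3.

A variant hitting several transcripts is reported with its most severe
consequence (nonsense > frameshift > missense > inframe_indel > synonymous >
utr > intronic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .panel import PanelDesign, Transcript

SEVERITY_ORDER = [
    "nonsense",
    "frameshift",
    "missense",
    "inframe_indel",
    "synonymous",
    "utr",
    "intronic",
]
_SEVERITY = {c: i for i, c in enumerate(SEVERITY_ORDER)}

CODING_CLASSES = frozenset({"synonymous", "missense", "nonsense", "frameshift", "inframe_indel"})
NONSYNONYMOUS_CLASSES = frozenset({"missense", "nonsense"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Consequence:
    """Functional class of one variant, with protein change when coding."""

    klass: str
    gene: str | None = None
    protein_change: str | None = None

    def __post_init__(self):
        if self.klass not in _SEVERITY:
            raise ValueError(f"unknown consequence class {self.klass!r}")


def _classify_snv_in_tx(pos: int, ref: str, alt: str, tx: Transcript, reference) -> Consequence:
    off = tx.cds_offset(pos)
    if off is None:
        in_exon = any(s <= pos <= e for s, e in tx.exons)
        return Consequence("utr" if in_exon else "intronic", tx.gene)
    cds = tx.cds_sequence(reference)
    # base as read in translation orientation
    tx_ref, tx_alt = (ref, alt) if tx.strand == "+" else (
        ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT))
    if cds[off] != tx_ref:
        raise ValueError(
            f"reference mismatch at {tx.contig}:{pos} ({tx.gene}): "
            f"panel has {cds[off]}, variant claims {tx_ref}"
        )
    ci = off // 3
    codon = cds[3 * ci : 3 * ci + 3]
    mut = codon[: off % 3] + tx_alt + codon[off % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mut).translate())
    aa_alt_sym = "X" if aa_alt == "*" else aa_alt
    change = f"p.{aa_ref}{ci + 1}{aa_alt_sym}"
    if aa_alt == aa_ref:  # includes stop-retained (e.g. TAA -> TGA)
        return Consequence("synonymous", tx.gene, change)
    if aa_alt == "*":
        return Consequence("nonsense", tx.gene, change)
    return Consequence("missense", tx.gene, change)


def classify_snv(contig: str, pos: int, ref: str, alt: str, panel: PanelDesign) -> Consequence:
    """Classify a single-nucleotide substitution (1-based ``pos``)."""
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError("classify_snv expects a single-base substitution")
    if contig not in panel.reference:
        raise ValueError(f"unknown contig {contig}")
    if panel.reference[contig][pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at {contig}:{pos}: panel has "
            f"{panel.reference[contig][pos - 1]}, variant claims {ref}"
        )
    hits = [
        _classify_snv_in_tx(pos, ref, alt, tx, panel.reference)
        for tx in panel.transcripts
        if tx.contig == contig and tx.span[0] - 1 <= pos <= tx.span[1] + 1
    ]
    if not hits:
        return Consequence("intronic")
    return min(hits, key=lambda c: _SEVERITY[c.klass])


def classify_indel(contig: str, pos: int, length: int, var_type: str, panel: PanelDesign) -> Consequence:
    """Classify an insertion/deletion of ``length`` bases at 1-based ``pos``.

    For deletions the affected reference span is [pos, pos+length-1]; an
    insertion is anchored between pos and pos+1.
    """
    if var_type not in ("insertion", "deletion"):
        raise ValueError(f"var_type must be insertion/deletion, got {var_type!r}")
    if length < 1:
        raise ValueError("indel length must be >= 1")
    span = (pos, pos + length - 1) if var_type == "deletion" else (pos, pos + 1)
    hits = []
    for tx in panel.transcripts:
        if tx.contig != contig or span[1] < tx.span[0] - 1 or span[0] > tx.span[1] + 1:
            continue
        in_cds = any(s <= span[1] and span[0] <= e for s, e in tx.cds)
        if in_cds:
            klass = "inframe_indel" if length % 3 == 0 else "frameshift"
        elif any(s <= span[1] and span[0] <= e for s, e in tx.exons):
            klass = "utr"
        else:
            klass = "intronic"
        hits.append(Consequence(klass, tx.gene))
    if not hits:
        return Consequence("intronic")
    return min(hits, key=lambda c: _SEVERITY[c.klass])


def annotate_variants(variants: pd.DataFrame, panel: PanelDesign) -> pd.DataFrame:
    """Annotate a table with columns contig,pos,ref,alt,var_type.

    Returns a copy with consequence / gene / protein_change columns appended.
    """
    out = variants.copy()
    klasses, genes, changes = [], [], []
    for row in out.itertuples(index=False):
        if row.var_type == "SNV":
            c = classify_snv(row.contig, int(row.pos), row.ref, row.alt, panel)
        else:
            length = abs(len(row.ref) - len(row.alt)) or 1
            c = classify_indel(row.contig, int(row.pos), length, row.var_type, panel)
        klasses.append(c.klass)
        genes.append(c.gene)
        changes.append(c.protein_change)
    out["consequence"] = klasses
    out["gene"] = genes
    out["protein_change"] = changes
    return out


def flag_novelty(variants: pd.DataFrame, known_tables: list[pd.DataFrame]) -> tuple[pd.Series, int]:
    """Flag each variant known/novel against user-supplied known-variant tables.

    Tables need columns contig,pos,ref,alt; malformed rows are skipped and
    counted.  Returns (boolean Series ``known``, n_skipped_rows).
    """
    known_keys: set[tuple] = set()
    skipped = 0
    for tab in known_tables:
        for row in tab.itertuples(index=False):
            try:
                key = (str(row.contig), int(row.pos), str(row.ref).upper(), str(row.alt).upper())
            except (AttributeError, TypeError, ValueError):
                skipped += 1
                continue
            if not key[2] or not key[3]:
                skipped += 1
                continue
            known_keys.add(key)
    flags = pd.Series(
        [
            (str(r.contig), int(r.pos), str(r.ref).upper(), str(r.alt).upper()) in known_keys
            for r in variants.itertuples(index=False)
        ],
        index=variants.index,
        name="known",
    )
    return flags, skipped


DEFAULT_SPECTRUM_EDGES = (0.05, 0.10, 0.20, 0.50)


def frequency_spectrum(
    maf: pd.Series,
    minor_count: pd.Series,
    consequences: pd.Series,
    edges: tuple[float, ...] = DEFAULT_SPECTRUM_EDGES,
) -> pd.DataFrame:
    """Site-frequency spectrum by functional class.

    Bin 0 holds singletons (minor-allele count == 1); the remaining bins are
    (previous edge, edge] intervals of minor allele frequency starting just
    above the singleton frequency.  Returns a bin x consequence count table
    with per-bin nonsynonymous/synonymous ratio (``inf`` when no synonymous
    variants fall in a bin).
    """
    if list(edges) != sorted(edges) or any(not 0 < e <= 1 for e in edges):
        raise ValueError("edges must be increasing and within (0, 1]")
    labels = ["singleton"] + [
        f"({edges[i - 1] if i else 'singleton'},{edges[i]:g}]" for i in range(len(edges))
    ]
    bins = np.full(len(maf), -1, dtype=int)
    singleton = minor_count.to_numpy() == 1
    bins[singleton] = 0
    rest = ~singleton
    idx = np.searchsorted(np.asarray(edges), maf.to_numpy()[rest], side="left")
    bins[rest] = idx + 1
    ok = bins < len(labels)
    table = pd.crosstab(
        pd.Categorical([labels[b] for b in bins[ok]], categories=labels),
        consequences[ok],
        dropna=False,
    ).reindex(labels, fill_value=0)
    ns = table.get("missense", 0) + table.get("nonsense", 0)
    syn = table.get("synonymous", 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(syn > 0, ns / np.where(syn > 0, syn, 1), np.inf)
    table["nonsyn_syn_ratio"] = ratio
    return table
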