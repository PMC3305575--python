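"""Pileup construction and QC-annotated variant calling.

Per sample, filtered reads are stacked into per-position pileups over the
target.  A candidate variant is emitted wherever at least ``min_alt_reads``
base-quality-passing observations support a non-reference allele; its call
quality is the Phred-scaled probability of seeing that many error reads
under a binomial error model with the per-observation error rate implied by
the base quality scores.  A final QC step applies the allele-balance,
strand-bias, depth and quality filters; failed calls are retained with their
reasons since downstream genotyping treats failed variant evidence as
missing rather than reference.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PanelDesign

FAIL_LOW_AB = "low_allele_balance"
FAIL_STRAND = "strand_bias"
FAIL_DEPTH = "low_depth"
FAIL_QUALITY = "low_quality"

_MAX_QUAL = 9999.0


@dataclass
class CallParams:
    """Calling and QC thresholds (all configurable; QC values are the
    allele-balance >= 20%, both-strand, 10X-depth criteria)."""

    min_base_qual: int = 20
    min_alt_reads: int = 2
    hom_threshold: float = 0.8
    min_call_quality: float = 20.0
    min_depth: int = 10
    min_allele_balance: float = 0.20

    def validate(self):
        if not 0 < self.hom_threshold <= 1 or not 0 <= self.min_allele_balance <= 1:
            raise ValueError("thresholds out of range")
        if self.min_alt_reads < 1 or self.min_depth < 0 or self.min_base_qual < 0:
            raise ValueError("count thresholds out of range")


@dataclass
class PileupSite:
    """Stack of read observations over one reference position."""

    contig: str
    pos: int
    ref: str
    # observation arrays, one entry per covering read (post base-qual filter)
    bases: np.ndarray  # str '-' encodes a deleted base
    quals: np.ndarray
    strands: np.ndarray
    mapqs: np.ndarray

    @property
    def depth(self) -> int:
        return len(self.bases)


@dataclass
class VariantCall:
    contig: str
    pos: int
    ref: str
    alt: str
    var_type: str  # SNV / insertion / deletion
    depth: int
    alt_reads: int
    ref_reads: int
    allele_balance: float
    strand_counts: tuple[int, int]  # alt observations on (+, -)
    genotype: str  # het / homvar
    call_quality: float
    qc_status: str = "PASS"
    fail_reasons: tuple[str, ...] = ()
    multiallelic: bool = False
    single_strand_site: bool = False  # ALL coverage on one strand, not just alt

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)

    def validate(self):
        if not 0 <= self.allele_balance <= 1:
            raise ValueError("allele balance outside [0,1]")
        if self.alt_reads > self.depth:
            raise ValueError("alt reads exceed depth")
        if (self.qc_status == "FAIL") != bool(self.fail_reasons):
            raise ValueError("qc_status must be FAIL iff fail_reasons nonempty")


@dataclass
class SampleCalls:
    """One sample's candidate calls plus post-filter target depth."""

    sample: str
    calls: list[VariantCall]
    depth: dict[str, np.ndarray]  # contig -> depth aligned to panel.target_positions
    _pos_index: dict[str, dict[int, int]] = field(default_factory=dict, repr=False)
    n_offpanel_reads: int = 0

    def depth_at(self, contig: str, pos: int) -> int:
        idx = self._pos_index.get(contig, {}).get(pos)
        return 0 if idx is None else int(self.depth[contig][idx])

    def passing(self) -> list[VariantCall]:
        return [c for c in self.calls if c.qc_status == "PASS"]


def build_pileup(
    reads: pd.DataFrame, panel: PanelDesign, min_base_qual: int = 20
) -> tuple[list[PileupSite], dict[str, np.ndarray], dict[str, dict[int, int]], int]:
    """Stack one sample's reads into pileups over the target.

    Returns (mismatch sites, per-contig depth arrays aligned to
    ``panel.target_positions``, per-contig position->index maps, count of
    reads rejected for lying off the panel contigs).  Only observations with
    base quality >= ``min_base_qual`` contribute.  Sites are materialised
    only where at least one non-reference observation survives; depth arrays
    cover every target position.
    """
    pos_index: dict[str, dict[int, int]] = {}
    depth: dict[str, np.ndarray] = {}
    for contig in sorted(panel.target_intervals):
        tp = panel.target_positions(contig)
        pos_index[contig] = {int(p): i for i, p in enumerate(tp)}
        depth[contig] = np.zeros(len(tp), dtype=np.int32)

    n_offpanel = int((~reads["contig"].isin(pos_index)).sum()) if len(reads) else 0
    sites: list[PileupSite] = []
    for contig in sorted(pos_index):
        sub = reads.loc[reads["contig"] == contig]
        if sub.empty:
            continue
        tp = panel.target_positions(contig)
        # dense lookup: 1-based position -> target index (or -1)
        lo, hi = int(tp.min()), int(tp.max())
        lookup = np.full(hi - lo + 2, -1, dtype=np.int64)
        lookup[tp - lo] = np.arange(len(tp))
        refseq = np.frombuffer(panel.reference[contig].encode(), dtype=np.uint8)

        # flatten all read bases into parallel observation arrays, per length
        pos_l, base_l, qual_l, strand_l, mapq_l = [], [], [], [], []
        for L, grp in sub.groupby(sub["bases"].str.len()):
            nL = len(grp)
            starts = grp["start"].to_numpy()
            bases = np.frombuffer("".join(grp["bases"]).encode(), dtype=np.uint8).reshape(nL, L)
            quals = (
                np.frombuffer("".join(grp["quals"]).encode(), dtype=np.uint8).reshape(nL, L) - 33
            )
            positions = starts[:, None] + np.arange(L)[None, :]
            strands = np.repeat(grp["strand"].to_numpy(), L).reshape(nL, L)
            mapqs = np.repeat(grp["mapq"].to_numpy(), L).reshape(nL, L)
            keep = (quals >= min_base_qual) & (positions >= lo) & (positions <= hi)
            keep &= np.where(keep, lookup[np.clip(positions - lo, 0, hi - lo)] >= 0, False)
            pos_l.append(positions[keep])
            base_l.append(bases[keep])
            qual_l.append(quals[keep])
            strand_l.append(strands[keep])
            mapq_l.append(mapqs[keep])
        if not pos_l:
            continue
        positions = np.concatenate(pos_l)
        bases = np.concatenate(base_l)
        quals = np.concatenate(qual_l)
        strands = np.concatenate(strand_l)
        mapqs = np.concatenate(mapq_l)

        idx = lookup[positions - lo]
        np.add.at(depth[contig], idx, 1)

        mismatch = bases != refseq[positions - 1]
        mm_positions = np.unique(positions[mismatch])
        for pos in mm_positions.tolist():
            at = positions == pos
            sites.append(
                PileupSite(
                    contig,
                    int(pos),
                    chr(refseq[pos - 1]),
                    bases=np.array([chr(b) for b in bases[at]]),
                    quals=quals[at].astype(int),
                    strands=strands[at],
                    mapqs=mapqs[at].astype(int),
                )
            )
    return sites, depth, pos_index, n_offpanel


def call_site(site: PileupSite, params: CallParams | None = None) -> VariantCall | None:
    """Candidate call at one pileup site, or None below ``min_alt_reads``.

    At multi-allelic sites (more than one alternate allele passing the
    read-support threshold) the majority alternate is emitted and the call is
    flagged.  Call quality is -10 log10 P[X >= alt_reads] with
    X ~ Binomial(depth, mean per-observation error).
    """
    params = params or CallParams()
    params.validate()
    counts = Counter(site.bases.tolist())
    alt_counts = {a: c for a, c in counts.items() if a != site.ref and c >= params.min_alt_reads}
    if not alt_counts:
        return None
    alt = max(sorted(alt_counts), key=lambda a: alt_counts[a])
    alt_reads = alt_counts[alt]
    ref_reads = counts.get(site.ref, 0)
    depth = site.depth
    ab = alt_reads / (ref_reads + alt_reads)
    err = float(np.mean(10 ** (-site.quals.astype(float) / 10)))
    tail = stats.binom.sf(alt_reads - 1, depth, err)
    quality = _MAX_QUAL if tail <= 0 else min(-10 * math.log10(tail), _MAX_QUAL)
    alt_mask = site.bases == alt
    plus = int((site.strands[alt_mask] == "+").sum())
    minus = int(alt_mask.sum() - plus)
    if alt == "-":
        var_type = "deletion"
    elif alt.startswith("+"):
        var_type = "insertion"
    else:
        var_type = "SNV"
    call = VariantCall(
        contig=site.contig,
        pos=site.pos,
        ref=site.ref,
        alt=alt,
        var_type=var_type,
        depth=depth,
        alt_reads=alt_reads,
        ref_reads=ref_reads,
        allele_balance=ab,
        strand_counts=(plus, minus),
        genotype="het" if ab < params.hom_threshold else "homvar",
        call_quality=quality,
        multiallelic=len(alt_counts) > 1,
        single_strand_site=len(set(site.strands.tolist())) < 2,
    )
    call.validate()
    return call


def qc_filter(call: VariantCall, params: CallParams | None = None) -> VariantCall:
    """Apply the QC criteria; failed calls keep their reasons, never dropped.

    Fails with low_allele_balance below 20% (20% passes), strand_bias when
    the alternate allele was not seen on both read orientations (including
    sites whose entire coverage is single-stranded, conservatively; such
    sites carry a distinct flag so users may exempt them), low_depth below
    10 reads, and low_quality below the call-quality floor.
    """
    params = params or CallParams()
    reasons = []
    if call.allele_balance < params.min_allele_balance:
        reasons.append(FAIL_LOW_AB)
    if min(call.strand_counts) == 0:
        reasons.append(FAIL_STRAND)
    if call.depth < params.min_depth:
        reasons.append(FAIL_DEPTH)
    if call.call_quality < params.min_call_quality:
        reasons.append(FAIL_QUALITY)
    call.fail_reasons = tuple(reasons)
    call.qc_status = "FAIL" if reasons else "PASS"
    call.validate()
    return call


def call_sample(
    reads: pd.DataFrame, panel: PanelDesign, sample: str, params: CallParams | None = None
) -> SampleCalls:
    """Full per-sample calling: pileup -> candidate calls -> QC."""
    params = params or CallParams()
    sites, depth, pos_index, n_off = build_pileup(reads, panel, params.min_base_qual)
    calls = []
    for site in sites:
        call = call_site(site, params)
        if call is not None:
            calls.append(qc_filter(call, params))
    return SampleCalls(sample, calls, depth, pos_index, n_off)


# ------------------------------------------------------------------ VCF I/O

def _vcf_alleles(call: VariantCall, reference: dict[str, str]) -> tuple[int, str, str]:
    """Normalise internal allele spelling to VCF (anchor base for indels)."""
    if call.var_type == "SNV":
        return call.pos, call.ref, call.alt
    anchor_pos = call.pos - 1
    anchor = reference[call.contig][anchor_pos - 1]
    if call.var_type == "deletion":
        return anchor_pos, anchor + call.ref, anchor
    return anchor_pos, anchor, anchor + call.alt[1:]


def write_vcf(callset: SampleCalls, panel: PanelDesign, path: str | Path) -> None:
    """Single-sample VCF v4.2; FILTER carries the QC fail reasons."""
    lines = ["##fileformat=VCFv4.2", "##source=hemoseq"]
    for contig in sorted(panel.reference):
        lines.append(f"##contig=<ID={contig},length={len(panel.reference[contig])}>")
    for rid, desc in [
        (FAIL_LOW_AB, "Allele balance below threshold"),
        (FAIL_STRAND, "Variant allele not observed on both strands"),
        (FAIL_DEPTH, "Coverage below threshold"),
        (FAIL_QUALITY, "Call quality below threshold"),
    ]:
        lines.append(f'##FILTER=<ID={rid},Description="{desc}">')
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=ALTR,Number=1,Type=Integer,Description="Alt-supporting reads">',
        '##INFO=<ID=AB,Number=1,Type=Float,Description="Allele balance">',
        '##INFO=<ID=SBP,Number=1,Type=Integer,Description="Alt reads on plus strand">',
        '##INFO=<ID=SBM,Number=1,Type=Integer,Description="Alt reads on minus strand">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + callset.sample,
    ]
    for call in sorted(callset.calls, key=lambda c: (c.contig, c.pos, c.alt)):
        pos, ref, alt = _vcf_alleles(call, panel.reference)
        filt = "PASS" if call.qc_status == "PASS" else ";".join(call.fail_reasons)
        info = (
            f"DP={call.depth};ALTR={call.alt_reads};AB={call.allele_balance:.4f};"
            f"SBP={call.strand_counts[0]};SBM={call.strand_counts[1]}"
        )
        gt = "0/1" if call.genotype == "het" else "1/1"
        qual = f"{call.call_quality:.1f}"
        lines.append(
            f"{call.contig}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t{filt}\t{info}\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def calls_frame(callsets: dict[str, SampleCalls]) -> pd.DataFrame:
    """Flat per-call table across samples (debugging / reports)."""
    rows = []
    for sample, cs in callsets.items():
        for c in cs.calls:
            rows.append(
                {
                    "sample": sample,
                    "contig": c.contig,
                    "pos": c.pos,
                    "ref": c.ref,
                    "alt": c.alt,
                    "var_type": c.var_type,
                    "depth": c.depth,
                    "alt_reads": c.alt_reads,
                    "allele_balance": c.allele_balance,
                    "plus": c.strand_counts[0],
                    "minus": c.strand_counts[1],
                    "genotype": c.genotype,
                    "call_quality": c.call_quality,
                    "qc_status": c.qc_status,
                    "fail_reasons": ",".join(c.fail_reasons),
                }
            )
    return pd.DataFrame(rows)
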