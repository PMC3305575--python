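"""Capture-panel model: reference sequences, toy gene models, target intervals.

The panel is a scaled-down analogue of a multi-gene capture design targeting
the protein-coding exons, UTRs and intron-exon boundaries of a set of
candidate genes.  It bundles everything downstream stages need: the reference
sequence of each contig, per-transcript exon/CDS structure (both strands), the
merged target intervals (BED convention, 0-based half-open) and named gene
sets used by the collapsing burden analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
NONSTOP_CODONS = [c for c in _CODONS if c not in STOP_CODONS]


def merge_intervals(intervals):
    """Merge 0-based half-open intervals; returns sorted non-overlapping list.

    Adjacent (abutting) intervals are merged as well, so the result is the
    minimal sorted cover.
    """
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"interval end {e} before start {s}")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class Transcript:
    """One transcript: exon and CDS intervals, 1-based inclusive, genomic order."""

    gene: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"CDS ({cs},{ce}) not nested in an exon of {self.gene}")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length of {self.gene} not a multiple of 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_sequence(self, reference: dict[str, str]) -> str:
        """Spliced CDS in translation order (reverse-complemented on minus)."""
        seq = "".join(reference[self.contig][s - 1 : e] for s, e in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of genomic ``pos`` within the spliced CDS, or None."""
        off = 0
        blocks = self.cds if self.strand == "+" else self.cds[::-1]
        for s, e in blocks:
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        return None


@dataclass
class PanelDesign:
    """A capture panel: reference, gene models, merged targets, gene sets."""

    reference: dict[str, str]
    transcripts: list[Transcript]
    target_intervals: dict[str, list[tuple[int, int]]]
    gene_sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def validate(self) -> None:
        for contig, ivs in self.target_intervals.items():
            if contig not in self.reference:
                raise ValueError(f"target contig {contig} has no reference sequence")
            clen = len(self.reference[contig])
            if ivs != merge_intervals(ivs):
                raise ValueError(f"target intervals on {contig} not merged/sorted")
            for s, e in ivs:
                if s < 0 or e > clen:
                    raise ValueError(f"interval ({s},{e}) outside {contig} (len {clen})")
        for tx in self.transcripts:
            if tx.contig not in self.reference:
                raise ValueError(f"transcript {tx.gene} on unknown contig {tx.contig}")
        genes = {tx.gene for tx in self.transcripts}
        for name, members in self.gene_sets.items():
            unknown = set(members) - genes
            if unknown:
                raise ValueError(f"gene set {name} references unknown genes {sorted(unknown)}")

    @property
    def target_bp(self) -> int:
        return sum(e - s for ivs in self.target_intervals.values() for s, e in ivs)

    def in_target(self, contig: str, pos: int) -> bool:
        """Membership of a 1-based position in the merged target."""
        for s, e in self.target_intervals.get(contig, []):
            if s < pos <= e:
                return True
        return False

    def target_positions(self, contig: str) -> np.ndarray:
        """All 1-based target positions of one contig."""
        ivs = self.target_intervals.get(contig, [])
        if not ivs:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([np.arange(s + 1, e + 1) for s, e in ivs])

    def transcripts_of(self, gene: str) -> list[Transcript]:
        return [tx for tx in self.transcripts if tx.gene == gene]

    # ---------------------------------------------------------------- I/O

    def write(self, outdir: str | Path, prefix: str = "panel") -> dict[str, Path]:
        """Write FASTA / BED / gene-model TSV / gene-set TSV; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / f"{prefix}.fa",
            "bed": outdir / f"{prefix}.targets.bed",
            "genes": outdir / f"{prefix}.genes.tsv",
            "gene_sets": outdir / f"{prefix}.gene_sets.tsv",
        }
        records = [
            SeqRecord(Seq(seq), id=contig, description="")
            for contig, seq in sorted(self.reference.items())
        ]
        with open(paths["fasta"], "w") as fh:
            SeqIO.write(records, fh, "fasta")
        with open(paths["bed"], "w") as fh:
            for contig in sorted(self.target_intervals):
                for s, e in self.target_intervals[contig]:
                    fh.write(f"{contig}\t{s}\t{e}\n")
        with open(paths["genes"], "w") as fh:
            fh.write("gene\tcontig\tstrand\tfeature\tstart\tend\n")
            for tx in self.transcripts:
                for s, e in tx.exons:
                    fh.write(f"{tx.gene}\t{tx.contig}\t{tx.strand}\texon\t{s}\t{e}\n")
                for s, e in tx.cds:
                    fh.write(f"{tx.gene}\t{tx.contig}\t{tx.strand}\tCDS\t{s}\t{e}\n")
        with open(paths["gene_sets"], "w") as fh:
            fh.write("set\tgene\n")
            for name in sorted(self.gene_sets):
                for gene in sorted(self.gene_sets[name]):
                    fh.write(f"{name}\t{gene}\n")
        return paths

    @classmethod
    def read(cls, fasta, bed, genes, gene_sets=None) -> "PanelDesign":
        reference = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        targets: dict[str, list[tuple[int, int]]] = {}
        for line in Path(bed).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, s, e = line.split("\t")[:3]
            targets.setdefault(contig, []).append((int(s), int(e)))
        targets = {c: merge_intervals(ivs) for c, ivs in targets.items()}
        rows: dict[str, dict] = {}
        for line in Path(genes).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            gene, contig, strand, feature, s, e = line.split("\t")
            d = rows.setdefault(gene, {"contig": contig, "strand": strand, "exon": [], "CDS": []})
            d[feature].append((int(s), int(e)))
        transcripts = [
            Transcript(g, d["contig"], d["strand"], tuple(sorted(d["exon"])), tuple(sorted(d["CDS"])))
            for g, d in rows.items()
        ]
        sets: dict[str, frozenset[str]] = {}
        if gene_sets is not None:
            acc: dict[str, set] = {}
            for line in Path(gene_sets).read_text().splitlines()[1:]:
                if not line.strip():
                    continue
                name, gene = line.split("\t")
                acc.setdefault(name, set()).add(gene)
            sets = {k: frozenset(v) for k, v in acc.items()}
        panel = cls(reference, transcripts, targets, sets)
        panel.validate()
        return panel


def build_panel(
    n_genes: int,
    exons_per_gene: int = 3,
    seed: int = 0,
    *,
    codons_per_gene: int = 90,
    utr_len: int = 24,
    intron_len: int = 120,
    boundary_pad: int = 12,
    intergenic_gap: int = 300,
    genes_per_contig: int = 5,
    gene_set_names: tuple[str, str] = ("coagulation_factor", "anticoagulant"),
) -> PanelDesign:
    """Generate a deterministic synthetic capture panel.

    Genes are laid out left to right on contigs (``genes_per_contig`` each),
    alternating strand.  Each gene gets ``exons_per_gene`` exons whose CDS
    blocks carry a random open reading frame (ATG ... stop, no internal stop);
    CDS blocks are NOT individually codon-aligned, so codons may straddle exon
    junctions as in real transcripts.  The first and last exon carry UTR.
    Targets are the exons padded by ``boundary_pad`` to include intron-exon
    boundaries, merged per contig.  The first half of the genes form the first
    gene set, the second half the second (default "coagulation_factor" /
    "anticoagulant").

    Fixing ``seed`` fixes the panel exactly.
    """
    if n_genes < 1 or exons_per_gene < 1:
        raise ValueError("n_genes and exons_per_gene must be >= 1")
    if codons_per_gene < exons_per_gene + 2:
        raise ValueError("codons_per_gene too small for the requested exon count")
    rng = np.random.default_rng(seed)

    reference: dict[str, list[str]] = {}
    transcripts: list[Transcript] = []
    targets: dict[str, list[tuple[int, int]]] = {}

    for gi in range(n_genes):
        contig = f"chr{gi // genes_per_contig + 1}"
        buf = reference.setdefault(contig, [])
        if not buf:
            buf.extend(rng.choice(list("ACGT"), size=intergenic_gap))
        strand = "+" if gi % 2 == 0 else "-"
        gene = f"GENE{gi + 1:03d}"

        # ORF in translation order: ATG + random non-stop codons + stop.
        n_internal = codons_per_gene - 2
        orf = "ATG" + "".join(rng.choice(NONSTOP_CODONS, size=n_internal)) + \
            str(rng.choice(["TAA", "TAG", "TGA"]))
        cds_total = len(orf)
        # split the CDS into exons_per_gene blocks of random positive lengths
        if exons_per_gene == 1:
            blocks = [cds_total]
        else:
            cuts = np.sort(rng.choice(np.arange(1, cds_total), size=exons_per_gene - 1, replace=False))
            blocks = np.diff(np.concatenate([[0], cuts, [cds_total]])).tolist()

        # genomic layout in transcription order; flip afterwards for minus strand
        parts: list[tuple[str, int]] = [("utr", utr_len)]
        for bi, blen in enumerate(blocks):
            parts.append(("cds", blen))
            if bi < len(blocks) - 1:
                parts.append(("intron", intron_len))
        parts.append(("utr", utr_len))

        # sequence of the transcription-order layout
        tx_seq: list[str] = []
        cds_seen = 0
        part_spans: list[tuple[str, int, int]] = []  # (kind, start_off, end_off) 0-based
        off = 0
        for kind, length in parts:
            if kind == "cds":
                seg = orf[cds_seen : cds_seen + length]
                cds_seen += length
            else:
                seg = "".join(rng.choice(list("ACGT"), size=length))
            tx_seq.append(seg)
            part_spans.append((kind, off, off + length))
            off += length
        gene_seq = "".join(tx_seq)
        if strand == "-":
            gene_seq = str(Seq(gene_seq).reverse_complement())
            glen = len(gene_seq)
            part_spans = [(k, glen - e, glen - s) for k, s, e in part_spans]

        gstart = len(buf)  # 0-based genomic start of the gene block
        buf.extend(gene_seq)
        buf.extend(rng.choice(list("ACGT"), size=intergenic_gap))

        # exon = contiguous run of non-intron parts; CDS = the cds parts
        exon_ivs: list[tuple[int, int]] = []
        cds_ivs: list[tuple[int, int]] = []
        for kind, s, e in sorted(part_spans, key=lambda t: t[1]):
            iv = (gstart + s + 1, gstart + e)  # 1-based inclusive
            if kind == "intron":
                continue
            if kind == "cds":
                cds_ivs.append(iv)
            if exon_ivs and iv[0] == exon_ivs[-1][1] + 1:
                exon_ivs[-1] = (exon_ivs[-1][0], iv[1])
            else:
                exon_ivs.append(iv)
        transcripts.append(Transcript(gene, contig, strand, tuple(exon_ivs), tuple(cds_ivs)))
        targets.setdefault(contig, []).extend(
            (max(0, s - 1 - boundary_pad), e + boundary_pad) for s, e in exon_ivs
        )

    reference_str = {c: "".join(b) for c, b in reference.items()}
    targets = {
        c: [(s, min(e, len(reference_str[c]))) for s, e in merge_intervals(ivs)]
        for c, ivs in targets.items()
    }
    genes = [tx.gene for tx in transcripts]
    half = (n_genes + 1) // 2
    gene_sets = {
        gene_set_names[0]: frozenset(genes[:half]),
        gene_set_names[1]: frozenset(genes[half:]),
    }
    panel = PanelDesign(reference_str, transcripts, targets, gene_sets)
    panel.validate()
    return panel
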