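"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
implementation it checks: exhaustive enumeration, full reconstruction, or
naive grouping.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq
from scipy import stats


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Conditions on all margins and sums the point probabilities of every
    table as or less probable than the observed one.
    """
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    n = r1 + r2
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(min(pmf[pmf <= p_obs * (1 + 1e-12)].sum(), 1.0))


_RC = str.maketrans("ACGT", "TGCA")


def classify_by_retranslation(contig, pos, ref, alt, panel):
    """Consequence of an SNV by rebuilding and translating the whole mutant CDS.

    Independent of the implementation's codon-offset arithmetic: mutates the
    genome, re-extracts every spliced CDS from scratch, translates reference
    and mutant proteins in full, and diffs them.
    """
    assert panel.reference[contig][pos - 1] == ref
    severity = ["nonsense", "missense", "synonymous", "utr", "intronic"]
    hits = []
    mutated = {
        c: (s[: pos - 1] + alt + s[pos:]) if c == contig else s
        for c, s in panel.reference.items()
    }
    for tx in panel.transcripts:
        if tx.contig != contig or not (tx.span[0] <= pos <= tx.span[1]):
            continue
        in_cds = any(s <= pos <= e for s, e in tx.cds)
        if not in_cds:
            in_exon = any(s <= pos <= e for s, e in tx.exons)
            hits.append("utr" if in_exon else "intronic")
            continue
        def spliced(genome):
            seq = "".join(genome[tx.contig][s - 1 : e] for s, e in tx.cds)
            return seq[::-1].translate(_RC) if tx.strand == "-" else seq
        prot_ref = str(Seq(spliced(panel.reference)).translate())
        prot_mut = str(Seq(spliced(mutated)).translate())
        if prot_mut == prot_ref:
            hits.append("synonymous")
        else:
            diffs = [i for i, (x, y) in enumerate(zip(prot_ref, prot_mut)) if x != y]
            hits.append("nonsense" if prot_mut[diffs[0]] == "*" else "missense")
    if not hits:
        return "intronic"
    return min(hits, key=severity.index)


def dedup_by_grouping(reads_df, with_strand=False):
    """Brute-force duplicate grouping: dict of coordinate -> best read id."""
    groups: dict[tuple, list] = {}
    for row in reads_df.itertuples(index=False):
        key = (row.contig, row.start, row.end) + ((row.strand,) if with_strand else ())
        groups.setdefault(key, []).append(row)
    best = []
    for key, rows in groups.items():
        rows.sort(key=lambda r: (-r.mapq, r.read_id))
        best.append(rows[0].read_id)
    return sorted(best)


def merge_by_coverage(intervals):
    """Interval merge via an explicit boolean coverage array."""
    if not intervals:
        return []
    hi = max(e for _, e in intervals)
    cov = np.zeros(hi + 1, dtype=bool)
    for s, e in intervals:
        cov[s:e] = True
    out = []
    i = 0
    while i < len(cov):
        if cov[i]:
            j = i
            while j < len(cov) and cov[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out
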