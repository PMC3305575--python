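"""Synthetic cohort generator for the targeted case-control resequencing design.

Emulates the statistical structure the downstream analysis assumes, without
any external data: a multi-gene capture panel, case/control truth genotypes
(Hardy-Weinberg controls; one common risk SNP with a configurable allelic
odds ratio; a configurable excess of rare missense alleles in a designated
gene set in cases), and pooled barcoded aligned reads with PCR duplicates,
quality-driven base errors and a configurable on-target fraction.

The retrospective sampling model specifies case/control allele frequencies
directly: at the risk site with control minor-allele frequency ``q`` and
allelic odds ratio ``OR``, the case frequency is

    p_case = OR * q / (1 + q * (OR - 1))

so the allelic 2x2 odds ratio equals ``OR`` by construction.  Everything is
driven by a single seed; per-stage random streams are derived from it so the
whole cohort is reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import classify_indel, classify_snv
from .panel import PanelDesign, build_panel

_BASES = np.array(list("ACGT"))

# sub-stream keys so stages draw from independent, reproducible streams
_STREAM_GENOTYPES = 1
_STREAM_READS = 2
_STREAM_BARCODES = 3


def case_frequency(q: float, odds_ratio: float) -> float:
    """Case minor-allele frequency implied by a control MAF and allelic OR."""
    if not 0 < q < 1:
        raise ValueError("control MAF must be in (0,1)")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    return odds_ratio * q / (1 + q * (odds_ratio - 1))


@dataclass
class BaseErrorModel:
    """Two-point Phred quality mixture; error probability is 10^(-Q/10)."""

    quality_levels: tuple[int, ...] = (20, 30)
    weights: tuple[float, ...] = (0.2, 0.8)

    def validate(self):
        if len(self.quality_levels) != len(self.weights):
            raise ValueError("quality_levels and weights must align")
        if abs(sum(self.weights) - 1) > 1e-9 or any(w < 0 for w in self.weights):
            raise ValueError("weights must be a probability vector")
        if any(q < 0 for q in self.quality_levels):
            raise ValueError("qualities must be non-negative")


@dataclass
class CommonRisk:
    """One common risk SNP: control MAF q and allelic odds ratio."""

    q: float = 0.22
    odds_ratio: float = 1.45
    site: tuple[str, int] | None = None  # None -> auto-placed missense site


@dataclass
class RareBurden:
    """Excess of rare missense alleles in one gene set in cases."""

    gene_set: str = "anticoagulant"
    per_gene: int = 1
    control_maf: float = 0.02
    enrichment: float = 4.0  # case:control allele-frequency ratio


@dataclass
class SimConfig:
    """Study-design constants of the simulated cohort.

    Defaults mirror the sequenced discovery cohort: 10 cases and 12 controls
    at 42X mean on-target depth with 7% of raw reads on target.
    """

    n_cases: int = 10
    n_controls: int = 12
    mean_depth: float = 42.0
    on_target_fraction: float = 0.07
    dup_rate: float = 0.15
    read_length: int = 50
    read_length_jitter: int = 8  # fragment lengths uniform in length +/- jitter
    barcode_length: int = 6
    base_error_model: BaseErrorModel = field(default_factory=BaseErrorModel)
    mapq_high: int = 60
    mapq_low: int = 20
    low_mapq_fraction: float = 0.05
    tag_error_rate: float = 0.002
    common_risk: CommonRisk | None = field(default_factory=CommonRisk)
    rare_burden: RareBurden | None = field(default_factory=RareBurden)
    n_common_background: int = 30
    n_rare_background: int = 60
    n_deletion_sites: int = 3
    seed: int = 0

    def validate(self):
        for name in ("on_target_fraction", "dup_rate", "low_mapq_fraction", "tag_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.on_target_fraction <= 0:
            raise ValueError("on_target_fraction must be positive")
        if self.read_length < 1 or self.barcode_length < 1:
            raise ValueError("read_length and barcode_length must be >= 1")
        if not 0 <= self.read_length_jitter < self.read_length:
            raise ValueError("read_length_jitter must be in [0, read_length)")
        self.base_error_model.validate()
        if self.common_risk is not None:
            case_frequency(self.common_risk.q, self.common_risk.odds_ratio)
        if self.rare_burden is not None:
            rb = self.rare_burden
            if not 0 < rb.control_maf < 1 or rb.enrichment <= 0 or rb.per_gene < 0:
                raise ValueError("invalid rare_burden block")


@dataclass
class TruthSet:
    """Ground truth: per-sample phenotype/barcode, sites, diploid genotypes.

    ``genotypes`` is an (n_samples, n_sites) int8 array of alt-allele dosages
    in {0,1,2}.  Phenotype coding: 1 = control, 2 = case.
    """

    samples: pd.DataFrame  # sample, phenotype, barcode
    sites: pd.DataFrame  # contig,pos,ref,alt,var_type,site_class,control_maf,case_maf,consequence,gene
    genotypes: np.ndarray

    def validate(self):
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError("genotype array shape mismatch")
        if not np.isin(self.genotypes, [0, 1, 2]).all():
            raise ValueError("genotypes must be dosages in {0,1,2}")

    @property
    def case_mask(self) -> np.ndarray:
        return (self.samples["phenotype"].to_numpy() == 2)

    def segregating(self) -> np.ndarray:
        """Boolean mask of sites carrying >=1 alt allele in the cohort."""
        return self.genotypes.sum(axis=0) > 0

    def to_matrix(self, segregating_only: bool = True):
        """Project the truth directly into a complete GenotypeMatrix.

        This is the error-free limit of the sequencing pipeline (every
        genotype observed, nothing missing), restricted by default to sites
        actually segregating in the cohort, as the variable-site union
        would be.
        """
        from .gmatrix import GenotypeMatrix

        keep = self.segregating() if segregating_only else np.ones(len(self.sites), bool)
        sites = self.sites.loc[keep, ["contig", "pos", "ref", "alt"]].reset_index(drop=True)
        sites["site_id"] = [
            f"{r.contig}:{r.pos}:{r.ref}:{r.alt}" for r in sites.itertuples(index=False)
        ]
        matrix = GenotypeMatrix(
            sites, self.samples[["sample", "phenotype"]].copy(), self.genotypes[:, keep].copy()
        )
        matrix.validate()
        return matrix

    def write(self, outdir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "phenotypes": outdir / f"{prefix}.phenotypes.tsv",
            "barcodes": outdir / f"{prefix}.barcodes.tsv",
            "sites": outdir / f"{prefix}.truth_sites.tsv",
            "genotypes": outdir / f"{prefix}.truth_genotypes.tsv",
        }
        self.samples[["sample", "phenotype"]].to_csv(paths["phenotypes"], sep="\t", index=False)
        self.samples[["sample", "barcode"]].to_csv(paths["barcodes"], sep="\t", index=False)
        self.sites.to_csv(paths["sites"], sep="\t", index=False)
        recs = []
        for si, site in enumerate(self.sites.itertuples(index=False)):
            sid = f"{site.contig}:{site.pos}:{site.ref}:{site.alt}"
            for pi, sample in enumerate(self.samples["sample"]):
                recs.append((sid, sample, int(self.genotypes[pi, si])))
        pd.DataFrame(recs, columns=["site", "sample", "genotype"]).to_csv(
            paths["genotypes"], sep="\t", index=False
        )
        return paths


def _pick_positions(rng, available: list[tuple[str, int]], n: int) -> list[tuple[str, int]]:
    if n > len(available):
        raise ValueError("panel too small for the requested number of sites")
    idx = rng.choice(len(available), size=n, replace=False)
    picked = [available[i] for i in sorted(idx, reverse=True)]
    for i in sorted(idx, reverse=True):
        del available[i]
    return picked


def _missense_site(rng, panel: PanelDesign, gene: str, available_set: set) -> tuple[str, int, str, str]:
    """Pick a CDS position + alt base in ``gene`` whose substitution is missense."""
    tx = panel.transcripts_of(gene)[0]
    cds_positions = [p for s, e in tx.cds for p in range(s, e + 1)]
    order = rng.permutation(len(cds_positions))
    for i in order:
        pos = cds_positions[i]
        if (tx.contig, pos) not in available_set:
            continue
        ref = panel.reference[tx.contig][pos - 1]
        for alt in rng.permutation([b for b in "ACGT" if b != ref]):
            if classify_snv(tx.contig, pos, ref, alt, panel).klass == "missense":
                return tx.contig, pos, ref, alt
    raise ValueError(f"no available missense site in gene {gene}")


def simulate_genotypes(panel: PanelDesign, config: SimConfig) -> TruthSet:
    """Draw truth sites and diploid genotypes for the configured cohort.

    Controls follow Hardy-Weinberg at each site's control MAF.  Cases follow
    Hardy-Weinberg at the site's case frequency: equal to the control MAF at
    background sites, the retrospective-odds-ratio frequency at the risk
    site, and ``min(enrichment * control_maf, 0.5)`` at rare-burden sites.
    """
    config.validate()
    panel.validate()
    rng = np.random.default_rng([config.seed, _STREAM_GENOTYPES])
    brng = np.random.default_rng([config.seed, _STREAM_BARCODES])

    n = config.n_cases + config.n_controls
    samples = pd.DataFrame(
        {
            "sample": [f"CASE{i + 1:02d}" for i in range(config.n_cases)]
            + [f"CTRL{i + 1:02d}" for i in range(config.n_controls)],
            "phenotype": [2] * config.n_cases + [1] * config.n_controls,
        }
    )
    samples["barcode"] = _make_barcodes(brng, n, config.barcode_length)

    available = [
        (contig, int(p))
        for contig in sorted(panel.target_intervals)
        for p in panel.target_positions(contig)
    ]
    available_set = set(available)
    records = []

    def _take(contig, pos):
        available_set.discard((contig, pos))
        try:
            available.remove((contig, pos))
        except ValueError:
            pass

    # common risk SNP
    if config.common_risk is not None:
        cr = config.common_risk
        if cr.site is None:
            gene = sorted(panel.gene_sets.get("coagulation_factor", {t.gene for t in panel.transcripts}))[0]
            contig, pos, ref, alt = _missense_site(rng, panel, gene, available_set)
        else:
            contig, pos = cr.site
            if not panel.in_target(contig, pos):
                raise ValueError(f"risk site {contig}:{pos} outside the panel target")
            ref = panel.reference[contig][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        _take(contig, pos)
        records.append(
            (contig, pos, ref, alt, "SNV", "risk", cr.q, case_frequency(cr.q, cr.odds_ratio))
        )

    # rare burden sites in the designated gene set
    if config.rare_burden is not None and config.rare_burden.per_gene > 0:
        rb = config.rare_burden
        if rb.gene_set not in panel.gene_sets:
            raise ValueError(f"unknown gene set {rb.gene_set!r}")
        p_case = min(rb.enrichment * rb.control_maf, 0.5)
        for gene in sorted(panel.gene_sets[rb.gene_set]):
            for _ in range(rb.per_gene):
                contig, pos, ref, alt = _missense_site(rng, panel, gene, available_set)
                _take(contig, pos)
                records.append((contig, pos, ref, alt, "SNV", "burden", rb.control_maf, p_case))

    # Neutral background SNVs (common + rare) and small deletions.
    # Background SNVs avoid the CDS of the burden gene set: the missense
    # variation of that set is governed entirely by the rare_burden block,
    # mirroring the emulated study panel whose designated gene set carried
    # only the handful of rare missense variants under test.
    burden_cds: set[tuple[str, int]] = set()
    if config.rare_burden is not None:
        for gene in panel.gene_sets.get(config.rare_burden.gene_set, ()):
            for tx in panel.transcripts_of(gene):
                for s, e in tx.cds:
                    burden_cds.update((tx.contig, p) for p in range(s, e + 1))
    background_pool = [xy for xy in available if xy not in burden_cds]

    def _background(pool, n, lo_maf, hi_maf, var_type, klass):
        for contig, pos in _pick_positions(rng, pool, n):
            if (contig, pos) in available_set:
                available_set.discard((contig, pos))
            q = float(rng.uniform(lo_maf, hi_maf))
            ref = panel.reference[contig][pos - 1]
            if var_type == "SNV":
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            else:
                alt = "-"
            records.append((contig, pos, ref, alt, var_type, klass, q, q))

    _background(background_pool, config.n_common_background, 0.05, 0.5, "SNV", "background_common")
    _background(background_pool, config.n_rare_background, 0.005, 0.05, "SNV", "background_rare")
    _background(background_pool, config.n_deletion_sites, 0.01, 0.2, "deletion", "background_indel")
    sites = pd.DataFrame(
        records,
        columns=["contig", "pos", "ref", "alt", "var_type", "site_class", "control_maf", "case_maf"],
    ).sort_values(["contig", "pos"], kind="stable").reset_index(drop=True)

    csq, genes = [], []
    for row in sites.itertuples(index=False):
        if row.var_type == "SNV":
            c = classify_snv(row.contig, int(row.pos), row.ref, row.alt, panel)
        else:
            c = classify_indel(row.contig, int(row.pos), 1, row.var_type, panel)
        csq.append(c.klass)
        genes.append(c.gene)
    sites["consequence"] = csq
    sites["gene"] = genes

    if len(sites):
        freqs = np.where(
            samples["phenotype"].to_numpy()[:, None] == 2,
            sites["case_maf"].to_numpy(dtype=float)[None, :],
            sites["control_maf"].to_numpy(dtype=float)[None, :],
        )
        genotypes = rng.binomial(2, freqs).astype(np.int8)
    else:
        genotypes = np.zeros((n, 0), dtype=np.int8)
    truth = TruthSet(samples, sites, genotypes)
    truth.validate()
    return truth


def _make_barcodes(rng, n: int, length: int, min_distance: int = 3) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= min_distance."""
    if 4**length < 4 * n:
        raise ValueError("barcode length too short for the cohort size")
    codes: list[np.ndarray] = []
    attempts = 0
    while len(codes) < n:
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != c).sum()) >= min_distance for c in codes):
            codes.append(cand)
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("failed to generate a separated barcode set")
    return ["".join(_BASES[c]) for c in codes]


@dataclass
class ReadSimStats:
    """Bookkeeping of the read simulation (off-target reads are counted, not emitted)."""

    on_target_reads: int
    off_target_reads: int
    duplicate_fragments: int

    @property
    def total_reads(self) -> int:
        return self.on_target_reads + self.off_target_reads


READ_COLUMNS = ["read_id", "tag", "contig", "start", "end", "strand", "mapq", "bases", "quals"]


def simulate_reads(
    panel: PanelDesign, truth: TruthSet, config: SimConfig
) -> tuple[pd.DataFrame, ReadSimStats]:
    """Emit tagged, pre-aligned on-target reads plus an off-target read count.

    Per-sample coverage at target sites is Poisson(mean_depth); a
    ``dup_rate`` fraction of fragments is emitted twice with identical
    coordinates (independent base errors and mapping quality, as PCR
    duplicates of one molecule re-sequenced); base calls are flipped at the
    Phred error rate implied by their quality score.  Off-target reads carry
    no sequence and are returned as a count so downstream enrichment
    bookkeeping works without bulk.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_READS])
    L = config.read_length
    qual_levels = np.array(config.base_error_model.quality_levels)
    qual_weights = np.array(config.base_error_model.weights, dtype=float)
    err_by_level = 10 ** (-qual_levels / 10)

    # per-sample haplotypes as sparse {contig: {pos: (alt_hap0, alt_hap1)}}
    hap_alt: list[dict[str, dict[int, list[str | None]]]] = []
    for pi in range(len(truth.samples)):
        d: dict[str, dict[int, list[str | None]]] = {}
        for si, site in enumerate(truth.sites.itertuples(index=False)):
            g = int(truth.genotypes[pi, si])
            if g == 0:
                continue
            alleles: list[str | None] = [None, None]
            if g == 2:
                alleles = [site.alt, site.alt]
            else:
                alleles[int(rng.integers(0, 2))] = site.alt
            d.setdefault(site.contig, {})[int(site.pos)] = alleles
        hap_alt.append(d)

    rows: list[tuple] = []
    n_dup_fragments = 0
    for pi, sample_row in enumerate(truth.samples.itertuples(index=False)):
        barcode = sample_row.barcode
        counter = 0
        for contig in sorted(panel.target_intervals):
            refseq = panel.reference[contig]
            clen = len(refseq)
            variants = hap_alt[pi].get(contig, {})
            lengths = np.arange(L - config.read_length_jitter, L + config.read_length_jitter + 1)
            for s0, e0 in panel.target_intervals[contig]:
                # one Poisson stream per fragment-length class so coverage at
                # target sites stays Poisson(mean_depth) exactly
                frag_lens_parts = []
                frag_starts_parts = []
                for length in lengths:
                    lo = max(1, s0 + 2 - length)
                    hi = min(e0, clen - length + 1)
                    if hi < lo:
                        continue
                    window = hi - lo + 1
                    n_l = rng.poisson(config.mean_depth / len(lengths) * window / length)
                    if n_l == 0:
                        continue
                    frag_starts_parts.append(rng.integers(lo, hi + 1, size=n_l))
                    frag_lens_parts.append(np.full(n_l, length))
                if not frag_starts_parts:
                    continue
                starts = np.concatenate(frag_starts_parts)
                lens = np.concatenate(frag_lens_parts)
                n_frag = len(starts)
                haps = rng.integers(0, 2, size=n_frag)
                strands = np.where(rng.random(n_frag) < 0.5, "+", "-")
                dup = rng.random(n_frag) < config.dup_rate
                n_dup_fragments += int(dup.sum())
                copies = np.where(dup, 2, 1)
                starts = np.repeat(starts, copies)
                lens = np.repeat(lens, copies)
                haps = np.repeat(haps, copies)
                strands = np.repeat(strands, copies)
                n_reads = len(starts)
                mapqs = np.where(
                    rng.random(n_reads) < config.low_mapq_fraction,
                    config.mapq_low,
                    config.mapq_high,
                )
                maxL = int(lengths[-1])
                qual_idx = rng.choice(len(qual_levels), size=(n_reads, maxL), p=qual_weights)
                quals = qual_levels[qual_idx]
                err = rng.random((n_reads, maxL)) < err_by_level[qual_idx]
                err_sub = rng.integers(1, 4, size=(n_reads, maxL))  # offset to another base
                for ri in range(n_reads):
                    start = int(starts[ri])
                    rlen = int(lens[ri])
                    bases = list(refseq[start - 1 : start - 1 + rlen])
                    for pos, alleles in variants.items():
                        if start <= pos < start + rlen:
                            a = alleles[haps[ri]]
                            if a is not None:
                                bases[pos - start] = a
                    for bi in np.nonzero(err[ri][:rlen])[0]:
                        b = bases[bi]
                        if b == "-":
                            continue  # deleted base: nothing sequenced
                        bases[bi] = "ACGT"[("ACGT".index(b) + err_sub[ri, bi]) % 4]
                    tag = barcode
                    if config.tag_error_rate > 0:
                        terr = rng.random(len(barcode)) < config.tag_error_rate
                        if terr.any():
                            t = list(tag)
                            for ti in np.nonzero(terr)[0]:
                                t[ti] = "ACGT"[("ACGT".index(t[ti]) + int(rng.integers(1, 4))) % 4]
                            tag = "".join(t)
                    counter += 1
                    rows.append(
                        (
                            f"r{sample_row.sample}_{counter:06d}",
                            tag,
                            contig,
                            start,
                            start + rlen - 1,
                            strands[ri],
                            int(mapqs[ri]),
                            "".join(bases),
                            "".join(chr(q + 33) for q in quals[ri][:rlen]),
                        )
                    )
    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    n_on = len(reads)
    f = config.on_target_fraction
    n_off = int(round(n_on * (1 - f) / f))
    stats = ReadSimStats(n_on, n_off, n_dup_fragments)
    return reads, stats


def hwe_genotype_matrix(
    n_cases: int,
    n_controls: int,
    case_freqs,
    control_freqs,
    rng: np.random.Generator,
):
    """Genotype-level cohort draw at given per-site allele frequencies.

    Genotypes are Hardy-Weinberg (dosage ~ Binomial(2, freq)) and complete
    (no missingness).  Used for statistical calibration studies — null
    screens, power and coverage checks — where read-level simulation adds
    nothing but cost.
    """
    from .gmatrix import GenotypeMatrix

    case_freqs = np.atleast_1d(np.asarray(case_freqs, dtype=float))
    control_freqs = np.atleast_1d(np.asarray(control_freqs, dtype=float))
    if case_freqs.shape != control_freqs.shape:
        raise ValueError("case and control frequency vectors must align")
    n_sites = len(case_freqs)
    samples = pd.DataFrame(
        {
            "sample": [f"CASE{i + 1:04d}" for i in range(n_cases)]
            + [f"CTRL{i + 1:04d}" for i in range(n_controls)],
            "phenotype": [2] * n_cases + [1] * n_controls,
        }
    )
    sites = pd.DataFrame(
        {
            "contig": "chrS",
            "pos": np.arange(1, n_sites + 1),
            "ref": "A",
            "alt": "G",
            "site_id": [f"chrS:{j + 1}:A:G" for j in range(n_sites)],
        }
    )
    freqs = np.vstack(
        [np.tile(case_freqs, (n_cases, 1)), np.tile(control_freqs, (n_controls, 1))]
    )
    matrix = GenotypeMatrix(sites, samples, rng.binomial(2, freqs).astype(np.int8))
    matrix.validate()
    return matrix


def simulate_cohort(panel: PanelDesign, config: SimConfig):
    """Convenience wrapper: genotypes then reads; returns (truth, reads, stats)."""
    truth = simulate_genotypes(panel, config)
    reads, stats = simulate_reads(panel, truth, config)
    return truth, reads, stats
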