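"""Cross-sample genotype matrix over the union of variable sites.

Projects per-sample calls, QC failures and coverage onto the union of sites
found variable (QC-PASS) in at least one sequenced individual, with an
explicit missing/homref distinction:

* PASS call at the site        -> the called genotype (het / homvar)
* QC-FAILED variant evidence   -> missing (evidence is untrustworthy, not absent)
* no variant evidence, depth >= min_ref_depth -> homozygous reference
* otherwise                    -> missing

The matrix is exported as PLINK 1 text PED/MAP (missing genotype "0 0") and
as a multi-sample VCF.  ``min_ref_depth`` defaults to the 10X confident-call
coverage threshold; the exact depth rule of the original genotyping script
is unpublished, so this linkage is a documented reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import SampleCalls

HOMREF, HET, HOMVAR, MISSING = 0, 1, 2, -1
_GT_CODE = {"het": HET, "homvar": HOMVAR}


@dataclass
class GenotypeMatrix:
    """samples x sites genotype grid with phenotypes.

    ``genotypes[i, j]`` is 0 homref / 1 het / 2 homvar / -1 missing for
    sample i at site j.  Phenotype coding: 1 = control, 2 = case.
    """

    sites: pd.DataFrame  # contig, pos, ref, alt, site_id (sorted)
    samples: pd.DataFrame  # sample, phenotype[, sex]
    genotypes: np.ndarray  # int8

    def validate(self):
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError("genotype array shape mismatch")
        if not np.isin(self.genotypes, [HOMREF, HET, HOMVAR, MISSING]).all():
            raise ValueError("invalid genotype codes")
        if not self.samples["phenotype"].isin([1, 2]).all():
            raise ValueError("phenotypes must be 1 (control) or 2 (case)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def case_mask(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy() == 2

    def missingness(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        return (self.genotypes == MISSING).mean(axis=0)

    def minor_allele_stats(self) -> pd.DataFrame:
        """Pooled minor-allele frequency/count over non-missing alleles.

        ``minor_is_alt`` records which allele is the minor one at each site
        (ties count the alt allele as minor).
        """
        g = self.genotypes
        nonmiss = g != MISSING
        alt = np.where(nonmiss, g, 0).sum(axis=0)
        total = 2 * nonmiss.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_freq = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
        minor_is_alt = alt_freq <= 0.5
        minor = np.where(minor_is_alt, alt, total - alt)
        maf = np.where(total > 0, minor / np.maximum(total, 1), np.nan)
        return pd.DataFrame(
            {
                "site_id": self.sites["site_id"],
                "minor_count": minor,
                "total_alleles": total,
                "maf": maf,
                "minor_is_alt": minor_is_alt,
            }
        )

    def genotyping_success(self) -> float:
        """Overall fraction of non-missing genotype calls."""
        return float((self.genotypes != MISSING).mean())


def union_sites(callsets: dict[str, SampleCalls]) -> pd.DataFrame:
    """Sorted union of QC-PASS call sites across samples.

    Conflicting reference bases at one position indicate panel inconsistency
    and raise.
    """
    if not callsets:
        raise ValueError("need at least one callset")
    seen: dict[tuple[str, int, str], str] = {}
    for cs in callsets.values():
        for c in cs.passing():
            key = (c.contig, c.pos, c.alt)
            if key in seen and seen[key] != c.ref:
                raise ValueError(
                    f"conflicting reference base at {c.contig}:{c.pos} "
                    f"({seen[key]} vs {c.ref})"
                )
            seen[key] = c.ref
    rows = [
        {"contig": contig, "pos": pos, "ref": ref, "alt": alt}
        for (contig, pos, alt), ref in seen.items()
    ]
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    sites = sites.sort_values(["contig", "pos", "alt"], kind="stable").reset_index(drop=True)
    sites["site_id"] = [
        f"{r.contig}:{r.pos}:{r.ref}:{r.alt}" for r in sites.itertuples(index=False)
    ]
    return sites


def genotype_at(
    sample_calls: SampleCalls,
    contig: str,
    pos: int,
    alt: str,
    min_ref_depth: int = 10,
) -> int:
    """Genotype of one sample at one union site (see module rules)."""
    for c in sample_calls.calls:
        if c.contig == contig and c.pos == pos and c.alt == alt:
            if c.qc_status == "PASS":
                return _GT_CODE[c.genotype]
            return MISSING
    # any other QC-failed variant evidence at the position also blocks homref
    for c in sample_calls.calls:
        if c.contig == contig and c.pos == pos and c.qc_status != "PASS":
            return MISSING
    if sample_calls.depth_at(contig, pos) >= min_ref_depth:
        return HOMREF
    return MISSING


def build_matrix(
    callsets: dict[str, SampleCalls],
    phenotypes: pd.DataFrame,
    min_ref_depth: int = 10,
) -> GenotypeMatrix:
    """Assemble the genotype matrix from per-sample callsets.

    ``phenotypes`` needs columns sample, phenotype (1=control, 2=case) and
    fixes the sample order; every phenotype row must have a callset.
    """
    missing_cs = set(phenotypes["sample"]) - set(callsets)
    if missing_cs:
        raise ValueError(f"no callset for samples {sorted(missing_cs)}")
    sites = union_sites(callsets)
    samples = phenotypes.reset_index(drop=True)
    geno = np.full((len(samples), len(sites)), MISSING, dtype=np.int8)
    for i, sample in enumerate(samples["sample"]):
        cs = callsets[sample]
        by_pos: dict[tuple[str, int], list] = {}
        for c in cs.calls:
            by_pos.setdefault((c.contig, c.pos), []).append(c)
        for j, site in enumerate(sites.itertuples(index=False)):
            calls_here = by_pos.get((site.contig, site.pos), [])
            g = None
            for c in calls_here:
                if c.alt == site.alt:
                    g = _GT_CODE[c.genotype] if c.qc_status == "PASS" else MISSING
                    break
            if g is None:
                if any(c.qc_status != "PASS" for c in calls_here):
                    g = MISSING
                elif cs.depth_at(site.contig, site.pos) >= min_ref_depth:
                    g = HOMREF
                else:
                    g = MISSING
            geno[i, j] = g
    matrix = GenotypeMatrix(sites, samples, geno)
    matrix.validate()
    return matrix


# ----------------------------------------------------------------- PED/MAP

def write_ped_map(matrix: GenotypeMatrix, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write PLINK 1 text PED/MAP; returns (ped_path, map_path).

    MAP rows are (contig, site id, 0, pos); PED rows carry FID=IID=sample,
    unknown parents, sex from the sample table when present (else 0), the
    1/2 phenotype, and one allele pair per site with missing coded "0 0".
    Indel alleles are written as I (variant) / D or R per PLINK text
    convention for non-SNP alleles; single-base alleles are written as is.
    """
    out_prefix = Path(out_prefix)
    ped_path = out_prefix.with_suffix(".ped")
    map_path = out_prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for site in matrix.sites.itertuples(index=False):
            fh.write(f"{site.contig}\t{site.site_id}\t0\t{site.pos}\n")
    sex = (
        matrix.samples["sex"].astype(int).to_numpy()
        if "sex" in matrix.samples.columns
        else np.zeros(matrix.n_samples, dtype=int)
    )
    refs = [_ped_allele(s.ref, is_ref=True) for s in matrix.sites.itertuples(index=False)]
    alts = [_ped_allele(s.alt, is_ref=False) for s in matrix.sites.itertuples(index=False)]
    with open(ped_path, "w") as fh:
        for i, row in enumerate(matrix.samples.itertuples(index=False)):
            fields = [row.sample, row.sample, "0", "0", str(sex[i]), str(row.phenotype)]
            for j in range(len(matrix.sites)):
                g = matrix.genotypes[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == HOMREF:
                    fields += [refs[j], refs[j]]
                elif g == HET:
                    fields += [refs[j], alts[j]]
                else:
                    fields += [alts[j], alts[j]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def _ped_allele(allele: str, is_ref: bool) -> str:
    if allele in ("A", "C", "G", "T"):
        return allele
    return "R" if is_ref else ("D" if allele == "-" else "I")


def read_ped_map(prefix: str | Path, sites_like: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a PED/MAP pair back into a GenotypeMatrix.

    PED encodes alleles, not ref/alt orientation; ``sites_like`` (a sites
    table with contig,pos,ref,alt,site_id) restores allele spelling, and by
    default the MAP site ids (written as contig:pos:ref:alt) are parsed.
    """
    prefix = Path(prefix)
    map_rows = []
    for line in prefix.with_suffix(".map").read_text().splitlines():
        contig, site_id, _, pos = line.split("\t")
        map_rows.append({"contig": contig, "site_id": site_id, "pos": int(pos)})
    sites = pd.DataFrame(map_rows)
    if sites_like is not None:
        sites = sites.merge(
            sites_like[["site_id", "ref", "alt"]], on="site_id", how="left", validate="1:1"
        )
    else:
        parts = sites["site_id"].str.split(":", expand=True)
        sites["ref"], sites["alt"] = parts[2], parts[3]
    sites = sites[["contig", "pos", "ref", "alt", "site_id"]]

    sample_rows, geno_rows = [], []
    refs = [_ped_allele(s.ref, True) for s in sites.itertuples(index=False)]
    for line in prefix.with_suffix(".ped").read_text().splitlines():
        fields = line.split()
        sample_rows.append(
            {"sample": fields[1], "sex": int(fields[4]), "phenotype": int(fields[5])}
        )
        alleles = fields[6:]
        row = []
        for j in range(len(sites)):
            a, b = alleles[2 * j], alleles[2 * j + 1]
            if a == "0" or b == "0":
                row.append(MISSING)
            else:
                n_ref = (a == refs[j]) + (b == refs[j])
                row.append({2: HOMREF, 1: HET, 0: HOMVAR}[n_ref])
        geno_rows.append(row)
    samples = pd.DataFrame(sample_rows)[["sample", "phenotype", "sex"]]
    matrix = GenotypeMatrix(sites, samples, np.array(geno_rows, dtype=np.int8))
    matrix.validate()
    return matrix


def write_matrix_vcf(matrix: GenotypeMatrix, path: str | Path, contig_lengths=None) -> None:
    """Multi-sample VCF v4.2 with GT per sample (./. for missing)."""
    lines = ["##fileformat=VCFv4.2", "##source=hemoseq"]
    contigs = sorted(matrix.sites["contig"].unique())
    for contig in contigs:
        if contig_lengths:
            lines.append(f"##contig=<ID={contig},length={contig_lengths[contig]}>")
        else:
            lines.append(f"##contig=<ID={contig}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples["sample"])
    )
    gt_str = {MISSING: "./.", HOMREF: "0/0", HET: "0/1", HOMVAR: "1/1"}
    for j, site in enumerate(matrix.sites.itertuples(index=False)):
        ref, alt = site.ref, site.alt
        if alt == "-":  # internal deletion spelling; VCF needs an anchor we lack here
            ref, alt = ref, "<DEL>"
        gts = "\t".join(gt_str[int(g)] for g in matrix.genotypes[:, j])
        lines.append(f"{site.contig}\t{site.pos}\t{site.site_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")
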