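"""Concordance reports: repeat-run callset overlap and genotype agreement.

These are the validation operations of the study design: comparing the
variant calls of two sequencing runs of the same sample, and comparing
genotype calls against an orthogonal platform, stratified by the genotype of
the reference platform (homozygous wild-type vs variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gmatrix import HET, HOMREF, HOMVAR, MISSING


def callset_overlap(keys_a, keys_b) -> dict:
    """Fraction of callset B's variants also present in callset A.

    Callsets are iterables of (contig, pos, ref, alt) keys.  Returns n_b,
    n_shared and the percentage (one decimal) of B found in A.
    """
    set_a, set_b = set(keys_a), set(keys_b)
    if not set_b:
        raise ValueError("empty comparison callset")
    shared = len(set_a & set_b)
    return {
        "n_b": len(set_b),
        "n_shared": shared,
        "percent": round(100 * shared / len(set_b), 1),
    }


@dataclass
class AgreementTable:
    """Per-stratum comparison counts (stratified by platform A's genotype)."""

    homref_compared: int
    homref_agreeing: int
    variant_compared: int
    variant_agreeing: int

    def validate(self):
        if self.homref_agreeing > self.homref_compared or self.variant_agreeing > self.variant_compared:
            raise ValueError("agreeing counts exceed compared counts")

    @property
    def n_compared(self) -> int:
        return self.homref_compared + self.variant_compared

    def percentages(self) -> dict:
        out = {}
        for name, agree, comp in [
            ("homref", self.homref_agreeing, self.homref_compared),
            ("variant", self.variant_agreeing, self.variant_compared),
        ]:
            out[name] = round(100 * agree / comp, 1) if comp else float("nan")
        total_agree = self.homref_agreeing + self.variant_agreeing
        out["overall"] = round(100 * total_agree / self.n_compared, 1) if self.n_compared else float("nan")
        return out


def genotype_agreement(genotypes_a: dict, genotypes_b: dict) -> AgreementTable:
    """Agreement of paired genotype calls over shared (sample, site) keys.

    Inputs map (sample, site) -> genotype code (0 homref / 1 het / 2 homvar /
    -1 missing).  Pairs missing on either side are excluded.  Strata follow
    input A's genotype: homozygous reference vs variant (het or homvar);
    agreement requires identical genotypes.  The overall rate is symmetric in
    the inputs; only the stratification follows A.
    """
    shared = [
        k
        for k in genotypes_a.keys() & genotypes_b.keys()
        if genotypes_a[k] != MISSING and genotypes_b[k] != MISSING
    ]
    if not shared:
        raise ValueError("no shared non-missing genotype pairs")
    hr_c = hr_a = var_c = var_a = 0
    for k in shared:
        ga, gb = genotypes_a[k], genotypes_b[k]
        if ga == HOMREF:
            hr_c += 1
            hr_a += ga == gb
        elif ga in (HET, HOMVAR):
            var_c += 1
            var_a += ga == gb
    table = AgreementTable(hr_c, hr_a, var_c, var_a)
    table.validate()
    return table


def agreement_report(table: AgreementTable) -> pd.DataFrame:
    pct = table.percentages()
    return pd.DataFrame(
        [
            {"stratum": "homref", "n_compared": table.homref_compared,
             "n_agreeing": table.homref_agreeing, "percent": pct["homref"]},
            {"stratum": "variant", "n_compared": table.variant_compared,
             "n_agreeing": table.variant_agreeing, "percent": pct["variant"]},
            {"stratum": "overall", "n_compared": table.n_compared,
             "n_agreeing": table.homref_agreeing + table.variant_agreeing,
             "percent": pct["overall"]},
        ]
    )
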