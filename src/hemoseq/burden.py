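"""Gene-set collapsing (burden) analysis of nonsynonymous variants.

Per-sample minor-allele dosages (het = 1, homvar = 2, missing = 0) at
qualifying sites — by default nonsynonymous SNVs in the chosen gene set —
are summed into group totals T_case and T_control.  The totals are compared
with an exact binomial tail: conditional on n = T_case + T_control observed
minor alleles, each allele falls in the case group with probability
p0 = n_cases / (n_cases + n_controls) under the null of no enrichment, and

    p = P(X >= T_case),  X ~ Binomial(n, p0)

one-sided in the case-excess direction (a two-sided doubled variant is
available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import NONSYNONYMOUS_CLASSES
from .gmatrix import MISSING, GenotypeMatrix


@dataclass
class BurdenResult:
    gene_set: str
    t_case: int
    t_control: int
    n_cases: int
    n_controls: int
    mean_case: float
    mean_control: float
    p: float
    qualifying_sites: tuple[str, ...]

    def validate(self):
        if self.t_case < 0 or self.t_control < 0:
            raise ValueError("negative burden totals")


def collapse(
    matrix: GenotypeMatrix,
    annotations: pd.DataFrame,
    gene_set: frozenset[str] | set[str],
    consequence_classes: frozenset[str] = NONSYNONYMOUS_CLASSES,
    var_types: frozenset[str] = frozenset({"SNV"}),
    damaging_only: bool = False,
) -> tuple[int, int, np.ndarray, list[str]]:
    """Total qualifying minor-allele dosage per group.

    ``annotations`` must align to the matrix sites (column site_id, plus
    gene, consequence, var_type, and optionally ``damaging`` when restricting
    to externally predicted damaging sites).  Returns
    (T_case, T_control, per-sample counts, qualifying site ids).
    """
    if not gene_set:
        raise ValueError("empty gene set")
    ann = annotations.set_index("site_id").reindex(matrix.sites["site_id"])
    qual = (
        ann["gene"].isin(gene_set)
        & ann["consequence"].isin(consequence_classes)
        & ann["var_type"].isin(var_types)
    )
    if damaging_only:
        if "damaging" not in ann.columns:
            raise ValueError("damaging_only requires a 'damaging' annotation column")
        qual &= ann["damaging"].fillna(False).astype(bool)
    qual = qual.fillna(False).to_numpy()

    g = matrix.genotypes[:, qual].astype(np.int64)
    # minor-allele dosage: flip sites where the minor allele is the reference
    minor_is_alt = matrix.minor_allele_stats()["minor_is_alt"].to_numpy()[qual]
    dose = np.where(g == MISSING, 0, np.where(minor_is_alt[None, :], g, 2 - g))
    per_sample = dose.sum(axis=1)
    cases = matrix.case_mask
    sites = matrix.sites["site_id"].to_numpy()[qual].tolist()
    return int(per_sample[cases].sum()), int(per_sample[~cases].sum()), per_sample, sites


def binomial_burden_test(
    t_case: int, t_control: int, n_cases: int, n_controls: int, two_sided: bool = False
) -> float:
    """Exact binomial tail probability of the observed case excess."""
    if t_case < 0 or t_control < 0:
        raise ValueError("negative totals")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("group sizes must be >= 1")
    n = t_case + t_control
    if n == 0:
        return 1.0
    p0 = n_cases / (n_cases + n_controls)
    p = float(stats.binom.sf(t_case - 1, n, p0))
    if two_sided:
        p = min(1.0, 2 * min(p, float(stats.binom.cdf(t_case, n, p0))))
    return p


def burden_test(
    matrix: GenotypeMatrix,
    annotations: pd.DataFrame,
    gene_sets: dict[str, frozenset[str]],
    **collapse_kwargs,
) -> list[BurdenResult]:
    """Collapse + test every named gene set; returns one result per set."""
    n_cases = int(matrix.case_mask.sum())
    n_controls = matrix.n_samples - n_cases
    results = []
    for name in sorted(gene_sets):
        t_case, t_control, _, sites = collapse(
            matrix, annotations, gene_sets[name], **collapse_kwargs
        )
        res = BurdenResult(
            gene_set=name,
            t_case=t_case,
            t_control=t_control,
            n_cases=n_cases,
            n_controls=n_controls,
            mean_case=t_case / n_cases,
            mean_control=t_control / n_controls,
            p=binomial_burden_test(t_case, t_control, n_cases, n_controls),
            qualifying_sites=tuple(sites),
        )
        res.validate()
        results.append(res)
    return results


def burden_report(results: list[BurdenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_set": r.gene_set,
                "t_case": r.t_case,
                "t_control": r.t_control,
                "mean_case": r.mean_case,
                "mean_control": r.mean_control,
                "p": r.p,
                "n_sites": len(r.qualifying_sites),
                "sites": ",".join(r.qualifying_sites),
            }
            for r in results
        ]
    )
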