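"""Single-variant case-control allelic association screen.

Each variable site is tabulated as a 2x2 minor/major allele table over
cases and controls (two alleles per non-missing genotype), tested with the
two-sided Fisher exact test, and summarised with the cross-product odds
ratio and a Woolf (log-OR normal) 95% confidence interval, with the
Haldane-Anscombe +0.5 correction when any cell is zero.

The screen applies the study-design filters before testing: pooled minor
allele frequency of at least ``maf_min`` (default 8%, the smallest MAF able
to reach p < 0.05 at the discovery sample size) and per-site genotype
missingness strictly below ``miss_max`` (default 10%).  Survivors are ranked
by ascending p (ties: larger |log OR|, then genomic position) and the top-K
carried to replication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .gmatrix import MISSING, GenotypeMatrix


@dataclass
class ScreenConfig:
    maf_min: float = 0.08
    miss_max: float = 0.10
    top_k: int = 5
    alpha: float = 0.05

    def validate(self):
        for name in ("maf_min", "miss_max", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class AssocResult:
    site_id: str
    contig: str
    pos: int
    case_minor: int
    case_major: int
    control_minor: int
    control_major: int
    maf_pooled: float
    missingness: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float

    @property
    def table(self) -> list[list[int]]:
        return [[self.case_minor, self.case_major], [self.control_minor, self.control_major]]


def allele_table(matrix: GenotypeMatrix, site_index: int) -> tuple[int, int, int, int]:
    """2x2 allele counts (case minor, case major, control minor, control major).

    The minor allele is defined on pooled non-missing alleles of cases plus
    controls; each non-missing genotype contributes two alleles.  A site with
    no non-missing genotype raises.
    """
    g = matrix.genotypes[:, site_index]
    cases = matrix.case_mask
    nonmiss = g != MISSING
    if not nonmiss.any():
        raise ValueError("site is fully missing")
    alt_case = int(g[cases & nonmiss].sum())
    tot_case = 2 * int((cases & nonmiss).sum())
    alt_ctrl = int(g[~cases & nonmiss].sum())
    tot_ctrl = 2 * int((~cases & nonmiss).sum())
    if 2 * (alt_case + alt_ctrl) <= tot_case + tot_ctrl:  # alt is the minor allele (tie: alt)
        return alt_case, tot_case - alt_case, alt_ctrl, tot_ctrl - alt_ctrl
    return tot_case - alt_case, alt_case, tot_ctrl - alt_ctrl, alt_ctrl


@lru_cache(maxsize=200000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric point probabilities
    not exceeding that of the observed table).

    A zero margin carries no information and returns 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return min(_fisher_cached(int(a), int(b), int(c), int(d)), 1.0)


def odds_ratio_ci(table, alpha: float = 0.05) -> tuple[float, float, float]:
    """Cross-product odds ratio with Woolf log-normal CI.

    Applies the Haldane-Anscombe +0.5 continuity correction to every cell
    when any cell is zero, keeping the estimate and interval finite.
    """
    (a, b), (c, d) = (float(x) for x in table[0]), (float(x) for x in table[1])
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return or_, or_ * math.exp(-z * se), or_ * math.exp(z * se)


def associate_site(matrix: GenotypeMatrix, site_index: int) -> AssocResult:
    """Fisher test + OR/CI for one site of the matrix."""
    a, b, c, d = allele_table(matrix, site_index)
    or_, lo, hi = odds_ratio_ci([[a, b], [c, d]])
    total = a + b + c + d
    site = matrix.sites.iloc[site_index]
    return AssocResult(
        site_id=site["site_id"],
        contig=site["contig"],
        pos=int(site["pos"]),
        case_minor=a,
        case_major=b,
        control_minor=c,
        control_major=d,
        maf_pooled=(a + c) / total if total else float("nan"),
        missingness=float((matrix.genotypes[:, site_index] == MISSING).mean()),
        p=fisher_two_sided([[a, b], [c, d]]),
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
    )


def screen(
    matrix: GenotypeMatrix, config: ScreenConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filtered, ranked single-variant screen.

    Returns (all ranked results, top-K selection).  Sites failing the pooled
    MAF floor or the missingness ceiling are excluded before testing.
    """
    config = config or ScreenConfig()
    config.validate()
    stats_df = matrix.minor_allele_stats()
    missing = matrix.missingness()
    rows = []
    for j in range(len(matrix.sites)):
        if stats_df["total_alleles"].iat[j] == 0:
            continue
        if stats_df["maf"].iat[j] < config.maf_min or missing[j] >= config.miss_max:
            continue
        rows.append(associate_site(matrix, j))
    frame = pd.DataFrame([r.__dict__ for r in rows])
    if frame.empty:
        return frame, frame
    frame["abs_log_or"] = np.abs(np.log(frame["odds_ratio"]))
    frame = frame.sort_values(
        ["p", "abs_log_or", "contig", "pos"],
        ascending=[True, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame, frame.head(config.top_k).copy()


def min_detectable_mac(n_case_alleles: int, n_control_alleles: int, alpha: float = 0.05) -> int:
    """Smallest minor-allele count able to reach two-sided Fisher p < alpha.

    Considers the maximally unbalanced allelic table — all m minor alleles in
    one group (whichever placement is more extreme) — and returns the
    smallest such m.  Raises when no count up to the total reaches alpha.
    """
    if n_case_alleles < 1 or n_control_alleles < 1:
        raise ValueError("allele totals must be positive")
    total = n_case_alleles + n_control_alleles
    for m in range(1, total + 1):
        best = 1.0
        if m <= n_case_alleles:
            best = min(best, fisher_two_sided([[m, n_case_alleles - m], [0, n_control_alleles]]))
        if m <= n_control_alleles:
            best = min(best, fisher_two_sided([[0, n_case_alleles], [m, n_control_alleles - m]]))
        if best < alpha:
            return m
    raise ValueError("no minor-allele count reaches the requested significance")


def results_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Report columns mirroring the published association table layout."""
    if frame.empty:
        return frame
    out = frame[
        ["rank", "site_id", "contig", "pos", "case_minor", "control_minor", "maf_pooled",
         "missingness", "p", "odds_ratio", "ci_low", "ci_high"]
    ].copy()
    out.columns = [
        "rank", "site", "contig", "pos", "alleles_cases", "alleles_controls", "maf_pooled",
        "missingness", "p", "or", "ci95_low", "ci95_high",
    ]
    return out
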