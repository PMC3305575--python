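"""Two-stage replication: power-gated carry-over and combined analysis.

Stage-1 hits are carried to full replication only when, given their stage-1
case/control allele frequencies, a two-proportion z-test at the full sample
size would reject at level ``alpha2`` with probability at least
``power_threshold`` (defaults 0.005 and 80%).  The power computation uses
the normal approximation with the pooled-variance null standard error and
the unpooled alternative standard error, on allele proportions (two alleles
per individual, treated as independent).  The combined analysis sums the
per-stage 2x2 allele tables and re-applies the Fisher test and Woolf CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import fisher_two_sided, odds_ratio_ci


@dataclass
class StageConfig:
    stage1_n: int = 284  # individuals in the initial replication
    full_n_cases: int = 719
    full_n_controls: int = 719
    alpha2: float = 0.005
    power_threshold: float = 0.80

    def validate(self):
        if not 0 < self.alpha2 < 1 or not 0 < self.power_threshold < 1:
            raise ValueError("alpha2 and power_threshold must be in (0,1)")
        if self.stage1_n > self.full_n_cases + self.full_n_controls:
            raise ValueError("stage-1 cohort larger than the full cohort")
        if min(self.stage1_n, self.full_n_cases, self.full_n_controls) < 1:
            raise ValueError("sample sizes must be positive")


def two_proportion_power(
    p1: float, p2: float, n1: int, n2: int, alpha: float = 0.005
) -> float:
    """Power of the two-sided two-proportion z-test at level ``alpha``.

    ``n1``/``n2`` are allele counts (2 x individuals).  Pooled-variance
    standard error under the null, unpooled under the alternative; both
    rejection directions contribute, so the null limit p1 == p2 gives
    power == alpha (alpha/2 per direction).
    """
    if not 0 < p1 < 1 or not 0 < p2 < 1:
        raise ValueError("proportions must be strictly inside (0,1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("allele counts must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    delta = p1 - p2
    pbar = (p1 * n1 + p2 * n2) / (n1 + n2)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z = stats.norm.ppf(1 - alpha / 2)
    upper = stats.norm.cdf((delta - z * se0) / se1)
    lower = stats.norm.cdf((-delta - z * se0) / se1)
    return float(upper + lower)


def select_for_stage2(stage1_freqs, config: StageConfig | None = None):
    """Power-gate stage-1 estimates for full replication.

    ``stage1_freqs`` is an iterable of (site_id, case_freq, control_freq)
    from stage 1.  Returns a list of dicts with the computed power and the
    selection decision (power >= threshold selects; the boundary is
    inclusive).
    """
    config = config or StageConfig()
    config.validate()
    n1 = 2 * config.full_n_cases
    n2 = 2 * config.full_n_controls
    out = []
    for site_id, f_case, f_ctrl in stage1_freqs:
        power = two_proportion_power(f_case, f_ctrl, n1, n2, config.alpha2)
        out.append(
            {
                "site": site_id,
                "stage1_case_freq": f_case,
                "stage1_control_freq": f_ctrl,
                "power": power,
                "selected": power >= config.power_threshold,
            }
        )
    return out


def combined_analysis(stage1_table, stage2_table):
    """Cell-wise sum of per-stage allele tables -> Fisher p, OR, 95% CI.

    ``stage2_table`` may be None/empty, in which case the result equals the
    stage-1 analysis.
    """
    (a1, b1), (c1, d1) = stage1_table
    if stage2_table is None:
        a2 = b2 = c2 = d2 = 0
    else:
        (a2, b2), (c2, d2) = stage2_table
    table = [[a1 + a2, b1 + b2], [c1 + c2, d1 + d2]]
    p = fisher_two_sided(table)
    or_, lo, hi = odds_ratio_ci(table)
    return {
        "table": table,
        "p": p,
        "odds_ratio": or_,
        "ci_low": lo,
        "ci_high": hi,
        "n_case_alleles": table[0][0] + table[0][1],
        "n_control_alleles": table[1][0] + table[1][1],
    }
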