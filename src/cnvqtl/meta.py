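"""Cross-population meta-analysis by the chi-square-sum rule.

Per-variant 1-df chi-square statistics from independent population scans are
summed; under the null the sum is chi-square distributed with degrees of
freedom equal to the number of populations in which the variant was actually
tested. Bonferroni control divides alpha by the number of variants tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetaResult", "meta_chi2", "bonferroni", "meta_scan"]


@dataclass
class MetaResult:
    variant_id: str
    chi2_sum: float
    df: int
    p: float
    lod: float
    contributing_populations: list[str] = field(default_factory=list)


def meta_chi2(per_population_chi2: dict[str, float],
              variant_id: str = "") -> MetaResult:
    """Sum per-population chi-square values for one variant.

    Populations with a non-finite statistic (variant not tested there) are
    dropped; df is the count of contributors, and the P-value is the upper
    tail of chi-square(df).
    """
    contributing = {k: v for k, v in per_population_chi2.items()
                    if v is not None and math.isfinite(v)}
    if not contributing:
        raise ValueError(f"no finite chi-square for variant {variant_id!r}")
    if any(v < 0 for v in contributing.values()):
        raise ValueError("chi-square values must be >= 0")
    chi2_sum = float(sum(contributing.values()))
    df = len(contributing)
    p = float(stats.chi2.sf(chi2_sum, df=df))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return MetaResult(
        variant_id=variant_id,
        chi2_sum=chi2_sum,
        df=df,
        p=p,
        lod=float(-np.log10(p)),
        contributing_populations=sorted(contributing),
    )


def bonferroni(alpha: float, n_tests: int) -> float:
    """Multiple-testing threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def meta_scan(population_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-population association tables (variant_id, chi2 columns).

    Variants are matched by id across populations; a variant missing from a
    population simply contributes fewer degrees of freedom.
    """
    chi2_by_variant: dict[str, dict[str, float]] = {}
    for pop, frame in population_results.items():
        for vid, chi2 in zip(frame["variant_id"], frame["chi2"]):
            chi2_by_variant.setdefault(str(vid), {})[pop] = float(chi2)
    rows = []
    for vid, per_pop in chi2_by_variant.items():
        r = meta_chi2(per_pop, variant_id=vid)
        rows.append(
            {
                "variant_id": r.variant_id,
                "chi2_sum": r.chi2_sum,
                "df": r.df,
                "p": r.p,
                "lod": r.lod,
                "populations": ",".join(r.contributing_populations),
            }
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "chi2_sum", "df", "p", "lod", "populations"]
    )
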