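"""Cohort-level statistics: Mendelian segregation and protein filters.

Chi-square goodness of fit of offspring genotype counts against an
expected segregation ratio (1:2:1 for a heterozygote intercross),
observed-over-expected summaries per genotype, and the differential-
protein filter rule (|log2 fold change| > 0.5 and P < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "mendelian_test",
    "observed_over_expected",
    "dep_filter",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Offspring counts per genotype, ordered (+/+, mut/+, mut/mut)."""

    wildtype: int
    het: int
    hom: int

    def __post_init__(self) -> None:
        if min(self.wildtype, self.het, self.hom) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("total count must be positive")

    @property
    def total(self) -> int:
        return self.wildtype + self.het + self.hom

    def as_array(self) -> np.ndarray:
        return np.array([self.wildtype, self.het, self.hom], dtype=float)


def _expected(counts: GenotypeCounts, ratio: Sequence[float]) -> np.ndarray:
    ratio = np.asarray(ratio, dtype=float)
    if ratio.shape != (3,) or np.any(ratio < 0) or ratio.sum() == 0:
        raise ValueError("ratio must be 3 non-negative weights with positive sum")
    exp = counts.total * ratio / ratio.sum()
    if np.any(exp == 0):
        raise ValueError("degenerate ratio: an expected cell is zero")
    return exp


def mendelian_test(
    counts: GenotypeCounts, ratio: Sequence[float] = (1, 2, 1)
) -> tuple[float, int, float]:
    """Chi-square test of genotype counts against a segregation ratio.

    Expected counts derive from the observed total partitioned by the
    ratio; returns (chi2, df, p) with df = 2.
    """
    exp = _expected(counts, ratio)
    chi2, p = stats.chisquare(counts.as_array(), f_exp=exp)
    return float(chi2), len(exp) - 1, float(p)


def observed_over_expected(
    counts: GenotypeCounts,
    ratio: Sequence[float] = (1, 2, 1),
    anchor: str = "total",
) -> pd.Series:
    """Observed counts as percent of expectation, per genotype.

    With ``anchor="total"`` (default, the chi-square convention) the
    expectation partitions the observed total by the ratio. With
    ``anchor="wildtype"`` the wild-type count is taken at face value and
    the other genotypes are expected in ratio-proportion to it — useful
    when lethality depletes mutant classes and the wild-type count is
    the natural denominator.
    """
    obs = counts.as_array()
    if anchor == "total":
        exp = _expected(counts, ratio)
    elif anchor == "wildtype":
        ratio = np.asarray(ratio, dtype=float)
        if ratio[0] <= 0 or counts.wildtype == 0:
            raise ValueError("wildtype anchoring requires nonzero wild-type weight and count")
        exp = counts.wildtype * ratio / ratio[0]
    else:
        raise ValueError("anchor must be 'total' or 'wildtype'")
    return pd.Series(
        100.0 * obs / exp, index=["wildtype", "het", "hom"], name="percent_of_expected"
    )


def dep_filter(
    records: pd.DataFrame,
    log2fc_col: str = "log2fc",
    p_col: str = "p",
    log2fc_cut: float = 0.5,
    p_cut: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differentially expressed proteins by fold-change and P-value cuts.

    Up: log2FC > cut and P < p_cut; down: log2FC < -cut and P < p_cut;
    both inequalities strict, so boundary values are excluded. The two
    returned frames are disjoint.
    """
    fc = records[log2fc_col].to_numpy(dtype=float)
    p = records[p_col].to_numpy(dtype=float)
    if not (np.all(np.isfinite(fc)) and np.all(np.isfinite(p))):
        raise ValueError("log2 fold changes and P values must be finite")
    up = records[(fc > log2fc_cut) & (p < p_cut)]
    down = records[(fc < -log2fc_cut) & (p < p_cut)]
    return up, down
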