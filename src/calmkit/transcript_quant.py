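"""Transcript-level quantification.

FPKM computation, allele-specific read fractions at a tagging variant,
the share of total calmodulin transcripts contributed by the mutant
allele, and 2^-ddCt based absolute transcript estimates for chambers
without RNA-Seq coverage.

The mutant-share calculation rests on the fact that the three Calm genes
encode an identical protein, so the mutant allele's contribution to the
calmodulin transcript pool is its within-Calm1 allelic fraction scaled by
Calm1's share of summed Calm1+Calm2+Calm3 expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlleleCount",
    "AlleleFractions",
    "DdctEstimate",
    "compute_fpkm",
    "fpkm_table",
    "allele_fractions",
    "mutant_transcript_share",
    "ddct_estimate",
]


@dataclass(frozen=True)
class AlleleCount:
    """Read counts supporting each allele at one variant position.

    ``ref_count`` counts fragments carrying the reference (wild-type)
    nucleotide, ``alt_count`` those carrying the mutant nucleotide.
    """

    ref_count: int
    alt_count: int
    position: str = ""

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class AlleleFractions:
    ref_fraction: float
    alt_fraction: float
    ref_over_alt_fold: float
    fold_defined: bool


@dataclass(frozen=True)
class DdctEstimate:
    """Relative expression (2^-ddCt) scaled to an absolute reference level.

    ``estimate`` is ``fold_change`` times the calibrator-tissue FPKM;
    ``margin_low``/``margin_high`` are the 2^-(ddCt +/- SEM) band, where
    the SEM is that of the target-tissue mean dCt.
    """

    fold_change: float
    estimate: float
    margin_low: float
    margin_high: float
    ddct: float
    sem: float


def compute_fpkm(
    fragment_count: float | np.ndarray,
    length_kb: float | np.ndarray,
    library_size_millions: float | np.ndarray,
) -> float | np.ndarray:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``fpkm = count / (length_kb * library_size_millions)``. Isoform-level
    counts should be pooled per gene before calling.
    """
    count = np.asarray(fragment_count, dtype=float)
    length = np.asarray(length_kb, dtype=float)
    lib = np.asarray(library_size_millions, dtype=float)
    if np.any(count < 0):
        raise ValueError("fragment counts must be non-negative")
    if np.any(length <= 0):
        raise ValueError("transcript length (kb) must be strictly positive")
    if np.any(lib <= 0):
        raise ValueError("library size (millions) must be strictly positive")
    fpkm = count / (length * lib)
    if np.ndim(fragment_count) == 0 and np.ndim(length_kb) == 0:
        return float(fpkm)
    return fpkm


def fpkm_table(
    counts: pd.DataFrame,
    library_size_millions: float,
    count_col: str = "count",
    length_col: str = "length_kb",
) -> pd.DataFrame:
    """Add an ``fpkm`` column to a per-gene fragment-count table."""
    out = counts.copy()
    out["fpkm"] = compute_fpkm(
        out[count_col].to_numpy(), out[length_col].to_numpy(), library_size_millions
    )
    return out


def allele_fractions(counts: AlleleCount) -> AlleleFractions:
    """Fractions of reads supporting each allele and the ref/alt fold.

    The fold (reference over alternate) is flagged undefined when no
    alternate reads were observed; ``inf`` is returned in that case.
    """
    total = counts.total
    if total <= 0:
        raise ValueError("cannot compute allele fractions from zero total reads")
    ref_f = counts.ref_count / total
    alt_f = counts.alt_count / total
    if counts.alt_count == 0:
        return AlleleFractions(ref_f, alt_f, float("inf"), fold_defined=False)
    return AlleleFractions(ref_f, alt_f, counts.ref_count / counts.alt_count, True)


def alt_fraction_from_fold(ref_over_alt_fold: float) -> float:
    """Alternate-allele fraction implied by a reference/alternate fold.

    With ref = fold * alt, the alternate fraction is 1 / (1 + fold).
    """
    if ref_over_alt_fold < 0:
        raise ValueError("fold must be non-negative")
    return 1.0 / (1.0 + ref_over_alt_fold)


def mutant_transcript_share(
    alt_fraction: float,
    fpkm_calm: Sequence[float],
    ndigits: int | None = 1,
) -> float:
    """Percent of the total Calm transcript pool carrying the mutation.

    ``share = alt_fraction * fpkm_Calm1 / sum(fpkm_Calm1..Calm3)``,
    reported as a percentage. The first entry of ``fpkm_calm`` must be the
    mutated gene (Calm1). Rounded to ``ndigits`` decimals (``None`` keeps
    the raw value).
    """
    if not 0.0 <= alt_fraction <= 1.0:
        raise ValueError("alt_fraction must lie in [0, 1]")
    fpkm = np.asarray(fpkm_calm, dtype=float)
    if np.any(fpkm < 0):
        raise ValueError("FPKM values must be non-negative")
    total = fpkm.sum()
    if total == 0:
        raise ValueError("all-zero FPKM vector: share undefined")
    share = 100.0 * alt_fraction * fpkm[0] / total
    return share if ndigits is None else round(share, ndigits)


def _delta_ct(ct: pd.DataFrame, gene: str, tissue: str, ct_col: str, ref_col: str) -> np.ndarray:
    sub = ct[(ct["gene"] == gene) & (ct["tissue"] == tissue)]
    if sub.empty:
        raise ValueError(f"no Ct replicates for gene={gene!r}, tissue={tissue!r}")
    if sub[ref_col].isna().any():
        raise ValueError("reference-gene Ct missing for at least one replicate")
    return (sub[ct_col] - sub[ref_col]).to_numpy(dtype=float)


def ddct_estimate(
    ct: pd.DataFrame,
    gene: str,
    target_tissue: str,
    calibrator_tissue: str,
    calibrator_fpkm: float,
    ct_col: str = "ct",
    ref_col: str = "ref_ct",
) -> DdctEstimate:
    """Absolute transcript estimate for a tissue via the 2^-ddCt method.

    Per replicate, dCt = Ct(target gene) - Ct(reference gene); ddCt is the
    difference of tissue mean dCts (target minus calibrator). The fold
    change 2^-ddCt multiplied by the calibrator tissue's FPKM yields an
    FPKM-equivalent estimate. The error band uses the SEM of the
    target-tissue dCt mean: 2^-(ddCt -/+ SEM) scaled likewise.

    ``ct`` is a long table with columns ``gene``, ``tissue``, ``ct_col``
    (target-gene Ct) and ``ref_col`` (reference-gene Ct measured in the
    same replicate).
    """
    d_target = _delta_ct(ct, gene, target_tissue, ct_col, ref_col)
    d_cal = _delta_ct(ct, gene, calibrator_tissue, ct_col, ref_col)
    ddct = float(d_target.mean() - d_cal.mean())
    if len(d_target) > 1:
        sem = float(d_target.std(ddof=1) / np.sqrt(len(d_target)))
    else:
        sem = 0.0
    fold = 2.0 ** (-ddct)
    return DdctEstimate(
        fold_change=fold,
        estimate=fold * calibrator_fpkm,
        margin_low=2.0 ** (-(ddct + sem)) * calibrator_fpkm,
        margin_high=2.0 ** (-(ddct - sem)) * calibrator_fpkm,
        ddct=ddct,
        sem=sem,
    )
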