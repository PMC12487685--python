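"""Stable-isotope-dilution (AQUA) absolute protein quantification.

A known amount of a synthetic, isotopically heavy copy of a proteotypic
peptide is spiked into each digest; the analyte amount follows from the
light/heavy chromatographic peak-area ratio. Quantifying the wild-type
(N98) and mutant (S98) calmodulin peptides separately gives absolute
amounts of each protein isoform and hence the mutant fraction per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# monoisotopic mass excess per substituted atom, in daltons
DELTA_13C = 1.003355
DELTA_15N = 0.997035

__all__ = [
    "IsotopeLabel",
    "PeptideQuant",
    "heavy_label_mass_shift",
    "absolute_amount",
    "normalize_amount",
    "mutant_fraction",
    "summarize_by_genotype",
]


@dataclass(frozen=True)
class IsotopeLabel:
    """Heavy-isotope composition of a labeled residue (e.g. Leu 13C6,15N1)."""

    n_13c: int
    n_15n: int

    def __post_init__(self) -> None:
        if self.n_13c < 0 or self.n_15n < 0:
            raise ValueError("isotope counts must be non-negative")


@dataclass(frozen=True)
class PeptideQuant:
    """Light/heavy peak areas with the spiked standard amount for one peptide."""

    peptide: str
    light_area: float
    heavy_area: float
    spike_fmol: float
    total_protein_ug: float | None = None

    def __post_init__(self) -> None:
        if self.light_area < 0 or self.heavy_area < 0:
            raise ValueError("peak areas must be non-negative")
        if self.spike_fmol <= 0:
            raise ValueError("spike amount must be strictly positive")


def heavy_label_mass_shift(label: IsotopeLabel) -> float:
    """Monoisotopic mass shift (Da) of a heavy-labeled peptide.

    For the common Leu(13C6, 15N1) label this is 7.017 Da, observed as a
    7 Da shift at unit mass resolution (use ``round`` for the nominal
    value).
    """
    return label.n_13c * DELTA_13C + label.n_15n * DELTA_15N


def absolute_amount(q: PeptideQuant) -> float:
    """Analyte amount in fmol from single-point internal-standard calibration.

    amount = spike * light_area / heavy_area. Assumes identical ionization
    and detection efficiency for the light and heavy forms, which the
    isotope label guarantees up to chromatographic co-elution.
    """
    if q.heavy_area <= 0:
        raise ValueError(
            "heavy (internal standard) peak area must be positive for quantification"
        )
    return q.spike_fmol * q.light_area / q.heavy_area


def normalize_amount(amount_fmol: float, total_protein_ug: float) -> float:
    """Amount per microgram of total protein loaded (fmol/ug)."""
    if total_protein_ug <= 0:
        raise ValueError("total protein amount must be strictly positive")
    return amount_fmol / total_protein_ug


def mutant_fraction(
    wt_amount: float, mut_amount: float, ndigits: int | None = 1
) -> float:
    """Mutant share of total calmodulin protein, in percent.

    ``100 * mut / (wt + mut)``; complements sum to exactly 100 before
    rounding. Rounded to ``ndigits`` decimals (``None`` keeps raw).
    """
    if wt_amount < 0 or mut_amount < 0:
        raise ValueError("amounts must be non-negative")
    total = wt_amount + mut_amount
    if total <= 0:
        raise ValueError("cannot compute mutant fraction when both amounts are zero")
    pct = 100.0 * mut_amount / total
    return pct if ndigits is None else round(pct, ndigits)


def summarize_by_genotype(
    samples: pd.DataFrame,
    value_col: str,
    group_col: str = "genotype",
) -> pd.DataFrame:
    """Median and range of a per-sample quantity within each genotype.

    The median uses the midpoint-of-two convention for even group sizes
    (numpy default). Returns a frame indexed by genotype with columns
    ``median``, ``min``, ``max``, ``n``.
    """
    if samples.empty:
        raise ValueError("at least one sample required")
    g = samples.groupby(group_col)[value_col]
    out = g.agg(median="median", min="min", max="max", n="count")
    return out


def quantify_samples(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized AQUA quantification of a long-format peak-area table.

    Expects columns ``light_area``, ``heavy_area``, ``spike_fmol`` and
    optionally ``total_protein_ug``; appends ``amount_fmol`` and, when
    total protein is present, ``amount_fmol_per_ug``.
    """
    heavy = table["heavy_area"].to_numpy(dtype=float)
    if np.any(heavy <= 0):
        raise ValueError("heavy peak area must be positive in every row")
    out = table.copy()
    out["amount_fmol"] = (
        table["spike_fmol"].to_numpy(dtype=float)
        * table["light_area"].to_numpy(dtype=float)
        / heavy
    )
    if "total_protein_ug" in table.columns:
        tot = table["total_protein_ug"].to_numpy(dtype=float)
        if np.any(tot <= 0):
            raise ValueError("total protein must be positive in every row")
        out["amount_fmol_per_ug"] = out["amount_fmol"] / tot
    return out
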