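"""Abundance and activity quantification from molecular tables.

Four independent measurements of *Ca.* Methanoliparum presence/activity:

* absolute 16S rRNA gene copies per gram of sample from qPCR, via a
  log-linear standard curve fitted to a plasmid dilution series;
* relative abundance within the archaeal community from an amplicon
  feature table, as the read fraction of the exact-match target features;
* genome-level transcriptional activity as the length-normalized share of
  metatranscriptomic reads mapping to each MAG;
* gene-level expression as FPKM (fragments per kilobase of transcript per
  million mapped reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QpcrMeasurement",
    "fit_standard_curve",
    "quantify_copies",
    "target_relative_abundance",
    "mag_relative_activity",
    "compute_fpkm",
]


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear qPCR calibration: Cq = slope * log10(copies) + intercept.

    A valid dilution-series curve has a negative slope; the amplification
    efficiency follows as ``10**(-1/slope) - 1`` (slope -3.3219 at perfect
    doubling, i.e. 100% efficiency).
    """

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def is_valid(self) -> bool:
        return self.slope < 0


@dataclass(frozen=True)
class QpcrMeasurement:
    """One sample's qPCR observation plus the metadata needed to convert
    copies per reaction into copies per gram of sample.

    ``cq`` may be NaN for a below-quantification (undetected) sample.
    """

    sample_id: str
    cq: float
    dilution_factor: float = 1.0
    input_mass_g: float = 1.0
    extract_fraction_per_reaction: float = 1.0

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.input_mass_g <= 0:
            raise ValueError("input mass must be positive")
        if not (0 < self.extract_fraction_per_reaction <= 1):
            raise ValueError("extract fraction must lie in (0, 1]")
        if not math.isnan(self.cq) and self.cq <= 0:
            raise ValueError("cq must be positive when observed")


def fit_standard_curve(log10_copies: np.ndarray, cq: np.ndarray) -> StandardCurve:
    """Least-squares standard curve from a dilution series.

    Requires at least three points with distinct copy numbers.  A fitted
    nonnegative slope is returned but flagged invalid (``is_valid``),
    since it cannot come from a working dilution series.
    """
    x = np.asarray(log10_copies, float)
    y = np.asarray(cq, float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired dilution points")
    if np.unique(x).size < 2:
        raise ValueError("dilution points must span distinct copy numbers")
    res = stats.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


def quantify_copies(m: QpcrMeasurement, curve: StandardCurve) -> float:
    """Absolute abundance in 16S gene copies per gram of sample.

    Copies per reaction invert the standard curve,
    ``10**((cq - intercept)/slope)``; the per-gram conversion applies the
    user-supplied dilution and extraction metadata.  A missing (NaN) Cq
    reports NaN — below quantification, deliberately never zero so that
    log-scale summaries stay well defined.
    """
    if not curve.is_valid:
        raise ValueError("standard curve is invalid (nonnegative slope)")
    if math.isnan(m.cq):
        return float("nan")
    copies_per_reaction = 10.0 ** ((m.cq - curve.intercept) / curve.slope)
    return copies_per_reaction * m.dilution_factor / (
        m.input_mass_g * m.extract_fraction_per_reaction
    )


def target_relative_abundance(counts: pd.DataFrame, target_features: list[str]) -> pd.Series:
    """Per-sample read fraction of the target features.

    ``counts`` is samples x features (nonnegative).  Samples with zero
    total reads are reported as NaN (missing), not zero.
    """
    missing = [f for f in target_features if f not in counts.columns]
    if missing:
        raise ValueError(f"target features not in table: {missing}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1).astype(float)
    frac = counts[list(target_features)].sum(axis=1) / totals.where(totals > 0)
    return frac.rename("target_fraction")


def mag_relative_activity(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Length-normalized per-sample MAG activity fractions.

    Each MAG's mapped-read count is divided by its genome length, then
    normalized to the per-sample sum over all MAGs, so fractions sum to 1
    for every sample with any mapped reads; zero-read samples are NaN.
    """
    lengths = lengths.reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError("every MAG needs a length")
    if (lengths <= 0).any():
        raise ValueError("MAG lengths must be positive")
    density = counts.div(lengths, axis=1)
    totals = density.sum(axis=1)
    return density.div(totals.where(totals > 0), axis=0)


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    total_mapped: pd.Series,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``fpkm = counts * 1e9 / (length_bp * total_mapped)`` per gene and
    sample; samples with zero total mapped fragments are NaN.
    """
    gene_lengths = gene_lengths.reindex(counts.columns)
    if gene_lengths.isna().any() or (gene_lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    totals = total_mapped.reindex(counts.index).astype(float)
    return counts.mul(1e9).div(gene_lengths, axis=1).div(totals.where(totals > 0), axis=0)
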