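"""Targeted MRM screening of the alkyl-coenzyme M homolog series.

Alkyl-CoM thioethers (CnH2n+1-S-C2H4-SO3-, n = 4..28) are the initial
intracellular metabolites of archaeal alkane activation and serve as a
biomarker for alkylotrophic methanogenesis in oil-reservoir samples.  In
negative-mode MS/MS the molecular anion fragments into three diagnostic
product ions: bisulfite (HSO3-, m/z 80.9), vinylsulfonate (C2H3SO3-,
m/z 106.9) and the chain-length-specific alkyl sulfonate (CnH2n+1-SO3-).
This module builds the theoretical transition list for the whole homolog
series, matches observed MRM transitions against it, applies the intensity
detection threshold, and reports the per-sample homolog "variety" (the
number of distinct detected chain lengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FragmentMassModel",
    "AlkylComHit",
    "VarietyResult",
    "fragment_mz",
    "precursor_mz",
    "build_transitions",
    "screen",
]

# Fragment names used throughout the transition tables.
HSO3 = "HSO3-"
C2H3SO3 = "C2H3SO3-"
ALKYL = "alkyl"

CHAIN_MIN = 4
CHAIN_MAX = 28


@dataclass(frozen=True)
class FragmentMassModel:
    """Generalized fragment-mass model for alkyl-CoM MRM transitions.

    The product-ion masses follow the empirical one-decimal rule
    ``m/z = carbon_mass * n + hydrogen_mass * (2n + 1) + so3_constant``
    calibrated on authentic hexadecyl- and eicosyl-CoM standards; the
    effective per-atom constants absorb the electron mass and instrument
    calibration, hence they differ slightly from the IUPAC monoisotopic
    masses.  ``sulfur_mass`` enters only the precursor (molecular anion).
    """

    carbon_mass: float = 12.00055
    hydrogen_mass: float = 1.00837
    so3_constant: float = 79.9
    sulfur_mass: float = 31.97207
    report_decimals: int = 1

    def __post_init__(self) -> None:
        for name in ("carbon_mass", "hydrogen_mass", "so3_constant", "sulfur_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AlkylComHit:
    """A detected alkyl-CoM homolog in one sample.

    ``matched_ions`` always contains the qualifying bisulfite transition;
    matches to the other two product ions are corroborating only.
    """

    chain_length: int
    matched_ions: frozenset[str]
    qualifying_intensity: float

    def __post_init__(self) -> None:
        if not (CHAIN_MIN <= self.chain_length <= CHAIN_MAX):
            raise ValueError(f"chain length {self.chain_length} outside [{CHAIN_MIN}, {CHAIN_MAX}]")
        if not self.matched_ions:
            raise ValueError("a hit requires at least one matched ion pair")


@dataclass(frozen=True)
class VarietyResult:
    """Per-sample summary: which chain lengths were detected and how many."""

    sample_id: str
    detected_chain_lengths: frozenset[int] = field(default_factory=frozenset)

    @property
    def variety(self) -> int:
        return len(self.detected_chain_lengths)


def fragment_mz(model: FragmentMassModel, fragment: str, n: int | None = None) -> float:
    """m/z of a product ion, rounded to the model's reporting precision.

    Parameters
    ----------
    fragment : {"HSO3-", "C2H3SO3-", "alkyl"}
        Product-ion identity.  ``"alkyl"`` is the chain-length-specific
        CnH2n+1-SO3- ion and requires ``n``.
    n : int, optional
        Alkyl chain length, 1..40, required for ``fragment="alkyl"``.
    """
    if fragment == HSO3:
        mz = model.hydrogen_mass * 1 + model.so3_constant
    elif fragment == C2H3SO3:
        mz = model.carbon_mass * 2 + model.hydrogen_mass * 3 + model.so3_constant
    elif fragment == ALKYL:
        if n is None:
            raise ValueError("alkyl fragment requires a chain length n")
        if not (1 <= n <= 40):
            raise ValueError(f"alkyl chain length {n} outside [1, 40]")
        mz = model.carbon_mass * n + model.hydrogen_mass * (2 * n + 1) + model.so3_constant
    else:
        raise ValueError(f"unknown fragment {fragment!r}")
    return round(mz, model.report_decimals)


def precursor_mz(model: FragmentMassModel, n: int) -> float:
    """m/z of the intact alkyl-CoM molecular anion CnH2n+1-S-C2H4-SO3-.

    Relative to the alkyl-sulfonate product, the precursor carries the
    thioether bridge: two extra carbons, four extra hydrogens, and one
    sulfur.
    """
    if not (CHAIN_MIN <= n <= CHAIN_MAX):
        raise ValueError(f"chain length {n} outside [{CHAIN_MIN}, {CHAIN_MAX}]")
    mz = (
        model.carbon_mass * (n + 2)
        + model.hydrogen_mass * (2 * n + 5)
        + model.sulfur_mass
        + model.so3_constant
    )
    return round(mz, model.report_decimals)


def build_transitions(
    model: FragmentMassModel | None = None,
    n_min: int = CHAIN_MIN,
    n_max: int = CHAIN_MAX,
) -> pd.DataFrame:
    """Theoretical MRM transition list for the homolog series.

    Returns a DataFrame with one row per (precursor, product) ion pair:
    three transitions per chain length, i.e. ``3 * (n_max - n_min + 1)``
    rows with columns ``chain_length, precursor_mz, product_mz,
    product_ion``.
    """
    model = model or FragmentMassModel()
    if not (CHAIN_MIN <= n_min <= n_max <= CHAIN_MAX):
        raise ValueError(
            f"chain-length range [{n_min}, {n_max}] must be ordered and within "
            f"[{CHAIN_MIN}, {CHAIN_MAX}]"
        )
    rows = []
    for n in range(n_min, n_max + 1):
        prec = precursor_mz(model, n)
        rows.append((n, prec, fragment_mz(model, HSO3), HSO3))
        rows.append((n, prec, fragment_mz(model, C2H3SO3), C2H3SO3))
        rows.append((n, prec, fragment_mz(model, ALKYL, n), ALKYL))
    return pd.DataFrame(rows, columns=["chain_length", "precursor_mz", "product_mz", "product_ion"])


def screen(
    observed: pd.DataFrame,
    theoretical: pd.DataFrame | None = None,
    mz_tolerance: float = 0.3,
    intensity_threshold: float = 2000.0,
    sample_id: str = "",
) -> tuple[VarietyResult, list[AlkylComHit]]:
    """Match observed MRM transitions against the theoretical homolog list.

    A chain length n counts as detected iff some observed row matches the
    precursor(n) -> HSO3- ion pair within ``mz_tolerance`` on both m/z
    coordinates with intensity strictly greater than
    ``intensity_threshold``.  Matches of the same precursor to the
    vinylsulfonate or alkyl-sulfonate products are recorded on the hit as
    corroboration but are neither necessary nor sufficient for detection.

    ``observed`` needs columns ``precursor_mz, product_mz, intensity``; an
    empty table yields variety 0.
    """
    if mz_tolerance <= 0:
        raise ValueError("mz_tolerance must be positive")
    theo = theoretical if theoretical is not None else build_transitions()
    if observed.empty:
        return VarietyResult(sample_id), []

    obs_prec = observed["precursor_mz"].to_numpy(float)
    obs_prod = observed["product_mz"].to_numpy(float)
    obs_int = observed["intensity"].to_numpy(float)

    hits: list[AlkylComHit] = []
    for n, group in theo.groupby("chain_length"):
        matched: set[str] = set()
        qualifying = 0.0
        for row in group.itertuples():
            in_tol = (np.abs(obs_prec - row.precursor_mz) <= mz_tolerance) & (
                np.abs(obs_prod - row.product_mz) <= mz_tolerance
            )
            if not in_tol.any():
                continue
            best = float(obs_int[in_tol].max())
            if row.product_ion == HSO3:
                if best > intensity_threshold:
                    matched.add(HSO3)
                    qualifying = best
            else:
                matched.add(row.product_ion)
        if HSO3 in matched:
            hits.append(AlkylComHit(int(n), frozenset(matched), qualifying))

    detected = frozenset(h.chain_length for h in hits)
    return VarietyResult(sample_id, detected), hits
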