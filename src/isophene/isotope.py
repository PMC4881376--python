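"""Isotope arithmetic: ratios from accumulated counts, fractionation
correction, delta/ratio/atom-fraction conversions and label mass balance.

All single-cell quantities are expressed as isotope *ratios* (e.g. 13C/12C)
or as count-based elemental ratios (C/CN, S/CN).  Delta notation and atom
fractions are provided for interoperability with bulk IRMS measurements and
labeling-recipe calculations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .presets import ALL_RATIOS

log = logging.getLogger(__name__)

KEY_COLUMNS = ["session", "region", "roi_id"]
COUNT_COLUMNS = ["c12", "c13", "nc14", "nc15", "s32", "s33", "s34"]


@dataclass(frozen=True)
class ReferenceRatios:
    """International reference isotope ratios used in delta conversions.

    Defaults: VPDB for carbon, atmospheric N2 for nitrogen, VCDT for sulfur.
    """

    R_VPDB_13C: float = 0.0112372
    R_AIR_15N: float = 0.0036765
    R_VCDT_33S: float = 0.0078772
    R_VCDT_34S: float = 0.0441626

    def __post_init__(self):
        for name in ("R_VPDB_13C", "R_AIR_15N", "R_VCDT_33S", "R_VCDT_34S"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


REFERENCE = ReferenceRatios()


@dataclass
class CalibrationStandard:
    """Instrument calibration pairs for fractionation correction.

    ``measured`` holds the mean on-instrument ratio of the standard (e.g.
    Clostridia spores) and ``true`` the independently measured (EA-IRMS)
    value, keyed by ratio column.  Only ratios present in both mappings are
    corrected; sulfur ratios are typically left uncorrected because spore
    standards carry too little sulfur.
    """

    measured: dict[str, float] = field(default_factory=dict)
    true: dict[str, float] = field(default_factory=dict)

    def factors(self) -> dict[str, float]:
        out = {}
        for col in self.measured:
            if col not in self.true:
                continue
            if self.measured[col] <= 0:
                raise ValueError(f"measured standard ratio for {col} must be > 0")
            if self.true[col] <= 0:
                raise ValueError(f"true standard ratio for {col} must be > 0")
            out[col] = self.true[col] / self.measured[col]
        return out


@dataclass
class MixRecipe:
    """Two-endmember label mixing recipe (amount-weighted atom fractions)."""

    F_unlabeled: float
    m_unlabeled: float
    F_labeled: float
    m_labeled: float

    def __post_init__(self):
        for F in (self.F_unlabeled, self.F_labeled):
            if not 0.0 <= F <= 1.0:
                raise ValueError("atom fractions must lie in [0, 1]")
        if self.m_unlabeled < 0 or self.m_labeled < 0:
            raise ValueError("amounts must be >= 0")
        if self.m_unlabeled + self.m_labeled <= 0:
            raise ValueError("total amount must be > 0")


def compute_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Compute per-ROI isotope and elemental ratios from accumulated counts.

    Ratios are formed from ROI-summed counts (never from per-pixel ratio
    averages): r13C = c13/c12, r15N = nc15/nc14, r33S = s33/s32,
    r34S = s34/s32, rC_CN = (c12+c13)/CN and rS_CN = (s32+s33+s34)/CN with
    CN = nc14+nc15.  Rows with any zero denominator are dropped and logged —
    a cell with no CN signal is not a cell measurement.

    Parameters
    ----------
    table
        ROI count table with the seven mass-count columns and the
        (session, region, roi_id) key columns.

    Returns
    -------
    DataFrame indexed by (session, region, roi_id) with the six ratio
    columns; ``attrs["corrected"]`` is False.
    """
    for col in COUNT_COLUMNS:
        if (table[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    t = table.set_index(KEY_COLUMNS) if not isinstance(table.index, pd.MultiIndex) else table
    cn = t["nc14"] + t["nc15"]
    bad = (t["c12"] == 0) | (t["nc14"] == 0) | (t["s32"] == 0) | (cn == 0)
    if bad.any():
        for key in t.index[bad]:
            log.warning("dropping ROI %s: zero denominator counts", (key,))
    t = t[~bad]
    cn = cn[~bad]
    out = pd.DataFrame(
        {
            "r13C": t["c13"] / t["c12"],
            "r15N": t["nc15"] / t["nc14"],
            "r33S": t["s33"] / t["s32"],
            "r34S": t["s34"] / t["s32"],
            "rC_CN": (t["c12"] + t["c13"]) / cn,
            "rS_CN": (t["s32"] + t["s33"] + t["s34"]) / cn,
        },
        index=t.index,
    )
    out.attrs["corrected"] = False
    return out


def fractionation_correct(ratios: pd.DataFrame, std: CalibrationStandard) -> pd.DataFrame:
    """Correct instrumental isotope fractionation against a measured standard.

    Each ratio column named in the standard is multiplied by
    ``true_std / measured_std``; columns without a standard pass through
    unchanged (e.g. 33S/32S when no sulfur standard is available).
    """
    out = ratios.copy()
    for col, f in std.factors().items():
        if col in out.columns:
            out[col] = out[col] * f
    out.attrs["corrected"] = True
    return out


def ratio_from_delta(delta: float, R_ref: float) -> float:
    """Convert per-mil delta notation to an isotope ratio: R = R_ref(1 + δ/1000)."""
    if R_ref <= 0:
        raise ValueError("R_ref must be > 0")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("delta <= -1000 permil implies a nonpositive ratio")
    return R_ref * (1.0 + delta / 1000.0) if delta.ndim else float(R_ref * (1.0 + delta / 1000.0))


def delta_from_ratio(ratio: float, R_ref: float) -> float:
    """Convert an isotope ratio to per-mil delta: δ = 1000·(R/R_ref − 1)."""
    if R_ref <= 0:
        raise ValueError("R_ref must be > 0")
    ratio = np.asarray(ratio, dtype=float)
    out = 1000.0 * (ratio / R_ref - 1.0)
    return out if out.ndim else float(out)


def atom_fraction_from_ratio(R) -> float:
    """Two-isotope atom fraction F = R/(1+R); at.% = 100·F."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("ratio must be >= 0")
    out = R / (1.0 + R)
    return out if out.ndim else float(out)


def ratio_from_atom_fraction(F) -> float:
    """Inverse of :func:`atom_fraction_from_ratio`: R = F/(1−F)."""
    F = np.asarray(F, dtype=float)
    if np.any((F < 0) | (F >= 1)):
        raise ValueError("atom fraction must lie in [0, 1)")
    out = F / (1.0 - F)
    return out if out.ndim else float(out)


def mass_balance_mix(recipe: MixRecipe) -> float:
    """Amount-weighted mean atom fraction of a two-endmember mixture.

    F_final = (F_u·m_u + F_l·m_l) / (m_u + m_l).  Used to plan labeling
    recipes, e.g. diluting a 98 at.% 15N stock to ~10 at.% in an incubation.
    """
    m_final = recipe.m_unlabeled + recipe.m_labeled
    return (recipe.F_unlabeled * recipe.m_unlabeled
            + recipe.F_labeled * recipe.m_labeled) / m_final


def labeled_amount_fraction(F_unlabeled: float, F_labeled: float, F_target: float) -> float:
    """Solve the mixing equation for the labeled amount fraction.

    Returns x such that F_target = (1−x)·F_unlabeled + x·F_labeled.
    """
    if F_labeled == F_unlabeled:
        raise ValueError("endmember atom fractions must differ")
    return (F_target - F_unlabeled) / (F_labeled - F_unlabeled)


RATIO_COLUMNS = list(ALL_RATIOS)
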