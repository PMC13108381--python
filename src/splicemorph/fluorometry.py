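"""Sodium-fluorescein (NaFl) standard curves and tissue tracer quantification.

A linear standard curve fitted to known NaFl concentrations converts plate
readings of homogenized tissue extracts into concentrations; brain-to-blood
ratios of mass-normalized concentrations quantify blood-brain barrier
permeability (a perfectly tight barrier keeps tracer out of the brain, so a
larger ratio means a leakier barrier).

Normalization follows concentration x total extract volume / tissue mass,
with the extract volume configurable per measurement (the dilution series
applied during extraction varies between protocols).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "TissueMeasurement",
    "fit_standard_curve",
    "invert_concentration",
    "normalized_concentration",
    "permeability_ratio",
]


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple  # (min, max) of fitted concentrations


@dataclass
class TissueMeasurement:
    sample_id: str
    tissue: str  # "brain" | "blood" | "liver"
    reading: float
    mass_mg: float
    extract_volume_ul: float = 1200.0  # 500 PBS + 500 TCA + 200 NaOH

    def __post_init__(self) -> None:
        if self.mass_mg <= 0:
            raise ValueError("tissue mass must be positive")
        if not np.isfinite(self.reading):
            raise ValueError("reading must be finite")


def fit_standard_curve(concentrations, readings) -> StandardCurve:
    """Ordinary least-squares line through (concentration, reading) pairs."""
    conc = np.asarray(concentrations, dtype=float)
    reads = np.asarray(readings, dtype=float)
    if conc.size < 2 or np.unique(conc).size < 2:
        raise ValueError("need at least two distinct concentrations")
    fit = stats.linregress(conc, reads)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        conc_range=(float(conc.min()), float(conc.max())),
    )


def invert_concentration(
    curve: StandardCurve, reading: float
) -> tuple[float, bool]:
    """Concentration from a reading; flags extrapolation beyond the fit range."""
    if curve.slope == 0:
        raise ValueError("cannot invert a flat standard curve")
    conc = (reading - curve.intercept) / curve.slope
    lo, hi = curve.conc_range
    return float(conc), bool(conc < lo or conc > hi)


def normalized_concentration(
    sample: TissueMeasurement, curve: StandardCurve
) -> tuple[float, bool]:
    """Mass-normalized tracer content: conc x extract volume / tissue mass."""
    conc, extrapolated = invert_concentration(curve, sample.reading)
    return conc * sample.extract_volume_ul / sample.mass_mg, extrapolated


def permeability_ratio(
    brain: TissueMeasurement,
    blood: TissueMeasurement,
    curve: StandardCurve,
) -> dict:
    """Brain-to-blood NaFl ratio with the per-tissue components reported."""
    brain_norm, brain_flag = normalized_concentration(brain, curve)
    blood_norm, blood_flag = normalized_concentration(blood, curve)
    if blood_norm == 0:
        raise ValueError("blood concentration is zero; ratio undefined")
    return {
        "ratio": brain_norm / blood_norm,
        "brain": brain_norm,
        "blood": blood_norm,
        "extrapolated": brain_flag or blood_flag,
    }
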