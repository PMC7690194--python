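"""NAD+/NADH cycling-assay quantification and FDH activity.

The enzymatic cycling assay reads out pyridine-nucleotide pools as the
rate of absorbance increase at 570 nm (dA570/min); concentrations follow
from a linear calibration against standard solutions (0.01-0.05 mM).  The
calibration keeps its intercept (the assay has a reagent blank) rather
than being forced through the origin.

Formate dehydrogenase (FDH) activity is computed from the NADH formation
rate at 340 nm; one unit is the amount of enzyme forming 1 mmol NADH per
minute under assay conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "AssayResult",
    "fit_calibration",
    "quantify_samples",
    "nad_ratio",
    "fdh_activity",
]

#: NADH molar extinction coefficient at 340 nm, mM^-1 cm^-1
NADH_EXTINCTION_340 = 6.22
#: NADH concentrations below this (mM) make the NAD+/NADH ratio unreliable
NADH_FLOOR_MM = 1e-3
#: quantifications beyond this multiple of the top standard are flagged
EXTRAPOLATION_FACTOR = 1.5


@dataclass
class CalibrationCurve:
    """Least-squares line of assay slope (dA570/min) vs concentration (mM)."""

    slope_per_mM: float
    intercept: float
    r_squared: float
    standards: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class AssayResult:
    analyte: str
    concentration: float  # mM, extract basis
    t: float | None = None
    qc_flags: list[str] = field(default_factory=list)


def fit_calibration(standards) -> CalibrationCurve:
    """Fit the calibration line through (concentration mM, slope) pairs."""
    standards = [(float(c), float(s)) for c, s in standards]
    if len(standards) < 2:
        raise ValueError("need at least 2 standards")
    conc = np.array([c for c, _ in standards])
    slope = np.array([s for _, s in standards])
    if np.allclose(conc, conc[0]):
        raise ValueError("standards must span at least two distinct concentrations")
    res = stats.linregress(conc, slope)
    return CalibrationCurve(
        slope_per_mM=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        standards=standards,
    )


def quantify_samples(
    sample_slopes, curve: CalibrationCurve, analyte: str = "NAD+", times=None
) -> list[AssayResult]:
    """Convert sample slopes to concentrations via the calibration.

    concentration = (slope - intercept) / slope_per_mM.  Negative values
    after blank correction are clipped to zero and flagged; values beyond
    1.5x the top standard are flagged as extrapolated.
    """
    if curve.slope_per_mM <= 0:
        raise ValueError("calibration slope must be positive for a valid assay")
    top = max(c for c, _ in curve.standards) if curve.standards else np.inf
    out: list[AssayResult] = []
    slopes = np.atleast_1d(np.asarray(sample_slopes, dtype=float))
    for i, s in enumerate(slopes):
        conc = (s - curve.intercept) / curve.slope_per_mM
        flags: list[str] = []
        if conc < 0:
            flags.append("negative_clipped")
            conc = 0.0
        if conc > EXTRAPOLATION_FACTOR * top:
            flags.append("extrapolated")
        out.append(
            AssayResult(
                analyte=analyte,
                concentration=float(conc),
                t=None if times is None else float(times[i]),
                qc_flags=flags,
            )
        )
    return out


def nad_ratio(
    nad_series, nadh_series, floor: float = NADH_FLOOR_MM
) -> np.ndarray:
    """Elementwise NAD+/NADH ratio; NADH at/below ``floor`` masked (NaN).

    Scale-covariant in the numerator: scaling NAD+ by k scales the ratio
    by k.
    """
    nad = np.asarray(nad_series, dtype=float)
    nadh = np.asarray(nadh_series, dtype=float)
    if nad.shape != nadh.shape:
        raise ValueError("NAD+ and NADH series must have matched time points")
    masked = ~(nadh > floor)
    ratio = np.where(masked, np.nan, nad / np.where(masked, 1.0, nadh))
    return ratio


def fdh_activity(
    dA340_per_min: float,
    path_cm: float = 1.0,
    extinction_mM_cm: float = NADH_EXTINCTION_340,
    assay_volume_mL: float = 1.0,
    extract_volume_mL: float = 0.2,
    protein_mg_per_mL: float | None = None,
) -> dict:
    """FDH activity from the 340-nm absorbance slope.

    NADH formation rate = dA340/min / (extinction * path) [mM/min] scaled
    by the assay volume, giving mmol NADH per minute = units (U).  Returns
    total units in the cuvette, units per mL extract, and (if protein is
    given) specific activity in U/mg.
    """
    if dA340_per_min < 0:
        raise ValueError("absorbance slope must be >= 0")
    for name, v in (
        ("path_cm", path_cm),
        ("extinction_mM_cm", extinction_mM_cm),
        ("assay_volume_mL", assay_volume_mL),
        ("extract_volume_mL", extract_volume_mL),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    rate_mM_per_min = dA340_per_min / (extinction_mM_cm * path_cm)
    units = rate_mM_per_min * assay_volume_mL / 1000.0  # mmol/min in the cuvette
    u_per_mL = units / extract_volume_mL
    out = {"units": units, "units_per_mL_extract": u_per_mL}
    if protein_mg_per_mL is not None:
        if protein_mg_per_mL <= 0:
            raise ValueError("protein_mg_per_mL must be > 0")
        out["specific_activity_U_per_mg"] = u_per_mL / protein_mg_per_mL
    return out
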