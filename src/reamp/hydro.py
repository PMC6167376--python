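"""Hydrodynamic mass bookkeeping for protein-detergent complexes (PDCs).

Membrane proteins are purified inside detergent micelles, so every
hydrodynamic mass estimate reports the whole protein-detergent complex.
This module implements the arithmetic used to untangle the two:

* the Erickson relation ``M = 4.205 (S · Rs)`` combining a sedimentation
  coefficient (Svedberg) with a Stokes radius (nm) into a mass (kDa);
* SEC calibration against soluble standards (log10 mass linear in Rs);
* the Kunji micelle-series extrapolation, which regresses apparent PDC
  mass against micelle mass across a detergent series and reads the
  protein contribution off the zero-micelle intercept;
* protomer counting from (PDC − micelle) / monomer mass.

The two regressions follow the package's Model/fit()/Results convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ERICKSON_CONSTANT",
    "CYMAL5_MICELLE_KDA",
    "SEC_STANDARDS",
    "HydroMeasurement",
    "SECStandard",
    "MicellePoint",
    "PDCEstimate",
    "erickson_mass",
    "SECCalibration",
    "SECCalibrationResults",
    "MicelleSeries",
    "KunjiResults",
    "kunji_protein_mass",
    "protomer_count",
]

#: Erickson's constant: kDa per (Svedberg · nm).
ERICKSON_CONSTANT = 4.205

#: Literature mass contribution of a Cymal-5 micelle, midpoint of the
#: commonly quoted 20-25 kDa range.
CYMAL5_MICELLE_KDA = 22.5


@dataclass(frozen=True)
class HydroMeasurement:
    s_value: float
    stokes_radius: float
    method: str = "SEC"

    def __post_init__(self):
        if self.s_value < 0 or self.stokes_radius <= 0:
            raise ValueError("s_value must be >= 0 and stokes_radius > 0")


@dataclass(frozen=True)
class SECStandard:
    name: str
    mass: float           # kDa
    stokes_radius: float  # nm
    s_value: float | None = None

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("standard mass must be positive")


#: The four soluble calibration standards used throughout.
SEC_STANDARDS = (
    SECStandard("Ferritin", 440.0, 6.1),
    SECStandard("Aldolase", 158.0, 4.8, 7.3),
    SECStandard("Conalbumin", 75.0, 3.6, 5.1),
    SECStandard("Ovalbumin", 44.0, 3.1, 3.5),
)


@dataclass(frozen=True)
class MicellePoint:
    micelle_mass: float       # kDa
    apparent_pdc_mass: float  # kDa
    detergent: str = ""

    def __post_init__(self):
        if self.micelle_mass <= 0 or self.apparent_pdc_mass <= 0:
            raise ValueError("masses must be positive")


@dataclass(frozen=True)
class PDCEstimate:
    pdc_mass: float
    micelle_mass_range: tuple
    monomer_mass: float
    protomer_count: int


def erickson_mass(s_value, stokes_radius):
    """PDC mass (kDa) from sedimentation coefficient (S) and Stokes radius (nm)."""
    s_value = np.asarray(s_value, dtype=float)
    stokes_radius = np.asarray(stokes_radius, dtype=float)
    if np.any(s_value < 0) or np.any(stokes_radius < 0):
        raise ValueError("s_value and stokes_radius must be non-negative")
    return float(ERICKSON_CONSTANT * s_value * stokes_radius) if s_value.ndim == 0 \
        else ERICKSON_CONSTANT * s_value * stokes_radius


class SECCalibration:
    """Size-exclusion calibration model: log10(mass) linear in Stokes radius.

    Parameters
    ----------
    standards : sequence of SECStandard
        At least three calibration proteins.
    """

    def __init__(self, standards=SEC_STANDARDS):
        standards = list(standards)
        if len(standards) < 3:
            raise ValueError("at least 3 standards are required")
        self.standards = standards

    def fit(self):
        rs = np.array([s.stokes_radius for s in self.standards])
        logm = np.log10([s.mass for s in self.standards])
        if np.ptp(rs) == 0:
            # degenerate input (replicates of one standard): constant fit
            class _Const:
                slope, stderr = 0.0, float("nan")
                intercept, rvalue = float(np.mean(logm)), float("nan")
            res = _Const()
        else:
            res = stats.linregress(rs, logm)
        fitted = res.intercept + res.slope * rs
        return SECCalibrationResults(
            model=self,
            slope=float(res.slope),
            intercept=float(res.intercept),
            rvalue=float(res.rvalue),
            slope_stderr=float(res.stderr),
            residuals_log10=logm - fitted,
        )


@dataclass
class SECCalibrationResults:
    """Fitted SEC calibration line with mass queries."""

    model: SECCalibration
    slope: float
    intercept: float
    rvalue: float
    slope_stderr: float
    residuals_log10: np.ndarray

    def apparent_mass(self, stokes_radius):
        """Apparent mass (kDa) at a Stokes radius (nm)."""
        return float(10.0 ** (self.intercept + self.slope * np.asarray(stokes_radius)))

    def summary(self):
        lines = [
            "SEC calibration: log10(M/kDa) = "
            f"{self.intercept:.4f} + {self.slope:.4f} · Rs/nm   (r = {self.rvalue:.4f})",
            f"{'standard':<12} {'Rs/nm':>6} {'M/kDa':>8} {'fit M/kDa':>10}",
        ]
        for s, r in zip(self.model.standards, self.residuals_log10):
            lines.append(
                f"{s.name:<12} {s.stokes_radius:>6.2f} {s.mass:>8.1f} "
                f"{self.apparent_mass(s.stokes_radius):>10.1f}"
            )
        return "\n".join(lines)


class MicelleSeries:
    """Kunji micelle-series model: apparent PDC mass vs micelle mass.

    Across a homologous detergent series the apparent PDC mass is linear
    in the micelle mass; extrapolating to a zero-mass micelle isolates
    the protein contribution.
    """

    def __init__(self, points):
        points = list(points)
        if len(points) < 2:
            raise ValueError("at least 2 micelle points are required")
        x = np.array([p.micelle_mass for p in points])
        if np.ptp(x) == 0:
            raise ValueError("micelle masses are degenerate (no spread in x)")
        self.points = points

    def fit(self):
        x = np.array([p.micelle_mass for p in self.points])
        y = np.array([p.apparent_pdc_mass for p in self.points])
        res = stats.linregress(x, y)
        return KunjiResults(
            model=self,
            protein_mass=float(res.intercept),
            protein_mass_stderr=float(res.intercept_stderr),
            slope=float(res.slope),
            slope_stderr=float(res.stderr),
            rvalue=float(res.rvalue),
        )


@dataclass
class KunjiResults:
    model: MicelleSeries
    protein_mass: float         # kDa, zero-micelle intercept
    protein_mass_stderr: float
    slope: float
    slope_stderr: float
    rvalue: float

    def summary(self):
        return (
            "Micelle-series extrapolation (Kunji):\n"
            f"  protein contribution = {self.protein_mass:.1f} "
            f"± {self.protein_mass_stderr:.1f} kDa (intercept)\n"
            f"  slope = {self.slope:.3f} ± {self.slope_stderr:.3f} kDa/kDa, "
            f"r = {self.rvalue:.4f}, n = {len(self.model.points)}"
        )


def kunji_protein_mass(points):
    """Protein contribution to the PDC (kDa) and its standard error."""
    fit = MicelleSeries(points).fit()
    return fit.protein_mass, fit.protein_mass_stderr


def protomer_count(pdc_mass, micelle_mass, monomer_mass):
    """Number of protomers in a PDC: round((PDC − micelle) / monomer), >= 1."""
    if min(pdc_mass, micelle_mass, monomer_mass) <= 0:
        raise ValueError("all masses must be positive")
    if pdc_mass <= micelle_mass:
        raise ValueError("pdc_mass must exceed micelle_mass")
    return max(int(round((pdc_mass - micelle_mass) / monomer_mass)), 1)
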