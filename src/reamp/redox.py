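"""Redox potentiometry: one-electron Nernst fits and midpoint-shift analysis.

The fraction of heme reduced at ambient potential Eh follows the Nernst
equation; tracked through an optical signal this gives the sigmoid

    A(Eh) = Abs_min + (Abs_max - Abs_min) / (1 + 10^((Eh - Em) / 59))

with a fixed 59 mV/decade slope for a one-electron couple at 25 C: the
signal sits at Abs_max when the sample is fully reduced (Eh << Em),
at Abs_min when fully oxidized, and at the midpoint when Eh = Em.  The
model fits Em and the two asymptotes; the slope can be freed as a
diagnostic.  Helpers compare midpoints between variants (Em shift) and
between reductive and oxidative sweeps (hysteresis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NERNST_SLOPE_MV",
    "PotentiometrySeries",
    "nernst_signal",
    "NernstModel",
    "NernstFit",
    "em_shift",
    "sweep_hysteresis",
]

#: One-electron Nernst slope at 25 C, mV per decade.
NERNST_SLOPE_MV = 59.0


@dataclass
class PotentiometrySeries:
    """Ambient potential (mV vs SHE) vs absorbance, for one sweep."""

    eh: np.ndarray
    absorbance: np.ndarray
    sweep: str = "reductive"

    def __post_init__(self):
        self.eh = np.asarray(self.eh, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.eh.shape != self.absorbance.shape:
            raise ValueError("eh and absorbance must have the same shape")
        d = np.diff(self.eh)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("eh must be strictly monotone within a sweep")
        if self.sweep not in ("reductive", "oxidative"):
            raise ValueError("sweep must be 'reductive' or 'oxidative'")


def nernst_signal(eh, em, abs_min, abs_max, slope_mv=NERNST_SLOPE_MV):
    """Optical signal of a one-electron couple at ambient potential ``eh`` (mV)."""
    eh = np.asarray(eh, dtype=float)
    frac_reduced = 1.0 / (1.0 + 10.0 ** ((eh - em) / slope_mv))
    return abs_min + (abs_max - abs_min) * frac_reduced


class NernstModel:
    """One-electron Nernst model for a potentiometric sweep.

    Requires at least 6 points spanning at least 120 mV; the transition
    must lie inside the sampled range for the fit to be meaningful.
    """

    def __init__(self, series):
        if len(series.eh) < 6:
            raise ValueError("need at least 6 potentiometry points")
        if np.ptp(series.eh) < 120.0:
            raise ValueError("sweep must span at least 120 mV")
        self.series = series

    def fit(self, fix_slope=True):
        import lmfit

        eh, y = self.series.eh, self.series.absorbance
        span = np.ptp(y)
        if span <= 1e-12 * max(1.0, np.max(np.abs(y))):
            raise ValueError("absorbance is constant: no redox transition to fit")

        def residual(p):
            return nernst_signal(eh, p["em"].value, p["abs_min"].value,
                                 p["abs_max"].value, p["slope_mv"].value) - y

        # midpoint guess: potential at half signal span
        half = y.min() + span / 2.0
        em0 = float(eh[np.argmin(np.abs(y - half))])
        pars = lmfit.Parameters()
        pars.add("em", value=em0)
        pars.add("abs_min", value=float(y.min()))
        pars.add("abs_max", value=float(y.max()))
        pars.add("slope_mv", value=NERNST_SLOPE_MV, vary=not fix_slope, min=1.0)
        out = lmfit.minimize(residual, pars)
        if not out.success:
            raise RuntimeError(f"Nernst fit failed: {out.message}")
        p = out.params
        em = float(p["em"].value)
        if not (eh.min() <= em <= eh.max()):
            raise ValueError(
                f"fitted midpoint {em:.1f} mV lies outside the sampled range "
                f"[{eh.min():.1f}, {eh.max():.1f}] mV"
            )
        return NernstFit(
            model=self,
            em=em,
            abs_min=float(p["abs_min"].value),
            abs_max=float(p["abs_max"].value),
            slope_mv=float(p["slope_mv"].value),
            em_stderr=float(p["em"].stderr) if p["em"].stderr is not None else float("nan"),
            covar=out.covar,
            sweep=self.series.sweep,
        )


@dataclass
class NernstFit:
    model: NernstModel | None
    em: float          # mV vs SHE
    abs_min: float
    abs_max: float
    slope_mv: float
    em_stderr: float
    covar: np.ndarray | None = None
    sweep: str = "reductive"

    def predict(self, eh):
        return nernst_signal(eh, self.em, self.abs_min, self.abs_max, self.slope_mv)

    def plot(self, ax=None):
        """Quick-look plot of the sweep and fitted sigmoid."""
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        if self.model is not None:
            s = self.model.series
            ax.plot(s.eh, s.absorbance, "o", label=f"{s.sweep} sweep")
        grid = np.linspace(self.em - 180.0, self.em + 180.0, 200)
        ax.plot(grid, self.predict(grid), "-",
                label=f"Em = {self.em:.0f} mV")
        ax.set_xlabel("Eh (mV vs SHE)")
        ax.set_ylabel("absorbance (AU)")
        ax.legend()
        return ax

    def summary(self):
        return (
            f"One-electron Nernst fit ({self.sweep} sweep)\n"
            f"  Em = {self.em:.1f} ± {self.em_stderr:.1f} mV vs SHE\n"
            f"  Abs_min = {self.abs_min:.4g}, Abs_max = {self.abs_max:.4g}, "
            f"slope = {self.slope_mv:.1f} mV/decade"
        )


def em_shift(fit_variant, fit_parent):
    """Midpoint shift (variant − parent) in mV, with propagated uncertainty."""
    shift = fit_variant.em - fit_parent.em
    errs = [e for e in (fit_variant.em_stderr, fit_parent.em_stderr)
            if np.isfinite(e)]
    stderr = float(np.sqrt(np.sum(np.square(errs)))) if errs else float("nan")
    return shift, stderr


def sweep_hysteresis(reductive_fit, oxidative_fit, threshold_mv=10.0):
    """Absolute midpoint gap between sweeps and a hysteresis flag."""
    delta = abs(reductive_fit.em - oxidative_fit.em)
    return delta, bool(delta > threshold_mv)
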