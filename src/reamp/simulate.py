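"""Seeded synthetic-data generators for every pipeline input.

Each generator is a deterministic function of its seed and parameters and
returns a :class:`SyntheticDataset` bundling the payload, the ground-truth
parameters it was generated from, and an echo of the configuration, so
the closed loop (generate → analyse → recover truth) is testable end to
end without any external data.

Defaults mirror the study conditions of the design/characterisation
workflow: an 8-sequence alignment of SMR-like 4-TM proteins, heme
titrations into 1.4 uM protein from a 150 uM hemin stock in ~3.5 ul
aliquots, stopped-flow transients in pseudo-first-order ligand excess,
potentiometric sweeps bracketing the midpoint, and a maltoside micelle
series for the Kunji extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .binding import Spectrum, TitrationSeries, SORET_CENTERS, simulate_isotherm
from .design import Alignment, REAMP_PATTERN, ResidueClassScheme
from .redox import PotentiometrySeries, nernst_signal

__all__ = [
    "HYDROPHOBIC_ALPHABET",
    "POLAR_ALPHABET",
    "SyntheticDataset",
    "gen_smr_like_alignment",
    "gen_isotherm",
    "gen_kinetics",
    "gen_potentiometry",
    "gen_micelle_series",
    "gen_spectrum",
]

#: Sampling alphabets for h and p columns.  Both exclude glycine so that
#: the conservation rule alone decides G positions.
HYDROPHOBIC_ALPHABET = "LIVFAM"
POLAR_ALPHABET = "STNQEK"


@dataclass
class SyntheticDataset:
    """A generated payload with its ground truth and provenance."""

    payload: object
    truth: dict
    provenance: dict


def _rng(seed):
    return np.random.default_rng(seed)


def gen_smr_like_alignment(seed, pattern=REAMP_PATTERN, n_sequences=8,
                           scheme=None, loop_length=6, gly_prob=0.9):
    """An alignment of 4-TM membrane proteins realizing a given h/p/G pattern.

    Each of the four TM windows repeats the pattern: hydrophobic columns
    sample from {L,I,V,F,A,M}, polar columns from {S,T,N,Q,E,K}, and G
    columns emit glycine with probability ``gly_prob`` (alanine
    otherwise), topped up so every G column is glycine-conserved at the
    scheme's threshold.  By construction the consensus of every window
    abstracts back to ``pattern``.  Loops and termini are sampled freely
    from the polar alphabet.
    """
    if n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    scheme = scheme or ResidueClassScheme()
    rng = _rng(seed)
    n_tm, tm_len = 4, len(pattern)

    def tm_block():
        cols = []
        for sym in pattern:
            if sym == "h":
                cols.append(rng.choice(list(HYDROPHOBIC_ALPHABET), n_sequences))
            elif sym == "p":
                cols.append(rng.choice(list(POLAR_ALPHABET), n_sequences))
            else:  # G column: mostly glycine, guaranteed conserved
                col = np.where(rng.random(n_sequences) < gly_prob, "G", "A")
                need = math.ceil(scheme.gly_conservation_threshold * n_sequences)
                short = need - int(np.sum(col == "G"))
                if short > 0:
                    col[np.nonzero(col != "G")[0][:short]] = "G"
                cols.append(col)
        return np.array(cols).T  # (n_sequences, tm_len)

    def loop_block():
        return rng.choice(list(POLAR_ALPHABET), (n_sequences, loop_length))

    blocks, tm_windows, col = [], [], 1
    blocks.append(loop_block())
    col += loop_length
    for k in range(n_tm):
        tm_windows.append((col, col + tm_len - 1))
        blocks.append(tm_block())
        col += tm_len
        blocks.append(loop_block())
        col += loop_length

    matrix = np.concatenate(blocks, axis=1)
    sequences = ["".join(row) for row in matrix]
    aln = Alignment(sequences, [f"smr{i + 1:02d}" for i in range(n_sequences)],
                    tm_windows)
    return SyntheticDataset(
        payload=aln,
        truth={"pattern": pattern},
        provenance={"seed": seed, "n_sequences": n_sequences,
                    "loop_length": loop_length, "gly_prob": gly_prob},
    )


def gen_isotherm(seed, kd=2.2, n_sites=0.5, protein_conc=1.4,
                 signal_per_bound=0.08, background_slope=0.0,
                 noise_sd=0.0, n_points=40, stock_um=150.0,
                 aliquot_ml=0.005, volume_ml=1.0, dilution_correction=True):
    """A heme titration series with cumulative-aliquot ligand values.

    Ligand totals follow additions of ``aliquot_ml`` of a ``stock_um``
    hemin stock into ``volume_ml`` of protein; with dilution correction
    the i-th total is ``stock · v_i / (volume + v_i)``.  The defaults
    titrate 1.4 uM protein to ~25 uM total hemin (deep saturation for
    low-micromolar Kd); the background slope defaults to zero, matching
    low-detergent conditions where heme partitioning into empty micelles
    is suppressed.  Gaussian noise of sd ``noise_sd`` (AU) is added to
    the forward-model signal.
    """
    rng = _rng(seed)
    added = aliquot_ml * np.arange(n_points + 1)
    if dilution_correction:
        ligand = stock_um * added / (volume_ml + added)
    else:
        ligand = stock_um * added / volume_ml
    series = simulate_isotherm(kd, n_sites, protein_conc, ligand,
                               signal_per_bound, background_slope)
    if noise_sd > 0:
        series = TitrationSeries(
            protein_conc, ligand,
            series.signal + rng.normal(0.0, noise_sd, ligand.shape),
        )
    return SyntheticDataset(
        payload=series,
        truth={"kd": kd, "n_sites": n_sites, "protein_conc": protein_conc,
               "signal_per_bound": signal_per_bound,
               "background_slope": background_slope},
        provenance={"seed": seed, "noise_sd": noise_sd, "n_points": n_points,
                    "stock_um": stock_um, "aliquot_ml": aliquot_ml,
                    "dilution_correction": dilution_correction},
    )


def gen_kinetics(seed, kon=1.0, koff=1.7, ligand_um=(5.0, 10.0, 20.0, 40.0),
                 amplitude=0.1, noise_sd=0.0, n_times=200):
    """Stopped-flow transients with kobs = kon·[L] + koff.

    Each trace rises as ``amplitude · (1 − exp(−kobs t))``; time grids run
    to 5 relaxation times of the slowest transient.
    """
    rng = _rng(seed)
    traces = []
    k_min = kon * min(ligand_um) + koff
    t_end = 5.0 / k_min
    for ligand in ligand_um:
        kobs = kon * ligand + koff
        t = np.linspace(0.0, t_end, n_times)
        y = amplitude * (1.0 - np.exp(-kobs * t))
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, t.shape)
        traces.append((float(ligand), t, y))
    return SyntheticDataset(
        payload=traces,
        truth={"kon": kon, "koff": koff,
               "kd_kinetic": koff / kon if kon > 0 else float("inf")},
        provenance={"seed": seed, "noise_sd": noise_sd, "n_times": n_times,
                    "ligand_um": tuple(ligand_um), "amplitude": amplitude},
    )


def gen_potentiometry(seed, em=-133.0, abs_min=0.10, abs_max=0.60,
                      eh_grid=None, noise_sd=0.0, sweep="reductive",
                      hysteresis_offset_mv=0.0):
    """A potentiometric sweep around the midpoint.

    The default grid spans em ± 150 mV in 10 mV steps, descending for a
    reductive sweep.  ``hysteresis_offset_mv`` displaces the apparent
    midpoint (used to emulate the slow-equilibration artefact seen on
    oxidative sweeps).
    """
    rng = _rng(seed)
    if eh_grid is None:
        eh_grid = np.arange(em + 150.0, em - 150.0 - 1e-9, -10.0)
    eh = np.asarray(eh_grid, dtype=float)
    if sweep == "oxidative":
        eh = eh[::-1] if eh[0] > eh[-1] else eh
    y = nernst_signal(eh, em + hysteresis_offset_mv, abs_min, abs_max)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, eh.shape)
    return SyntheticDataset(
        payload=PotentiometrySeries(eh, y, sweep),
        truth={"em": em + hysteresis_offset_mv, "abs_min": abs_min,
               "abs_max": abs_max},
        provenance={"seed": seed, "noise_sd": noise_sd, "sweep": sweep,
                    "hysteresis_offset_mv": hysteresis_offset_mv},
    )


def gen_micelle_series(seed, protein_mass=43.0,
                       micelle_masses=(20.0, 25.0, 33.0, 40.0),
                       slope=1.0, noise_sd=0.0):
    """Apparent PDC masses across a detergent micelle series."""
    from .hydro import MicellePoint

    if len(micelle_masses) < 2:
        raise ValueError("need at least 2 micelle masses")
    rng = _rng(seed)
    pts = []
    for m in micelle_masses:
        app = protein_mass + slope * m
        if noise_sd > 0:
            app += rng.normal(0.0, noise_sd)
        pts.append(MicellePoint(float(m), float(app)))
    return SyntheticDataset(
        payload=pts,
        truth={"protein_mass": protein_mass, "slope": slope},
        provenance={"seed": seed, "noise_sd": noise_sd,
                    "micelle_masses": tuple(micelle_masses)},
    )


def gen_spectrum(seed, state="bound_oxidized", amplitude=0.5, width_nm=12.0,
                 noise_sd=0.0, wavelengths=None):
    """A UV/Vis spectrum with a Gaussian Soret band at the state's centre.

    Bound states get small Q-region bumps (530/560 nm), sharper for the
    reduced state.
    """
    if state not in SORET_CENTERS:
        raise ValueError(f"state must be one of {sorted(SORET_CENTERS)}")
    rng = _rng(seed)
    if wavelengths is None:
        wavelengths = np.arange(350.0, 701.0, 1.0)
    wl = np.asarray(wavelengths, dtype=float)

    def gauss(center, amp, sd):
        return amp * np.exp(-0.5 * ((wl - center) / sd) ** 2)

    y = gauss(SORET_CENTERS[state], amplitude, width_nm)
    if state == "bound_oxidized":
        y += gauss(535.0, 0.08 * amplitude, 20.0)
    elif state == "bound_reduced":
        y += gauss(530.0, 0.12 * amplitude, 8.0) + gauss(560.0, 0.12 * amplitude, 8.0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, wl.shape)
    return SyntheticDataset(
        payload=Spectrum(wl, y, state_label=state),
        truth={"state": state, "soret_nm": SORET_CENTERS[state]},
        provenance={"seed": seed, "noise_sd": noise_sd, "amplitude": amplitude,
                    "width_nm": width_nm},
    )
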