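# Methods

This note documents the models and procedures the package implements, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generators do and do not emulate.

## Sequence design

The design procedure turns a family of small four-TM membrane proteins
(SMR-like) into a single minimal-complexity chain in four steps.

**Consensus.** For each annotated TM window of an aligned input, columns
with a gap majority are dropped; a kept column contributes its modal
residue when that residue's frequency among non-gap entries reaches
`consensus_threshold` (default 0.5), otherwise the marker of the modal
residue class (`h` or `p`). The per-column glycine frequency is carried
forward.

**Abstraction.** Each consensus position maps to `h` (hydrophobic) or `p`
(polar) under a binary residue classification; positions whose glycine
frequency reaches `gly_conservation_threshold` (default 0.5) are emitted
as `G` instead, preserving conserved glycines for their role in
helix–helix packing. The hydrophobic class is {A,C,F,I,L,M,V,W,Y}; every
other residue is polar, with glycine handled solely by the conservation
rule. The thresholds quantify "modal" and "relatively conserved"; both
are exposed in the config and 0.5 (simple majority) is the natural
default for each.

**Idealization.** `h → L`, `p → S`, `G → G`. Leucine is the most common
residue in natural TM helices and serine is a small polar residue
compatible with helix packing; the 21-position pattern
`hhhhpGhGhhhhphhGhhhhp` idealizes to `LLLLSGLGLLLLSLLGLLLLS`.

**Assembly.** Four copies of the idealized helix are joined by three
`SSGXXGSS` loops (X = E in loops 1 and 3, K in loop 2), preceded by Met
and followed by a V5 epitope and an affinity tag (default `LE` + His10).
A single tryptophan replaces the residue at chain position 50 as an
optical/immunodetection reporter. Numbering is 1-based at the initiator
Met: H1 = 2–22, L1 = 23–30, H2 = 31–51, L2 = 52–59, H3 = 60–80,
L3 = 81–88, H4 = 89–109, then epitope and tag. Under this convention the
helix-2 pattern-position-5 serine is chain residue 35 and W50 sits at
helix-2 position 20. Published constructs of this design family contain
additional linker residues that shift some residue numbers; the
annotation table (`DesignedProtein.annotation_table()`) is the
authoritative map for this package's constructs, and segment positions
rather than absolute indices are used wherever possible.

**Topology.** The positive-inside score counts K+R on each membrane side
under a side assignment of the extramembrane segments (the free
N-terminal amine is not counted). The designed assignment (termini and
loop 2 inside) gives inside − outside = +3 − 0, predicting N_in/C_in.

**Physical properties.** ε280 = 5500·nW + 1490·nY + 125·n_cystine
(/M/cm); average molecular weight is the residue-mass sum plus one water.
The hydrophobic moment is the length-normalized vector sum of per-residue
hydrophobicities spaced 100° apart (Eisenberg consensus scale by
default). Note that a homopolymer's moment is only approximately zero:
unit vectors at 100° spacing do not close a circle for arbitrary lengths.

## Idealized bundle geometry

The bundle model is an ideal-helix CA trace standing in for a relaxed
molecular-dynamics model, which is out of scope. Helices are ideal
α-helices (rise 1.5 Å/residue, twist 100°/residue, CA radius 2.3 Å)
placed on a 10 Å square lattice with consecutive helices antiparallel
(H1 up, H2 down, H3 up, H4 down), so H1/H3 and H2/H4 are the diagonals.
The membrane is a slab of half-thickness 15.75 Å (the 21-residue helix
span / 2) normal to z. All constants are config-overridable.

**Helix phasing.** Each helix is rotated so that the mean direction of
its small/polar face — the serines *and* the conserved glycines, i.e.
every non-`h` pattern position — points at the bundle axis. Using
serines alone leaves the first serine (pattern position 5) 80° from the
face centre; including the glycines, which belong to the same packing
face, centres the face such that position 5 is interior-facing, matching
the design intent that the polar stripes stay inside.

**His-site selection.** A candidate site must face inward (angle between
its radial CA vector and the direction to the bundle axis ≤ 60°) and be
buried 10 ± 4 Å below the nearer membrane surface — the porphyrin ring
partitions into the membrane, so the ligating residue must sit well
below the headgroups. Bis-His pairs must lie on diagonal helices
("diametrically opposed"), differ in depth by ≤ 4 Å and have a CA–CA
separation of 9–14 Å, a window a bis-His-ligated heme can bridge. Under
the default geometry the helix-2 position-5 serine (chain residue 35)
has a burial depth of 6.75 Å, inside the selection band, and pairs with
helix-4 sites — reproducing the helix-2/helix-4 pairing used
experimentally. The angular cutoff, depth band and bridge window are
design-judgement constants exposed in config.

**Cavity mutations.** Leucines whose CA lies within 7 Å of the projected
heme centroid (CA midpoint for bis pairs; the bundle axis at the site's
depth for mono sites) are listed for L→A "hollowing". The mutation set is
monotone in the cutoff.

## Protein–detergent complex masses

* **Erickson relation** `M = 4.205 (S·Rs)` with S in Svedberg and Rs in
  nm gives the PDC mass in kDa; no buoyancy correction is applied, i.e.
  the detergent complex is compared directly with soluble standards.
* **SEC calibration** regresses log10(mass) on Stokes radius over the
  standards (Ferritin 440 kDa/6.1 nm, Aldolase 158/4.8, Conalbumin
  75/3.6, Ovalbumin 44/3.1) and reads apparent masses off the line.
  Regressing in this direction (mass on radius) is the standard
  calibration form and is required for the apparent mass at 3.5 nm to
  land near the 65 kDa reference value; the inverted regression (radius
  on log-mass, then inverted) lands near 49 kDa and is not used.
* **Micelle-series (Kunji) extrapolation** fits apparent PDC mass
  against micelle mass across a detergent series by ordinary least
  squares; the zero-micelle intercept is the protein contribution, with
  the intercept standard error as its uncertainty.
* **Protomer count** = round((PDC − micelle)/monomer), floor 1. The
  Cymal-5 micelle defaults to 22.5 kDa (midpoint of the quoted 20–25
  kDa range).

## Heme binding

**Equilibrium.** The observed signal is fit to the single-site
ligand-depletion model: with P = n_sites·[protein] and L total ligand,

    bound = ((P + L + Kd) − sqrt((P + L + Kd)² − 4·P·L)) / 2
    signal = signal_per_bound·bound + background_slope·(L − bound)

The quadratic (rather than hyperbolic) form is required because the
protein (1.4 μM) is comparable to the Kd (~2 μM). The background term
models heme partitioning into empty micelles; when a matched control
titration is supplied its signal is interpolated and subtracted
point-wise instead. Stoichiometry is reported both as heme per protomer
(`n_sites`) and as heme:His using the His count per protomer (1 for
mono-His, 2 for bis-His constructs).

*Identifiability.* When Kd exceeds the site concentration, kd and
n_sites lie along a shallow likelihood ridge and a single local search
can collapse n_sites to zero; `IsothermModel.fit` therefore multi-starts
over a 3×3 grid of (kd, n_sites) initial values and keeps the best
χ². Even so, a titration must reach deep saturation (~10×Kd) for both
parameters to be determined from noisy data — the generator's default
titration does exactly this.

**Kinetics.** Each stopped-flow transient (ligand in pseudo-first-order
excess) is fit to a single exponential; the observed rates are regressed
on ligand concentration, kobs = kon·[L] + koff, and Kd(kinetic) =
koff/kon. A negative fitted intercept is clamped to zero and flagged.

**Spectra.** The Soret-band argmax inside 380–450 nm is assigned to the
nearest reference centre — 394 nm free aqueous hemin, 415 nm bound
ferric, 427 nm bound ferrous — within ±6 nm, otherwise unclassified;
flat spectra are unclassified and a resolved secondary maximum is
reported.

**Peroxidase turnover.** Oxidized ABTS (μM) = 10⁶·ΔA420/(36 000·path);
turnovers = oxidized ABTS / hemoprotein concentration. Exactly linear by
construction (Beer–Lambert).

## Redox potentiometry

The one-electron Nernst sigmoid is

    A(Eh) = Abs_min + (Abs_max − Abs_min) / (1 + 10^((Eh − Em)/59))

with the 59 mV/decade slope fixed (one electron, 25 °C); `fit_nernst`
can free it as a diagnostic. The printed source form of this equation,
"Absorbance = Abs_min + (Abs_max/(10^{Em−Eh/59})+1)", is typographically
corrupted (ambiguous parenthesization, inverted sign); the asymptote
definitions (Abs_min/Abs_max as the minimum and maximum observed
signals) force the standard sigmoid implemented here. Fits default to
the reductive sweep; `em_shift` propagates the two Em standard errors in
quadrature, and `sweep_hysteresis` flags reductive/oxidative midpoint
gaps above 10 mV (configurable).

## Synthetic data

All generators are deterministic in (seed, parameters) and attach their
ground truth.

* **Alignment**: 8 sequences, four TM windows each realizing the target
  pattern — h columns sample {L,I,V,F,A,M}, p columns {S,T,N,Q,E,K}
  (both gap- and glycine-free), G columns are glycine with probability
  0.9 and are topped up to guarantee conservation at the threshold, so
  consensus → abstraction recovers the input pattern by construction.
  Loops are sampled freely from the polar alphabet. The generator
  emulates the *abstraction behaviour* of a real SMR alignment, not its
  composition, phylogeny or gap structure.
* **Isotherm**: cumulative aliquots (default 40 × 5 μl of a 150 μM hemin
  stock into 1 ml of 1.4 μM protein, dilution-corrected, reaching
  ~25 μM ≈ 10×Kd) through the forward model plus homoscedastic Gaussian
  noise. The background slope defaults to zero, matching low-detergent
  conditions in which partitioning of heme into empty micelles is
  suppressed.
* **Kinetics**: rising exponentials with kobs = kon·[L] + koff at four
  ligand concentrations in pseudo-first-order excess.
* **Potentiometry**: the Nernst sigmoid over Em ± 150 mV in 10 mV steps
  (descending for reductive sweeps), with an optional midpoint offset to
  emulate oxidative-sweep hysteresis.
* **Micelle series / spectra**: a line plus noise; Gaussian Soret bands
  with small Q-region features for bound states.

Noise is homoscedastic Gaussian throughout; real titrations and sweeps
have drift, heteroscedastic photometric error and correlated baselines
that these generators do not emulate, so parameter-recovery results here
bound estimator behaviour under idealized noise only.

## Problem sizes and numerical choices

Parameter-recovery checks use 100 noisy replicates per condition at a
noise sd of 2% of the noise-free signal span; the acceptance script
averages 50 replicates per fitted quantity. Nonlinear fits use
least-squares (lmfit/MINPACK) with analytic-free Jacobians; linear fits
use closed-form OLS. Ties and degenerate inputs: a gap-majority column
is dropped; an exact positive-charge tie reports "ambiguous" topology;
a zero-spread calibration input degenerates to a constant fit; a
negative kinetic intercept clamps to zero with a flag; PDB coordinates
round-trip at the format's 10⁻³ Å precision.

## Known limitations

* The bundle is an ideal CA trace: no side chains, no packing, no
  porphyrin docking; the His-site rules operate on geometry proxies
  (radial CA vectors), not rotamers.
* The SEC calibration form and the choice of Rs (SEC vs DLS) are
  config-switchable; defaults follow the mass-on-radius form and the SEC
  radius.
* The equilibrium model is single-site; cooperative or multi-site
  binding is not modelled, and peroxidase inactivation kinetics are out
  of scope.
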