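"""Minimal-complexity membrane-protein sequence design.

This module implements the consensus-abstraction design procedure for a
four-transmembrane-helix protein built from a minimal residue alphabet:

1. take a multiple sequence alignment of small 4-TM membrane proteins,
2. derive a per-column consensus for each transmembrane (TM) window,
3. abstract the consensus to a binary hydrophobic/polar (h/p) pattern,
   retaining glycine where it is conserved,
4. idealize the pattern (h -> Leu, p -> Ser, G -> Gly) and
5. assemble a full chain: four copies of the idealized helix joined by
   short flexible loops, with a single reporter tryptophan, an epitope
   and an affinity tag.

Sequence-derived physical properties (composition, average molecular
weight, molar extinction at 280 nm), helical hydrophobic moments and
positive-inside topology scoring live here too.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STANDARD_AA",
    "HYDROPHOBIC_CLASS",
    "EISENBERG_SCALE",
    "REAMP_PATTERN",
    "REAMP_HELIX",
    "V5_EPITOPE",
    "HIS10_TAG",
    "ResidueClassScheme",
    "HPPattern",
    "Alignment",
    "TMConsensus",
    "LoopSpec",
    "ConstructSpec",
    "DesignedProtein",
    "CompositionProperties",
    "TopologyScore",
    "consensus_from_alignment",
    "abstract_pattern",
    "idealize",
    "assemble",
    "default_construct",
    "reamp_loop_sides",
    "positive_inside_score",
    "hydrophobic_moment",
    "composition_properties",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Apolar residues for the binary h/p abstraction.  Gly is deliberately
#: excluded from both classes at the pattern level: it is assigned by the
#: conservation rule and otherwise falls into the polar class.
HYDROPHOBIC_CLASS = frozenset("ACFILMVWY")

#: Eisenberg consensus hydrophobicity, used as the default scale for
#: hydrophobic-moment calculations.
EISENBERG_SCALE = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

#: The 21-position h/p/G pattern shared by the four TM helices.
REAMP_PATTERN = "hhhhpGhGhhhhphhGhhhhp"
#: Its idealization.
REAMP_HELIX = "LLLLSGLGLLLLSLLGLLLLS"
#: V5 antibody epitope appended at the C-terminus for immunodetection.
V5_EPITOPE = "GKPIPNPLLGLDST"
#: Deca-histidine purification tag with an LE cloning scar.
HIS10_TAG = "LE" + "H" * 10

# Average (isotope-weighted) residue masses in Da; peptide MW adds one water.
_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
_WATER_MASS = 18.0153

# Per-chromophore molar extinction coefficients at 280 nm (/M/cm).
_EPS_TRP, _EPS_TYR, _EPS_CYSTINE = 5500, 1490, 125


@dataclass(frozen=True)
class ResidueClassScheme:
    """Binary residue classification plus the consensus thresholds.

    Parameters
    ----------
    class_of : dict
        Map from one-letter code to ``"h"`` or ``"p"``; must cover all 20
        standard residues.
    gly_conservation_threshold : float
        Column glycine frequency at or above which a pattern position is
        emitted as ``G`` rather than its h/p class.
    consensus_threshold : float
        Minimum modal-residue frequency for a column to keep its modal
        residue in the consensus; below it the class marker is emitted.
    """

    class_of: dict = field(
        default_factory=lambda: {
            aa: ("h" if aa in HYDROPHOBIC_CLASS else "p") for aa in STANDARD_AA
        }
    )
    gly_conservation_threshold: float = 0.5
    consensus_threshold: float = 0.5

    def __post_init__(self):
        missing = sorted(set(STANDARD_AA) - set(self.class_of))
        if missing:
            raise ValueError(f"residue classes missing for {missing}")
        bad = {aa: c for aa, c in self.class_of.items() if c not in ("h", "p")}
        if bad:
            raise ValueError(f"classes must be 'h' or 'p', got {bad}")
        for name in ("gly_conservation_threshold", "consensus_threshold"):
            t = getattr(self, name)
            if not (0.0 < t <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {t}")


@dataclass(frozen=True)
class HPPattern:
    """A string over the alphabet {h, p, G}."""

    symbols: str

    def __post_init__(self):
        bad = set(self.symbols) - set("hpG")
        if bad:
            raise ValueError(f"pattern may contain only h, p, G; got {sorted(bad)}")
        if not self.symbols:
            raise ValueError("empty pattern")

    def __len__(self):
        return len(self.symbols)

    def __str__(self):
        return self.symbols


@dataclass
class Alignment:
    """Gapped multiple sequence alignment with annotated TM windows.

    ``tm_windows`` are 1-based inclusive column ranges marking the four
    transmembrane domains, in N-to-C order and non-overlapping.
    """

    sequences: list
    ids: list
    tm_windows: list

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty alignment")
        width = len(self.sequences[0])
        if any(len(s) != width for s in self.sequences):
            raise ValueError("alignment sequences differ in length")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids/sequences length mismatch")
        prev_end = 0
        for start, end in self.tm_windows:
            if not (1 <= start <= end <= width):
                raise ValueError(
                    f"tm_window ({start}, {end}) outside alignment width {width}"
                )
            if start <= prev_end:
                raise ValueError("tm_windows overlap or are out of order")
            prev_end = end

    @property
    def width(self):
        return len(self.sequences[0])


@dataclass(frozen=True)
class TMConsensus:
    """Consensus of one TM window: residues or class markers, plus the
    per-kept-column glycine frequency needed by the abstraction step."""

    symbols: str
    gly_freq: tuple


@dataclass(frozen=True)
class LoopSpec:
    """One flexible inter-helix loop, ``SSGXXGSS`` with X = E or K.

    Glutamate marks periplasmic loops and lysine the cytoplasmic loop,
    following the positive-inside rule.
    """

    x_residue: str
    side: str
    template: str = "SSGXXGSS"

    def __post_init__(self):
        if self.template != "SSGXXGSS":
            raise ValueError("loop template must be SSGXXGSS")
        if self.x_residue not in ("E", "K"):
            raise ValueError("loop X residue must be E or K")
        if self.side not in ("periplasmic", "cytoplasmic"):
            raise ValueError("loop side must be periplasmic or cytoplasmic")

    @property
    def sequence(self):
        return self.template.replace("X", self.x_residue)


@dataclass(frozen=True)
class ConstructSpec:
    """Everything needed to assemble a full-length designed chain."""

    helix_sequence: str = REAMP_HELIX
    loops: tuple = (
        LoopSpec("E", "periplasmic"),
        LoopSpec("K", "cytoplasmic"),
        LoopSpec("E", "periplasmic"),
    )
    trp_position: int | None = 50
    n_terminal: str = "M"
    epitope: str = V5_EPITOPE
    affinity_tag: str = HIS10_TAG

    def __post_init__(self):
        if len(self.loops) != 3:
            raise ValueError("exactly three loops are required")
        if len(self.helix_sequence) != 21:
            raise ValueError("helix sequence must be 21 residues")


@dataclass
class DesignedProtein:
    """Assembled chain with per-residue segment annotation.

    ``segment_map[i]`` names the segment of residue ``i+1`` (1-based
    numbering starts at the first N-terminal residue); ``helix_position[i]``
    is the 1-21 index within its TM helix, or ``None`` outside the helices.
    """

    sequence: str
    segment_map: list
    helix_position: list

    def __post_init__(self):
        n = len(self.sequence)
        if len(self.segment_map) != n or len(self.helix_position) != n:
            raise ValueError("annotation arrays must match sequence length")

    def segment(self, name):
        """Residue string of one named segment (e.g. ``"H2"``, ``"L1"``)."""
        return "".join(
            aa for aa, seg in zip(self.sequence, self.segment_map) if seg == name
        )

    def helices(self):
        return [self.segment(f"H{k}") for k in range(1, 5)]

    def tm_residue_types(self):
        """Set of residue types occurring in the four TM segments."""
        return set("".join(self.helices()))

    def residue_index(self, helix, helix_pos):
        """Chain residue number (1-based) of ``helix_pos`` within helix ``helix``."""
        seg = f"H{helix}"
        for i, (s, hp) in enumerate(zip(self.segment_map, self.helix_position)):
            if s == seg and hp == helix_pos:
                return i + 1
        raise KeyError(f"no residue at helix {helix} position {helix_pos}")

    def annotation_table(self):
        """Per-residue annotation as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "residue_index": np.arange(1, len(self.sequence) + 1),
                "residue": list(self.sequence),
                "segment": self.segment_map,
                "helix_position": [
                    hp if hp is not None else np.nan for hp in self.helix_position
                ],
            }
        )


@dataclass(frozen=True)
class CompositionProperties:
    counts: dict
    mw_average: float
    eps280: float
    n_trp: int
    n_tyr: int
    n_cystine: int


@dataclass(frozen=True)
class TopologyScore:
    orientation: str  # "N_in_C_in", "N_out_C_out" or "ambiguous"
    inside_positive_charge: int
    outside_positive_charge: int

    @property
    def score(self):
        return self.inside_positive_charge - self.outside_positive_charge


# ---------------------------------------------------------------------------
# consensus and abstraction
# ---------------------------------------------------------------------------

def consensus_from_alignment(aln, scheme=None):
    """Per-column consensus of each TM window of an alignment.

    Columns where gaps are in the majority are dropped.  A kept column
    contributes its modal residue when that residue's frequency (among
    non-gap entries) reaches ``scheme.consensus_threshold``; otherwise the
    marker of the modal residue class (``h`` or ``p``) is emitted.

    Returns a list of :class:`TMConsensus`, one per TM window, carrying the
    glycine frequency of each kept column for the abstraction step.
    """
    scheme = scheme or ResidueClassScheme()
    out = []
    for start, end in aln.tm_windows:
        symbols, gly = [], []
        for col in range(start - 1, end):
            residues = [s[col] for s in aln.sequences]
            non_gap = [r for r in residues if r != "-"]
            if len(non_gap) * 2 <= len(residues):
                continue  # gap-majority column
            for r in non_gap:
                if r not in scheme.class_of:
                    raise ValueError(f"unknown residue code {r!r} in column {col + 1}")
            counts = Counter(non_gap)
            modal, n_modal = counts.most_common(1)[0]
            if n_modal / len(non_gap) >= scheme.consensus_threshold:
                symbols.append(modal)
            else:
                # no dominant residue: fall back to the dominant class
                class_counts = Counter(scheme.class_of[r] for r in non_gap)
                symbols.append(class_counts.most_common(1)[0][0])
            gly.append(counts.get("G", 0) / len(non_gap))
        out.append(TMConsensus("".join(symbols), tuple(gly)))
    return out


def abstract_pattern(consensus, scheme=None, gly_freq=None):
    """Abstract a consensus string to an h/p/G pattern.

    ``consensus`` may be a :class:`TMConsensus` (its glycine frequencies are
    used) or a plain string of residues and/or ``h``/``p`` markers.  When
    ``gly_freq`` is not supplied for a plain string, a literal ``G`` is
    treated as fully conserved.  A position is emitted as ``G`` when its
    glycine frequency reaches ``scheme.gly_conservation_threshold``;
    otherwise it is mapped to its residue class.
    """
    scheme = scheme or ResidueClassScheme()
    if isinstance(consensus, TMConsensus):
        gly_freq = consensus.gly_freq
        consensus = consensus.symbols
    if gly_freq is None:
        gly_freq = [1.0 if c == "G" else 0.0 for c in consensus]
    if len(gly_freq) != len(consensus):
        raise ValueError("gly_freq length must match consensus length")

    symbols = []
    for c, gf in zip(consensus, gly_freq):
        if gf >= scheme.gly_conservation_threshold:
            symbols.append("G")
        elif c in ("h", "p"):
            symbols.append(c)
        elif c in scheme.class_of:
            symbols.append(scheme.class_of[c])
        else:
            raise ValueError(f"unknown residue code {c!r}")
    return HPPattern("".join(symbols))


def idealize(pattern):
    """Translate an h/p/G pattern into the minimal sequence (h→L, p→S, G→G)."""
    if isinstance(pattern, str):
        pattern = HPPattern(pattern)
    return pattern.symbols.translate(str.maketrans("hpG", "LSG"))


# ---------------------------------------------------------------------------
# chain assembly
# ---------------------------------------------------------------------------

def assemble(spec=None):
    """Assemble the full designed chain from a :class:`ConstructSpec`.

    Segment order is Nterm, H1, L1, H2, L2, H3, L3, H4, epitope, tag.  The
    reporter tryptophan replaces the residue at ``spec.trp_position``
    (1-based over the whole chain), which must fall inside a TM helix.
    A lysine-bearing loop on the periplasmic side violates the
    positive-inside design intent and triggers a warning.
    """
    spec = spec or ConstructSpec()
    for i, loop in enumerate(spec.loops, start=1):
        if loop.x_residue == "K" and loop.side != "cytoplasmic":
            warnings.warn(
                f"loop {i} carries lysine but is assigned {loop.side}; "
                "the positive-inside rule expects K on the cytoplasmic side",
                stacklevel=2,
            )

    segments = [("Nterm", spec.n_terminal)]
    for k in range(1, 5):
        segments.append((f"H{k}", spec.helix_sequence))
        if k < 4:
            segments.append((f"L{k}", spec.loops[k - 1].sequence))
    if spec.epitope:
        segments.append(("epitope", spec.epitope))
    if spec.affinity_tag:
        segments.append(("tag", spec.affinity_tag))

    seq, seg_map, helix_pos = [], [], []
    for name, s in segments:
        for j, aa in enumerate(s, start=1):
            seq.append(aa)
            seg_map.append(name)
            helix_pos.append(j if name.startswith("H") else None)

    if spec.trp_position is not None:
        idx = spec.trp_position - 1
        if not (0 <= idx < len(seq)) or not seg_map[idx].startswith("H"):
            raise ValueError(
                f"trp_position {spec.trp_position} does not fall inside a TM helix"
            )
        seq[idx] = "W"

    return DesignedProtein("".join(seq), seg_map, helix_pos)


def default_construct(tag="his10"):
    """The default designed protein (V5 epitope, deca-His tag, W50)."""
    tags = {"his10": HIS10_TAG, "none": "", None: ""}
    return assemble(ConstructSpec(affinity_tag=tags[tag]))


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def reamp_loop_sides():
    """The designed side assignment: termini and loop 2 cytoplasmic (in),
    loops 1 and 3 periplasmic (out)."""
    return {"Nterm": "in", "L1": "out", "L2": "in", "L3": "out", "Cterm": "in"}


def positive_inside_score(protein, loop_sides=None):
    """Score a topology by the positive-inside rule.

    ``loop_sides`` assigns each extramembrane segment (``Nterm``, ``L1``,
    ``L2``, ``L3`` and ``Cterm`` = epitope + tag) to ``"in"`` or ``"out"``.
    Lysines and arginines are counted per side (the free N-terminal amine is
    not counted); the predicted orientation is the one placing more positive
    charge inside.  An exact tie is reported as ``"ambiguous"``.
    """
    loop_sides = loop_sides or reamp_loop_sides()
    counts = {"in": 0, "out": 0}
    for aa, seg in zip(protein.sequence, protein.segment_map):
        if seg.startswith("H"):
            continue
        key = "Cterm" if seg in ("epitope", "tag") else seg
        if key not in loop_sides:
            raise ValueError(f"extramembrane segment {key!r} has no side assignment")
        if aa in "KR":
            counts[loop_sides[key]] += 1

    inside, outside = counts["in"], counts["out"]
    if inside == outside:
        orientation = "ambiguous"
    else:
        n_side = loop_sides["Nterm"] if inside > outside else (
            "out" if loop_sides["Nterm"] == "in" else "in"
        )
        orientation = "N_in_C_in" if n_side == "in" else "N_out_C_out"
    return TopologyScore(orientation, inside, outside)


# ---------------------------------------------------------------------------
# physical properties
# ---------------------------------------------------------------------------

def hydrophobic_moment(helix, scale=None, twist_deg=100.0):
    """Helical hydrophobic moment of a sequence.

    The per-residue hydrophobicities are summed as vectors spaced
    ``twist_deg`` apart around the helical wheel; the magnitude is
    normalized by the sequence length (mean-vector convention).

    Returns
    -------
    (magnitude, direction_deg) : tuple of float
        Moment per residue and the azimuth of the resultant in degrees.
    """
    scale = scale or EISENBERG_SCALE
    if len(helix) < 3:
        raise ValueError("helix must have at least 3 residues")
    missing = sorted(set(helix) - set(scale))
    if missing:
        raise ValueError(f"residues missing from hydrophobicity scale: {missing}")
    angles = np.deg2rad(twist_deg) * np.arange(len(helix))
    h = np.array([scale[aa] for aa in helix])
    x, y = np.sum(h * np.cos(angles)), np.sum(h * np.sin(angles))
    return float(np.hypot(x, y) / len(helix)), float(np.rad2deg(np.arctan2(y, x)))


def composition_properties(protein):
    """Residue counts, average MW and molar extinction at 280 nm.

    ``eps280 = 5500·nW + 1490·nY + 125·n_cystine`` (/M/cm), with every
    cysteine conservatively paired into half-cystines.  MW is the average
    peptide mass: sum of residue masses plus one water.
    """
    seq = protein.sequence if isinstance(protein, DesignedProtein) else protein
    if not seq:
        raise ValueError("empty sequence")
    bad = sorted(set(seq) - set(STANDARD_AA))
    if bad:
        raise ValueError(f"nonstandard residues: {bad}")
    counts = dict(Counter(seq))
    mw = sum(_RESIDUE_MASS[aa] * n for aa, n in counts.items()) + _WATER_MASS
    n_trp, n_tyr = counts.get("W", 0), counts.get("Y", 0)
    n_cystine = counts.get("C", 0) // 2
    eps = _EPS_TRP * n_trp + _EPS_TYR * n_tyr + _EPS_CYSTINE * n_cystine
    return CompositionProperties(counts, mw, float(eps), n_trp, n_tyr, n_cystine)
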