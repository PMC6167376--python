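"""Sequence-design rules: consensus, abstraction, assembly, properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reamp.design import (
    Alignment,
    ConstructSpec,
    HPPattern,
    LoopSpec,
    REAMP_HELIX,
    REAMP_PATTERN,
    ResidueClassScheme,
    abstract_pattern,
    assemble,
    composition_properties,
    consensus_from_alignment,
    default_construct,
    hydrophobic_moment,
    idealize,
    positive_inside_score,
    reamp_loop_sides,
)


class TestConsensus:
    def test_unanimous_column_keeps_residue(self):
        aln = Alignment(["L"] * 8, [f"s{i}" for i in range(8)], [(1, 1)])
        (cons,) = consensus_from_alignment(aln)
        assert cons.symbols == "L"

    def test_no_modal_residue_emits_class_marker(self):
        # 8 hydrophobic residues, the mode (L, 3/8) is below the 0.5 cutoff
        col = list("LIVFLALM")
        aln = Alignment(col, [f"s{i}" for i in range(8)], [(1, 1)])
        (cons,) = consensus_from_alignment(aln)
        assert cons.symbols == "h"

    def test_gap_majority_column_dropped(self):
        seqs = ["L-A", "L-A", "L-A", "LGA", "L-A", "LGA", "L-A", "L-A"]
        aln = Alignment(seqs, [f"s{i}" for i in range(8)], [(1, 3)])
        (cons,) = consensus_from_alignment(aln)
        assert cons.symbols == "LA"

    def test_window_outside_width_errors(self):
        with pytest.raises(ValueError):
            Alignment(["LL"], ["a"], [(1, 5)])

    def test_empty_alignment_errors(self):
        with pytest.raises(ValueError):
            Alignment([], [], [(1, 1)])


class TestAbstraction:
    def test_printed_pattern_from_conserved_glycines(self):
        # idealized consensus with G conserved exactly at the G positions
        consensus = REAMP_HELIX
        gly = [1.0 if s == "G" else 0.0 for s in REAMP_PATTERN]
        assert str(abstract_pattern(consensus, gly_freq=gly)) == REAMP_PATTERN

    def test_all_leucine_maps_to_h(self):
        assert str(abstract_pattern("LLLLL")) == "hhhhh"

    def test_mixed_consensus_with_terminal_gly(self):
        assert str(abstract_pattern("LSLSG")) == "hphpG"

    def test_unconserved_gly_falls_to_polar_class(self):
        assert str(abstract_pattern("LGL", gly_freq=[0.0, 0.3, 0.0])) == "hph"

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            abstract_pattern("LBL")


class TestIdealize:
    @pytest.mark.parametrize(
        "pattern, expected",
        [
            (REAMP_PATTERN, REAMP_HELIX),
            ("h", "L"),
            ("pGp", "SGS"),
        ],
    )
    def test_symbolwise_mapping(self, pattern, expected):
        assert idealize(pattern) == expected

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            idealize("hxp")

    @given(st.text(alphabet="hpG", min_size=1, max_size=40))
    @settings(deadline=None)
    def test_design_rules_are_a_fixed_point(self, symbols):
        """idealize(abstract(idealize(p))) == idealize(p) when the G
        positions of p are declared conserved."""
        seq = idealize(symbols)
        gly = [1.0 if c == "G" else 0.0 for c in seq]
        again = idealize(abstract_pattern(seq, gly_freq=gly))
        assert again == seq


class TestAssembly:
    def test_tm_alphabet_is_minimal(self, protein):
        assert protein.tm_residue_types() == {"L", "S", "G", "W"}

    def test_loops_contribute_only_sgek(self, protein):
        loops = "".join(protein.segment(f"L{k}") for k in (1, 2, 3))
        assert set(loops) <= {"S", "G", "E", "K"}

    def test_bare_chain_length_is_109(self):
        spec = ConstructSpec(trp_position=None, epitope="", affinity_tag="")
        assert len(assemble(spec).sequence) == 1 + 4 * 21 + 3 * 8

    def test_trp50_lands_in_helix2(self, protein):
        assert protein.sequence[49] == "W"
        assert protein.segment_map[49] == "H2"
        # numbering convention: H2 spans residues 31-51, so W50 is helix
        # position 20 and S35 is the helix-2 pattern-position-5 serine
        assert protein.helix_position[49] == 20
        assert protein.sequence[34] == "S"
        assert protein.residue_index(2, 5) == 35

    def test_trp_outside_helix_rejected(self):
        with pytest.raises(ValueError):
            assemble(ConstructSpec(trp_position=25))  # loop 1

    def test_periplasmic_lysine_loop_warns(self):
        loops = (
            LoopSpec("K", "periplasmic"),
            LoopSpec("K", "cytoplasmic"),
            LoopSpec("E", "periplasmic"),
        )
        with pytest.warns(UserWarning, match="positive-inside"):
            assemble(ConstructSpec(loops=loops))

    def test_segment_concatenation_reproduces_sequence(self, protein):
        order = ["Nterm", "H1", "L1", "H2", "L2", "H3", "L3", "H4",
                 "epitope", "tag"]
        assert "".join(protein.segment(s) for s in order) == protein.sequence


class TestTopology:
    def test_designed_construct_is_n_in_c_in(self, protein):
        score = positive_inside_score(protein)
        assert score.orientation == "N_in_C_in"
        assert score.inside_positive_charge > score.outside_positive_charge

    def test_no_basic_residues_is_ambiguous(self):
        spec = ConstructSpec(
            loops=(
                LoopSpec("E", "periplasmic"),
                LoopSpec("E", "cytoplasmic"),
                LoopSpec("E", "periplasmic"),
            ),
            epitope="",
            affinity_tag="",
        )
        assert positive_inside_score(assemble(spec)).orientation == "ambiguous"

    def test_side_flip_mirrors_the_score(self, protein):
        sides = reamp_loop_sides()
        flipped = {k: ("out" if v == "in" else "in") for k, v in sides.items()}
        a = positive_inside_score(protein, sides)
        b = positive_inside_score(protein, flipped)
        assert a.score == -b.score
        assert a.orientation == b.orientation == "N_in_C_in"

    def test_unassigned_segment_errors(self, protein):
        with pytest.raises(ValueError, match="L2"):
            positive_inside_score(protein, {"Nterm": "in", "L1": "out"})


def _moment_oracle(seq, scale, twist=100.0):
    vx = vy = 0.0
    for i, aa in enumerate(seq):
        ang = np.deg2rad(twist * i)
        vx += scale[aa] * np.cos(ang)
        vy += scale[aa] * np.sin(ang)
    return float(np.hypot(vx, vy) / len(seq))


class TestHydrophobicMoment:
    TWO_VALUED = {"L": 1.0, "S": -1.0, "G": -1.0}

    def test_homopolymer_below_uniform_bound(self):
        # identical terms cancel only approximately over the wheel: the
        # exact value is the uniform-scale partial sum, computed here
        bound = _moment_oracle("LLLLL", {"L": 1.0})
        mag, _ = hydrophobic_moment("LLLLL", {"L": 1.0})
        assert mag == pytest.approx(bound, abs=1e-12)
        assert mag < 1.0  # well below the aligned maximum

    def test_idealized_helix_matches_vector_sum_oracle(self):
        mag, _ = hydrophobic_moment(REAMP_HELIX, self.TWO_VALUED)
        assert mag == pytest.approx(_moment_oracle(REAMP_HELIX, self.TWO_VALUED),
                                    abs=1e-12)
        assert mag > 0.1  # the serine face makes the helix amphipathic

    def test_alternating_sequence_matches_oracle(self):
        seq = "LSLSLSLSLS"
        mag, _ = hydrophobic_moment(seq, self.TWO_VALUED)
        assert mag == pytest.approx(_moment_oracle(seq, self.TWO_VALUED), abs=1e-12)

    @given(st.text(alphabet="LSGW", min_size=3, max_size=21))
    @settings(deadline=None)
    def test_agrees_with_bruteforce_on_random_sequences(self, seq):
        scale = {"L": 1.06, "S": -0.18, "G": 0.48, "W": 0.81}
        mag, _ = hydrophobic_moment(seq, scale)
        assert mag == pytest.approx(_moment_oracle(seq, scale), abs=1e-9)

    def test_missing_scale_entry_errors(self):
        with pytest.raises(ValueError, match="W"):
            hydrophobic_moment("LLW", {"L": 1.0})


class TestComposition:
    def test_designed_construct_has_single_trp_chromophore(self, protein):
        props = composition_properties(protein)
        assert (props.n_trp, props.n_tyr, props.n_cystine) == (1, 0, 0)
        assert props.eps280 == 5500.0

    def test_glycine_dipeptide_mass(self):
        assert composition_properties("GG").mw_average == pytest.approx(132.12, abs=0.01)

    def test_no_chromophores_gives_zero_eps(self):
        assert composition_properties("GASL").eps280 == 0.0

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            composition_properties("GAX")

    def test_counts_sum_to_length(self, protein):
        props = composition_properties(protein)
        assert sum(props.counts.values()) == len(protein.sequence)


class TestSchemeValidation:
    def test_incomplete_class_map_rejected(self):
        with pytest.raises(ValueError):
            ResidueClassScheme(class_of={"L": "h"})

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            ResidueClassScheme(consensus_threshold=0.0)

    def test_pattern_alphabet_enforced(self):
        with pytest.raises(ValueError):
            HPPattern("hpx")
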