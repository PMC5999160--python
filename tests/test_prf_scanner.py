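import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barnaslip.genome_io import Genome, Interval
from barnaslip.orf_annotator import OrfRecord, annotate
from barnaslip.prf_scanner import (
    MotifConfig,
    PrematureStopError,
    SlipperyMatch,
    StructureElement,
    StructureParams,
    assemble_signal,
    dot_bracket,
    find_structures,
    heptamer_matches_grammar,
    scan_prf,
    scan_slippery,
    translate_fusion,
)
from barnaslip.synthetic_data import GenomeConfig, generate_genome

# --------------------------------------------------------------------------
# slippery grammar
# --------------------------------------------------------------------------


def independent_grammar_check(h: str) -> bool:
    """Re-derivation of the X_XXY_YYZ rule, written separately on purpose."""
    if len(h) != 7 or set(h) - set("ACGU"):
        return False
    ok_yyy = h[3:6] in ("AAA", "UUU")
    ok_z = h[6] != "G"
    ok_xxx = h[0] == h[1] == h[2] or h[0:3] in ("GGU", "GAU")
    return ok_yyy and ok_z and ok_xxx


@pytest.mark.parametrize(
    "heptamer,expected",
    [
        ("GGUUUUU", True),   # the MBV/RsBV1 site, nudged register
        ("GAUUUUU", True),   # the CqABV1 variant (G_RUU_UUU consensus)
        ("AAAUUUC", True),   # homopolymer XXX
        ("UUUAAAA", True),
        ("GGUUUUG", False),  # Z = G is disallowed
        ("AAAAAAG", False),
        ("GCUUUUU", False),  # XXX neither homopolymer nor known exception
        ("GGUCUUU", False),  # YYY not AAA/UUU
        ("GGUNUUU", False),  # N never matches
    ],
)
def test_slippery_grammar(heptamer, expected):
    assert heptamer_matches_grammar(heptamer) is expected


@settings(derandomize=True, max_examples=300)
@given(st.text(alphabet="ACGUN", min_size=7, max_size=7))
def test_grammar_agrees_with_independent_checker(h):
    assert heptamer_matches_grammar(h) == independent_grammar_check(h)


def test_scan_reports_only_frame_anchored_registers():
    """A heptamer is found only where its codon boundaries match the frame."""
    g = Genome(id="t", seq="AAAGGUUUUUCAAA")
    hits = {
        fa: [m.position for m in scan_slippery(g, fa, Interval(1, len(g.seq)))]
        for fa in range(3)
    }
    assert hits == {0: [], 1: [4], 2: []}
    (m,) = scan_slippery(g, 1, Interval(1, len(g.seq)))
    assert (m.xxx, m.yyy, m.z) == ("GGU", "UUU", "U")


def test_scan_respects_configured_exception_set():
    g = Genome(id="t", seq="AAAGAUUUUUCAA")
    no_exceptions = MotifConfig(xxx_exceptions=frozenset())
    assert scan_slippery(g, 1, Interval(1, 13), no_exceptions) == []
    assert len(scan_slippery(g, 1, Interval(1, 13))) == 1


# --------------------------------------------------------------------------
# structures
# --------------------------------------------------------------------------

PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def test_perfect_palindrome_gives_four_bp_hairpin():
    g = Genome(id="t", seq="GGGGAAAACCCC")
    structures = find_structures(g, Interval(1, 12))
    assert structures
    top = structures[0]
    assert top.kind == "stem_loop"
    assert top.total_bp == 4
    assert top.loop_lengths == (4,)


def test_all_a_window_has_no_structure():
    g = Genome(id="t", seq="A" * 60)
    assert find_structures(g, Interval(1, 60)) == []


def best_single_helix_oracle(w: str, min_loop: int = 3, allow_gu: bool = True) -> int:
    """Nussinov-style maximum over single contiguous helices (independent).

    A helix closing (i, j) with L stacked pairs needs j - i + 1 - 2L >=
    min_loop; longer greedy runs are trimmed to respect the hairpin loop.
    """
    pairs = PAIRS if allow_gu else {p for p in PAIRS if p not in {("G", "U"), ("U", "G")}}
    best = 0
    n = len(w)
    for i in range(n):
        for j in range(i + 1, n):
            L = 0
            while i + L < j - L and (w[i + L], w[j - L]) in pairs:
                L += 1
            best = max(best, min(L, (j - i + 1 - min_loop) // 2))
    return best


@pytest.mark.parametrize("seed", range(8))
def test_every_reported_pair_is_in_pairing_table(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGU"), size=60))
    g = Genome(id="r", seq=seq)
    for allow_gu in (True, False):
        params = StructureParams(allow_gu=allow_gu, min_stem=3)
        allowed = (
            PAIRS if allow_gu
            else {p for p in PAIRS if p not in {("G", "U"), ("U", "G")}}
        )
        for s in find_structures(g, Interval(1, 60), params):
            for five, three in s.stems:
                for k in range(len(five)):
                    a = seq[five.start - 1 + k]
                    b = seq[three.end - 1 - k]
                    assert (a, b) in allowed, (s.kind, a, b)


@pytest.mark.parametrize("seed", range(8))
def test_max_hairpin_pairs_match_single_helix_oracle(seed):
    """The best unbulged hairpin equals the exhaustive single-helix maximum."""
    rng = np.random.default_rng(100 + seed)
    seq = "".join(rng.choice(list("ACGU"), size=60))
    g = Genome(id="r", seq=seq)
    params = StructureParams(min_stem=3, min_loop=3, max_loop=54,
                             max_structures=2000)
    found = [
        s.total_bp
        for s in find_structures(g, Interval(1, 60), params)
        if s.kind == "stem_loop" and not s.bulges
    ]
    oracle = best_single_helix_oracle(seq)
    if oracle >= 3:
        assert found and max(found) == oracle
    else:
        assert not found


def test_planted_pseudoknot_is_found_with_crossing_topology(bundle, arch):
    truth = bundle.signal.structure
    window = Interval(truth.start - 3, truth.start + 45)
    structures = find_structures(bundle.genome, window)
    pks = [s for s in structures if s.kind == "pseudoknot"]
    assert pks
    top = pks[0]
    (a5, a3), (b5, b3) = top.stems
    # H-type crossing: stem2's 5' arm inside stem1's loop, 3' arm beyond
    assert a5.end < b5.start <= b5.end < a3.start <= a3.end < b3.start


# --------------------------------------------------------------------------
# signal assembly
# --------------------------------------------------------------------------

SLIP = SlipperyMatch(position=94, heptamer="GGUUUUU", xxx="GGU", yyy="UUU",
                     z="U", frame_anchor=0)


def _stem_loop(start, stems, bulges=(), loops=(4,)):
    return StructureElement(kind="stem_loop", stems=stems,
                            loop_lengths=loops, bulges=bulges, start=start)


def test_spacer_five_is_valid():
    se = _stem_loop(106, ((Interval(106, 111), Interval(116, 121)),))
    sig = assemble_signal(SLIP, [se])
    assert sig.valid and sig.spacer == 5 and sig.effective_spacer is None


def test_bulge_rescues_short_spacer():
    """Raw spacer 3 with a mid-stem bulge whose distal part starts 8 nt out."""
    se = _stem_loop(
        104,
        ((Interval(104, 106), Interval(120, 122)),
         (Interval(108, 112), Interval(114, 118))),
        bulges=(107,),
        loops=(1,),
    )
    sig = assemble_signal(SLIP, [se])
    assert sig.valid
    assert sig.spacer == 3
    assert sig.effective_spacer == 7


def test_structure_outside_spacer_range_is_rejected():
    se = _stem_loop(116, ((Interval(116, 121), Interval(126, 131)),))
    assert assemble_signal(SLIP, [se]) is None


def test_spacer_range_boundaries():
    for start, ok in ((105, False), (106, True), (110, True), (111, False)):
        se = _stem_loop(start, ((Interval(start, start + 5),
                                 Interval(start + 10, start + 15)),))
        sig = assemble_signal(SLIP, [se])
        assert (sig is not None) is ok, start


# --------------------------------------------------------------------------
# fusion
# --------------------------------------------------------------------------


def _toy_parts(seq: str):
    """Fixed toy geometry for a 32-nt construct.

    zero frame (ORF2, 1..27): AUG AAA CAG GUU UUU ...
    slippery heptamer G_GUU_UUU at 9..15 (the G at 9 is codon-final).
    -1 frame (ORF3, 6..26): resumes at the Z nucleotide, position 15.
    """
    from barnaslip.prf_scanner import FrameshiftSignal

    g = Genome(id="toy", seq=seq)
    orf2 = OrfRecord("ORF2", Interval(1, 27), "AUG_to_stop", 9)
    orf3 = OrfRecord("ORF3", Interval(6, 26), "stop_bracketed", 7)
    m = SlipperyMatch(position=9, heptamer="GGUUUUU", xxx="GGU", yyy="UUU",
                      z="U", frame_anchor=0)
    sig = FrameshiftSignal(slippery=m, structure=None, spacer=5,
                           effective_spacer=None, valid=True)
    return g, orf2, orf3, sig


def test_toy_fusion_is_hand_traceable():
    # zero frame through YYZ: AUG AAA CAG GUU UUU -> M K Q V F
    # -1 frame from 15:       UAU GCA UUG CCC     -> Y A L P (stop at 27..29)
    g, orf2, orf3, sig = _toy_parts("AUGAAACAGGUUUUUAUGCAUUGCCCUAGUAA")
    fusion = translate_fusion(g, orf2, sig, orf3)
    assert fusion.aa_seq == "MKQVFYALP"
    assert fusion.junction_index == 5
    assert fusion.length == 9
    assert fusion.p2_length == 9


def test_fusion_length_invariant_to_bookkeeping_convention():
    g, orf2, orf3, sig = _toy_parts("AUGAAACAGGUUUUUAUGCAUUGCCCUAGUAA")
    a = translate_fusion(g, orf2, sig, orf3, "decode_then_slip")
    b = translate_fusion(g, orf2, sig, orf3, "slip_then_decode")
    assert a.length == b.length == 9
    assert a.junction_index == b.junction_index + 1


def test_fusion_premature_stop_names_position():
    # -1 frame reads UCA UAG ...: stop at position 18, before ORF3's end
    g, orf2, orf3, sig = _toy_parts("AUGAAACAGGUUUUUCAUAGCCCUAGUAACCC")
    with pytest.raises(PrematureStopError, match="18"):
        translate_fusion(g, orf2, sig, orf3)


def test_synthetic_truth_fusion_lengths(bundle, arch):
    orf2, orf3 = arch.get("ORF2"), arch.get("ORF3")
    signals = scan_prf(bundle.genome, orf2, orf3)
    (primary,) = [s for s in signals if s.primary]
    for convention in ("decode_then_slip", "slip_then_decode"):
        fusion = translate_fusion(bundle.genome, orf2, primary, orf3, convention)
        assert fusion.length == bundle.fusion_length == 1076
        assert fusion.p2_length == 700


def test_dot_bracket_uses_square_brackets_for_pseudoknot(bundle):
    s = bundle.signal.structure
    region = Interval(s.start, max(arm.end for stem in s.stems for arm in stem))
    db = dot_bracket(s, region)
    assert db.count("(") == db.count(")") == 6
    assert db.count("[") == db.count("]") == 5


def test_planted_hairpin_agrees_with_thermodynamic_folder():
    """RNAfold's MFE structure for the planted hairpin is the same 6-bp stem.

    An independent cross-check of the pairing geometry only; the package's
    finder is combinatorial, not thermodynamic.
    """
    import shutil
    import subprocess

    if shutil.which("RNAfold") is None:
        pytest.skip("RNAfold not on PATH")
    hairpin = "GGCAGCAAAAGCUGCC"
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=hairpin + "\n",
        capture_output=True, text=True, check=True,
    ).stdout.splitlines()
    mfe_db = out[1].split()[0]
    assert mfe_db == "((((((....))))))"
    g = Genome(id="h", seq=hairpin)
    (top, *_) = find_structures(g, Interval(1, len(hairpin)))
    ours = dot_bracket(top, Interval(1, len(hairpin)))
    assert ours == mfe_db
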