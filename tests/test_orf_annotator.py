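import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barnaslip.genome_io import Genome, Interval
from barnaslip.orf_annotator import (
    NoCandidateOrf2Error,
    OrfRecord,
    annotate,
    assign_layout,
    enumerate_orfs,
    overlap_region,
    upstream_inframe_stop,
)

STOPS = {"UAA", "UAG", "UGA"}


def brute_force_orfs(seq: str, min_aa: int, rule: str):
    """Independent oracle: test every position as a codon start in each frame.

    An AUG_to_stop ORF starts at an AUG whose in-frame upstream context back
    to the previous stop holds no earlier AUG; a stop_bracketed ORF starts
    right after a stop (or at the frame's first position).
    """
    out = set()
    n = len(seq)
    for i in range(n - 2):
        codon = seq[i : i + 3]
        if rule == "AUG_to_stop":
            if codon != "AUG":
                continue
            j = i - 3
            first = True
            while j >= 0:
                c = seq[j : j + 3]
                if c in STOPS:
                    break
                if c == "AUG":
                    first = False
                    break
                j -= 3
            if not first:
                continue
        else:
            if i >= 3 and seq[i - 3 : i] not in STOPS:
                continue
            if i < 3 and i != i % 3:  # not the frame's first codon position
                continue
        # walk forward to the stop (or last complete codon)
        j = i
        while j + 3 <= n and seq[j : j + 3] not in STOPS:
            j += 3
        length = (j - i) // 3
        if length >= min_aa:
            out.add((i + 1, j, rule))
    return out


@pytest.mark.parametrize("rule", ["AUG_to_stop", "stop_bracketed"])
@pytest.mark.parametrize("seed", range(10))
def test_enumeration_equals_exhaustive_oracle(rule, seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGU"), size=600))
    g = Genome(id="r", seq=seq)
    got = {
        (o.interval.start, o.interval.end, o.rule)
        for o in enumerate_orfs(g, min_aa=5, rule=rule)
    }
    assert got == brute_force_orfs(seq, 5, rule)


@settings(derandomize=True, max_examples=60)
@given(st.text(alphabet="ACGU", min_size=30, max_size=300), st.integers(1, 10))
def test_enumeration_oracle_property(seq, min_aa):
    g = Genome(id="h", seq=seq)
    for rule in ("AUG_to_stop", "stop_bracketed"):
        got = {
            (o.interval.start, o.interval.end, o.rule)
            for o in enumerate_orfs(g, min_aa=min_aa, rule=rule)
        }
        assert got == brute_force_orfs(seq, min_aa, rule)


def test_hand_traced_toy_orf():
    g = Genome(id="t", seq="AAAUGAAAUAA")
    (orf,) = enumerate_orfs(g, min_aa=1)
    assert (orf.interval.start, orf.interval.end) == (3, 8)
    assert orf.protein_length == 2
    # the codon after the interval is the stop, which is excluded
    assert g.subseq(9, 11) == "UAA"


def test_min_aa_larger_than_genome_gives_empty():
    g = Genome(id="t", seq="AUGAAAUAA")
    assert enumerate_orfs(g, min_aa=100) == []


def test_orf_truncated_by_3prime_end_is_flagged_incomplete():
    g = Genome(id="t", seq="AUGAAACCCGG")  # no stop before the end
    (orf,) = enumerate_orfs(g, min_aa=1)
    assert orf.incomplete_3prime
    assert orf.interval.end == 9  # last complete codon


def test_layout_recovers_planted_truth(bundle, arch):
    for name, truth_orf in bundle.orfs.items():
        got = arch.get(name)
        assert got is not None, name
        assert got.interval == truth_orf.interval
        assert got.protein_length == truth_orf.protein_length
    assert arch.relative_frames["ORF3"] == 2  # -1 frame
    assert arch.relative_frames["ORF1"] == 2
    assert arch.get("ORF4").interval.start > arch.get("ORF3").interval.end


def test_single_orf_genome_assigns_only_orf2():
    # the GUA-GCU-AGU body keeps both shifted registers stop-rich, so no
    # stop-bracketed run long enough for ORF3 exists in the -1 frame
    g = Genome(id="t", seq="CCC" + "AUG" + "GUAGCUAGU" * 20 + "UAA" + "CCC")
    layout = annotate(g, min_aa=10)
    assert layout.get("ORF2") is not None
    assert layout.get("ORF1") is None and layout.get("ORF3") is None
    assert set(layout.unassigned_reasons) == {"ORF1", "ORF3", "ORF4"}


def test_no_aug_orf_raises_named_error():
    g = Genome(id="t", seq="CCCGGGCCCGGG" * 10)
    with pytest.raises(NoCandidateOrf2Error, match="no candidate ORF2"):
        annotate(g, min_aa=5)


def test_overlap_region_from_printed_coordinates():
    """The ORF2/ORF3 overlap between stop codons: 1704..2133 spans 430 nt."""
    a = OrfRecord("ORF3", Interval(1704, 2135), "stop_bracketed", 144)
    b = OrfRecord("ORF2", Interval(1000, 2133), "AUG_to_stop", 378)
    ov = overlap_region(a, b)
    assert (ov.start, ov.end, len(ov)) == (1704, 2133, 430)


def test_overlap_region_disjoint_is_none():
    a = OrfRecord("a", Interval(1, 30), "AUG_to_stop", 10)
    b = OrfRecord("b", Interval(34, 63), "AUG_to_stop", 10)
    assert overlap_region(a, b) is None


@settings(derandomize=True, max_examples=100)
@given(st.integers(1, 300), st.integers(0, 99), st.integers(1, 300), st.integers(0, 99))
def test_overlap_matches_position_set_intersection(s1, l1, s2, l2):
    a = OrfRecord("a", Interval(s1 * 3 + 1, s1 * 3 + 3 * (l1 + 1)), "AUG_to_stop", l1 + 1)
    b = OrfRecord("b", Interval(s2 * 3 + 1, s2 * 3 + 3 * (l2 + 1)), "AUG_to_stop", l2 + 1)
    got = overlap_region(a, b)
    expected = set(range(a.interval.start, a.interval.end + 1)) & set(
        range(b.interval.start, b.interval.end + 1)
    )
    if got is None:
        assert expected == set()
    else:
        assert set(range(got.start, got.end + 1)) == expected


def test_upstream_inframe_stop_two_codons_away():
    g = Genome(id="t", seq="UAACCCCCCAUGAAAUAG")
    orf = [o for o in enumerate_orfs(g, min_aa=1) if o.interval.start == 10][0]
    assert upstream_inframe_stop(g, orf) == 2


def test_upstream_inframe_stop_absent_is_none():
    g = Genome(id="t", seq="CCCCCCAUGAAAUAG")
    orf = [o for o in enumerate_orfs(g, min_aa=1) if o.interval.start == 7][0]
    assert upstream_inframe_stop(g, orf) is None


def test_default_genome_has_stop_three_codons_before_orf2(bundle, arch):
    assert upstream_inframe_stop(bundle.genome, arch.get("ORF2")) == 3
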