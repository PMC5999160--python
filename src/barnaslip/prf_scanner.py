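"""-1 programmed ribosomal frameshift (PRF) signal detection.

A -1 PRF signal is a slippery heptamer ``X_XXY_YYZ`` (underscores mark
zero-frame codon boundaries: the first X is the final nucleotide of the
preceding codon) followed, after a short spacer, by a stimulatory RNA
structure (a stem-loop or an H-type pseudoknot).  Grammar: YYY is AAA or
UUU, Z is anything but G, and XXX is a homopolymer or one of a small set of
documented exceptions (the barnavirus sites are G_GUU_UUU and G_AUU_UUU,
i.e. consensus G_RUU_UUU).  The canonical spacer is 5-9 nt; a stem-loop
whose proximal base pairs start closer than that can still qualify when a
single-nt bulge splits the stem and the distal portion falls in range
(the "effective spacer").

Tandem slippage joins the zero-frame ORF2 product to the -1-frame ORF3,
yielding the P2+3 fusion polyprotein deduced by :func:`translate_fusion`.
"""

from __future__ import annotations

import dataclasses
import functools
from typing import Literal, Optional, Sequence

from .genome_io import ContractViolation, Genome, Interval, translate
from .orf_annotator import OrfRecord

# --------------------------------------------------------------------------
# slippery heptamer grammar
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MotifConfig:
    """Grammar knobs for the slippery-site scan."""

    xxx_exceptions: frozenset[str] = frozenset({"GGU", "GAU"})
    allow_homopolymer_xxx: bool = True


@dataclasses.dataclass(frozen=True)
class SlipperyMatch:
    """A slippery heptamer XXXYYYZ in the "nudged" register.

    ``position`` is the 1-based coordinate of the first X, which is the last
    nucleotide of a zero-frame codon; the codons XXY and YYZ follow.
    """

    position: int
    heptamer: str
    xxx: str
    yyy: str
    z: str
    frame_anchor: int

    @property
    def end(self) -> int:
        return self.position + 6


def heptamer_matches_grammar(h: str, config: MotifConfig = MotifConfig()) -> bool:
    """Pure grammar check on a 7-nt heptamer (frame not considered)."""
    if len(h) != 7 or "N" in h:
        return False
    xxx, yyy, z = h[:3], h[3:6], h[6]
    if yyy not in ("AAA", "UUU"):
        return False
    if z == "G":
        return False
    if len(set(xxx)) == 1 and config.allow_homopolymer_xxx:
        return True
    return xxx in config.xxx_exceptions


def scan_slippery(
    genome: Genome,
    frame_anchor: int,
    region: Interval,
    config: MotifConfig = MotifConfig(),
) -> list[SlipperyMatch]:
    """All grammar-satisfying heptamers in ``region`` anchored to a frame.

    ``frame_anchor`` is the frame of the zero-frame (ORF2) codons; a heptamer
    is only reported where its internal codon boundaries X_XXY_YYZ coincide
    with that frame, i.e. its first nucleotide is codon-final.
    """
    if region.end > len(genome):
        raise ContractViolation("scan region outside genome")
    seq = genome.seq
    out = []
    # codon-final 0-based offsets satisfy i % 3 == (frame_anchor + 2) % 3
    want = (frame_anchor + 2) % 3
    for i in range(region.start - 1, region.end - 6):
        if i % 3 != want:
            continue
        h = seq[i : i + 7]
        if heptamer_matches_grammar(h, config):
            out.append(
                SlipperyMatch(
                    position=i + 1,
                    heptamer=h,
                    xxx=h[:3],
                    yyy=h[3:6],
                    z=h[6],
                    frame_anchor=frame_anchor,
                )
            )
    return out


# --------------------------------------------------------------------------
# downstream structure search
# --------------------------------------------------------------------------

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


@dataclasses.dataclass(frozen=True)
class StructureParams:
    min_stem: int = 4
    min_loop: int = 3
    max_loop: int = 12
    max_spacer: int = 9
    max_span: int = 60
    allow_gu: bool = True
    # H-type pseudoknot loop caps (loop1: between stem1 5' arm and stem2 5'
    # arm; loop2: between stem2 5' arm and stem1 3' arm; loop3: between
    # stem1 3' arm and stem2 3' arm)
    pk_loop1_max: int = 10
    pk_loop2_max: int = 15
    pk_loop3_max: int = 10
    max_structures: int = 50


@dataclasses.dataclass(frozen=True)
class StructureElement:
    """A stem-loop or H-type pseudoknot; all coordinates 1-based genomic."""

    kind: Literal["stem_loop", "pseudoknot"]
    stems: tuple[tuple[Interval, Interval], ...]
    loop_lengths: tuple[int, ...]
    bulges: tuple[int, ...]
    start: int  # first paired nucleotide

    @property
    def total_bp(self) -> int:
        return sum(len(five) for five, _ in self.stems)


def _pair_ok(a: str, b: str, allow_gu: bool) -> bool:
    if (a, b) in WC_PAIRS:
        return True
    return allow_gu and (a, b) in WOBBLE_PAIRS


@functools.lru_cache(maxsize=4096)
def _find_structures_cached(
    window_seq: str, window_start: int, params: StructureParams
) -> tuple[StructureElement, ...]:
    w = window_seq
    n = len(w)
    gu = params.allow_gu

    def helix_len(i: int, j: int) -> int:
        L = 0
        while i + L < j - L and _pair_ok(w[i + L], w[j - L], gu):
            L += 1
        return L

    # maximal plain helices: outermost pair (i, j) not extendable outward
    helices: list[tuple[int, int, int]] = []
    for i in range(n):
        for j in range(i + 2 * params.min_stem, n):
            if not _pair_ok(w[i], w[j], gu):
                continue
            if i > 0 and j < n - 1 and _pair_ok(w[i - 1], w[j + 1], gu):
                continue  # not maximal
            L = helix_len(i, j)
            if L >= params.min_stem:
                helices.append((i, j, L))

    found: list[StructureElement] = []

    def g(pos0: int) -> int:  # window offset -> genomic 1-based
        return window_start + pos0

    # --- stem-loops (single helix, optional single-nt bulge) ---
    for i, j, L in helices:
        # shrink the helix if its greedy extension pinches the loop below
        # the minimum hairpin loop size
        L_eff = min(L, (j - i + 1 - params.min_loop) // 2)
        loop = j - i + 1 - 2 * L_eff
        if L_eff >= params.min_stem and loop <= params.max_loop:
            found.append(
                StructureElement(
                    kind="stem_loop",
                    stems=(
                        (Interval(g(i), g(i + L_eff - 1)),
                         Interval(g(j - L_eff + 1), g(j))),
                    ),
                    loop_lengths=(loop,),
                    bulges=(),
                    start=g(i),
                )
            )
        # try a single-nt bulge after a partial proximal helix
        for l1 in range(1, L + 1):
            for strand in ("five", "three"):
                if strand == "five":
                    i2, j2 = i + l1 + 1, j - l1
                    bulge0 = i + l1
                else:
                    i2, j2 = i + l1, j - l1 - 1
                    bulge0 = j - l1
                if i2 >= j2:
                    continue
                l2 = helix_len(i2, j2)
                if l2 < 1 or l1 + l2 < params.min_stem:
                    continue
                loop2 = (j2 - l2) - (i2 + l2) + 1
                if not params.min_loop <= loop2 <= params.max_loop:
                    continue
                found.append(
                    StructureElement(
                        kind="stem_loop",
                        stems=(
                            (Interval(g(i), g(i + l1 - 1)),
                             Interval(g(j - l1 + 1), g(j))),
                            (Interval(g(i2), g(i2 + l2 - 1)),
                             Interval(g(j2 - l2 + 1), g(j2))),
                        ),
                        loop_lengths=(loop2,),
                        bulges=(g(bulge0),),
                        start=g(i),
                    )
                )

    # --- H-type pseudoknots: two crossing helices ---
    for i1, j1, L1 in helices:
        a_end, a3_start = i1 + L1 - 1, j1 - L1 + 1
        for i2, j2, L2 in helices:
            b_start, b_end = i2, i2 + L2 - 1
            b3_start = j2 - L2 + 1
            if not (a_end < b_start and b_end < a3_start and j1 < b3_start):
                continue
            loop1 = b_start - a_end - 1
            loop2 = a3_start - b_end - 1
            loop3 = b3_start - j1 - 1
            if (
                loop1 > params.pk_loop1_max
                or loop2 > params.pk_loop2_max
                or loop3 > params.pk_loop3_max
            ):
                continue
            found.append(
                StructureElement(
                    kind="pseudoknot",
                    stems=(
                        (Interval(g(i1), g(a_end)), Interval(g(a3_start), g(j1))),
                        (Interval(g(b_start), g(b_end)),
                         Interval(g(b3_start), g(j2))),
                    ),
                    loop_lengths=(loop1, loop2, loop3),
                    bulges=(),
                    start=g(i1),
                )
            )

    found.sort(key=lambda s: (-s.total_bp, s.start, s.kind))
    return tuple(found[: params.max_structures])


def find_structures(
    genome: Genome, window: Interval, params: StructureParams = StructureParams()
) -> list[StructureElement]:
    """Enumerate stem-loops and H-type pseudoknots inside ``window``.

    Ranked by total base pairs, then 5'-most start. Pairing is Watson-Crick
    plus (toggleable) GU wobble; N never pairs.
    """
    if window.end > len(genome):
        raise ContractViolation("structure window outside genome")
    seq = genome.subseq(window.start, window.end)
    return list(_find_structures_cached(seq, window.start, params))


# --------------------------------------------------------------------------
# signal assembly
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FrameshiftSignal:
    slippery: SlipperyMatch
    structure: Optional[StructureElement]
    spacer: Optional[int]
    effective_spacer: Optional[int]
    valid: bool
    primary: bool = False


def assemble_signal(
    slippery: SlipperyMatch,
    structures: Sequence[StructureElement],
    spacer_range: tuple[int, int] = (5, 9),
) -> Optional[FrameshiftSignal]:
    """Best downstream structure whose (effective) spacer is in range.

    The raw spacer is the nucleotide count between the heptamer's last
    nucleotide and the structure's first paired nucleotide. For a bulged
    stem-loop whose raw spacer is short, the distal helix portion (starting
    just past the bulge) is used instead.
    """
    lo, hi = spacer_range
    for structure in structures:
        if structure.start <= slippery.end:
            continue
        raw = structure.start - slippery.end - 1
        if lo <= raw <= hi:
            return FrameshiftSignal(
                slippery=slippery,
                structure=structure,
                spacer=raw,
                effective_spacer=None,
                valid=True,
            )
        if structure.kind == "stem_loop" and structure.bulges:
            bulge = structure.bulges[0]
            # distal portion only helps when the bulge sits on the 5' arm
            if bulge == structure.stems[0][0].end + 1:
                eff = bulge - slippery.end  # distal start = bulge + 1
                if lo <= eff <= hi:
                    return FrameshiftSignal(
                        slippery=slippery,
                        structure=structure,
                        spacer=raw,
                        effective_spacer=eff,
                        valid=True,
                    )
    return None


def scan_prf(
    genome: Genome,
    orf2: OrfRecord,
    orf3: OrfRecord,
    motif_config: MotifConfig = MotifConfig(),
    structure_params: StructureParams = StructureParams(),
    spacer_range: tuple[int, int] = (5, 9),
) -> list[FrameshiftSignal]:
    """Full PRF scan of the ORF2/ORF3 overlap.

    Every grammar-satisfying heptamer is reported (invalid ones with no
    qualifying structure included, ``valid=False``); among valid signals the
    one with the smallest spacer is marked primary.
    """
    overlap = orf2.interval.intersection(orf3.interval)
    if overlap is None:
        return []
    matches = scan_slippery(genome, orf2.frame, overlap, motif_config)
    signals: list[FrameshiftSignal] = []
    for m in matches:
        win_start = m.end + 1
        win_end = min(
            len(genome), m.end + structure_params.max_spacer + structure_params.max_span
        )
        structures: Sequence[StructureElement] = ()
        if win_start < win_end:
            structures = find_structures(
                genome, Interval(win_start, win_end), structure_params
            )
        sig = assemble_signal(m, structures, spacer_range)
        if sig is None:
            sig = FrameshiftSignal(
                slippery=m, structure=None, spacer=None,
                effective_spacer=None, valid=False,
            )
        signals.append(sig)
    valid = [s for s in signals if s.valid]
    if valid:
        best = min(
            valid,
            key=lambda s: (
                s.effective_spacer if s.effective_spacer is not None else s.spacer,
                s.slippery.position,
            ),
        )
        signals = [
            dataclasses.replace(s, primary=(s is best)) for s in signals
        ]
    return signals


# --------------------------------------------------------------------------
# fusion polyprotein
# --------------------------------------------------------------------------

Convention = Literal["decode_then_slip", "slip_then_decode"]


class PrematureStopError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class FusionProduct:
    """The trans-frame P2+3 polyprotein."""

    aa_seq: str
    length: int
    junction_index: int  # aa position of the last zero-frame-derived residue
    p2_length: int
    convention: Convention


def translate_fusion(
    genome: Genome,
    orf2: OrfRecord,
    signal: FrameshiftSignal,
    orf3: OrfRecord,
    convention: Convention = "decode_then_slip",
) -> FusionProduct:
    """Deduce the fusion polyprotein produced by -1 slippage at ``signal``.

    ``decode_then_slip`` books the YYZ codon to the zero frame and resumes
    -1-frame decoding at the Z nucleotide; ``slip_then_decode`` shifts after
    XXY so YYY is read in the -1 frame. The two conventions change the
    junction residue, never the total length.
    """
    overlap = orf2.interval.intersection(orf3.interval)
    if overlap is None:
        raise ContractViolation("ORF2 and ORF3 do not overlap")
    m = signal.slippery
    if not (overlap.contains(m.position) and overlap.contains(m.end)):
        raise ContractViolation(
            f"slippery heptamer at {m.position} lies outside the ORF2/ORF3 "
            f"overlap {overlap.start}..{overlap.end}"
        )
    if (orf3.frame - orf2.frame) % 3 != 2:
        raise ContractViolation("ORF3 is not in the -1 frame relative to ORF2")
    seq = genome.seq
    s2 = orf2.interval.start
    if convention == "decode_then_slip":
        zero_end = m.end  # through the YYZ codon
        minus_from = m.end  # Z re-read as first -1-frame nucleotide
    else:
        zero_end = m.end - 3  # through the XXY codon
        minus_from = m.end - 3
    zero_aa = translate(seq[s2 - 1 : zero_end])
    minus_aa = translate(seq[minus_from - 1 : orf3.interval.end])
    if "*" in minus_aa:
        stop_idx = minus_aa.index("*")
        stop_pos = minus_from + 3 * stop_idx
        raise PrematureStopError(
            f"premature stop codon in the -1 frame at position {stop_pos}, "
            f"before ORF3's stop"
        )
    aa_seq = zero_aa + minus_aa
    return FusionProduct(
        aa_seq=aa_seq,
        length=len(aa_seq),
        junction_index=len(zero_aa),
        p2_length=orf2.protein_length,
        convention=convention,
    )


# --------------------------------------------------------------------------
# reporting helpers
# --------------------------------------------------------------------------


def dot_bracket(structure: StructureElement, region: Interval) -> str:
    """Dot-bracket rendering over ``region``; stem 2 of a pseudoknot uses []."""
    marks = ["."] * len(region)
    brackets = [("(", ")"), ("[", "]")]
    for stem_idx, (five, three) in enumerate(structure.stems):
        ob, cb = brackets[min(stem_idx, 1)] if structure.kind == "pseudoknot" else brackets[0]
        for pos in range(five.start, five.end + 1):
            marks[pos - region.start] = ob
        for pos in range(three.start, three.end + 1):
            marks[pos - region.start] = cb
    return "".join(marks)
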