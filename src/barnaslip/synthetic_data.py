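"""Synthetic barnavirus-like genomes with machine-readable ground truth.

The default configuration emulates the canonical barnavirus genome plan on
a 4206-nt positive-sense RNA: ORF1 nested in the -1 frame within ORF2's 5'
region, a long AUG-defined ORF2 (700 aa) with an in-frame stop three codons
upstream of its AUG, a stop-bracketed ORF3 overlapping ORF2's 3' region by
430 nt in the -1 frame, a planted slippery heptamer (G_AUU_UUU by default)
with a compact H-type pseudoknot 5 nt downstream inside that overlap (P2+3
fusion of 1076 aa), a non-overlapping downstream ORF4, and five 21-aa
hydrophobic blocks in P2's N-terminal region with none in P1.

Construction is codon-wise so that every planted reading frame is sense by
construction; the non-feature "flank" codons inside ORF2 alternate AUA with
G/A-started charged codons, which leaves the +1-shifted register densely
populated with stop codons.  That density is what lets the misassembly
detector localise single-nucleotide indels: a correction at the wrong place
leaves a frame-shifted window that almost immediately hits a stop.  A final
validation pass re-checks every constraint with independent string scans
and redraws the random filler if a chance feature (a competing long ORF, a
spurious slippery heptamer) slipped in.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .genome_io import CODON_TABLE, Genome, Interval
from .orf_annotator import OrfRecord
from .prf_scanner import (
    FrameshiftSignal,
    SlipperyMatch,
    StructureElement,
    heptamer_matches_grammar,
)
from .read_walker import Read, ReadSet

_STOPS = ("UAA", "UAG", "UGA")
_SENSE = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
_ZRANK = {"C": 0, "G": 1, "A": 2, "U": 3}
# deterministic completion preference: C/G-ending codons first (they cannot
# seed a stop or an AUG at the -1 register inside ORF2)
_COMPLETION_ORDER = sorted(_SENSE, key=lambda c: (_ZRANK[c[2]], c))

# C-ending hydrophobic codons (V/L/I/F): no dinucleotide of theirs can be
# completed into an AUG by a single-base edit that reads back into an intact
# planted frame, and their -1-register products stay hydrophilic enough
_TM_CODONS = ("GUC", "CUC", "AUC", "UUC")
# sprinkled polar residues (S/T), as in real TM helices; breaks tandem
# repetitiveness so reads cannot anchor at the wrong phase of a block
_TM_POLAR = ("AGC", "ACC")
# ORF1-span filler alternates the two sets below. The AUA codons seed stops
# (UAA/UAG) in the +1-shifted register, which is what localises 1-nt indel
# corrections; every combination keeps ORF1's -1 frame stop- and AUG-free,
# no window of the alternation can cross the TM hydropathy threshold, and no
# single-base edit of any combination can seed an AUG that reads back into
# an intact planted frame.
_ORF1_EVEN = ("AUA", "CAA", "CGA", "ACA")  # I/Q/R/T
_ORF1_ODD = ("AAC", "ACC", "GAC", "GGC")  # N/T/D/G
# ORF2/ORF3 overlap filler: C/G-ending sense codons; the -1 frame can then
# never read a stop, and no slippery heptamer (YYY = AAA/UUU needs an A/U at
# a codon-final position) can arise by chance
_CG_ENDING = tuple(c for c in _SENSE if c[2] in "CG")
# non-positive Kyte-Doolittle residues, so chance filler can never assemble
# an extra hydrophobic window N-terminal to the protease-region boundary
_HYDROPHILIC = tuple(
    c for c, aa in CODON_TABLE.items() if aa not in "*IVLFCMA"
)
_AC_CODONS = ("AAC", "ACA", "ACC", "CAA", "CAC", "CCA")  # pair-free filler

_STRUCTURES = {
    # stem1-5' GGCAGC, loop1 AA, stem2-5' GGGAG, loop2 ACA,
    # stem1-3' GCUGCC, loop3 AAAA, stem2-3' CUCCC
    "pseudoknot": "GGCAGCAAGGGAGACAGCUGCCAAAACUCCC",
    # 6-bp stem, 4-nt loop
    "hairpin": "GGCAGCAAAAGCUGCC",
    # 3-bp proximal stem, 1-nt bulge, 5-bp distal stem, 4-nt loop
    "hairpin_bulged": "GGCAGCAGCAAAAGCUGCGCC",
}


class ConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class GenomeConfig:
    """Layout parameters; the defaults are the study conditions.

    Coordinates are 1-based. ``slippery_pos`` is the heptamer's first
    nucleotide and must be codon-final in ORF2's frame; ``overlap_nt`` is
    the ORF2/ORF3 overlap between stop codons and must be 1 mod 3 for ORF3
    to sit in the -1 frame.
    """

    total_length: int = 4206
    orf1_start: int = 15
    # ORF1 sized so its stop codon (read in ORF2's frame as two Asn codons)
    # falls between P2's TM blocks rather than inside one
    p1_aa: int = 170
    orf2_start: int = 34
    p2_aa: int = 700
    overlap_nt: int = 430
    fusion_aa: int = 1076
    slippery: str = "GAUUUUU"
    slippery_pos: int = 1800
    spacer: int = 5
    structure: str = "pseudoknot"
    orf4_aa: int = 180
    tm_blocks: tuple[tuple[int, int], ...] = (
        (20, 40), (60, 80), (100, 120), (140, 160), (180, 200),
    )
    tm_boundary_aa: int = 290
    decoys: bool = False

    # ---- derived coordinates -------------------------------------------
    @property
    def orf2_end(self) -> int:
        return self.orf2_start + 3 * self.p2_aa - 1

    @property
    def orf1_end(self) -> int:
        return self.orf1_start + 3 * self.p1_aa - 1

    @property
    def orf3_first(self) -> int:
        return self.orf2_end - self.overlap_nt + 1

    @property
    def zero_frame_codons(self) -> int:
        """ORF2 codons decoded through the YYZ codon at the shift site."""
        return (self.slippery_pos + 6 - self.orf2_start + 1) // 3

    @property
    def orf3_end(self) -> int:
        return self.slippery_pos + 5 + 3 * (self.fusion_aa - self.zero_frame_codons)

    @property
    def orf4_start(self) -> int:
        return self.orf3_end + 10

    @property
    def orf4_end(self) -> int:
        return self.orf4_start + 3 * self.orf4_aa - 1

    @property
    def structure_start(self) -> int:
        return self.slippery_pos + 6 + self.spacer + 1

    @property
    def decoy_pos(self) -> int:
        return self.slippery_pos + 150

    @classmethod
    def small(cls) -> "GenomeConfig":
        """A ~1.2-kb scaled-down layout for fast exercises."""
        return cls(
            total_length=1150,
            p1_aa=60,
            p2_aa=200,
            overlap_nt=130,
            fusion_aa=280,
            slippery_pos=540,
            orf4_aa=60,
            tm_blocks=((20, 40), (60, 80)),
            tm_boundary_aa=100,
        )

    def validate(self) -> None:
        c = self
        f2 = (c.orf2_start - 1) % 3
        if (c.orf1_start - 1) % 3 != (f2 + 2) % 3:
            raise ConfigError("ORF1 start is not in the -1 frame relative to ORF2")
        if (c.orf2_start - c.orf1_start) % 3 != 1:
            raise ConfigError("ORF1/ORF2 start spacing breaks codon bookkeeping")
        if c.orf1_start < 4:
            raise ConfigError("no room for ORF1's 5' bracketing stop")
        if c.orf1_start + 5 >= c.orf2_start - 12:
            raise ConfigError("ORF1 start too close to ORF2's upstream stop")
        if c.overlap_nt % 3 != 1:
            raise ConfigError("overlap_nt must be 1 mod 3 for a -1-frame ORF3")
        if c.overlap_nt >= 3 * c.p2_aa:
            raise ConfigError("overlap longer than ORF2")
        if c.orf1_end + 3 >= c.orf3_first - 3:
            raise ConfigError("ORF1 runs into the ORF2/ORF3 overlap")
        if len(c.slippery) != 7 or not heptamer_matches_grammar(c.slippery):
            raise ConfigError(f"slippery {c.slippery!r} violates the X_XXY_YYZ grammar")
        if (c.slippery_pos - c.orf2_start) % 3 != 2:
            raise ConfigError("slippery_pos is not codon-final in ORF2's frame")
        if not c.orf3_first <= c.slippery_pos <= c.orf2_end - 6:
            raise ConfigError("slippery heptamer outside the ORF2/ORF3 overlap")
        for codon in (c.slippery[1:4], c.slippery[4:7]):
            if CODON_TABLE.get(codon) in (None, "*"):
                raise ConfigError("slippery heptamer contains a zero-frame stop")
        if c.structure not in _STRUCTURES:
            raise ConfigError(f"unknown structure kind {c.structure!r}")
        if not 3 <= c.spacer <= 9:
            raise ConfigError("spacer must be 3..9")
        struct_end = c.structure_start + len(_STRUCTURES[c.structure]) - 1
        if struct_end > c.orf2_end:
            raise ConfigError("planted structure overruns ORF2")
        if c.fusion_aa <= c.zero_frame_codons:
            raise ConfigError("fusion_aa shorter than its zero-frame part")
        if c.orf3_end <= c.orf2_end:
            raise ConfigError("ORF3 ends inside ORF2; enlarge fusion_aa")
        if c.orf4_end + 3 >= c.total_length:
            raise ConfigError("ORF4 does not fit in total_length")
        for lo, hi in c.tm_blocks:
            if not 2 <= lo < hi <= c.p2_aa:
                raise ConfigError(f"TM block {lo}..{hi} outside P2")
            if hi >= c.tm_boundary_aa:
                raise ConfigError("TM block crosses the protease-region boundary")
        if c.decoys:
            if (c.decoy_pos - c.orf2_start) % 3 != 2:
                raise ConfigError("decoy position not codon-final")
            if c.decoy_pos + 80 > c.orf2_end:
                raise ConfigError("no room for the decoy heptamer + pair-free window")


@dataclasses.dataclass
class TruthBundle:
    """A generated genome plus every planted feature, for oracle use."""

    genome: Genome
    original: Genome  # pre-lesion sequence
    orfs: dict[str, OrfRecord]
    signal: FrameshiftSignal
    fusion_length: int
    junction_index: int
    tm_blocks: dict[str, tuple[tuple[int, int], ...]]
    tm_boundary_aa: int
    indel: Optional[tuple[str, int, str]]  # (kind, after_position, base)
    truncations: tuple[int, int]
    seed: int
    config: GenomeConfig
    decoy_positions: tuple[int, ...] = ()


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------


class _Canvas:
    def __init__(self, length: int):
        self.arr: list[Optional[str]] = [None] * length

    def put(self, pos1: int, s: str) -> None:
        for k, ch in enumerate(s):
            i = pos1 - 1 + k
            cur = self.arr[i]
            if cur is not None and cur != ch:
                raise ConfigError(
                    f"planted features collide at position {i + 1} "
                    f"({cur!r} vs {ch!r})"
                )
            self.arr[i] = ch

    def complete_codon(self, start1: int) -> None:
        """Deterministically fill a partially fixed codon with a sense codon."""
        i = start1 - 1
        fixed = self.arr[i : i + 3]
        if all(f is not None for f in fixed):
            codon = "".join(fixed)
            if CODON_TABLE.get(codon, "*") == "*":
                raise ConfigError(
                    f"planted features force a stop codon at {start1}"
                )
            return
        for cand in _COMPLETION_ORDER:
            if all(f is None or f == c for f, c in zip(fixed, cand)):
                self.put(start1, cand)
                return
        raise ConfigError(f"no sense codon completes position {start1}")


def _build(config: GenomeConfig, rng: np.random.Generator) -> str:
    c = config
    canvas = _Canvas(c.total_length)
    put = canvas.put

    # hard-planted features
    put(c.orf1_start - 3, "UAA")            # ORF1 5' bracketing stop
    put(c.orf1_start, "AUG")
    put(c.orf2_start - 12, "UAG")           # in-frame stop 3 codons before ORF2
    put(c.orf2_start - 9, "CCUCCUCCU")
    put(c.orf2_start, "AUG")
    put(c.orf2_end + 1, "UGA")
    put(c.orf1_end + 1, "UAA")              # ORF1 stop (inside ORF2, -1 frame)
    put(c.orf3_first - 3, "UAA")            # ORF3 5' bracketing stop
    put(c.slippery_pos, c.slippery)
    put(c.slippery_pos + 7, ("CACCACACA" * 2)[: c.spacer])
    put(c.structure_start, _STRUCTURES[c.structure])
    put(c.orf3_end + 1, "UAA")
    put(c.orf3_end + 4, "CCACCA")
    put(c.orf4_start, "AUG")
    put(c.orf4_end + 1, "UAG")
    if c.decoys:
        # grammar-valid heptamer followed by a pairing-free A/C window, so
        # no stimulatory structure can validate it
        put(c.decoy_pos - 2, "CCA")
        put(c.decoy_pos, "AAAAAAC")
        ac_start = c.decoy_pos + 7
        n_ac = (min(c.decoy_pos + 82, c.orf2_end - 2) - ac_start) // 3
        for m in range(n_ac):
            put(ac_start + 3 * m, _AC_CODONS[rng.integers(0, len(_AC_CODONS))])

    in_block = set()
    polar_slots = set()
    for lo, hi in c.tm_blocks:
        in_block.update(range(lo, hi + 1))
        # polar residues at fixed, well-separated offsets: enough to break
        # tandem repetitiveness, never enough to clip the hydropathy run
        for off in (5, 13):
            if lo + off < hi:
                polar_slots.add(lo + off)

    # ORF2 codons (zero frame); three filler regimes: the indel-fragile
    # alternation across ORF1's span, unconstrained sense codons in the
    # ORF2-only middle, C/G-ending codons across the ORF2/ORF3 overlap
    orf1_last_codon = (c.orf1_end + 3 - c.orf2_start) // 3 + 1
    overlap_first_codon = (c.orf3_first - 3 - c.orf2_start) // 3 + 1
    for k in range(2, c.p2_aa + 1):
        s = c.orf2_start + 3 * (k - 1)
        seg = canvas.arr[s - 1 : s + 2]
        if all(x is not None for x in seg):
            continue
        if any(x is not None for x in seg):
            canvas.complete_codon(s)
        elif k in in_block:
            if k in polar_slots:
                put(s, _TM_POLAR[rng.integers(0, len(_TM_POLAR))])
            else:
                put(s, _TM_CODONS[rng.integers(0, len(_TM_CODONS))])
        elif k <= orf1_last_codon:
            if k % 2 == 0:
                put(s, _ORF1_EVEN[rng.integers(0, len(_ORF1_EVEN))])
            else:
                put(s, _ORF1_ODD[rng.integers(0, len(_ORF1_ODD))])
        elif k >= overlap_first_codon:
            put(s, _CG_ENDING[rng.integers(0, len(_CG_ENDING))])
        elif k <= c.tm_boundary_aa + 19:
            put(s, _HYDROPHILIC[rng.integers(0, len(_HYDROPHILIC))])
        else:
            put(s, _SENSE[rng.integers(0, len(_SENSE))])

    # ORF1 codons 5' of ORF2 (the rest of ORF1 is induced by ORF2's fill)
    s = c.orf1_start + 3
    while s + 2 < c.orf2_start + 2:
        canvas.complete_codon(s)
        s += 3

    # ORF3-only codons (-1 frame) past ORF2's stop
    s = c.orf3_first
    while s + 2 <= c.orf3_end:
        seg = canvas.arr[s - 1 : s + 2]
        if all(x is not None for x in seg):
            s += 3
            continue
        if any(x is not None for x in seg):
            canvas.complete_codon(s)
        else:
            put(s, _SENSE[rng.integers(0, len(_SENSE))])
        s += 3

    # ORF4 codons
    for m in range(1, c.orf4_aa):
        s = c.orf4_start + 3 * m
        if any(x is not None for x in canvas.arr[s - 1 : s + 2]):
            canvas.complete_codon(s)
        else:
            put(s, _SENSE[rng.integers(0, len(_SENSE))])

    # everything else (5' head, 3' tail) is unconstrained
    bases = "ACGU"
    for i in range(c.total_length):
        if canvas.arr[i] is None:
            canvas.arr[i] = bases[rng.integers(0, 4)]
    return "".join(canvas.arr)


# --------------------------------------------------------------------------
# independent validation scans
# --------------------------------------------------------------------------


def _aug_orfs_all_frames(seq: str) -> list[tuple[int, int, int]]:
    """(start0, n_codons, frame) of every first-AUG-to-stop ORF."""
    out = []
    n = len(seq)
    for frame in range(3):
        seg_start = frame
        aug = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if aug is not None:
                    out.append((aug, (i - aug) // 3, frame))
                aug = None
                seg_start = i + 3
            elif aug is None and codon == "AUG":
                aug = i
            i += 3
        if aug is not None:
            out.append((aug, (i - aug) // 3, frame))
    return out


def _bracketed_runs(seq: str, frame: int) -> list[tuple[int, int]]:
    """(start0, n_codons) between consecutive stops in one frame."""
    runs = []
    prev = None
    i = frame
    n = len(seq)
    while i + 3 <= n:
        if seq[i : i + 3] in _STOPS:
            if prev is not None and i > prev:
                runs.append((prev, (i - prev) // 3))
            prev = i + 3
        i += 3
    return runs


def _validate(seq: str, c: GenomeConfig) -> Optional[str]:
    f2 = (c.orf2_start - 1) % 3

    def codon(pos1: int) -> str:
        return seq[pos1 - 1 : pos1 + 2]

    # planted anchors
    for pos, want in (
        (c.orf1_start, "AUG"), (c.orf2_start, "AUG"), (c.orf4_start, "AUG"),
    ):
        if codon(pos) != want:
            return f"missing planted AUG at {pos}"
    for pos in (
        c.orf1_start - 3, c.orf1_end + 1, c.orf2_start - 12, c.orf2_end + 1,
        c.orf3_first - 3, c.orf3_end + 1, c.orf4_end + 1,
    ):
        if codon(pos) not in _STOPS:
            return f"missing planted stop at {pos}"

    # planted frames are sense
    frames_sense = (
        (c.orf2_start, c.orf2_end),       # ORF2 zero frame
        (c.orf1_start, c.orf1_end),       # ORF1 -1 frame
        (c.orf3_first, c.orf3_end),       # ORF3 -1 frame
        (c.orf4_start, c.orf4_end),       # ORF4
    )
    for lo, hi in frames_sense:
        for s in range(lo, hi - 1, 3):
            if codon(s) in _STOPS:
                return f"stop codon inside planted ORF at {s}"

    mid = c.orf2_start + (3 * c.p2_aa) // 2
    orf3_codons = (c.orf3_end - c.orf3_first + 1) // 3
    for start0, n_codons, frame in _aug_orfs_all_frames(seq):
        start1 = start0 + 1
        end1 = start1 + 3 * n_codons - 1
        if start1 == c.orf2_start and frame == f2:
            if n_codons != c.p2_aa:
                return "ORF2 length mismatch"
            continue
        if n_codons > c.p2_aa or (n_codons == c.p2_aa):
            return f"competing long AUG ORF at {start1}"
        if start1 == c.orf1_start:
            continue
        if frame != f2 and end1 < mid and (
            n_codons > c.p1_aa or (n_codons == c.p1_aa and start1 < c.orf1_start)
        ):
            return f"competing ORF1 candidate at {start1}"
        if start1 == c.orf4_start:
            continue
        if start1 > c.orf3_end and (
            n_codons > c.orf4_aa
            or (n_codons == c.orf4_aa and start1 < c.orf4_start)
        ):
            return f"competing ORF4 candidate at {start1}"

    for start0, n_codons in _bracketed_runs(seq, (f2 + 2) % 3):
        start1 = start0 + 1
        end1 = start1 + 3 * n_codons - 1
        if start1 == c.orf3_first:
            continue
        if end1 >= mid and start1 <= c.orf2_end and n_codons >= orf3_codons:
            return f"competing ORF3 candidate at {start1}"

    # slippery uniqueness inside the overlap
    expected = {c.slippery_pos} | ({c.decoy_pos} if c.decoys else set())
    found = set()
    want_mod = (f2 + 2) % 3
    for i in range(c.orf3_first - 1, c.orf2_end - 6):
        if i % 3 == want_mod and heptamer_matches_grammar(seq[i : i + 7]):
            found.add(i + 1)
    if found != expected:
        return f"unexpected slippery heptamer set {sorted(found)}"
    return None


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def _truth_structure(c: GenomeConfig) -> StructureElement:
    ss = c.structure_start
    if c.structure == "pseudoknot":
        return StructureElement(
            kind="pseudoknot",
            stems=(
                (Interval(ss, ss + 5), Interval(ss + 16, ss + 21)),
                (Interval(ss + 8, ss + 12), Interval(ss + 26, ss + 30)),
            ),
            loop_lengths=(2, 3, 4),
            bulges=(),
            start=ss,
        )
    if c.structure == "hairpin":
        return StructureElement(
            kind="stem_loop",
            stems=((Interval(ss, ss + 5), Interval(ss + 10, ss + 15)),),
            loop_lengths=(4,),
            bulges=(),
            start=ss,
        )
    return StructureElement(  # hairpin_bulged
        kind="stem_loop",
        stems=(
            (Interval(ss, ss + 2), Interval(ss + 18, ss + 20)),
            (Interval(ss + 4, ss + 8), Interval(ss + 13, ss + 17)),
        ),
        loop_lengths=(4,),
        bulges=(ss + 3,),
        start=ss,
    )


def generate_genome(
    config: GenomeConfig = GenomeConfig(),
    seed: int = 0,
    max_attempts: int = 50,
) -> TruthBundle:
    """Generate a genome satisfying ``config`` with full planted truth.

    Deterministic under ``seed``: the filler is redrawn (still from the
    seeded stream) until the independent validation scans pass, so the same
    seed always yields the same genome byte-for-byte.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    err = "no attempt"
    for _ in range(max_attempts):
        seq = _build(config, rng)
        err = _validate(seq, config)
        if err is None:
            break
    else:
        raise GenerationError(f"could not satisfy config after {max_attempts} tries: {err}")

    c = config
    genome = Genome(id=f"synthetic-barnavirus-seed{seed}", seq=seq)
    orfs = {
        "ORF1": OrfRecord("ORF1", Interval(c.orf1_start, c.orf1_end),
                          "AUG_to_stop", c.p1_aa),
        "ORF2": OrfRecord("ORF2", Interval(c.orf2_start, c.orf2_end),
                          "AUG_to_stop", c.p2_aa),
        "ORF3": OrfRecord("ORF3", Interval(c.orf3_first, c.orf3_end),
                          "stop_bracketed",
                          (c.orf3_end - c.orf3_first + 1) // 3),
        "ORF4": OrfRecord("ORF4", Interval(c.orf4_start, c.orf4_end),
                          "AUG_to_stop", c.orf4_aa),
    }
    slippery = SlipperyMatch(
        position=c.slippery_pos,
        heptamer=c.slippery,
        xxx=c.slippery[:3],
        yyy=c.slippery[3:6],
        z=c.slippery[6],
        frame_anchor=(c.orf2_start - 1) % 3,
    )
    structure = _truth_structure(c)
    raw_spacer = structure.start - slippery.end - 1
    eff = None
    if c.structure == "hairpin_bulged" and not 5 <= raw_spacer <= 9:
        eff = structure.bulges[0] - slippery.end
    signal = FrameshiftSignal(
        slippery=slippery, structure=structure, spacer=raw_spacer,
        effective_spacer=eff, valid=True, primary=True,
    )
    return TruthBundle(
        genome=genome,
        original=genome,
        orfs=orfs,
        signal=signal,
        fusion_length=c.fusion_aa,
        junction_index=c.zero_frame_codons,
        tm_blocks={"P2": c.tm_blocks, "P1": ()},
        tm_boundary_aa=c.tm_boundary_aa,
        indel=None,
        truncations=(0, 0),
        seed=seed,
        config=c,
        decoy_positions=(c.decoy_pos,) if c.decoys else (),
    )


def simulate_reads(
    genome: Genome,
    depth: float = 20.0,
    read_len: int = 100,
    error_rate: float = 0.01,
    seed: int = 0,
) -> ReadSet:
    """Uniform-start reads at ~``depth`` mean interior coverage.

    The read count is Poisson(depth * L / read_len); starts are uniform,
    strands random, and errors are independent per-base substitutions.
    """
    if read_len > len(genome):
        raise ConfigError("read_len exceeds genome length")
    if not 0 <= error_rate < 0.25:
        raise ConfigError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    L = len(genome)
    n_reads = int(rng.poisson(depth * L / read_len)) if depth > 0 else 0
    reads: list[Read] = []
    bases = "ACGU"
    from .genome_io import reverse_complement

    for i in range(n_reads):
        start = int(rng.integers(0, L - read_len + 1))
        seq = genome.seq[start : start + read_len]
        if error_rate > 0:
            n_err = rng.binomial(read_len, error_rate)
            if n_err:
                pos = rng.choice(read_len, size=n_err, replace=False)
                chars = list(seq)
                for p in pos:
                    alt = [b for b in bases if b != chars[p]]
                    chars[p] = alt[rng.integers(0, 3)]
                seq = "".join(chars)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(Read(id=f"r{i:06d}", seq=seq, quality="I" * read_len))
    return ReadSet(reads=reads, source=f"simulated:{genome.id}:seed{seed}")


def apply_lesions(
    bundle: TruthBundle,
    indel: Optional[tuple[str, int, str]] = None,
    truncations: Optional[tuple[int, int]] = None,
) -> TruthBundle:
    """Return a copy of ``bundle`` with an indel and/or terminal truncations.

    ``indel`` is ``(kind, after_position, base)``: an insertion places
    ``base`` between ``after_position`` and ``after_position + 1``; a
    deletion removes the base at ``after_position + 1`` (so inserting the
    deleted base back at the same after_position is the exact inverse).
    Truth coordinates keep referring to the original genome, retained in
    ``bundle.original``.
    """
    seq = bundle.genome.seq
    if indel is not None:
        kind, p, base = indel
        if kind == "insertion":
            if not 0 <= p <= len(seq):
                raise ConfigError("insertion position outside genome")
            seq = seq[:p] + base + seq[p:]
        elif kind == "deletion":
            if not 0 <= p < len(seq):
                raise ConfigError("deletion position outside genome")
            seq = seq[:p] + seq[p + 1 :]
        else:
            raise ConfigError(f"unknown indel kind {kind!r}")
    five, three = truncations or (0, 0)
    if five or three:
        if five + three >= len(seq):
            raise ConfigError("truncations remove the whole genome")
        seq = seq[five : len(seq) - three]
    lesioned = Genome(id=bundle.genome.id + "-lesioned", seq=seq)
    return dataclasses.replace(
        bundle,
        genome=lesioned,
        original=bundle.original,
        indel=indel,
        truncations=(five, three),
    )
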