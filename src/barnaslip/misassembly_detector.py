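"""Detection and correction of single-nucleotide indel assembly errors.

A 1-nt indel inside the ORF1/ORF2 overlap of a barnavirus-like genome swaps
the 5' portions of the two overlapping ORFs between frames, which shows up
as a broken architecture signature: the ORF1 slot empties or picks up a TM
cluster while P2's N-terminal TM cluster degrades, the -1-frame relations
fail, and so on.  The detector scores each candidate correction by how many
of seven binary architecture features the corrected genome satisfies, and
reports the correction(s) restoring the maximum score.

Because a 1-nt indel inside (or next to) a homopolymer run is positionally
unidentifiable from the sequence alone, top-scoring hypotheses are grouped
into contiguous position windows and each group is reported by its 5'-most
``after_position`` and window extent; sequencing reads (``read_support``)
are the way to pin the exact residue, as was done for the published
correction this module emulates.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from .genome_io import ContractViolation, Genome, Interval
from .orf_annotator import (
    NoCandidateOrf2Error,
    annotate,
    orf_protein,
)
from .prf_scanner import MotifConfig, StructureParams, scan_prf
from .read_walker import ReadSet
from .tm_predictor import TmParams, count_tm_before, predict_tm_segments

FEATURES = (
    "orf1_present_5prime",
    "orf1_minus1_frame",
    "orf3_overlaps_orf2_minus1",
    "prf_signal_in_overlap",
    "orf4_downstream_nonoverlapping",
    "tm_cluster_p2_nterm",
    "no_tm_cluster_p1",
)


@dataclasses.dataclass(frozen=True)
class DetectorConfig:
    min_aa: int = 50
    tm_params: TmParams = TmParams()
    tm_boundary_aa: int = 290
    tm_cluster_min: int = 2
    motif_config: MotifConfig = MotifConfig()
    structure_params: StructureParams = StructureParams()
    spacer_range: tuple[int, int] = (5, 9)
    max_region: int = 2000


def score_architecture(
    genome: Genome, config: DetectorConfig = DetectorConfig()
) -> tuple[int, dict[str, bool]]:
    """Count of satisfied architecture features, with the breakdown.

    Features: ORF1 present with its start 5' of ORF2's; ORF1 in the -1
    frame relative to ORF2; ORF3 overlapping ORF2 in the -1 frame; a valid
    PRF signal inside the ORF2/ORF3 overlap; ORF4 present, 3' of and not
    overlapping ORF3; >= ``tm_cluster_min`` TM segments N-terminal to the
    protease-region boundary in P2; ORF1 present with zero TM segments in
    P1.
    """
    breakdown = {f: False for f in FEATURES}
    try:
        arch = annotate(genome, config.min_aa)
    except NoCandidateOrf2Error:
        return 0, breakdown
    orf2 = arch.get("ORF2")
    orf1 = arch.get("ORF1")
    orf3 = arch.get("ORF3")
    orf4 = arch.get("ORF4")
    if orf1 is not None:
        breakdown["orf1_present_5prime"] = orf1.interval.start < orf2.interval.start
        breakdown["orf1_minus1_frame"] = (orf1.frame - orf2.frame) % 3 == 2
        p1 = orf_protein(genome, orf1)
        breakdown["no_tm_cluster_p1"] = not predict_tm_segments(p1, config.tm_params)
    if orf3 is not None:
        breakdown["orf3_overlaps_orf2_minus1"] = True
        signals = scan_prf(
            genome, orf2, orf3,
            config.motif_config, config.structure_params, config.spacer_range,
        )
        breakdown["prf_signal_in_overlap"] = any(s.valid for s in signals)
        if orf4 is not None:
            breakdown["orf4_downstream_nonoverlapping"] = (
                orf4.interval.start > orf3.interval.end
            )
    p2 = orf_protein(genome, orf2)
    boundary = min(config.tm_boundary_aa, len(p2))
    if boundary >= 1 and len(p2) >= config.tm_params.window:
        breakdown["tm_cluster_p2_nterm"] = (
            count_tm_before(p2, boundary, config.tm_params) >= config.tm_cluster_min
        )
    return sum(breakdown.values()), breakdown


def apply_indel(seq: str, kind: str, after_position: int, base: str = "") -> str:
    """Apply one hypothesis to a sequence string (1-based after_position).

    Insertion places ``base`` between ``after_position`` and the next
    position; deletion removes the base at ``after_position + 1``. With
    this convention insertion followed by deletion at the same position is
    the identity.
    """
    p = after_position
    if kind == "insertion":
        if not 0 <= p <= len(seq) or len(base) != 1:
            raise ContractViolation("bad insertion hypothesis")
        return seq[:p] + base + seq[p:]
    if kind == "deletion":
        if not 0 <= p < len(seq):
            raise ContractViolation("bad deletion hypothesis")
        return seq[:p] + seq[p + 1 :]
    raise ContractViolation(f"unknown indel kind {kind!r}")


@dataclasses.dataclass(frozen=True)
class IndelHypothesis:
    """A top-scoring correction group.

    ``after_position``..``window_end`` is the positional-ambiguity window
    (5'-most equivalent placement through the last equivalent placement,
    e.g. a homopolymer run); ``base`` is N when several inserted bases are
    equivalent. ``example_base`` is one concrete base achieving the score,
    for applying the correction.
    """

    kind: str
    after_position: int
    window_end: int
    base: str
    architecture_score: int
    tm_signature_ok: bool
    example_base: str
    members: tuple[tuple[int, str], ...] = ()  # concrete (position, base)
    read_support: Optional[int] = None


def scan_indels(
    genome: Genome,
    region: Interval,
    reference_score: Optional[int] = None,
    config: DetectorConfig = DetectorConfig(),
) -> list[IndelHypothesis]:
    """Exhaustive single-nt indel scan over ``region``.

    Every position gets five variants (deletion, insertion of each base);
    each variant genome is re-annotated and re-scored identically. Groups
    of hypotheses achieving the maximum score are returned only if that
    maximum improves on ``reference_score`` (the input genome's own score
    when not given).
    """
    if len(region) > config.max_region:
        raise ContractViolation(
            f"region of {len(region)} nt exceeds the {config.max_region}-nt cap; "
            "narrow the scan to the suspect ORF overlap"
        )
    if region.end > len(genome):
        raise ContractViolation("region outside genome")
    if reference_score is None:
        reference_score, _ = score_architecture(genome, config)
    seq = genome.seq
    cache: dict[str, tuple[int, dict[str, bool]]] = {}

    def score_of(variant: str) -> tuple[int, dict[str, bool]]:
        hit = cache.get(variant)
        if hit is None:
            hit = score_architecture(Genome(id="v", seq=variant), config)
            cache[variant] = hit
        return hit

    records = []  # (kind, after_position, base, score, breakdown)
    for p in range(region.start, region.end + 1):
        if p < len(seq):
            var = apply_indel(seq, "deletion", p)
            sc, bd = score_of(var)
            records.append(("deletion", p, "", sc, bd))
        for base in "ACGU":
            var = apply_indel(seq, "insertion", p, base)
            sc, bd = score_of(var)
            records.append(("insertion", p, base, sc, bd))

    best = max((r[3] for r in records), default=0)
    if best <= reference_score:
        return []
    top = [r for r in records if r[3] == best]
    return _group_hypotheses(top, best)


def _group_hypotheses(top: list[tuple], best: int) -> list[IndelHypothesis]:
    """Merge top hypotheses of one kind into positional-ambiguity windows.

    Placements separated by less than one codon belong to the same window:
    an isolated interior position where every inserted base happens to
    create a stop codon punctures the window without ending the
    register-equivalence stretch around it.
    """
    groups: list[IndelHypothesis] = []
    for kind in ("insertion", "deletion"):
        recs = sorted((r for r in top if r[0] == kind), key=lambda r: r[1])
        if not recs:
            continue
        run: list[tuple] = [recs[0]]
        for r in recs[1:]:
            if r[1] - run[-1][1] <= 3:
                run.append(r)
            else:
                groups.append(_make_group(kind, run, best))
                run = [r]
        groups.append(_make_group(kind, run, best))
    groups.sort(key=lambda g: g.after_position)
    return groups


def _make_group(kind: str, run: list[tuple], best: int) -> IndelHypothesis:
    bases = sorted({r[2] for r in run if r[2]})
    breakdown = run[0][4]
    tm_ok = breakdown.get("tm_cluster_p2_nterm", False) and breakdown.get(
        "no_tm_cluster_p1", False
    )
    return IndelHypothesis(
        kind=kind,
        after_position=run[0][1],
        window_end=run[-1][1],
        base=(bases[0] if len(bases) == 1 else "N") if kind == "insertion" else "N",
        architecture_score=best,
        tm_signature_ok=tm_ok,
        example_base=bases[0] if bases else "",
        members=tuple((r[1], r[2]) for r in run),
    )


@dataclasses.dataclass(frozen=True)
class SupportCount:
    corrected: int
    uncorrected: int


def read_support(
    genome: Genome,
    hypothesis: IndelHypothesis,
    reads: ReadSet,
    flank: int = 15,
) -> SupportCount:
    """Reads exactly containing the corrected vs. uncorrected local sequence.

    The corrected genome is formed by applying the hypothesis (its concrete
    example base for N groups); the window spans ``flank`` nt either side
    of the edit. Reads are matched in both orientations.
    """
    if flank < 5:
        raise ContractViolation("flank must be >= 5")
    from .genome_io import reverse_complement

    p = hypothesis.after_position
    base = hypothesis.example_base or "A"
    corrected = apply_indel(genome.seq, hypothesis.kind, p, base)
    extra = 1 if hypothesis.kind == "insertion" else 0
    lo = max(0, p - flank)
    win_corr = corrected[lo : min(len(corrected), p + flank + extra)]
    win_orig = genome.seq[lo : min(len(genome.seq), p + flank)]
    n_corr = n_orig = 0
    for read in reads.reads:
        seqs = (read.seq, reverse_complement(read.seq))
        if any(win_corr in s for s in seqs):
            n_corr += 1
        if any(win_orig in s for s in seqs):
            n_orig += 1
    return SupportCount(corrected=n_corr, uncorrected=n_orig)


def resolve_with_reads(
    genome: Genome,
    hypothesis: IndelHypothesis,
    reads: ReadSet,
    flank: int = 15,
) -> tuple[IndelHypothesis, SupportCount]:
    """Pick the concrete member of an ambiguity window that reads support.

    Within a homopolymer run the architecture score cannot distinguish
    placements; exact read matches to the corrected local sequence can.
    Returns the hypothesis narrowed to the best-supported (position, base)
    with its support counts.
    """
    best_member = None
    best_support = SupportCount(-1, 0)
    for pos, base in hypothesis.members or (
        (hypothesis.after_position, hypothesis.example_base),
    ):
        cand = dataclasses.replace(
            hypothesis, after_position=pos, window_end=pos,
            base=base or "N", example_base=base, members=((pos, base),),
        )
        support = read_support(genome, cand, reads, flank)
        if support.corrected > best_support.corrected:
            best_member, best_support = cand, support
    narrowed = dataclasses.replace(best_member, read_support=best_support.corrected)
    return narrowed, best_support
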