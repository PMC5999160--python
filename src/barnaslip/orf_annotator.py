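"""ORF enumeration and barnavirus ORF1-ORF4 layout assignment.

Two ORF definitions are supported, matching how barnavirus genome maps are
drawn: most ORFs span the first in-frame AUG to the first downstream stop
(``AUG_to_stop``); the frameshift-expressed ORF3 has no initiator of its own
and is delimited by its bracketing in-frame stop codons (``stop_bracketed``).
Coordinates exclude the stop codon throughout.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Literal, Optional

from .genome_io import ContractViolation, Genome, Interval, translate

Rule = Literal["AUG_to_stop", "stop_bracketed"]

_STOP_RE = re.compile(r"(?=(?:UAA|UAG|UGA))")
_AUG_RE = re.compile(r"(?=AUG)")


def stop_starts_by_frame(seq: str) -> list[list[int]]:
    """0-based start offsets of stop codons, split by frame."""
    frames: list[list[int]] = [[], [], []]
    for m in _STOP_RE.finditer(seq):
        i = m.start()
        if i + 3 <= len(seq):
            frames[i % 3].append(i)
    return frames


def aug_starts_by_frame(seq: str) -> list[list[int]]:
    frames: list[list[int]] = [[], [], []]
    for m in _AUG_RE.finditer(seq):
        i = m.start()
        if i + 3 <= len(seq):
            frames[i % 3].append(i)
    return frames


@dataclasses.dataclass(frozen=True)
class OrfRecord:
    """One open reading frame (stop codon excluded from the interval)."""

    name: str  # ORF1..ORF4 once assigned, else "unassigned"
    interval: Interval
    rule: Rule
    protein_length: int
    incomplete_5prime: bool = False
    incomplete_3prime: bool = False
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.interval) % 3:
            raise ContractViolation(
                f"ORF interval {self.interval.start}..{self.interval.end} "
                "not a whole number of codons"
            )
        if self.protein_length != len(self.interval) // 3:
            raise ContractViolation("protein_length inconsistent with interval")

    @property
    def frame(self) -> int:
        return self.interval.frame

    def rename(self, name: str) -> "OrfRecord":
        return dataclasses.replace(self, name=name)


def orf_protein(genome: Genome, orf: OrfRecord) -> str:
    """Amino-acid sequence of an ORF (no stop symbol)."""
    return translate(genome.subseq(orf.interval.start, orf.interval.end))


def enumerate_orfs(
    genome: Genome, min_aa: int = 50, rule: Rule = "AUG_to_stop"
) -> list[OrfRecord]:
    """All maximal ORFs of ``rule`` in the three positive-sense frames.

    ``AUG_to_stop``: first in-frame AUG after the previous in-frame stop (or
    the 5' terminus) through the last codon before the next stop.
    ``stop_bracketed``: the full codon run between consecutive in-frame stops;
    runs truncated by a sequence end are flagged incomplete.
    Results are sorted by start position, then frame.
    """
    if min_aa < 1:
        raise ContractViolation("min_aa must be >= 1")
    seq = genome.seq
    n = len(seq)
    stops = stop_starts_by_frame(seq)
    augs = aug_starts_by_frame(seq) if rule == "AUG_to_stop" else None
    orfs: list[OrfRecord] = []
    for frame in range(3):
        fr_stops = stops[frame]
        # segment boundaries: [seg_start, seg_end) in 0-based codon starts
        seg_edges = [frame] + [s + 3 for s in fr_stops]
        seg_stops: list[Optional[int]] = list(fr_stops) + [None]
        for seg_start, stop_at in zip(seg_edges, seg_stops):
            if stop_at is None:
                # runs to the 3' terminus: last complete codon
                n_codons = (n - seg_start) // 3
                seg_end = seg_start + 3 * n_codons
                incomplete3 = True
            else:
                seg_end = stop_at
                incomplete3 = False
            if seg_end <= seg_start:
                continue
            if rule == "AUG_to_stop":
                start0 = _first_at_or_after(augs[frame], seg_start, seg_end)
                if start0 is None:
                    continue
                incomplete5 = False
            else:
                start0 = seg_start
                incomplete5 = seg_start == frame  # no 5' bracketing stop seen
            length = seg_end - start0
            if length < 3 * min_aa:
                continue
            orfs.append(
                OrfRecord(
                    name="unassigned",
                    interval=Interval(start0 + 1, seg_end),
                    rule=rule,
                    protein_length=length // 3,
                    incomplete_5prime=incomplete5,
                    incomplete_3prime=incomplete3,
                )
            )
    orfs.sort(key=lambda o: (o.interval.start, o.frame))
    return orfs


def _first_at_or_after(sorted_list: list[int], lo: int, hi: int) -> Optional[int]:
    import bisect

    i = bisect.bisect_left(sorted_list, lo)
    if i < len(sorted_list) and sorted_list[i] < hi:
        return sorted_list[i]
    return None


@dataclasses.dataclass
class GenomeArchitecture:
    """ORF1-ORF4 assignment plus frame/overlap diagnostics.

    ``relative_frames`` maps each assigned ORF to its frame offset relative
    to ORF2 (ORF2 itself is 0; a -1-frame ORF has offset 2 = -1 mod 3).
    """

    orfs: dict[str, OrfRecord]
    relative_frames: dict[str, int]
    overlaps: dict[tuple[str, str], Interval]
    unassigned_reasons: dict[str, str]

    def get(self, name: str) -> Optional[OrfRecord]:
        return self.orfs.get(name)


class NoCandidateOrf2Error(ValueError):
    pass


def _longest(cands: list[OrfRecord]) -> Optional[OrfRecord]:
    """Longest ORF; ties broken by 5'-most start, then frame index."""
    if not cands:
        return None
    return min(
        cands,
        key=lambda o: (-o.protein_length, o.interval.start, o.frame),
    )


def assign_layout(
    orfs_aug: list[OrfRecord],
    orfs_bracketed: list[OrfRecord],
    genome: Genome,
) -> GenomeArchitecture:
    """Assign the four-slot barnavirus layout.

    ORF2 is the longest AUG-defined ORF; ORF3 the longest stop-bracketed ORF
    overlapping ORF2's 3' half in the -1 frame; ORF1 the longest AUG ORF
    lying entirely 5' of ORF2's midpoint in another frame; ORF4 the longest
    AUG ORF starting 3' of ORF3's end. Empty slots carry a stated reason.
    """
    assigned: dict[str, OrfRecord] = {}
    reasons: dict[str, str] = {}

    orf2 = _longest(orfs_aug)
    if orf2 is None:
        raise NoCandidateOrf2Error(
            "no candidate ORF2: no AUG-defined ORF meets the length threshold"
        )
    assigned["ORF2"] = orf2.rename("ORF2")
    f2 = orf2.frame
    mid = orf2.interval.start + len(orf2.interval) // 2
    three_prime_half = Interval(mid, orf2.interval.end)

    orf3_cands = [
        o
        for o in orfs_bracketed
        if (o.frame - f2) % 3 == 2
        and o.interval.overlaps(three_prime_half)
        and o.interval != orf2.interval
    ]
    orf3 = _longest(orf3_cands)
    if orf3 is not None:
        assigned["ORF3"] = orf3.rename("ORF3")
    else:
        reasons["ORF3"] = (
            "no stop-bracketed ORF overlaps ORF2's 3' half in the -1 frame"
        )

    orf1_cands = [
        o
        for o in orfs_aug
        if o.interval.end < mid and o.frame != f2 and o is not orf2
    ]
    orf1 = _longest(orf1_cands)
    if orf1 is not None:
        assigned["ORF1"] = orf1.rename("ORF1")
    else:
        reasons["ORF1"] = (
            "no AUG-defined ORF in another frame lies entirely 5' of "
            "ORF2's midpoint"
        )

    after = orf3.interval.end if orf3 is not None else orf2.interval.end
    orf4_cands = [o for o in orfs_aug if o.interval.start > after]
    orf4 = _longest(orf4_cands)
    if orf4 is not None:
        assigned["ORF4"] = orf4.rename("ORF4")
    else:
        reasons["ORF4"] = "no AUG-defined ORF starts 3' of ORF3's end"

    rel = {name: (o.frame - f2) % 3 for name, o in assigned.items()}
    overlaps: dict[tuple[str, str], Interval] = {}
    names = sorted(assigned)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ov = overlap_region(assigned[a], assigned[b])
            if ov is not None:
                overlaps[(a, b)] = ov
    return GenomeArchitecture(
        orfs=assigned,
        relative_frames=rel,
        overlaps=overlaps,
        unassigned_reasons=reasons,
    )


def annotate(genome: Genome, min_aa: int = 50) -> GenomeArchitecture:
    """enumerate both rules + assign the layout in one call."""
    return assign_layout(
        enumerate_orfs(genome, min_aa, "AUG_to_stop"),
        enumerate_orfs(genome, min_aa, "stop_bracketed"),
        genome,
    )


def overlap_region(a: OrfRecord, b: OrfRecord) -> Optional[Interval]:
    """Overlap of two ORFs "between stop codons".

    ORF intervals already exclude their stop codons, so the region between
    stop codons is the plain positional intersection (e.g. ORF3's first codon
    after its 5' bracketing stop through ORF2's last sense codon).
    """
    return a.interval.intersection(b.interval)


def upstream_inframe_stop(genome: Genome, orf: OrfRecord) -> Optional[int]:
    """Codons between the nearest upstream in-frame stop and the ORF's AUG.

    0 means the stop immediately abuts the AUG. ``None`` means no upstream
    in-frame stop exists in the available sequence (the ORF is possibly
    5'-incomplete).
    """
    if orf.rule != "AUG_to_stop":
        raise ContractViolation("upstream_inframe_stop requires an AUG-defined ORF")
    seq = genome.seq
    pos = orf.interval.start - 1 - 3  # 0-based candidate stop start
    while pos >= 0:
        if seq[pos : pos + 3] in {"UAA", "UAG", "UGA"}:
            return (orf.interval.start - 1 - pos - 3) // 3
        pos -= 3
    return None
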