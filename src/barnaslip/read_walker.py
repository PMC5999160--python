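"""Read-walking contig extension.

Iteratively recruits sequencing reads that overlap a contig terminus via an
exact k-mer anchor, verifies the overlap with a mismatch budget, and extends
the consensus one column at a time by majority vote.  This reproduces, with
a self-contained overlap detector instead of a database search tool, the
procedure of walking a truncated transcriptome contig out to the genome
termini using archived read sets.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from Bio import SeqIO

from .genome_io import normalize_seq, reverse_complement

_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


@dataclasses.dataclass(frozen=True)
class Read:
    id: str
    seq: str
    quality: Optional[str] = None


@dataclasses.dataclass
class ReadSet:
    reads: list[Read]
    source: str = ""

    def usable(self, k: int) -> list[Read]:
        return [r for r in self.reads if len(r.seq) >= k]

    def skipped(self, k: int) -> list[Read]:
        return [r for r in self.reads if len(r.seq) < k]

    def __len__(self) -> int:
        return len(self.reads)


def load_reads(path: str | Path) -> ReadSet:
    """Load FASTQ or FASTA reads (format chosen by extension, default FASTQ)."""
    path = Path(path)
    fmt = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} else "fastq"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = None
        if "phred_quality" in rec.letter_annotations:
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
        reads.append(Read(id=rec.id, seq=normalize_seq(str(rec.seq)), quality=qual))
    return ReadSet(reads=reads, source=str(path))


@dataclasses.dataclass(frozen=True)
class WalkParams:
    k: int = 21
    max_mismatches: int = 2
    min_support: int = 2
    max_rounds: int = 100
    agree_window: int = 10


@dataclasses.dataclass
class ExtensionResult:
    final_seq: str
    added_5prime: int
    added_3prime: int
    reads_used: int
    depth: np.ndarray
    rounds: int


def _index_reads(reads: list[Read], k: int) -> dict[str, list[tuple[int, int, int]]]:
    """kmer -> [(read_idx, orientation 0/1, offset in oriented read)]."""
    index: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for ridx, read in enumerate(reads):
        for orient, seq in enumerate((read.seq, reverse_complement(read.seq))):
            for off in range(len(seq) - k + 1):
                index[seq[off : off + k]].append((ridx, orient, off))
    return dict(index)


def _mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _walk_3prime(
    contig: str,
    reads: list[Read],
    index: dict[str, list[tuple[int, int, int]]],
    params: WalkParams,
    used: set[int],
) -> tuple[str, int]:
    """Extend the 3' end; returns (extended sequence, rounds executed)."""
    consensus = contig
    k = params.k
    rounds = 0
    oriented_cache: dict[tuple[int, int], str] = {}

    def oriented(ridx: int, orient: int) -> str:
        key = (ridx, orient)
        if key not in oriented_cache:
            seq = reads[ridx].seq
            oriented_cache[key] = seq if orient == 0 else reverse_complement(seq)
        return oriented_cache[key]

    max_rlen = max((len(r.seq) for r in reads), default=0)
    while rounds < params.max_rounds:
        rounds += 1
        n = len(consensus)
        window_lo = max(0, n - max_rlen)
        candidates: dict[tuple[int, int, int], None] = {}
        for pos in range(window_lo, n - k + 1):
            for ridx, orient, off in index.get(consensus[pos : pos + k], ()):
                start = pos - off
                candidates[(ridx, orient, start)] = None
        accepted: list[tuple[int, str]] = []  # (start, oriented read seq)
        accepted_ridx: list[int] = []
        for ridx, orient, start in candidates:
            seq = oriented(ridx, orient)
            if start + len(seq) <= n:
                continue  # no overhang past the terminus
            ov_lo = max(start, 0)
            overlap_len = n - ov_lo
            if overlap_len < k:
                continue
            if (
                _mismatches(
                    consensus[ov_lo:n], seq[ov_lo - start : ov_lo - start + overlap_len],
                    params.max_mismatches,
                )
                > params.max_mismatches
            ):
                continue
            # chimera guard: must agree exactly with the trailing consensus
            guard_lo = max(ov_lo, n - params.agree_window)
            if consensus[guard_lo:n] != seq[guard_lo - start : n - start]:
                continue
            accepted.append((start, seq))
            accepted_ridx.append(ridx)
        if not accepted:
            break
        new_cols: list[str] = []
        col = n
        while True:
            votes = Counter()
            for start, seq in accepted:
                idx = col - start
                if 0 <= idx < len(seq):
                    votes[seq[idx]] += 1
            if not votes:
                break
            base = min(votes, key=lambda b: (-votes[b], _BASE_ORDER.get(b, 9)))
            if votes[base] < params.min_support:
                break
            new_cols.append(base)
            col += 1
        if not new_cols:
            break
        added_lo = n
        consensus = consensus + "".join(new_cols)
        for (start, seq), ridx in zip(accepted, accepted_ridx):
            if start + len(seq) > added_lo:
                used.add(ridx)
    return consensus, rounds


def extend_terminus(
    contig: str,
    reads: ReadSet,
    end: Literal["five_prime", "three_prime"],
    params: WalkParams = WalkParams(),
) -> ExtensionResult:
    """Extend one terminus of ``contig`` with overlapping reads.

    Reads are used in either orientation; columns are appended by majority
    vote (ties broken A<C<G<U) and require ``min_support`` agreeing reads.
    Zero extension is a valid result.
    """
    contig = normalize_seq(contig)
    usable = reads.usable(params.k)
    if not usable:
        depth = np.zeros(len(contig), dtype=int)
        return ExtensionResult(contig, 0, 0, 0, depth, 0)
    index = _index_reads(usable, params.k)
    used: set[int] = set()
    if end == "three_prime":
        final, rounds = _walk_3prime(contig, usable, index, params, used)
        added5, added3 = 0, len(final) - len(contig)
    else:
        # the k-mer index holds both read orientations, so walking the
        # reverse-complemented contig 3'-ward extends the true 5' end
        rc = reverse_complement(contig)
        final_rc, rounds = _walk_3prime(rc, usable, index, params, used)
        final = reverse_complement(final_rc)
        added5, added3 = len(final) - len(contig), 0
    stats = coverage_stats(final, reads, params)
    return ExtensionResult(
        final_seq=final,
        added_5prime=added5,
        added_3prime=added3,
        reads_used=len(used),
        depth=stats.depth,
        rounds=rounds,
    )


def extend_both(
    contig: str, reads: ReadSet, params: WalkParams = WalkParams()
) -> ExtensionResult:
    """Extend the 3' then the 5' terminus and combine the bookkeeping."""
    res3 = extend_terminus(contig, reads, "three_prime", params)
    res5 = extend_terminus(res3.final_seq, reads, "five_prime", params)
    stats = coverage_stats(res5.final_seq, reads, params)
    return ExtensionResult(
        final_seq=res5.final_seq,
        added_5prime=res5.added_5prime,
        added_3prime=res3.added_3prime,
        reads_used=stats.reads_used,
        depth=stats.depth,
        rounds=res3.rounds + res5.rounds,
    )


@dataclasses.dataclass
class CoverageStats:
    reads_used: int
    mean_depth: float
    min_depth: int
    max_depth: int
    depth: np.ndarray


def coverage_stats(
    final_seq: str, reads: ReadSet, params: WalkParams = WalkParams()
) -> CoverageStats:
    """Per-position depth of all reads accepted by the overlap matcher."""
    final_seq = normalize_seq(final_seq)
    n = len(final_seq)
    depth = np.zeros(n, dtype=int)
    k = params.k
    if n < k:
        return CoverageStats(0, 0.0, 0, 0, depth)
    ref_index: dict[str, list[int]] = defaultdict(list)
    for pos in range(n - k + 1):
        ref_index[final_seq[pos : pos + k]].append(pos)
    used = 0
    for read in reads.usable(k):
        placed = None
        for orient_seq in (read.seq, reverse_complement(read.seq)):
            for off in range(0, len(orient_seq) - k + 1):
                hits = ref_index.get(orient_seq[off : off + k])
                if not hits:
                    continue
                for pos in hits:
                    start = pos - off
                    lo = max(start, 0)
                    hi = min(start + len(orient_seq), n)
                    if hi - lo < k:
                        continue
                    if (
                        _mismatches(
                            final_seq[lo:hi], orient_seq[lo - start : hi - start],
                            params.max_mismatches,
                        )
                        <= params.max_mismatches
                    ):
                        placed = (lo, hi)
                        break
                if placed:
                    break
            if placed:
                break
        if placed:
            used += 1
            depth[placed[0] : placed[1]] += 1
    mean = float(depth.mean()) if n else 0.0
    return CoverageStats(
        reads_used=used,
        mean_depth=mean,
        min_depth=int(depth.min()) if n else 0,
        max_depth=int(depth.max()) if n else 0,
        depth=depth,
    )
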