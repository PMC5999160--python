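"""Sequence/annotation I/O and the coordinate + alphabet conventions.

Conventions fixed here and used by every other module:

* sequences are positive-sense RNA strings over ``{A, C, G, U}`` (``N``
  tolerated but never matching motifs and translating to ``X``); DNA input
  (``T``) is normalised on read;
* all coordinates are 1-based and inclusive, so an interval's length is
  ``end - start + 1``;
* frames are 0/1/2 relative to genome position 1: an interval starting at
  ``start`` lies in frame ``(start - 1) % 3``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGUN")

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

#: Standard genetic code on RNA codons; codons containing N map to X.
CODON_TABLE = {
    "UUU": "F", "UUC": "F", "UUA": "L", "UUG": "L",
    "CUU": "L", "CUC": "L", "CUA": "L", "CUG": "L",
    "AUU": "I", "AUC": "I", "AUA": "I", "AUG": "M",
    "GUU": "V", "GUC": "V", "GUA": "V", "GUG": "V",
    "UCU": "S", "UCC": "S", "UCA": "S", "UCG": "S",
    "CCU": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACU": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCU": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "UAU": "Y", "UAC": "Y", "UAA": "*", "UAG": "*",
    "CAU": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAU": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAU": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "UGU": "C", "UGC": "C", "UGA": "*", "UGG": "W",
    "CGU": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGU": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGU": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class FormatError(ValueError):
    """Malformed input file (FASTA/FASTQ/GFF3)."""


class ContractViolation(ValueError):
    """A caller broke an operation's precondition."""


def normalize_seq(raw: str) -> str:
    """Uppercase, T->U. Raises on characters outside the RNA alphabet + N."""
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise FormatError(
            f"invalid nucleotide character(s) {sorted(bad)}; "
            f"allowed: A, C, G, U/T, N"
        )
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate an in-frame RNA string; stops are '*', N-codons are 'X'.

    Trailing bases that do not fill a codon are ignored.
    """
    aas = []
    table = CODON_TABLE
    for i in range(0, len(seq) - 2, 3):
        aas.append(table.get(seq[i : i + 3], "X"))
    return "".join(aas)


@dataclasses.dataclass(frozen=True)
class Genome:
    """A positive-sense RNA sequence with a stable identifier."""

    id: str
    seq: str
    positive_sense: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid nucleotide character(s) "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_count(self) -> int:
        return self.seq.count("N")

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice."""
        if not 1 <= start <= end <= len(self.seq):
            raise ContractViolation(
                f"subseq {start}..{end} outside 1..{len(self.seq)}"
            )
        return self.seq[start - 1 : end]


@dataclasses.dataclass(frozen=True, order=True)
class Interval:
    """1-based inclusive interval; frame is derived from the start position."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ContractViolation(f"bad interval {self.start}..{self.end}")

    @property
    def frame(self) -> int:
        return (self.start - 1) % 3

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end

    def intersection(self, other: "Interval") -> "Interval | None":
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return Interval(lo, hi) if lo <= hi else None


def read_fasta(path: str | Path) -> list[Genome]:
    """Read a FASTA file into normalised :class:`Genome` records.

    Errors name the offending line where the malformation can be located.
    """
    path = Path(path)
    _prescan_fasta(path)
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = normalize_seq(str(rec.seq))
            genomes.append(Genome(id=rec.id, seq=seq))
        except FormatError as err:
            line = _locate_record_line(path, rec.id)
            raise FormatError(f"{path}:{line}: {err}") from err
    if not genomes:
        raise FormatError(f"{path}:1: no sequences found")
    return genomes


def _prescan_fasta(path: Path) -> None:
    """Cheap structural scan so errors can carry line numbers."""
    with open(path) as fh:
        header_line = None
        body_seen = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if line == ">":
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if not body_seen:
                    raise FormatError(
                        f"{path}:{header_line}: record with no sequence lines"
                    )
                header_line = lineno
                body_seen = False
            else:
                if header_line is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                body_seen = True
        if header_line is not None and not body_seen:
            raise FormatError(
                f"{path}:{header_line}: record with no sequence lines"
            )


def _locate_record_line(path: Path, rec_id: str) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0] == rec_id:
                return lineno
    return 1


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write (id, seq) pairs as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _gff3_escape(value: str) -> str:
    return (
        value.replace("%", "%25").replace(";", "%3B")
        .replace("=", "%3D").replace(",", "%2C").replace("\t", "%09")
    )


def write_gff3(genome: Genome, features: Sequence[dict], path: str | Path) -> None:
    """Write annotated intervals as GFF3.

    Each feature dict carries ``interval`` (:class:`Interval`), ``type``
    (``CDS`` or ``sequence_feature``) and arbitrary string attributes
    (ORF name, frame, defining rule, flags...).
    """
    lines = [
        "##gff-version 3",
        f"##sequence-region {genome.id} 1 {len(genome)}",
    ]
    for feat in features:
        iv: Interval = feat["interval"]
        if iv.end > len(genome):
            raise ContractViolation(
                f"feature {feat.get('attributes', {}).get('Name', '?')} "
                f"interval {iv.start}..{iv.end} exceeds genome length "
                f"{len(genome)}"
            )
        ftype = feat.get("type", "sequence_feature")
        attrs = feat.get("attributes", {})
        attr_str = ";".join(
            f"{_gff3_escape(str(k))}={_gff3_escape(str(v))}"
            for k, v in attrs.items()
        )
        lines.append(
            "\t".join(
                [
                    genome.id,
                    "barnaslip",
                    ftype,
                    str(iv.start),
                    str(iv.end),
                    ".",
                    "+",
                    ".",
                    attr_str or ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
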