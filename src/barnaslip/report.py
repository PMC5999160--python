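"""JSON report assembly and a versioned structural schema.

Reports are plain dicts serialised with sorted keys so identical runs give
byte-identical files. ``validate_report`` checks a report against the
shipped schema (a minimal structural checker: required keys and types).
"""

from __future__ import annotations

from typing import Any, Optional

from .genome_io import Genome, Interval
from .orf_annotator import (
    GenomeArchitecture,
    OrfRecord,
    upstream_inframe_stop,
)
from .prf_scanner import FrameshiftSignal, StructureElement, dot_bracket
from .tm_predictor import TmSegment

SCHEMA_VERSION = "1.0"

#: type spec mini-language: python type, "?" prefix = optional/nullable,
#: [spec] = list of, {..} = nested object (extra keys allowed)
REPORT_SCHEMA: dict[str, Any] = {
    "schema_version": str,
    "genome": {"id": str, "length": int, "n_count": int},
    "architecture": {
        "orfs": [
            {
                "name": str,
                "start": int,
                "end": int,
                "frame": int,
                "rule": str,
                "protein_length": int,
                "incomplete_5prime": bool,
                "incomplete_3prime": bool,
            }
        ],
        "relative_frames": dict,
        "overlaps": [
            {"pair": str, "start": int, "end": int, "length": int}
        ],
        "unassigned": dict,
    },
    "prf_signals": [
        {
            "position": int,
            "heptamer": str,
            "valid": bool,
            "primary": bool,
            "spacer": "?int",
            "effective_spacer": "?int",
            "structure": "?dict",
        }
    ],
    "fusion": "?dict",
    "tm": dict,
    "misassembly": "?dict",
}


class SchemaError(ValueError):
    pass


def validate_report(obj: Any, spec: Any = None, path: str = "$") -> None:
    """Raise :class:`SchemaError` if ``obj`` does not match the schema."""
    if spec is None:
        spec = REPORT_SCHEMA
    if isinstance(spec, str) and spec.startswith("?"):
        if obj is None:
            return
        spec = {"int": int, "str": str, "dict": dict, "bool": bool}[spec[1:]]
    if isinstance(spec, dict) and spec:
        if not isinstance(obj, dict):
            raise SchemaError(f"{path}: expected object, got {type(obj).__name__}")
        for key, sub in spec.items():
            if key not in obj:
                raise SchemaError(f"{path}.{key}: missing")
            validate_report(obj[key], sub, f"{path}.{key}")
    elif isinstance(spec, list):
        if not isinstance(obj, list):
            raise SchemaError(f"{path}: expected array")
        for i, item in enumerate(obj):
            validate_report(item, spec[0], f"{path}[{i}]")
    elif isinstance(spec, type):
        if spec is int and isinstance(obj, bool):
            raise SchemaError(f"{path}: expected int, got bool")
        if not isinstance(obj, spec):
            raise SchemaError(
                f"{path}: expected {spec.__name__}, got {type(obj).__name__}"
            )


def orf_to_dict(orf: OrfRecord) -> dict:
    return {
        "name": orf.name,
        "start": orf.interval.start,
        "end": orf.interval.end,
        "frame": orf.frame,
        "rule": orf.rule,
        "protein_length": orf.protein_length,
        "incomplete_5prime": orf.incomplete_5prime,
        "incomplete_3prime": orf.incomplete_3prime,
    }


def structure_to_dict(s: StructureElement) -> dict:
    lo = s.start
    hi = max(arm.end for stem in s.stems for arm in stem)
    return {
        "kind": s.kind,
        "start": s.start,
        "end": hi,
        "total_bp": s.total_bp,
        "stems": [
            {
                "five_prime": [five.start, five.end],
                "three_prime": [three.start, three.end],
            }
            for five, three in s.stems
        ],
        "loop_lengths": list(s.loop_lengths),
        "bulges": list(s.bulges),
        "dot_bracket": dot_bracket(s, Interval(lo, hi)),
    }


def signal_to_dict(sig: FrameshiftSignal) -> dict:
    return {
        "position": sig.slippery.position,
        "heptamer": sig.slippery.heptamer,
        "xxx": sig.slippery.xxx,
        "yyy": sig.slippery.yyy,
        "z": sig.slippery.z,
        "valid": sig.valid,
        "primary": sig.primary,
        "spacer": sig.spacer,
        "effective_spacer": sig.effective_spacer,
        "structure": structure_to_dict(sig.structure) if sig.structure else None,
    }


def tm_to_dict(segments: dict[str, list[TmSegment]],
               counts_before: dict[str, Optional[int]]) -> dict:
    return {
        protein: {
            "segments": [
                {
                    "start_aa": s.start_aa,
                    "end_aa": s.end_aa,
                    "mean_hydropathy": round(s.mean_hydropathy, 3),
                }
                for s in segs
            ],
            "n_before_boundary": counts_before.get(protein),
        }
        for protein, segs in segments.items()
    }


def build_report(
    genome: Genome,
    arch: Optional[GenomeArchitecture],
    signals: list[FrameshiftSignal],
    fusion: Optional[dict],
    tm: dict,
    misassembly: Optional[dict] = None,
) -> dict:
    arch_block = {
        "orfs": [],
        "relative_frames": {},
        "overlaps": [],
        "unassigned": {},
    }
    if arch is not None:
        arch_block["orfs"] = [
            orf_to_dict(arch.orfs[name]) for name in sorted(arch.orfs)
        ]
        arch_block["relative_frames"] = dict(sorted(arch.relative_frames.items()))
        arch_block["overlaps"] = [
            {
                "pair": f"{a}/{b}",
                "start": iv.start,
                "end": iv.end,
                "length": len(iv),
            }
            for (a, b), iv in sorted(arch.overlaps.items())
        ]
        arch_block["unassigned"] = dict(sorted(arch.unassigned_reasons.items()))
        orf2 = arch.get("ORF2")
        if orf2 is not None:
            dist = upstream_inframe_stop(genome, orf2)
            arch_block["orf2_upstream_inframe_stop_codons"] = dist
            arch_block["orf2_possibly_5prime_incomplete"] = dist is None
    return {
        "schema_version": SCHEMA_VERSION,
        "genome": {
            "id": genome.id,
            "length": len(genome),
            "n_count": genome.n_count,
        },
        "architecture": arch_block,
        "prf_signals": [signal_to_dict(s) for s in signals],
        "fusion": fusion,
        "tm": tm,
        "misassembly": misassembly,
    }
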