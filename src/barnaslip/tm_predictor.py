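"""Hydropathy-window transmembrane (TM) segment prediction.

A deliberately simple, fully documented predictor: the Kyte-Doolittle scale
averaged over a centred sliding window, thresholded, with a minimum run
length.  It stands in for web-tool TM predictors whose exact algorithms are
unpublished; the pipeline only relies on the coarse architecture signature
(a TM cluster in the P2 N-terminal region, none in P1), which is robust to
the choice of predictor.
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: Kyte & Doolittle residue hydropathy values.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
    # unknown residues (X from N-containing codons) treated as neutral
    "X": 0.0, "*": 0.0,
}


@dataclasses.dataclass(frozen=True)
class TmParams:
    window: int = 19
    threshold: float = 1.6
    min_core: int = 10


@dataclasses.dataclass(frozen=True)
class TmSegment:
    start_aa: int  # 1-based inclusive
    end_aa: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end_aa - self.start_aa + 1


def hydropathy_profile(protein: str, window: int = 19) -> np.ndarray:
    """Centred sliding-window mean hydropathy, one value per residue.

    Windows are truncated at the termini (the mean runs over however many
    residues actually fall inside the window).
    """
    if not protein:
        raise ValueError("empty protein")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(protein):
        raise ValueError("window exceeds protein length")
    vals = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in protein])
    n = len(vals)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def predict_tm_segments(
    protein: str, params: TmParams = TmParams()
) -> list[TmSegment]:
    """Maximal runs of profile >= threshold, at least ``min_core`` long."""
    if len(protein) < params.window:
        return []
    profile = hydropathy_profile(protein, params.window)
    above = profile >= params.threshold
    segments: list[TmSegment] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= params.min_core:
                segments.append(
                    TmSegment(
                        start_aa=i + 1,
                        end_aa=j + 1,
                        mean_hydropathy=float(profile[i : j + 1].mean()),
                    )
                )
            i = j + 1
        else:
            i += 1
    return segments


def count_tm_before(
    protein: str, boundary_aa: int, params: TmParams = TmParams()
) -> int:
    """Segments ending strictly before ``boundary_aa`` (N-terminal count).

    A segment straddling the boundary does not count.
    """
    if not 1 <= boundary_aa <= len(protein):
        raise ValueError("boundary_aa outside protein")
    return sum(
        1 for s in predict_tm_segments(protein, params) if s.end_aa < boundary_aa
    )
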