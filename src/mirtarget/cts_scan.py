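"""Candidate-target-site search over a transcript (13-mer seed scan).

The scan arranges the miRNA 5'->3' and the transcript 3'->5' (i.e. the
stored 5'->3' transcript is reversed). The seed sequence is the positionwise
Watson-Crick complement of the miRNA's first 13 bases. Every length-13
window of the arranged transcript whose Levenshtein distance to the seed is
at most 4 marks a hit; each hit is expanded around its 5'-terminal base into
a candidate target site of at most 3l bases (l = miRNA length): l bases on
the 3' side of the anchor and 2l bases from the anchor toward the 5' end,
clipped at the transcript ends.

All coordinates are 0-based half-open on the *arranged* (reversed)
transcript, where position increases toward the transcript's 5' end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib

from .seqio import LengthError, RnaSequence, watson_crick_complement

SEED_LENGTH = 13
DEFAULT_MAX_DISTANCE = 4


@dataclass(frozen=True)
class CtsWindow:
    """A matched 13-mer and its expanded candidate target site."""

    start: int          # matched 13-mer, arranged coordinates
    end: int
    distance: int       # edit distance of the 13-mer to the seed
    cts_start: int      # expanded window, arranged coordinates
    cts_end: int
    cts_seq: RnaSequence


def seed_sequence(mirna: RnaSequence | str) -> RnaSequence:
    """Watson-Crick complement of the miRNA's first 13 bases (5' end)."""
    if isinstance(mirna, str):
        mirna = RnaSequence.parse(mirna)
    if len(mirna) < SEED_LENGTH:
        raise LengthError(
            f"miRNA of length {len(mirna)} is shorter than the {SEED_LENGTH}-base seed")
    return watson_crick_complement(RnaSequence(mirna.bases[:SEED_LENGTH]))


def scan_arranged(arranged: str, seed: str, max_distance: int = DEFAULT_MAX_DISTANCE
                  ) -> list[tuple[int, int]]:
    """(offset, distance) of every length-13 window within *max_distance*."""
    hits: list[tuple[int, int]] = []
    k = len(seed)
    for i in range(len(arranged) - k + 1):
        d = edlib.align(arranged[i:i + k], seed, task="distance", k=max_distance)["editDistance"]
        if d != -1:
            hits.append((i, d))
    return hits


def find_cts(mirna: RnaSequence | str, transcript: RnaSequence | str,
             max_distance: int = DEFAULT_MAX_DISTANCE) -> list[CtsWindow]:
    """Scan a transcript (given 5'->3') for candidate target sites.

    Returns windows in ascending match start on the arranged transcript.
    Expanded intervals that coincide are collapsed, keeping the smallest
    edit distance among the merged hits. A transcript shorter than the seed
    yields no windows (with a warning).
    """
    if isinstance(mirna, str):
        mirna = RnaSequence.parse(mirna)
    if isinstance(transcript, str):
        transcript = RnaSequence.parse(transcript)
    seed = seed_sequence(mirna)
    if len(transcript) < SEED_LENGTH:
        warnings.warn(
            f"transcript of length {len(transcript)} is shorter than the seed; no windows",
            stacklevel=2)
        return []
    l = len(mirna)
    arranged = transcript.bases[::-1]
    by_interval: dict[tuple[int, int], CtsWindow] = {}
    for offset, dist in scan_arranged(arranged, seed.bases, max_distance):
        anchor = offset + SEED_LENGTH - 1          # 5'-terminal base of the match
        cts_start = max(0, anchor - l)             # l bases toward the 3' end
        cts_end = min(len(arranged), anchor + 2 * l)  # 2l bases toward the 5' end
        win = CtsWindow(
            start=offset, end=offset + SEED_LENGTH, distance=dist,
            cts_start=cts_start, cts_end=cts_end,
            cts_seq=RnaSequence(arranged[cts_start:cts_end]),
        )
        key = (cts_start, cts_end)
        kept = by_interval.get(key)
        if kept is None or dist < kept.distance:
            by_interval[key] = win
    return sorted(by_interval.values(), key=lambda w: (w.start, w.cts_start))
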