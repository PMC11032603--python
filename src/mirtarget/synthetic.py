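"""Seeded generator of labeled miRNA/CTS pairs and transcripts.

The generator emulates the statistical shape of public miRNA-target
datasets: miRNAs of ~22 uniformly random bases; candidate target sites of
3l bases in the arranged (3'->5') orientation; positives carrying a
near-complement of the miRNA's 5' seed region (up to a small substitution
budget) at the position where the transcript scanner would anchor it;
negatives produced by shuffling (mirroring negative sets built by shuffling
real mature miRNAs) or by uniform resampling. Negatives are
rejection-sampled against the seed scan itself so that no negative contains
any 13-mer within the scanner's edit-distance budget of the seed -- labels
are correct by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cts_scan import DEFAULT_MAX_DISTANCE, SEED_LENGTH, scan_arranged, seed_sequence
from .seqio import (
    RNA_BASES,
    LabeledPair,
    RnaSequence,
    watson_crick_complement,
    write_fasta,
)

_REJECTION_LIMIT = 200


@dataclass(frozen=True)
class SyntheticSpec:
    n_pairs: int = 400
    positive_fraction: float = 0.5
    mirna_length: int = 22
    cts_length: int | None = None       # default 3 * mirna_length
    complement_span: int = SEED_LENGTH  # 5'-end bases complemented into positives
    max_edits: int = 4                  # substitution budget on the implant
    negative_mode: str = "shuffle"      # "shuffle" | "random"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0,1]")
        if self.complement_span > self.mirna_length:
            raise ValueError("complement_span cannot exceed mirna_length")
        if self.complement_span < SEED_LENGTH:
            raise ValueError(f"complement_span must be >= {SEED_LENGTH}")
        if self.site_length < self.complement_span:
            raise ValueError("cts_length shorter than the implanted complement")
        if self.negative_mode not in ("shuffle", "random"):
            raise ValueError(f"unknown negative_mode {self.negative_mode!r}")
        if self.max_edits > DEFAULT_MAX_DISTANCE:
            raise ValueError(
                f"max_edits > {DEFAULT_MAX_DISTANCE} would break the positive-label guarantee")

    @property
    def site_length(self) -> int:
        return 3 * self.mirna_length if self.cts_length is None else self.cts_length


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA_BASES), size=length))


def _mutate(rng: np.random.Generator, seq: str, n_edits: int) -> str:
    """Apply n substitutions at distinct positions, each to a different base."""
    bases = list(seq)
    for pos in rng.choice(len(bases), size=n_edits, replace=False):
        options = [b for b in RNA_BASES if b != bases[pos]]
        bases[pos] = options[rng.integers(len(options))]
    return "".join(bases)


def _implant_offset(mirna_length: int) -> int:
    """Offset of the matched 13-mer inside an arranged, unclipped CTS window.

    The scanner expands a hit anchored at its 5'-terminal base with l bases
    on the 3' side, so inside the 3l window the 13-mer occupies
    [l - 12, l + 1).
    """
    return mirna_length - (SEED_LENGTH - 1)


def _is_negative(arranged_site: str, seed: str) -> bool:
    return not scan_arranged(arranged_site, seed, DEFAULT_MAX_DISTANCE)


def _make_negative_site(rng: np.random.Generator, spec: SyntheticSpec,
                        template: str, seed: str) -> str:
    for _ in range(_REJECTION_LIMIT):
        if spec.negative_mode == "shuffle":
            cand = "".join(rng.permutation(list(template)))
        else:
            cand = _random_seq(rng, spec.site_length)
        if _is_negative(cand, seed):
            return cand
    raise RuntimeError("could not rejection-sample a clean negative site")


def generate_pairs(spec: SyntheticSpec) -> list[LabeledPair]:
    """Generate a labeled pair set with exact label counts.

    Exactly floor(n_pairs * positive_fraction) positives are produced.
    Every positive contains a 13-mer within the scanner's edit budget of the
    miRNA's seed complement; every negative contains none.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_pos = int(spec.n_pairs * spec.positive_fraction)
    pairs: list[LabeledPair] = []
    offset = _implant_offset(spec.mirna_length)
    for i in range(spec.n_pairs):
        label = 1 if i < n_pos else 0
        mirna = RnaSequence(_random_seq(rng, spec.mirna_length))
        seed = seed_sequence(mirna).bases
        if label == 1:
            span = spec.complement_span
            implant = watson_crick_complement(RnaSequence(mirna.bases[:span])).bases
            n_edits = int(rng.integers(0, spec.max_edits + 1))
            implant = _mutate(rng, implant, n_edits)
            site = list(_random_seq(rng, spec.site_length))
            site[offset:offset + span] = implant
            site_str = "".join(site[:spec.site_length])
            # the mutated implant must still be inside the scan budget
            if _is_negative(site_str, seed):  # pragma: no cover - guard only
                site_str = "".join(
                    list(site_str[:offset]) + list(seed) + list(site_str[offset + SEED_LENGTH:]))
            pairs.append(LabeledPair(mirna, RnaSequence(site_str), 1))
        else:
            template = _random_seq(rng, spec.site_length)
            site_str = _make_negative_site(rng, spec, template, seed)
            pairs.append(LabeledPair(mirna, RnaSequence(site_str), 0))
    return pairs


def generate_transcripts(spec: SyntheticSpec, n_transcripts: int,
                         transcript_length: int = 200,
                         fasta_path: str | Path | None = None
                         ) -> tuple[dict[str, RnaSequence], dict[str, RnaSequence], pd.DataFrame]:
    """Generate miRNA-transcript pairs with implanted target sites.

    Half the transcripts (rounded down by positive_fraction) carry one
    implanted near-complement site at a random interior position of the
    arranged transcript; the rest are rejection-sampled to contain no
    candidate site at all. Transcripts are returned (and written) in the
    stored 5'->3' orientation; truth-table coordinates refer to the
    arranged (3'->5') transcript, matching the scanner's output.

    Returns (mirnas, transcripts, truth) where truth has one row per pair.
    """
    if transcript_length < 3 * spec.mirna_length:
        raise ValueError("transcript_length must be >= 3 * mirna_length")
    rng = np.random.default_rng([spec.rng_seed, 7])
    n_pos = int(n_transcripts * spec.positive_fraction)
    l = spec.mirna_length
    mirnas: dict[str, RnaSequence] = {}
    transcripts: dict[str, RnaSequence] = {}
    rows = []
    for i in range(n_transcripts):
        label = 1 if i < n_pos else 0
        mid, tid = f"mir_{i:04d}", f"tx_{i:04d}"
        mirna = RnaSequence(_random_seq(rng, l))
        seed = seed_sequence(mirna).bases
        implant_start = implant_end = -1
        if label == 1:
            arranged = list(_random_seq(rng, transcript_length))
            n_edits = int(rng.integers(0, spec.max_edits + 1))
            implant = _mutate(rng, seed, n_edits)
            lo = max(0, l - (SEED_LENGTH - 1))
            hi = transcript_length - 2 * l - (SEED_LENGTH - 1)
            s = int(rng.integers(lo, hi + 1))
            arranged[s:s + SEED_LENGTH] = implant
            arranged_str = "".join(arranged)
            implant_start, implant_end = s, s + SEED_LENGTH
        else:
            for _ in range(_REJECTION_LIMIT):
                arranged_str = _random_seq(rng, transcript_length)
                if _is_negative(arranged_str, seed):
                    break
            else:
                raise RuntimeError("could not rejection-sample a clean negative transcript")
        mirnas[mid] = mirna
        transcripts[tid] = RnaSequence(arranged_str[::-1])  # store 5'->3'
        rows.append({
            "mirna_id": mid, "transcript_id": tid, "label": label,
            "implant_start": implant_start, "implant_end": implant_end,
            "implant_seq": arranged_str[implant_start:implant_end] if label else "",
        })
    truth = pd.DataFrame(rows)
    if fasta_path is not None:
        write_fasta(transcripts, fasta_path)
    return mirnas, transcripts, truth


def train_val_test_split(pairs: Sequence[LabeledPair], rng_seed: int,
                         fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
                         ) -> tuple[list[LabeledPair], list[LabeledPair], list[LabeledPair]]:
    """Stratified-ish split: shuffles positives and negatives separately so
    each split keeps the label balance."""
    rng = np.random.default_rng([rng_seed, 13])
    pos = [p for p in pairs if p.label == 1]
    neg = [p for p in pairs if p.label == 0]
    out: tuple[list[LabeledPair], ...] = ([], [], [])
    for group in (pos, neg):
        idx = rng.permutation(len(group))
        n1 = int(len(group) * fractions[0])
        n2 = n1 + int(len(group) * fractions[1])
        for j, sl in enumerate((idx[:n1], idx[n1:n2], idx[n2:])):
            out[j].extend(group[k] for k in sl)
    return out
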