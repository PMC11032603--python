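"""RNA alphabet handling and file I/O.

This module owns the four-letter RNA alphabet {A, G, C, U}, the integer
encoding used by the model (1: A, 2: G, 3: C, 4: U; 0 reserved for padding),
Watson-Crick complementation, Levenshtein edit distance, and readers/writers
for FASTA files and delimited miRNA/site/label pair tables.

Normalization policy: input is uppercased and the DNA alias T is accepted as
U (public miRNA/UTR data mixes DNA and RNA alphabets). Any other character,
including N, is rejected -- the model's embedding dictionary has exactly five
entries, so there is no defined code for an ambiguous base.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_BASES = "AGCU"
#: token ids of the model's embedding dictionary; 0 is the padding symbol
BASE_TO_CODE = {"A": 1, "G": 2, "C": 3, "U": 4}
CODE_TO_BASE = {v: k for k, v in BASE_TO_CODE.items()}
_COMPLEMENT = str.maketrans("AGCU", "UCGA")


class AlphabetError(ValueError):
    """A character outside {A, G, C, U} (after normalization) was seen."""


class LengthError(ValueError):
    """A sequence does not fit a required length bound."""


class ParseError(ValueError):
    """A sequence or pair-table file is malformed."""


def normalize(raw: str) -> str:
    """Uppercase and map the DNA alias T to U; validate the alphabet.

    Raises :class:`AlphabetError` on any residual non-AGCU character and
    :class:`LengthError` on an empty string (the model has no defined
    behavior for a zero-length sequence).
    """
    bases = raw.strip().upper().replace("T", "U")
    if not bases:
        raise LengthError("empty sequence")
    bad = set(bases) - set(RNA_BASES)
    if bad:
        raise AlphabetError(f"invalid base(s) {sorted(bad)} in sequence {raw!r}")
    return bases


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over {A, G, C, U}.

    Construct with :meth:`parse` to apply normalization; the plain
    constructor expects already-normalized bases and re-validates them.
    """

    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", normalize(self.bases))

    @classmethod
    def parse(cls, raw: str) -> "RnaSequence":
        return cls(normalize(raw))

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def reverse(self) -> "RnaSequence":
        """The same bases read in the opposite orientation."""
        return RnaSequence(self.bases[::-1])


@dataclass(frozen=True)
class LabeledPair:
    """A labeled miRNA / candidate-target-site sample pair."""

    mirna: RnaSequence
    site: RnaSequence
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ParseError(f"label must be 0 or 1, got {self.label!r}")


def encode_sequence(seq: RnaSequence | str, pad_to: int) -> np.ndarray:
    """Integer-encode *seq* and zero-pad it on the right to length *pad_to*.

    A -> 1, G -> 2, C -> 3, U -> 4; positions past the sequence end are 0
    (the padding token, which carries its own learned embedding).
    """
    if isinstance(seq, str):
        seq = RnaSequence.parse(seq)
    if len(seq) > pad_to:
        raise LengthError(f"sequence of length {len(seq)} exceeds pad_to={pad_to}")
    codes = np.zeros(pad_to, dtype=np.int64)
    codes[: len(seq)] = [BASE_TO_CODE[b] for b in seq.bases]
    return codes


def decode_sequence(codes: Iterable[int]) -> RnaSequence:
    """Invert :func:`encode_sequence`, dropping trailing padding zeros."""
    bases = []
    for c in codes:
        if c == 0:
            break
        try:
            bases.append(CODE_TO_BASE[int(c)])
        except KeyError:
            raise AlphabetError(f"invalid code {c}") from None
    return RnaSequence("".join(bases))


def watson_crick_complement(seq: RnaSequence | str) -> RnaSequence:
    """Positionwise Watson-Crick complement (A<->U, G<->C), order preserved.

    No reversal is applied; orientation bookkeeping belongs to the caller
    (the transcript scanner works on an explicitly arranged transcript).
    """
    if isinstance(seq, str):
        seq = RnaSequence.parse(seq)
    return RnaSequence(seq.bases.translate(_COMPLEMENT))


def edit_distance(a: RnaSequence | str, b: RnaSequence | str) -> int:
    """Levenshtein distance: minimum insertions, deletions or substitutions."""
    sa = a.bases if isinstance(a, RnaSequence) else str(a)
    sb = b.bases if isinstance(b, RnaSequence) else str(b)
    if not sa or not sb:
        return max(len(sa), len(sb))
    return edlib.align(sa, sb, task="distance")["editDistance"]


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ("mirna_seq", "site_seq", "label")


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_pair_table(path: str | Path, delimiter: str | None = None) -> list[LabeledPair]:
    """Read a delimited (TSV/CSV) table of (mirna_seq, site_seq, label) rows.

    The delimiter is auto-detected among tab and comma unless given. Columns
    are located by header name when a header row is present, otherwise by
    position. Every row is validated; a malformed row raises
    :class:`ParseError` carrying its line number.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    start_line = 1
    first = [str(x).strip().lower() for x in df.iloc[0]]
    if set(PAIR_COLUMNS) <= set(first):
        order = [first.index(c) for c in PAIR_COLUMNS]
        df = df.iloc[1:, order]
        start_line = 2
    elif df.shape[1] < 3:
        raise ParseError(f"{path}: expected 3 columns, found {df.shape[1]}")
    else:
        df = df.iloc[:, :3]
    pairs: list[LabeledPair] = []
    for offset, row in enumerate(df.itertuples(index=False)):
        lineno = start_line + offset
        mirna_raw, site_raw, label_raw = row
        try:
            label = int(str(label_raw).strip())
            pairs.append(LabeledPair(RnaSequence.parse(mirna_raw), RnaSequence.parse(site_raw), label))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return pairs


def write_pair_table(pairs: Sequence[LabeledPair], path: str | Path,
                     header_lines: Sequence[str] = ()) -> None:
    """Write pairs as a TSV with a header row (and optional # comment lines)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(f"{p.mirna}\t{p.site}\t{p.label}\n")


def read_fasta(path: str | Path) -> dict[str, RnaSequence]:
    """Read a multi-record FASTA into {record id: RnaSequence}."""
    records: dict[str, RnaSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records[rec.id] = RnaSequence.parse(str(rec.seq))
        except ValueError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: dict[str, RnaSequence | str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(str(seq)), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def pairs_to_frame(pairs: Sequence[LabeledPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_seq": [str(p.mirna) for p in pairs],
            "site_seq": [str(p.site) for p in pairs],
            "label": [p.label for p in pairs],
        }
    )
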