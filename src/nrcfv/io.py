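"""Alignment container and FASTA / relaxed-PHYLIP readers and writers.

The :class:`Alignment` stores a rectangular n-taxa × p-columns character
matrix as uint8 state codes (missing cells hold the sentinel
:data:`~nrcfv.alphabets.MISSING`), together with taxon labels and the
alphabet.  Columns are 0-based half-open internally; user-facing messages
use 1-based inclusive coordinates.

Supported formats: multi-record FASTA (wrapped or unwrapped) and relaxed
PHYLIP (whitespace-delimited names of any length, sequential or
interleaved).  ``format="auto"`` decides by the first non-blank byte:
FASTA iff it is ``>``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabets import MISSING, Alphabet, AlphabetError, detect_alphabet


class AlignmentError(ValueError):
    """Base class for alignment input problems."""


class FormatError(AlignmentError):
    """Unparseable or empty input."""


class ShapeError(AlignmentError):
    """Ragged rows or otherwise non-rectangular input."""


class LabelError(AlignmentError):
    """Duplicate or invalid taxon labels."""


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment.

    ``codes[i, j]`` is the canonical state index of taxon ``i`` at column
    ``j``, or :data:`MISSING` for gaps/ambiguities.
    """

    taxa: list[str]
    codes: np.ndarray
    alphabet: Alphabet

    def __post_init__(self) -> None:
        self.taxa = [" ".join(str(t).split()) for t in self.taxa]
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise LabelError(f"duplicate taxon labels: {dupes}")
        if any(not t for t in self.taxa):
            raise LabelError("empty taxon label")
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ShapeError(
                f"code matrix shape {self.codes.shape} does not match "
                f"{len(self.taxa)} taxa"
            )
        if self.n_taxa < 2:
            raise ShapeError("an alignment needs at least 2 taxa")
        if self.n_columns < 1:
            raise ShapeError("an alignment needs at least 1 column")
        valid = (self.codes < self.alphabet.n_states) | (self.codes == MISSING)
        if not valid.all():
            raise ShapeError("code matrix contains out-of-range state codes")

    # -- shape -----------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean n×p mask, True where a cell is missing."""
        return self.codes == MISSING

    # -- conversion ------------------------------------------------------
    @classmethod
    def from_sequences(
        cls,
        taxa: Sequence[str],
        sequences: Sequence[str],
        alphabet: Alphabet | None = None,
    ) -> "Alignment":
        """Build an alignment from raw strings, canonicalizing characters.

        With ``alphabet=None`` the alphabet is auto-detected (DNA vs
        protein) from the pooled character content.
        """
        if len(taxa) != len(sequences):
            raise ShapeError("taxa and sequences differ in number")
        if not sequences:
            raise FormatError("no sequences given")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ShapeError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        if alphabet is None:
            alphabet = detect_alphabet(sequences)
        rows = []
        for taxon, seq in zip(taxa, sequences):
            try:
                rows.append(alphabet.encode(seq))
            except AlphabetError as exc:
                raise AlignmentError(f"taxon {taxon!r}: {exc}") from None
        return cls(list(taxa), np.vstack(rows), alphabet)

    def sequences(self) -> list[str]:
        """Decode rows back to canonical strings (missing → '-')."""
        return [self.alphabet.decode(row) for row in self.codes]

    def copy(self) -> "Alignment":
        return replace(self, taxa=list(self.taxa), codes=self.codes.copy())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _sniff_format(text: str) -> str:
    for ch in text:
        if not ch.isspace():
            return "fasta" if ch == ">" else "phylip"
    raise FormatError("empty file")


def _parse_fasta(text: str) -> tuple[list[str], list[str]]:
    import io as _io

    records = list(SimpleFastaParser(_io.StringIO(text)))
    if not records:
        raise FormatError("no FASTA records found")
    taxa = [title.split()[0] if title.split() else title for title, _ in records]
    seqs = [seq.replace(" ", "") for _, seq in records]
    return taxa, seqs


def _parse_phylip(text: str) -> tuple[list[str], list[str]]:
    """Parse relaxed PHYLIP, accepting sequential and interleaved layouts."""
    lines = text.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if line.strip():
            header_idx = i
            break
    if header_idx is None:
        raise FormatError("empty file")
    header = lines[header_idx].split()
    if len(header) < 2:
        raise FormatError(f"bad PHYLIP header: {lines[header_idx]!r}")
    try:
        n, p = int(header[0]), int(header[1])
    except ValueError:
        raise FormatError(f"bad PHYLIP header: {lines[header_idx]!r}") from None
    if n < 1 or p < 1:
        raise FormatError(f"bad PHYLIP dimensions: {n} x {p}")
    body = lines[header_idx + 1:]

    taxa, seqs = _phylip_sequential(body, n, p)
    if taxa is None:
        taxa, seqs = _phylip_interleaved(body, n, p)
    if taxa is None:
        raise FormatError(
            "could not parse PHYLIP body as sequential or interleaved "
            f"({n} taxa x {p} columns expected)"
        )
    return taxa, seqs


def _phylip_sequential(body: list[str], n: int, p: int):
    """Greedy sequential parse: name token, then sequence tokens until p."""
    tokens: list[str] = []
    for line in body:
        tokens.extend(line.split())
    taxa: list[str] = []
    seqs: list[str] = []
    it = iter(tokens)
    try:
        for _ in range(n):
            name = next(it)
            chunks: list[str] = []
            total = 0
            while total < p:
                piece = next(it)
                chunks.append(piece)
                total += len(piece)
            if total != p:
                return None, None
            taxa.append(name)
            seqs.append("".join(chunks))
    except StopIteration:
        return None, None
    if any(True for _ in it):  # leftover tokens → not sequential
        return None, None
    return taxa, seqs


def _phylip_interleaved(body: list[str], n: int, p: int):
    """First block carries names; later blocks are bare continuations."""
    rows = [ln for ln in body if ln.strip()]
    if len(rows) < n or len(rows) % n != 0:
        return None, None
    taxa: list[str] = []
    parts: list[list[str]] = [[] for _ in range(n)]
    for i, line in enumerate(rows[:n]):
        fields = line.split()
        if len(fields) < 2:
            return None, None
        taxa.append(fields[0])
        parts[i].append("".join(fields[1:]))
    for block_start in range(n, len(rows), n):
        for i in range(n):
            parts[i].append("".join(rows[block_start + i].split()))
    seqs = ["".join(chunks) for chunks in parts]
    if any(len(s) != p for s in seqs):
        return None, None
    return taxa, seqs


def read_alignment(
    path: str | Path,
    format: str = "auto",
    alphabet: Alphabet | None = None,
) -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment from ``path``.

    Characters are upper-cased and canonicalized (DNA ``U``→``T``);
    missing codes become the missing sentinel.  Unrecognized characters
    raise an error naming taxon, column and character.
    """
    text = Path(path).read_text()
    fmt = format
    if fmt == "auto":
        fmt = _sniff_format(text)
    if fmt == "fasta":
        taxa, seqs = _parse_fasta(text)
    elif fmt == "phylip":
        taxa, seqs = _parse_phylip(text)
    else:
        raise ValueError(f"unknown format {format!r}")
    aln = Alignment.from_sequences(taxa, seqs, alphabet)
    return aln


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_alignment(
    aln: Alignment, path: str | Path, format: str = "fasta", wrap: int = 70
) -> None:
    """Write ``aln`` to ``path`` as FASTA or relaxed sequential PHYLIP.

    Round-trip guarantee: reading the written file reproduces taxa,
    matrix and shape exactly (missing cells are emitted as ``-``).
    """
    seqs = aln.sequences()
    out: list[str] = []
    if format == "fasta":
        for taxon, seq in zip(aln.taxa, seqs):
            out.append(f">{taxon}")
            if wrap:
                out.extend(seq[i:i + wrap] for i in range(0, len(seq), wrap))
            else:
                out.append(seq)
    elif format == "phylip":
        out.append(f"{aln.n_taxa} {aln.n_columns}")
        width = max(len(t) for t in aln.taxa)
        for taxon, seq in zip(aln.taxa, seqs):
            safe = taxon.replace(" ", "_")
            out.append(f"{safe:<{width}}  {seq}")
    else:
        raise ValueError(f"unknown format {format!r}")
    Path(path).write_text("\n".join(out) + "\n")
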