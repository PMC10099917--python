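"""Character-state alphabets with explicit missing-data semantics.

An :class:`Alphabet` fixes the universe of canonical character states (the
``c`` of the normalization formulas) and declares which input characters are
treated as *missing*.  Following common phylogenomic practice, missing data
comprises gaps (``-``), unknowns (``?``, ``.``) and IUPAC ambiguity codes:
a cell that does not pin down a single state carries no compositional
information and is excluded from frequency calculations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: Integer sentinel used for missing cells in encoded alignments.
MISSING: int = 255

_INVALID: int = 254

#: Character emitted for missing cells when writing alignments.
GAP_CHAR: str = "-"

#: Missing codes shared by every alphabet.
UNIVERSAL_MISSING = frozenset("-?.")


class AlphabetError(ValueError):
    """Raised for malformed alphabet definitions or undetectable data."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of canonical single-character states.

    Parameters
    ----------
    name:
        Short label ("dna", "protein", "binary", "custom", ...).
    states:
        Ordered, unique canonical states. ``len(states)`` is the state
        count ``c`` used by the normalized metrics.
    missing_codes:
        Characters mapped to the missing sentinel (disjoint from states).
    canonicalization:
        Extra accepted input characters mapped to a canonical state,
        e.g. ``{"U": "T"}`` so RNA input folds onto the 4-state DNA
        alphabet. Input is upper-cased before this map applies.
    """

    name: str
    states: tuple[str, ...]
    missing_codes: frozenset[str] = field(default=UNIVERSAL_MISSING)
    canonicalization: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise AlphabetError("an alphabet needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise AlphabetError("alphabet states must be unique")
        if any(len(s) != 1 for s in self.states):
            raise AlphabetError("states must be single characters")
        overlap = set(self.states) & set(self.missing_codes)
        if overlap:
            raise AlphabetError(
                f"missing codes overlap with states: {sorted(overlap)}"
            )
        for src, dst in self.canonicalization.items():
            if dst not in self.states:
                raise AlphabetError(
                    f"canonicalization target {dst!r} is not a state"
                )
            if src in self.states:
                raise AlphabetError(
                    f"canonicalization source {src!r} shadows a state"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def _lut(self) -> np.ndarray:
        """256-entry char-code → state-code lookup table (cached per instance)."""
        cached = self.__dict__.get("_lut_cache")
        if cached is not None:
            return cached
        lut = np.full(256, _INVALID, dtype=np.uint8)

        def put(ch: str, code: int) -> None:
            lut[ord(ch.upper())] = code
            lut[ord(ch.lower())] = code

        for idx, st in enumerate(self.states):
            put(st, idx)
        for src, dst in self.canonicalization.items():
            put(src, self.states.index(dst))
        for mc in self.missing_codes:
            o = ord(mc)
            lut[o] = MISSING
            if mc.upper() != mc or mc.lower() != mc:
                put(mc, MISSING)
        object.__setattr__(self, "_lut_cache", lut)
        return lut

    def encode(self, seq: str) -> np.ndarray:
        """Encode a sequence string to uint8 state codes.

        Unrecognized characters raise :class:`AlphabetError` naming the
        1-based column and the offending character.
        """
        try:
            raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        except UnicodeEncodeError as exc:
            raise AlphabetError(f"non-ASCII character in sequence: {exc}") from None
        codes = self._lut()[raw]
        bad = np.nonzero(codes == _INVALID)[0]
        if bad.size:
            col = int(bad[0])
            raise AlphabetError(
                f"unrecognized character {seq[col]!r} at column {col + 1} "
                f"for alphabet {self.name!r}"
            )
        return codes

    def decode(self, codes: np.ndarray) -> str:
        """Decode uint8 state codes back to a string (missing → '-')."""
        out = np.full(codes.shape, GAP_CHAR, dtype="<U1")
        for idx, st in enumerate(self.states):
            out[codes == idx] = st
        return "".join(out.tolist())


#: IUPAC nucleotide ambiguity letters (treated as missing).
DNA_AMBIGUITY = frozenset("NRYSWKMBDHV")

DNA = Alphabet(
    name="dna",
    states=("A", "C", "G", "T"),
    missing_codes=UNIVERSAL_MISSING | DNA_AMBIGUITY,
    canonicalization={"U": "T"},
)

#: Protein ambiguity letters (B=D/N, Z=E/Q, J=I/L, X=any) plus stop '*'.
PROTEIN_AMBIGUITY = frozenset("XBZJ*")

PROTEIN = Alphabet(
    name="protein",
    states=tuple("ACDEFGHIKLMNPQRSTVWY"),
    missing_codes=UNIVERSAL_MISSING | PROTEIN_AMBIGUITY,
)

BINARY = Alphabet(name="binary", states=("0", "1"))


def custom_alphabet(
    states: Iterable[str],
    missing_codes: Iterable[str] = UNIVERSAL_MISSING,
    name: str = "custom",
    canonicalization: Mapping[str, str] | None = None,
) -> Alphabet:
    """Build a user-defined alphabet (e.g. for recoded or morphological data)."""
    return Alphabet(
        name=name,
        states=tuple(states),
        missing_codes=frozenset(missing_codes),
        canonicalization=dict(canonicalization or {}),
    )


_DNA_CHARS = frozenset("ACGT") | DNA_AMBIGUITY


def detect_alphabet(sequences: Iterable[str]) -> Alphabet:
    """Guess DNA vs protein from raw sequence strings.

    The non-missing character set (upper-cased, with U folded onto T) is
    compared against the nucleotide universe including IUPAC ambiguity
    letters; anything outside it is classed as protein.
    """
    chars: set[str] = set()
    for seq in sequences:
        chars.update(seq.upper())
    chars -= UNIVERSAL_MISSING
    chars.discard("*")
    if "U" in chars:
        chars.discard("U")
        chars.add("T")
    if not chars:
        raise AlphabetError("cannot detect alphabet: all characters are missing")
    if chars <= _DNA_CHARS:
        return DNA
    return PROTEIN
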