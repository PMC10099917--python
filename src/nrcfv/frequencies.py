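"""Per-taxon state counts and relative frequencies.

For taxon *i* and state *j*, ``counts[i, j]`` is the occurrence count
O_ij over the taxon's non-missing cells, ``freqs[i, j]`` the relative
frequency μ_ij = O_ij / (non-missing length of taxon i), and
``mean_freqs[j]`` the unweighted dataset mean μ̄_j = Σ_i μ_ij / n.

Missing cells are excluded throughout: using the per-taxon non-missing
count as the denominator is what makes the downstream heterogeneity
metrics robust to gaps.  With complete data it coincides with dividing
by the column count p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabets import MISSING, Alphabet
from .io import Alignment


class DegenerateTaxonError(ValueError):
    """A taxon has zero non-missing cells and carries no information."""


class GroupDefinitionError(ValueError):
    """Overlapping, empty or unknown-state character groups."""


@dataclass
class FrequencyTable:
    """Counts and relative frequencies of character states per taxon."""

    taxa: list[str]
    states: tuple[str, ...]
    counts: np.ndarray            # n × c, int64
    freqs: np.ndarray             # n × c, rows sum to 1
    mean_freqs: np.ndarray        # length c
    effective_lengths: np.ndarray  # per-taxon non-missing cell count
    n_columns: int
    alphabet: Alphabet | None = None
    #: False when built from a partial state grouping, in which case row
    #: frequencies are fractions of effective length and need not sum to 1.
    complete: bool = True

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_states(self) -> int:
        return self.counts.shape[1]

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise GroupDefinitionError(
                f"unknown state {state!r}; known: {list(self.states)}"
            ) from None

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None


def tabulate(aln: Alignment) -> FrequencyTable:
    """Tally per-taxon state counts and frequencies for an alignment."""
    n, c = aln.n_taxa, aln.alphabet.n_states
    codes = aln.codes.astype(np.int64)
    valid = codes != MISSING
    eff = valid.sum(axis=1)
    if (eff == 0).any():
        bad = [aln.taxa[i] for i in np.nonzero(eff == 0)[0]]
        raise DegenerateTaxonError(
            f"taxa with zero non-missing cells: {bad}"
        )
    flat = (codes + np.arange(n)[:, None] * c)[valid]
    counts = np.bincount(flat, minlength=n * c).reshape(n, c)
    freqs = counts / eff[:, None]
    return FrequencyTable(
        taxa=list(aln.taxa),
        states=aln.alphabet.states,
        counts=counts,
        freqs=freqs,
        mean_freqs=freqs.mean(axis=0),
        effective_lengths=eff,
        n_columns=aln.n_columns,
        alphabet=aln.alphabet,
    )


# ---------------------------------------------------------------------------
# State groupings (purines/pyrimidines, AT/GC, amino-acid classes, ...)
# ---------------------------------------------------------------------------

#: Purine / pyrimidine (RY) recoding of nucleotides.
PURINE_PYRIMIDINE: dict[str, tuple[str, ...]] = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
}

#: AT vs GC content grouping.
AT_GC: dict[str, tuple[str, ...]] = {
    "AT": ("A", "T"),
    "GC": ("G", "C"),
}

#: Hydrophobic amino-acid class.
HYDROPHOBIC: dict[str, tuple[str, ...]] = {
    "hydrophobic": tuple("AWMILFP"),
}

GROUP_PRESETS: dict[str, dict[str, tuple[str, ...]]] = {
    "purines": {"R": PURINE_PYRIMIDINE["R"]},
    "pyrimidines": {"Y": PURINE_PYRIMIDINE["Y"]},
    "ry": PURINE_PYRIMIDINE,
    "atgc": AT_GC,
    "hydrophobic": HYDROPHOBIC,
}


def collapse_states(
    ft: FrequencyTable, groups: Mapping[str, Iterable[str]]
) -> FrequencyTable:
    """Sum counts and frequencies of member states into named groups.

    Groups must be disjoint, non-empty subsets of the table's states.
    If they partition the full alphabet, the result is a complete table
    (rows sum to 1); otherwise the grouped frequencies remain fractions
    of the per-taxon effective length, so e.g. the "purine frequency" is
    (O_A + O_G) / effective_length.
    """
    if not groups:
        raise GroupDefinitionError("no groups given")
    seen: set[int] = set()
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name, members in groups.items():
        members = list(members)
        if not members:
            raise GroupDefinitionError(f"group {name!r} is empty")
        idx = [ft.state_index(m) for m in members]
        overlap = seen & set(idx)
        if overlap:
            raise GroupDefinitionError(
                f"group {name!r} overlaps a previous group on states "
                f"{[ft.states[i] for i in sorted(overlap)]}"
            )
        seen.update(idx)
        names.append(name)
        cols.append(np.asarray(idx))
    counts = np.stack([ft.counts[:, c].sum(axis=1) for c in cols], axis=1)
    freqs = np.stack([ft.freqs[:, c].sum(axis=1) for c in cols], axis=1)
    complete = len(seen) == ft.n_states
    return FrequencyTable(
        taxa=list(ft.taxa),
        states=tuple(names),
        counts=counts,
        freqs=freqs,
        mean_freqs=freqs.mean(axis=0),
        effective_lengths=ft.effective_lengths.copy(),
        n_columns=ft.n_columns,
        alphabet=None,
        complete=complete,
    )


def load_groups(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read group definitions from JSON or simple ``name = A,C`` lines."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        raw = json.loads(text)
        return {str(k): tuple(v) for k, v in raw.items()}
    groups: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise GroupDefinitionError(
                f"line {lineno}: expected 'name = STATES', got {line!r}"
            )
        name, _, rhs = line.partition("=")
        members = tuple(
            m.strip() for m in rhs.replace(",", " ").split() if m.strip()
        )
        groups[name.strip()] = members
    if not groups:
        raise GroupDefinitionError(f"no group definitions found in {path}")
    return groups
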