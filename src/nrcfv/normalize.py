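"""Size-normalized RCFV variants (nRCFV, ntsRCFV, ncsRCFV).

Raw RCFV values shrink as alignments grow, because any one compositional
difference is diluted over more columns and taxa.  The normalized family
divides by an empirically fitted size constant:

    nRCFV   = RCFV   / (p^-0.5 · n^0.01 · c · 100)
    ntsRCFV = tsRCFV / (p^-0.5 · n^-1   · c · 100)
    ncsRCFV = csRCFV / (p^-0.5          · 100)

with p the number of positions, n the number of taxa and c the number of
possible character states (4 for nucleotides, 20 for amino acids, 2 for
RY/binary recodings; group metrics use the collapsed state count).  The
exponents are published constants and are deliberately not refit here.

A consequence of normalizing each family member with its own constant is
that the normalized components no longer sum to the normalized total.
"""

from __future__ import annotations

from typing import Mapping

from .frequencies import FrequencyTable
from .io import Alignment
from .metrics import MetricResult, compute_metrics


def _check(p: float, n: float | None = None, c: float | None = None) -> None:
    if p < 1:
        raise ValueError(f"number of positions must be >= 1, got {p}")
    if n is not None and n < 2:
        raise ValueError(f"number of taxa must be >= 2, got {n}")
    if c is not None and c < 2:
        raise ValueError(f"number of character states must be >= 2, got {c}")


def nrcfv(rcfv: float, p: int, n: int, c: int) -> float:
    """Normalized total RCFV: rcfv · √p / (n^0.01 · c · 100)."""
    _check(p, n, c)
    if rcfv < 0:
        raise ValueError("RCFV must be non-negative")
    return rcfv / (p ** -0.5 * n ** 0.01 * c * 100.0)


def nts_rcfv(tsrcfv: float, p: int, n: int, c: int) -> float:
    """Normalized taxon-specific RCFV: tsrcfv · √p · n / (c · 100)."""
    _check(p, n, c)
    if tsrcfv < 0:
        raise ValueError("tsRCFV must be non-negative")
    return tsrcfv / (p ** -0.5 * n ** -1.0 * c * 100.0)


def ncs_rcfv(csrcfv: float, p: int) -> float:
    """Normalized character-specific RCFV: csrcfv · √p / 100.

    Deliberately independent of n and c: a single (possibly grouped)
    frequency is compared, so only the number of positions matters.  The
    same formula applies to single states and to grouped states.
    """
    _check(p)
    if csrcfv < 0:
        raise ValueError("csRCFV must be non-negative")
    return csrcfv / (p ** -0.5 * 100.0)


def normalize_all(mr: MetricResult) -> MetricResult:
    """Populate the normalized fields of a MetricResult in place.

    Raw fields are untouched; calling twice is a no-op beyond the first.
    Returns ``mr`` for chaining.
    """
    p, n, c = mr.n_columns, mr.n_taxa, mr.n_states
    mr.nrcfv = nrcfv(mr.rcfv, p, n, c)
    mr.nts_rcfv = {t: nts_rcfv(v, p, n, c) for t, v in mr.ts_rcfv.items()}
    mr.ncs_rcfv = {s: ncs_rcfv(v, p) for s, v in mr.cs_rcfv.items()}
    mr.group_ncs_rcfv = {g: ncs_rcfv(v, p) for g, v in mr.group_cs_rcfv.items()}
    return mr


def analyze(
    source: Alignment | FrequencyTable,
    groups: Mapping[str, tuple[str, ...]] | None = None,
) -> MetricResult:
    """One-stop computation of raw and normalized RCFV family metrics."""
    return normalize_all(compute_metrics(source, groups=groups))
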