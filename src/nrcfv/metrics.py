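"""Relative Composition Frequency Variability (RCFV) and its components.

RCFV measures compositional heterogeneity of an alignment as the mean
absolute deviation of per-taxon state frequencies from the dataset mean,

    RCFV = Σ_i Σ_j |μ_ij − μ̄_j| / n ,

summed over the n taxa and the alphabet's m states.  Restricting the sum
to one state j gives the character-specific component csRCFV_j; to one
taxon i, the taxon-specific component tsRCFV_i.  By construction the
components each sum back to the total, so a single division gives the
percentage a state or taxon contributes to overall heterogeneity.

The module also exposes the closed-form prediction for how a single
character substitution shifts these quantities, which serves as an
analytic oracle for the metric's dependence on alignment size: in a
complete-data alignment of n taxa and p columns, one cell changing from
state a to state g moves the dataset means μ̄_a, μ̄_g by ±1/(n·p) and the
affected taxon's deviations by (n−1)/(n·p), so the metric's sensitivity
to any single change vanishes as alignments grow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .frequencies import FrequencyTable, collapse_states, tabulate
from .io import Alignment


def _deviations(ft: FrequencyTable) -> np.ndarray:
    return np.abs(ft.freqs - ft.mean_freqs[None, :])


def rcfv_total(ft: FrequencyTable) -> float:
    """Total RCFV: Σ_i Σ_j |μ_ij − μ̄_j| / n."""
    return float(_deviations(ft).sum() / ft.n_taxa)


def cs_rcfv_all(ft: FrequencyTable) -> dict[str, float]:
    """Character-specific RCFV for every state, as a dict."""
    vals = _deviations(ft).sum(axis=0) / ft.n_taxa
    return dict(zip(ft.states, vals.tolist()))


def ts_rcfv_all(ft: FrequencyTable) -> dict[str, float]:
    """Taxon-specific RCFV for every taxon, as a dict."""
    vals = _deviations(ft).sum(axis=1) / ft.n_taxa
    return dict(zip(ft.taxa, vals.tolist()))


def cs_rcfv(ft: FrequencyTable, state: str) -> float:
    """csRCFV for one state (or group name on a collapsed table)."""
    j = ft.state_index(state)
    return float(_deviations(ft)[:, j].sum() / ft.n_taxa)


def ts_rcfv(ft: FrequencyTable, taxon: str) -> float:
    """tsRCFV for one taxon."""
    i = ft.taxon_index(taxon)
    return float(_deviations(ft)[i, :].sum() / ft.n_taxa)


@dataclass(frozen=True)
class PerturbationPrediction:
    """Frequency-deviation shifts caused by one cell substitution.

    ``affected_shift`` = (n−1)/(n·p) applies to the changed taxon's two
    touched states; ``background_shift`` = 1/(n·p) to every other taxon's
    deviation for those states (via the moved dataset mean).
    """

    n_taxa: int
    n_columns: int
    affected_shift: float
    background_shift: float


def predict_single_change(n: int, p: int) -> PerturbationPrediction:
    """Closed-form size sensitivity of RCFV to a single substitution."""
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if p < 1:
        raise ValueError("need at least 1 column")
    return PerturbationPrediction(
        n_taxa=n,
        n_columns=p,
        affected_shift=(n - 1) / (n * p),
        background_shift=1.0 / (n * p),
    )


@dataclass
class MetricResult:
    """RCFV family values for one alignment (raw, plus normalized twins).

    The normalized fields are populated by
    :func:`nrcfv.normalize.normalize_all`; they are ``None`` until then.
    """

    rcfv: float
    cs_rcfv: dict[str, float]
    ts_rcfv: dict[str, float]
    n_taxa: int
    n_columns: int
    n_states: int
    group_cs_rcfv: dict[str, float] = field(default_factory=dict)
    nrcfv: float | None = None
    ncs_rcfv: dict[str, float] | None = None
    nts_rcfv: dict[str, float] | None = None
    group_ncs_rcfv: dict[str, float] | None = None

    def contribution_pct(self, state: str) -> float:
        """Percentage of total RCFV contributed by one state.

        E.g. with RCFV = 0.1 and csRCFV(A) = 0.025, A contributes 25%.
        """
        if self.rcfv == 0.0:
            raise ZeroDivisionError("total RCFV is zero; contributions undefined")
        pool = self.cs_rcfv if state in self.cs_rcfv else self.group_cs_rcfv
        return 100.0 * pool[state] / self.rcfv

    def taxon_contribution_pct(self, taxon: str) -> float:
        """Percentage of total RCFV contributed by one taxon."""
        if self.rcfv == 0.0:
            raise ZeroDivisionError("total RCFV is zero; contributions undefined")
        return 100.0 * self.ts_rcfv[taxon] / self.rcfv


def compute_metrics(
    source: Alignment | FrequencyTable,
    groups: Mapping[str, tuple[str, ...]] | None = None,
) -> MetricResult:
    """Compute raw RCFV, csRCFV and tsRCFV for an alignment or table.

    ``groups`` optionally adds grouped-state csRCFV values (computed on
    the collapsed table, so e.g. csRCFV of purines uses the summed A+G
    frequency as one state).
    """
    ft = source if isinstance(source, FrequencyTable) else tabulate(source)
    result = MetricResult(
        rcfv=rcfv_total(ft),
        cs_rcfv=cs_rcfv_all(ft),
        ts_rcfv=ts_rcfv_all(ft),
        n_taxa=ft.n_taxa,
        n_columns=ft.n_columns,
        n_states=ft.n_states,
    )
    if groups:
        collapsed = collapse_states(ft, groups)
        result.group_cs_rcfv = cs_rcfv_all(collapsed)
    return result
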