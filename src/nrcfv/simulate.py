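"""Synthetic alignments for studying size and missing-data effects.

The generator draws every cell i.i.d. from a fixed stationary state
distribution, which makes the alignments compositionally homogeneous *in
expectation*: any nonzero RCFV is pure multinomial sampling noise.  That
is exactly the property needed to isolate how alignment size (taxa n,
columns p) biases the raw metric — the noise shrinks as 1/√p — while the
normalized metric should stay flat.  Tree-based simulation (GTR/WAG
along random phylogenies) is deliberately out of scope: for composition
it has the same expectation and is radically more expensive.

Three experiment helpers are provided:

* :func:`run_bias_study` sweeps an (n, p) grid with replicated
  homogeneous simulation and fits the trend of mean RCFV / nRCFV
  against p and n.
* :func:`apply_missingness` knocks out an exact fraction of cells.
* :func:`mimic_pair` re-simulates a template alignment from its own
  per-taxon composition, once copying the template's missing-data mask
  ("gapped") and once gap-free ("ungapped"), so the pair differs only by
  the mask — the design used to show missing data does not bias RCFV.

Determinism: every operation is a pure function of (inputs, seed).  A
study-level seed expands to per-replicate substreams as ``seed + k`` with
``k`` enumerating (grid cell, replicate) pairs in order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabets import MISSING, Alphabet, DNA
from .frequencies import tabulate
from .io import Alignment
from .metrics import rcfv_total
from .normalize import nrcfv


def _taxon_names(n: int) -> list[str]:
    return [f"t{i + 1:04d}" for i in range(n)]


@dataclass
class SimulationConfig:
    """Settings for one homogeneous simulation cell."""

    n_taxa: int
    n_columns: int
    alphabet: Alphabet = DNA
    state_frequencies: np.ndarray | None = None  # default: uniform
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_columns < 1:
            raise ValueError("need n_taxa >= 2 and n_columns >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        c = self.alphabet.n_states
        if self.state_frequencies is None:
            self.state_frequencies = np.full(c, 1.0 / c)
        self.state_frequencies = np.asarray(self.state_frequencies, dtype=float)
        if self.state_frequencies.shape != (c,):
            raise ValueError(
                f"state_frequencies must have length {c}, "
                f"got shape {self.state_frequencies.shape}"
            )
        if (self.state_frequencies < 0).any():
            raise ValueError("state_frequencies must be non-negative")
        if abs(self.state_frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("state_frequencies must sum to 1")


def _draw_codes(
    n: int, p: int, freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    c = len(freqs)
    if np.allclose(freqs, 1.0 / c):
        return rng.integers(0, c, size=(n, p), dtype=np.uint8)
    # inverse-CDF draw; much faster than rng.choice for large matrices
    cdf = np.cumsum(freqs)
    cdf[-1] = 1.0
    u = rng.random(size=(n, p))
    return np.searchsorted(cdf, u, side="right").astype(np.uint8)


def simulate_homogeneous(cfg: SimulationConfig) -> Alignment:
    """Draw one alignment with every cell i.i.d. from the stationary frequencies."""
    rng = np.random.default_rng(cfg.seed)
    codes = _draw_codes(cfg.n_taxa, cfg.n_columns, cfg.state_frequencies, rng)
    return Alignment(_taxon_names(cfg.n_taxa), codes, cfg.alphabet)


@dataclass
class BiasStudyResult:
    """Replicated RCFV / nRCFV values over an (n, p) grid, with trends.

    ``replicates`` has one row per simulated alignment; ``summary`` one
    row per grid cell; ``trends`` the OLS slope of the cell-mean metric
    against p and against n.
    """

    replicates: pd.DataFrame
    summary: pd.DataFrame
    trends: pd.DataFrame
    seed: int

    def write_tsv(self, out_dir: str | Path, prefix: str = "bias_study") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.replicates.to_csv(out / f"{prefix}_replicates.tsv", sep="\t", index=False)
        self.summary.to_csv(out / f"{prefix}_summary.tsv", sep="\t", index=False)
        self.trends.to_csv(out / f"{prefix}_trends.tsv", sep="\t", index=False)


def run_bias_study(
    grid: Sequence[tuple[int, int]],
    alphabet: Alphabet = DNA,
    state_frequencies: np.ndarray | None = None,
    replicates: int = 100,
    seed: int = 0,
) -> BiasStudyResult:
    """Replicated homogeneous simulation over a grid of (n_taxa, n_columns).

    Requires at least two distinct taxon counts and two distinct column
    counts so both size trends are identifiable, and >= 2 replicates per
    cell for within-cell standard deviations.
    """
    import statsmodels.api as sm

    grid = [(int(n), int(p)) for n, p in grid]
    if len({n for n, _ in grid}) < 2 or len({p for _, p in grid}) < 2:
        raise ValueError("grid needs >= 2 distinct n values and >= 2 distinct p values")
    if replicates < 2:
        raise ValueError("need >= 2 replicates per cell for statistics")

    c = alphabet.n_states
    rows = []
    k = 0
    for n, p in grid:
        for rep in range(replicates):
            cfg = SimulationConfig(
                n_taxa=n,
                n_columns=p,
                alphabet=alphabet,
                state_frequencies=state_frequencies,
                seed=seed + k,
            )
            k += 1
            aln = simulate_homogeneous(cfg)
            raw = rcfv_total(tabulate(aln))
            rows.append((n, p, rep, raw, nrcfv(raw, p, n, c)))
    replicates_df = pd.DataFrame(
        rows, columns=["n_taxa", "n_columns", "replicate", "rcfv", "nrcfv"]
    )
    summary = (
        replicates_df.groupby(["n_taxa", "n_columns"], as_index=False)
        .agg(
            mean_rcfv=("rcfv", "mean"),
            sd_rcfv=("rcfv", "std"),
            mean_nrcfv=("nrcfv", "mean"),
            sd_nrcfv=("nrcfv", "std"),
            replicates=("rcfv", "size"),
        )
    )
    trend_rows = []
    for metric in ("mean_rcfv", "mean_nrcfv"):
        for predictor in ("n_columns", "n_taxa"):
            X = sm.add_constant(summary[predictor].to_numpy(dtype=float))
            fit = sm.OLS(summary[metric].to_numpy(), X).fit()
            trend_rows.append(
                (
                    metric.removeprefix("mean_"),
                    predictor,
                    fit.params[1],
                    fit.bse[1],
                    fit.pvalues[1],
                )
            )
    trends = pd.DataFrame(
        trend_rows, columns=["metric", "predictor", "slope", "stderr", "pvalue"]
    )
    return BiasStudyResult(replicates_df, summary, trends, seed=seed)


# ---------------------------------------------------------------------------
# Missing data
# ---------------------------------------------------------------------------

def apply_missingness(
    aln: Alignment, fraction: float, seed: int = 0, max_tries: int = 100
) -> Alignment:
    """Set exactly round(fraction · n · p) uniformly chosen cells to missing.

    Resamples (up to ``max_tries``) if a draw would leave some taxon with
    zero non-missing cells.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    n, p = aln.n_taxa, aln.n_columns
    m = int(round(fraction * n * p))
    if m == 0:
        return aln.copy()
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        flat = rng.choice(n * p, size=m, replace=False)
        codes = aln.codes.copy()
        codes.reshape(-1)[flat] = MISSING
        if ((codes != MISSING).sum(axis=1) > 0).all():
            return Alignment(list(aln.taxa), codes, aln.alphabet)
    raise ValueError(
        f"could not place {m} missing cells without emptying a taxon "
        f"(fraction={fraction}, {n}x{p})"
    )


def simulate_graded_genes(
    n_genes: int,
    n_taxa: int = 20,
    lengths: Iterable[int] | int = 500,
    alphabet: Alphabet = DNA,
    max_skew: float = 0.5,
    seed: int = 0,
) -> list[tuple[str, Alignment]]:
    """Synthetic genes with a known heterogeneity gradient.

    Gene g (g = 0..G−1) interpolates each taxon's state distribution
    between the uniform vector and a taxon-specific skewed vector with
    weight ``max_skew · g/(G−1)``: gene 0 is compositionally homogeneous
    and heterogeneity grows monotonically along the list, which defines
    the true heterogeneity ranking by construction.  ``lengths`` may be
    a single length or one per gene.  Gene names sort in gradient order.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if isinstance(lengths, int):
        lengths = [lengths] * n_genes
    lengths = list(lengths)
    if len(lengths) != n_genes:
        raise ValueError("need one length per gene")
    rng = np.random.default_rng(seed)
    c = alphabet.n_states
    uniform = np.full(c, 1.0 / c)
    # one fixed skew direction per taxon, shared across genes
    targets = rng.dirichlet(np.full(c, 0.5), size=n_taxa)
    genes: list[tuple[str, Alignment]] = []
    width = len(str(n_genes - 1))
    for g in range(n_genes):
        w = max_skew * g / (n_genes - 1)
        p = lengths[g]
        codes = np.empty((n_taxa, p), dtype=np.uint8)
        for i in range(n_taxa):
            freqs = (1 - w) * uniform + w * targets[i]
            codes[i] = _draw_codes(1, p, freqs / freqs.sum(), rng)[0]
        genes.append(
            (f"gene{g:0{width}d}", Alignment(_taxon_names(n_taxa), codes, alphabet))
        )
    return genes


@dataclass
class MimicPair:
    """Gapped/ungapped re-simulation of a template alignment.

    Both members share the template's shape and per-taxon composition;
    ``gapped`` copies the template's missing mask verbatim, ``ungapped``
    has no missing cells.
    """

    gapped: Alignment
    ungapped: Alignment
    template_summary: pd.DataFrame

    def __post_init__(self) -> None:
        assert self.gapped.codes.shape == self.ungapped.codes.shape


def mimic_pair(template: Alignment, seed: int = 0) -> MimicPair:
    """Simulate a gapped/ungapped pair mimicking a template alignment.

    Each taxon's cells are drawn i.i.d. from that taxon's own observed
    (non-missing) composition, so the pair differs from the template
    only by sampling noise and from each other only by the missing mask.
    """
    ft = tabulate(template)  # raises DegenerateTaxonError on empty taxa
    rng = np.random.default_rng(seed)
    n, p = template.n_taxa, template.n_columns
    mask = template.missing_mask
    gapped = np.empty((n, p), dtype=np.uint8)
    ungapped = np.empty((n, p), dtype=np.uint8)
    for i in range(n):
        comp = ft.freqs[i]
        gapped[i] = _draw_codes(1, p, comp, rng)[0]
        ungapped[i] = _draw_codes(1, p, comp, rng)[0]
    gapped[mask] = MISSING
    summary = pd.DataFrame(
        {
            "taxon": template.taxa,
            "missing_fraction": mask.mean(axis=1),
            **{
                f"freq_{st}": ft.freqs[:, j]
                for j, st in enumerate(ft.states)
            },
        }
    )
    return MimicPair(
        gapped=Alignment(list(template.taxa), gapped, template.alphabet),
        ungapped=Alignment(list(template.taxa), ungapped, template.alphabet),
        template_summary=summary,
    )
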