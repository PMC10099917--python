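"""Per-gene scoring, quantile binning and selection comparison.

Phylogenomic pipelines score each gene (partition) of a supermatrix for
compositional heterogeneity, rank the genes, cut the ranking into
equal-count quantile bins (sextiles by default), and build cumulative
datasets from the least-heterogeneous bins upward.  Because raw RCFV is
biased by gene length, ranking by RCFV and by nRCFV selects different
genes; :func:`compare_selections` quantifies that disagreement per bin
(percentage of non-shared genes, summed alignment lengths, and where the
non-shared genes end up).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabets import MISSING, Alphabet
from .io import Alignment, AlignmentError, read_alignment

GeneList = Sequence[tuple[str, Alignment]]


def score_partitions(genes: GeneList) -> pd.DataFrame:
    """Score each gene independently with its own n, p and c.

    Taxa with zero non-missing cells in a gene carry no compositional
    information there and are excluded from that gene's taxon count.
    Returns a GeneMetricsTable: one row per gene with columns
    ``gene, n_taxa, length, n_states, rcfv, nrcfv``.
    """
    from .normalize import analyze

    if not genes:
        raise ValueError("empty gene list")
    names = [name for name, _ in genes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene names: {dupes}")
    rows = []
    for name, aln in genes:
        present = (aln.codes != MISSING).any(axis=1)
        if present.sum() < 2:
            raise ValueError(
                f"gene {name!r} has fewer than 2 taxa with data"
            )
        if not present.all():
            aln = Alignment(
                [t for t, keep in zip(aln.taxa, present) if keep],
                aln.codes[present],
                aln.alphabet,
            )
        mr = analyze(aln)
        rows.append(
            (name, mr.n_taxa, mr.n_columns, mr.n_states, mr.rcfv, mr.nrcfv)
        )
    return pd.DataFrame(
        rows, columns=["gene", "n_taxa", "length", "n_states", "rcfv", "nrcfv"]
    )


@dataclass
class QuantileAssignment:
    """Equal-count binning of genes by a heterogeneity metric.

    Bin 1 holds the least heterogeneous genes.  Sizes are as equal as
    possible; with remainder r, the first r bins get one extra gene.
    Ties are broken by gene name (lexicographic) so the assignment is
    deterministic.
    """

    metric: str
    k: int
    bins: dict[str, int]          # gene -> bin index in 1..k
    bin_sizes: list[int]

    def members(self, b: int) -> set[str]:
        return {g for g, i in self.bins.items() if i == b}


def assign_quantiles(
    tbl: pd.DataFrame, metric: str = "nrcfv", k: int = 6
) -> QuantileAssignment:
    """Sort genes ascending by ``metric`` and cut into k equal-count bins."""
    if metric not in tbl.columns:
        raise ValueError(f"metric {metric!r} not in table columns")
    m = len(tbl)
    if k < 1 or k > m:
        raise ValueError(f"k must be in 1..{m}, got {k}")
    order = sorted(zip(tbl[metric], tbl["gene"]))
    base, rem = divmod(m, k)
    sizes = [base + 1 if b < rem else base for b in range(k)]
    bins: dict[str, int] = {}
    pos = 0
    for b, size in enumerate(sizes, start=1):
        for _, gene in order[pos:pos + size]:
            bins[gene] = b
        pos += size
    return QuantileAssignment(metric=metric, k=k, bins=bins, bin_sizes=sizes)


@dataclass
class SelectionComparison:
    """Per-bin disagreement between two quantile assignments.

    ``table`` has one row per bin: the percentage of assignment-b genes
    absent from assignment-a's same bin, and the summed gene lengths
    under each assignment.  ``crosstab[i, j]`` counts b-bin-i genes that
    are non-shared and land in a-bin j.
    """

    table: pd.DataFrame
    crosstab: pd.DataFrame


def compare_selections(
    a: QuantileAssignment, b: QuantileAssignment, tbl: pd.DataFrame
) -> SelectionComparison:
    """Compare gene selections of two equal-k assignments per bin."""
    if a.k != b.k:
        raise ValueError(f"assignments have different k: {a.k} vs {b.k}")
    if set(a.bins) != set(b.bins):
        raise ValueError("assignments cover different gene sets")
    lengths = dict(zip(tbl["gene"], tbl["length"]))
    rows = []
    xt = np.zeros((a.k, a.k), dtype=int)
    for bin_idx in range(1, a.k + 1):
        in_a = a.members(bin_idx)
        in_b = b.members(bin_idx)
        non_shared = in_b - in_a
        for gene in non_shared:
            xt[bin_idx - 1, a.bins[gene] - 1] += 1
        rows.append(
            (
                bin_idx,
                len(in_b),
                len(non_shared),
                100.0 * len(non_shared) / len(in_b) if in_b else 0.0,
                sum(lengths[g] for g in in_a),
                sum(lengths[g] for g in in_b),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "bin",
            "n_genes",
            "non_shared",
            "pct_non_shared",
            f"length_{a.metric}",
            f"length_{b.metric}",
        ],
    )
    crosstab = pd.DataFrame(
        xt,
        index=[f"{b.metric}_bin_{i}" for i in range(1, a.k + 1)],
        columns=[f"{a.metric}_bin_{i}" for i in range(1, a.k + 1)],
    )
    return SelectionComparison(table=table, crosstab=crosstab)


def cumulative_dataset(
    assignment: QuantileAssignment,
    genes: GeneList | Mapping[str, Alignment],
    upto: int,
) -> tuple[Alignment, pd.DataFrame]:
    """Concatenate all genes of bins 1..upto into one supermatrix.

    Columns are concatenated gene by gene (ascending bin, then gene
    name) over the union of taxa; a taxon absent from a gene gets
    missing cells for that gene's columns.  Returns the supermatrix and
    a boundary table with 1-based inclusive column ranges per gene.
    """
    if isinstance(genes, Mapping):
        gene_map = dict(genes)
    else:
        gene_map = dict(genes)
    if upto < 1 or upto > assignment.k:
        raise ValueError(f"upto must be in 1..{assignment.k}")
    chosen: list[str] = []
    for b in range(1, upto + 1):
        members = sorted(assignment.members(b))
        if not members:
            raise ValueError(f"bin {b} is empty")
        chosen.extend(members)
    missing_genes = [g for g in chosen if g not in gene_map]
    if missing_genes:
        raise ValueError(f"genes absent from input: {missing_genes}")

    taxa: list[str] = []
    seen: set[str] = set()
    for g in chosen:
        for t in gene_map[g].taxa:
            if t not in seen:
                seen.add(t)
                taxa.append(t)
    alphabet = gene_map[chosen[0]].alphabet
    total_p = sum(gene_map[g].n_columns for g in chosen)
    codes = np.full((len(taxa), total_p), MISSING, dtype=np.uint8)
    index = {t: i for i, t in enumerate(taxa)}
    boundaries = []
    pos = 0
    for g in chosen:
        aln = gene_map[g]
        if aln.alphabet.states != alphabet.states:
            raise ValueError(
                f"gene {g!r} uses a different alphabet than the first gene"
            )
        rows = [index[t] for t in aln.taxa]
        codes[rows, pos:pos + aln.n_columns] = aln.codes
        boundaries.append((g, assignment.bins[g], pos + 1, pos + aln.n_columns))
        pos += aln.n_columns
    bounds = pd.DataFrame(boundaries, columns=["gene", "bin", "start", "end"])
    return Alignment(taxa, codes, alphabet), bounds


# ---------------------------------------------------------------------------
# Partition input: per-gene directories and RAxML-style partition files
# ---------------------------------------------------------------------------

_PARTITION_RE = re.compile(
    r"^\s*(?:[A-Za-z][\w+]*\s*,\s*)?"      # optional leading 'DNA,' type tag
    r"(?P<name>[^=\s][^=]*?)\s*=\s*(?P<ranges>[\d,\s-]+)\s*$"
)


def read_partition_file(path: str | Path) -> list[tuple[str, list[tuple[int, int]]]]:
    """Parse a RAxML-style partition file (``GENE1 = 1-2340``).

    Ranges are 1-based inclusive; multiple comma-separated ranges per
    gene are accepted.  Codon subsetting (``1-99\\3``) is not supported.
    """
    parts: list[tuple[str, list[tuple[int, int]]]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        m = _PARTITION_RE.match(line)
        if not m:
            raise AlignmentError(
                f"{path}:{lineno}: cannot parse partition line {line!r}"
            )
        ranges: list[tuple[int, int]] = []
        for chunk in m.group("ranges").split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            if "-" in chunk:
                lo, hi = chunk.split("-", 1)
                start, end = int(lo), int(hi)
            else:
                start = end = int(chunk)
            if start < 1 or end < start:
                raise AlignmentError(
                    f"{path}:{lineno}: bad column range {chunk!r}"
                )
            ranges.append((start, end))
        if not ranges:
            raise AlignmentError(f"{path}:{lineno}: no column ranges")
        parts.append((m.group("name").strip(), ranges))
    if not parts:
        raise AlignmentError(f"no partitions found in {path}")
    return parts


def split_supermatrix(
    aln: Alignment, partitions: Sequence[tuple[str, Sequence[tuple[int, int]]]]
) -> list[tuple[str, Alignment]]:
    """Slice a supermatrix into per-gene alignments by 1-based ranges."""
    genes: list[tuple[str, Alignment]] = []
    for name, ranges in partitions:
        cols: list[np.ndarray] = []
        for start, end in ranges:
            if end > aln.n_columns:
                raise AlignmentError(
                    f"partition {name!r} range {start}-{end} exceeds "
                    f"alignment length {aln.n_columns}"
                )
            cols.append(aln.codes[:, start - 1:end])
        genes.append(
            (name, Alignment(list(aln.taxa), np.hstack(cols), aln.alphabet))
        )
    return genes


def read_gene_directory(
    path: str | Path,
    alphabet: Alphabet | None = None,
    pattern: str = "*.fa*",
) -> list[tuple[str, Alignment]]:
    """Read a directory of per-gene FASTA files (sorted by filename)."""
    files = sorted(Path(path).glob(pattern))
    if not files:
        raise AlignmentError(f"no alignment files matching {pattern!r} in {path}")
    return [
        (f.stem, read_alignment(f, format="fasta", alphabet=alphabet))
        for f in files
    ]
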