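# nrcfv

Compositional-heterogeneity metrics for multiple sequence alignments:
**RCFV** (Relative Composition Frequency Variability) and its
size-normalized successors **nRCFV**, **ncsRCFV** and **ntsRCFV**, with
the simulation and gene-binning machinery needed to study and correct
the raw metric's dependence on alignment size.

## Who this is for

Phylogenomic pipelines routinely screen genes and taxa for
compositional heterogeneity — variation in nucleotide or amino-acid
proportions across taxa that violates the stationarity assumption of
standard substitution models and can distort tree inference.  RCFV is a
cheap pre-tree screen for this, but its raw value shrinks as alignments
grow, so length and taxon sampling leak into gene selection.  This
package computes both the raw and the normalized family, and ships the
tooling to demonstrate the bias and verify the correction.

## The metrics

For an alignment with $n$ taxa, $p$ columns and $m$ possible character
states, let $\mu_{ij}$ be the relative frequency of state $j$ in taxon
$i$ (computed over the taxon's non-missing cells) and
$\bar{\mu}_j = \frac{1}{n}\sum_i \mu_{ij}$ the dataset mean:

$$\mathrm{RCFV} = \sum_{i=1}^{n}\sum_{j=1}^{m} \frac{|\mu_{ij}-\bar{\mu}_j|}{n}$$

Restricting the double sum to one state gives csRCFV$_j$; to one taxon,
tsRCFV$_i$; each family sums back to the total, so `cs/total` is the
percentage a state contributes to overall heterogeneity.

The raw value is exactly invariant under duplicating all columns or all
taxa, yet on finite data it is noise-dominated and scales like
$1/\sqrt{p}$.  The normalized family divides by a fitted size constant
($c$ = number of possible states: 4, 20, or 2 for RY/binary recodings):

$$\mathrm{nRCFV} = \frac{\mathrm{RCFV}}{p^{-0.5}\, n^{0.01}\, c \cdot 100},\qquad
\mathrm{ntsRCFV} = \frac{\mathrm{tsRCFV}}{p^{-0.5}\, n^{-1}\, c \cdot 100},\qquad
\mathrm{ncsRCFV} = \frac{\mathrm{csRCFV}}{p^{-0.5} \cdot 100}$$

Gaps, `?`, `.` and IUPAC ambiguity letters are treated as missing and
excluded from the frequency denominators.

## Worked example

```sh
nrcfv compute example.fasta --preset ry --out reports
```

on a toy 4-taxon, 20-column DNA alignment in which one taxon (`eel`) is
GC-shifted prints `summary.tsv`:

```
n_taxa  n_columns  n_states  rcfv     nrcfv
4       20         4         0.38125  0.004203821421928669
```

and `states.tsv` (the `--preset ry` adds grouped purine/pyrimidine rows
computed on the collapsed two-state table):

```
state  cs_rcfv               ncs_rcfv
A      0.13749999999999998   0.00614918693812442
C      0.075                 0.0033541019662496844
G      0.14999999999999997   0.006708203932499367
T      0.018750000000000003  0.0008385254915624212
R      0.06875000000000003   0.0030745934690622123
Y      0.06875000000000002   0.0030745934690622114
```

Reading: G deviates most between taxa (csRCFV 0.15, i.e. 39% of the
total 0.38125), and `taxa.tsv` flags `eel` as the most deviant taxon
(tsRCFV 0.15, twice any other).  The same numbers are available from
Python:

```python
import nrcfv as nv
aln = nv.read_alignment("example.fasta")
mr = nv.analyze(aln, groups=nv.PURINE_PYRIMIDINE)
mr.rcfv, mr.nrcfv, mr.contribution_pct("G")
# (0.38125, 0.004203821421928669, 39.34426229508196)
```

Other subcommands: `nrcfv simulate` (homogeneous-simulation bias study
over an (n, p) grid), `nrcfv partition` (per-gene scoring, sextile
binning and RCFV-vs-nRCFV selection comparison), `nrcfv mimic`
(gapped/ungapped re-simulation of a template for missing-data
experiments).

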