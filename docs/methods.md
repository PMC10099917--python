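# Methods

## The model

RCFV treats an alignment as a bag of per-taxon state-frequency vectors
and scores how far each taxon's composition sits from the dataset mean:

RCFV = Σ_i Σ_j |μ_ij − μ̄_j| / n

with n taxa, m possible states, μ_ij the relative frequency of state j
in taxon i and μ̄_j the *unweighted* mean of the per-taxon frequencies
(Σ_i μ_ij / n — not the pooled frequency over all residues; the two
differ when taxa have different amounts of missing data).  The
character-specific (csRCFV_j, fix j) and taxon-specific (tsRCFV_i, fix
i) components each sum to the total exactly, which is what licenses the
"state X contributes Y%" reading.

Two exact invariances follow from using frequencies rather than counts:
duplicating every column, or duplicating every taxon, leaves RCFV and
all of its components unchanged.  Nevertheless the metric is size
biased on real (finite, noisy) data: for i.i.d. composition the
deviations |μ_ij − μ̄_j| are sampling noise of magnitude
√(f_j(1−f_j)/p), so raw RCFV decays like 1/√p and comparisons across
genes of different length conflate length with heterogeneity.  A single
substitution moves the affected taxon's deviation terms by
(n−1)/(n·p) and every other taxon's by 1/(n·p)
(`predict_single_change` exposes these closed forms; property tests
verify them to 1e−12), and only the two touched states' terms carry
these factors — with 20 states, 10% of the calculation.

The normalized family divides by fixed size constants:

- nRCFV = RCFV / (p^−0.5 · n^0.01 · c · 100)
- ntsRCFV = tsRCFV / (p^−0.5 · n^−1 · c · 100)
- ncsRCFV = csRCFV / (p^−0.5 · 100)

The exponents are published fit constants and are deliberately
hard-coded, not refit (refitting them is a research exercise outside
the tested API; n^0.01 is implemented exactly as printed).  c is the
*possible* state count of the alphabet in use — 4 for nucleotides, 20
for amino acids, the group count for collapsed tables (2 for RY) —
never the observed-distinct count.  A consequence of per-family
constants is that normalized components no longer sum to the normalized
total; the tests assert this inequality rather than "fixing" it.

## Missing data

Gaps (`-`), unknowns (`?`, `.`) and IUPAC ambiguity letters (N R Y S W
K M B D H V for DNA; X B Z J and `*` for protein) are all treated as
missing, matching the convention that a cell which does not pin down a
single state carries no compositional information.  μ_ij is computed
over the taxon's non-missing cells, so frequency vectors always sum
to 1 and the metric is insensitive to where gaps fall.  Fractional
counting of ambiguity codes (e.g. 0.5 A + 0.5 G for R) would change
μ_ij slightly; it is intentionally not implemented.  For normalization,
p is the full column count of the (sub)alignment being scored,
including columns missing in some taxa.  Taxa participate with their
renormalized vectors regardless of coverage — no minimum-coverage
filter is applied, though one can be imposed upstream by the caller.

## Input conventions

FASTA (via Biopython's parser) and relaxed PHYLIP (whitespace-delimited
names of any length; sequential tried first, then interleaved) are
accepted; `auto` decides by the first non-blank byte.  Input is
case-folded to upper case and RNA `U` canonicalizes to `T` so a 4-state
alphabet holds.  Alphabet auto-detection calls a sequence set DNA when
its non-missing characters fit the nucleotide universe (including
ambiguity letters), else protein.  Columns are 0-based half-open
internally; every user-facing report is 1-based inclusive.

## The synthetic-data generator

`simulate_homogeneous` draws every cell i.i.d. from a fixed stationary
distribution.  This emulates exactly one feature of real data — the
expected per-taxon composition — and none of the others: no tree
structure, no rate variation, no among-site dependence.  That is a
deliberate choice: compositional homogeneity in expectation is the
property the bias study needs, and i.i.d. draws deliver it at a
fraction of the cost of tree-based simulation (which is out of scope).
Consequently, passing tests demonstrate the size bias and its
normalization for sampling-noise heterogeneity; they say nothing about
tree-induced effects such as the bimodal metric distributions that
phylogenetic simulations can produce.

Default study conditions: DNA grids use p ∈ {900, 4500, 9000} and
n ∈ {50, 150} with 100 replicates per cell (full-scale sweeps in the
source literature use 10× finer grids; the reduced grid reproduces the
same phenomenon on one CPU in seconds and the sizes used are recorded
in each result).  A study seed expands to per-replicate substreams as
`seed + k` with k enumerating (cell, replicate) pairs in order, so
every result is a pure function of (config, seed).

`apply_missingness` knocks out an exact number of uniformly chosen
cells (resampling if a taxon would be left empty).  `mimic_pair`
re-simulates a template from its own *per-taxon* (not pooled) observed
composition, once with the template's missing mask copied verbatim and
once gap-free, so a pair differs only by the mask.

## Numerical choices

Frequencies and deviation sums are double precision accumulated in
numpy order; identities (component sums, duplication invariance) are
asserted at 1e−10/1e−12, which absorbs float reordering without hiding
real defects.  Quantile binning sorts ascending by metric with
lexicographic gene-name tie-break and gives the remainder genes to the
earliest bins — a documented, deterministic rule (638 genes in sextiles
gives sizes 107, 107, 106, 106, 106, 106); other splits of a ranked
list are possible and published gene sets may use one.  Degenerate
inputs fail loudly: empty taxa, ragged rows, duplicate labels,
overlapping state groups and unknown characters raise typed errors
naming the offender.

## Known limitations

- The missing-data "neutrality" of RCFV is approximate, not exact.
  Because noise scales with effective (non-missing) length, a gapped
  alignment's RCFV exceeds its gap-free mimic's by roughly
  1/√(1−f) − 1 at missing fraction f when composition is homogeneous.
  On the default mimic conditions this is a ~5–10% relative difference
  that *does* grow with f; a sufficiently powered regression detects
  the trend even though its magnitude stays small and real
  heterogeneity shrinks it further.  The test suite asserts the
  magnitude band and, separately, the (strict) no-trend property; the
  latter documents this limitation by failing under clean homogeneous
  conditions.
- Significance testing of RCFV-family values is out of scope; the
  metrics are descriptive screens.
- No NEXUS input, no codon alphabets, no site-wise (columnar) profiles,
  no tree inference on the assembled supermatrices.
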