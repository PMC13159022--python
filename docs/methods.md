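# Methods

## The generative model

The generator treats a multiple sequence alignment as a bag of independent
columns. For each retained column it computes a conservation distribution,
a physicochemical distribution, and their convex combination, then samples
sequences position by position. There is deliberately no pair or column
covariation model, no pseudocounts and no redundancy-based sequence
weighting: the design philosophy is a transparent, tunable per-position
profile whose two extremes are easy to reason about (r = 0 can only emit
residues observed in the family; r = 1 ignores observation counts entirely
and follows the column's average chemistry).

### Conservation route

`A_C(a) = f_a / N` over the column multiset, where N counts canonical
residues only. Gaps and ambiguity codes (X, B, Z, J, U, O) are excluded
from both f and N, because the scoring properties are defined only for the
20 canonical amino acids. Columns whose modal residue reaches the
conservation cutoff (default 0.90) are collapsed to probability 1 on that
residue. The collapse is applied to the stored A_C and wins over the
r-combination at every r, including r = 1: preservation of essential
residues is an unconditional design guarantee, not a large-r tendency.
Modal ties break alphabetically by one-letter code, deterministically.

### Physicochemical route

Each residue is scored against the column's mean property vector by a
weighted sum of reciprocal absolute differences over Kyte–Doolittle
hydropathy, residue isoelectric point and van der Waals volume:

    S(a) = sum_k w_k / (|x_{a,k} - mean_k| + epsilon)

The sum (rather than a product) is the natural linear aggregation
consistent with per-property weights; with a product the weights would act
as exponents and lose their stated meaning. Properties are used on their
raw scales; the unequal default weights (0.22 H_KD, 0.44 pI, 0.33 vdW,
renormalised internally to sum to 1 while preserving their ratios) are
taken as the intended compensation for scale differences. An optional
z-scoring of the three axes is available (`standardize=True`) but off by
default. `epsilon = 1e-6` guards the reciprocal when a residue's property
coincides exactly with the column mean; shrinking it further does not
change the argmax away from exact equidistance ties.

### Property tables

Shipped as a versioned TSV (`data/aa_properties.tsv`): Kyte–Doolittle
hydropathy (range −4.5 R to +4.5 I), Zimmerman residue pI (2.77 D to
10.76 R, pH units) and Darby–Creighton van der Waals volumes (48 G to
163 W, Å³). The table is swappable (`PropertyTable.from_tsv`) because the
exact scale variants matter less than their ordering for the reciprocal
scoring, and practitioners may prefer other accessions. Residue-level pI
(profile input) and sequence-level pI (reporting) are distinct quantities
in separate code paths.

### Sampling

Sequences are drawn left to right by categorical draws from each position's
A_U. The RNG substream for sequence *i* is keyed by `(seed, i)` via numpy's
`SeedSequence`, so sequence *i* is identical regardless of how many other
sequences the run requests; duplicate draws are rejected on exact string
equality and the attempt counter simply advances to the next substream.
The attempt budget is `max_attempts_factor x n_sequences` (default factor
20); exhausting it — e.g. asking a fully conserved profile for two unique
sequences — raises an error reporting the diversity actually achieved.

### Chimeras

Two pre-aligned, equal-length, ungapped parents form a two-row alignment;
the conservation route then gives each identical column probability 1 (via
the modal override) and each differing column a 0.5/0.5 coin. Requests
beyond the 2^d outcome space (d = differing positions) are rejected up
front. Gapped parents are rejected: no gap policy is defined because the
intended use is recombining equal-length designs from the same frame.

## Set-level evaluation

Positional property means (mean H_KD, pI, vdW per position across a set)
are compared to the same means of the input MSA columns by squared Pearson
correlation per property. The "pairwise correlation" is Pearson's R^2 of
the two positional mean vectors; Spearman is not used because the
comparison is about linear reproduction of the property profile, not rank
order. Per sweep point, the three R^2 values are averaged within the set
first; the grand mean is then the mean of those per-set averages across
the sweep; residual(r) = avg_R2(r) − grand mean. The selected r minimises
|residual|, ties to the smaller r (the more conservative design). The
default sweep grid is 0.00–1.00 inclusive in steps of 0.05 (21 points).
Signed residuals over any sweep sum to zero by construction; the test
suite asserts this to 1e-12 as a numerical-integrity check.

Set summaries report per-sequence GRAVY (mean Kyte–Doolittle hydropathy)
and sequence pI with a normal-approximation 95% CI (1.96·sd/√n); a
single-sequence set reports the CI as NaN rather than 0 to distinguish
"no spread information" from "zero spread".

### Sequence isoelectric point

A Henderson–Hasselbalch net-charge model (N/C termini plus D, E, C, Y, H,
K, R side chains) solved by bisection on [0, 14] to 1e-4 pH. The charge
function is strictly decreasing in pH, so the root is unique. Two named
pKa sets ship: `emboss` (default) and `bjellqvist`. The bisection result
is cross-checked in tests against an exhaustive 0.001-pH grid search over
the same model for 100 random peptides.

## Novelty profiling

Substitutions of a query against a reference in the same coordinate frame
are annotated with: the query residue's frequency in the matching MSA
column (rarity flags at < 5% and < 1%, strict inequalities, both
configurable); BLOSUM62 score (non-conservative iff <= 0); and Grantham
distance (divergent iff >= 43). The Grantham matrix is shipped as data and
cross-checked in the suite by recomputing it from the published
composition/polarity/molecular-volume formula (agreement within rounding
for 189 of 190 pairs; the D–W entry is a known historical table/formula
discrepancy and is carried as published).

Percentile context for a distance uses the 190 distinct substitution
pairs with a midpoint tie rule. The *median context* — the boundary between
moderate and extreme physicochemical divergence — is computed over all
20x20 pairings (self-pairs included), where it equals 96; over the 190
distinct substitutions alone it is 97. Both are exposed; the all-pairings
value is the default because the boundary describes "all possible
amino-acid pairings", identical ones included.

## PTM mass arithmetic

Average (not monoisotopic) masses by default, matching deconvoluted
intact-protein ESI-MS practice; a monoisotopic flag exists. The holo
adduct is C11H21N2O6PS (phosphopantetheine condensed onto serine with loss
of water, ~340.33 Da average), equal within 0.02 Da to CoA minus
3′,5′-ADP — the test suite checks both derivations. A saturated n-carbon
acyl thioester adds CnH(2n−2)O (~182.30 Da for C12). State assignment
picks the expected state minimising |observed − expected| within a
tolerance (default 1.0 Da, the practical deconvolution accuracy for small
proteins); ties break toward the less-modified state, and masses outside
tolerance are left unassigned rather than force-called. His-tag and
initiator-methionine processing are the caller's responsibility: the
module computes masses for exactly the sequence given.

## Synthetic fixture

The default fixture emulates the shape of a carrier-protein homologue
alignment: 200 rows x 78 columns, an invariant serine at 0-based position
36, and a deterministic interleave of 9 low-entropy (~0.95 dominant), 48
medium-entropy (~0.60 dominant over 5 residues) and 20 high-entropy
(Dirichlet over 12 residues) columns, with 2% gaps and 0.5% ambiguity
codes sprinkled outside conserved positions. 200 rows keeps every column
above the depth-50 retention threshold while exercising the filter
logic; the row count, width and serine position mirror the scale of a real
AcpP homologue collection without claiming its phylogenetic structure.
What these fixtures deliberately lack: sequence redundancy, column-column
covariation and realistic gap blocks. Passing tests on them demonstrate
the correctness of the profile arithmetic, the sampling guarantees and
the evaluation pipeline — not that generated sequences will express,
fold or accept modification in the laboratory.

Column distributions are drawn i.i.d. per column from the label recipes;
`column_distributions(cfg)` exposes the exact generating matrix so tests
can compare empirical frequencies against it.

## Statistical test conventions

Frequency-vs-profile checks over 10^4 draws use the per-cell 3-sigma
binomial envelope applied *simultaneously* across all (position, residue)
cells: about 0.27% of cells are expected outside 3 sigma by chance, so the
assertions require >= 99% of cells inside, no cell beyond 6 sigma, and
zero draws on zero-probability cells. Problem sizes in the suite and the
acceptance script (200-row fixture, 500 sequences per sweep point, 10^4
draws for sampling checks) were chosen to make sampling error a small
fraction of the tested effects while keeping the whole suite in the
seconds-to-minutes range.

## Known limitations

* Independent-column model: no epistasis, no covariation; designs can
  combine individually plausible residues into implausible combinations.
* The physicochemical route scores against the column *mean*, which for a
  bimodal column (e.g. half D, half K) targets chemistry no member has.
* Raw-scale reciprocal scoring makes A_P sensitive to the choice of
  property scales; swapping tables changes the distributions.
* Sequence pI is a simple charge model, not a trained predictor; expect
  systematic offsets versus calculators trained on experimental data.
* The cleaning "incomplete" rule (ungapped length < 0.5 x median) is a
  pragmatic stand-in for database-level completeness metadata.
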