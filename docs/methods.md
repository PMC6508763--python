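# Methods

## Model and procedure

The pipeline turns a normalized log2 expression matrix into a directed
network of Boolean implication relationships.

**Step fit.**  For each gene the values are sorted ascending and a rising
one-step function is fitted: for every breakpoint k ∈ [1, n−1], the first k
values are modelled by their mean m₁ and the rest by m₂, and
SSE(k) = Σ_left (x − m₁)² + Σ_right (x − m₂)² is minimized.  Ties are broken
toward the smallest k, for determinism.  The implementation uses cumulative
sums (O(n) after the sort) and is tested against an exhaustive breakpoint
scan.  The threshold is placed at t = (m₁ + m₂)/2, the midpoint of the two
segment means.  The midpoint is the natural location of the fitted step and
makes thresholding exactly shift-equivariant: adding a constant to a gene
shifts t by that constant and leaves every call unchanged.  Whether the
original procedure placed t at this midpoint or at the step's x-location is
not something we assert; the midpoint is this package's documented choice.
A gene whose values are all identical gets a degenerate fit (t = the common
value, SSE = 0) and, having no extreme calls, never enters the network.
Fewer than two non-missing values is an error.

**Discretization.**  Calls are high (> t + margin), low (< t − margin) or
intermediate, with margin 0.5 log2 units by default (configurable).  The
margin buffers threshold noise: values within half a log2 unit of t carry
little evidence about which regime the sample is in, and are ignored by the
pair test rather than forced into a quadrant.  Missing cells stay missing
and drop out of any pair involving them (pairwise-complete handling; the
minimal-assumption choice, since nothing in the data dictates imputation).

**Dynamic-range gate.**  A gene enters the network only with at least
min_low LOW and min_high HIGH calls, default max(3, ⌈0.025·n⌉) each.
Without a gate, a gene with (say) no LOW calls makes "A low ⇒ …" vacuously
true and the zero-margin quadrants undefined; the gate plus the
zero-margin rule below removes exactly those cases.  Both minima are
configurable.

**Sparse-quadrant test.**  For ordered pair (A, B), samples with both calls
extreme fill a 2×2 table.  Quadrant (A=i, B=j) with observed O, row margin
R (samples with A=i), column margin C (samples with B=j) and total T has
expected occupancy E = R·C/T under independence; it is sparse when
S = (E − O)/√E > 3 and e = (O/R + O/C)/2 < 0.1.  Both thresholds are
configurable; 3 and 0.1 are the defaults throughout.  A quadrant with
R = 0 or C = 0 is untestable and treated as not sparse.  The label map is:
one sparse quadrant → the corresponding asymmetric implication (sparse
(low, high) quadrant → `lolo`, etc.); both diagonals sparse → `eqv` or
`opo`; any other pattern (none, adjacent pair, ≥ 3 sparse) → none — the
method defines exactly six meaningful outcomes, so ambiguous patterns are
refused rather than guessed.  The full ordered-pair scan is implemented as
four boolean matrix products (counts of LOW/HIGH co-occurrence), so a
network over G genes costs four G×G matrix multiplications; a scalar
per-pair path exists and the two are tested to agree.  Symmetric classes
are stored in both orders, which is what makes per-probe class counting
well defined.  No multiple-testing correction is applied: the method uses
fixed thresholds by design.

**Universes and candidate invariants.**  A universe is a named sample
subset built from tissue annotations (exact label match after case-folding
and trimming) plus the all-samples universe.  A pair is re-counted and
re-classified within each universe; by default the *global* thresholds are
reused (a sample's quadrant then does not depend on the universe it is
viewed in), with per-universe refitting available as an option.  The
violation count reports the universe's occupancy of the sparse quadrant(s)
of the globally assigned relationship.  True logical invariance over all
possible samples of a universe is unverifiable from finite data, so the
package only ever flags *candidates* (relationship ≠ none in that
universe).

**Network comparison.**  Per probe A and class r, the number of partners X
with (A, X) classified r is tabulated for each network.  The probe universe
for comparison is the union of the two tables' ids with absent probes given
zero counts (an empty id *intersection* is an error — the networks share
nothing to match).  Each class is tested with a two-sided Wilcoxon
signed-rank on the paired per-probe counts, zero differences dropped;
differences are oriented Y − X.  The test is this package's choice for
paired, non-normal count data — the underlying study's test is unnamed, so
exact p-value agreement with it is not claimed.  A class with no nonzero
differences gets p = NaN and is never flagged.  Scatter data use
log2(count + 1) so zero-count probes remain plottable.  The significance
flag defaults to α = 0.001.

**Duplicate detection.**  Files are hashed as opaque bytes (streaming, 1 MiB
chunks), MD5 by default to match common practice for this QC, SHA-256
offered (MD5's cryptographic weakness is irrelevant for accidental
duplicates, but the option is cheap).  duplicate_count is the number of
*redundant copies*, Σ(group size − 1), so removing duplicates from N files
leaves N − duplicate_count — the arithmetic users expect when pruning a
compendium.

**TPM transform.**  RNA-seq abundances enter the pipeline as log2(TPM) for
TPM > 1 and TPM − 1 for TPM < 1.  Both branches are 0 at TPM = 1, so the
map is continuous and monotone; it compresses the high range
logarithmically while keeping near-zero abundances linearly separated.

## Synthetic data generator

The generator emulates the statistical structure of an RMA-normalized
multi-tissue compendium; its defaults are the conditions under which the
pipeline's recovery properties are stated.

* **Samples**: n = 300 by default, tissues drawn i.i.d. from
  {root 0.3, shoot 0.2, leaf 0.3, flower 0.2}.
* **Dynamic genes** (default 20): two-component Gaussian mixture on the
  log2 scale, modes at low_mean = 4 and high_mean = 9 with measurement
  noise sd 0.5.  Genes belong to co-activation blocks (one per tissue
  label); each block is switched on in a random non-empty tissue subset,
  and a gene is in its high state with probability 0.9 (block on) or 0.1
  (block off).  Tissue-driven blocks are what fill quadrants
  tissue-by-tissue and what induce cross-gene correlation; with a single
  tissue label the genes are mutually independent, which is how the null
  simulations are constructed.
* **Flat genes** (default 5): unimodal Gaussian at a random baseline in
  [4, 9] with sd flat_sd = 0.2.  A non-dynamic gene fluctuates with
  technical noise only, so its spread is set below the dynamic genes'
  noise_sd; at this spread the step fit's margin band swallows essentially
  all calls and the dynamic gate rejects the gene, which is the behaviour
  the gate exists to provide.  (With flat genes as wide as the dynamic
  noise, ~16% of samples would exceed t ± 0.5 on each side and a pure
  count gate could not tell them from bimodal genes.)
* **Planted pairs**: each pair's joint state is drawn per sample from a
  fixed distribution over the relationship's *allowed* quadrants — 0.4/0.4
  on the implication's two corner quadrants and 0.2 on the free quadrant
  (0.5/0.5 for `eqv`/`opo`) — and with probability ε (the leakage) the
  sample is placed in the forbidden quadrant instead.  The corner-heavy
  allocation keeps both genes' low/high margins balanced, so ε maps
  directly onto the classifier's error rate e (e ≈ 1.8·ε at these margins)
  and a planted implication is detectable by design whenever ε is well
  below e_max.  The separability constraint
  high_mean − low_mean > 2·margin + 4·noise_sd guarantees the two modes
  straddle the margin band.
* **Duplicate fixtures**: n small binary files with planted byte-identical
  groups and a JSON manifest; byte-identical under regeneration with the
  same seed.

What the generator does *not* emulate: probe-level array artifacts,
normalization-method discrepancies (RMA vs MAS 5.0), batch effects across
series, or realistic gene-gene pathway structure beyond block
co-activation.  Passing the planted-recovery tests therefore demonstrates
the correctness and calibration of the inference machinery under the
stated mixture model, not performance on real compendia.

## Numerical choices and degenerate inputs

* Step-fit SSE via cumulative sums with negative round-off clipped at 0;
  breakpoint ties go to the smallest k; equality with the brute-force scan
  is asserted at rel. tolerance 1e-9.
* Values exactly at t ± margin are intermediate (strict inequalities for
  low/high), matching the open-interval reading of the margin band.
* Quadrants with zero margins, universes with < 2 usable values
  (when refitting), and networks with < 2 dynamic genes are each handled
  explicitly (not-sparse / untestable report / empty network with warning).
* Matrix round trips preserve values to < 1e-9 (repr-based serialization)
  and id order exactly; "NA", "na" and empty cells read as missing.
* All simulation seeds are explicit; the CLI records the full parameter
  set and package version in `#` comment lines of every output.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run entirely on generated data:
1,000 random vectors (lengths 2–200) for the step-fit oracle scan;
exhaustive enumeration of all 135,751 quadrant tables with total ≤ 40 for
the classifier oracle scan; 200 replicates per relationship class at
n = 300, ε = 0.02 for recovery; 100 replicates of 10 independent genes at
n = 200 for the null; 600 probes (500 shifted) for the comparison test.
These sizes give the binomial/rank statistics enough resolution for the
stated ≥ 95% / ≥ 99% bounds while keeping a full run to a few seconds.

## Known limitations

* Only the rising one-step model is fitted; falling or two-step expression
  profiles (e.g. circadian genes summarized across time courses) get a
  threshold that may split them poorly.
* Fixed statistic/error thresholds, not FDR control: with tens of
  thousands of probes the network-wide false-positive count scales with
  the number of testable pairs.
* Pairwise-complete missing-value handling can make different pairs use
  different sample subsets of the same matrix.
* The Wilcoxon choice for network comparison is a reasonable default for
  paired count data, not a claim about the original analysis' test.
* Universe membership relies on exact (case-folded) tissue labels; no
  ontology mapping or label harmonization is attempted.
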