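# Methods

`tregprov` implements the quantitative procedures used to characterise a
tissue regulatory T cell (Treg) population — here motivated by aortic Tregs
in experimental abdominal aortic aneurysm, but applicable to any tissue
T-cell compartment: paired-chain clonotype calling with clonality
statistics, provenance arithmetic for parabiosis and photoconversion
experiments, and signature-concordance scoring of expression profiles.
This note records the models, the parameters that matter, the numerical
conventions, and the limits of what the synthetic-data tests demonstrate.

## Clonotype calling

A cell enters the repertoire only if it carries **both** a productive TCRα
and a productive TCRβ chain. Cells are collapsed into clonotypes by exact
identity of the paired receptor. Because published descriptions of
clonotype identity often leave the sequence level unstated, the key level
is configuration:

| knob | values | default | rationale |
|---|---|---|---|
| sequence level | CDR3 nucleotide / amino acid | nucleotide | strictest interpretation; avoids spurious merging of convergent receptors |
| V/J calls in key | yes / no | yes | 10x Cell Ranger convention |
| multi-chain policy | keep-dominant / drop-multi | keep-dominant | preserves cells while staying deterministic |

`keep-dominant` resolves a cell with several productive contigs of one
locus to the highest-UMI contig, ties broken by read count and then by
lexicographic CDR3 nucleotide sequence, so resolution is reproducible.
Nucleotide-level keys refine amino-acid-level keys (translation is a
function), so switching to AA keys can only merge clonotypes, never split
them — asserted as a property test.

Barcode GEM-well suffixes (`-1`) are stripped before grouping; sample
identity always comes from a declared `sample_id` column or flag, never
from the barcode. Cross-sample clonotype identity is by key equality only.

## Clonality statistics

* **Clonal-expansion ratio** — the proportion of cells belonging to
  clonotypes of size ≥ 2 among all cells analysed. The ≥ 2 threshold is
  fixed, not configurable. Verified against a brute-force oracle that
  enumerates all cell pairs.
* **Gini coefficient** of clone sizes, population (uncorrected) form
  `G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄)`, computed via the sorted-rank identity. G = 0
  for a perfectly even repertoire; the finite-n upper bound is (n−1)/n,
  approached under single-clone dominance. No small-sample correction is
  applied, matching the conventional immune-repertoire usage. The
  implementation is cross-checked against the pairwise-difference double
  sum, the Lorenz trapezoid area (agreement to 1e-9), and scikit-bio's
  `gini_index(method="trapezoids")`.
* **Lorenz curve** — clonotypes sorted ascending by size (ties broken by
  key string for bit-reproducibility), cumulative clonotype proportion on
  x, cumulative cell proportion on y.
* **Overlap and sharing** — set algebra over distinct clonotype keys;
  `shared_clonotypes_across_samples` lists keys recurring in ≥ k samples,
  ordered by descending total size then key.

Statistics are computed per sample and aggregated as mean ± SEM per tissue;
between-group hypothesis testing is out of scope.

A note on monotonicity: merging two singleton clones into one size-2 clone
never decreases the expansion ratio, but it *can* decrease the clone-size
Gini (e.g. sizes [2,1,1] → [2,2] even the distribution). The test suite
asserts the true form of the property.

## Parabiosis recruitment arithmetic

Per mouse, recruitment% = 100 × tissue chimerism / blood chimerism. The
cohort value is the **unweighted mean of per-mouse ratios** — never the
ratio of means (a test uses a cohort where the two disagree). Values above
100% (measurement noise) are flagged but not truncated; truncation would
bias the mean downward. The count chain is then

    accumulated = post_injury − steady_state
    recruited   = round(mean_recruitment% × accumulated)
    fraction_of_total% = 100 × recruited / post_injury

Rounding convention: intermediates at full precision; display values
rounded half-up to 1 decimal; the recruited count rounded to the nearest
cell **before** the final fraction. This order exactly reproduces the
published worked chain (blood 35.7%, aorta 30.9% → 86.6%; mean 78.6% of the
5355-cell accumulation → 4209; 4209/5375 → 78.3%). The three distinct
percentages (per-mouse mean, fraction of accumulation, fraction of the
total pool) are reported side by side and explicitly labelled rather than
collapsed into one headline number. A seeded percentile bootstrap
(resampling mice, 2000 draws by default) is offered for uncertainty, since
cohort-level spreads are rarely published.

## Photoconversion migration ratio

Migration ratio of an organ = its photoconverted-cell fraction divided by
the fraction in a designated nondraining lymph node, which measures what
systemic circulation alone would deliver; the reference organ's ratio is 1
by construction. Exactly one reference per experiment group is enforced.
Kinetics of photoconversion decay are out of scope.

## Signature concordance

A signature gene is concordant when present and expressed in the DE table
and its log2 fold change exceeds log2(min_fold) in the anticipated
direction. Defaults: `min_fold = 1` (any correct-direction change), the
2-fold volcano threshold available through the same argument, and the
denominator restricted to signature genes present in the table (the
`all`-signature denominator is a flag). Both thresholds are deliberately
surfaced because the field's "% of signature expressed as anticipated"
statements rarely state them. Gene symbols match case-insensitively; no
ortholog mapping is attempted.

## Synthetic-data generators

Each generator owns one `numpy.random.Generator` stream seeded
independently; identical model + seed gives byte-identical files (LF
endings, fixed column order).

* **Repertoires** (default 200 cells): abundance via explicit sizes,
  symmetric Dirichlet (concentration → ∞ gives Gini → 0), or rank power
  law (the default, exponent 1.0 over 150 clones, giving the mix of
  singletons and expanded clones typical of tissue repertoires). CDR3s are
  uniform random non-stop codons between a TGT leader and TTT terminator
  (canonical C…F junction), lengths 30–48 nt in multiples of 3, with
  rejection sampling against collisions so key uniqueness is guaranteed.
  Optional unpaired and extra-chain cell fractions plant exact decoy counts
  (`round(fraction × n_cells)`) recorded in the truth; extra β chains get
  strictly lower UMI counts so the keep-dominant policy has a unique right
  answer.
* **Parabiosis** (default 5 mice, matching the published cohort size):
  blood chimerism ~ Gaussian(40, 10) truncated to (0, 100]; tissue =
  blood × true fraction + Gaussian noise (default 5 percentage points),
  floored at 0. The default true fraction 0.786 mirrors the published mean.
* **Photoconversion**: organ fraction = reference × enrichment (+ noise);
  the reference is emitted noise-free.
* **DE tables** (default 10 000 genes, 100 signature genes): the number of
  concordant signature genes is planted **exactly** as
  `round(fraction × n_signature)` (a Bernoulli draw per gene could not
  support exact noise-free recovery, which the tests rely on); which genes
  are concordant is random. Effect size 2 log2 units, noise 0.25 log2 units
  by default.

What the generators do **not** emulate: V(D)J recombination statistics,
sequencing error, UMI collisions, batch effects, compositional noise in DE
estimates, or inter-mouse heterogeneity in true recruitment. Passing
recovery tests therefore demonstrates the correctness of the arithmetic
and bookkeeping on clean, well-specified inputs — not robustness to the
failure modes of real single-cell or bulk data.

## Numerical and degenerate-input conventions

* Empty repertoires are explicit markers (`is_empty`); every statistic
  raises on them rather than returning NaN.
* Gini requires at least one positive count; zeros are tolerated as
  abundances (the single-dominant limit [1,0,…,0] gives (n−1)/n).
* Rounding is half-up (ties away from zero) via `decimal`, not banker's.
* `read_cohort_csv` parses floats with `float_precision="round_trip"` so
  simulated cohorts survive a CSV round trip bit-exactly.
* All JSON reports carry full-precision floats; rounding is applied only
  in labelled display fields.

## Test problem sizes

The recovery suites use 50-mouse cohorts (50–200 replicates), repertoires
of 60–200 cells, and DE tables of 400–10 000 genes. At these sizes the
planted-truth recoveries are exact (clone-size multisets, filter counts,
noise-free concordance) or have Monte-Carlo standard errors of ~0.15
percentage points (recruitment bias), which the assertions use directly.
Single-cohort recruitment estimates carry a standard error near 2
percentage points under the default noise model, so cohort-level accuracy
is asserted on replicate means and on the fraction of cohorts inside the
2-point band, not on one simulated cohort.

## Known limitations

* No γδ T cells, B-cell receptors, or dual-TCR biology; non-TRA/TRB loci
  are dropped (and counted) at parse time.
* The canonical Treg signature gene list is not shipped — only the format;
  concordance against a user-supplied signature.
* DE estimation (dispersion, shrinkage, FDR) is consumed, not computed.
* No modelling of parabiont blood-sharing kinetics; the chimerism
  normalisation assumes equilibrated exchange.
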