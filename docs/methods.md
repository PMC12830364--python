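# Methods

`pacefinder` implements the comparative-genomics route by which a
clade-restricted cis-regulatory element can be discovered in the promoter
of a focal gene and tied to the evolutionary gains and losses of a binary
trait. The motivating system is root nodule symbiosis (RNS): a ~29-bp
element in the promoter of the *NIN* transcription-factor gene, present
exclusively in the nodulation-competent FaFaCuRo clade (Fabales, Fagales,
Cucurbitales, Rosales), conserved in every nodulating member, and absent
from the promoters of the *NLP* paralogue family. The package reproduces
that analysis pattern end to end on synthetic, fully ground-truthed
promoter worlds, since the original genome-scale inputs are not deposited.

## 1. Upstream-region extraction (`promoters`)

Upstream regions are anchored at the translation start (first base of the
start codon), so the extracted stretch includes the 5' UTR. Coordinates
are 0-based half-open: for a `+`-strand gene at start `t` with requested
length `L` the region is `contig[max(0, t-L) : t)`; for a `-`-strand gene
it is the reverse complement of `contig[t+1 : t+1+L)`. When the contig is
too short, the longest available stretch is returned and flagged
truncated. Per-gene length overrides in the coordinate table absorb
species-specific exceptions. Non-ACGT characters are uppercased and kept;
every window containing one is skipped downstream, both in discovery and
scanning (soft-masked bases are *not* excluded — a deliberate choice, as
masking policies vary across genome releases).

Discovery designs:

* **discriminative** — positives are the focal-family promoters of
  trait-positive clade species; controls are focal-family promoters of all
  non-clade species plus every paralogue-family promoter. Focal promoters
  of trait-negative clade species belong to neither set (their status is
  the question, not the training signal).
* **normal** — the same positives, no controls.
* **one_per_species** — positives reduced to the single best-scoring
  promoter per species, from a prior scan.

## 2. Motif model and discovery (`motifdisc`)

The motif is a 4×w column-stochastic PWM scored by log-odds in bits
against an order-0 background (estimated from the controls in
discriminative mode, from the positives in normal mode, with one
pseudo-observation per base). The occurrence model is ZOOPS: a sequence
carries at most one site, with prior probability `gamma` and a uniform
offset prior over its valid windows.

**EM.** The E-step computes, per sequence, a posterior over all site
offsets plus the no-site event; the M-step re-estimates PWM columns from
posterior-weighted counts plus a pseudocount (0.25 per base) and `gamma`
from the mean site posterior. The reported objective is the observed-data
ZOOPS log-likelihood ratio against the all-background model *plus* the
Dirichlet prior term induced by the pseudocount (bits). The prior term
matters: the pseudocount M-step maximises the MAP objective, not the bare
likelihood, so only the MAP objective is guaranteed non-decreasing — the
package asserts that ascent (tolerance 1e-9) on every run, and the E-step
is evaluated in float64 precisely so float noise cannot fake a descent.
Convergence: relative objective change below 1e-6, at most 200 iterations.
`gamma0 = 0` is honoured as the degenerate no-responsibility case (the
initial PWM is returned unchanged).

**Seeding.** Seeds are soft-consensus PWMs (0.7 on the seed base, 0.1
elsewhere) built from distinct w-mers of the positive set, uniformly
subsampled to `max_seeds` (default 2000). Uniform subsampling alone would
miss a once-per-sequence implant with appreciable probability (~50% in
the default world), so discovery adds *anchor seeds*: the exact 8-mers
shared by the most positive sequences are located and every w-window
placement covering one occurrence is added as a seed. Each seed receives
a cheap vectorised one-step ZOOPS objective (with the per-sequence sum
approximated by its best window — tight for the peaked seed model and used
only for ranking); the top `n_refine` (default 3) seeds are refined by
full EM. Running full EM on every seed, as a literal reading of the
procedure would suggest, is intractable; this prescore-then-refine economy
is the same one the established discovery tools use.

**Mode objectives and significance.** In normal mode the model objective
is the EM objective; significance is a Poisson upper tail on the number of
sequences whose best site exceeds a score threshold, with the expected
count taken from the exact null table (an E-value analogue — the published
tool's E-value formula is out of scope). In discriminative mode the
objective is the positive-set EM objective minus `n_pos` times the mean
positive part of the control best-site scores, and significance is the
one-sided Fisher exact p on the presence split (best score ≥ threshold)
between positives and controls, minimised over thresholds taken from the
positive best scores. Within a width the best model is chosen by
objective; across widths by significance (ties by objective). Additional
motifs are discovered after masking the previous motif's sites
(site posterior ≥ 0.5) with N; rounds stop at `n_motifs` or when
significance exceeds the reporting threshold (0.05).

**Width refinement.** Given the aligned sites of a wide motif, the
conserved core is the length-`target_w` window maximising summed
per-column relative-entropy information (pseudocount-regularised, against
the background); ties go left.

**The four-pass protocol.** Pass A: discriminative discovery over the
width grid (default 6–50). Pass B: normal-mode discovery at the wide width
(default 45), refined to the core width (default 29). Pass C:
discriminative discovery at the fixed core width, then a scan keeps the
single best-scoring focal promoter per species (lowest site p; ties by
lowest q, leftmost hit, lexicographic gene id) — "best-scoring" is
interpreted at the site level, which the source procedure leaves
ambiguous. Pass D: discriminative discovery at the core width on the
one-per-species set, removing per-species copy-number bias; its PWM is the
final consensus.

## 3. Scanning and presence calls (`motifscan`)

Only the given strand is scanned, ever. Window scores are discretised to
0.01-bit bins; the exact null distribution of the discretised score under
i.i.d. background draws is built by column-wise DP convolution, so p-values
agree with full 4^w enumeration to within one bin (asserted up to w = 6).
q-values are Benjamini–Hochberg (via statsmodels); per promoter only the
lowest-q hit is retained (ties leftmost) and presence is called iff
q ≤ 0.1, boundary inclusive.

The multiple-testing batch is configurable and logged. The default,
`pooling="batch"`, adjusts over every window of the scan — the
genome-scanning convention. `pooling="per_promoter"` adjusts each
promoter separately; measurement on synthetic worlds shows it grants each
null promoter its own α = 0.1 family (~10% false presences among
motif-free promoters), so it exists to probe sensitivity, not as a
recommendation. One property of batch-pooled FDR deserves emphasis: a
batch containing k genuine sites admits ~0.1·k false presences *in
expectation*. Clade-exclusivity claims made from a q ≤ 0.1 scan therefore
carry an irreducible false-presence risk of a few promoters per scan; the
synthetic-world tests quantify exactly this (a false outgroup focal call
arises in roughly a quarter of seeds). A claim of strict absence outside
a clade is, statistically, a lucky draw at this threshold — which the
package reports honestly rather than hiding.

The consensus matrix is built from one matched w-mer per species
(column frequencies plus pseudocount), with per-column information
content exported for logo plotting.

## 4. Phylogenetic evaluation (`phylotrait`)

* **Criteria.** Criterion 1: no non-clade species carries the element in
  its focal promoter. Criterion 2: every trait-positive clade species
  does. A separate specificity flag records paralogue-promoter hits
  (reported, never fatal — mirroring the known paralogue "element-like"
  edge case).
* **Dollo reconstruction.** One gain, any number of losses: the gain maps
  to the MRCA of the present leaves; losses are the maximal subtrees below
  it containing no present leaf. Polytomies are accepted. Verified against
  exhaustive (gain, loss-subset) minimisation on all trees with ≤ 6 leaves.
* **Loss attribution.** Losses are the trait-negative clade species. A
  loss is ORF-attributed when the focal ORF is disrupted *or* absent
  (species with an absent ORF have no promoter to scan and never reach
  motif attribution); otherwise motif-attributed when the element is
  absent; otherwise unexplained. Percentages are integer-rounded (half
  away from zero), reproducing the published worked example
  18/28 → 64%, 5/28 → 18%, 23/28 → 82%.

## 5. The synthetic world (`simdata`)

The generator emulates the analysis inputs: a rooted ultrametric species
tree (pure-birth, birth rate 1, clade and outgroup as sister subtrees,
rescaled to unit root depth), per-species promoter sets (default 20 clade
+ 20 outgroup species, one focal + 2 paralogue promoters each, 3 kb,
i.i.d. uniform background), and one 29-bp implant per implant-bearing
focal promoter at a uniform offset (replacing background bases, so
lengths stay constant). Implants diverge by per-site substitution at
`rate × root-to-leaf path length` (default rate 0.1 → 10% expected
divergence), giving the alignment phylogenetic signal. Trait losses hit a
`loss_fraction` (default 0.3) of clade species; causes are drawn from
(orf, motif, other) with default probabilities (0.64, 0.18, 0.18), the
published attribution fractions. "orf" losers keep the implant but carry
a disrupted ORF; "motif" losers lose the implant; "other" losers keep
both. A single seeded generator drives every draw, so bundles regenerate
byte-identically.

What the generator does **not** emulate — and what a green test therefore
does not establish robustness against: indels and motif turnover,
non-uniform or autocorrelated genomic background (real promoters are
AT-rich and repetitive; null p-values calibrated on an order-0 model can
be optimistic there), promoter/5'-UTR substructure, annotation error in
translation starts, and ORF-absent species (the simulator emits only
full-length or disrupted ORFs, since an absent ORF implies no promoter —
attribution treats disrupted and absent identically anyway).

## 6. Numerical and design choices

* Score discretisation 0.01 bits; error ≪ any decision boundary used.
* Pseudocount 0.25 per base everywhere a matrix is estimated from counts.
* Tie-breaks: leftmost window on equal q or equal information; lowest
  q → leftmost → lexicographic gene id for per-species best hits.
* Sequences shorter than the current width are dropped from discovery
  (logged); inside EM they are a hard error, as the contract requires.
* `run_pipeline` writes every artifact with a sha256 manifest; identical
  config + seed reproduces identical checksums.
* No command-line interface: the package is a library; `examples/` holds
  narrative scripts and `scripts/acceptance.py` the end-to-end run.

## 7. Known limitations

* The published discovery tool's E-values, priors and position-specific
  background are intentionally not reproduced; significance here is a
  computable stand-in with the same discriminative intent.
* Pass A's width choice is significance-then-objective; on saturated
  Fisher splits (all positives vs no controls at every width) the
  objective tie-break favours wider motifs that extend beyond the true
  element. The fixed-width passes C/D are what the final consensus relies
  on, matching the source procedure.
* FDR-thresholded presence calling cannot certify strict absence (see §3);
  results should quote q-values, not just +/- patterns.
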