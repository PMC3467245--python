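# Methods

This note records the statistical conventions, default parameters and
design choices behind `commphylo`, and what the synthetic-data tests do
and do not demonstrate about real survey data.

## Sequence preparation

Filters run in a fixed order: ambiguity → small sources → per-source
clustering → length outliers. The order matters (clustering can shrink a
source below the minimum-count threshold, so counting happens first), and
re-running the pipeline on its own output changes nothing.

* **Ambiguity filter.** A record is removed when its fraction of
  non-ACGT IUPAC characters strictly exceeds `max_ambiguous_frac`
  (default 0.001); a record exactly at the threshold is retained. All
  eleven ambiguity letters (including N) count; `-` and `.` are
  alignment characters and are rejected when a record is constructed.
* **Small-source filter.** Isolation sources with fewer than
  `min_seqs_per_source` (default 5) records lose all their records:
  per-source statistics on smaller samples are not informative.
* **Greedy clustering** (default identity 0.98) is performed
  independently within each source so that identical sequences recovered
  from different environments all survive — cross-habitat comparisons
  need them. Sequences are processed in descending length order, ties
  broken by id, and each joins the first cluster whose founder it matches
  at or above the threshold, else founds a new cluster. This tie-break
  makes clustering fully deterministic; the `seed` parameter exists for
  interface uniformity only. One consequence worth knowing: among
  identical sequences the lexicographically earliest id becomes the
  representative.
* **Percent identity** is computed from an end-to-end (global) alignment
  under match +1 / mismatch −1 / gap −2 linear scoring, with identity =
  identical columns / total alignment columns (gaps count in the
  denominator). The scoring is exposed on `FilterConfig`. Because
  co-optimal alignments can differ in identity, the argument pair is
  canonically ordered before aligning, which makes the function exactly
  symmetric.
* **Length filter.** The cut is one-sided: a record is dropped when its
  length falls below mean − `length_sd_multiplier`·SD (default
  multiplier 2, population SD), with mean and SD computed per domain
  group over the pre-removal lengths in a single pass. The one-sided
  reading is deliberate — the filter's purpose is to remove fragments
  that are too short to align reliably, and an upper cut would discard
  legitimately complete genes.

## Habitat annotation

Annotation is data, not algorithm: the shipped mapping is a keyword table
from isolation-source phrasings to a controlled vocabulary of eleven
habitat terms plus two fine host-associated terms that merge upward into
`organism-associated`. Merge rules are applied exactly once (no
transitive chains). Two conventions are enforced: `cultured` contains
only artificial biofilters and bioreactors (laboratory strains keep their
original habitat), and `wastewater` (liquid) and `sludge` (semi-solid
residue) remain distinct. Sources absent from the mapping are reported
and their records excluded from community analyses rather than guessed.
Users can replace or extend the mapping with a TSV.

## Community phylogenetics

* **PD** uses the rooted convention: the minimal spanning subtree is
  anchored at the root, so a single tip has PD equal to its root-to-tip
  path. This matches the classical definition of the index and keeps PD
  monotone under set inclusion. `include_root=False` switches to the
  unrooted variant.
* **PSV** is computed from the exact tree covariance (V_ij = shared
  root-to-MRCA path length), converted to a correlation matrix;
  PSV = 1 − mean off-diagonal correlation. A star phylogeny yields
  exactly 1; lengthening a clade's stem drives the index toward 0.
* **UniFrac** is the unweighted (presence/absence) flavor: habitat
  membership here is presence/absence of sequences, so abundance
  weighting has nothing to weigh by. Each edge of the joint spanning
  subtree is classified shared/unique by a single postorder pass.
* **Rarefaction** corrects for unequal sample sizes by subsampling
  without replacement (default 1000 replicates, seeded); the common
  subsample size for cross-habitat comparison defaults to the smallest
  habitat's size. At the full community size the curve degenerates to
  the exact statistic with SD 0 (no resampling performed).
* **Habitat network**: complete graph, node attributes `pd` and `psv`
  (rarefied means when a common subsample size is given), edge weight
  1 − UniFrac. Written as GraphML plus a plain edge-list TSV.
* Boxplot-style five-number summaries use linear-interpolation quartiles.

## Diversification

* **MPL ultrametricization** uses the plain mean-path-length form: each
  internal node's age is the unweighted mean of its path lengths to
  descendant tips. Rate variation can date a child older than its
  parent; such conflicts are resolved by clamping the child to the
  parent's age, which produces a legal zero-length branch and keeps the
  output exactly ultrametric (root-to-tip spread ≤ 1e-9 relative). No
  standard-error weighting is applied — the plain form is deterministic
  and assumption-free.
* **Relative time**: root at 1, present at 0, by linear rescaling of
  ages. γ is invariant under this rescaling (checked numerically), so
  the convention is cosmetic but keeps LTT plots comparable across trees.
* **Internode intervals and γ.** Internal-node ages are sorted in
  decreasing order with each multifurcating node contributing its age
  (out-degree − 1) times — arithmetically identical to resolving
  multifurcations into zero-length binary ladders, since only interval
  durations enter the statistic; zero-length intervals (simultaneous
  events) are legal. Ties sort stably and do not affect γ.
* **Induced subtrees** for per-habitat γ: prune to the subset, suppress
  unifurcations, re-root at the subset's MRCA, retain original node
  ages, rescale to root age 1 before computing γ. γ rarefaction uses a
  geometric size grid from 3 to the smallest habitat size and 100
  replicates by default.
* No correction for incomplete taxon sampling is applied to γ (raw
  values are reported); a missing-taxa Monte-Carlo correction would be a
  natural extension.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with exact ground truth:

* **Trees**: constant-rate pure-birth simulation conditioned on the tip
  count (exponential waiting times between splits, a final interval after
  the last split, root rescaled to 1). With a positive death rate the
  simulation runs forward and prunes extinct lineages; stopping at the
  first time the extant count reaches n is exact for the pure-birth case
  and approximate conditioning when death > 0 — adequate for fixtures,
  not for inference about birth–death parameters.
* **γ regimes** come from the power transform age ↦ age^β on relative
  ages: β > 1 compresses node ages toward the present (γ > 0), β < 1
  toward the root (γ < 0), β = 1 is the identity. The transform is
  monotone, so topology and ultrametricity are preserved.
* **Habitat labels**: the tree is cut into n_habitats disjoint clades
  (splitting the oldest frontier node repeatedly); each tip inherits its
  clade's habitat with probability `clustering`, else draws uniformly.
  clustering = 1 gives exactly clade-faithful labels (minimal
  within-habitat PSV), clustering = 0 labels independent of phylogeny.
  Clade-based assignment was chosen over a Markov trait model because it
  gives exact ground truth for clustering-detection tests.
* **Sequences** evolve by Jukes–Cantor down the branches (per-site change
  probability 3/4·(1 − e^(−4μt/3))); ambiguity is injected as 'N' only,
  into a designated fraction of records, so filter accounting is exact.
  Isolation-source strings are drawn from the shipped mapping's keywords
  for each habitat, guaranteeing zero unmapped sources on round-trip.

Defaults (`SimulationConfig`): 120 tips, birth rate 1, death rate 0,
4 habitats, clustering 0.7, 400 nt, JC rate 0.25 substitutions/site per
unit of relative time (placing typical within-habitat identities in the
70–90% band), 5% ambiguous sites in 10% of records. Tests and the
acceptance checks use 30–120-tip trees and 100–500 replicates — sizes at
which every property being asserted is already statistically decisive.

What synthetic fixtures do **not** capture: real codon structure and GC
content, PCR/primer bias, alignment uncertainty, recombination, and
rate heterogeneity across sites and lineages. Passing tests demonstrate
the correctness of the statistics and the internal consistency of the
pipeline, not the robustness of biological conclusions drawn from any
particular public-database compilation.

## Numerical conventions

* Ultrametricity tolerance: 1e-9 relative on root-to-tip spread.
* Quartiles: linear interpolation.
* All randomized operations take explicit integer seeds and are bitwise
  reproducible; generators emit byte-identical files under a fixed seed.
* Degenerate inputs fail loudly: empty sequences, unknown tip ids,
  non-ultrametric trees where ages are required, p ≥ 0.75 for the JC
  distance (flagged as saturated rather than silently clamped).
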