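# Methods

## The model

The package predicts whether two small molecules share a protein binding
target by fusing heterogeneous similarity evidence in a naive-Bayes
likelihood-ratio framework, and layers target voting, mechanism clustering
and network construction on top.

**Evidence channels.** Five drug–drug similarity scores, each with a
defined range and an explicit notion of "undefined":

| channel | score | range | undefined when |
|---|---|---|---|
| `gi50` | Pearson r of growth-inhibition profiles (60 cell lines), pairwise-complete | [-1, 1] | < 3 shared observations, or constant restricted profile |
| `cmap` | Pearson r of averaged expression fold-change signatures | [-1, 1] | same |
| `bioassay` | Jaccard over shared *positive* assay outcomes | [0, 1] | no co-tested assay, or empty positives union |
| `sideeffect` | Jaccard over side-effect preferred terms | [0, 1] | empty union |
| `structure` | DICE over atom-pair count fingerprints | [0, 1] | both fingerprints empty |

Undefined scores are masked, never coerced to 0: zero is itself a
meaningful similarity value.

The atom-pair fingerprint uses the descriptor (element, heavy-neighbor
count, aromatic flag) per atom and the uncapped shortest topological bond
path between each unordered heavy-atom pair. This deliberately simple
variant keeps every unit-test fingerprint enumerable by hand (ethane has
exactly one feature; propane vs butane gives DICE 4/9); RDKit supplies
SMILES parsing and path lengths only.

**Likelihood ratios.** For each channel, scores of labeled drug pairs
(shared-target, ST, vs non-ST — a pair is ST iff the known target sets
intersect; drugs without annotations are orphans, not negatives) are
binned into 20 evenly spaced intervals over the channel's *natural* range
(not the observed extremes, so "evenly spaced" is dataset-independent).
The per-bin ratio with Laplace pseudocount α (default 1, so empty bins
stay finite) is

    L_b = [(ST_b + α)/(N_ST + αB)] / [(nonST_b + α)/(N_nonST + αB)]

and a smoothing curve L(s) = a·exp(b·s) is fit by least squares on
log L_b at bin centers, weighted by sqrt of total bin occupancy (empty
bins carry zero weight). If fewer than two bins are occupied the model
degenerates to a constant, which is still valid. Query scores marginally
outside the range (≤ 1% of its width, float noise) are clamped with a
warning; anything further out is a hard error.

**Total likelihood ratio.** Assuming approximate class-conditional
independence across channels — supported by the low cross-channel
correlation of the underlying scores — evidence multiplies:

    TLR = Π_channels L(s_channel)

The TLR is reported as the raw product, proportional to the posterior
odds of a shared target; all cutoffs (100 for ordinary predictions, 500
for high-confidence calls) are on this raw scale. A channel the pair
lacks contributes L(m), where m is the median of all observed scores of
that channel; imputation happens *after* the similarity→likelihood
conversion so that missing data never distorts the fitted curve.

**Target voting.** Partners with known targets whose TLR to the query
clears the cutoff are shared-target predictions; each known target of a
partner receives a vote weighted by that prediction's raw TLR (log-TLR
weighting is available as an option). Ties in vote mass break by higher
supporting-prediction count, then higher maximum supporting TLR, then
lexical target ID — deterministic and logged. The high-confidence filter
confirms the top-voted target only if it appears in the known targets of
a strict majority (> half) of the predictions *and* in the targets of the
single highest-TLR prediction; otherwise it abstains rather than
substituting a weaker call.

**Mechanism clustering and networks.** Pairwise distance is exactly
1/TLR. Mechanism-of-action dendrograms use average-linkage agglomeration
(implemented here so that ties break lexically on cluster member IDs and
trees export as Newick with merge heights; scipy's implementation is the
independent test oracle). Undefined TLRs inside a clustering set are a
hard error naming the missing pairs — silently imputing a distance would
fabricate mechanism structure. Shared-target networks keep edges with
TLR ≥ cutoff (default 500) and retain an orphan node only if it connects
to at least 2 annotated drugs. Universe embedding uses classical
(Torgerson) multidimensional scaling via eigendecomposition of the
double-centered squared distance matrix, the direct analogue of R's
`cmdscale`.

## Evaluation machinery

Cross-validation is stratified at the *pair* level (per-fold ST:non-ST
ratio equals the global ratio within one pair); models are refit on each
training fold and the held-out TLRs of all folds are pooled into one ROC
curve. Pair-level CV lets one drug appear on both sides of a split; this
leakage is inherent to the pairwise design being evaluated and is kept as
the default. A `drug_disjoint=True` mode partitions drugs instead,
keeping training pairs fully clear of test-group drugs at the cost of
discarding cross-group pairs. AUROC uses the Mann–Whitney formulation (ties
half credit). KS separation is the two-sample D statistic with the
asymptotic p-value (exact available). Channel-subset AUROCs are computed
under two availability policies: require every included channel observed,
or impute channel medians; only the imputation policy yields subset means
over a common pair population, so monotonicity in the number of channels
is asserted there.

## The synthetic universe

The generator plants ground truth with the statistical structure the
method needs and nothing more. Each target owns an independent latent
signature per channel (a Gaussian profile vector; a latent positive
feature set; a fingerprint count template). A drug's payload inherits its
targets' signatures at signal strength `s` (profiles:
`s·base + √(1−s²)·noise` with the multi-target base variance-normalized;
binary/fingerprint features kept with probability `s`) plus independent
background noise, so at `s = 0` every channel is pure noise and at the
default `s = 0.8` shared-target pairs are strongly similar in every
channel while channels stay class-conditionally independent.

Defaults (the stated world): 200 drugs, 10 targets, targets-per-drug
= 1 + Poisson(0.3), 15% orphans, per-channel whole-payload missingness
10%; GI50 profiles 60-dimensional (the panel width) with 5% cell-level
gaps; expression signatures 978-dimensional (landmark-gene scale);
bioassay vocabulary 500 with 60% tested fraction; side-effect vocabulary
300, presence/absence; 400 structure fingerprint keys. The structure
channel is generated directly as count vectors — generating molecules
with controlled pairwise DICE is a research problem in its own right —
and the real-SMILES fixture set covers the SMILES→fingerprint path. One
seed drives per-stage splittable generators, so adding a channel never
perturbs another's draws, and regeneration is bit-identical.

What the generator does *not* emulate: real marginal distributions of
GI50/expression data, pharmacological co-occurrence structure of side
effects, and realistic chemical similarity landscapes. A green test on
this world establishes that the machinery is correct and that integration
behaves as designed — not that real-corpus performance numbers are
reproduced.

**Mechanism scenario.** The mechanism-clustering tests use a dedicated
configuration (`mechanism_universe_config`): two targets, single-target
drugs, no orphans, full channel coverage, with the first target split
into two sub-mechanisms whose latent signatures overlap by 0.3. This
emulates a curated mechanism study (e.g. microtubule stabilizers vs
destabilizers, all well-annotated marketed drugs). It is deliberately
*not* the default screening universe: recovery of mechanisms from raw
1/TLR distances under average linkage is dominated by the single weakest
within-mechanism pair, so

* a drug covered in only 3 of 5 channels has every TLR deflated by the
  two imputed channels' L(median) factors and its distances inflate by a
  constant, making the dendrogram's top split a coverage artifact; and
* multi-target drugs dilute the mechanism signature (their payload is a
  mixture over targets), producing weak within-mechanism pairs.

Both failure modes are real limitations of the 1/TLR metric and are the
reason mechanism clustering should be run on well-covered,
mechanism-dedicated drug sets (the original analysis likewise restricted
to drugs present in at least three data sources).

## Numerical choices and degenerate inputs

* Pseudocount α = 1 on bin counts (the raw ratio can divide by zero).
* Histogram edges include the right boundary in the last bin, so a score
  equal to the range maximum is counted.
* Profile correlations are computed via masked sufficient statistics
  (five matrix products) rather than per-pair loops; variances below
  1e-12 are treated as constant profiles (undefined).
* An empty prediction set is an explicit abstention everywhere
  (vote tally, confidence filter, accuracy denominators); leave-one-out
  accuracy reports abstention counts separately instead of scoring them.
* TP/FP ratio is reported as infinite when FP = 0, with the counts, and
  flagged degenerate when TP = 0 as well.
* Model serialization stores floats as hex (`float.hex`), so bin edges,
  ratios, fit coefficients, medians — and hence TLRs — round-trip
  bit-exactly; a version header mismatch or truncated file is a hard
  error with no partial model.
* Orphan screening requires data in ≥ 3 of the 5 channels (configurable).

## Known limitations

* Channel dependence is not modeled; strongly correlated channels would
  double-count evidence (the naive-Bayes assumption is validated on the
  synthetic world, approximated on real data).
* The exponential smoothing family is a strong prior on the shape of
  L(s); channels whose true log-likelihood ratio is non-monotone in the
  score would be misfit. The binned raw ratios are retained in the model
  for inspection.
* Raw 1/TLR distances have enormous dynamic range when channels separate
  strongly; see the mechanism-scenario discussion above.
* Pair-level CV leaks drug identity across folds (by design, to match
  the evaluated protocol).
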