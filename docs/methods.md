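# Methods

This note documents the models implemented in `ctpdn`, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Network construction and compound ranking

The compound–target–pathway–disease network (CTPDN) is an undirected graph
with typed nodes and typed, weighted edges.  Edge scores `S` are
class-specific:

* **CTI** — the docking-score ratio `S = s_i / s_m` between the candidate
  compound's interaction score and the target's native-ligand score.  Both
  are sign-flipped interaction energies, so larger is stronger; `S = 1`
  means the compound binds like the native ligand.  A failed docking is "no
  interaction": the pair simply has no edge.
* **TTI** — the PPI combined score in (0, 1], taken as `S` directly
  (default `tti_mode="combined"`).  The source phrasing "reciprocal of the
  combined score" is ambiguous because the length rule below takes a
  reciprocal already; `tti_mode="reciprocal"` applies a second reciprocal
  for users who read it the other way.
* **TPI** — membership, `S = 1` by default.  `tpi_mode="qweight"` instead
  uses `S = −log₁₀ q` (clipped to [1e−3, 1e3]) so that more significant
  pathways attract shorter paths.
* **PDI** — existence; the normalized weight is fixed at exactly 1.

Every score becomes a length `L = 1/S` (+∞ for no interaction) and a weight
`W = 1/(1 + e^(−L))` (PDI excepted).  Finite non-PDI weights therefore lie
strictly in (0.5, 1), so a canonical compound–target–pathway–disease path
has total weight strictly between 2 and 3; the test suite asserts this.
Note that the mapping is *increasing* in `L`: weaker interactions (longer
`L`) get weights closer to 1 and are penalized by the shortest-path search,
while strong interactions approach 0.5.  A `sigmoid_sign` switch exposes the
mirrored variant `1/(1 + e^(+L))` for sensitivity analyses; the default is
the literal rule.  (In double precision the logistic saturates to exactly
1.0 for `L` beyond ~37; no realistic score ratio comes close.)

The adjacency matrix is symmetric with an exactly-zero diagonal and +∞ for
absent pairs (serialized as the string `"inf"`).  Duplicate score records
for a pair keep the largest `S` (strongest binding) with a warning; edges
whose endpoints are not declared nodes are an error naming the offending id.

All-pairs shortest paths use the Floyd–Warshall recurrence with a successor
matrix for path reconstruction.  Updates are strict improvements only, so
results are deterministic for a fixed node order; nodes are ordered by layer
and lexicographically within a layer, which also fixes tie-breaking.
Compound ranking averages the shortest-path length over all disease nodes
and sorts ascending, ties broken by compound id; a compound that cannot
reach every disease is reported with mean length +∞ and left unranked, with
a warning.  Path shapes are classified from the layer sequence:
one intermediate target → `C-T-P-D`, a chain of two or more targets →
`C-T-T-P-D`, anything else (including layer zigzags) → `other`.

Node screening applies before construction: compounds need oral
bioavailability ≥ 30% and drug-likeness ≥ 0.18 (inclusive bounds, as the
criteria are stated with ≥), pathways need enrichment p strictly below
1×10⁻⁸ and a nonempty member-target list.  All thresholds are `RunConfig`
fields, not constants, so the pipeline transfers to other formulas.

*Remark.*  Under this literal normalization no compound–disease shortest
path can be shorter than 2, so reports of mean path lengths well below 2 in
comparable analyses must arise from a different weight convention; the
`sigmoid_sign` and `tti_mode` switches exist to explore such variants, and
no acceptance value depends on them.

## CTI feature construction

Compound block: MACCS keys are emitted as 167 positions (position 0 is
unused by the key definition but kept, which is what makes the MACCS-based
descriptor count 167 + 5 + 29 = 201); ECFP6 is a Morgan fingerprint of
radius 3 folded to 2048 bits, giving 2048 + 5 + 29 = 2082.  The five ADMET
levels (aqueous solubility, blood–brain barrier, CYP2D6 inhibition,
hepatotoxicity, plasma protein binding) are consumed as given — they are
upstream predictions, not computed here.

Protein block (29 entries, fixed order): 20 amino-acid counts, theoretical
pI, molar extinction coefficients at 280 nm (all-cystine and all-reduced;
5500 per Trp, 1490 per Tyr, 125 per cystine pair), three N-end-rule
half-life estimates in hours (mammalian reticulocyte, yeast, E. coli;
open-ended table entries like ">20 h" are encoded as their bound, and the
untabulated E. coli value for N-terminal Pro as 10 h), the Guruprasad
instability index, Ikai's aliphatic index, and Kyte–Doolittle GRAVY.  The
hydropathy and dipeptide-instability tables are imported from Biopython's
published ProtParam data module rather than re-typed; pI uses the Bjellqvist
pKa set including the residue-specific free-terminus values, solved by
bisection on the Henderson–Hasselbalch net charge to a 1e−6 pH interval.
The descriptor code is written here and cross-checked in the tests against
Biopython's independent ProtParam implementation.

Non-standard residues (B, Z, X, U) are rejected by default;
`tolerate_ambiguous` drops them, so they contribute to no descriptor.

Each target carries two sequence variants (`<id>|full`, `<id>|motif` FASTA
records); the dataset kind (MF/MM/EF/EM) selects fingerprint × variant.
Duplicate-column removal deletes any descriptor column whose values repeat
an earlier column across all rows (constant columns are deduplicated the
same way), keeps the first occurrence, never touches the label, and is
idempotent.  Conformance counts (201/2082) refer to the roster before this
removal; both counts are observable.

## Classifier and evaluation

The ensemble is discrete (SAMME) AdaBoost over depth-limited CART trees.
"Maximum number of splits 20" is enforced as `max_leaf_nodes = 21`; defaults
are 30 learners and learning rate 0.1 (multiplying the learner weights αₖ).
Weak learners are fitted with scikit-learn; the fitted trees are then
flattened to arrays and the decision rule `sign(Σₖ αₖ (2Gₖ(x) − 1))` — with
a tie at exactly 0 predicting negative — is evaluated by this package's own
traversal, which is also what the JSON model serialization round-trips.

Feature normalization is per-column min–max to [0, 1] by default (z-score
selectable); constant columns map to 0; the fitted parameters are stored in
the model and reused at prediction time, so out-of-range test values may
leave [0, 1] — that is intentional.

Metrics come from the confusion counts: precision TP/(TP+FP), recall
TP/(TP+FN), F1 as their harmonic mean, MCC with the convention that a zero
denominator factor yields 0, and AUC by the rank statistic
(Σ ranks of positives − M(M+1)/2)/(M·N) with average ranks on ties — equal
to brute-force positive–negative pair counting with ties at 0.5.

Cross validation is stratified 10-fold.  Rows are first placed in a
content-canonical (lexicographic) order and then permuted by the seeded RNG
before round-robin fold assignment, which makes the folds — and hence every
reported metric — invariant to the order in which rows arrive.
Normalization is refitted inside each training fold.  The pooled report
carries a per-fold breakdown and the seed.  A one-stump baseline is
available behind the same interface for comparisons.

Per-target screening featurizes every compound against a target with the
model's own dataset kind and reports the percentage predicted positive
("CTI success rate").

## Metabolomics screen

The preprocessing chain runs in a fixed order and logs survivor counts per
stage: (1) drop features missing in >80% of samples, impute the rest with
the feature's observed mean; (2) drop features whose pooled-QC relative
standard deviation exceeds 20% (undefined RSD — QC mean 0 — also drops, with
a warning); (3) drop the 40% of features with the lowest raw-scale standard
deviation over the biological samples, ties resolved by feature id;
(4) sum-normalize each sample to the median sample total, log₁₀ with a
pseudo-count of half the minimum positive intensity, mean-center each
feature (`autoscale` adds unit variance; off by default, since "scaled" in
the source protocol is ambiguous and centering alone is the conservative
reading).  Because the variance filter acts on raw intensities, it removes
low-abundance features regardless of biological signal — a property users
should be aware of when interpreting negatives.

VIP scores come from a PLS-DA fit (scikit-learn's NIPALS PLS on the centred
class indicator, 2 components by default, capped at the data rank):
VIPⱼ = sqrt(p·Σₐ SSₐ(w_{aj}/‖wₐ‖)² / Σₐ SSₐ) with SSₐ the y-variance
captured by component a, so mean(VIP²) = 1 identically.  The differential
criterion is VIP > 1 AND two-sided Welch t-test p < 0.05 (computed on the
log-centred scale) AND bidirectional fold change max(FC, 1/FC) > 1, with FC
the ratio of group means on the pre-log, sum-normalized scale.  The
bidirectional form is used because an "absolute fold change" of a positive
ratio would only ever select up-regulation; with the default threshold 1 it
passes any non-equal means, and the threshold is configurable.  p-values are
reported raw (no multiplicity adjustment) to match the screening convention;
a Benjamini–Hochberg column can be added downstream.  Sum normalization
makes the whole screen invariant to per-sample global scaling, which the
tests assert exactly.  An orthogonalized PLS variant is deliberately not
implemented: VIP thresholding is the operative criterion, and plain PLS-DA
supplies it.

Biomarker panels rank features by mean random-forest importance across
stratified CV training folds and keep the top k (default 10).  The reported
accuracy and rank-AUC come from an outer stratified CV in which features are
re-ranked on each training fold alone and a fresh forest is fitted on that
fold's top-k — selection never sees its test samples.  Fold counts clamp to
the smaller class.  Panels from two group contrasts intersect preserving the
first panel's order.

## Synthetic data

The generator emulates a complete study design at desk scale; every output
is a
pure function of (spec, seed), and ground truth is emitted alongside the
data so recovery tests never reach into generator internals.

* **Network**: 10 compounds, 8 targets, 4 pathways, 2 diseases by default;
  docking success probability 0.6, PPI density 0.3; reference scores `s_m`
  uniform in [20, 60] and score ratios uniform in [0.5, 1.0].  One planted
  compound docks successfully against every target with ratios multiplied
  by 2 — since 2 × 0.5 ≥ 1.0, each of its edges is strictly lighter than any
  competitor's edge to the same target, which guarantees rank 1.  The truth
  record names that compound and its expected shortest path per disease,
  found by brute-force enumeration over layered paths (up to three relayed
  targets) with locally re-derived edge weights.
* **CTI dataset**: SMILES come from a deterministic scaffold + chain +
  terminal fragment grammar (~420 parseable molecules) — fingerprints need
  diversity, not natural-product realism.  Protein sequences are i.i.d.
  draws from database-like residue frequencies (uniform selectable),
  lengths 50–300; the motif variant is a contiguous slice.  Labels follow
  "designated MACCS bit set AND target GRAVY above the median", the bit
  chosen so the positive rate lands in [0.3, 0.7], then flipped at the label
  noise rate.  The default pair count is 966, the size of docking-labelled
  pair set the classifier is designed for.
* **Peak table**: groups Con/Mod/BWG with 6 animals each (a typical
  preclinical group size) plus 6 pooled-QC injections; 200 features with log₁₀ baselines
  uniform in [4, 7] and within-group log-sd 0.2.  Planted features (3 by
  default) shift the Mod mean by 4 within-group sd on the log scale, with
  BWG midway back toward Con (partial recovery); their baselines are drawn
  from the upper half of the intensity range because a marker below the
  raw-scale variance-filter floor would be undetectable by construction.
  QC noise is set so the raw-scale QC RSD matches 5% (optionally some
  features get a deliberately high RSD to exercise the QC filter);
  missingness is completely at random on biological samples only — pooled
  QC mixes contain every analyte, so their peaks are present.

What the generator does **not** emulate: correlated metabolite modules,
intensity-dependent (left-censored) missingness, drift across injection
order, chemically realistic fingerprint correlation structure, or docking
scores derived from structures.  Passing recovery tests therefore shows the
pipeline's statistical machinery is correct and calibrated under the stated
noise model, not that it will achieve the same power on a given real
dataset.

## Problem sizes used in the checks

The automated conformance checks run at sizes chosen to exercise every code
path while staying convenient on a laptop: Floyd–Warshall versus a Dijkstra
oracle on 100 random 12-node graphs; rank-AUC versus pair counting on 1,000
random score sets; planted-compound recovery over 100 simulated networks;
classifier recovery on 1,000 labelled pairs (half held out) at label noise 0
and 0.5; screen calibration over 100 null replicates of 200 features and
power over 100 replicates with planted 4-sd effects.

## Known limitations

* The network is undirected; the "direction" of pharmacological action is
  expressed only through the path-shape classifier, not through edge
  orientation.
* Edge weights are additive costs; there is no probabilistic interpretation
  of a path's total weight.
* The AdaBoost variant, normalization method and CV stratification are
  stated conventions where the source protocol is silent; all are switchable
  and recorded in reports, but a different upstream toolchain may have used
  different defaults and produce different absolute metric values.
* The metabolomics chain assumes one peak table with a shared QC pool;
  batch correction and injection-order drift are out of scope.
* Pathway enrichment, metabolite identification and all upstream score
  generation (docking, ADMET, motif discovery) are consumed as inputs.
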