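# Methods

## Problem and data model

The unit of prediction is a single cysteine residue in a protein sequence,
represented by the window of `n` residues on each side (`2n+1`-mer, default
`n = 10`). Positions beyond a terminus are filled with the pad symbol `-`,
treated as the 21st alphabet symbol by positional encoders. Non-standard
residues (B, J, O, U, Z) are mapped to `X`, which encodes as all-zero in
every feature block and belongs to no residue group; how ambiguous residues
were handled in the original corpora is generally unreported, and the
zero-vector convention keeps them from asserting evidence they do not carry.

A training corpus is a set of proteins with annotated modified cysteines.
Positives are windows at the annotated sites; negatives are windows at every
other cysteine of the same proteins, which reflects how such corpora are
built (the experiment certifies the protein, not the unmodified sites) and
yields a realistic class imbalance — about 4.66 negatives per positive in
the reference mouse S-nitrosoproteome scale this package emulates
(384 proteins, 586 positive and 2,728 negative sites). Coordinates are
1-based in all files, 0-based internally.

## Homology reduction

Independent-test evaluation first removes test windows the model has
effectively seen. Two proteins are homologous when their pairwise identity
exceeds 0.30; identity is computed from a local alignment (BLOSUM62, gap
open 11 / extend 1, BL2SEQ-like defaults) as identical pairs over aligned
columns. For homologous protein pairs, a test window identical to a training
window of the same class (exact `2n+1`-mer string equality, pads included)
is discarded; the training set is never modified. The identity function is
pluggable so a global-alignment definition can be swapped in. The operation
is idempotent and only ever shrinks the test set.

## Feature encodings

* `AA_20D` — per-position one-hot over the 21 symbols, length `21(2n+1)`.
* `AA_PWM` — the window's per-position relative frequency under a positional
  weight matrix built from positive windows; inside the model each MDD leaf
  fits its own PWM from its member positives so the encoding reflects the
  leaf motif (a global-PWM mode is available by training a single-leaf
  model). Length `2n+1`.
* `AAC` — composition over the 20 standard residues; pads and `X` are
  excluded from numerator and denominator, so the vector sums to 1 whenever
  a standard residue is present.
* `ASA` — per-residue relative accessible surface area consumed from an
  external predictor's output (percent, rescaled to [0, 1]; pads are 0).
  No structure prediction is performed here.
* AAindex blocks — one value per residue under a physicochemical scale
  parsed from the AAindex1 flat file. Values are min-max scaled over the 20
  residues before encoding (chosen over z-scoring; it only affects SVM
  conditioning since the downstream F-score is affine-invariant). Entries
  containing `NA` are excluded from ranking by default.
* Motif blocks — one bit per user-supplied pattern (a conjunction of
  (position, allowed-residue-set) constraints); patterns come from a
  tab-separated pattern file since curated motif lists are corpus-specific.

Descriptive analyses mirror the standard figures for a PTM corpus:
per-position residue frequencies (sequence-logo content), a
positive-vs-negative enrichment table per (position, residue) using
two-proportion z-tests at p < 0.05, and class-wise mean ASA profiles.
No graphical rendering is bundled; the tables are the contract.

## F-score ranking and forward selection

For one numeric feature the F-score is the squared deviation of the two
class means from the grand mean divided by the sum of the two sample
variances. It is label-symmetric and invariant under common affine maps.
A property scale is scored per window position and ranked by the
position-averaged score, ties broken by accession. The degenerate case
(zero within-class variance, unequal means) returns `inf` so perfectly
separating scales sort first instead of crashing. Forward selection adds
ranked scales into a base feature set one at a time, keeps an addition only
if cross-validated accuracy improves, and stops after three consecutive
non-improvements (configurable).

## Maximal dependence decomposition

Residues are collapsed to five biochemical groups — aliphatic `AGILPV`,
polar-uncharged `CMNQST`, acid `DE`, basic `HKR`, aromatic `FWY`. This
grouping is a reconstruction of the conventional scheme and is fully
overridable from a scheme file. Pads and `X` belong to no group: windows
carrying them at either position of a pair are dropped from that pair's
contingency table, and any split routes them to the "absent" branch.

For every ordered pair of flanking positions the 5×5 Pearson chi-square is
computed (plain statistic, no continuity correction; cells with zero
expectation contribute nothing). A pair is significant above 34.3, the
upper 0.005 quantile of chi-square with 16 = (5−1)(5−1) degrees of freedom;
the degrees of freedom are held at 16 regardless of empty rows or columns to
match the fixed cutoff. A position's dependence score sums its significant
pairwise statistics only; the position with the largest score is the split
position (ties prefer positions closer to the modified cysteine, then the
more N-terminal). The split group at that position is the one whose
presence/absence partition maximizes the summed 2×2 chi-square against every
group at every other position — an adaptation of consensus-based splitting
to residue groups, since only the outcome of the selection, not its rule, is
conventionally reported; ties break by the scheme's group order.

Recursion stops when a subgroup is smaller than `max_cluster_size`
(default 100, chosen so corpora of a few hundred positives yield on the
order of ten subgroups), when no pair is significant, or when a child would
fall below `min_leaf_size` (default 15, keeping leaf SVMs trainable).
Leaves are numbered in depth-first order (present branch first), carry their
member windows and a per-position dominant-group motif summary (≥ 60%
occupancy), and always partition the input. Prediction-time routing is a
deterministic descent of the same tests.

## Per-leaf SVMs

Each leaf trains an RBF-kernel SVM on the leaf positives plus negatives
sampled without replacement from the full negative pool at
`round(ratio × leaf size)`, with ratio defaulting to the training data's
own negative:positive ratio. To guard against a skewed draw, ten negative
sets are sampled per leaf (reproducibly from the seed and round index) and
stratified 5-fold cross-validation is repeated on each; hyper-parameters
(C from 2⁻⁵…2¹⁵, gamma from 2⁻¹⁵…2³, both in ×4 steps, LibSVM practice) are
grid-searched per round by CV accuracy, and the configuration winning the
most rounds is refit once on the positives plus the first (seed-fixed)
negative sample to give the deployed leaf model. Single-point grids skip
the search. The leaf PWM lives inside the CV pipeline, so it is always
fitted on training folds only. The model-level CV accuracy is the
leaf-size-weighted mean of per-leaf pooled CV accuracies. The decision
threshold on the SVM decision value defaults to 0; class weighting is off
because negatives are already ratio-matched.

The fitted model serializes to a directory archive (tree JSON, per-leaf PWM
TSV and SVM blob, config snapshot); a save/load round trip reproduces
decision values exactly.

## Evaluation

Six metrics derive from the confusion counts: Sn, Sp, Pre, Acc,
BAcc = (Sn+Sp)/2, and MCC (defined as 0 when its denominator vanishes;
other zero-denominator metrics are reported as NaN). Cross-validation uses
label-stratified folds and reports pooled counts — folds' confusion counts
are summed before metrics are derived — because pooled counts are exactly
recomputable and insensitive to fold-size jitter; per-fold reports are also
emitted. Independent testing tallies counts overall and per species tag.
Printed tables keep six decimals; full precision is preserved in memory.

## Synthetic data generator

The generator emulates the statistical structure the method exploits, not
the biology of any real S-nitrosoproteome. Defaults mirror the reference
corpus scale: 384 proteins of length 100–400 (uniform), 586 positive sites,
negative:positive ratio 4.655, SwissProt-like background composition.
Cysteines are placed only deliberately (background excludes C), sites are
spaced more than `n` residues apart so a planted flank residue never
collides with a neighbouring site's cysteine, and positives keep a full
flank inside the chain so every planted target is in bounds; negatives
relax the spacing only when a protein is too short. Planted rules set a
residue from a named group at a signed offset with a given penetrance,
optionally together with a partner (offset, group) — the co-occurrence that
creates true between-position dependence. Rules can fire independently per
positive or as an exclusive mixture (each positive draws one rule), the
regime that produces distinct motif subpopulations. Planted residues never
include C. The optional ASA model draws per-residue Gaussian percentages
with elevated upstream (−n…−2) means at positive sites and the lowest mean
at cysteines in both classes. Outputs are the exact input formats of the
I/O layer plus a manifest recording which rules fired at each site; equal
seeds give byte-identical files.

What passing synthetic tests does **not** show: robustness to homologous
redundancy inside a real training set, to annotation noise, to
composition differences across proteomes, or to ASA predictors' error
structure — real corpora are messier than planted penetrance.

## Problem sizes used in tests and the acceptance script

The bundled checks run the full method at reduced scale as the package's
own choice of test conditions: planted-dependence recovery uses 600
positives at penetrance 0.6 over 20 seeds; the MDD-versus-single-SVM
comparison uses 400 positives (exclusive mixture of four full-penetrance
motifs) over 10 seeds with fixed hyper-parameters (C = 8, gamma = 0.125) and
one negative round for both arms, so the comparison isolates the clustering;
the end-to-end pipeline smoke uses ~100 positives. Grid search and
ten-round resampling remain the training defaults.

## Known limitations

* The five-group scheme and the group-selection rule at a split are
  principled reconstructions; alternative schemes can change the tree.
* Windows are purely sequence-local; structural context enters only through
  externally supplied ASA values.
* Accuracy under heavy class imbalance is dominated by specificity; BAcc
  and MCC are reported for that reason and should be preferred when
  comparing models.
* The decomposition is greedy: an early split is never revisited, and small
  leaves can surface background-dominant "motifs" in their summaries.
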