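# Methods

This note documents the models and procedures implemented in
`amesqsar`, the defaults chosen where the design was genuinely open, and
what the synthetic test bed does and does not establish about behavior
on real assay data.

## Problem setting

The Ames bacterial reverse-mutation assay yields a binary endpoint per
compound: mutagen (1) or nonmutagen (0), with some outcomes recorded as
equivocal. A QSAR classifier maps molecular structure, encoded as
fingerprints or descriptors, onto that endpoint. Because the assay
itself calls a compound mutagenic if *any* required bacterial strain
responds, an any-positive (OR) vote over member models is a natural
integration rule, and it is the one implemented here.

## Curation

Structures are parsed with RDKit, sanitized, and reduced to the largest
connected component, which removes counter-ions and solvents.
Canonical aromatic (non-kekulized) SMILES is the deduplication key — a
stable key is more important than any particular dialect.
Stereochemistry is retained as supplied. Equivocal labels are removed
before binary modeling. When duplicated structures carry *conflicting*
binary labels, all of their records are dropped and the conflict is
reported: silently preferring one label would bias the set in an
unauditable way, and such compounds are rare enough that losing them is
cheaper than guessing. The train/test split draws a seeded uniform
permutation and assigns the first ⌊(1−f)·n⌋ compounds to training, so a
90:10 split of 5866 compounds gives 5279/587. Splitting is *not*
stratified by label; the class balance of the pool carries over in
expectation.

## Featurization

All built-in families are pure functions of the canonical SMILES,
computed locally with RDKit. Defaults: circular fingerprints (ECFP
standard, FCFP feature-class invariants) radius 2 with 2048 bits; the
hashed atom-pair, topological-torsion, RDKit path, layered and pattern
fingerprints also 2048 bits; Avalon 2048; MACCS fixed at 167 keys.
These are the community defaults and keep matrices desk-scale. The
continuous family, `Descriptors2D`, is RDKit's 2-D descriptor set
(~210 constitutional, topological and physicochemical values); it may
contain non-finite entries before hygiene, which is exactly what
`clean_matrix` handles. Language-model or other external embeddings are
supported only as precomputed tables keyed by molecule id
(`register_external_family`) — they are never computed in-process.

Feature hygiene: columns containing any non-finite value are always
dropped; constant columns are dropped only when explicitly requested
(the correlation-filter comparison turns this on; the main pipeline
leaves it off, since constant fingerprint bits are harmless to the
network and keep key numbering intact). The correlation filter removes
one member of every pair with |Pearson r| above the threshold (default
0.9), keeping the larger-variance member; offending pairs are resolved
greedily in descending |r| with ties broken by column index, which makes
the output independent of input column order up to that documented rule.

X-randomization permutes whole rows of the feature matrix against fixed
labels (classical X-scrambling). A per-column variant is available
behind a flag but is not the default, because row permutation preserves
within-molecule feature correlations and therefore tests exactly the
structure–label association and nothing else.

## Classifier

The network is a fully connected ReLU stack with a single logistic
output trained on binary cross-entropy, implemented directly in NumPy.
This makes every run bit-reproducible from one integer seed (weight
initialization and epoch shuffling share a generator) on any machine —
a property worth more than training speed at these model sizes.
Defaults where the architecture family leaves them open: learning rate
1e-3, 100 epochs, batch size 32, no early stopping, no batch
normalization, no class weighting. He initialization for hidden layers,
Glorot for the output. Optimizers: Adam and Adamax (β₁ = 0.9,
β₂ = 0.999, ε = 1e-8); Adamax replaces the second-moment average with
an infinity-norm running maximum. The decision threshold is 0.5 with
the boundary mapped to the positive class. Cross-validation is
stratified (plain k-fold can produce single-class folds at small n,
which makes several scores undefined); fold models get distinct
deterministic seeds derived from the configuration seed.

## Integration and selection

OR-voting operates on hard labels after thresholding, not on
probabilities — the vote mirrors an assay decision rule, not a
probabilistic ensemble. Two set identities follow directly and are
asserted in the tests: integrated false negatives are the intersection
of member false negatives, integrated false positives the union of
member false positives; hence recall(pair) ≥ max member recall and
specificity(pair) ≤ min member specificity on any fixed evaluation set.
Pair selection uses cross-validation metrics only (never the test set):
the winner maximizes the unweighted mean of CV accuracy, balanced
accuracy and precision, with ties broken by balanced accuracy and then
pair name.

## Scores

The six scores are computed from exact integer confusion counts with the
mutagen class positive. Zero-denominator conventions: precision and
recall are 0 when undefined, F1 is 0 when precision + recall is 0, and
the MCC is 0 whenever a factor under its root vanishes — these keep
every score total so fold aggregation never fails.
`reconstruct_confusion` inverts rounded precision/recall back to integer
counts by exhaustive search over (TP, FP); it reports ambiguity
explicitly (all consistent matrices) rather than picking one, because
the inverse is only trustworthy when unique.

## Applicability domain

Leverage h = x (XᵀX)⁺ xᵀ against h\* = 3(p+1)/n. No intercept column
is added; p counts features as supplied. Binary fingerprint designs are
routinely rank-deficient, so the Gram matrix is inverted with a
Moore–Penrose pseudo-inverse at NumPy's machine-epsilon-scaled cutoff;
this keeps in/out decisions reproducible where a naive inverse would be
numerically unstable. The boundary h = h\* counts as in-domain. For
full-rank designs the training hat values lie in [0, 1] and sum to p
(trace of the projection); both properties are asserted in tests. Note
that at desk scale (p comparable to n) h\* can exceed 1, making the flag
vacuous — meaningful AD decisions need n ≫ p, as in the continuous
descriptor space used by the AD example.

## Shapley attribution

The estimator is permutation-sampling Shapley: per explained compound,
each Monte-Carlo draw picks a background compound and a random feature
ordering, walks the path from background to explained row, and credits
each feature with its output increment. Path increments telescope, so
the attribution sum per row equals f(x) minus the mean output of the
*sampled* backgrounds exactly; against the reported baseline (mean
output over the full background) local accuracy holds up to the
Monte-Carlo error of that mean, which is the tolerance the tests use
(0.02 at 2048 samples). Null features receive exactly zero; duplicated
features share credit in expectation (symmetry). Default background is
100 training rows. MACCS keys are grouped for reporting into halogen,
nitrogen-containing, oxygen-containing, ring-related and other by
inspecting their SMARTS definitions, with halogen > nitrogen > oxygen >
ring precedence when a key contains several element classes.

## Counterfactual analogs

The search returns the candidate with the smallest Tanimoto distance
d = 1 − T(x, x′) (radius-2 circular fingerprints, 2048 bits) among
those whose predicted label differs from the base compound. Candidates
come either from the caller or from a deterministic single-edit
enumerator: add, remove or swap one substituent from {F, Cl, Br, I,
NO₂, NH₂, CH₃, OH} at substitutable positions. The enumerator is
deliberately conservative — it demonstrates boundary-crossing edits, it
does not claim synthetic feasibility of the analogs.

## ARKA and activity cliffs

Descriptors are min-max scaled on training data and partitioned by class
preference: D⁺ (higher mutagen mean) and D⁻ (higher nonmutagen mean),
with exactly tied descriptors excluded. ARKA₁ is a compound's average
over D⁺ centered by the training grand mean of that average; ARKA₂ the
same over D⁻. Centering puts the training set at (0, 0) on average and
gives the sign symmetry the quadrant thresholds assume. The
class-expected regions are ARKA₁ > 0.5 ∧ ARKA₂ < −0.5 (mutagen) and
ARKA₁ < −0.5 ∧ ARKA₂ > 0.5 (nonmutagen); a compound in the opposite
class's region is flagged a potential cliff and paired with its nearest
neighbor by L1 distance in the ARKA plane. The published ARKA residual
has variant formulations; the set-average-minus-grand-mean form used
here is documented as this package's definition, and the region
thresholds and cliff rule are applied to it verbatim. One practical
consequence: the strict ±0.5 regions are only populated when class
descriptor profiles are strong and class balance is uneven, so mild
libraries can legitimately contain zero cliffs.

## Synthetic test bed

The generator assembles molecules from a small grammar (substituted
benzenes, naphthalenes, short alkyl chains; substituents F, Cl, Br,
NO₂, NH₂, OH, CH₃, OCH₃) and plants the rule *nitro group ⇒ mutagen*,
then flips a per-class-stratified fraction of labels
(label = rule XOR flip). Defaults: n = 600, positive fraction 0.5,
label noise 5 %, chosen as the smallest configuration at which a
10-fold CV of the selected architecture is comfortably separated from
both chance and the noise ceiling. The X-randomization check uses
n = 600 with a 50:50 holdout so the chance-level balanced-accuracy
estimate has small binomial error.

What passing on this bed shows: the pipeline wiring, the determinism
contracts, the vote algebra, the attribution axioms and the diagnostic
machinery all behave as specified, and the classifier can recover a
real structure–label rule through fingerprint features. What it does
not show: performance on real Ames collections, whose chemistry is far
more diverse than the two-ring grammar, whose labels encode aggregated
multi-strain assay outcomes, and whose class signal is carried by many
weak features rather than one strong alert. Absolute scores on real
data are therefore not claimed anywhere in this package.

## Problem sizes and numerical choices

Tests and the acceptance script run the full network (512, 128, 8) at
n = 600 on 167 MACCS keys for the cross-validation checks, and smaller
single-hidden-layer networks for attribution demonstrations, keeping
every suite desk-scale. Degenerate inputs are rejected loudly rather
than patched: single-class label vectors, empty feature matrices after
hygiene, zero-width queries and empty ARKA descriptor sets all raise
with the offending names.
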