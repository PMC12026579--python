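# Methods

## The problem

Curated knowledgebases (KEGG, Reactome, MetaCyc and their like) record which
small molecules participate in which pathways, but the annotations are
incomplete and expensive to extend. `pathcolor` implements a pipeline that
predicts pathway involvement from compound structure by reformulating the
many-thousand-class problem as binary classification over compound–pathway
pairs, and it implements the data-engineering step that makes such models
transfer across knowledgebases: canonicalizing every structure's chemical
representation with an InChI round trip before featurization.

## Atom coloring

Compounds are featurized as counts of *atom colors*: canonical labels
summarizing the chemical substructure around each heavy atom. The semantics
are 1-dimensional Weisfeiler–Lehman refinement with chemistry-aware labels:

* base label of an atom: `(element, formal charge, total attached hydrogens,
  tetrahedral parity if atom-stereo is enabled)`. Explicit hydrogen atoms
  are folded into the heavy-atom hydrogen count first, so the
  explicit/implicit-H dialect of a molfile cannot change the features.
* edge label: bond order, plus the molfile stereo flag when bond-stereo is
  enabled. Aromatic (type 4) bonds are their own edge label; harmonizing
  kekulized vs aromatic dialects is the standardizer's job, not the
  featurizer's.
* round update: an atom's new label is the canonical string of its old
  label together with the lexicographically sorted multiset of
  `(edge label, neighbour label)` pairs. Labels are digested to 128-bit
  keyed BLAKE2 hashes; a registry detects (astronomically unlikely) digest
  collisions and refuses rather than merging colors silently.
* with `max_rounds="auto"` the refinement iterates until the induced
  partition of atoms stabilizes, which happens within `n_atoms` rounds
  because partitions can only refine. The final color records the
  stabilization depth, so two atoms in different molecules compare equal
  exactly when their rooted neighborhood unfolding trees to that depth are
  isomorphic. An integer `max_rounds=r` instead fixes the neighborhood
  radius at `r`.

A molecule's feature vector is the multiset of its heavy-atom colors; the
total count always equals the heavy-atom count, and the vector is invariant
to atom reindexing by construction.

### Neighborhood radius in the synthetic studies

The library default is full stabilization ("auto"), which makes colors
maximally discriminative — in the limit, each color characterizes its whole
molecule. The bundled synthetic studies instead fix `max_rounds=1`
(first-shell environments, the smallest chemistry-aware radius). The reason
is statistical rather than chemical: pathway involvement only generalizes
to a held-out compound–pathway pair if colors are *shared* across
compounds, so that what the model learned about a pathway from other
members applies to a new one. Whole-molecule colors make every compound's
support private and turn prediction into set-containment detection, which a
feed-forward network approximates poorly. Radius-1 colors represent
functional groups in a stable local context and keep the task low-rank.
Real deployments should treat the radius as a tunable with this trade-off
in mind.

## Representation standardization

Knowledgebases draw tautomers, resonance forms and protonation states
differently. The standardizer round-trips each structure through standard
InChI (molfile → InChI → molfile), letting the InChI algorithm select one
canonical tautomeric/resonance representative per compound; a SMILES
round-trip mode is included for comparison, and `mode="none"` is the
identity. Encoding and decoding delegate to the IUPAC InChI library bundled
with RDKit; the module owns round-trip orchestration, kekulization handling
and error policy. Standard InChI options are used; stereo layers are
dropped when `keep_stereo=False` (`/SNon`). Structures that fail conversion
are excluded with a logged manifest so standardized and raw runs stay
comparable on their intersection. The operation is feature-idempotent: a
second round trip cannot change a molecule's color counts.

## Dataset construction

1. **Compound matrix** — one row per compound, one column per distinct
   color observed in the corpus (lexicographic column order).
2. **Pathway matrix** — a pathway's row is the elementwise sum of its
   member compounds' *raw* count rows (normalization happens later and
   separately per entity class).
3. **De-duplication** — rows with identical count vectors merge; the merged
   row represents the union of the entities (and, for compounds, the union
   of their pathway annotations). Columns identical across all rows merge
   likewise, keeping the lexicographically smallest color as
   representative. Compound and pathway matrices are de-duplicated
   independently.
4. **Normalization** — row-wise softmax over all columns (max-subtracted
   for stability), then column-wise min–max scaling; constant columns map
   to 0. The per-column min/max of the softmaxed training matrix are frozen
   on the matrix so novel compounds can be projected later without
   refitting — avoiding leakage into cross-reference predictions.
5. **Cross-join** — compounds and pathways of the same knowledgebase are
   paired, giving a block-diagonal pair dataset with a binary label:
   positive when any represented compound of the row is annotated to any
   represented pathway of the column (union semantics after merging).
   The cross-join is *virtual*: a global pair index maps arithmetically to
   (compound row, pathway row), and features are gathered per batch, so
   memory scales with batch size × feature width rather than pair count.
   A pair whose merged rows make it appear in two blocks counts once and is
   attributed, for per-KB metrics, to every knowledgebase witnessed by both
   of its rows.

## Classifier

A multi-layer perceptron on the concatenated compound+pathway rows, trained
with Adam on binary cross-entropy via scikit-learn's `MLPClassifier` in an
epoch-wise `partial_fit` loop over batches gathered from the virtual pair
dataset. Library defaults: hidden layers (512, 256), ReLU, L2 penalty
`alpha=1e-4`, learning rate 1e-3, batch 256, at most 50 epochs with
early stopping after 5 non-improving epochs, seeded weight init and
shuffling. Training folds are class-balanced by duplicating each positive
`k = max(1, round(n_neg/n_pos))` times; test folds are never oversampled.

The decision threshold defaults to 0.5. The option
`decision_threshold="auto"` applies the standard prior-shift correction for
balanced training: the posterior learned at an oversampled 50/50 prior is
thresholded at `1 − π`, with `π` the positive rate of the training pairs
before oversampling. The correction is computed from training data only.
The synthetic studies use it because their test prior (~0.27) is far from
the balanced training prior and a 0.5 cutoff systematically over-predicts
positives.

Novel structures (e.g. cross-referenced twins) are projected into a trained
feature space by standardizing and coloring them with the training configs,
dropping colors outside the training vocabulary (the dropped fraction is
reported), and applying the frozen softmax→min-max statistics. Projecting a
training compound reproduces its stored row exactly. Trained models carry a
fingerprint of the feature store and refuse mismatched datasets unless
explicitly overridden.

## Evaluation protocols

* **Metrics** — MCC (primary; zero whenever a denominator factor is zero),
  plus F1, precision, recall, accuracy with 0/0 → 0 conventions.
* **CV** — each iteration is an independent label-stratified 10-fold split
  (seed+i) testing exactly one fold; positives of the train portion are
  oversampled; confusion counts are tallied overall and per knowledgebase;
  iteration-level metrics are aggregated as mean/median/standard deviation.
* **Cross-KB** — for each knowledgebase, a model trained on all of its
  pairs predicts every pair of each other knowledgebase; diagonal cells
  are held-out (one stratified tenth excluded) sanity values.
* **Cross-reference analysis** — one model trained on all pairs predicts
  each cross-referenced training compound's pathway slate twice: from its
  stored row and from its cross-reference's projected row, against the same
  labels. The report gives both MCCs, their difference, and how many pairs
  have identical raw color counts.

## Synthetic knowledgebases

The generator emulates the multi-knowledgebase setting end to end:

* **Molecules** — valence-valid graphs: a 1–3 carbon alkyl scaffold with
  1–3 functional-group motifs grafted at random carbons, each motif carried
  on a methylene linker so its atoms sit in a stable first-shell
  environment. Half the compounds carry one decoration (an amide or a
  charge-separated nitro group) that hosts a standardization-sensitive
  site. Molfiles are emitted with zeroed coordinates.
* **Pathways** — each knowledgebase owns a disjoint subset of the motif
  library (independently curated resources define their own chemistry) and
  each pathway a signature of one motif (85%) or two (15%), sampled with
  replacement — duplicate pathway definitions are realistic and exercised
  deliberately. A compound belongs to a pathway when it contains the
  signature; every membership bit is flipped with probability ε
  (default 0.05) to model annotation incompleteness.
* **Cross-references** — a configurable fraction of each KB's compounds is
  copied into the next KB under a sampled representation perturbation:
  atom reordering, explicit hydrogens, the nitro charge-separated ↔
  pentavalent resonance rewrite, or the amide ↔ imidic-acid tautomer swap.
  The first two are resolved by the featurizer alone; the last two only by
  InChI standardization — so the identical-feature fraction under
  `mode="none"` approximates the reorder+explicit-H weight, and approaches
  1 under `mode="inchi"`.

Deliberate simplifications: molecules are far smaller and more stereotyped
than real metabolites; memberships are driven by single-site motifs rather
than reaction chemistry; annotation noise is independent per bit. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that its qualitative claims (learnability, standardization effect,
cross-KB degradation) hold under controlled conditions — not that real-data
performance figures carry over.

Two geometric choices matter and were made deliberately. Scaffolds are
small so that a pathway's aggregated counts are dominated by its signature
motifs: softmax normalization is exponential in the counts, and a generic
backbone color that out-counts the signature would otherwise collapse
different pathways onto the same near-one-hot row. Motifs ride on linkers
for the same reason — without them, a signature color splits into variants
by the hydrogen count of its attachment carbon and loses the count race.

## Study configurations

The bundled studies (`pathcolor.protocols`) run on 3 KBs × 150 compounds ×
30 pathways, ε = 0.05, cross-reference fraction 0.5 with the perturbation
mix 0.1/0.1/0.4/0.4 (reorder/explicit-H/resonance/tautomer), radius-1
coloring, and a (256, 128) MLP (batch 2048, learning rate 3e-3, ≤120
epochs, patience 12, `decision_threshold="auto"`); cross-reference models
use a 40-epoch schedule since only the paired difference of two prediction
passes of the same model is of interest. With label noise ε and test
positive rate π ≈ 0.27, an oracle that predicts true membership attains
MCC ≈ 0.86 on this design (de-duplication merges amplify effective noise
slightly); observed held-out MCC sits a few points under that ceiling, so
small fold-to-fold variation around 0.8 is expected and real.

## Numerical notes and edge cases

* Softmax of an all-zero row is exactly uniform (1/F).
* Constant columns normalize to 0 and stay 0 under projection.
* Colors compare by digest; digest equality is collision-checked.
* Degenerate confusion tables (empty classes) yield 0-valued metrics, not
  errors; degenerate training splits (single class) raise.
* Implicit hydrogens come from a fixed valence table (charge-adjusted;
  S/Se/P/As may use their higher valence states); atoms whose explicit
  bonds still exceed the table are flagged, never rejected — the
  deliberately pentavalent nitro perturbation relies on this.
* V2000 only; V3000 is rejected. Files larger than 999 atoms cannot be
  written.

## Known limitations

* Cross-molecule color comparability under `max_rounds="auto"` holds only
  between molecules with equal stabilization depth; this is inherent to
  depth-adaptive refinement.
* The MLP backend exposes L2 regularization rather than dropout.
* The pipeline assumes annotations and structures fit in memory; only the
  pair cross-join is virtualized.
* Models do not generalize to pathways absent from training — the cross-KB
  study quantifies exactly this — so predictions should be restricted to
  the pathway set the model was trained on.
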