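# Methods

## Problem and approach

`npjury` implements a consensus ("jury") QSAR screening workflow for
discovering modulators of the 5-lipoxygenase (5-LO) pathway. Public
bioactivity data for 5-LO and its activating protein FLAP are curated into
a binary strong/weak modulator set, featurized with two-dimensional
physicochemical descriptors, and used to train three heterogeneous
classifiers. Only candidates voted active by *all three* models
("triple-positive") are treated as screening positives; "double-positive"
candidates (any two models) form a secondary pool. The rationale is
false-positive control at library scale: the unanimous positive set is the
intersection of the members' positive sets, so the consensus false-positive
count is bounded by the smallest member's and its true-negative rate (TNR)
dominates every member's — a theorem, asserted exactly in the tests, not
an empirical tendency.

Physicochemical descriptors are used instead of structural fingerprints so
that model votes depend on bulk properties (lipophilicity, polarity, size,
charge distribution) rather than memorized scaffolds; this matters when the
screening library (e.g. natural products) occupies a different region of
chemical space than the medicinal-chemistry training molecules.

## Curation

Records are kept iff: measurement type is IC50, Kd or Ki
(case-insensitive); relation is literally `=` ("exact"); units are
literally nM (case-insensitive, no μM→nM conversion — silent conversion
would change the curated counts that make a run auditable); the value is
positive and parseable; and the SMILES parses. Each dropped record is
charged to the *first* failing criterion in the fixed order type →
relation → units → value → SMILES, so provenance counts always sum to the
input size. Molecule identity is the canonical SMILES of the largest
organic fragment (salt stripping, no charge neutralization). Replicates
collapse to the **median** value — robust to one discordant replicate and
deterministic; the data sources do not dictate an aggregation rule, so this
is a package choice. The strong/weak label uses a strict cutoff:
label 1 ⇔ aggregated potency < 1000 nM; exactly 1000 nM is weak.

## Descriptors and normalization

The default panel is every RDKit 2D descriptor except the `fr_`
substructure-count family (structural features, deliberately excluded for
the reason above) and `Ipc` (grows combinatorially with molecule size;
`AvgIpc` is kept) — 124 names at the pinned toolkit version. The panel is
configurable and each artifact records a `panel_version` (toolkit version
+ SHA1 of the resolved name list) so matrices are comparable across runs.
Failed descriptor values are imputed with the column median when sparse; a
molecule with > 5 % failed descriptors is dropped and logged.

Normalization is per-column min–max to [0, 1], fit on training data only.
Screening candidates outside the training envelope are clipped to [0, 1]
rather than extrapolated, keeping jury inputs in the trained domain.
Constant columns map to 0 for any input. Inside cross-validation the
normalizer is refit per fold on the training 9/10 only.

## Jury members

* **Gradient-boosted trees** — tree depth 4, 500 trees, learning rate 0.05
  (0.15 for the FLAP-style imbalanced task), random state 1234.
* **Logistic regression** — trained by full-batch gradient descent: at
  most 100 epochs, step size 0.1, stopping when the loss change drops
  below 1e-5, no regularization. Gradient descent is used deliberately
  instead of a second-order or closed-form solver so that these three
  hyperparameters are meaningful; the consequence, visible in the tests,
  is that the epoch cap underfits relative to a converged solver
  (training MCC ≈ 0.8 on a noiseless benchmark where GBT reaches 1.0).
* **Gaussian naive Bayes** — per-class, per-descriptor Gaussian densities,
  with an optional floor (the "default probability", 0.005 for the FLAP
  task) bounding each class-conditional density term from below so a
  single extreme feature cannot veto a class; a floor of 0 is exactly
  standard Gaussian NB. NB cannot represent a linear threshold exactly,
  so it also plateaus below the tree model even without noise.

Votes use a 0.5 positive-score threshold. Tier = number of positive votes
∈ {0..3}; consensus positive ⇔ tier 3. Raising the vote threshold can
only lower tiers (monotonicity, property-tested).

## Evaluation

Metrics: TNR, PPV, MCC, BA, computed from a TP/TN/FP/FN contingency
table; a vanishing denominator yields 0 with a "degenerate" flag rather
than an exception, keeping shuffle controls well-defined when a fold
predicts one class. Cross-validation is stratified 10-fold (stratification
prevents empty-class folds on heavily imbalanced sets), with metrics
reported primarily on pooled out-of-fold predictions (fold-averaged values
recorded alongside) — pooling gives a single consensus number per task.
AUC per member uses the Mann–Whitney rank formula on pooled out-of-fold
scores. The y-randomization control permutes the labels (class counts
preserved, seeded) and reruns the identical procedure; |MCC| near zero on
shuffled labels is the evidence that the unshuffled models learned signal.

## Fragments

"Fragments" are connected bond-subgraphs of 4–8 bonds, enumerated with
ring closures included — simple paths alone could never contain an intact
aromatic ring, which would exclude exactly the ring motifs (e.g.
paraquinones, plausible redox cyclers for an iron-dependent enzyme) the
analysis is meant to surface. A fragment is discarded if any of its
aromatic atoms lacks its complete smallest aromatic ring within the
fragment ("interrupted aromatic system"); benzene therefore contributes
exactly one fragment, the intact ring. Identity is the canonical SMILES of
the subgraph with aromaticity inherited from the parent; no
attachment-point marking. Frequencies are molecule-level incidences
(multiple occurrences in one molecule count once) over the set size; the
enrichment ratio is freq(strong)/freq(weak). Fragments absent from one
set are reported in side lists instead of receiving an infinite or
pseudocount-smoothed ratio.

## Similarity

Novelty of hits is judged against known strong modulators with two hashed
2048-bit fingerprint families: linear paths of 1–7 bonds, and atom pairs
with topological distances 1–30. Tanimoto similarity |A∩B|/|A∪B|, with
the all-zero/all-zero case defined as 1 (identical objects) and
zero/non-zero as 0. The nearest-known report is an exhaustive all-pairs
scan; ties go to the earlier reference in input order. No numeric
"novel/not novel" cutoff is imposed — the report is for human triage.
Bit-level agreement across toolkits is not asserted, only
similarity-level properties within this implementation.

## Synthetic benchmark

The generator emulates a ChEMBL-style export so the pipeline is testable
end-to-end without external data. Molecules come from a fixed grammar —
linear/branched alkyl chains (4–12 carbons) and benzene, pyridine, furan,
cyclohexane scaffolds with hydroxyl, methoxy, halogen, acetyl, amine and
carboxyl substituents — guaranteeing validity without a rejection loop.
The planted signal is a latent variable z = w·d + ε over three named,
standardized descriptors (MolLogP, TPSA, MolWt; weights 1.0, −0.8, 0.5)
with ε ~ N(0, noise_sd); label 1 ⇔ z above the sample median (balanced
classes by construction), and the emitted potency is
1000·exp(−(z−median)/sd(z)) nM, placing the class boundary exactly at the
1000 nM curation cutoff. Replicate records jitter the log-distance from
that boundary, so replicates never cross it and curation recovers the
planted labels exactly whenever the decoy mixes are off.

Defaults, chosen once as plausible study conditions: noise_sd = 0.5 (the
descriptor term has roughly unit variance after standardization, so this
is a moderate signal-to-noise regime); duplicate_rate = 0.1; unit mix
85 % nM / 10 % μM / 5 % other; relation mix 85 % `=` / 10 % `>` / 5 % `<`.
Records carrying non-`=` relations or non-nM units are curation decoys;
their molecules are intentionally lost to strict filtering. One global
seed drives four independent derived streams (molecule identity, latent
noise, record decoration, duplicate selection), so changing the duplicate
rate or noise level never changes which molecules are drawn.

What the generator does **not** emulate: natural-product-like scaffold
complexity and stereochemistry, assay heterogeneity beyond the six export
columns, correlated replicate error, and activity cliffs. Passing tests
therefore demonstrate that the machinery is correct and that a planted
descriptor-linear signal is recovered; they do not certify classifier
performance on real bioactivity data, where the descriptor–activity
relationship is neither linear nor noiseless.

## Problem sizes and numerical choices

The shipped study configuration draws 2000 records (≈ 740 unique
molecules, ≈ 590 surviving curation), evaluates with 10-fold CV at seed
1234, and screens a separately-seeded 1000-draw candidate library; these
sizes keep a full run in the low minutes on one CPU while leaving every
class with well over k members per fold. Degenerate-denominator metrics
return flagged zeros; nearest-neighbor and fold ties break
deterministically (input order / seeded shuffles); model archives are
written with fixed zip timestamps so reruns are byte-identical.

## Known limitations

* The three members mirror a no-code environment's node parameters; split
  criteria and internal defaults of that environment are unknown, so
  metric parity with runs performed there is approximate by nature.
* The strict-nM, strict-`=` policy discards convertible information (a
  `0.5 μM` record is dropped, not converted) — deliberate, for count
  auditability.
* Fragment enumeration is exponential in the worst case; it is intended
  for drug-sized molecules (the 4–8-bond window keeps subgraph counts
  modest), not macromolecules.
* The unanimity TNR guarantee does not extend to PPV or MCC; those are
  reported, not bounded.
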