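# Methods

## Problem and protocol

Site predictors for post-translational modifications are usually trained and
evaluated on a pool of annotated sites aggregated from many experiments
(databases, individual mass-spectrometry studies, literature curation).
Random train/test splitting of such a pool lets every experiment contribute
to both sides, so any experiment-specific regularity — substrate bias of the
enzymes probed, cell-type context, detection chemistry — is available at
training time for the very data it is tested on. Cross-validation on a mixed
pool therefore estimates *interpolation* within the collected corpus, not
generalization to a future experiment.

The experiment-split test implemented here measures generalization directly.
Every annotated site carries the identifiers of the experimental sources that
reported it. For each source `E_i`:

1. test positives = windows attributed to `E_i`, **minus** any window also
   attributed to another source (those remain in training — shared windows
   would otherwise leak verbatim into the test set);
2. training positives = union of windows of all other sources;
3. negatives: a fixed number of unannotated lysine windows (40,000 at full
   scale) are sampled without replacement and cut into two disjoint halves,
   one per side;
4. a source retaining fewer than 5 test positives is skipped, and the
   protocol is reported as inapplicable when fewer than 5 sources survive —
   with tiny or few test sets the estimate is dominated by noise.

Each surviving source yields one independent test; the protocol reports
ROC-AUC and sensitivity at specificity ≥ 0.9 per source, aggregated as
mean ± SD, and compares them with mixed-source stratified ten-fold
cross-validation (negatives subsampled to class balance) using t-tests:
single-sample against a published reference value, paired for matched
vectors, and Welch's two-sample test when comparing a k-fold vector with an
n-source vector (these have no natural pairing, so a paired test would be
ill-defined; the package flags this and defaults to Welch).

## Data model

Sites are 1-based lysine positions on a protein. Each site becomes a
61-residue window (±30 residues, 'X'-padded at termini; non-standard residues
B/Z/U/O/* are mapped to 'X' before windowing so the alphabet has exactly 21
symbols). Windows identical as strings are merged, taking the union of
modification labels (Kme1/Kme2/Kme3, plus the union label Kme whenever any is
present) and the union of sources; a merged window belongs to every source
that reported any of its originating sites. Negatives are all remaining
lysine-centered 61-mers of the proteome, deduplicated, and never overlap the
positive set by construction. A record whose central residue is not 'K'
aborts corpus construction (optionally downgraded to a logged warning),
because silently dropping malformed annotations corrupts a benchmark.

## Classifiers

Nine architectures: {CNN, LSTM, GRU} × {One-Hot, PSSM, word-embedding}.
All end in a single sigmoid unit; one independent binary model is trained per
modification label.

* **CNN body** — conv(256 kernels × length 9, full channel depth, stride 1,
  no padding) → maxpool(2) → conv(32 × 7) → maxpool(2) → FC(128) → sigmoid.
  With 61×21 input the sizes are 53×256 → 26×256 → 20×32 → 10×32 → 128 → 1;
  pooling an odd length uses floor (53 → 26). Hidden activations are ReLU
  (the output sigmoid is the only activation the design fixes; ReLU is the
  conventional choice and is configurable). Dropout rates (0.5, 0.7) apply
  after the first and second pooling stages during training.
* **RNN bodies** — seven stacked LSTM (or GRU) sublayers of 32 hidden units
  running over the 61 positions; the score is read from the last timestep of
  the top sublayer. No bidirectionality, no recurrent dropout.
* **Encodings** — One-Hot uses the fixed 21-symbol order
  `Q A R N D C E G I L K M F P S T W Y V H X` (a single named constant;
  the convention pins 'Q' to the first slot and 'H' to the twentieth).
  PSSM input is the 61×20 block of per-residue log-odds rows from a
  PSI-BLAST ASCII profile, rows outside the protein all-zero, and by default
  squashed elementwise with the logistic function — bounded inputs stabilize
  training; a raw-score switch exists. The word-embedding variant learns a
  linear 21→5 map (no activation) jointly with the classifier, so it lives
  in the model, not the encoder. A BLOSUM62-broadcast pseudo-PSSM is
  provided for demos and tests; it is synthetic and carries no alignment
  information, and is labelled as such.

Because no deep-learning framework is part of this package's dependency set,
the layers (1-D convolution via im2col, max-pooling, dense, dropout, LSTM,
GRU) are implemented directly on numpy with hand-written reverse-mode
gradients, verified against central finite differences to ~1e-7 relative
error, and a standard Adam optimizer. Single precision is used for training
speed; parameter initialization is Glorot-uniform from a seeded generator,
so identical spec + seed gives bit-identical models.

## Training protocol

Binary cross-entropy on raw logits (numerically stable log1p form), Adam
(lr 0.001 canonical default, configurable), minibatches of 512, early
stopping when the *training* loss has not improved for 25 consecutive units,
and the parameter state with the smallest recorded loss is returned.
Monitoring training loss is deliberate protocol fidelity — most pipelines
monitor validation loss, and a validation-monitored mode exists behind
`monitor='val'`. The 25-unit patience window is counted in epochs by
default (`patience_unit='batch'` switches to minibatches; in that mode the
checkpoint is saved before the optimizer step, so the returned state exactly
reproduces the minimum recorded loss). `min_delta` (default 0) sets the
smallest decrease counted as improvement; it exists because a frozen model's
loss still jitters at the 1e-10 level with batch summation order. The
trainer never resamples: class balancing is an evaluation-protocol decision
and happens in the caller.

## Synthetic corpus generator

The generator emulates the *multi-source structure* the protocol depends on:

* proteome of 500 proteins, Poisson-length around 400 residues, drawn from a
  background (uniform by default; a human-like amino-acid frequency table is
  available);
* 8 experimental sources × 50 positives, per-source counts multiplied by a
  log-normal factor (σ = 0.25) because real sources are far from uniform in
  size;
* positive contexts: ten flank positions (±1..±5) each prefer one residue
  with log-enrichment `motif_strength` over background; the sampling PWM is
  the convex blend `(1-h)·core + h·source`, where `h` (heterogeneity ∈
  [0,1]) is the fraction of motif information private to the source;
* `overlap_rate` (default 0.1) of sites are attributed to a second source,
  reproducing re-discovery of the same site by independent experiments —
  exactly the windows the split construction must remove from test sets;
* modification labels drawn as 81% Kme1 / 11% Kme2 / 8% Kme3, the rough mix
  in curated human lysine-methylation data; all remaining lysines are
  negatives.

Default `motif_strength = 3.0` was chosen so that a desk-scale CNN reaches
mixed-source CV AUC in the 0.75–0.85 band typical of published
lysine-methylation predictors; at strength 0 positives are
indistinguishable from background (AUC ≈ 0.5), and the ideal
(Bayes-optimal) AUC at strength 3 is ≈ 0.97, leaving realistic headroom
between attainable and ideal performance. Sites are planted ≥ 11 residues
apart so contexts never overwrite each other.

What the generator does **not** emulate: realistic methyltransferase motifs,
position-dependent composition of real proteomes, homologous windows that
are similar-but-not-identical (overlap removal here is exact-string, matching
the corpus dedup unit; no 40%-identity style reduction is applied), or
mass-spectrometry detection artifacts. Passing benchmarks on this corpus
therefore demonstrate the *protocol's* behaviour under controlled source
heterogeneity, not performance on real methylomes.

## Desk-scale benchmark profile

The replicated CV-vs-split comparison (`splitbench.benchmark`) runs on one
CPU in minutes by scaling widths and budgets, not structure: CNN with 32/16
kernels and a 32-unit FC head, batch 128 (a desk corpus of ~800 windows
yields ~6 Adam steps per epoch; batch 512 would give 2), learning rate 0.002,
30 epochs, 1,200 split negatives (the synthetic proteome holds ~10k
lysines), ten replicates. Under this profile heterogeneous corpora
(h = 0.8) give mixed-source CV AUC ≈ 0.8 versus experiment-split ≈ 0.68
with a consistently positive per-replicate gap, and homogeneous corpora
(h = 0) give near-equal values — the qualitative signature the protocol is
designed to expose.

## Numerical choices and edge cases

* AUC uses the midrank tie convention (ties count ½), identical to the
  pairwise win-fraction definition; both-classes-present is enforced.
* Sensitivity-at-specificity sweeps all thresholds between distinct adjacent
  scores with the constraint specificity ≥ target (conservative); the full
  ROC point set is used (no intermediate-point dropping, which can discard
  the optimal feasible operating point).
* Split negatives are drawn independently per held-out source (keeps the
  per-source tests exchangeable); `shared_negatives` reproduces a
  draw-once reading.
* Zero-variance inputs to any t-test raise instead of returning a
  meaningless p-value; a paired test of identical vectors is flagged the
  same way.
* Max-pooling truncates a trailing odd element (floor semantics), forced by
  the 53 → 26 arithmetic of the published shape sequence.
* Every stochastic component (generator, initialization, shuffling, dropout,
  fold assignment, negative draws) descends from explicit integer seeds via
  `numpy` `SeedSequence` spawning.

## Limitations

* PSSM-based results depend on profile provenance (database, iterations,
  E-value), which this package does not control — it only parses profiles;
  the pseudo-PSSM stand-in is not evolutionary information.
* The experiment-split estimate inherits the granularity of source
  annotation: if two "sources" are re-publications of one experiment, the
  independence assumption weakens.
* At desk scale the absolute AUC values depend on the synthetic conditions;
  only the qualitative CV-vs-split contrast and its direction are meaningful
  claims.
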