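# Methods

This note documents the models implemented in `phideid`, the assumptions
behind them, the synthetic data they are exercised on, and the numerical
and design choices a maintainer would want to know about. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task and data model

PHI deidentification is cast as named-entity recognition over four
categories (PER, LOC, ORG, DAT) in strict BIO. Surface units default to
single characters, since clinical Chinese has no word delimiters and no
capitalization cues; a whitespace mode covers Latin-script corpora. Spans
are 0-based and half-open. The BIO dependency rules enforced everywhere
(validation, delinearization filtering, constrained decoding) are: no
sentence-initial `I-`, no `I-` after `O`, and no category switch inside an
entity (`B-X I-Y`, `I-X I-Y` with X ≠ Y). Gold inputs that violate the
rules are rejected by default; a repair-to-O mode exists but is opt-in,
because silent repair hides annotation bugs.

## Encoder

A BERT-family encoder: summed word/position/token-type embeddings with
layer norm, then post-norm transformer blocks (multi-head self-attention,
GELU feed-forward, residuals). Learned position embeddings match the
family being emulated. No `[CLS]`/`[SEP]` specials are used — the tagger
consumes every position directly. Padded key positions receive an additive
−1e9 before the attention softmax, which makes emissions at real positions
invariant to extra padding (tested to 1e-5). Sentence length is fixed per
model (`max_len`, full-scale default 128); tokens beyond it are truncated
and receive `O` at prediction time.

The default student shape is 6 layers × 768 dims × 12 heads and a 12-layer
teacher of the same width has strictly more parameters (asserted as an
inequality); all trained tests and experiments run desk-scale shapes
(16–32 dims, 1–4 layers, `max_len` 12–32) from random initialization — no
pretrained weights are involved anywhere.

The emission head maps final features to one raw logit per label. The
per-position scores are deliberately *not* softmax-normalized before the
CRF: the CRF renormalizes globally over paths, and a per-position softmax
would double-normalize; a `softmax_emissions` flag exposes the normalized
variant for comparison.

All neural components run on `phideid.autodiff`, a small reverse-mode
automatic-differentiation core over numpy arrays written for this package
(no autodiff framework is a dependency). Every primitive's gradient is
checked against central differences in the test suite.

## CRF

Path score = emission sum + transition sum with explicit START/END states,
giving the boundary terms a learnable score like any other transition.
`log Z` uses the forward recursion in log space with log-sum-exp
stabilization, O(L·K²); training loss is `log Z − score(gold)`, batched
over padded sentences with length masking. Decoding is Viterbi with ties
broken toward the lowest label index (deterministic across platforms).
Constraint masking adds −1e4 to forbidden transitions rather than −∞,
keeping arithmetic finite; the penalty dwarfs any score the desk-scale
models produce, and decoded outputs are validated in tests (zero
violations over 1000 sentences decoded with an untrained model — the
adversarial case, since random emissions exert no pressure toward
legality). The mask is applied at decode time by default; a
`constrain_training` flag applies it inside the partition function as
well.

## Distillation

Layer mapping g pairs student layer n with teacher layer k·n (M = k·N
enforced), plus the embedding pair (0,0). Losses:

* `L_tr`: Σ over mapped pairs of MSE(A^S, A^T) (mean over heads and
  positions) + MSE(H^S W_h, H^T), with W_h mapping student→teacher width
  (identity when widths agree).
* `L_emb`: MSE(E^S, E^T W_e), W_e mapping teacher→student width. The
  printed form of this loss in the source material is notationally
  ambiguous between an L2 norm and an MSE; MSE was chosen for consistency
  with the hidden-state term and for scale-invariance to tensor size.
* `L_pr`: cross-entropy of student logits against the teacher softmax,
  averaged over unmasked positions. No temperature by default (an optional
  parameter exists); the analytic floor is the teacher-distribution
  entropy, reached exactly at Z^S = Z^T, and the floors (0, 0, entropy)
  are asserted on a self-distillation fixture.
* `L_total = L_tr + L_emb + L_pr`, logged per step as a CSV-able trace.

The teacher is frozen (its states detached); Adam updates the student and
the projections. Distilling a tagger also copies the teacher's CRF
transition matrix into the student — the prediction layer is one of the
transferred structures. The benefit experiment trains a 4-layer teacher on
a 500-sentence synthetic corpus (6:2:2 split), distills a 2-layer student
(120 steps), then gives the distilled student and a same-shape
randomly-initialized control an identical one-epoch fine-tune and compares
held-out entity-level micro-F1 over 3 seeds. The short fine-tune is the
point: it measures what the initialization brought, before task training
can wash it out. The original distillation regime fed length-1 sequences;
`distill(..., length_one=True)` reproduces that mode, while the default
uses full sentences, which at task scale carries the contextual signal.

## Augmentation

**DAGA.** Linearization inserts the tag marker immediately before every
non-O token (both `B-` and `I-` markers are emitted; O tokens are bare).
The stream model is a single-layer Elman recurrence over the joint
vocabulary (markers + tokens + boundary symbols): `h_t = tanh(M e_t +
U h_{t−1} + b)` with a softmax output layer, trained by next-token
maximum likelihood with Adam. A stateless formulation (`h_t = M e_t`
alone) cannot condition on history, so the recurrent reading was adopted;
`M` remains the input weight matrix. Sampling draws symbols at a
configurable temperature until the end symbol; sampled streams are
de-linearized and kept only if they decode to valid BIO, with rejections
counted by reason (dangling marker, invalid BIO, empty). The sampler gives
up after 10× the requested count of attempts. At temperature → 0 on a
single-sentence corpus the argmax sampler regenerates the training
sentence exactly (tested).

**MR.** One independent Bernoulli(p) draw per entity (p = 0.5 by default —
the "replace when P > .5" rule); on success the mention is replaced by a
uniform draw from the same-category training pool excluding itself, and
tags are re-expanded to the new length. Singleton pools leave the entity
unchanged. The realized replacement rate over 1000 decisions is checked
against the 3σ binomial band, and p ∈ {0, 1} hit their boundaries exactly.

**Hybrid.** original ∪ DAGA ∪ MR with per-sentence provenance and a
per-category source-count summary. Default volumes are ~2× the original
sentence count from DAGA and 2 MR passes, in line with the roughly
2.7×/2× entity-count ratios of the emulated corpus's augmentation table;
evaluation/test splits are never augmented. The benefit experiment
compares a tagger trained on the hybrid set against the same tagger
trained on a 50% subsample of the raw training set (3 seeds, mean
micro-F1) — the directional data-volume comparison.

## Synthetic corpora

The generator emulates the structural properties of the private clinical
corpus this stack targets, not its text: four categories at proportions
PER .258 / LOC .054 / ORG .151 / DAT .537 (the normalized original
annotation counts 1448/302/846/3013), variable entity density
(Poisson, default 1.2 per non-sparse sentence) with a 30% entity-sparse
fraction (mostly-O sentences are what motivates MR alongside DAGA), and
per-category mention shape: each category draws from its own closed
pseudo-token sub-alphabet, with DAT mentions longer (4–8 units) and
internally structured as digit/separator alternations. Everything is
derived from a single seed; identical seeds yield byte-identical CoNLL.

What this does and does not show: the category-specific sub-alphabets make
type identity learnable from lexical plus contextual evidence, so the
experiments measure whether the machinery (CRF training, distillation
transfer, augmentation) works — they do not measure robustness to the
ambiguity of real clinical language, where surface forms are shared across
types and annotation noise exists. Surrogate pools for deidentification
are generated in a disjoint namespace, guaranteeing no gold mention
survives replacement.

Default experiment sizes (500-sentence corpora, 6:2:2 splits, desk-scale
encoder shapes, 3 seeds per directional comparison) were chosen so the
whole suite and the reproduction script each run in about a minute on one
CPU while leaving the directional effects far from the decision boundary.

## Evaluation

Entity-level exact span+type matching: TP requires (start, end, category)
equality; no partial credit. P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R), reported in percent with 2 decimals, per category and
micro (counts pooled before the ratios). Zero denominators give 0 — the
standard monotone convention. Whether the emulated study's micro metrics
were token- or entity-level is ambiguous; entity-level is implemented, as
it is the stricter and more common convention for NER. The scorer is
cross-checked in tests against an independent tag-run scorer on 50 random
corrupted-prediction fixtures.

## Pipeline

The tagger is trained end to end (encoder + CRF jointly) by Adam on the
CRF NLL; the optimizer and its defaults (lr 5e-3, batch 32) are this
package's choices, config-driven. With an eval split, the best-on-eval
checkpoint (entity micro-F1) is returned. Bootstrapping mirrors the
annotate-10%-then-review workflow: train on a labeled mini set, predict
the bulk, flag sentences whose normalized Viterbi path probability
`exp(score − log Z)` falls below a threshold for manual review — the
confidence measure is this package's choice, and the flagged set grows
monotonically with the threshold. Deidentification replaces predicted
spans with same-category surrogates; surrogates are length-free, and the
replacement log stores enough to invert the pass exactly (tested).
Checkpoints are single `.npz` files embedding config, vocabularies and
fingerprints; loading refuses a vocabulary mismatch. Every CLI subcommand
takes an explicit seed and is bit-reproducible for a fixed (config, seed)
on a given machine.

## Known limitations

* No pretrained language-model weights: the distillation studied here is
  task-scale, not the general-domain pretraining-stage distillation that
  produces production compact encoders.
* Synthetic text is structurally, not linguistically, realistic; absolute
  F1 values on it say nothing about clinical corpora.
* Strict BIO only (no BIOES, no nested or discontinuous entities).
* The numpy implementation is single-threaded and desk-scale; it is a
  reference implementation, not a production trainer.
* The −1e4 mask penalty is finite by design; emissions on a wildly
  different scale (|score| ≫ 1e3) could in principle out-vote it, which
  the desk-scale models never approach.
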