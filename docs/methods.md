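# Methods

## The problem

Whole-genome bisulfite sequencing reports, for every cytosine, how many
aligned reads called it methylated and how many unmethylated.  Coverage is
uneven: sites with fewer than four aligned reads carry too little evidence
for a reliable state call and are marked NA.  In plants the problem is
compounded by three methylation contexts — CpG, CHG and CHH (H = A, C or
T) — each maintained by a different pathway, so models built for
animal (CpG-only) methylomes do not transfer.  `methynet` predicts the
binary methylation state of any cytosine, in any of the three contexts,
from two signals that are available even where coverage is not: the
surrounding DNA sequence, and the observed states of nearby cytosines.

## Models

**Labels.** A site with depth ≥ 4 gets the label `round(n_meth / depth)`,
with the 0.5 boundary rounding *up* (a site methylated on exactly half its
reads is called methylated).  Sites below the threshold are NA and become
imputation targets.  On the prediction side the opposite boundary applies:
a predicted probability must *exceed* 0.5 to be called methylated.  Both
conventions are deliberate and fixed; they meet only on the measure-zero
event `p = 0.5`.

**DNA model** — a CNN over the one-hot encoded 1001 bp window centered on
the target (500 bp each side; channel order A, T, G, C; minus-strand
targets are encoded from the reverse complement so the model always sees a
centered C; N bases and off-chromosome positions are all-zero rows):

    conv(128 filters, kernel 11, stride 1) + ReLU
    maxpool(4)
    conv(256 filters, kernel 3, stride 1) + ReLU
    maxpool(2)
    flatten -> dense(256) + ReLU -> dropout(0.25)   <- 256-dim embedding
    dense(1) + sigmoid

**Methylation model** — two bidirectional GRU layers over the 25 nearest
labeled cytosines on each side of the target.  Each of the 50 neighbors
contributes a (state, distance) pair; distances are `|Δpos| / D_max`
clipped to 1, where `D_max` is the largest gap between consecutive
cytosines genome-wide (computed over all cytosines regardless of context
or NA status, since positions are known even when states are not, and
stored with the model).  Missing neighbors (chromosome edges, sparse
labeling) pad with state 0.5 and distance 1.0 — the maximally
uninformative values:

    time-distributed dense(32) + ReLU          # shared across timesteps
    BiGRU(128, L1 = L2 = 1e-4 on both kernels)
    BiGRU(256, final states)  -> dropout       <- 512-dim embedding
    dense(1) + sigmoid

The 100-vector is laid out as 50 state slots then 50 distance slots, both
in genomic order (upstream nearest-last, downstream nearest-first); the
estimator re-pairs them into 50 timesteps of 2 features.  This blocked
layout is asserted by the tests as this package's convention; only the
total length is externally constrained.

**Joint model** — the concatenated 768-dim embedding (256 + 512) through
two dense layers of 512 units (ReLU) and a sigmoid head.  By default it
trains end-to-end from scratch; a warm-start option initializes both
branches from trained single models.

The GRU uses the "reset-after" gate arrangement (the modern default in
mainstream frameworks).  All layers are implemented in numpy with
hand-derived backward passes; every gradient is verified against central
finite differences in the test suite, which is what licenses trusting the
training results.

**Training.** Binary cross-entropy on logits, Adam (lr 1e-3, batch 128),
early stopping on validation loss (patience 5) with best-weights restore.
None of these are constrained by the architecture; all are exposed
(`TrainConfig` / estimator parameters), including optional inverse-
frequency class weighting and decoupled (AdamW-style) weight decay, both
off by default.  Chromosome-holdout splits keep evaluation on unseen
sequence.

**Design choices where the design was open.**  The DNA dense width is 256
so that the joint input is the stated 768 (the alternative reading of the
layer as 128-wide is available via `fc_units`).  Context is always
recomputed from the genome, with a mismatch counter, to guard against
genome/annotation version drift.  Neighbor eligibility ignores context
(any labeled cytosine can be a neighbor); per-context neighborhoods are a
flag.  Imputation is a single pass using observed labels only — imputed
values are never fed back, so errors cannot compound.  No criterion is
defined for overriding a confidently observed state; `overwrite_observed`
exists but is off by default and documented as such.

## Evaluation

ACC, F1, MCC, TNR, TPR are computed from the confusion matrix at the
strict `p > 0.5` rule.  AUC is the Mann–Whitney probability of correct
ranking (ties half); PRC is average precision (step-wise, no trapezoid
interpolation) — the conservative choice, and the right companion to AUC
under the ~1:9 class imbalance these data show.  Conventions for
degenerate input: F1 = 0 when precision + recall = 0; MCC = 0 when a
marginal is 0; AUC/PRC are NaN with a warning when only one class is
present (threshold metrics are still reported).

## Motif readout

Each first-layer kernel (width 11) is read out as a candidate motif.
Activations are scanned over a window set; for each (window, filter) pair
the best-activating position contributes its 11-mer iff that activation
exceeds 50% of the filter's maximum *across all windows and positions*
(a per-window bar would select trivially), with at most one 11-mer per
window per filter.  Collected 11-mers are position-aligned by construction
(each centered on its best activation) and become a PWM with pseudocount
0.5; information content is `Σ_positions (2 − H)` bits.  Motif "activity"
is the mean (max also stored) activation per filter per window; the
"effect" of a motif on methylation is defined here as the Pearson
correlation between its activity and the window labels; PCA (top 2
components, filters as points, windows as features, deterministic sign
convention) maps co-occurring motifs together.  Activity/effect
definitions are this package's documented choices — the upstream analysis
names the quantities but not their formulas.  Export is MEME minimal
format plus a per-motif TSV.

## The synthetic-data generator

The generator produces the statistical structure the models exploit, with
known ground truth, and is itself first-class, tested code.  For each
cytosine `i` (both strands, all three contexts):

    z_i = b0 + Σ_m β_m · 1[occurrence of motif m within r bp] + u_i
    s_i ~ Bernoulli(logistic(z_i))
    d_i ~ Poisson(λ);   a low_depth_fraction share is forced to {0..3}
    n_meth_i ~ Binomial(d_i, 0.9·s_i + 0.1·(1−s_i))

`u` is a stationary AR(1) field over consecutive cytosines — the simplest
mechanism that produces the neighbor-state dependence real methylomes
show; the 10% per-read call error keeps observed labels imperfect so no
model can reach AUC 1.

Defaults (the conditions all headline numbers are computed under):
36% GC (Arabidopsis-like); one AT-rich hyper-methylating and one CG-rich
hypo-methylating 11-bp consensus at 0.25 occurrences/kb with logit effects
±4.0 and effect radius 500 bp; AR(1) with autocorrelation 0.99 and
marginal sd 2.5; depth λ = 20 with 15% of sites forced below the 4-read
threshold; baseline logit calibrated by bisection (`calibrate_baseline`)
so the methylated fraction is 0.10 (the ~1:9 imbalance of real plant
leaf methylomes).  The AR parameters were chosen so the neighbor signal
carries the dominant share of predictable variance, as it does in the
real data this generator emulates (where neighbor-based models clearly
outperform sequence-based ones); under these defaults the sequence
indicator alone reaches AUC ≈ 0.83 and the full latent field ≈ 0.94 —
the ceilings any model is working against.

**What the generator does not emulate:** TE/gene-body methylation
landscapes, context-specific pathways (e.g. RdDM), conversion-efficiency
artifacts, strand-asymmetric coverage, or any coupling between sequence
composition and read depth.  A CpG strand-symmetry option exists (off by
default).  Passing tests on these simulations shows the models learn the
two planted signal classes and that the pipeline's bookkeeping is exact;
it does not certify performance on real bisulfite data.

## Study regimes and problem sizes

Three named regimes (in `methynet.workflows`) isolate the branches:

* **default** (both signals, 4 × 40 kb chromosomes, ≈ 57k cytosines):
  all three models, trained on 12,000 sites from two chromosomes,
  validated on 1,500, tested on 3,000 from held-out chromosomes.
* **spatial-only**: no motifs; the methylation model should dominate.
* **motif-only** (4 × 80 kb): motif effects with a tight 25 bp radius, no
  AR field, and 85% of sites below the depth threshold.  The tight radius
  and sparse labeling are what isolate the sequence branch: a wide effect
  radius would re-express the sequence signal as neighbor-state
  correlation (a ±500 bp effect blankets the ~±100 bp neighbor span), and
  dense labeling would let the neighbor model read the motif regions off
  its neighbors.  Sparse coverage is also exactly the scenario where a
  sequence model earns its keep in practice.

Desk-scale model widths are used in these studies (16–32 conv filters,
16/24-unit GRUs, 501 bp windows, dense widths 32–64); the full-scale
architecture above is preserved as the package default and its dimensions
are asserted separately.  The joint model in the studies uses the
warm-start option (branches from the trained single models, short
end-to-end fine-tune at lr 3e-4): with a freshly initialized head,
from-scratch end-to-end training at these sizes tends to disturb the
stronger branch before the head has learned to read it.

Two desk-scale observations worth knowing: (i) in the default regime the
DNA branch learns little (test AUC ≈ 0.5) — with a few thousand training
windows under a dominant AR field, the CNN memorizes the training set
before it extracts the faint wide-radius motif signal; the joint model's
value there comes from its methylation branch.  (ii) Under the motif-only
regime the same CNN reaches AUC ≈ 0.8 and its first-layer filters recover
both planted consensus matrices at Pearson ≥ 0.8.  Both behaviors are
consistent with the relative branch performance reported for real plant
methylomes.

## Numerical details

* One-hot order A, T, G, C (input channels); PWM column order A, C, G, T
  (MEME convention).  The two orders coexist deliberately and are
  converted at the motif-readout boundary.
* External coordinates are 1-based inclusive everywhere (the cytosine-
  report convention); conversion to 0-based indices happens once, inside
  the encoder.
* Max pooling is non-overlapping and truncates the remainder (991 → 247
  after pool 4; 245 → 122 after pool 2), matching the flatten width
  122 × 256 the dense layer consumes.
* `MaxPool`/`argmax` ties break toward the earlier position; PCA axis
  signs are fixed by making each axis's largest-magnitude loading
  positive.
* Probabilities are produced through a numerically stable
  log1p/expit path; training is single-threaded-deterministic under a
  fixed seed (dropout and shuffling use the model's own generator).
* Degenerate inputs: empty training sets, single-class labels (warn,
  proceed), zero-variance activity rows (effect 0), empty motif
  selections (uniform PWM, IC 0), chromosome edges (pads / zero rows) are
  all defined behaviors with tests.

## Known limitations

* The numpy training loop is CPU-bound; full-scale (128/256-filter,
  128/256-unit) training on genome-scale data is outside its intended
  envelope.  The architecture is faithful; the throughput is not.
* The imputation AUC measured against simulated hidden truth (≈ 0.92
  under the default regime) says nothing about sites that are NA in real
  data for non-random reasons (repeats, structural variation).
* Cross-species transfer is supported mechanically (train on one genome,
  impute another via the saved model and its stored `D_max`), but no
  claim about its accuracy is made or tested here.
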