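# Methods

## The screening model

A systematic review's candidate pool is a set of references, each with
title/abstract text and a relevance label that becomes visible only when
the reference is "screened". Screening is simulated in two orders:

- **Prioritized (active learning).** The review protocol text acts as a
  single artificial positive example until the first real relevant
  reference has been screened, after which it is discarded. Each iteration,
  pseudo-negatives are drawn uniformly (fresh every iteration) from the
  *unscreened* pool so that the negative class holds at least 100 examples
  (screened true negatives count toward the floor); an L2-regularized
  logistic model is refit by SGD; the unscreened references are scored and
  the top *B_k* screened. Batch sizes follow B₁ = 1,
  B_{k+1} = B_k + ⌈B_k/10⌉, so effort between refits grows geometrically
  (~10% per iteration). The ranker never halts on its own — traces always
  cover the whole pool, and criteria are applied on top, retrospectively
  (simulation) or online (decision support).
- **Random** — a uniform permutation, the no-technology control.

Features are case-folded unigram and adjacent-bigram counts from the
concatenated title and abstract, weighted by smoothed idf (document
frequencies from the pool) and L2-normalized per document. The protocol is
vectorized in the same space; out-of-vocabulary protocol tokens are
dropped. SGD uses log loss, L2 penalty α = 1e-4, 5 passes per refit,
scikit-learn's "optimal" learning-rate schedule, with the per-refit RNG
seed drawn from the trace's seed stream. Ties in score break by original
pool index for determinism. If the training set degenerates to a single
class (possible only in pathological pools), scoring falls back to cosine
similarity with the protocol vector rather than crashing.

Pseudo-negatives are never references that have already been screened, and
an audit hook exposes each iteration's training set so tests can verify no
label leaks before its reference is screened.

## The meta-analysis model

Each relevant study contributes a 2×2 table. With continuity correction c,
the observed logit pair is

    y = (logit((tp+c)/(tp+fn+2c)), logit((tn+c)/(tn+fp+2c)))

with diagonal within-study covariance V = diag(1/(tp+c)+1/(fn+c),
1/(tn+c)+1/(fp+c)). By default c = 0.5 is applied only to studies with a
zero cell (a policy switch applies it to all studies, the convention of
some reference software). The bivariate random-effects model is

    y_i ~ N(mu, Psi + V_i),   i = 1..n  (n >= 3),

with unstructured 2×2 between-study covariance Psi. The summary
sensitivity/specificity are expit(mu), with Wald 95% CIs formed on the
logit scale and back-transformed (no Knapp–Hartung adjustment). Groups
with fewer than three studies are refused, mirroring the minimum-size rule
standard DTA software warns about.

**Estimation.** mu is profiled out by generalized least squares and the
restricted likelihood (REML; full ML available) is maximized over Psi with
L-BFGS-B. Psi is parameterized as (log τ₁, log τ₂, atanh ρ) with box
bounds log τ ∈ [−6, 3], atanh ρ ∈ [−6, 6]: every proposal is positive
semidefinite by construction (no post-hoc clipping), the lower τ bound
acts as the τ → 0 limit, and the parameterization is exactly symmetric
under exchanging the sensitivity and specificity axes, so mirrored data
give mirrored fits. Two starts are used (a moment estimate from the sample
covariance of y minus the mean V, and a fixed τ = 0.5/ρ = 0 start); the
better optimum wins. Convergence tolerance ftol = 1e-10, max 500
iterations; a fit where the optimizer does not report success is returned
with `converged=False` rather than raised. se(mu) = sqrt(diag((Σ_i
(Psi+V_i)^{-1})^{-1})) at the fitted Psi. REML is the default because the
widely used R implementation of this model fits by REML and because ML's
downward bias in τ at realistic meta-analysis sizes degrades CI coverage.
All per-study 2×2 inversions are closed-form, so a fit costs ~10 ms.

**Truth.** The reference ("truth") estimate for a meta-analysis is the
same fit over *all* its studies; every loss is the Euclidean (L2) distance
from an interim (sens, spec) estimate to this final pair, so the loss at
full screening is zero by construction.

**Known limitation — small-count bias.** The normal approximation weights
each study by its observed within-study variance, which is correlated with
the observed proportions; with small per-arm counts and proportions near 1
this pulls the summary estimate toward 0.5 (an effect shared by the
standard implementations of this model, and distinct from the exact
binomial GLMM formulation, which is out of scope here). The calibration
tests therefore generate their corpora with 500 subjects per arm, where
the approximation is accurate: parameter recovery within 3 SE and near-
nominal CI coverage hold there, and the test suite checks the fit against
an independent R implementation (metafor's bivariate mixed model) on
identical inputs. At the simulator's default of 50 subjects per arm the
model — like
its reference implementations — carries a visible bias on the specificity
axis; the stopping-criteria results are unaffected because all losses are
measured relative to the *final* estimate under the same model, not the
generator truth.

## Effort/loss curves and displacement

Replaying a trace against one meta-analysis: at each newly screened study
of the group, once at least three are found, the model is refit on the
found set. This yields

- the **effort/loss curve** (effort, L2 loss vs truth) — one point per
  update, final point at loss 0;
- the **displacement series** Δλ_t between consecutive estimates — defined
  from the 4th found study; its window-2 moving average (MA2) from the
  5th; MA2 uses full windows only (no partial window at the first
  displacement);
- per-update **found sets** for LOOCV displacement — defined from the 4th
  found study so each leave-one-out refit is itself analyzable (the
  minimum-fit rule forces the stricter bound).

Non-converged interim fits are skipped: the curve and displacement series
simply have no entry at that relevant study, and a per-replay tally
records how many updates were dropped.

## Stopping criteria

All threshold comparisons are strict, in the direction each rule states.
Retrospective rules (need the finished curve): **recall** triggers at the
⌈R·f_total⌉-th relevant reference; **knee** at the curve point farthest
from the chord between the first and last points after min-max normalizing
both axes to [0,1] (unit-dependence otherwise), ties to the earliest
point, computed on the raw curve; **loss/effort** at the left end of the
first segment of the curve's lower convex envelope whose slope exceeds
−Λ/E. The envelope is the monotone-chain lower hull truncated at its
minimum so it is non-increasing with non-decreasing slopes; the hull is
needed because single added studies routinely move the estimate away from
the truth, flipping the raw slope's sign.

Prospective rules (usable live): **relevant found** at the n-th relevant
reference; **found/effort** at the first effort, at or after the
min_found-th relevant (default 3), with no relevant among the last ⌈E/F⌉
screened — evaluated at every screened reference, which makes it exactly
the pairwise-slope rule on the found/effort curve with a constant effort
penalty of E/F; **displacement MA2** when the window-2 average falls below
the threshold; **LOOCV displacement** when the median leave-one-out shift
does (median of an even count = midpoint of the central order statistics).
Prospective rules are conservative by construction: with too few relevant
studies their preconditions never hold and they simply do not trigger.

An OR-combination of criteria triggers at the earliest member effort, with
recall and losses re-measured at that effort.

## Synthetic corpora

The generator emulates exactly the structure the simulator assumes:

- **2×2 tables.** Per-study (logit se_i, logit sp_i) ~ bivariate normal
  with means (logit 0.85, logit 0.92), SDs τ = 0.4, correlation ρ = −0.3
  (the negative sens/spec trade-off typical of threshold effects); counts
  binomial with 50 diseased and 50 non-diseased subjects per study —
  typical DTA study scale, keeping binomial noise visible. All defaults
  overridable.
- **Text.** Pseudo-word token streams over disjoint background (2000
  words) and signal (50 words) vocabularies. Relevant references draw each
  token from the signal vocabulary with probability `signal_weight`
  (default 0.8); irrelevant references use the background only; the
  protocol is pure signal vocabulary. `signal_weight` is the separability
  dial: at 0, relevant and irrelevant documents are exchangeable and the
  ranker can do no better than chance; near 1, relevance is trivially
  learnable from unigram counts. Bigram structure arises only from random
  adjacency. Default pool: 2000 candidates, 60 relevant, meta-analyses of
  12/8/5 studies mapped onto distinct relevant references.

What this does *not* emulate: natural language, citation networks,
duplicate records, publication bias, topic drift, or any correlation
between a study's text and its 2×2 table. Passing tests therefore show the
machinery is correct and the criteria behave as designed on corpora
satisfying the model's assumptions — not that the particular thresholds
transfer to any real review collection, whose separability and study
quality must be judged per corpus.

## Problem sizes and determinism

Simulation tests and the acceptance script run the default 2000-reference
corpus with 10–20 prioritized and 20–50 random replicates, and calibration
studies with 50 corpora of 200 studies / 200 corpora of 30 studies —
sizes chosen so the full suite completes in a few minutes on one CPU while
keeping Monte-Carlo error well below the effects asserted. All randomness
flows from explicit integer seeds through `numpy` seed sequences (method,
replicate and refit seeds are derived children), so traces and reports are
byte-identical across runs with the same seed. Reports aggregate triggered
events only, averaging within replicate first and then across replicates;
`triggered_ma` counts triggered (replicate, meta-analysis) pairs and
`triggered_sr` counts replicates where every analyzable meta-analysis
triggered.

## Open design choices taken

- The knee criterion operates on the raw effort/loss curve; the hull is
  applied only where the slope rule requires monotonicity.
- Found/effort is evaluated at every screened reference (not only at
  relevant-found events); its min_found floor defaults to 3.
- Pseudo-negatives come only from the unscreened pool, resampled each
  iteration; screened references are never pseudo-negatives.
- Real-data joins between qrels topics and 2×2 exports are left to the
  caller; the loaders validate cross-references and fail loudly.
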