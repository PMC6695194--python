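# Methods

This note records the models behind `ibrank`, the defaults that matter,
the numerical choices, and what the synthetic studies do and do not
demonstrate.

## Setting and notation

A bioactivity matrix X = {x_ij} holds quantitative readouts (percent
inhibition at a fixed concentration) of m targets (rows, index set I)
against n compounds (columns, index set J). Two derived views are used
throughout:

* **Binary calls** Z = {z_ij}: z_ij = 1 iff x_ij ≥ mean(x_i·) + 2·sd(x_i·),
  with the sample (n−1) standard deviation. The threshold is per target
  because assay scales differ between targets. A constant row yields
  sd = 0 and every entry ties the threshold; the literal outcome (all
  active) is kept, with a warning, because such rows are pathological
  screens rather than a case worth special semantics.
* **Column scaling**: each compound column mapped by (x − min)/(max − min)
  onto [0, 1], so clustering distances are not dominated by compounds
  with wide raw dynamic range. Constant columns map to 0 (no signal).
  The learned per-column min/max are reused to place a new target's
  informer readouts on the same scale, clipping to [0, 1].

The task: choose an informer set A ⊂ J (default n_A = 16) from X alone,
then, given assays x* of A on a new target, rank J \ A for activity.

## Regression selection (RS)

Targets are clustered on the scaled matrix by k-means with k-means++
initialization, restarted (default 100×, seeded) and keeping the lowest
within-cluster sum of squares. Cluster labels y_i are then regressed on
the full activity profiles with a multinomial logistic model penalized
by the group lasso λ Σ_j ‖ω_·j‖₂ (ω_·j collects the K weights of
compound j), λ = 10⁻⁶. Selection is greedy: fit, move the largest-norm
penalized group into A (exempting it from the penalty), refit, repeat
until |A| = n_A or every remaining group is zero. After selection the
model is refitted on A only, without the penalty but with a 10⁻⁸ ridge —
the unpenalized likelihood is unbounded when the clusters are linearly
separable on A, and the ridge pins a finite optimum without visibly
moving probabilities.

Ranking: cluster probabilities come from the refitted softmax
(intercepts included — they are part of the fitted model even though the
prediction formula is often written without them), and each non-informer
is scored by the probability-weighted cluster centroid of the **raw**
matrix, μ̂_j = Σ_k Pr(k|x*)·mean_{i∈S_k} x_ij. Using raw centroids is a
deliberate design decision: scaling is a clustering device, and a
compound active on every target min-max-scales to pure noise, which
would make its (high) expected activity invisible to the ranking. We
measured exactly this failure on synthetic data with uniformly active
compounds (held-out NEF10 dropped from 1.0 to ≈0.72 with scaled
centroids).

K is chosen by 5-fold cross-validation over targets: for each candidate
K the full pipeline runs on the in-fold targets and each held-out
target is ranked from its informer readouts and scored (NEF10 by
default, ROCAUC by flag) against its own μ+2σ calls; ties go to the
smaller K. Note that the CV score only distinguishes K where cluster
resolution changes ranking quality; once performance saturates, all
K ≥ K_true tie and the smaller-K rule resolves them. A fixed
`n_clusters` bypasses the search.

## Coding selection (CS)

For a candidate A, the distinct rows of Z restricted to A are code
words q_1..q_{L_A}; a partition π of code words into K blocks induces a
target clustering. The objective

f_{K,λ}(A, π) = Σ_k Σ_{pairs i<i′ ∈ S_k} d(z_i, z_i′ on A^c) − λ·L_A

sums, over unordered within-block target pairs, the asymmetric binary
distance (1 − |intersection|/|union| over active positions; 0/0 defined
as 0 — identical inactivity is not dissimilarity). λ = 5 rewards
code-word diversity. The minus sign on λ·L_A is implemented exactly as
the method defines it; since candidates with *lower* f are preferred,
this term favors many code words, consistent with its stated purpose of
reducing extrapolation, even though it is conventionally called a
penalty.

The search is Monte Carlo: for each K in {2..40}, B candidates are
drawn (A uniform without replacement; each code word assigned
independently and uniformly to one of min(K, L_A) blocks, empty blocks
compacted — a simple seedable reading of "random partition"). Compound
scores f_j accumulate (1/B)·1(j∈A_b)·f(A_b, π_b) summed over K: the
division is by B, not by the inclusion count, so a compound's score
mixes how often it is drawn with how good its candidates are — this is
the method's own stabilization and is preserved as such. Never-sampled
compounds score +∞ and cannot be selected. The informer set is the n_A
lowest scores, ties by compound ID. B defaults to 10⁵ (production runs
use 10⁶ or more; tests use far fewer trials because the tested spaces
are small). The scorer also tracks a per-compound Monte-Carlo standard
error, which the exchangeability tests use.

Ranking: the new target's informer readouts x* are matched to the code
word with the nearest centroid (mean raw informer activities of member
targets; ties to the lowest word index), and non-informers are ranked
by activity counts a_j among the n* matched targets, ties by descending
global column activity then compound ID. A crude FDR estimate
1 − Σ(a_j/n*)1(a_j≥κ) / Σ1(a_j≥κ) supports choosing the smallest κ with
estimated FDR ≤ 0.1 when binary predictions are needed; the ranking
itself never uses κ.

## Adaptive selection (AS)

K comes from the elbow rule: the smallest K with |1 − L_{K+1}/L_K| ≤ ε
(ε = 0.02), scanning K = 2.. up to K_max (default min(40, m−1)); a zero
objective stops the scan, and hitting K_max returns it with a warning.
The relative-drop rule only terminates when the objective flattens
within ε per step; on small or noisy panels the k-means objective can
keep improving by ≈3% per added cluster from noise alone, in which case
the rule runs to K_max. That behavior is inherent to the rule (the
ratio is scale-invariant in the noise level) and is surfaced rather
than patched; AS ranking quality is insensitive to it because ranking
depends on the informer set, not on K directly.

The base set is the group-lasso path point with exactly n₀ = 8 active
groups: 100 log-spaced penalties from the critical value λ_max down to
10⁻⁷λ_max, warm-started, with geometric bisection between bracketing
grid points; if groups enter in a batch that skips n₀, the first point
with ≥ n₀ groups is truncated to the n₀ largest norms (flagged). Path
fits carry a 10⁻⁸ ridge — without it, once the selected groups separate
the clusters perfectly the remaining gradients vanish and no further
group ever enters. Augmentation to n_A = 16 repeatedly adds the
compound j minimizing Σ_{k∉A∪{j}} ‖x_·k − c‖², with c the centroid of
the raw informer columns including j; the sum excludes the candidate
itself (the literal reading of the index set). Ranking delegates to the
CS code-word machinery on the final set.

## Baselines

BC clusters the library by average-linkage agglomerative clustering of
Jaccard distances between Morgan fingerprints (radius 2, 1024 bits) cut
at n_A clusters, taking each cluster's medoid (minimum summed
within-cluster distance, ties by compound ID). BF takes the n_A most
broadly active compounds by column sums of Z. Both rank non-informers
chemically: simple expansion (ascending distance to the nearest active
informer), loop expansion (round-robin over active informers by
descending activity, each visit ranking its nearest unranked
non-informer), and weighted expansion (w_j = v_jᵀx*, the inner product
of Jaccard similarities to the informers with the informer activities
min-max normalized to [0, 1]; constant activities map to 0.5).

Weighted expansion orders **descending** by w_j: w is an
activity-weighted similarity, so larger means more like the active
informers. A literal low-first reading survives behind
`ascending=True`. Informer active/inactive calls on the new target are
inferred by quantile matching: each training target's own μ+2σ
threshold is located as a quantile level within that target's informer
readouts, the median level κ̂ over targets is applied to x*, and an
informer is active iff its readout reaches the κ̂-quantile. Being
rank-based, the labels are invariant to monotone rescaling of x*. If no
informer is called active, expansions fall back to the single
highest-activity informer as the center. Fingerprints and scaffolds sit
behind provider objects, so precomputed bit matrices and integer
scaffold IDs replace chemistry entirely (the test suite and synthetic
studies never touch RDKit).

## Metrics and bookkeeping

Informers are assayed by construction, so evaluation rewards active
informers and does not punish inactive ones: active informers are
prepended to the ranking in descending experimental activity (an order
is required because percentage cutoffs can split the block), inactive
informers are removed, and the library size N for all percentage
cutoffs is the post-removal count. Cutoffs round half away from zero
with a floor of 1 — the rounding that reproduces the canonical counts
(10% of 366 → 37 = 16 informers + 21 non-informers; 5.5% of 366 → 20;
5.5% of 415 → 23).

* ROCAUC: normalized Mann–Whitney U with half credit for ties;
  undefined (NaN sentinel) for single-class labels.
* EF10 = (actives in top cutoff / cutoff) / (actives / N); NEF10 =
  (1 + (EF10 − 1)/(EF10max − 1))/2 with EF10max the all-actives-on-top
  value, so 0.5 is random and 1.0 perfect regardless of class balance;
  undefined when every compound is active.
* FASR10: |active scaffolds with an *active* member in the top 10%| /
  |active scaffolds|; inactive members of an active scaffold never
  count. Scaffolds are generic Bemis–Murcko frameworks (all-carbon,
  all-single-bond); acyclic molecules share a reserved ID.
* F1/MCC: the top round(0.055·N) compounds are called active (the
  median active fraction of the reference panels); MCC is 0 on a zero
  marginal.
* A strategy that cannot produce a ranking receives ROCAUC = NEF10 =
  0.5 and FASR10 = 0, with F1/MCC computed on a seed-0 random order.

## Evaluation drivers

The LOTO driver removes each target, lets every method select informers
from the reduced matrix only (a regression test asserts the selection
saw m−1 rows), reveals the left-out row's readouts on the informers,
ranks, and scores against the left-out target's μ+2σ calls computed on
its full row. Method failures are logged and receive the degenerate
scores; the run continues. All randomness fans out from one seed
through child streams, and runs are byte-reproducible.

Cross-method comparison uses the paired two-sided Wilcoxon signed-rank
test per (method, baseline) pair with zero differences dropped, the
exact null for ≤ 25 untied non-zero pairs and a continuity-corrected
normal approximation otherwise, at the Šidák-adjusted per-test level
1 − 0.95^(1/b) (b baselines; b = 6 gives α ≈ 0.0085). Hit-rate
stratification bins targets by active-fraction rank (ties by target ID)
into equal-size bins and fits the additive two-factor model
metric ~ target + method, reporting Tukey simultaneous 95% intervals on
method-effect differences via the studentized range.

## Synthetic studies

The generator plants the structure the strategies assume: K balanced
target clusters; `n_informative` compounds each strongly active
(`cluster_sep`, default 80 percent inhibition) exactly on its own
cluster's targets, so these columns predict cluster identity; a small
background set of compounds active on every target; per-target
idiosyncratic actives topping each row up to an active fraction drawn
from `active_fraction_range` (default 0.03–0.10, the heavy imbalance
typical of kinase panels); Gaussian readout noise (default SD 4,
i.e. separation/noise = 20) truncated to [−20, 120]. Defaults are
m = 60, n = 80, K = 3, n_informative = 6. Synthetic fingerprints give
each of `n_scaffolds` groups a random core bit pattern with 1% bit
flips; informative and background-active compounds concentrate in a
quarter of the groups, but those groups also receive their share of
inactive compounds — chemical similarity is informative, not
conclusive, mirroring how real chemotypes contain both active and
inactive members.

What passing tests show: the strategies recover planted informative
compounds, planted partitions, and rank planted actives essentially
perfectly at separation/noise = 20, and they beat the chemometric
baseline under conditions where chemistry is partially informative.
What they do not show: performance on real panels, where cluster
structure is soft, activity is graded rather than planted, assay noise
is non-Gaussian, and missing values appear. The held-out targets in the
end-to-end suite are drawn from the planted cluster profiles (no
idiosyncratic actives), which is the regime the methods are designed
for; matrix targets with idiosyncratic actives are by construction only
partially predictable, and LOTO scores on them sit below the held-out
ceiling.

Two recovery checks need specific regimes worth recording. The elbow
rule flattens below ε = 0.02 only when per-split noise gains are small,
which needs enough targets per cluster; the recovery test uses m = 150.
CV-based K selection needs conditions where cluster resolution matters
to the ranking (more informative compounds than informer slots and no
saturating background signal); its test uses 9 informative compounds
with n_A = 4.

## Numerical choices

* Group-lasso fits: FISTA with a monotone restart, fixed step
  1/(0.5·‖[1 X]‖₂² + ridge), relative-objective tolerance 10⁻⁶, 10⁴
  iteration cap (error with diagnostics beyond it). Smooth fits
  (λ = 0) go to L-BFGS instead — proximal steps crawl near separation.
* Tie-breaking is lexical on compound ID everywhere a score ties
  (greedy norms, μ̂, activity rates, medoids, expansions), for
  reproducibility.
* Degenerate inputs: constant rows/columns warn (see above); all-zero
  fingerprint pairs get Jaccard distance 0; an all-zero binary matrix
  makes BF fall back to lexical order with a warning.
* Seeds: every stochastic component (k-means restarts, CV folds, CS
  trials, degenerate-score permutation) derives from one integer seed
  via `numpy` child streams; identical inputs and seed reproduce every
  output byte-for-byte.

## Limitations

* Missing values are rejected, not imputed; incomplete panels need
  upstream handling.
* The CS search is Monte Carlo; at realistic library sizes it explores
  a vanishing fraction of the combinatorial space, and scores inherit
  sampling noise (quantified by the reported standard errors).
* The elbow rule may return K_max on small panels (see above).
* Replicate assays or mutant variants of one parent target are treated
  as independent rows; no aggregation is attempted.
* The quantile-matching rule for informer activity calls is one
  faithful reading of a terse procedure; it is isolated in
  `infer_informer_labels` for easy replacement.
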