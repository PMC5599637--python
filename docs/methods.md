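# Methods

## Profile model and preprocessing

A profile is a vector of $k \ge 2$ non-negative integrated peak areas over a
fixed, ordered compound list (bundled default: the eight cocaine alkaloids
EME, EC, TROPA, BENZO, NOR, CIS, TRANS, TMC in elution order, with
nonadecane as internal standard). Preprocessing applies, per profile:

1. **Total-area scaling** to $10^6 \times k$ — a conventional common scale
   so transformed values are comparable across profiles;
2. **Transformation** — identity, $x^{1/4}$ or $\ln(1+x)$, all defined on
   $[0,\infty)$; the root/log variants damp the dominance of large peaks;
3. **Row normalization** — division by the row sum, so each peak becomes a
   fraction of the profile total. When injected noise peaks are present they
   participate in the denominator; this is deliberate, as it reproduces how
   a single unstable compound contaminates *every* normalized peak.

The chain is invariant to positive rescaling of the raw profile. Step 1 is
redundant for the identity transform (step 3 alone gives raw proportions)
but makes the root/log variants well-defined; the steps are exposed
individually (`scale_to_total`, `transform_profile`, `row_normalize`) so the
order can be varied in sensitivity checks. All-zero profiles are rejected at
read/preprocess time rather than propagating NaN.

## Pair features

* **Pearson distance** $(1-r)/2 \in [0,1]$ over the two peak vectors; the
  traditional single-variable comparison. Undefined (error) for a
  zero-variance profile.
* **Single peak differences** $|x_1-x_2|/(x_1+x_2)$ per compound, on
  normalized peaks; $0/0 := 0$ (two absent peaks are identical).
* **Ratio differences** $|r^{(1)}_{ab} - r^{(2)}_{ab}|$ over all
  $k(k-1)/2$ unordered compound pairs, with $r_{ab} = x_a/(x_a+x_b)$ and
  $0/0 := 0$. The canonical orientation puts the compound earlier in the
  compound-table order in the numerator; feature columns are named
  `rd_<A>+<B>` so importance tables are interpretable.

Ratio differences are invariant to independent positive rescaling of either
profile (hence to any normalization), and a ratio of two original compounds
is bit-identical before and after appending noise columns to the raw table.
Through preprocessing the immunity holds to floating precision (~1 ulp),
because the per-profile scale factor cancels inside each ratio.

## Pairing and labels

Ground truth comes from batch membership: same non-single group → linked;
different groups, or group vs single → unlinked; single vs single →
discarded (no usable truth). Pairs never span the train/validation split,
and validation pairs use only validation-split profiles. The extreme class
imbalance (unlinked ≫ linked) is preserved — no resampling — because MCC
handles it.

## Classifiers

Both classifiers model $P(\text{unlinked})$; a pair is called unlinked when
the probability is ≥ 0.5 (ties go to unlinked — the conservative call in a
forensic context, favouring "no link").

* **Logistic regression**: unpenalized maximum likelihood. If the fit fails
  to converge (typically separation), it falls back to a weak ridge penalty
  ($C = 10^4$) and warns. Importance = |coefficient|.
* **Random forest**: 500 trees, $\lfloor\sqrt{p}\rfloor$ candidate features
  per split — the long-standing defaults of the classical implementation.
  Out-of-bag votes are retained per training pair; pairs that were in every
  bootstrap sample are flagged rather than silently imputed. Importance =
  mean decrease in out-of-bag classification accuracy, computed per tree:
  each tree is scored on its own out-of-bag pairs before and after permuting
  one feature, and the decreases are averaged over trees. This per-tree
  estimator is used rather than permuting through the whole ensemble at
  once, because with 28 highly correlated informative ratios the ensemble
  can compensate for any single permuted feature, which drives whole-model
  permutation importances to ~0 and erases the pure-vs-noisy contrast the
  statistic is meant to show. Per-tree decreases can be slightly negative
  for useless features; values are reported as computed.

## Evaluation protocol

MCC is computed in floating point with the denominator factored into two
square roots (exact in clean cases, no overflow at realistic pair counts);
a zero marginal yields 0 by convention. Internal performance: stratified
5-fold cross-validation for logistic regression (stratified because of the
imbalance; unstratified available), out-of-bag counts for the forest.
External performance: the fitted model applied unchanged to validation
pairs. `run_grid` sweeps transform × feature × classifier × noise condition
over replicate seeds (one independent child seed per replicate, derived
from the global seed via `numpy.random.SeedSequence`); SEM is computed
across replicate seeds and omitted for a single replicate. Noise injection
inside the grid pools peak values across both splits before re-splitting,
so injected values follow the whole dataset's empirical distribution.

## Noise injection

Artificial "extremely unstable" peaks are appended as new columns whose
cells are i.i.d. draws (with replacement) from the pool of all existing raw
peak values. Cell-level resampling was chosen over column-level because it
guarantees no correlation between samples or between peaks; the alternative
unit of resampling would preserve sample-level structure. Injection happens
on raw areas, before preprocessing, so the noise enters the normalization
denominator. Default: 4 noise peaks on 8 alkaloids → 12 peaks, 66 ratios,
of which 38 touch at least one noise peak and 28 stay pure.

## Synthetic data generator

Real forensic peak tables of this kind are not publicly deposited, so the
generator emulates the study design: 29 training batches / 280 grouped
specimens + 124 unrelated singles, and 10 validation batches / 68 specimens
by default, 8 compounds. Per batch a base composition is drawn from a
Dirichlet; each member specimen is

    base × lognormal(cv) per peak × (1 − rate)^months on unstable compounds × total area

with storage months uniform on [0, 15] per specimen and total area
log-uniform on [10^6, 5·10^7]. Group sizes partition the totals randomly
with every group ≥ 2. Defaults and why:

* **Dirichlet concentration 1.5 (symmetric)** — batch compositions that are
  clearly distinct yet not degenerate; per-compound means across many
  batches converge to the concentration-implied proportions.
* **Within-batch CV 0.10** (multiplicative lognormal) — the typical
  analytical repeatability of integrated GC-MS peak areas, and the
  "moderate variation" operating point of the stress test. The method
  degrades smoothly with this knob (external MCC ≈ 1.0 at 5 % CV, ≈ 0.95
  at 10 %, ≈ 0.86 at 15 % under the full stress conditions).
* **Degradation off by default**; the stress configuration uses 2 unstable
  compounds at 0.2/month, i.e. a ~28-fold range of decay across specimens —
  deliberately harsher than plausible real kinetics. Decay is modelled as
  the simplest monotone multiplicative instability; real kinetics are out
  of scope.
* Lognormal (not additive Gaussian) noise keeps peaks positive and the
  model scale-free; in the cv = 0, rate = 0 limit, batch members are exact
  positive rescalings of each other, giving an exact oracle (all linked
  ratio differences ≡ 0).

What the generator does **not** emulate: retention-time drift, co-eluting
or missing peaks, cutting agents, heteroscedastic integration error, or
correlated degradation across compounds. Passing stress tests therefore
demonstrate the method's noise/normalization immunity and its learning
behavior under known ground truth — not field performance on casework.

## Problem sizes

The bundled stress evaluation uses 10 training batches × ~5 specimens + 20
singles and 6 validation batches (≈ 2 200 training pairs, ≈ 430 validation
pairs) with 3 replicate seeds — large enough for stable MCC estimates at
interactive runtimes. The generator reproduces the full study shape
(472 profiles) on request (`--preset study-shape`).

## Known limitations

* The ratio features assume peaks are either present or truly zero; values
  below the integration limit are treated as 0, and the $0/0 := 0$
  convention makes two below-limit peaks look maximally similar.
* Logistic regression on 66 correlated ratio features is prone to
  separation and unstable weights; it is retained as a baseline, with the
  forest as the recommended classifier.
* Classifier probabilities are emitted as-is; calibration and
  likelihood-ratio evidential reporting are out of scope.
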