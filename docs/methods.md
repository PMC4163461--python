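# Methods

## Model overview

`hbfin` implements a staged (hierarchical, multistage) Bayesian inference
net for diagnosing heart pathologies from hemodynamic parameters (HDPs),
with fuzzy-logic quantification of its evidence nodes.  The design
deliberately avoids both full joint-distribution learning (which needs
large qualified data sets) and purely expert-elicited statics (which
suffer cognitive biases): the net *topology* comes mechanically from a
small knowledge base of predicate-logic implications, and the *evidence
strengths* come dynamically from fitted membership functions, so only a
handful of global constants remain to choose.

The probabilistic engine is the classic odds-likelihood scheme of
rule-based expert systems (PROSPECTOR lineage).  Each hypothesis node h
carries a prior P(h) and a pair of odds multipliers: LS (likelihood of
sufficiency, applied when the evidence is certainly present) and LN
(likelihood of necessity, applied when certainly absent).  Updates happen
in odds space, O(h|x) = [∏ᵢLᵢ]·O(h); unknown evidence contributes Lᵢ = 1.
Conditional independence of evidence is assumed literally — likelihoods
multiply and correlations between symptoms are not modeled.

### Uncertain evidence

Evidence whose current belief P(x|e) is strictly between 0 and 1 updates
by piecewise-linear interpolation through three anchors:

- (0, P(h|x′)) — posterior under certainly-false evidence (via LN),
- (P(x), P(h)) — the prior, at the evidence's baseline probability,
- (1, P(h|x)) — posterior under certainly-true evidence (via LS).

The two linear branches meet at P(x|e) = P(x), so the update is
continuous and monotone in P(x|e).  Certainty is decided with tolerance
1e−9; at exactly 0 or 1 the direct odds update applies.

### Evidence collapse at logic nodes

A formula's antecedents are collapsed into one effective evidence:
P(x|e) is the minimum (conjunction) or maximum (disjunction) of the
antecedent beliefs, and the baseline P(x) the same min/max over the
antecedent baselines.  A hypothesis antecedent contributes its propagated
posterior (belief) and its prior (baseline).  The collapsed evidence then
updates the consequent with the consequent node's own LS/LN — matching
the one-LS/LN-per-node quantification — except when a hypothesis is fed
by a single lone symptom, in which case that symptom's dynamically
assigned Rule-1/Rule-2 likelihoods apply directly.  When several formulas
share a consequent, their collapsed values combine through an implicit
disjunction.

Unknown evidence is excluded from the min/max; a node whose evidence is
entirely unknown retains its prior, and such a node also propagates as
*unknown* to its consumers (a prior-valued intermediate carries no
information).  This keeps the invariant "all evidence unknown ⇒ every
posterior equals its prior" exact at every stage.

### The symptom baseline P(x)

The interpolation needs a baseline probability for symptom evidence.  A
symptom node's belief *is* its membership grade, and the grade carries no
separate prior, so the package defines the baseline as the grade at which
evidence switches from being categorized false to being categorized true
— the Rule-1/Rule-2 threshold, 0.2 by default.  Below it, evidence pulls
the posterior below the prior (toward the LN anchor); above it, upward
(toward the LS anchor).  This makes the continuous interpolation the
smooth counterpart of the discrete true/false categorization, and it is
configurable (`QuantifyConfig.symptom_prior`) for users who prefer a
different neutral point.

## Quantification constants

| Constant | Default | Meaning |
|---|---|---|
| α | 100 | LS scale: LS = α·f when grade f ≥ threshold (Rule 1) |
| β | 10 | LN scale: LN = β·f when f < threshold (Rule 2) |
| threshold | 0.2 | rule switch, inclusive on the Rule-1 side; also the symptom baseline |
| PoI prior | 0.02 | indifference prior for every hypothesis node |
| PoI LS / LN | 200 / 0.01 | indifference likelihood pair for hypothesis nodes |

α and β may be any nonnegative values; a larger α strengthens
confirmation by present evidence, a smaller β strengthens disconfirmation
by absent evidence.  With α = 0 a Rule-1 assignment yields LS = 0, which
the engine treats as maximally disconfirming (posterior odds 0).  Exactly
one of LS/LN is assigned per known grade; the unassigned direction
defaults to 1 (uninformative), which keeps the likelihood product
well-defined.  Users may pin per-node parameters; pinned values survive
the indifference pass.

## Hemodynamic formulas

The elastic-cavity (two-element windkessel) solution maps per-beat SPG
morphology (systolic/diastolic pressure, mean pressure, systolic and
diastolic areas, period) to the auxiliary pressure index k, stroke volume
SV, auxiliary sphygmogram index η, arterial compliance AC, and peripheral
resistance R.  Notes:

- The η formula is implemented as η = 1 + A_s/A_d, the only reading
  consistent with its equivalent form (A_s + A_d)/A_d; the source's second
  printed form degenerates to a constant and is treated as a typo.
- The constant 0.28 in SV = 0.28·k²·T·(P_s − P_d) is treated as absorbing
  unit conversion; no derivation is available for it.
- Venous pressure P_v defaults to 0, giving the printed approximation
  R ≈ P̄/(SV·T).  R keeps the period in the denominator as printed, even
  though that is dimensionally unusual for a peripheral resistance.
- Units are documentation only; no unit-checking system is imposed.

## Condition table

The bundled table holds 16 symptom rows with bands `a` (pathological,
typically high), `b` (pathological, typically low) and `c` (normal).
Range bands (`x~y`) are closed on both ends; `≈x` bands are closed
intervals x·(1 ± tol) with tol = 0.10 by default (the source never
defines ≈).  Bounds may be arithmetic expressions over Wt, L and Q,
evaluated per record through an AST-whitelisted evaluator.

Two printed irregularities are handled explicitly:

- The AC row gives "≥1.2" for both `a` and `c`; the bundled table keeps
  `a` and omits `c` (the intended normal band is unknowable).
- The VPE row's `c` uses a different parenthesization,
  (2·Wt + 45)·0.0112, than its `a`/`b` bands, 2·(Wt + 45)·0.0112; both
  are implemented exactly as printed.

Several rows' pathological bands geometrically overlap the normal band
for realistic anthropometrics (Wt `a: >20` vs `c: 50~80`; CI `a: ≥2.2`
vs `c: 1.2(1+Q)~2(1+Q)`; FEK; VPE; BV shares a boundary point).  Rather
than silently editing the table, evaluation resolves label collisions by
the fixed precedence a > b > c: a value extreme enough to match a
pathological band is not normal.  Overlap between the two *pathological*
bands, or duplicated labels, is rejected when a table loads (checked by
interval arithmetic over a grid of weights and heights).  The recorded
pathological/normal overlaps are exposed as `ConditionTable.overlaps`.

## Membership functions

Three families are supported: high-order polynomial (default order 3,
output clipped to [0, 1]), S-type logistic 1/(1 + e^(−a(s−b))), and
quasi-Gaussian e^(−((s−a)/(2d))²).  "Quasi" because evaluation is
restricted to the fitted support — the observed data range — with
constant extrapolation beyond it, so the curve never extends to ±∞.

Fitting follows the frequency-plot construction: histogram the cohort
(Sturges' rule by default), histogram the records labeled with the
hypothesis, and take the labeled fraction per occupied bin as the
empirical grade at the bin center; the family is then least-squares
fitted to those pairs.  The labeled-fraction normalization is a design
choice — the construction is described in the source only pictorially.
Family selection, where not prescribed, minimizes the residual sum of
squares across all three fits (ties: polynomial < s_type <
quasi-Gaussian); the selection rule is a reproducible surrogate for an
unstated manual choice and can be overridden per symptom.  Fits require
at least 20 labeled values and non-degenerate variance.  Membership
functions are keyed by (symptom, hypothesis); a net node shared by
several formulas resolves to its lexicographically first consumer's
function, and nodes with no fitted function fall back to crisp band
grading (grade 1 if the value lies in the node's band, else 0).

Validation uses a stratified hold-out: 75% of each class fits the
membership functions, the remaining 25% tests the net.

## Synthetic cohorts

The generator emulates a multi-hospital cohort of per-patient symptom
records: per class, each defining symptom (from the class's recursively
expanded formula) is drawn uniformly within its designated band and every
other symptom within the normal band; weight and height are drawn per
record and anthropometric bounds evaluated against them.  Uniform
within-band sampling (not Gaussian) is deliberate: it stresses the
membership-function fitting across whole bands rather than concentrating
mass at band centers.  Bands open on one side are sampled on
[bound, bound + 3·width] using per-symptom width hints (e.g. 15 mmHg for
systolic pressure) chosen as plausible clinical spreads.  Default classes
are balanced — the emulated study reports only cohort totals, not
prevalences.  Corruption is controlled by `noise_fraction` (resample a
symptom from its global envelope) and `missing_fraction` (drop it).

What the generator does *not* emulate: measurement noise of real SPG
waveforms, within-patient correlation across repeated visits,
inter-symptom physiological correlations, or the source hospitals' actual
case mix.  Passing recovery tests on these cohorts therefore demonstrates
the internal consistency of the pipeline (bands → grades → likelihoods →
posteriors), not clinical accuracy; the published hospital accuracies are
not reproducible without the original private records and are not
targets of this package.

## Numerical choices

- Certainty tolerance 1e−9 for classifying grades/beliefs as 0, 1, or
  intermediate; the interpolation baseline is clamped to
  [1e−6, 1 − 1e−6] if a user configuration drives it degenerate.
- Hypothesis priors must lie strictly in (0, 1) (infinite odds are
  rejected at the type level).
- Deterministic traversal: hypothesis nodes are processed in
  (stage, name) order; net construction sorts formulas canonically, so
  the same knowledge base yields byte-identical serialized nets in any
  input order.
- Stage indices are longest-path layers from the symptom level (stage 0);
  symptom nodes are stage 0 regardless of where they attach.
- Curve fits run through `scipy.optimize.curve_fit` with data-driven
  initial values (grade-0.5 crossing for the logistic turning point, the
  argmax bin for the Gaussian center) and bounded positive bandwidth.

## Problem sizes

Default test and acceptance runs use six classes × 50 records (300
records, 75/25 split), exhaustive engine-vs-oracle enumeration over 2⁶
evidence assignments, and 500-draw hemodynamic round trips; these sizes
give stable statistics (the recovery criterion is ≥95% over 72 test
records) while keeping any run in the low seconds.

## Known limitations

- Hypothesis names must not end in `a`/`b`/`c`: the parser classifies a
  trailing band suffix lexically.  True of the bundled knowledge base.
- The knowledge base covers only the printed formula set (12 formulas,
  12 hypotheses); the larger nets extended to coronary heart disease,
  arrhythmia, etc. were never published and can only be user-supplied.
- Only the HDPs with printed formulas are derived; the remaining HDPs of
  the full 38-dimensional symptom space ride through records as
  pass-through columns.
- The engine is strictly the staged odds-likelihood scheme: no loopy or
  junction-tree inference, no evidence-correlation modeling.
- When a conjunction's known antecedents are certainly true but siblings
  are unknown, the collapsed evidence is treated as certainly true —
  absence of evidence is uninformative by design, not conservative.
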