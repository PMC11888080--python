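# Methods

## Problem and units of analysis

Wrong-site surgery is a never-event that leaves a statistical fingerprint in
coded claims: a procedure code whose laterality contradicts every diagnosis
that could justify it.  `lateraleye` works at the level of the **claim** —
one inpatient billing record carrying all ICD-10-PCS procedure codes and
ICD-10-CM diagnosis codes documented together.  Two detectors are compared:

* a **rule-based method** that flags a claim whenever its procedure-side and
  diagnosis-side laterality conflict (the LR and RL subgroups below), and
* an **association-outlier model** that flags a claim when some procedure
  has no sufficiently associated diagnosis anywhere on the claim.

## Laterality and subgroups

Code-level side and body-part semantics come from a longest-prefix-wins
`CodeMap`, because both coding systems encode side in family-specific
character positions; hard-coding a character index is not viable across
families.  Per-code laterality is one of LEFT, RIGHT, BILATERAL,
UNSPECIFIED_SIDE (a sided part documented as "unspecified") or
NO_LATERALITY.  Claim-level sides aggregate the lateralized codes only:
LEFT/RIGHT when all lateralized codes agree, BOTH when a bilateral code is
present or both sides appear, INDETERMINATE when no code carries a side.
UNSPECIFIED_SIDE and NO_LATERALITY codes are treated as carrying no side
evidence rather than as conflicts: the nonerror taxonomy explicitly expects
them to coexist with lateralized procedures.  A BILATERAL code forces BOTH
even when every other code agrees on one side, since "both" is defined by
receipt of both-side procedures.

Crossing procedure side with diagnosis side over {L, R, B} yields nine
subgroups (RR, RL, RB, LR, LL, LB, BR, BL, BB); the partition is total once
INDETERMINATE is included.  The study population filter retains claims that
(a) match the configured attending-specialty code (a configuration value,
not a constant, because specialty code tables vary by file vintage; the
orthopedic-surgery value `"20"` is the default), (b) have identifiable
laterality on at least one procedure *and* one diagnosis, and (c) are not
infusion-device insertions only — the insertion site is clinician-determined
and routinely undocumented, so those claims are unreviewable.  The filter
reports stage-by-stage counts in that order.

## The association model

Training counts claim-level co-occurrence: each distinct (procedure key,
diagnosis key) pair is counted once per claim, and marginals count claims
containing a key.  The default statistic is a Laplace-smoothed confidence

    s(p | d) = (c(p,d) + α) / (m(d) + α·|P|),

the probability that a procedure drawn from a claim containing diagnosis
`d` is `p`, with `m(d) = Σ_p c(p,d)` the pair mass of `d` and `|P|` the
number of distinct procedure keys at that resolution.  Using the pair mass
rather than the claim marginal keeps the smoothed scores a proper
distribution over the procedure universe for every diagnosis key even when
claims carry several procedures; the two denominators coincide for
single-procedure claims.  α = 1 by default: the floor must be positive so
unseen pairs rank below seen ones without degeneracy.  A lift mode
(`λ/(1+λ)` of the smoothed observed/expected ratio, 0.5 at independence) is
provided as an alternative; which disproportionality statistic is "the"
right one is genuinely open, so both are exposed and confidence is the
default as the simplest statistic consistent with a probability-scale
threshold.

Counts are kept at three key resolutions — full code, side-stripped
(body part + laterality class), bare body part.  A pair is scored **at the
finest resolution where the diagnosis key has training support**, falling
through to coarser levels only for codes unseen at the finer ones, and to
the smoothing floor when unseen everywhere.  This is deliberate: taking the
maximum across levels unconditionally would let the side-stripped level —
where a left-knee procedure and a right-knee diagnosis collapse onto the
same keys — assign a high score to exactly the opposite-side pairs the
model exists to catch.  Fall-through preserves the laterality signal while
still letting genuinely novel codes degrade gracefully instead of
defaulting to "unknown".

Claim aggregation: per-procedure score = **max** over the claim's
diagnoses; claim score = **min** over its procedures; the claim is flagged
when the claim score is strictly below the operating threshold (strict so
that floor-scored unseen pairs flag at any threshold above the floor).  The
max rule means a conflicting diagnosis cannot un-substantiate a procedure
that another diagnosis justifies; that asymmetry is an acknowledged
property of this class of model and is reproduced, not patched.

The operating threshold is read off the precision-recall curve of a
**labeled calibration set** (an explicit argument: the threshold must never
be tuned on the evaluation corpus).  Candidate thresholds are the distinct
observed claim scores plus 1.0; `MAX_F1` (default) breaks ties toward
higher precision and then lower threshold, `PRECISION_FLOOR` returns the
highest-recall point meeting a floor and raises — naming the best
attainable precision — when the floor is out of reach.

## The review engine

Review replaces a two-clinician consensus with a deterministic rule engine
over the same criteria.  For each procedure the diagnoses are searched in a
fixed priority order: same site + compatible side; same site +
UNSPECIFIED_SIDE; same site + NO_LATERALITY; a general diagnosis (gangrene,
bone metastasis, device complication — codes that justify surgery without
naming a body part); a proximate site with compatible side; and finally,
one level deep, a concurrent procedure at a same/proximate site and side
that is itself directly justified (combination).  The source criteria list
these categories without precedence; the specific-before-general order here
is this package's choice and is applied consistently.  A claim is an error
when any procedure remains unjustified, classified as same-body-part when
some diagnosis names the procedure's site on the opposite side, otherwise
different-body-part.  A nonerror claim is labeled with the *weakest*
justification used among its procedures — that is the rationale that made
it survive review.  "Same site" is computed through a site-alias table
(knee_joint → knee, glenoid_cavity → shoulder) so that joint-level
procedure parts match region-level diagnosis parts; "proximate" is a
symmetric, irreflexive relation over those sites (shoulder ↔ humerus).
Infusion-device insertions and procedures without a resolvable site/side
are not reviewable and never count as errors.  Precision with zero flagged
claims is reported as undefined, never 0 or 1.

Reports follow the standard contingency layout (per method × subgroup:
flagged, error/nonerror subcategory breakdown, precision, pooled
precision), with conservation (subcategories sum to categories, categories
to flagged) asserted on every report.  The cell-suppression guard masks any
displayed cell with count 1–10 at render time (11 is shown; 0 carries no
disclosure risk); internal totals stay exact and masking is flag-based.

## The synthetic generator

Restricted claims data cannot ship, so corpora are generated
condition-first: a latent condition (body part uniform over `n_body_parts`
= 24, side fair) emits a justifying diagnosis and the matching procedure,
making procedure-diagnosis association a real property of the corpus rather
than an artifact of the scorer — which is what allows the confidence
estimator to be validated by parameter recovery.  Documentation noise and
the nonerror taxonomy are generated by the same mechanism the review engine
tests for: unspecified-side (0.06) and no-laterality (0.10) variants,
general-diagnosis justification (0.12), proximate-part diagnoses (0.02,
over a chain proximity relation on adjacent parts), concurrent procedures
at a proximate part (0.10), comorbidities (Poisson, mean 2) of which a
fraction (0.05) are lateralized codes for random body parts — resolved
prior conditions such as "presence of left artificial hip joint".  Wrong
sites are planted at rate `p_wrong_site` = 0.02, of which 75% flip the side
at the same body part and 25% move to a distant part with the flipped side.
A small fraction of claims are infusion-insertion-only (0.01) or billed
under another specialty (0.02) to exercise the population filter.

Two defaults deserve justification:

* **General codes are linked to clusters of four adjacent body parts**
  (gangrene explains leg surgery, not shoulder surgery).  Under a pure
  confidence statistic, a body-system-free general code's association with
  any procedure equals that procedure's marginal frequency — numerically
  identical to a coincidental comorbidity — and "a general diagnosis
  substantiates the procedure" would be unlearnable in principle.  Real
  general diagnoses are system-linked in exactly this way.
* **`p_lateralized_comorbidity` = 0.05** was chosen analytically so that
  roughly half of the discordant-laterality claims are true errors, the
  regime reported for rule-based laterality matching in large claims
  reviews: with comorbidity count `K ~ Poisson(2)` and per-comorbidity
  lateralization rate `q`, the probability that a claim justified without a
  lateralized diagnosis acquires an all-opposite-side lateralized
  comorbidity is `e^{-2q}(e^{q} − 1)`, and at `q = 0.05` the implied
  false-positive mass roughly matches the planted-error mass inside the
  LR/RL subgroups.

What the generator does **not** emulate: real marginal code frequencies
(parts are uniform, real procedure volumes are heavy-tailed), real ICD-10
dictionaries (the grammar is synthetic by design), coding-system drift
across years, patients with multiple claims, bilateral procedure codes, and
free-text context.  Passing tests therefore demonstrate that the machinery
is correct and that the model separates planted errors from taxonomy-driven
nonerrors under controlled conditions — not that the same precision would
be observed on real claims.

## Numerical and degenerate-input choices

* Unknown codes resolve to a neutral record (no body part; diagnoses are
  treated as potentially justifying) with a logged warning — claims data
  always outrun any dictionary, and flagging on ignorance would swamp review.
* Ties in threshold selection: higher precision, then lower threshold.
* The flag-everything PR endpoint is represented by threshold 1.0 (all
  smoothed scores are strictly below 1); thresholds that flag nothing are
  omitted because their precision is undefined.
* Empty training corpora, zero positive labels, asymmetric/reflexive
  proximity pairs, conflicting duplicate prefixes, and missing truth
  annotations all raise typed errors rather than degrading silently.
* Claim tables round-trip losslessly through CSV (pipe-delimited list
  columns, hand-editable) and Parquet (native lists); validation is total —
  every row is either accepted or produces a located row error.

## Problem sizes

Parameter recovery uses a controlled corpus of 100,000 claims over 6 body
parts (proximity, lateralized comorbidities and second procedures off, so
the planted conditional probability is exactly `1 − p_wrong_site`), trained
at α = 0.1 to keep the smoothing bias an order of magnitude below the
3-standard-error band.  The rule-vs-model contrast trains on 100,000
default-condition claims and evaluates on 40,000-claim calibration and test
corpora.  Pipeline determinism and review-exactness checks run on smaller
corpora (≤ 6,000 claims) since the properties they assert are exact, not
statistical.

## Known limitations

* The review engine is a deterministic proxy for clinical judgment; it
  cannot reproduce chart-level adjudication, only the coded criteria.
* The combination rule is one level deep by design; chains of concurrent
  procedures are not followed.
* Confidence scores condition on single diagnosis keys; diagnosis
  *combinations* (beyond the claim-level max) are not modeled.
* The max rule's blind spot — a justified procedure accompanied by a
  conflicting diagnosis — is inherited deliberately.
* The packaged default code map covers common orthopedic families and is a
  starting vocabulary, not a standard; production use requires a fuller map.
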