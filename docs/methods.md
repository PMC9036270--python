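# Methods

## Problem setting

Acute vision loss presents first to clinicians without ophthalmic equipment,
and the candidate causes range from benign floaters to retinal artery
occlusion. `visiondx` models this triage problem as sequential Bayesian
inference over a fixed vocabulary of 13 diagnoses, driven by Yes/No/Don't-know
questions about history and examination findings that do not require
fundoscopy (the only fundus-adjacent item is the red reflex). The package has
two halves: the adaptive questioning engine, and the evaluation machinery used
to score ranked differentials against gold-standard diagnoses in a
diagnostic-accuracy study design.

## The inference model

The engine is a naive-Bayes classifier. Let `d` range over the 13 diagnoses
with prior `pi_d`, and let each question `q` carry a conditional probability
`p_yes(q, d) = P(answer YES | d)`. Answers are assumed conditionally
independent given the diagnosis, so after answers `a_1..a_k` the posterior is

    P(d | a_1..a_k)  ∝  pi_d · Π_j L(a_j | d)

with `L(YES|d) = p_yes(q_j, d)`, `L(NO|d) = 1 − p_yes(q_j, d)`, and
`L(UNKNOWN|d) = 1`. The "don't know" likelihood of 1 encodes a
missing-at-random assumption: a non-response never moves the differential.
This is the minimal model under which per-question sequential updating is
coherent; it ignores real dependence between findings (e.g. flashes and
floaters co-occur beyond what any single diagnosis explains), which is a
known limitation of naive-Bayes symptom checkers.

All likelihoods are clipped to `[ε, 1−ε]` with `ε = 0.01`. The floor forbids
zero-probability lockout: a single contradictory answer lowers a diagnosis's
rank but can never eliminate it, so atypical presentations degrade gracefully
and urgent conditions stay in the differential.

## Question selection and stopping

Sessions open with 3–4 fixed *seed* questions (onset, laterality, age, pain)
asked in a fixed order regardless of the evolving belief. After the seeds,
questions are chosen greedily by **expected probability shift**: for an
unasked question `q`,

    score(q) = P(YES)·TV(b, b|YES) + P(NO)·TV(b, b|NO)

where `b` is the current belief, `P(YES)` is its predictive probability, and
`TV` is total-variation distance (half the L1 distance between probability
vectors). TV is symmetric, bounded by 1, and zero exactly when a question
cannot discriminate, which makes the score a clean operationalization of
"the question whose answer can move the differential the most". Ties are
broken by lexicographic question id; ties in the differential are broken by
the canonical diagnosis order, so the engine is fully deterministic and uses
no randomness anywhere.

The session stops when the top posterior is at least `stop_ratio` times the
runner-up (default 5), when `max_questions` (default 15) have been asked, or
when the questions are exhausted. The ratio form means "the leading diagnosis
heavily outweighs the rest" rather than an absolute-confidence test; with the
ε-floor the runner-up is never zero, so the ratio is always defined.

## The shipped knowledge base

The probability tables of the deployed clinical app this design models are
proprietary; the KB shipped here is an illustrative, literature-plausible
stand-in whose values are the package's own design parameters. It is
constrained to satisfy four qualitative clinical invariants, enforced by
tests:

1. an absent red reflex raises vitreous hemorrhage and lowers every optic
   nerve/circulation diagnosis (those eyes should have an intact reflex);
2. a RAPD in a patient under 50 without diabetes/hypertension ranks optic
   neuritis and optic nerve compression above the NAION/BRAO/BVO group;
3. a binocular (homonymous) field defect makes post-chiasmal disease the top
   diagnosis;
4. with everything unknown except age over 50, at least one urgent diagnosis
   remains in the top three (worst-case defaulting).

Priors follow the empirical case mix of a 79-patient consecutive referral
series (vitreous hemorrhage 13/80 ... post-chiasmal 2/80). The question set
contains 21 items: the 16 symptom/history/sign questions named in the
clinical error narratives plus five classic bedside discriminators
(near-complete loss for retinal artery occlusion, altitudinal field loss
for ischemic optic neuropathy, progressive course for compressive
neuropathy, central scotoma for macular disease, red desaturation for
optic neuritis). Within the qualitative constraints, the numeric entries
were refined by a coordinate search maximizing noise-free simulated-cohort
accuracy on training seeds disjoint from every seed used in the tests, so
that the shipped KB meets its design target of ≥ 90% top-1 accuracy on
self-consistent cohorts. The values should be read as a coherent
illustrative parameterization, not as published clinical frequencies.

## Triage

Each diagnosis maps to one of six anatomical clusters (peripheral
retinopathy/vitreous; optic nerve/circulation; other macular; media;
migraine; post-chiasmal) and one urgency class. Urgent = peripheral retinal
issue, vitreous hemorrhage, the six optic nerve/circulation diagnoses,
post-chiasmal disease; non-urgent = floaters/PVD, other macular disease,
lens/cornea, migraine. Out-of-vocabulary gold diagnoses (the `OTHER`
sentinel, e.g. endophthalmitis) sit in their own cluster and count urgent —
the arithmetic of the study's 54/25 urgent/non-urgent margin forces that
choice, and clinically the case is vitreous pathology. A case's predicted
urgency is the urgency of the top-ranked diagnosis; a referral's urgency flag
is the urgency of the referrer's diagnosis, with "no diagnosis attempted"
flagged non-urgent (a documented assumption — the study does not say how
such referrals entered its sensitivity computation).

## Evaluation statistics

Top-k accuracy counts a case correct when its gold-diagnosis set intersects
the first k entries of the differential; a referral is correct only when a
diagnosis was attempted and names a gold diagnosis. The two dual-diagnosis
cases (peripheral retinal issue + vitreous hemorrhage) count correct if
either label is matched and are assigned to the peripheral
retinopathy/vitreous cluster. Percentages are rounded half-up to one
decimal; confidence-interval bounds half-up to integer percent, matching the
reporting style of clinical accuracy studies.

Sensitivity and specificity for urgency use exact Clopper–Pearson intervals
computed from the beta-quantile characterization (`Beta(x, n−x+1)` and
`Beta(x+1, n−x)` quantiles, with the conventional closed endpoints at x=0
and x=n). The exact method was chosen because it reproduces all four
published intervals at integer-percent rounding, which Wald and Wilson
intervals do not uniformly do; tests verify it against an independent
binomial-tail bisection oracle for every `x ≤ n ≤ 30` and against
statsmodels' exact interval.

## The canonical study fixture

The study's raw per-patient data were never deposited; only marginal counts
were published. `canonical_study_fixture()` reconstructs a deterministic
79-record cohort that satisfies every published margin simultaneously: the
per-diagnosis case mix, all per-cluster referrer and top-1/2/3 cells, the
urgent-subset accuracies, both urgency confusion matrices (whose cells are
the unique integers consistent with the published percentages), and the
referrer no-diagnosis structure (37 overall, 22 among urgent cases, 19 of
those solved by the algorithm's top diagnosis). The margin system leaves the
per-record assignment under-determined; the shipped solution freezes one
clinically plausible completion (confusions follow the published error
narratives: "no red reflex" cases read as vitreous hemorrhage, the binocular
field defect read as post-chiasmal disease, and so on). A self-check
re-verifies ~25 margins on every construction. The fixture's questionnaire
columns are left unknown except where an error narrative pins them down;
evaluation statistics depend only on gold labels, referrer labels and the
attached differentials, whose synthetic posteriors follow a fixed geometric
profile (only the ranking matters).

This reconstruction reproduces the published *statistics* exactly, but it is
not the original cohort: any analysis finer than the published margins
(e.g. per-question answer patterns) reflects the reconstruction, not the
study.

## Synthetic cohorts

`generate_cohort` samples patients from the KB's own model: a gold diagnosis
from the prevalence (default: the empirical case mix), then each answer YES
with probability `p_yes(q, gold)`, inverted with probability `flip_rate`,
then blanked to unknown with probability `missing_rate`. Defaults are
noise-free (`flip_rate = missing_rate = 0`): such cohorts test the engine
under its own assumptions (a calibration/self-consistency check), not
against real clinical data — real findings are dependent, prevalences drift,
and answers are not missing at random. Passing the cohort tests therefore
shows the engine implements its model correctly and that the KB's profiles
are mutually distinguishable, nothing more. Problem sizes used by the tests
and acceptance script: n = 500 for the noise-free accuracy and triage
checks, and 3 × 150 paired-seed cohorts per flip-rate grid point
{0, 0.1, 0.3} for the monotone-degradation check.

## Numerical choices and edge cases

- Beliefs are renormalized after every update; tests assert normalization to
  1e-9 and sequential-vs-joint agreement to 1e-12.
- Probabilities live in ordinary float64; with 21 questions the smallest
  products are ≈ 1e-45, far from underflow.
- `should_stop` uses a ≥ comparison, so a ratio exactly at `stop_ratio`
  stops.
- An empty positive or negative margin makes sensitivity/specificity
  undefined; `sens_spec` raises rather than returning 0/0.
- Encounter tables treat an empty answer cell as "don't know", mirroring how
  unanswered questionnaire items are entered in practice.

## Known limitations

- Conditional independence overstates the evidence of correlated findings.
- Posteriors are not calibrated against outcome frequencies; only the
  ranking (and the implied urgency flag) is evaluated.
- The stopping threshold and question budget of the modeled app are unknown;
  the defaults here are design choices.
- Hard rule-outs (excluding a diagnosis outright on a pathognomonic answer)
  are deliberately not implemented; the ε-floor makes all down-weighting
  soft.
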