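# visiondx

Dynamic Bayesian differential diagnosis for acute vision loss, with the
evaluation machinery of a diagnostic-accuracy study.

Acute vision loss is hard to triage at first contact: emergency and primary
care physicians must separate retinal detachment, vascular occlusion and
other urgent pathology from floaters, migraine and media opacities, usually
without ophthalmic equipment. `visiondx` implements an adaptive
questionnaire engine for this problem and the statistics needed to evaluate
one against an ophthalmologist's gold-standard diagnoses.

## The model

The engine is a naive-Bayes classifier over a fixed vocabulary of 13
diagnoses. Each Yes/No/Don't-know question `q` carries a likelihood
`p_yes(q, d) = P(YES | d)`; after answers `a_1..a_k` the belief is

    P(d | a_1..a_k) ∝ π_d · Π_j L(a_j | d),   L(UNKNOWN | d) = 1

so a "don't know" never moves the differential. Sessions open with 3–4
fixed seed questions, then proceed greedily: the next question maximizes
the expected total-variation shift between pre-test and post-test
probabilities, `E_a[TV(b, b|a)]`, weighted by the predictive probability of
each answer. The session stops when the top posterior outweighs the
runner-up by a factor `stop_ratio` (default 5) or the question budget is
exhausted, and returns a full ranked differential with per-question
supporting/refuting evidence. Likelihoods are floored at ε = 0.01 so no
single answer can eliminate a diagnosis.

On top of the engine sit triage maps (6 anatomical clusters; urgent vs
non-urgent), top-k and per-cluster accuracy, urgency confusion matrices,
and exact Clopper–Pearson confidence intervals. A canonical 79-patient
study cohort — reconstructed to satisfy every published marginal count of
the study this design models — and a synthetic-cohort generator are
included as first-class, tested modules. See `docs/methods.md` for the full
account.

## Worked example

```python
import visiondx as v

kb = v.builtin_kb()

# an older vasculopath with sudden monocular loss and an absent red reflex
answers = {
    "sudden_onset": "yes", "monocular": "yes", "age_over_50": "yes",
    "eye_pain": "no", "red_reflex_absent": "yes", "floaters": "yes",
}
session = v.run_session(kb, {q: v.AnswerValue(a) for q, a in answers.items()})
for dx, p in session.final_differential.ranked[:3]:
    print(f"{dx:24s} {p:.3f}")
print(session.terminated_by.value)
```

prints

```
vitreous_hemorrhage      0.934
peripheral_retinal       0.049
floaters_pvd             0.009
STOP_RULE
```

— the absent red reflex makes vitreous hemorrhage dominant (posterior
0.934, more than 5× the runner-up, so the stop rule fires), while the
optic-nerve causes, which should have an intact reflex, drop out of the top
ranks. Evaluating the canonical study cohort:

```python
fx = v.canonical_study_fixture(kb)
report = v.build_report(list(fx.records), list(fx.differentials), kb)
print(v.render_report(report))
```

reproduces the study's accuracy table — referrer 24/79 (30.4%) against
algorithm top-1/2/3 of 56/79 (70.9%), 68/79 (86.1%), 70/79 (88.6%) — and
the urgency triage statistics, e.g. algorithm sensitivity 94.4% (51/54,
95% CI 85–99%) versus referrer sensitivity 57.4% (31/54, 95% CI 43–71%).

The same operations are available from a CLI: `visiondx ask` (interactive
session), `visiondx evaluate`, `visiondx validate-kb`, `visiondx fixture`,
`visiondx simulate`.

## Caveat

The shipped knowledge base is an illustrative, literature-plausible
parameterization (the deployed clinical app's tables are proprietary), and
the canonical cohort is a reconstruction from published margins, not the
original patient data. Neither should be used for clinical decisions.
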