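# motimsg

Situation-based motivational messages for PTSD e-therapy — the message
composition engine, the expert-corpus statistics that build its tables,
and the evaluation-study machinery, all runnable end to end on synthetic
data with known ground truth.

## Who this is for

Researchers and engineers building behavior-change support systems in
e-mental health who want (a) a transparent, database-driven algorithm for
composing short motivational messages conditioned on a patient's
situation, and (b) the statistical tooling to derive such a database from
expert input and to evaluate its effect in a mixed-design study.

## The model in brief

A patient's **situation** is a pair: the trend of their brief
PTSD-Checklist (PCL) score across sessions (*dropping / stable / rising*)
and their initial trust in a good therapy outcome (*low / medium /
high*) — nine cells in all.  A statement database stores short
motivational statements in a two-level type hierarchy together with a
probability table `p(type | situation)`, a per-situation target message
length, and presentation ranks.

To compose a message the generator includes every type with `p > .5`
(super-types resolve to their best subtype, by threshold or by a weighted
random draw over subtype probabilities), fills the remaining slots by
weighted randomized selection — cumulative probability intervals, one
uniform draw — without repeating a type family, picks one stored sentence
per selected type, and orders the result (situation first, general
motivation near the end, the future last).

Around the generator:

- `motimsg.corpus` derives the tables from a coded expert-answer corpus:
  rare-type filtering, per-type random-intercept logistic regression
  (expert intercepts, saturated trend x trust cell means, Gauss–Hermite
  quadrature ML), half-up length rounding, statement retention at
  `p > .05`, Cohen's kappa, and likelihood-ratio tests.
- `motimsg.study` covers the evaluation statistics: noncentral-F a priori
  sample size, one-sample t, Cronbach's alpha, the M0..M7 mixed-model
  comparison ladder (ML, random participant intercept), and pairwise
  post hocs.
- `motimsg.simulate` generates all inputs with known truth: the bundled
  synthetic statement database, expert corpora from a true probability
  table, and user-study records from a chosen effect structure.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Generate three messages for a patient whose symptoms are worsening and
whose trust is low:

```sh
$ motimsg generate --trend rising --trust low --seed 11 --n 3
Your questionnaire shows your symptoms have been getting worse. That sounds really difficult. This phase of the treatment is demanding for almost everyone. Hold on!
Your questionnaire shows your symptoms have been getting worse. It is often hard work before results become visible. Many people feel exactly this way at this point in the treatment. Hold on!
The graph shows a rise in your symptom scores lately. Complaints can get worse for a while before they start to improve. Let's look together at what you need to keep going. It is important to stay with the program now.
```

Each message has the four statements the length table demands at
(rising, low), always contains a note of the rising trend (its subtype
probability exceeds the .5 inclusion threshold), a give-perspective
statement, and exactly one motivation subtype, and is ordered situation
-> empathy/perspective/together -> motivation.  The same seed reproduces
the same messages; `--json` adds the full selection trace.

The same in Python:

```python
import motimsg

db = motimsg.load_database(motimsg.default_database_path())
situation = motimsg.Situation.parse("rising:low")
message = motimsg.compose_message(situation, db, rng=11)
print(message.text)
print(message.trace.supertype_resolutions)
# {'note_pcl': ['note_pcl_rising'], 'motivation': ['motivation_hold_on']}
```

And the a priori sample size for a three-arm evaluation with a medium
effect (Cohen f = 0.25), alpha .05 and power .90:

```python
>>> motimsg.anova_power_n(3, 0.25, 0.05, 0.90)
207
```

i.e. 69 participants per message-type condition; the achieved power at
N = 207 is .9022.

Other entry points: `motimsg db validate <json>`, `motimsg fit-table`,
`motimsg simulate-corpus`, `motimsg simulate-study`,
`motimsg analyze-study`.

## Caveat

The bundled statement database is a clearly marked synthetic stand-in
that satisfies the documented structural constraints; it is not a
clinically validated statement set.  Drop in a real database (same JSON
schema) for production use.
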