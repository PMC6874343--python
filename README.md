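# sdtlatent

Latent-variable signal detection theory for m-alternative forced-choice
(m-AFC) data: joint estimation of item difficulty and person ability in d′
units.

## The problem

Psychophysics estimates ability against stimuli whose positions on the
measurement axis are physically known. Clinical and perceptual testing often
has no such axis — face recognition items, object identification items —
so item locations must themselves be estimated from responses, the way item
response theory (IRT) does for questionnaires. But standard IRT curves do
not model the forced-choice task: chance performance, and its dependence on
the number of alternatives m, enters only through ad-hoc guessing
parameters.

`sdtlatent` instead keeps the signal-detection model of the m-AFC trial.
Each alternative elicits an internal response (correct: N(d′, 1); each of
the m−1 incorrect: N(0, 1)); the largest wins. Probability correct at
separation d′ is

    L_m(d′) = ∫ φ(x − d′) [Φ(x)]^(m−1) dx ,    d′ = θ_i − b_h ,

with θ_i the ability of person i and b_h the difficulty of item h, both in
d′ units. Chance (1/m) sits at θ − b = 0 for every m; negative b means an
easier item. Estimation is two-stage — items calibrated against an
"average person" anchored at θ = 0 by inverting observed proportions
(with Wilson CIs mapped through the same inverse), then independent person
MLEs with observed-information SEs — optionally refined by an alternating
local-MLE ("EM") pass. A dichotomous Rasch comparator is included: the
Rasch model is the special case of the integral above with a point-mass
correct-choice density and a logistic CDF, so its logits relate linearly
to SDT measures within any fixed m. See `docs/methods.md` for details.

For: psychophysicists and clinical-outcomes researchers with scored
forced-choice trials in long format (person, item, m, score).

## Worked example

```python
import sdtlatent as sl

truth = sl.make_truth(seed=7, n_subjects=30, n_items=48,
                      design="complete", paired=False)
responses = sl.simulate_responses(truth)   # long-format DataFrame
res = sl.MAFCModel(responses).fit(method="em")
print(res.summary())
```

```
m-AFC latent-variable SDT fit
==============================================
method:          em
persons:         30  (0 degenerate)
items:           48  (1 degenerate)
responses:       1440
log-likelihood:  -704.7280
iterations:      5  (converged: True)
----------------------------------------------
item b:     mean -0.7257   sd 1.0103
person th:  mean -0.0000   sd 0.7776
mean person SE:  0.2818
==============================================
```

Person measures are anchored so the average person sits at θ = 0; the fit
converged in 5 alternating cycles. `res.items` and `res.persons` hold the
measure tables:

```
item_id  m  n_correct  n_total         b    ci_low   ci_high
    i00  2         30       30 -3.028111 -3.418945 -1.708445
    i01  3         19       30 -1.043341 -1.611747 -0.455261
    i02  2         24       30 -1.362144 -2.024923 -0.629789
```

Item `i01` was answered correctly 19/30 times on a 3-AFC task (chance 1/3),
placing it 1.04 d′ below the average person — moderately easy — with a 95%
CI of [−1.61, −0.46]. Item `i00` had a perfect score: its measure comes
from the adjusted proportion 30.5/31 and is flagged degenerate. Against
the generating truth this fit recovers item difficulty with r = 0.922.

The same operations are available from the shell:

```sh
sdtlatent simulate --out r.csv --seed 7 --n-subjects 30 --n-items 48
sdtlatent em --responses r.csv --out-items items.csv --out-persons persons.csv
sdtlatent compare-rasch --responses r.csv --out lines.csv
```

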