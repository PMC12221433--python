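# ordimirror

Statistical-mirroring-based ordinalysis: a model-free, scale-invariant
descriptive statistic for ordinal assessment data, with the simulation and
evaluation apparatus used to validate it against classical score summaries.

## The problem

Likert-type and rating-scale responses are ordered but not interval-scaled,
yet the workhorse summaries of an individual's composite answers — the sum,
mean and median of the raw codes — treat them as if they were.  Those
summaries are also blind to the *pattern* of responses (every 10-item set
summing to 30 gets mean 3.00) and tied to the particular scale in use (a
mean of 4 means different things on 5-point and 7-point scales).

`ordimirror` instead measures how statistically close an individual's whole
response set sits to the *highest positive scale point*.  The sorted
whole-encoded scores `x_(1) ≤ … ≤ x_(n)` are paired isoreflectively with a
mirror of n copies of the top scale value p about a center δ = 0, the
construct `d = (x_(1),…,x_(n), 0, p,…,p)` is weighted by its position index
`R = (1,…,2n+1)`, and the **Kabirian coefficient of positive ordinal
assessment** is

    KC1 = (n+1) Σ dᵢ / Σ Rᵢ dᵢ   ∈ [2/3, 1]

translated to a bounded probability of positive assessment

    PSprox = ((2n+1)·KC1 − (n+1)) / ((n+1) − KC1),   PSdev = 1 − PSprox.

KC1 = 1 iff every answer is the top category; 2/3 iff every answer is the
bottom one.  The statistics are permutation-invariant, strictly increasing
in every response, and invariant to rescaling the whole instrument —
properties the classical summaries lack.  See `docs/methods.md` for the
full model, the SAMD efficiency criterion, and the synthetic-data
generators (categorical, rounded-normal, Gaussian-copula ordinal).

## Worked example

Ten answers to 5-point items (natural 1–5 coding), eight of them "3" with
one "2" and one "4":

```python
>>> from ordimirror import sm_ordinalysis
>>> sm_ordinalysis([2, 3, 3, 3, 3, 3, 3, 3, 3, 4], 5, 5,
...                "natural_numbers", "all_in_dict")
{'kc_sprox': 0.8472400513478819,
 'kc2_sprox': 1.1803030303030302,
 'p_sprox': 0.6689847009735743,
 'p_sdev': 0.3310152990264257,
 'n': 10, 'p': 4.0,
 'kcalt1': 0.8472400513478819,
 'kcalt2': 0.6863793440698964,
 'kcalt': 1.1803030303030302,
 'meta': {'alternative_coefficients': 'provisional semantics'}}
```

The coefficient 0.847240 says the response set sits well above the
midpoint of the proximity range [2/3, 1]; on the probability scale the
individual's assessment is positive with probability 0.6690 and negative
with probability 0.3310.  Classically this set is indistinguishable from
any other 10-item set summing to 30 (mean 3.00); the mirroring statistics
separate all of them.  Single outputs are available with the documented
selectors (`"kc"`, `"pprox"`, `"pdev"`, or the long `"print:…"` forms).

From the shell, the same analysis over a CSV of respondents:

```bash
ordimirror analyze --input responses.csv --point-scale 5 --max-scale 5
ordimirror reproduce --table well-structured     # regression-lock the worked tables
ordimirror simulate --family copula --marginals m2 --correlation c3 \
    --n-items 10 --iterations 100 --seed 7
ordimirror evaluate --config grid.yaml --out-dir results/
```

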