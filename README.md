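# schemabg

A rate-coded cortico-basal-ganglia model of rule-based action selection,
simulating the unambiguous ("Madrid") Wisconsin Card Sorting Test in
healthy controls and in virtual Parkinson's-disease patients.

## The model

Behaviour is organised as a two-level hierarchy of *schemas*: three
cognitive schemas (the sorting rules — colour, shape, number) and four
sensorimotor schemas (placing the stimulus card under one of the four
target cards). Each schema node is a leaky rate unit,

    u_i(t)  = external + routed input + o_thal,i(t-1)
    a_i(t)  = δ a_i(t-1) + (1-δ) u_i(t)
    o_i(t)  = σ_{β,α}(a_i(t)),          σ_{β,α}(x) = 1 / (1 + e^{-α(x-β)})

and owns a basal-ganglia channel of six nuclei units — striatum D1 and D2,
STN, GPe, GPi, thalamus — wired as the direct (D1 → GPi), indirect
(D2 → GPe → STN/GPi) and hyperdirect (cortex → STN → GPi) pathways. The STN
projection onto the pallidum sums over all channels of a loop, so one
channel's activity raises everyone's inhibition: disinhibition of the most
active channel and suppression of its rivals emerge as a winner-take-all
competition. The thalamic unit outputs the negated logistic of GPi drive,
`o_thal ∈ (-1, 0)`: a quiet GPi releases the cortical node, an active GPi
suppresses it.

A schema is *selected* when its output exceeds a static threshold θ_s and
its output area accumulated since stimulus onset reaches an integration
threshold θ_A drawn per trial — response time is the number of cycles to
that bound. Two learning rules close the loop with feedback r ∈ {+1, -1}:

* striatal threshold adaptation (cognitive channels): each rule schema's
  striatal threshold moves by a reward-prediction error
  `δ_i = r (f_i - median a_i)`, where the feature-match value `f_i` is +1
  when the rule is consistent with the response and
  `(2 w_neg - 1) - m_r f_prev r_prev` otherwise;
* conflict-driven gain (sensorimotor layer):
  `α_sma ← (1+ζ) Π_i (1 + ε_sma + o_i)` after every feedback event.

Reducing the striatal learning rate ε_str (striatal dopamine sensitivity)
makes the model perseverate; blunting negative-reward sensitivity (w_neg)
destabilises the sensorimotor level. Model-internal proxies of two ERP
components are computed from the output dynamics: the error-related
negativity, `ERN_t = -absmax(o_sma(t) - o_sma(t-1))` response-locked and
contrasted correct vs incorrect, and the posterior switch positivity,
`SPP_t = absmax(o_pfc(t) - o_pfc(t-1))` contrasted shift vs post-shift
trials.

## Worked example

```python
from schemabg import ParameterSet, run_session

result = run_session(ParameterSet(), n_trials=64, seed=7)
print(f"correct {result.cards_correct}  categories {result.categories}  "
      f"PE {result.pe}  SL {result.sl}  IE {result.ie}  "
      f"RT+ {result.rt_post_positive_mean:.1f}  RT- {result.rt_post_negative_mean:.1f}")
```

```
correct 46  categories 4  PE 10  SL 0  IE 2  RT+ 131.2  RT- 134.8
```

Forty-six of 64 cards sorted correctly, four completed 10-correct
categories, ten perseverative errors (PE — this seed caught two slow rule
switches), no set-loss (SL) and two integration (IE) errors, and
responses on trials following negative feedback are slower than after
positive feedback — the post-error cost of re-establishing the task set.
The same run from the shell:

```bash
schemabg session --trials 64 --seed 7 --out session_log.csv
schemabg run --study 1 --runs 100 --seed 0 --out reports/
schemabg run --study 4 --subintervals 2 --runs 5 --seed 0 --out reports/
```

A virtual patient group:

```python
from schemabg import PD_GROUPS
pd1 = ParameterSet().override(**PD_GROUPS["PD_1"])   # eps_str 0.4 -> 0.1
run_session(pd1, seed=7).pe                          # -> markedly more PE
```

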