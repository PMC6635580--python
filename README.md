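# attnrl

Attention-controlled multi-attribute reinforcement-learning choice
modeling: a generative model of how a forager chooses among several
options that differ on several attributes at once, plus the sequence
statistics and likelihood machinery needed to analyze such choices.

## Who this is for

Behavioral and computational neuroscientists studying sequential choice
among multi-attribute options — e.g. a monkey repeatedly choosing among
four food items that differ in caloric value and in how far away they
sit. The package answers two linked questions: *which attribute guides
choice in a given context* (attention), and *why choices repeat in
bursts* (memory), and provides the tools to fit and test the model on
trial-by-trial choice logs.

## The model

Options live in attribute space with normalized values
`x_{k,i} ∈ (0, 1]` (each attribute divided by its maximum over the
choice set). The **preference vector** has component
`max_i x_{k,i} − min_i x_{k,i}` on attribute *k*; its direction encodes
which attribute most differentiates the options. A threshold gate on
the angles `θ_k` between this vector and the attribute axes sets the
attention weights `w_k`: **selective** (winner-take-all on the most
distinctive attribute, when `min_k θ_k < Θ_threshold`) or **divided**
(weights equal to the unit vector components).

Learning is Q-learning with one value per (attribute, option). After
each choice:

    Q_{k,c} ← Q_{k,c} + α_c (r_{k,c} − Q_{k,c})        (chosen)
    Q_{k,u} ← Q_{k,u} + α_u (0 − Q_{k,u})              (each unchosen)
    α_u = α_c · Q_{k,u}^(μ−1)                          (memory-dependent decay)
    r_{k,i} = N · x_{k,i}^γ                            (subjective reward)

and choice follows a softmax over `Q_i = Σ_k w_k Q_{k,i}` with inverse
temperature β. With μ > 1, strongly remembered unchosen options decay
fast while weak ones barely move (a soft bound) — the mechanism behind
bursty, perseverative runs of identical choices.

Sequence structure is quantified by the **B-index**
`1 − S_emp / ln(n_options)` (0 = uniform exploration, 1 = pure
exploitation) and the **P-index**
`A_emp−rand / A_sorted−rand`, where `A = ∫ |ln P₁(u) − ln P₂(u)| du`
compares complementary cumulative run-length distributions on
`u = ln(run length)` (probabilities floored at 1e−12), against 1,000
shuffled surrogates (0 = history-independent, 1 = fully perseverative).

Model fitting minimizes the negative log-likelihood of the observed
sequence (L-BFGS-B, Latin-hypercube multi-start) over the four free
parameters (α_c, μ, β, γ) and compares the full model (`Q_c+u`) with a
chosen-only variant (`Q_c`) via AIC/BIC and the likelihood pseudo-r².

## Worked example

```python
from attnrl import generate_subject, p_index, fit

# a synthetic subject in the four-foods condition (10 sessions x 150 trials)
subj = generate_subject(1, seed=42)
print(subj.trial_log["chosen_option"].value_counts().to_dict())
# {'PN': 957, 'FG': 376, 'PL': 116, 'KR': 51}

bp = p_index(subj.sequence, n_shuffles=1000, seed=42, n_options=4)
print(round(bp.b_index, 3), round(bp.p_index, 3))
# 0.317 0.676

res = fit(subj.sequence, subj.spec, "Q_c+u", n_restarts=10, seed=0)
print({k: round(getattr(res.params, k), 3) for k in ("alpha_c", "mu", "beta", "gamma")})
# {'alpha_c': 0.892, 'mu': 2.923, 'beta': 20.17, 'gamma': 0.093}
```

The choice counts show the calorie-driven preference bias (peanut
halves dominate); the B/P indices say the subject is moderately biased
and strongly perseverative; and the fit recovers the generating
parameters (truth: α_c 0.79, μ 2.82, β 20.50, γ 0.09) within sampling
error from 1,500 trials.

The same pipeline is scriptable from the shell:

```bash
attnrl simulate --condition 1 --seed 42 --out-dir run/
attnrl metrics run/trial_log.csv --out run/metrics.json
attnrl fit run/trial_log.csv --sidecar run/sidecar.json --out run/fit.json
attnrl reproduce --quick --seed 1 --out run/report.json
```

`reproduce` runs the full three-condition battery and reports whether
the signature cross-condition pattern emerges (bias lowest in the
color condition; persistence lowest with identical items; BIC favoring
the chosen+unchosen model).

A scikit-learn-style front end is available as
`attnrl.AttentionRLModel` (constructor parameters = model parameters,
`fit`/`predict_proba`/`sample`/`score`, fitted attributes with trailing
underscores).

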