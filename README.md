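# ctxlearn

Model-based analysis pipeline for an instrumental avoidance-learning fMRI
task with contextual cues — built entirely around synthetic data with
known ground truth, so every stage of the analysis can be validated by
parameter and model recovery.

## The problem

In a contextual avoidance task, participants repeatedly choose between two
shapes (square, rhombus) shown against one of two background pictures
(contexts A and B).  The chosen shape delivers a painful stimulus with a
probability that depends on both the shape and the context (80% vs 20%,
with the shape roles reversed between contexts).  Learning is modeled with
a Q-learning agent,

    RPE_t = κ·R_t − Q_t(s_t, a_t),      Q_{t+1}(s_t, a_t) = Q_t(s_t, a_t) + α·RPE_t,

where R_t ∈ {0, 1} flags a painful outcome, α is the learning rate and
κ ≤ 0 the subjective painfulness; choices follow a softmax over the action
values of the left and right shapes, P_t(a=L|s) = e^{Q_L}/(e^{Q_L}+e^{Q_R}).
Fitting maximizes Σ_t ln P_t(a_t|s_t) over an exhaustive grid
α ∈ {0.01,…,1.00}, κ ∈ {−10.0,…,0.0}.  The fitted aversive prediction
error (RPE) and state value V_t(s) = Σ_a P_t(a|s)Q_t(s,a) then enter an
ROI-level event-related GLM as parametric modulators, and a simplified
two-process effective-connectivity analysis selects which task inputs
drive a four-node habenula–hippocampus network and how the regions are
coupled.

The package is for computational-neuroscience practitioners who want a
tested, reproducible reference implementation of this analysis chain —
simulation, fitting, behavioral statistics, GLM, model selection — with
every estimator exercised against data whose generating parameters are
known.  See `docs/methods.md` for the full model account.

## Worked example

```python
import ctxlearn as cl

# one participant: 60 trials, two contexts, Q-learning agent
session = cl.simulate_session(cl.TaskConfig(), cl.AgentParams(alpha=0.3, kappa=-3.0), seed=1)
fit = cl.fit_grid(session)
print(f"alpha_hat={fit.alpha_hat:.2f} kappa_hat={fit.kappa_hat:.1f} "
      f"loglik={fit.loglik_max:.2f} ties={fit.n_ties}")

# a longer session pins the parameters down
long_cfg = cl.TaskConfig(n_trials=600, context_balance={"A": 300, "B": 300})
fit600 = cl.fit_grid(cl.simulate_session(long_cfg, cl.AgentParams(0.3, -3.0), seed=1))
print(f"T=600: alpha_hat={fit600.alpha_hat:.2f} kappa_hat={fit600.kappa_hat:.1f}")
```

prints

```
alpha_hat=0.11 kappa_hat=-10.0 loglik=-28.61 ties=1
T=600: alpha_hat=0.36 kappa_hat=-2.5
```

At the study's own 60 trials the likelihood surface is shallow and the
estimate lands far from the generating (0.30, −3.0) — the identifiability
the package's recovery analyses quantify — while 600 trials recover both
parameters to within a grid step or two.

The full pipeline (cohort simulation → grid fits → behavioral statistics
→ ROI GLM with RPE/state-value modulators → connectivity model recovery)
runs end to end from the command line:

```sh
ctxlearn --seed 0 --outdir run all
```

writing trial/latent/trait tables, fit results, a behavioral report, GLM
contrasts with group statistics and trait correlations, and a
connectivity recovery table, plus a manifest that makes the run
byte-for-byte reproducible.  Individual stages are available as
`simulate`, `fit`, `stats`, `glm`, `dcm` and `validate` subcommands.

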