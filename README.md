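# revpet

Reversal-learning behavior modelling and dynamic [¹¹C]Raclopride PET
kinetics, built as a fully simulatable pipeline.

## The problem

Probabilistic reversal-learning tasks probe how flexibly humans update
action–outcome associations: one of two actions is rewarded 80% of the
time through a long stable phase, then the contingencies silently
reverse and keep reversing. Striatal dopamine release at the first
reversal can be measured with dynamic [¹¹C]Raclopride PET, because
endogenous dopamine competes with the tracer for D2/D3 receptors and
transiently lowers the non-displaceable binding potential (BP_ND).
`revpet` implements the three analysis layers needed to study the link
between reversal behavior and dopamine release — and a synthetic-data
layer so the entire pipeline runs, and is tested, without any scan:

1. **Behavior** (`revpet.behavior`): a two-parameter reinforcement-
   learning model. Action values follow the delta rule
   `Q ← Q + α (r − Q)` with reward prediction error `δ = r − Q`, and
   choices follow a softmax with inverse temperature β,
   `p(a) = 1 / (1 + exp(−β ΔQ))`. Per-session (α, β) are estimated by
   multi-start bounded maximum likelihood; trial-wise |δ| (absRPE)
   summarises the unexpectedness of outcomes around a reversal, and
   perseverance errors count post-reversal choices of the previously
   best action.
2. **Kinetics** (`revpet.kinetics`): the multilinear reference-tissue
   baseline model `C_T = R1·C_R + k2∫C_R − k2a∫C_T` with fixed
   reference clearance k2′, extended per lp-ntPET with a reversal-
   locked time-varying efflux term `− γ∫B(s)C_T(s)ds`, where B is the
   best of five unit-peak gamma-variate basis functions starting at
   the reversal. Dynamic binding potential
   `BP_ND(t) = k2/(k2a + γB(t)) − 1` yields receptor occupancy
   `Occ(t) = (BP_pre − BP_ND(t))/BP_pre × 100`, and an extra-sum-of-
   squares F statistic against baseline (masked at F > 9.55) flags
   credible displacement, voxelwise or on ROI TACs.
3. **Group inference** (`revpet.stats`): Pearson correlations between
   peak occupancy and behavioral parameters, linear/quadratic OLS,
   one-sample sign-flip permutation tests with max-statistic
   correction, and paired t tests with a default JZS Bayes factor
   computed by quadrature.

The synthetic layer (`revpet.task`, `revpet.agents`, `revpet.tacsim`)
generates the 250-trial schedule (reversals at trials 151, 176, 201,
226; every 25-trial block spans exactly 5 min), softmax Q-learning
agents with known (α, β), and reference/target TACs on the standard
53-frame, 68-min acquisition, integrated from the compartment
equations with known ground truth and frame-duration-scaled noise.

## Worked example

```python
import revpet as rp

schedule = rp.generate_schedule(rp.TaskConfig(seed=0))
agent = rp.AgentSpec(alpha=0.4, beta=5.0, seed=11)
session = rp.simulate_agent(schedule, agent)
params, trace = rp.fit_rl(session, seed=0)
summary = rp.summarize_behavior(session, trace, reversal_trial=151)

gamma = rp.gamma_for_peak_occupancy(12.0, k2_per_min=0.35, bp_nd=2.5)
release = rp.ReleaseSpec(onset_s=2280.0, peak_s=2400.0, magnitude=gamma)
ref_tac, target_tac, truth = rp.simulate_tac(
    rp.TacSimSpec(release=release, noise_scale=0.05, seed=1)
)
ref0, whole, _ = rp.simulate_tac(rp.TacSimSpec(seed=2))        # release-free region
k2p = rp.mrtm_baseline_fit(whole, ref0).k2_prime_per_min       # fix k2' once
basis = rp.build_reversal_basis(2280.0, scan_end_s=4080.0)
fit = rp.lp_ntpet_fit(target_tac, ref_tac, basis, k2p)
occ = rp.occupancy_curve(fit, pre_window=(480, 2280), post_window=(2280, 2880))
```

prints, via the obvious format strings:

```
fitted alpha=0.392 beta=5.29 (truth 0.40, 5.00)
perseverance errors: 3
mean absRPE (25 trials post-reversal): 0.375
BP_ND=2.512 gamma=0.0111/min F=128.1
peak occupancy 14.09% at t=2400 s (truth 12.00% at 2400 s)
```

The fitted learning rate lands on the generating value, the agent kept
its old response for 3 trials after the reversal, and the kinetic fit
recovers the simulated dopamine release: the F statistic far exceeds
the 9.55 mask, the winning basis peaks 2 min after the reversal, and
the estimated peak occupancy sits near the simulated 12% (the 2-point
excess at this seed is within the noise-level spread of the
estimator). The same flow is available from the shell:

```bash
revpet run-all --out-dir out/demo --seed 1
```

which simulates a 26-subject cohort (population α, β matched to human
group statistics, with release magnitude coupled positively to α),
fits every stage, and reports group statistics — including a positive
occupancy–α correlation and a negative occupancy–absRPE correlation.

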