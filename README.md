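# ipdpool

Pooled survival analysis of randomized trials from published Kaplan-Meier
figures: reconstruct individual patient-level data (IPD) from digitized
curves and at-risk tables, derive an unreported biomarker subgroup by
matching-based subtraction, validate both steps, and fit one-stage pooled
Cox models with a gamma shared-frailty term and treatment-by-biomarker
interaction tests.

## The problem

Trials of PD-1 blockade plus chemotherapy in advanced gastric cancer
publish KM curves for the all-randomized population and for the
PD-L1-high subgroup (CPS ≥ 5), but usually not for the PD-L1-low
complement (CPS < 5) — exactly the patients for whom the added benefit is
in doubt. `ipdpool` closes that gap at the desk:

1. **Reconstruction** — invert the product-limit equations using digitized
   curve coordinates, the number-at-risk table and (optionally) total
   event counts to recover per-interval event and censoring counts, one
   (time, event) record per patient.
2. **Subtraction** — match each published-subgroup patient to its closest
   all-comers counterpart (minimal-cost bipartite assignment on follow-up
   time, with a prohibitive penalty for event-status mismatch, within
   each arm); the unmatched remainder is the derived complement cohort.
3. **Validation** — Bland-Altman and ECDF/KS agreement of matched pairs,
   matched-cohort overlap (Cox HR ≈ 1, log-rank p ≈ 1), concordance with
   published HRs/medians, and Monte Carlo limits of error on simulated
   trials with known ground truth.
4. **Pooling** — Cox proportional hazards with study-level gamma frailty
   w_s ~ Γ(1/θ, 1/θ): λ_i(t) = w_s λ₀(t) exp(x_i'β), fitted by EM with θ
   profiled; subgroup HRs with 95% CIs and the Wald test of the
   treatment×subgroup product term (P_interaction).

See `docs/methods.md` for the model details, assumptions and numerical
choices.

## Worked example

Run the full pipeline on a bundled synthetic preset that mirrors the
enrolment of a large gastric-cancer RCT (789/792 patients per arm, 60%
biomarker-high prevalence, true subgroup HRs 0.69 / 0.96):

```sh
ipdpool run-all --preset checkmate649_like --seed 7 --out-dir out/
python - <<'EOF'
import json
s = json.load(open("out/summary.json"))
a = s["analysis"]
print("max |dS| treatment arm:", s["reconstruction"]["max_abs_dS"]["treatment"])
print("HR high:", round(a["hr_high"]["hr"], 3),
      "CI", [round(x, 3) for x in (a["hr_high"]["ci_low"], a["hr_high"]["ci_high"])])
print("HR low :", round(a["hr_low"]["hr"], 3),
      "CI", [round(x, 3) for x in (a["hr_low"]["ci_low"], a["hr_low"]["ci_high"])])
print("P_interaction:", round(a["p_interaction"], 4))
EOF
```

which prints (seed 7):

```
max |dS| treatment arm: 0.005668437453952013
HR high: 0.663 CI [0.57, 0.77]
HR low : 0.896 CI [0.746, 1.077]
P_interaction: 0.0123
```

Reading: the reconstruction reproduces the digitized curve to within
about half a percentage point of survival probability; the treatment
effect is strong in the biomarker-high subgroup (HR 0.66), absent-to-weak
in the derived biomarker-low complement (HR 0.90, CI crossing 1), and the
interaction test rejects equality of the two effects for this
realization (p ≈ 0.01). The same stages are available programmatically
(`simulate_trial`, `render_published`, `reconstruct_trial`,
`derive_low_subgroup`, `qc_battery`, `pool_cohorts`, `interaction_test`)
and as individual subcommands (`simulate`, `reconstruct`, `subtract`,
`qc`, `pool`, `interact`, `mc-limits`).

## Analysing real digitized figures

Export the digitized curve of each arm (DigitizeIt, WebPlotDigitizer, …)
to CSV and run `reconstruct`/`subtract`/`pool` on the files:

* digitized curve — `time,survival` (add `--percent` if survival is
  0–100); times in months,
* risk table — `time,n_risk_treatment,n_risk_control`,
* IPD — `patient_id,time,event,arm,study,subgroup,endpoint`
  (`arm` ∈ treatment/control, `event` 1 = event, 0 = censored).

Lines starting with `#` are skipped on input; every file the CLI writes
starts with a `#` provenance header (version, seed, config hash).

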