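# nrsem

Non-recursive structural equation modelling of adolescent depression,
anxiety, and somatic symptoms.

## The problem

School-based mental-health surveys typically measure depression (PHQ-9A),
anxiety (GAS-7), somatic symptom burden (SSS-8), perceived stress (PSS-10)
and social support (OSSS-3) on the same adolescents, alongside demographic
and behavioural covariates.  Depression and anxiety influence *each other*,
so single-outcome regressions cannot describe the system: the right tool is
a simultaneous (non-recursive) structural equation model

    eta = B eta + Gamma xi + zeta,        (I - B) invertible,

where `B` carries the reciprocal depression <-> anxiety paths, `xi` stacks
latent stress/social support and observed covariates, and the disturbances
`zeta` are freely correlated.  Identification of the feedback loop rests on
exclusion restrictions (unique instrumental variables per loop member),
checked by the order condition, the rank condition on the 0/1 system
matrix, and data-based instrument screens (Cragg-Donald F, Sargan J).
Estimation is maximum likelihood on the covariance structure with
bootstrap percentile intervals; effects decompose as

    total = direct + indirect,   T_endo = (I - B)^-1 - I,   T_exo = (I - B)^-1 Gamma,

so a loop member exerts loop-amplified indirect effects even on its own
partner.  The package is for biostatisticians and psychiatric
epidemiologists who want this entire chain — scoring, screening
diagnostics, identification, parceling, ML fitting, effect decomposition —
as tested, scriptable code, plus a synthetic-population generator that
makes every stage verifiable by parameter recovery.

## Worked example

Generate a synthetic survey of 1379 respondents from the default
population (loop coefficients 0.74 both ways) and run the full pipeline:

    python analysis/02_simulate_survey.py
    python analysis/03_score_prevalence.py
    python analysis/05_identification.py
    python analysis/06_fit_model.py

which prints, in order: the scored prevalences

    phq9a: 35.68% (95% CI 33.2, 38.2; cutoff >= 10, n = 1379)
    gas7: 29.22% (95% CI 26.9, 31.7; cutoff >= 10, n = 1379)

the identification verdict for the printed three-equation system (rank two
for each loop equation, hence identified) together with the per-edge
instrument screen,

    depression <- anxiety: F =   47.1 (strong), Sargan p = 0.569
    depression <- somatic: F =    2.8 (weak),  Sargan p = 0.377
    ...

and the fitted model after the weak somatic feedback paths are deleted and
insignificant predictors trimmed (AIC-selected):

    pruned non-recursive paths: ['depression ~ somatic', 'anxiety ~ somatic']
    selected model: significant_only; CMIN/DF = 1.38, CFI = 0.998,
    TLI = 0.997, RMSEA = 0.0167, AIC = 305
      anxiety~depression: 0.675
      depression~anxiety: 0.714

The reciprocal paths land near the generating truth of 0.74; the effect
table then reports direct/indirect/total effects with bootstrap CIs (e.g.
stress reaches somatic symptoms both directly, 0.47, and through the loop,
0.36, totalling 0.83).  `python analysis/07_recovery_study.py` repeats the
fit over 30 fresh populations: every structural coefficient's mean bias
stays below 0.03 and bootstrap CI coverage of the loop paths is 93-95%.

The same operations are available as a CLI (`nrsem simulate|score|
diagnose|identify|fit|effects|plan-n|run`) and as plain library calls
(`nrsem.fit_sem`, `nrsem.effect_table`, ...).

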