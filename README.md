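# popivivc

Population-pharmacokinetic IVIVC modelling for drugs with site-dependent,
pH-dependent dissolution, built around sildenafil immediate-release (IR,
20 mg) and sustained-release (SR, 60 mg) tablets in Beagle dogs.

Sildenafil is a BCS class II drug: highly permeable but practically
insoluble above pH 6. As a tablet transits stomach → small intestine →
colon, its dissolution rate collapses and partially recovers, producing
secondary plasma peaks and dose-dependent bioavailability loss that defeat
conventional deconvolution-based in vitro–in vivo correlation (IVIVC). The
approach implemented here instead separates dissolution from absorption
inside a population PK model and correlates *rate parameters*:

- **Release**: Michaelis–Menten depletion of the tablet,
  dX_T/dt = −V_max·X_T/(AM_50+X_T), dose-normalized (X_T as fraction of
  dose, V_max in 1/h).
- **Site dependence**: the in-vivo rate is multiplied by a time-varying
  dissolved fraction F_Diss(t) = F_stomach(t) + F_intestine(t), built from
  Hill switches at the gastric-emptying time T_GET and the transit times
  T_trans1 = T_GET+T_ITT, T_trans2 = T_GET+T_ITT+T_CTT.
- **Absorption/disposition**: lumen → gut (k_lag) → central (k_a) with a
  linear two-compartment model (V1, V2, CL, CLD); concentrations in ng/mL.
- **Population model**: log-normal between-subject variability
  θ_i = θ·exp(η_i), η_i ~ N(0, ω²), proportional residual error, estimated
  by an importance-sampling Monte Carlo EM (MC-PEM) with an adaptive
  Laplace/defensive-mixture proposal.
- **IVIVC**: power law V_max,vivo = a·(V_max,vitro)^b + c fitted across
  formulations; predictions from in-vitro data alone are validated by the
  absolute percentage prediction error, %PE = |obs − pred|/obs × 100.

Because the original animal data are not public, the package ships a
first-class synthetic-data generator (`popivivc.synthetic_data`) that
emulates the study design: 4 formulations × 3 dogs, 19 plasma samples over
48 h with a 5 ng/mL LLOQ, and 6-vessel dissolution runs over 24 h.

## Worked example

```python
import popivivc as pv
from popivivc import defaults

# site-dependent dissolved fraction at the population means
lo, hi = pv.dissolved_fraction_window(defaults.FDISS, level=0.10)
print(f"dissolved fraction >= 10% between {lo:.1f} and {hi:.1f} h")

# in-vivo dissolution limit for the slow tablet
pct = pv.in_vivo_dissolved_pct(defaults.typical_subject("SR_slow"), 12.0)
print(f"SR_slow dissolved in vivo at 12 h: {pct:.1f}%")

# power-law correlation between in-vitro and in-vivo release rates
pairs = [(defaults.VMAX_INVITRO[f], defaults.VMAX_INVIVO[f])
         for f in defaults.FORMULATIONS]
m = pv.fit_power_ivivc(pairs)
print(f"V_max,vivo = {m.a:.4f} * V_max,vitro^{m.b:.4f} {m.c:+.4f}  (r2={m.r2:.3f})")

# predict the IR tablet from its in-vitro release rate alone
pred = pv.predict_from_invitro(m, defaults.reference_population(),
                               defaults.invitro_params("IR"), dose=20.0,
                               formulation_id="IR")
print(f"predicted IR Cmax: {pred.cmax:.1f} ng/mL")
```

Output:

```
dissolved fraction >= 10% between 3.2 and 6.3 h
SR_slow dissolved in vivo at 12 h: 21.0%
V_max,vivo = 2.1431 * V_max,vitro^0.4386 -0.6367  (r2=0.995)
predicted IR Cmax: 284.9 ng/mL
```

The 3.2–6.3 h window is the colonic re-dissolution phase that produces the
secondary plasma peaks of the SR tablets; the 21% cap at 12 h explains the
~19% relative bioavailability of the slowest formulation; the power law
converts dissolution-tester release rates to gut release rates across a
50-fold rate range.

## Analysis pipeline

`analysis/01_simulate_study.py` … `06_predict_validate.py` run the whole
study on synthetic data: simulate both arms, fit the in-vitro release
model per formulation, run non-compartmental analysis, fit the population
model by MC-PEM, build the power-law correlation, and validate predictions
by %PE. Each script prints what it found and writes tables under
`results/`. The same stages are available as a CLI
(`popivivc generate-synthetic | fit-invitro | nca | fit-popk | fit-ivivc |
predict | validate | simulate`).

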