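# npqkin

Analysis pipeline for **non-photochemical quenching (NPQ) kinetics** from
pulse-amplitude-modulation (PAM) chlorophyll-fluorescence measurements, aimed
at plant photosynthesis phenotyping: leaf discs arrayed in 96-well plates or
whole plants, imaged under defined light/dark flash protocols, compared
across genotypes, treatments and developmental stages.

## The quantities and models

A dark-adapted sample yields minimum and maximum fluorescence F<sub>o</sub>
and F<sub>m</sub>; each saturating flash under actinic light (and during the
subsequent dark relaxation) yields F<sub>m</sub>′. NPQ follows the
Stern-Volmer quenching model and PSII maximum quantum yield is

> NPQ = F<sub>m</sub>/F<sub>m</sub>′ − 1,  F<sub>v</sub>/F<sub>m</sub> = (F<sub>m</sub> − F<sub>o</sub>)/F<sub>m</sub>

The NPQ time course is fit per phase:

* induction (light): NPQ(t) = A<sub>L</sub>·t/(K<sub>L</sub> + t) (rectangular
  hyperbola) and NPQ(t) = A<sub>E</sub>·(1 − e<sup>−t/τ</sup>) (saturating
  exponential, giving the induction time constant);
* relaxation (dark): NPQ(t′) = N<sub>0</sub> − A<sub>D</sub>·t′/(K<sub>D</sub> + t′)
  with 0 ≤ A<sub>D</sub> ≤ N<sub>0</sub>, t′ measured from light-off.

The extracted trait panel: `NPQasymptote_lightH` (= Â<sub>L</sub>, induction
steady state), `NPQslope_lightH` (= Â<sub>L</sub>/K̂<sub>L</sub>, initial
induction rate, s⁻¹), `NPQamplitude_darkH` (= Â<sub>D</sub>, relaxation
range), `NPQslope_darkH` (= Â<sub>D</sub>/K̂<sub>D</sub>, s⁻¹),
`NPQtime_constant_light` (= τ̂, s), observed `NPQ_max` / `NPQ_end` (last
light / last dark reading), per-phase goodness of fit (R²), and Fv/Fm.

Around the fits: flash-schedule presets (`crop_default`: 13 light + 6 dark
flashes; `arabidopsis_fluctuating`: three 3-min-light / 2-min-dark cycles),
plate-image ROI extraction, fit-quality/data-integrity QC, and the
comparison layer — Brown-Forsythe + Shapiro-Wilk assumption screening with
conditional log transform, factorial ANOVA (Type II), two-sided Dunnett
tests against control, pairwise t-tests, and leaf-disc vs whole-plant
concordance regression (slope, intercept, adjusted R², RMSE). A synthetic
generator produces ground-truth kinetics, noisy traces, factorial studies,
paired-approach measurements and rendered plate stacks, so the whole
pipeline is testable without instrument data.

## Worked example

```python
import npqkin as nk

schedule = nk.crop_default()                        # 13 light + 6 dark flashes
truth = nk.GroundTruth(A_L=2.5, K_L=90.0, A_D=1.8, K_D=120.0)
trace = nk.trace_from_truth(truth, schedule, noise_sd=0.03, seed=7)
series = nk.npq_series(trace)                       # Stern-Volmer per flash
traits = nk.traits_for_sample(series)               # fit + trait panel
```

prints (via the fields of `traits`):

```
Fv/Fm                  0.830
NPQasymptote_lightH    2.295
NPQslope_lightH        0.02549 s^-1
NPQamplitude_darkH     1.614
NPQslope_darkH         0.01798 s^-1
NPQ_max / NPQ_end      2.019 / 0.712
tau (exponential)      104.8 s
gof light / dark       0.9907 / 0.9901
```

With 3% multiplicative fluorescence noise the hyperbolic induction fit
recovers the generating steady state 2.5 as 2.295 and the initial slope
2.5/90 ≈ 0.0278 s⁻¹ as 0.0255 s⁻¹ at R² ≈ 0.99 — single-replicate scatter
that averages out across replicates (the Monte-Carlo median bias per
parameter is below 2%, see `scripts/acceptance.py`). `NPQ_max` and
`NPQ_end` are the observed last light/dark readings, not fitted values.

The same flow is available from a shell:

```sh
npqkin all --schedule crop_default --seed 7 --out runs/demo
# or stage by stage: npqkin simulate / wells / npq / fit / qc / compare / concordance
```

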