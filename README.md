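# melmark

A dynamic Markov cohort model of melanoma incidence, detection and
mortality, built to put numbers on a public-health question that
epidemiological studies cannot reach directly: **has three decades of
intensified melanoma surveillance (secondary prevention) actually saved
lives, at what cost per life, and what should happen to it next?**

Australia has the world's highest melanoma burden. Since the public
awareness campaigns of the early 1980s, diagnostic incidence has roughly
doubled while mortality has crept up — a pattern compatible both with
"screening works and true incidence rose" and with "we are excising ever
more lesions to little effect". `melmark` disentangles the two by modelling
the *intrinsic* incidence I(t) (new invasive disease) separately from the
*diagnostic* incidence the registries report, with the detection likelihood
D(t) in between.

For biostatisticians and modellers in cancer-screening policy: everything
is a small, fast, deterministic pipeline — no external data needed.

## The model

An eight-state, one-year-cycle, time-inhomogeneous Markov chain on a closed
population: Baseline, undiagnosed Stage 1 / 2–3 / 4, diagnosed Stage
1 / 2–3 / 4, Death (recycled to Baseline to keep the population constant).
Annual transition probabilities: intrinsic incidence I(t) out of Baseline
(partitioned (f1, f23, f4) over the undiagnosed states), detection D(t) of
undiagnosed Stage 1, progression r, r/3 (untreated) vs r/p, r/3p (treated,
p-fold slower), fixed late-stage rates t4–t7, melanoma death q from
diagnosed Stage 4 only, background death d everywhere. Over-diagnosis O(t)
is a counting overlay on the Stage-1 diagnosis flux that never touches the
dynamics.

The analysis pipeline:

1. **Emulate** the 1982–2013 annual incidence/mortality series (and flat
   2014–2028 projections) from published summary anchors
   (`synthetic_aihw`).
2. **Calibrate** the 1982 steady state to the printed anchors — diagnostic
   incidence 27.08/100k/yr, mortality 4.76/100k/yr, treated-thin-melanoma
   prevalence 3215/100k (`calibration.calibrate_1982`).
3. **Fit** I(t) (parabola, 100×100 log-spaced grid search) under each
   monotone D(t) candidate, for ten (D0, p) configurations
   (`calibration.select_best_model`).
4. **Counterfactuals**: freeze/revert/double D(t), reduce q, ramp O(t);
   compare cumulative excisions (TE) and deaths (TM) (`scenarios`).
5. **Sensitivity**: 10,000-draw one-way Monte-Carlo at the 1982 steady
   state (`sensitivity`).
6. **Economics**: NNT/NNS composition and cost per life saved
   (`economics`).

## Worked example

```python
from melmark import AnchorSet, fit_configuration
from melmark import scenarios as sc

model = fit_configuration(AnchorSet(), d0=0.05, p=15.0)
print(f"fit error {model.fit.error:.3f}, "
      f"D(2013) = {model.curves.D_curve.v_end:.2f}")

effect = sc.secondary_prevention_effect(model)
print(f"1982-2013: {effect.excess_excisions:.0f} extra excisions, "
      f"{effect.reduced_mortality:.1f} deaths averted per 100,000 "
      f"({effect.ratio:.0f} excisions per life)")

maintain = sc.project_2028(model, "maintain-2013")
revert_q = sc.project_2028(model, "revert-1982", q_value=0.185)
print(f"2013-2028 deaths/100k: maintain detection {maintain.tm:.0f}, "
      f"abandon detection but halve Stage-4 death risk {revert_q.tm:.0f}")
```

prints

```
fit error 0.034, D(2013) = 0.10
1982-2013: 241 extra excisions, 6.3 deaths averted per 100,000 (38 excisions per life)
2013-2028 deaths/100k: maintain detection 86, abandon detection but halve Stage-4 death risk 73
```

Read: the model that best tracks the emulated registry history says the
detection likelihood doubled (0.05 → 0.10) between 1982 and 2013; that
enhancement bought ≈ 6.3 averted deaths per 100,000 at ≈ 38 melanoma
excisions per life saved; and looking forward, a modest improvement in
late-stage survival beats even maintained surveillance on mortality (73 vs
86 cumulative deaths per 100,000) — prevention is not automatically better
than cure here.

The same pipeline end-to-end, with tables, JSON summaries and optional
figures:

```bash
melmark run-all --outdir results --figures
melmark economics --ratio 50:120 --nnt 10 --cpe 25
```

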