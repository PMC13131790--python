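# lppkit

Statistical adjudication of instruction effects on the late positive
potential (LPP), for EEG/ERP researchers studying instructed emotion
regulation.

## The problem

In reappraisal experiments, participants view emotional pictures under
*View*, *Enhance*, or *Suppress* instructions. A reduced LPP under Suppress
is routinely read as neural evidence of down-regulation — but any
instruction imposes a concurrent cognitive task that free viewing does not,
so the same reduction is equally predicted by dual-task load. The two
accounts separate once *Enhance* is included:

- **directional regulation** predicts `Enhance > View > Suppress`;
- **cognitive load** predicts `View > Enhance ≈ Suppress`;
- **null** predicts no instruction effect at all.

`lppkit` implements the full decision pipeline between these accounts:

1. **LPP quantification** — mean amplitude over 10 a-priori centro-parietal
   sensors (EGI labels 7, 31, 37, 54, 55, 79, 80, 87, 106, 129) in the
   400–800 ms window, after baseline correction, average referencing, and
   absolute-threshold artifact rejection; subject × condition means
   winsorized at the 1st/99th percentiles.
2. **Orthogonal planned contrasts** — per subject, the reappraisal score
   `E − S` (weights 0, 1, −1) and the cognitive-load score `2V − E − S`
   (weights 2, −1, −1); the weight vectors are orthogonal, so the two
   scores carry independent evidence.
3. **Inference** — repeated-measures ANOVA with Greenhouse–Geisser ε and
   generalized η², paired *t*-tests with dz = t/√n and normal-approximation
   CIs, and JZS Bayes factors: the Cauchy-prior (scale √2/2) *t*-test BF01
   and the stretched-beta (width κ = √2/2) correlation BF01, both by
   numerical integration of the marginal likelihood.
4. **Decision rule** — `cognitive_load` iff load BF01 < 1/3 with positive
   mean and reappraisal BF01 > 1; `reappraisal` iff reappraisal BF01 < 1/3
   with positive mean; `null` iff both BF01 > 3; else `indeterminate`.
5. **Robustness** — sequential Bayes factors over random subject orderings
   and subject-level bootstrap effect-size distributions.
6. **Whole-scalp MVPA** — time-resolved and full-epoch decoding of
   condition from 129-sensor patterns with a pointwise 97.5th-percentile
   permutation envelope.
7. **Brain–behavior** — the 3 × 3 grid of correlations between rating
   contrasts and LPP contrasts, each with Pearson r, p, and BF01.

Because individual-level data of this kind are rarely shareable, the
package ships a calibrated synthetic-study generator (`lppkit.simulate`):
129-channel, 250 Hz epochs built from 1/f background noise plus a
spatially-weighted late-positivity template, with switchable generative
regimes (`reappraisal` / `load` / `null`) and intensity ratings that move
with instruction regardless of the neural regime — the dissociation the
pipeline is built to detect.

## Worked example

```python
from lppkit import GeneratorConfig, InstructionEffectModel, winsorize_table
from lppkit.simulate import simulate_condition_means

# a load-regime study at the default scale (107 subjects)
means = winsorize_table(simulate_condition_means(GeneratorConfig(regime="load"), seed=7))
res = InstructionEffectModel(means).fit()
print(res.summary())
```

```
Instruction-effect adjudication (LPP, pooled scope, n = 107)
==================================================================
contrast                 mean (uV)       t      dz     BF01      evidence
------------------------------------------------------------------
Reappraisal (E-S)           -0.108   -0.78  -0.075     6.96 moderate_null
Cognitive load (2V-E-S)      0.671    2.96   0.286    0.156  moderate_alt
------------------------------------------------------------------
decision: cognitive_load
load contrast favoured (BF01=0.156 < 0.333, mean +0.67 uV) while the reappraisal contrast does not (BF01=6.96 > 1)
```

The reappraisal contrast is near zero with moderate evidence *for* the
null (BF01 = 6.96), while the load contrast is positive with evidence for
the alternative (BF01 = 0.156) — the signature of dual-task load rather
than directional regulation. Robustness hangs off the same results object:

```python
boot = res.bootstrap_dz("load", n_boot=10_000, seed=0)
# load bootstrap dz CI95 = [0.10, 0.49], P(dz>0) = 0.999
```

Full EEG-level studies run through the same objects
(`InstructionEffectModel.from_epochs(epochs, trials, config)`) or the CLI:

```bash
lppkit simulate --config cfg.yaml --out data/
lppkit quantify --epochs data/epochs.h5 --trials data/trials.tsv --out means.tsv
lppkit adjudicate --means means.tsv
lppkit run-all --config cfg.yaml --out results/
lppkit bf ttest --t -0.09 --n 107     # {"bf01": 9.2959..., "evidence": "moderate_null"}
```

## Layout

- `src/lppkit/` — `io` (HDF5/TSV dialects), `simulate`, `lpp`,
  `freq_stats`, `bayes`, `model` (Model/Results adjudication),
  `robustness`, `mvpa`, `brain_behavior`, `pipeline`, `cli`.
- `docs/methods.md` — the model, numerical choices, generator calibration,
  and known limitations.
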