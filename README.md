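# sorsq — through-container quantification of hand sanitizers by SORS + SVR

`sorsq` is a tested re-implementation of a quantitative through-container
screening workflow for alcohol-based hand sanitizers.  Spatially offset Raman
spectroscopy (SORS) collects one spectrum at the laser incidence point
("traditional") and one at a lateral offset; because offset collection is
relatively enriched in subsurface photons, the scaled subtraction

    content(ν) = offset(ν) − s · traditional(ν)

isolates the Raman features of the liquid inside a container regardless of
its material (PE, PET, PP, glass) or opacity.  After baseline correction
(asymmetric-least-squares Whittaker filter) and area normalization, the
concentrations of the four relevant alcohols — ethanol, methanol,
2-propanol, 1-propanol, in % v/v — are predicted by ε-insensitive support
vector regression with a Gaussian RBF kernel (grid-searched C and γ,
venetian-blinds cross-validation), with PLS models (4 and 8 latent
variables) as linear baselines and MCR-ALS for variance attribution.
Predictions feed a decision tree that declares each product **fair**,
**sub-potent** (total approved alcohol below the 60 % v/v minimum) or
**contaminated** (methanol or 1-propanol at ≥ 5 % v/v).

Because no instrument data are publicly deposited, the package includes a
first-class simulator that reproduces the study's physical structure:
Lorentzian component bands at literature positions scaled by the
(ν₀−ν)⁴/(1−e^(−hcν/kT)) emission factor, concentration-dependent band
shifts Δν = ±A·e^(−x/t), nine containers spanning four materials and three
opacities, the 4 × 9 = 36-combination training design with binary-mixture and
dilution augmentation (78 training spectra), and a 173-sample test cohort
(65 fair / 24 subpotent / 84 contaminated).  See `docs/methods.md` for the
model and all numerical choices.

## Worked example

```python
from sorsq import RunConfig, run_study_replication

report = run_study_replication(RunConfig(seed=1))
svr = report.regression["svr"]
for alcohol in ("ethanol", "methanol", "propan2ol", "propan1ol"):
    cv, pr = svr["cross_validation"][alcohol], svr["prediction"][alcohol]
    print(f"{alcohol:10s} cv rmse {cv['rmse']:.2f} r2 {cv['r2']:.3f} | "
          f"pred rmse {pr['rmse']:.2f} r2 {pr['r2']:.3f}")
print("screening accuracy:", round(report.confusions["svr"].accuracy, 3))
```

prints

```
ethanol    cv rmse 1.17 r2 0.999 | pred rmse 2.89 r2 0.992
methanol   cv rmse 1.09 r2 0.998 | pred rmse 0.98 r2 0.985
propan2ol  cv rmse 1.02 r2 0.999 | pred rmse 2.10 r2 0.996
propan1ol  cv rmse 1.09 r2 0.998 | pred rmse 1.07 r2 0.985
screening accuracy: 0.936
```

RMSE values are in % v/v: the SVR models recover each alcohol's
concentration through the container wall to within ~1–3 % v/v, and the
decision tree classifies 94 % of the 173 test products correctly (its
errors are almost exclusively samples contaminated below the 5 % v/v
decision threshold).  The same report carries the MCR comparison — for
traditional spectra a 7-component model (fit 99.4 %) attributes 60.9 % of
the variance to container materials and 38.5 % to contents, while for
scaled-subtracted spectra a 4-component model fits 99.3 % with every
component matching an alcohol — and the PLS-4/PLS-8 confusion matrices.

The same workflow is scriptable from the shell:

```sh
sorsq simulate --design training --seed 0 --out-prefix train
sorsq preprocess --in train --out train_processed.csv
sorsq train --method svr --in train --matrix train_processed.csv --model-out svr.json
sorsq predict --model svr.json --matrix test_processed.csv --out pred.csv
sorsq screen --pred pred.csv --policy cdc --out screened.csv
sorsq evaluate --pred screened.csv --truth test_metadata.csv --out confusion.json
sorsq replicate --seed 1 --out-dir results/   # the whole study in one step
```

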