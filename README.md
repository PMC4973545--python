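# nirscal

Near-infrared spectroscopy (NIRS) calibration for feed-energy prediction:
a tested, open implementation of the classic chemometrics workflow used to
predict the **digestible energy (DE)** and **metabolizable energy (ME)**
content of corn fed to growing pigs from log(1/R) reflectance spectra.

It is written for animal-nutrition and chemometrics researchers who want a
scriptable, auditable equivalent of the commercial calibration workflow:

* **Spectral pre-treatment grid** — 7 scatter corrections (SNV, Detrend,
  SNVD, standard/weighted/inverse MSC, none) × 11 gap-segment derivative
  codes (`d,g,s1,s2`), 77 combinations.
* **Modified PLS (MPLS)** — NIPALS PLS1 with per-factor residual
  standardization (plain-PLS oracle mode included for cross-checking).
* **Model selection** — 6-group cross-validated factor choice (minimum
  SECV), global-H (Mahalanobis, GH ≥ 10) and T (> 2.5) outlier elimination
  with at most two passes, and full grid search ranked by SECV.
* **Evaluation statistics** — SEC, SECV, SEP, RSQ_cal, R²cv, RSQ_v,
  RPD = SD/SECV (or SD/SEP), SEL/RSEL from duplicate lab determinations.
* **Reference energies** — the Noblet–Perez equations

      DE (MJ/kg DM) = (4168 − 9.1·Ash + 1.9·CP + 3.9·EE − 3.6·NDF) × 4.18/1000
      ME (MJ/kg DM) = DE × (1.003 − 0.00021·CP)        (composition in g/kg DM)

  and the direct method for balance-trial DE/ME at a given ingredient
  inclusion rate.
* **Synthetic data** — a seeded generator of corn-like compositions,
  reference energies and spectra (Gaussian band library + baseline +
  multiplicative scatter + noise, duplicate scans) so the whole pipeline
  is testable end to end without proprietary data.

See `docs/methods.md` for the model definitions, numerical conventions and
the simulator's limitations.

## Worked example

Simulate a 117-sample dataset (two scans per sample on the 400–2498 nm
grid), calibrate determined DE on a random 88-sample calibration set with
a 20-cell screening grid, and validate on the held-out 29:

```bash
$ nirscal simulate --n 117 --seed 11 --out sim
wrote sim/spectra.csv and sim/reference.csv

$ nirscal calibrate --spectra sim/spectra.csv --reference sim/reference.csv \
      --constituent de_d --out run --grid reduced --seed 11
winner 2,8,8,1+SMSC: 1 factors, n=85, SECV=0.132, R2cv=0.94, RPDcv=4.18; \
validation SEP=0.189, RSQv=0.92, RPDv=3.20
```

Reading the output: the best pre-treatment was a second derivative with
gap/segment 8 plus standard multiplicative scatter correction; 3 of 88
calibration samples were discarded as outliers (n = 85); cross-validation
error SECV = 0.132 MJ/kg DM gives RPD_cv = SD/SECV = 4.18; on the
untouched validation set the prediction error is SEP = 0.189 MJ/kg DM and
RPD_v = 3.20, well above the 2.5 bound conventionally required for routine
quantitative use. `run/` contains the ranked 20-row leaderboard TSV, the
serialized winning model (pre-treatment + MPLS chain + outlier log), a
validation TSV and a run log.

Energy equations from a composition table (% DM by default):

```bash
$ printf 'ash,cp,ee,ndf\n1.41,9.41,3.87,12.02\n' > comp.csv
$ nirscal energy --input comp.csv
ash,cp,ee,ndf,de_c,me_c
1.41,9.41,3.87,12.02,16.455,16.18
```

Everything is also available as a library:

```python
from nirscal import SimConfig, make_dataset, average_duplicates, grid_search

spectra, reference = make_dataset(SimConfig(), seed=11)
s = average_duplicates(spectra)
result = grid_search(s, reference.values("de_d", s.sample_ids), seed=11)
print(result.leaderboard.head())
```

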