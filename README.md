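# edscreen

Early-tier screening of chemicals for **endocrine-disruption (ED) potential**
— estrogenic (ER), androgenic (AR) and steroidogenic (aromatase) effects —
for toxicologists and safety assessors running next-generation risk
assessments (NGRA) without new animal data.

No single assay predicts ED, so screening combines many weak signals:
panels of in silico models (QSAR, docking, expert systems) predicting
receptor binding, activation, antagonism and aromatase inhibition, plus a
battery of in vitro assays (yeast YES/YAS reporters, ER/AR radioligand
binding, CALUX transactivation, recombinant aromatase inhibition, H295R
steroidogenesis). `edscreen` implements the decision layer of that
workflow:

* **In vitro calling rules** — four-parameter logistic (4PL) fitting of
  concentration–response data, relative IC50 (half of the compound's *own*
  maximal effect, so solubility-limited plateaus are handled correctly),
  Cheng–Prusoff conversion Ki = IC50 / (1 + L/K_d), Lowest Effective
  Concentration (LEC) at 10 % of the reference maximum, single-dose binding
  triage bands, non-specificity and cytotoxicity-masking rules for the
  reporter assays, and 1.5-fold-of-control steroidogenesis calls.
* **In silico consensus** — majority voting over a chemical's distinct
  model calls per target, with a high-confidence flag when binding-role and
  activation/antagonism-role models agree on a positive.
* **Model scoring** — per-model **% efficiency** (share of included
  chemicals receiving any distinct call; out-of-domain and inconclusive
  predictions count against it) and **% correct** (distinct calls matching
  the reference sign), against a reference-call set with
  reference-inconclusive chemicals excluded; both rounded half-up.
* **Weight-of-evidence integration** — a fixed rule order combining the in
  silico, in vitro and reference streams into an overall call with a
  confidence tier, plus the colour-coded summary heatmap.
* **Synthetic data** — generators for prediction matrices (per-model
  sensitivity / specificity / inconclusive / out-of-domain profiles against
  a known truth panel) and noisy 4PL curves with optional solubility
  plateaus and cytotoxicity onset, so the whole pipeline is testable with
  known ground truth.

A transcribed ten-chemical reference panel (tamoxifen, 4-tert-octylphenol,
mestanolone, daidzein, BBP, MBP, DEABA, DBABA, isoeugenol, terephthalic
acid), the published model-evaluation table and an in vitro summary ship as
packaged fixtures.

## Worked example

Fit a plateau-limited ER-binding curve (a compound whose inhibition maxes
out at 69 %, as happens when solubility caps the tested range), derive its
relative IC50 and Ki, then summarise the packaged model-evaluation table:

```python
from edscreen import (cheng_prusoff_ki, derive_relative_ic50,
                      fit_concentration_response)
from edscreen.simulate import CurveSpec, generate_dose_response

curve = generate_dose_response(
    CurveSpec(bottom=0, top=69, midpoint=0.46, hill_slope=1.0, noise_sd=0.0),
    seed=0, chemical_id="BBP", assay_id="er_binding")
fit = fit_concentration_response(curve)
ic50 = derive_relative_ic50(fit)
print(f"max inhibition (top) = {fit.top:.0f}%")
print(f"relative IC50        = {ic50:.2f} uM")
print(f"Ki (L = 2.07 Kd)     = {cheng_prusoff_ki(ic50, 2.07, 1.0):.2f} uM")
```

```
max inhibition (top) = 69%
relative IC50        = 0.46 uM
Ki (L = 2.07 Kd)     = 0.15 uM
```

The IC50 is read at 34.5 % inhibition — half of this compound's own 69 %
maximum, not half of the positive control's — and the Cheng–Prusoff
correction turns it into a binding constant given the radioligand
concentration L and affinity K_d.

```python
from edscreen.consensus import summarize_performance
from edscreen.io import load_table1_fixture

summary = summarize_performance(load_table1_fixture())
for target, s in sorted(summary.per_target.items()):
    print(target, s.mean_pct_correct, s.min_pct_correct, s.n_full_efficiency, s.n_models)
```

```
AR 79 0 6 17
ER 78 50 13 18
aromatase 75 33 3 4
```

Read: across the 18 ER models the mean correct-call rate on the 8-chemical
included panel is 78 % (minimum 50 %) with 13 models fully efficient; the
17 AR models average 79 % with 6 fully efficient.

## Command line

```bash
edscreen simulate -o study --seed 5          # synthetic truth + matrix + curves
edscreen evaluate study/matrix.csv --reference study/truth.csv -o perf.csv
edscreen consensus study/matrix.csv -o final.csv
edscreen fit study/curves.csv -o fits.csv
edscreen report final.csv invitro.csv -o overall.csv --format png
```

`evaluate` accepts `--oad-policy {exclude,count_as_incorrect}` (how
out-of-domain chemicals enter the %-correct denominator) and
`--denominator {included,panel}`.

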