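# vegrisk

Probabilistic human-health risk assessment of heavy-metal intake via
vegetable consumption, for environmental-health scientists working with
paired soil–vegetable surveys around contamination sources (mining and
smelting areas in particular).

The package implements the full assessment chain for As, Cd, Cu, Pb and Zn:

* **Exposure equations** — fresh-weight conversion C_fw = C_dw·(1 − w);
  bioaccumulation factor BCF = C_veg(fw)/C_soil(dw); estimated daily intake
  EDI = EF·ED·C_fw·IR/(BW·AT) with AT = ED·365 d, reported in µg/(kg·d);
  target hazard quotient THQ = EDI/RfD; hazard index HI = Σ THQ.
* **Contamination screening** — descriptive statistics (min/max/median/
  mean/SD/CV%/Shapiro–Wilk p) and exceedance against soil risk screening
  values (GB 15618-2018), food MACs (GB 2762-2017, category-specific) and
  FAO/WHO PTDIs.
* **Monte Carlo propagation** — input variables (C_veg per metal, IR, BW,
  EF, ED) as fitted or configured distributions, 30,000 independent draws
  per population group pushed through the EDI→THQ→HI chain; THQ
  percentiles (5/25/50/75/95), HI median/mean/95th percentile and full HI
  CDFs.
* **Sensitivity analysis** — Spearman rank correlation per input,
  normalised to signed contribution-to-variance percentages for tornado
  plots, with the per-metal concentrations pooled into one C_veg entry.
* **Synthetic survey generator** — paired soil–vegetable samples
  (lognormal soils × transfer factors with category structure) and
  exposure questionnaires per age group, calibrated to published survey
  summary tables, so the whole pipeline is testable without field data.

See `docs/methods.md` for the model, the calibration and its limitations.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
synthetic survey (97 paired samples, 87 questionnaire respondents;
seed 2023) and write their tables under `results/`:

```sh
python analysis/01_generate_data.py
python analysis/02_screen_contamination.py
python analysis/03_bioaccumulation.py
python analysis/04_daily_intake.py
python analysis/05_monte_carlo_risk.py
python analysis/06_sensitivity.py
```

Screening (step 02) prints, for this survey,

```
   name       mean  cv_percent  rsv_mg_kg  exceeding_percent
soil_Cd   3.116285  105.927696        0.3          96.907216
soil_Pb 195.127890   77.981193       90.0          78.350515
```

— mean soil Cd of 3.1 mg/kg with a CV above 100% and ~97% of samples above
the 0.3 mg/kg screening value: heavily and heterogeneously contaminated
soil. Step 03 ranks soil-to-plant transfer, Cd first (mean per-sample
BCF 0.100) and Pb last (0.003). Step 04 reports mean daily intakes; for
children the mean As intake is 3.11 µg/(kg·d), above the 3.0 PTDI, and
Cd and Pb also exceed their tolerable intakes in every group. Step 05
propagates the fitted distributions; the HI summary

```
 population  median  mean   p95
   children    7.59 14.57 49.49
adolescents    5.59  9.20 28.46
     adults    4.70  9.52 32.77
```

puts even the median cumulative hazard well above 1 for every group, with
children highest. Step 06 attributes the output variance: ingestion rate
~54–70% and vegetable concentration ~29–44% per group, with BW/EF/ED minor
— measure intake rates and concentrations well before anything else.

The same pipeline is scriptable on your own tables via the CLI:

```sh
vegrisk simulate --n-sites 97 --seed 1 --out-dir results/sim
vegrisk risk --samples results/sim/samples.tsv \
             --exposure results/sim/exposure.tsv \
             --seed 7 --iterations 30000 --out-dir results/risk
```

Every output directory contains a `manifest.json` (command, input digest,
seed, iterations, version) sufficient to reproduce the run exactly.

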