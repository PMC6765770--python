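# Methods

## Scope and model

`vegrisk` implements a probabilistic non-carcinogenic risk assessment of
heavy-metal intake (As, Cd, Cu, Pb, Zn) through vegetable consumption, the
standard USEPA dietary-route chain applied to paired soil–vegetable surveys
around point sources such as Pb/Zn smelters:

1. **Fresh-weight conversion.** Vegetable concentrations measured on a dry
   basis convert to fresh weight via the tissue water content,
   C_fw = C_dw · (1 − w), with w = (fresh − dry)/fresh measured per sample.
2. **Bioaccumulation factor.** BCF = C_veg(fw) / C_soil(dw), the
   soil-to-edible-part transfer propensity, summarised as the mean of
   per-sample ratios (not the ratio of survey means; for right-skewed
   concentration data the two differ materially).
3. **Estimated daily intake.**
   EDI = EF · ED · C_fw · IR / (BW · AT) with AT = ED · 365 d, so ED cancels
   algebraically and EDI = C_fw[mg/kg] · IR[g/d] · (EF/365) / BW[kg] in
   µg/(kg·d). All unit factors (g→kg, mg→µg) live inside `edi()`;
   published sources commonly mix mg- and µg-based statements of this
   equation, so the package fixes µg/(kg·d) as the single internal exposure
   unit, making THQ a bare ratio.
4. **Hazard characterisation.** THQ = EDI / RfD per metal;
   HI = Σ THQ under additivity. THQ or HI > 1 flags potential
   non-carcinogenic risk. Default RfDs (µg/(kg·d)): As 0.3, Cd 1, Cu 40,
   Pb 3.57, Zn 300. ADI in the quotient is identified with the EDI — it is
   the only intake the chain computes.
5. **Screening.** Soil concentrations are screened against GB 15618-2018
   risk screening values (As 40, Cd 0.3, Cu 50, Pb 90, Zn 200 mg/kg dw) and
   vegetable concentrations against the GB 2762-2017 MACs of each sample's
   own category (e.g. Pb: leafy 0.3, rootstalk 0.1, legume 0.2,
   fruit 0.1 mg/kg fw). "Exceeding" is strictly above the threshold; ties
   count as compliant. FAO/WHO PTDIs are used for the deterministic intake
   comparison; Pb is age-dependent (adults 1.5, adolescents 0.5 µg/(kg·d));
   the children's value is not separately established and the more
   protective adolescent value is applied.

Bioavailability is assumed to be 100% (no adjustment), risks are
non-carcinogenic only, and no metal-interaction or spatial modelling is
attempted.

## Monte Carlo propagation

Uncertain inputs — vegetable concentration per metal, IR, BW, EF, ED — are
modelled as independent parametric distributions per population group
(children 4–11, adolescents 12–17, adults 18–60) and propagated with
simple random sampling, 30,000 iterations by default. RfDs are point
values (toxicological data too sparse to justify distributions).

* Each (group, variable) pair draws from its own random stream derived
  from the root seed and the variable's name via a stable SHA-256 digest:
  runs are bit-reproducible and adding a variable never perturbs another's
  draws.
* Truncation (concentrations/IR/BW/ED ≥ 0, EF ∈ (0, 365]) is enforced by
  rejection with resampling; a bound set so tight that acceptance falls
  below ~1e−6 raises instead of hanging.
* Percentiles use linear interpolation between adjacent order statistics
  (numpy's default). The choice moves 30,000-draw percentiles only in the
  fourth decimal but is fixed for exact reproducibility.
* HI is accumulated per draw, so HI = Σ THQ holds exactly, not just in
  summary statistics. Input draws are retained so sensitivity analysis
  runs on exactly the draws that produced the risk output.

**Distribution assignment.** When input distributions are not supplied,
they are fitted from data: maximum likelihood per candidate family, the
fit with the smallest Kolmogorov–Smirnov statistic kept, ties broken by
candidate order. Candidates are lognormal/normal for concentrations
(concentration surveys with CVs up to ~118% are strongly right-skewed),
lognormal/normal for IR, normal/lognormal for BW and ED, uniform/normal
for EF. Constant data degenerate to a point distribution. The fitted
family and n are logged per variable so the assignment of any run is
auditable.

## Sensitivity

Spearman rank correlation ρ_v between each input's retained draws and the
HI draws, normalised to a contribution to variance
100 · ρ_v² / Σ_u ρ_u², signed by sign(ρ_v) — the convention commercial
risk packages print on tornado plots. Rank-based, it is invariant to
strictly monotone transforms. Sensitivity is computed against HI (one
tornado per population); the five per-metal concentration inputs are
pooled into a single `C_veg` entry by summing their signed contributions
(pooled ρ reported as the signed root of the summed ρ²). Because the sum
is signed, noise-level negative correlations inside a pool can shave a
fraction of a percent off the 100% total; unpooled contributions always
sum to 100% in absolute value. ED correlates with nothing by
construction — it cancels in the intake — and serves as an internal
negative control.

## Synthetic survey generator

No field data ship with the package; `synthetic.py` generates surveys with
the statistical structure the analysis assumes, calibrated to published
summary tables of a smelter-impacted vegetable survey (97 paired samples,
87 questionnaire respondents).

* **Soils**: lognormal per metal, parameterised by method of moments from
  the published mean and CV (e.g. Cd mean 3.59 mg/kg, CV 117.5%).
* **Vegetables**: generated through the soil × BCF mechanism so per-sample
  BCFs are meaningful: C_fw = C_soil · B · m(metal, category) · ε, with B
  the per-metal target BCF, m a category multiplier normalised to
  weight-average 1 (leafy > rootstalk > legume ≈ fruit, from the published
  category means), and ε lognormal with unit mean (σ_log = 0.4). BCF draws
  are independent of the soil draw, so the survey-mean per-sample BCF
  recovers the configured target.
* **Default BCF targets** are the ratios of the published vegetable means
  to the published soil means (As 0.0039, Cd 0.092, Cu 0.0071, Pb 0.0031,
  Zn 0.018). The published *per-sample* mean BCFs (Cd 0.055 … Pb 0.002)
  are mutually inconsistent with the published soil and vegetable means
  under any soil × BCF mechanism (mean of ratios ≠ ratio of means, and the
  raw pairings are unavailable); the ratio-of-means defaults reproduce the
  published vegetable means in expectation — hence the published intake
  ordering Zn > Cu > Pb > As > Cd and risk ordering As > Cd > Pb > Cu > Zn
  — while preserving the published BCF *ordering* Cd > Zn > Cu > As > Pb.
  The generator recovers any configured target (tested at the published
  Cd value 0.055).
* **Exposure factors**: BW and ED truncated normal, EF uniform on
  [330, 365] d/yr (near-daily consumption of home-grown vegetables), IR
  lognormal. IR is deliberately lognormal rather than truncated normal:
  self-reported intake rates are right-skewed, and ingestion-rate
  variability dominates the variance of such assessments — the shipped IR
  CV of 1.0 yields the tornado ranking IR > C_veg > {BW, EF, ED} with
  IR ≈ 60% and C_veg ≈ 35%, the qualitative pattern this type of survey
  reports. Group means (children BW 25.5 kg / IR 180 g/d; adolescents
  47 kg / 270 g/d; adults 58 kg / 275 g/d) are calibrated so mean intakes
  land near the published magnitudes (children's mean As EDI ≈ 3 µg/(kg·d)).
* Water content is uniform on [0.70, 0.95]; fresh mass is fixed at the
  500 g composite-sample protocol and dry mass follows from w, so the
  fresh/dry-weight identity is exact in every record.

**What the generator does not emulate**: spatial or village-level
structure (distance/wind effects), correlation between soil level and
transfer factor (saturation), inter-metal correlation beyond the shared
category effect, detection-limit censoring, and within-person correlation
of IR with BW. Passing tests therefore demonstrate the correctness of the
machinery and the self-consistency of the calibration, not agreement with
any particular field data set; absolute THQ/HI percentiles depend on the
unpublished survey distributions and are not reproduced.

## Problem sizes and numerical choices

* Moment-recovery checks run at 5,000 sites, where lognormal mean/CV
  estimates are within a few percent of their targets; ordering and
  tornado checks run at 1,000 sites and 500 people per group, where fitted
  parameters are stable enough that the qualitative orderings are
  properties of the calibration rather than of the seed. The default
  survey size remains the emulated campaign's 97/87.
* Sample SD uses the n−1 denominator; the median of an even-sized sample
  is the mean of the central order statistics; CV% = 100·SD/mean (undefined
  for non-positive means); normality is Shapiro–Wilk, reported as a
  p-value and omitted below n = 3 or at zero variance.
* Below-detection-limit values are substituted at LOD/2 before statistics,
  with substitutions logged; no distributional censoring model is fitted.
* Degenerate inputs are handled explicitly: constant data fit to a point
  distribution, point distributions short-circuit rejection sampling, a
  constant simulation output is a sensitivity error ("output has no
  variance"), and an empty THQ map has no hazard index.

## Known limitations

Independence between all inputs is assumed (no copulas or rank-correlation
induction); sampling is simple random, not Latin hypercube; risks are
additive across metals with no interaction; concentrations are pooled
across vegetable categories when fitting the Monte Carlo concentration
inputs, discarding the category contrast the screening stage reports.
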