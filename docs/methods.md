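# Methods

`dryseason` quantifies the length, timing and water deficit of tropical dry
seasons under three water-balance definitions of "dry", estimates their
long-term trends, labels agreement across an ensemble of rainfall datasets,
and decomposes trends in atmospheric water demand into meteorological
drivers. This note records the model choices, parameters and numerical
conventions, and what the synthetic data used for validation do and do not
establish.

## Dry-season definitions and detection

A day is dry when daily precipitation P falls below a demand term D:

* **P < P̄** — D is the multi-year mean daily precipitation (supply-only);
* **P < Ep** — D is potential evapotranspiration from the FAO-56
  Penman–Monteith equation (atmospheric demand);
* **P < E** — D is actual evapotranspiration (realized water loss, here a
  single-layer bucket model).

Rather than counting intermittent dry days, timing is read from the
cumulative anomaly curve A(d) = Σ_{j≤d} (P_j − D_j) built on 30-day-smoothed
series: A rises through the wet season, peaks at the dry-season arrival
(DSA), declines while supply lags demand, and bottoms out at the dry-season
end (DSE). The dry-season length is DSL = (DSE − DSA) mod 365 and the water
deficit WD = A(DSA) − A(DSE) ≥ 0 (mm).

**Climatological seasons** are found on the day-of-year climatology.
Because cumulative P − Ep and P − E carry a secular drift (their annual sum
is not zero), a literal global argmax/argmin of the 1 Jan–31 Dec curve can
land on the window boundary; we instead locate maximal circular runs of
negative P − D on the smoothed climatology. Each run is exactly one local
max→min pair of the curve, seasons spanning 31 Dec stay intact, and for the
drift-free P − P̄ case the result coincides with the argmax/argmin rule.
Unimodal regimes keep the deepest run (largest WD); bimodal regimes keep the
two longest.

**Modality** comes from the full daily precipitation record: the ratio of
the Fourier amplitude at two cycles per year to that at one cycle per year,
read at the exact harmonic bins of the 365·n-point transform. A ratio
strictly greater than 0.75 marks a bimodal (two-dry-season) regime. The
classifier is run on precipitation only and applied to all three
definitions; `harmonic_ratio` accepts any series for callers who want a
per-definition variant.

**Year-by-year timing** rebuilds the curve on that year's smoothed daily
values inside a window from DSA_clim − 60 to DSE_clim + 60 days (±45 days
per season in bimodal regimes), indexed across calendar-year boundaries.
The P̄ threshold is always the record-wide mean, never a per-year mean.
Within the window the season is the maximum-drawdown pair of the curve
(the i < j maximizing A(i) − A(j)), which is the deepest deficit segment
and is robust both to drift and to noisy years where an unrestricted argmin
would precede the argmax. The first and last years of a record are never
scored: their windows can leave the record when a season spans New Year.

Ties in extrema resolve to the earliest day (NumPy argmax semantics),
making results scan-order independent. A supply-minus-demand series that
never changes sign (arid points with no wet season under P < Ep, humid
points with no dry season, or flat climatologies) yields no season and the
reason code `no_climatological_season`; such points are excluded from
percent-area summaries.

## Smoothing

All climatologies and per-year series use a 30-day running mean. Thirty is
even, so the window is fixed at offsets −15…+14 relative to the centre day;
this half-day asymmetry shifts timing by at most one day and is applied
identically everywhere. The climatological smoother is circular (exactly
mean-preserving); per-year smoothing is linear over the contiguous record,
with edge windows averaging the days actually available (only the first and
last 15 days of the record are affected, inside the excluded years). The
window attenuates an annual harmonic by factor ≈0.989, which is why the
detected sinusoidal-benchmark deficit (172.3 mm) sits ~1.1 % below the
continuous closed form 1.5·365/π ≈ 174.3 mm.

## Atmospheric demand

Daily potential evapotranspiration:

Ep = [0.408·Δ·(Rn − G) + γ·(900/(T+273))·u₂·(e_s − e_a)] / [Δ + γ·(1 + 0.34·u₂)]

with the Tetens saturation curve e_s = 0.6108·exp(17.27·T/(T+237.3)),
e_a = e_s·RH/100, Δ = 4098·e_s/(T+237.3)², γ = 0.665×10⁻³·p. Soil heat flux
G defaults to 0 at daily steps and surface pressure to 101.3 kPa when no
pressure field is supplied. Negative Ep (strongly negative net radiation)
is clipped to zero by default: for season detection, negative demand is no
demand. Winds reported above 2 m are scaled with the FAO-56 logarithmic
profile u₂ = u_h·4.87/ln(67.8·h − 5.42); radiation read from files in
W m⁻² is converted by ×0.0864.

## Bucket model for actual evapotranspiration

E is supply-limited through an evaporative stress factor S:
E = S·Ep + Ei with S = W/W_max for a single store W (mm) updated daily as
W ← min(W + P − E, W_max), overflow leaving as runoff; there is no drainage
term, and interception Ei defaults to 0 (its contribution to E *changes* is
negligible). E is additionally capped at W + P within a day so the store
never goes negative and W(t+1) − W(t) = P − E − runoff closes exactly; the
cap is inactive whenever Ep ≪ W_max. Defaults W_max = 200 mm (a root-zone
store), W0 = 120 mm. The linear S = W/W_max closure is a deliberate
simplification of multi-layer, vegetation-aware retrieval schemes; it
reproduces the qualitative behaviour that matters here — S ≈ 1 and E → Ep
in humid climates, E collapsing toward supply in dry ones — not any
particular product.

## Trends and consistency

Annual diagnostics (DSL, DSA, DSE, WD) are trended with OLS against the
year index (slopes reported per decade; two-tailed t test, p from n−2 df),
with the Mann–Kendall test as a nonparametric cross-check (S statistic,
tie-corrected variance, continuity-corrected normal approximation).
Constant series report slope 0 with p = 1. Significance is P < 0.05
everywhere, per point, with no multiple-testing correction.

Ensemble agreement at a point is labelled from the counts of significant
trends by sign: any conflict of significant signs → *uncertain*; none
significant → *no change*; otherwise k significant same-sign members map to
*very likely* (6–8 of 8), *likely* (4–5) or *probably* (1–3), with
direction. For ensemble sizes other than 8 the same fractions apply
(≥3/4, ≥1/2, >0). Note the lowest tier is permissive by construction: under
a true null, ≥1 of 8 members crosses P < 0.05 in ~34 % of ensembles, so
*probably* labels alone are weak evidence; calibration claims in the tests
are therefore made for the confident tiers. The OLS p-value drives the
label; MK is reported alongside. Regional series are area-weighted
(cos-latitude) means of the diagnostics, trended at the regional level.

## Attribution of Ep trends

The contribution of driver I ∈ {T, RH, u₂, Rn} is C_I(t) = Ep_all(t) −
Ep_{I fixed}(t), where "fixed" replaces I, day by day, with its 30-day
smoothed day-of-year climatology (the same smoothing as season detection).
Contributions are computed daily and then trended over annual means of an
optional day-of-year window (e.g. the detected dry season); the sum of
driver trends need not equal the Ep trend, and the difference is reported
as a nonlinearity residual, never redistributed. Because the record
climatology centres each perturbation, the even-order error term cancels
and the relative residual in practice shrinks ~quadratically as
perturbations scale down (a factor ~100 for amplitude ÷10) — at least the
linear consistency one would demand of a first-order decomposition. With a
single trending driver the decomposition is exact.

## Synthetic climate generator

The generator is the ground truth for every validation: rainfall is
(map_total/365)·(1 + a₁(t)·cos(2π(doy−φ₁(t))/365) + a₂·cos(4π(doy−φ₂)/365)),
clipped at zero, times mean-one gamma noise with coefficient of variation
`noise_cv`; T, RH, u₂, Rn are mean + annual harmonic + linear trend (RH
clipped to [0,100] %, u₂ to ≥0); trends enter linearly in time (phase drift
in d/decade, amplitude change per decade, met trends in units/decade). The
calendar is a strict 365-day year. Defaults describe a seasonally dry
tropical point over a 34-year record (1983–2016): 1200 mm yr⁻¹, annual
amplitude 0.8, wet peak in mid-October, noise_cv 0.3, T 25 °C ± 2,
RH 70 % ± 12, u₂ 2 m s⁻¹, Rn 14 MJ m⁻² d⁻¹.

What it emulates: harmonic (uni/bimodal) seasonality, synoptic-scale noise,
supply limitation of E, secular shifts in timing, amount and meteorology.
What it does not: wet-day occurrence structure (no dry-spell clustering),
spatial correlation between points, interannual modes (ENSO), or any named
observational product. Passing tests therefore establish that the *method*
recovers known structure under realistic noise levels — not that any
particular real-world trend estimate is unbiased in the presence of, e.g.,
autocorrelated rainfall or product-specific inhomogeneities.

Reference scenarios (in `dryseason.scenarios`) fix the study conditions:
a sinusoidal benchmark with closed-form timing (mean 3 mm d⁻¹, relative
amplitude 0.5, minimum day 200 → crossings 108.75/291.25, deficit
1.5·365/π mm); two-harmonic regimes with semiannual minima at days 25 and
207.5 and the annual harmonic 135° from the first minimum, so both DJF and
JJA stay dry across the bimodal range; humid (2800 mm yr⁻¹, W_max 2000 mm,
never stressed) and semi-arid (900 mm yr⁻¹, W_max 50 mm, chronically
stressed) limit points that separate the three definitions; an ensemble
experiment (8 members, 34 years, DSE delay 8 d decade⁻¹, σ = 6 d, 200
repeats) at the diagnostic level; and a Mann–Kendall calibration run
(2000 iid series of length 34). These sizes run in seconds and are the ones
reported by `scripts/acceptance.py`.

## Pipeline conventions

Day-of-year is 1-based (1…365); latitudes are degrees north; season
intervals are closed [DSA, DSE] with the deficit accumulating over
(DSA, DSE]. NetCDF I/O uses the NetCDF-3 (scipy) backend with an integer
day index and a `365_day` calendar attribute; files with a datetime axis
have 29 Feb dropped on load. A point-year with more than 10 % missing daily
precipitation (configurable) is excluded from annual detection; remaining
gaps are filled with the day-of-year climatology before smoothing. Output
tables are schema-checked before writing, floats are formatted at 6
significant digits so identical configs produce byte-identical CSVs, and
each run writes a manifest with a config hash.

## Known limitations

* The bucket's linear stress function is the simplest closure with the
  right limits; real stress–soil-moisture relations are nonlinear and
  vegetation-dependent, so P < E results quantify the *mechanism*, not any
  observational E product.
* Maximum-drawdown detection returns at most one season per climatological
  season per year; a year with two genuine deficit spells inside one window
  reports only the deeper one.
* The consistency labeller treats members as exchangeable and independent;
  real precipitation products share inputs, so labels on real ensembles
  overstate independence.
* No spatial-field significance testing; per-point labels are marginal.
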