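# Methods

This note documents the models and procedures implemented in `phenolai`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical decisions made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Gaussian process regression engine

Both the multiband LAI retrieval and the 1-D temporal gap-filling use the
same GP model: observations `y = f(x) + ε`, `ε ~ N(0, σ_n²)`, with a
zero-mean GP prior on `f` and the ARD squared-exponential covariance

    k(x_i, x_j) = σ_s² exp(−½ Σ_b ((x_ib − x_jb)/σ_b)²).

Predictions at `x*` are Gaussian with mean `k*ᵀ(K+σ_n²I)⁻¹y` and variance
`k(x*,x*) + σ_n² − k*ᵀ(K+σ_n²I)⁻¹k*`; the predictive variance therefore
includes the noise term and, for this kernel, can never exceed
`σ_s² + σ_n²`. The inverse lengthscale `1/σ_b` is reported as the
relevance of input dimension `b`.

Training maximises the log marginal likelihood

    log p(y|X,θ) = −½ yᵀA⁻¹y − ½ log|A| − (N/2) log 2π,  A = K + σ_n²I,

with L-BFGS-B in log-parameter space using analytic gradients
(`∂A/∂log σ_s² = K`, `∂A/∂log σ_b = K ∘ D_b/σ_b²` with `D_b` the squared
per-dimension distances, `∂A/∂log σ_n² = σ_n²I`). Numerical choices:

* **Target centring.** The prior assumes zero-mean `f`, but LAI is
  non-negative; targets are mean-centred internally and the centre added
  back at prediction. Far from all training points the prediction
  reverts to the training mean with variance `σ_s² + σ_n²`.
* **Initialisation.** `σ_b` = per-dimension input standard deviation,
  `σ_s²` = var(y), `σ_n²` = 0.1·var(y) — moment-based and scale-free.
* **Restarts.** Three additional starts perturb the initial point
  log-uniformly within a factor of 10, drawn from a seeded generator;
  the best optimum is kept. Fits are bit-reproducible for a fixed seed.
* **Bounds.** Lengthscales within 10³ of their initialisation (prevents
  degenerate flat or spiky fits on short series); `σ_n²` within
  `[10⁻⁹, 10]·σ_s²(init)`.
* **Conditioning.** If the Cholesky factorisation fails, diagonal jitter
  starts at `10⁻⁸·σ_s²` and escalates tenfold up to `10⁻⁴·σ_s²`, after
  which an error reports the conditioning problem.
* **Duplicate inputs.** Exactly duplicated input rows are collapsed by
  averaging their targets before fitting. Exact duplicates make `K`
  singular, and under marginal-likelihood training they drive `σ_n²` to
  its floor (duplicate consistency mimics zero noise), after which a
  tiny-lengthscale interpolant attains arbitrarily high likelihood via
  the jitter floor. Averaging is the standard remedy and matches the
  same-day averaging convention used when merging sensor streams.

Trained models serialise to JSON (hyperparameters, centred training set,
centre, band metadata), making retrieval models portable artifacts.

## LAI retrieval

Per sensor dialect — 10 bands (blue through SWIR including red edge) or
6 shared bands — a GPR model is trained on paired (reflectance, LAI)
samples and applied per table row or per pixel, returning LAI and its
predictive standard deviation. The 6-band training set is obtained from
the 10-band one by selecting the shared-band columns by nearest centre
wavelength (10-band B2,B3,B4,B8A,B11,B12 → 6-band B2…B7); with synthetic
spectra a column selection is the exact analogue of resampling to the
coarser band set. Negative LAI predictions are clipped to zero with a
logged count (physical non-negativity); NaN reflectance propagates to NaN
LAI and is never imputed at this stage.

## Time-series collections

* **Merging.** The union of both sensors' dates, sorted; observations
  closer than half a day are averaged into one sample tagged `both`.
  Merging is commutative and idempotent on its own output, and the merged
  time axis is strictly increasing.
* **Savitzky–Golay smoothing.** Window of 7 consecutive observations,
  quadratic fit, evaluated at the window centre. The window is
  index-based, not day-based: the acquisition axis is irregular, and a
  fixed observation count is the standard convention for unevenly spaced
  series. At the edges the window shrinks symmetrically; below
  `degree+1` points the fit would interpolate, so the value is left
  unchanged. The filter reproduces any quadratic-in-index signal exactly.
* **GPR gap-filling.** A 1-D GP in time fitted to the merged series and
  evaluated on a regular grid (default 10-day spacing) anchored at the
  first observation — a reproducible origin that avoids calendar
  alignment ambiguity. The output carries the predictive sd, which grows
  inside observation gaps.

The four analysis collections are `S30`/`L30` (each single-sensor stream
SG-smoothed), `SL30_SG` (merge → SG) and `SL30_GPR` (merge → gap-fill).
Smoothing of the merged stream happens in a single pass after merging.

## Season detection and LSP metrics

Candidate peaks are local maxima with prominence ≥ `prominence_frac` ×
(series max − min); among peaks closer than `min_separation` days only
the largest survives, ties keeping the earlier (determinism). Defaults:
`prominence_frac = 0.30` (the top of the 10–30% range used in this kind
of workflow), `min_separation = 90` days, `amplitude_frac = 0.30`.
Flanking minima are located between consecutive kept peaks or toward the
series ends.

**Incomplete seasons.** A series that starts mid-green-up or ends
mid-senescence does not contain the full cycle, and no season should be
computed from it. A naive "crossing outside the series" rule never
triggers, because the truncated endpoint itself becomes the flank
minimum and the threshold level adapts to it. The operative rule: when a
flank minimum sits on a series endpoint, it is accepted only if the
endpoint value has already descended below the season's threshold level
(computed from the lower of the two flank minima as base proxy);
otherwise the season is discarded as incomplete. Flat pre-season
baselines — where the endpoint happens to be the arg-min but interior
samples are equally low — are correctly treated as complete.

**Thresholds.** SOS is the last upward crossing, before the peak, of
`left_min + amplitude_frac × amplitude`; EOS the first downward crossing
after it, both located by linear interpolation between samples (the
grid is ~10-day; day-level metrics need sub-grid precision). The two
methods differ only in the amplitude: the *seasonal* method uses
`peak − mean(flanking minima)` per season; the *relative* method uses one
fixed value, `mean(kept peak values) − mean(their flanking minima
values)`, for the whole series. This peaks-and-troughs reading of the
relative amplitude is the only one that reduces to the seasonal method
when all seasons have equal amplitude. Seasons whose curve never reaches
the fixed relative level are not detected — the designed behaviour that
makes the relative method miss low-amplitude seasons in rotations with
unequal crops.

**Metrics.** LOS = EOS − SOS in absolute days. Area is the trapezoidal
integral over [SOS, EOS] of the curve above the chord joining the curve
values at SOS and EOS, floored at zero. The chord baseline (rather than
a horizontal minimum level) was chosen because the two season shoulders
generally sit at different levels; with SOS/EOS at equal levels the two
conventions coincide. Day-of-year reporting is 1-based via real calendar
dates; a season belongs to the calendar year of its SOS, and a winter
season's EOS falls in the following year. Summary arithmetic on reported
DOY values uses a 365-day wrap (`los = (eos − sos) mod 365`), the
convention of the field's summary tables; across a leap year it differs
from the absolute span by one day.

**Crop labelling.** A season is classed summer if its SOS DOY falls in
[91, 245) (April through August), winter otherwise — winter crops green
up in autumn, or as late as January when delayed. The crop comes from
the planted record (parcel, SOS-year, class) when available, else from
the calendar crop of the matching class whose planting day most closely
precedes the SOS; with no candidate the season is labelled `unknown`,
never dropped.

## Mapping and evaluation

Pixels whose maximum LAI over time does not exceed 1 m²/m² are masked as
non-vegetated. Cropping frequency is the count of seasons with SOS in
the map year. LSP maps are split into summer and winter sets;
single-cropping pixels carry their one season in both sets. Per-crop
statistics use wrap-aware (circular, period 365) means and SDs for
SOS/EOS DOY — winter green-up dates can straddle the year boundary in
degraded scenarios, and circular statistics prevent silent six-month
errors — reported back on the 1–365 scale. The per-collection overall SD
is the unweighted mean of the per-crop SDs rounded to the nearest day.

Detection accuracy matches detected seasons to planted entries within
each (parcel, SOS-year, season-class) cell, one-to-one, greedily by SOS
proximity to the calendar planting day; accuracy is 100 × detected /
planted rounded to integer percent, with totals summed over crops and
unmatched detections counted separately. The Area–LOS relation is an
ordinary least-squares fit after scaling Area by the table's mean peak
LAI and z-standardising both axes, so a perfectly proportional relation
has slope 1 regardless of season shape (the standardized slope equals
the correlation).

## Synthetic generator

Truth curves are sums of per-season double-logistic pulses on a constant
base (default 0.2 LAI): a sigmoid rise and a sigmoid fall, scaled so the
pulse maximum equals the crop's peak LAI (defaults: rice 5.5, maize 5.0,
wheat 4.5, clover 4.0 m²/m², ±10% seeded jitter; planting/harvest days
jittered ±5 days). The pulse shape is class-dependent, anchored on the
crop calendar's planting–harvest window `L`:

* summer crops: inflections at 0.30·L and 0.80·L, 10–90% transitions
  over 0.25·L / 0.20·L — green-up roughly a month after planting and a
  threshold-level season of ~60% of the window (~90 days);
* winter crops: a symmetric domed pulse, inflections at 0.15·L and
  0.85·L with 0.28·L transitions — a high winter canopy held for most of
  the half-year cycle (~140–170 days at the 30% level) with a unique
  central maximum, which keeps truth peaks of consecutive seasons more
  than 140 days apart so the 90-day separation rule is satisfiable by
  construction.

Each season records its true 30%-amplitude crossing days (solved by
bisection to 1e-8 day), the reference against which SOS/EOS recovery is
scored. Acquisition schedules emulate a 5-day and a 16-day revisit with
±1-day uniform jitter, Bernoulli cloud-gap dropout, and additive Gaussian
observation noise (0.3 LAI in the default noisy scenario — a plausible
magnitude for retrieval plus surface heterogeneity at parcel scale; the
source system's actual noise level is not published, so this is a free
parameter of the generator). Scenes rasterize parcel polygons onto a
pixel grid (noise drawn per parcel or per pixel); spectra–LAI training
pairs come from a fixed monotone forward model per band,
`r(LAI) = r_veg + (r_soil − r_veg)·e^{−k·LAI}`, with band-specific soil
and dense-canopy asymptotes (red decreasing, NIR increasing, saturating)
— monotone and invertible, so retrieval parameter recovery is
well-posed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no radiative transfer (the forward model is a
caricature with exact monotone structure), no atmospheric or BRDF
effects, no spatially correlated cloud masks (dropout is independent per
date), no mixed pixels or parcel-boundary effects, no within-parcel
heterogeneity beyond white noise, and crop curves that are exactly
double-logistic (real canopies have irregular management events such as
cuts and irrigation pulses). Detection accuracies near 100% on clean
synthetic scenes therefore validate the machinery, not field
performance.

## Study conditions and problem sizes

The reproduction script (`scripts/acceptance.py`) and the acceptance
tests run: a clean-sampling study (8 parcels, 2 years plus the closing
spring, no noise, no gaps); a degraded-sampling study (20 seeded
scenarios × 8 parcels: dense 5-day and sparse 16-day streams, both with
40% dropout and 0.3-LAI noise) reporting median per-collection detection
accuracy; phenology recovery on 10 noiseless and 50 noisy double-cropping
parcels; and a 12-parcel Area–LOS regression on the merged gap-filled
collection. These sizes keep a full run in the minutes range on one CPU
while leaving enough seasons (hundreds) for stable medians.

## Known limitations

* The GPR engine is exact (dense Cholesky); series of a few hundred
  points are instant, but the per-pixel mapping path deliberately reuses
  per-parcel fits rather than fitting every pixel.
* The relative method's amplitude uses kept peaks only; very noisy
  series where no peak passes prominence yield no seasons rather than
  falling back to a weaker criterion.
* Circular SDs approximate linear SDs only for concentrated samples —
  adequate for within-crop spreads of a few weeks.
* Season-class assignment is calendar-driven (SOS DOY window); exotic
  calendars with summer planting after September would need a different
  split.
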