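# Methods

This note records the models, conventions and open design choices
behind `soilmulch`, in the order the pipeline runs.

## Mulch hydrological indices

The infiltrometer reduction takes the ring area `S` in cm² and refill
volumes `Q` in mL, so `Q/S` is a water depth in cm and the printed
factor 10 in `V = 10·Q/(S·T)` converts it to mm; only this unit
reading makes `V` come out in mm s⁻¹. The steady plateau has no
universally agreed definition ("infiltration slowed and began to
stabilize"), so we use an explicit rule: scanning from the last step
backwards, a step joins the plateau while its rate is within 10%
(relative, configurable) of the running plateau mean, and a plateau
must span at least two steps. SPR is the plateau mean. IPR defaults
to the mean of the pre-plateau steps; a first-step-only variant is
exposed because some labs report that instead. For a constant-rate
trial the whole series is the plateau and IPR = SPR by construction.
The ring area is always a required input — ring sizes vary between
instruments and defaulting one silently would corrupt every rate.

The soak-and-drain indices are plain ratio arithmetic on the four
weighings; the water-loss rate SWL is averaged over the fixed 24-h
drain window (the drain duration is protocol metadata, not a model
parameter). The weight ordering `G_d ≤ G_n ≤ G_a24` and
`G_l24 ≤ G_a24` is validated because a violation almost always means
two weighings were swapped on the bench sheet.

## Daily profile metrics

The "0–30 cm profile" series is the unweighted mean of the four
sensor depths (5/10/20/30 cm) at each timestamp. No depth weighting
is implied by profile-mean language in field reports, so unweighted
is the default; a thickness-weighted variant is available. Days are
civil days (local midnight boundaries). DMnT/DMxT are the extremes of
the profile-mean series within the day — not the mean of per-depth
extremes, which is larger whenever depths peak out of phase; the
per-depth-range variant is exposed as an option. Days with fewer than
80% of the expected samples (expected count inferred from the modal
sampling interval unless given) are flagged and excluded from period
statistics; no gap-filling is attempted. Timestamps missing any
configured depth are dropped before aggregation so the profile mean
is always over the same depth set.

## Irrigation events and the water balance

Irrigation timing is treated as unknown (spray irrigation "when
drying was observed" leaves no log), so events are detected from the
moisture stream itself: an event opens where the profile-mean
moisture rises by at least δ (default 1.5 v/v points) within a search
window (default 6 h); onsets closer than the window merge into one
event. θ_IB is the last reading before the onset, θ_IA the
post-infiltration peak. A known irrigation log can bypass detection
(`events_from_log`).

Consumption uses three 100-mm layers over 0–30 cm; each layer's
moisture is the mean of its bounding sensors (0–10 ← {5,10 cm},
10–20 ← {10,20}, 20–30 ← {20,30}), a configurable mapping. Negative
interval consumption (net gain from redistribution or percolation) is
kept and flagged rather than clipped so that the season total is
exactly the sum of its parts.

The extraction pattern is defined on moisture *reduction*: each
layer's Δθ·h as a share of the profile total. It is reported per
sensor depth with thicknesses from midpoint boundaries (0–7.5,
7.5–15, 15–25, 25–30 cm → 75/75/100/50 mm), again configurable.
Intervals with non-positive total depletion carry no extraction
signal and are excluded with a warning.

## Agronomic indices

WUE and the taste index are computed both as per-sample means of
ratios (default when replicates exist) and as ratios of treatment
means. Published tables rarely state which estimator they used and
the two differ under replicate skew, so both are always reported.
Report-style rounding is one decimal for indices and temperatures,
integers for WUE.

## ANOVA and Duncan letters

The one-way ANOVA is the classical fixed-effects decomposition. The
Duncan critical range for a stretch of `p` ordered means is
`R_p = q(1−(1−α)^{p−1}; p, df_e) · √(MS_e/n_h)` with the studentized-
range quantile taken from `scipy.stats.studentized_range` rather than
printed tables, so results are reproducible to machine precision.
Unequal group sizes use the harmonic mean `n_h` (the designs this
serves are balanced; the harmonic mean is the standard
generalization). The sequential protection rule — a pair inside any
non-significant stretch is itself non-significant — makes the
non-significant relation interval-structured on the sorted means, so
the compact letters (maximal non-significant stretches, 'a' on the
largest mean) encode the pairwise decisions exactly. The replication
unit is the caller's choice: days for sensor-derived metrics, plants
or fruits for outcome tables.

## The synthetic season

The generator emulates the *regimes* of a winter greenhouse mulching
trial, not any measured series:

- **Temperature** is the classical damped-harmonic ground solution:
  a seasonal cosine (mean 19 °C, amplitude 2 °C, coldest 25 December)
  plus a diurnal wave of surface amplitude A₀ = 7 °C peaking at
  14:00, damped by `exp(−z/d)` and phase-lagged by `z/d` with damping
  depth d = 10 cm. These constants put the bare-soil profile daily
  range near 3 °C and profile means near 17–19 °C — typical winter
  greenhouse magnitudes.
- **Moisture** per depth is a bucket: each irrigation refills
  instantly to 95% of field capacity (36 v/v %), then decays
  exponentially toward the wilting point (14 v/v %) with rates 0.10 /
  0.06 / 0.035 / 0.02 d⁻¹ at 5/10/20/30 cm — drying fastest at the
  surface. There is no coupled vertical flow: the water-balance
  arithmetic consumes only θ snapshots, and a bucket keeps every
  truth quantity closed-form.
- **Treatments** scale the diurnal amplitude (mulch buffers the
  swing), shift the mean temperature and scale the drydown rate
  (mulch slows evaporation). The default four treatments are
  illustrative parameterizations reproducing the qualitative ordering
  of such trials (bare: widest DTR, driest; grass: narrowest,
  wettest; bran: warmest); they are not fitted to measurements.
- **Outcomes** are per-plant/per-fruit normal draws (12 each per
  treatment) around treatment means with magnitudes typical of
  greenhouse fruit tomato, clipped at 5% of the mean to stay
  physical.
- **Schedule**: eight irrigations, the first 10 days into the season
  and then every 16 days, so the first event's drawdown is already
  well above the detection threshold.
- **Noise**: Gaussian, SD 0.3 °C and 0.2 v/v points, added after the
  bounded pre-noise signal.

Ground truth (event times, bracketing θ per depth, per-interval layer
consumption) is evaluated from the closed forms *on the sampling
grid*, so at zero noise the pipeline must recover it exactly and does.
The default season is 136 days at 10-minute sampling (~1.25 M
readings); tests mostly use a 5-week, 30-minute variant, since the
aggregation metrics are insensitive to the interval.

What passing synthetic tests do **not** show: robustness to sensor
drift and dropout, to irrigation water arriving at depth with delay
(infiltration is instantaneous here), to lateral inhomogeneity, or to
real evapotranspiration dynamics. Those require field data.

## Numerical and degenerate-input conventions

- SMEP interval shares sum to 100 by construction; the normalization
  check is at 1e-9.
- A single infiltrometer step yields a rate but no plateau (SPR is
  NaN).
- All-constant ANOVA groups with unequal means give F = ∞, p = 0;
  identical groups give F = 0, p = 1.
- Detection requires δ > 0; a monotone drydown returns an empty event
  list with a warning, and downstream SWC then refuses to run (it
  needs ≥ 2 events).
- Ties in Duncan sorting are broken by the stable sort of group
  labels; letters are invariant to relabeling up to renaming.

## Known limitations

Evaporation and transpiration are not partitioned; there is no
Richards-equation flow, no mulch-decomposition dynamics, and the
taste index is an empirical palatability score, not a sensory model.
The water-consumption accounting sees only the root zone between
irrigations: deep percolation shows up as negative consumption
(flagged) rather than being modelled.
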