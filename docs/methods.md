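# Methods

This note records the models, the synthetic-data design, the numerical
choices and the known limitations of `colonyflux`, in the spirit of a
package methods appendix. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Behaviour model

Behaviour is a latent first-order Markov chain over three states —
flight, colony, water — on a tumbling 15-s analysis window grid. Two
observation streams are conditionally independent given the state:

* **Wingbeat frequency** (Hz): a zero-inflated gamma. The point mass at
  zero is the probability that a window shows no dominant flapping
  peak; positive values follow a gamma with per-state shape k_s and
  rate θ_s. Flapping flight concentrates tightly around the wingbeat
  frequency; colony and water windows are almost all zeros.
* **Near-colony indicator**: Bernoulli(p_s) on the half-open 500 m
  dichotomy (near ⇔ distance < 500 m). Colony attendance is near with
  probability ≈ 1; at-sea states are mostly far.

Missing values in either stream are marginalised (they contribute a
factor 1 to the likelihood); a window missing both streams is excluded
from budget numerators and denominators.

Inference is exact and from scratch: scaled forward–backward for the
likelihood and posteriors, Viterbi for decoding (ties break toward the
lower state index in the fixed order flight, colony, water), Baum–Welch
over pooled sequences for fitting. The gamma M-step solves
log k − ψ(k) = log(weighted mean) − weighted mean log by Newton
iteration with shape bounded to [1e−3, 1e6]; probabilities are floored
at 1e−6; a state whose expected occupancy falls below one window keeps
its previous emission parameters (with a warning) instead of
collapsing. Initialisation is deterministic and quantile-based (flight
from top-tercile wingbeat windows, colony from near low-wingbeat
windows, water the rest; sticky 0.9-diagonal transitions), which avoids
label switching across runs; fitted states are mapped to behaviours by
mean wingbeat emission (flight) then near-probability (colony), with
exact ties treated as an ambiguous fit and rejected. Budgets use the
Viterbi path (posterior decoding is available as an option): one
coherent path per bird.

Sequences of equal length are batched through forward–backward, which
keeps EM on sixty 4-hour birds (≈ 58k windows) around a second per
iteration.

## Feature extraction

Per window the dorsoventral channel is mean-centred (this removes
gravity and posture offset, and makes the features invariant to
constant channel offsets), Hann-tapered, and a periodogram taken. The
reported frequency is the in-band ([1.5, 8] Hz) peak; dominance is the
power in the peak and its two neighbouring bins over total in-band
power — the neighbours absorb the leakage of tones that fall between
Fourier bins. Dominance below 0.2 is reported as frequency 0 ("no
flapping"); the 0.2 default cleanly separates a flapping tone from
white noise at this window length (noise dominance stays below ≈ 0.18).
Windows shorter than 2 s are missing observations. The 15-s window
holds ≈ 50 flap cycles at 3.5 Hz and divides the 3-minute GPS cadence.

GPS positions are linearly interpolated to window midpoints in a local
equirectangular plane centred on the colony (metre-accurate well beyond
trip scales; distances are reported as haversine on a 6371 km sphere).
Midpoints more than one GPS period outside coverage are missing.

## Energetics

DEE_act = Σ_b MR_b T_b with MR in ml CO₂ g⁻¹ day⁻¹ and the caloric
equivalent 27.63 J ml⁻¹ CO₂, giving kJ g⁻¹ day⁻¹ (mass-specific; an
optional body-mass multiplication gives whole-animal kJ day⁻¹ — which
convention the original calibration used is not stated, so both modes
exist). Because the activity-specific rates themselves are published
only as a table figure, `solve_mr_from_stage_means` calibrates them by
solving the 3×3 linear system of the DEE equation across the three
stage budgets and the published stage DEE means (1.64 / 2.05 / 2.17
kJ g⁻¹ day⁻¹); the `MRConfig` defaults are exactly this solution for
the default budgets (flight 159.2, colony 32.0, water 42.6 ml CO₂ g⁻¹
day⁻¹ — flight by far the costliest, as expected). The solver rejects
singular systems (condition number > 1e8) and non-positive rates.

## Space use

At-sea foraging locations are the GPS fixes whose enclosing window
decodes to flight or water and that lie ≥ 500 m from the colony — a
stand-in for formal area-restricted-search detection, whose algorithm
the source analysis names but does not specify. The utilization
distribution is a binned bivariate Gaussian kernel estimate: points are
histogrammed on a 250 m grid padded by three bandwidths and convolved
with the kernel; the bandwidth default is the normal-scale reference
rule h = sqrt((var_x + var_y)/2) · n^(−1/6) per axis (the default
family of the standard home-range software). The p-isopleth is the
smallest set of highest-density cells with mass ≥ p; its area is cell
count × cell area, its polygons the union of cell boxes (GeoJSON export
in geographic coordinates). Levels default to {0.50, 0.75, 0.85, 0.95},
the union of the two level sets quoted in different places by the
source. For points from a bivariate normal, isopleth area is
proportional to −ln(1−p), so the 95 %/50 % area ratio ≈ 4.32 — used as
a closed-form check.

## Stage statistics

Per-bird outcomes (budgets per behaviour on the raw proportion scale,
DEE, mean T3) are modelled by OLS on sex and breeding stage. The
interactive model is assessed with type III ANOVA under sum-to-zero
contrasts; main effects with type II. Least-squares means are model
predictions averaged with equal weight over the other factor's levels;
pairwise stage differences use Tukey adjustment via the studentized
range (unadjusted p available). Proportions are deliberately not
logit-transformed, mirroring the source analysis (a logit option would
be the statistically safer choice near the simplex boundary). The
paired t-test on body mass uses d = pre − post (positive t = decline),
with explicit handling of zero-variance differences. A constant
response reports F = 0, p = 1 for all terms rather than 0/0.

## Synthetic colony generator

The generator is the package's stand-in for field data and defines the
study conditions; its defaults are the published colony parameters
wherever those exist: colony at 58.4167° N, 146.3167° W; season 19 May
– 27 July 2019; 20/20/32 birds across pre-laying/incubation/chick
rearing with 34:38 females:males; deployments 2.42 d (range 1.77–2.98,
drawn from a truncated normal); GPS every 180 s; acceleration at 25 Hz;
T3 stage mean ± sd 2.66 ± 1.30, 4.71 ± 1.97, 3.16 ± 2.85 pg ml⁻¹
(truncated at zero — the simplest non-negative law matching the two
published moments); masses 392 ± 7 g (females), 425 ± 7.7 g (males),
treated as printed (they may be standard errors in the source; both are
config). The pre-laying budget baseline (0.20, 0.62, 0.18) is a free
parameter chosen so the published stage shifts (+11/+15 flight, −19/−16
colony points, residue renormalised to water) are encoded exactly:
incubation (0.31, 0.43, 0.26), chick rearing (0.35, 0.46, 0.19).

**Behaviour chain.** Per-bird budgets are Dirichlet draws around the
stage budget (concentration 100 — mild between-bird heterogeneity).
The transition matrix is the reversible family P_ij = a·π_j (i ≠ j),
P_ii = 1 − a(1 − π_i) with a = window/dwell: its stationary
distribution equals the target budget exactly (detailed balance), and
`dwell` sets the mean time between switching attempts; realized mean
sojourns are dwell/(1 − π_i). For a general 3-state target no chain can
make every state's sojourn equal while holding an arbitrary stationary
vector (the required no-self-loop jump chain is only non-negative when
no state exceeds probability ½), so this family trades exact-sojourn
for exact-stationarity, which is the property the analysis consumes.

**Dwell default (240 s).** Two constraints pull against each other:
bouts must span several GPS fixes so the interpolated distance stream
can resolve trips (pushes dwell up), while a deployment must contain
many independent bouts for a stable per-bird budget (pushes dwell
down; occupancy variance ≈ 2 π(1−π)·dwell/duration). A design scan
over {180, 240, 420, 600} s against the package's own recovery
invariants selected 240 s: longer dwells leave stage-budget recovery
noisier than 3 percentage points under the scaled study conditions;
180 s breaks the colony/water separation because 3-minute fixes no
longer resolve the shorter trips. Four-minute behavioural bouts are
short relative to real colony attendance; this is a deliberate
consequence of scaling deployments to hours while keeping the
published 3-minute cadence.

**Signals.** Flight windows add a flapping sinusoid at 3.5 Hz (a
plausible mid-sized gull wingbeat; config) with 0.1 Hz per-window
jitter and random phase on the z channel; water adds a 0.3 Hz swell;
all channels carry 0.05 g white noise around 1 g gravity. Trips are
out-and-back along a random bearing with a triangular range profile,
extent = flight speed (10 m s⁻¹) × half the bout, capped at the 40 km
trip range; colony fixes jitter 30 m around the nest. Position is
continuous in time, which matters: drawing trip extents independent of
bout duration makes interpolation smear large distances over adjacent
at-colony windows and visibly corrupts classification.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: irregular sampling, tag gaps and GPS
error; wind/tide effects on movement; diurnal and tidal rhythms in
behaviour; flapping/gliding mixtures, variable wingbeat amplitude and
body-pitch changes; partner coordination at the nest; hour-scale
colony attendance bouts; assay error in T3; any true link between an
individual's behaviour and its hormones (T3 is drawn independently of
the track). Recovery results certify the pipeline's internal
consistency under the stated noise model, not field validity.

**Reproducibility.** Every bird has its own stream keyed by
(CRC32(bird id), root seed), so outputs are bit-identical across runs
and independent of iteration order.

## Problem sizes for the recovery studies

The stage-contrast study runs 20 birds/stage with 4-hour deployments —
a scaled design that keeps a full end-to-end run under a minute — and
averages the least-squares-mean contrasts over 11 independent replicate
colonies. The replicate count follows from a power analysis: one scaled
colony's contrast error has sd ≈ 2.5–3.3 percentage points (measured,
and matching the chain-occupancy arithmetic above), so 11 replicates
bring the Monte-Carlo standard error of the worst contrast to about
one point, a third of the 3-point recovery band. The T3 study uses the
published per-stage deployment allocation (20/20/32); the DEE study
20 birds/stage with Dirichlet(100·budget) individual budgets.

## Known limitations

* The near/far stream is blind below the 500 m radius and degrades at
  trip edges: windows whose interpolated position straddles the
  boundary are the dominant decoding error (water ↔ colony), ≈ 3–4 %
  of windows under defaults, and leave a ≈ −1 point bias in the
  chick-rearing colony contrast.
* EM drives the near/far emission probabilities to their floors
  (p_near ≈ 1 for colony, ≈ 0 for water), making that stream an
  effectively hard switch; with richer real data a covariate model
  would be preferable.
* Type III tests are meaningful only under the sum-to-zero coding used
  here; budgets are analysed on the raw scale by design, so inference
  near 0/1 proportions inherits the usual caveats.
* The respiratory-exchange-ratio correction to flight costs and any
  conversion of T3 to energy units are out of scope.
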