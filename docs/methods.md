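# Methods

## Model

A single grid cell is simulated as a leaky integrate-and-fire (LIF) unit
receiving summed, half-wave-rectified input from six head-direction band
cell populations acting as velocity-controlled oscillators (VCOs). The
membrane follows the explicit Euler recurrence

    Vm(t+dt) = Vm(t) + [I(t) − (Vm(t) − E_L)/τ_GL]·dt

with no reset and no refractory period: at dt = 2 ms those dynamics would
be sub-sample, so a "spike" is simply any sample with Vm > V_t, and several
spike samples may occur within one theta cycle. Analyses that need sparse
spikes (precession, rate correlations) first thin the spike samples to at
most one per membrane theta cycle — the above-threshold sample nearest the
peak of the 5–10 Hz membrane component, with cycles delimited by its
troughs. Rate maps and field classification consume the raw spike samples.

Each VCO population n combines a 6 Hz baseline cosine, phase-offset by
φ_n ∈ {0°,…,300°}, with an active oscillation whose phase accumulates as

    dθ_n/dt = ω_b + g·β·s(t)·cos(Φ(t) − Φ_n),

so the phase lead of the active oscillation over the baseline equals
g·β times the displacement projected on the preferred direction Φ_n —
path integration by phase. The per-step increment is computed from the
step displacement itself (dx·cosΦ_n + dy·sinΦ_n), which makes the
accumulated phase an exact function of position, independent of speed
profile. Phases are initialised to θ_n(0) = φ_n, making the trajectory
start a constructive-interference point; the grid lattice is therefore
anchored at the start position (the arena centre for generated walks).

The interference sum of the two cosines passes through the offset sigmoid
S(x) = 1/(1+e^{−a(x−T)}) − 1/(1+e^{aT}) (a = 4, T = 1), which is zero at
zero input and saturates near S(2) ≈ 0.964. Because of the offset, S is
marginally negative (≥ −0.018) for negative drive; population outputs are
clamped at zero so the drive to the grid cell is genuinely non-negative —
the populations model purely excitatory firing-rate output. A Heaviside
gate silences a population whenever |heading − Φ_n| > 90° (boundary
inclusive), so 3–4 of the 6 populations are active at any instant and all
active oscillators run at or above baseline frequency, which is what makes
spikes precess rather than process.

### Parameters

| parameter | default | meaning |
| --- | --- | --- |
| τ_GL | 0.1 s | membrane leak time constant; the long value lets rectified theta-frequency input integrate into an in-field DC ramp |
| E_L | −67 mV | resting potential (membrane floor, since input ≥ 0) |
| V_t | −56 mV | spike threshold; co-adapted to τ_GL in the sweep (−66 + τ_GL/10 mV for τ_GL in ms over 10–100) |
| ω_b | 2π·6 rad/s | baseline theta frequency |
| φ_n, Φ_n | 0°…300° | baseline phase offsets and preferred headings, both in 60° steps |
| β | 0.002 (0.00385 transect) | grid-spacing scale factor |
| g | 30 | dimensionless phase gain; g·β is the band wavenumber in rad/cm |
| a, T | 4, 1 | sigmoid slope and inflection |
| G_I | 100 | input scaling |
| dt | 0.002 s | global time step; trajectory, cell and analyses all validate against it |

**Calibration of g.** The source formulation mixes a phase-valued
expression with a velocity term whose unit convention cannot be
reconstructed, so the absolute grid spacing is not recoverable; `oigrid`
introduces the single dimensionless gain g and calibrates it once against
the only stated geometric anchor: at β = 0.00385 a 200 cm straight
transect must cross exactly two discrete firing fields. With g = 30 the
along-track field spacing is 4π/(g·β) ≈ 109 cm (fields at the start and
~+9 cm; a third would fall just beyond the far wall), and at the default
β = 0.002 the hexagonal spacing is 4π/(√3·g·β) ≈ 121 cm — a sparse grid in
the 200×200 cm arena: one central field plus the inner ring of six partly
visible at the walls. Consequences of this (unavoidably pinned) sparse
scale are flagged under "Limitations".

## Trajectories

The open-field walk follows the momentum recurrence
Δx(t) = s(1−m)p + mΔx(t−1) per axis (p ~ N(0,1); s = 1.7, m = 0.999,
dt = 2 ms), starting at the arena centre with the conventional initial
movement vector (0.35, 0.35). That seed step implies a 2–4 s high-speed
transient before the stationary regime (mean speed ≈ 23 cm/s) — retained
deliberately as part of the stated generator. A step that would exit the
±100 cm arena is reversed and scaled by R = 0.6; if the reversed step still
exits (corner case) the position is clamped to the wall. Straight-line
trajectories move at constant velocity (5 cm/s by convention for the
transect figures; the speed is a parameter since the sources state both 5
and 10 cm/s). Recorded trajectories are plain `t,x,y` CSV at a uniform
step (typically 0.02 s), linearly interpolated down to 2 ms; the target
step must divide the source step.

## Analysis conventions

**Field classification.** 5 cm bins; the null distribution per bin comes
from 1000 circular rotations of the whole spike series by a uniform
integer in [0.05N, 0.95N]. The per-bin percentile is the fraction of
shuffles with rate *strictly below* the observed rate. Ties therefore
count against the observation: a never-firing bin scores 0 and can
classify as below-chance. (The alternative convention — ties count as "not
higher" — makes the out-of-field criterion unsatisfiable here: over 13% of
rotations leave any given bin without spikes, so no bin can ever fall
below the 5th percentile.) In-field bins are those in any 3×3 block wholly
at or above the 85th percentile, extended one bin (8-neighbourhood, single
pass) at the 70th; out-of-field bins are those in any 2×2 block at or
below the 5th. Bins visited for fewer than 2 samples are excluded from
rate maps.

**Amplitude series.** Both bands use 2nd-order Butterworth filters applied
forwards and backwards (zero net phase), with reflective padding of three
time constants of the low band edge; series shorter than three settling
lengths are rejected. The trace mean is removed before filtering. For
Δamp the DC series is re-centred on its out-of-field mean and the first
and last 2 s are excluded from all means (filter edges). Δamp_DC is then
the in-field mean of the DC series; Δamp_MPO the in-field minus
out-of-field mean of the theta envelope.

**Field index and pass index.** The field-index map is a 1 cm
occupancy-normalised rate map smoothed with a 5-bin-SD Gaussian
(nearest-edge padding, so a uniform map stays uniform and min–max
normalisation degenerates to zeros with a warning) and normalised to
[0, 1]. The pass index is the analytic-signal angle of the mean-centred
field-index series; mean-centring is required because the raw series is
non-negative and its positive mean would otherwise dominate the Hilbert
phase.

**Circular–linear correlation.** The regression slope (cycles per unit)
maximises the resultant of phase − 2π·a·x over a dense grid (default
bounds ±2 cycles across the observed range) with bounded refinement; rho
is the circular–circular correlation between the measured phases and
2π·|a|·x, so phase falling along x yields negative rho; the p-value uses
the standard large-sample normal approximation. Fewer than 5 spikes →
undefined (NaN).

**Rate correlations, MI, Steiger.** Per-ISI records pair 1/ISI with the
interval means of each amplitude series, pooled over ten one-minute
simulations; binned variants average rate in 8 equal-width amplitude bins
(empty bins dropped, sparse bins kept). The sliding-window protocol counts
thinned spikes in 1 s windows stepped one sample at a time, normalised by
each simulation's mean rate. Mutual information uses the plug-in estimator
on an 8×8 equal-width joint histogram (bits); the reported quantity is the
per-simulation ratio MI(DC; field index) / MI(MPO; field index), whose
ratio form is much less estimator-sensitive than the absolute values. MI
simulations are ten minutes long: at the calibrated grid scale a one-minute
walk undersamples the field-index map so badly that map noise dominates the
estimates. Differences between the two dependent correlations are tested
with Steiger's Z_H (shared-variable form, Fisher-transformed, using the
mean of the two correlations in the covariance term); the implementation
was checked against a Monte Carlo null calibration (Z ~ N(0,1) when the
true correlations are equal).

**Gridness.** The spatial autocorrelogram is the overlap-normalised
Pearson correlation at every 2-D lag (FFT-evaluated; lags with < 20
overlapping valid bins are undefined). The scoring annulus runs from the
central peak's first zero crossing to 1.25× the median distance of the six
nearest surrounding autocorrelogram peaks (fixed fractions of the map size
as fallback). Annulus values are sampled on a polar grid and correlated
with copies rotated by 30°…150°; score = min(r60, r120) − max(r30, r90,
r150).

**τ_GL sweep.** For each τ_GL in 10–100 ms (V_t co-adapted by +1 mV per
10 ms, or held at −65 mV for the comparison condition) fresh random-walk
simulations are classified and summarised by the mean of per-episode
in-field DC maxima and the mean in-field theta envelope, optionally with
gridness. The packaged tests run a reduced sweep (4 τ values × 2
repetitions × 20 min walks, 300 shuffles) — sizes chosen to make the
monotonicity and saturation trends unambiguous; the full 50×10-min design
is available through the same function. Reliable in-field detection needs
long sessions: at this grid scale 3×3 blocks of above-chance bins only
consolidate after ~10–20 min of coverage, so very short sweep repetitions
can yield no classified fields (such repetitions are skipped and counted).

## What the generated data do and do not emulate

The random-walk generator reproduces the study conditions (arena size,
step statistics, wall avoidance, mean speed) and the model is fully
deterministic given a trajectory — there is no membrane or synaptic noise,
no spike-waveform dynamics, no extracellular contamination (the
`add_field_rhythm` helper adds a fixed-frequency sinusoid to emulate the
latter). Passing tests therefore show that the *pipeline* recovers the
model's structure, not that real grid cells behave this way: real
recordings add noise sources, theta frequency drift, firing-rate
adaptation and head-direction tuning widths that this generator does not
model.

## Known limitations

* **Absolute spatial scale.** Only the two-fields-per-transect anchor
  constrains g, which pins a sparse (~120 cm) grid in the 200 cm arena.
  Quantities that depend on the ratio of field size to arena — how much
  out-of-field area carries subthreshold band-ridge depolarisation, how
  long field dwells last relative to the 0.1 Hz filter edge — inherit that
  choice. In particular the theta envelope is nearly as informative about
  firing rate as the DC series here (per-ISI unbinned r ≈ 0.6–0.7 for
  both; sliding-window r_MPO slightly exceeds r_DC), whereas sparser
  out-of-field theta statistics at other scales can widen the gap in
  favour of the DC series. The binned DC correlation (~0.96), the Δamp
  values (~2 mV vs ~1 mV) and the MI ratio (~1.3) are scale-robust.
* **Gridness under threshold mis-adaptation.** With V_t held at −65 mV and
  τ_GL = 100 ms the cell fires on ~98% of samples, yet the
  contrast-normalised autocorrelogram still amplifies the residual
  hexagonal structure of the interference dark zones, so the gridness
  score does not collapse; a collapse requires bin-level saturation, i.e.
  a grid period comparable to the 5 cm bins.
* **Whole-session precession is diluted.** Within any single field pass the
  spike phase falls by ~1 rad, but the phase offset at the centre of a
  pass depends on the traversal heading (the baseline offsets equal the
  preferred headings, so the grid cell's theta phase shifts with the
  active ensemble) and on chord geometry. Pooling a whole 2000 s session
  into one regression therefore yields |rho| ≈ 0.05. Short analysis
  stretches (~80 s, the convention adopted here) show clear negative rho,
  though significance varies between realisations; `segmented_precession`
  combines per-segment statistics with Stouffer's method for whole-session
  inference. The straight-line transect, free of these geometry effects,
  shows near-perfect precession (rho ≈ −0.99).
* The bootstrap percentile's strict-inequality tie rule slightly deflates
  both tails for discrete spike counts; the uniform-spiking calibration
  test quantifies this.
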