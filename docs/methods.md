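# Methods

## The measurement problem

A larval zebrafish, immobilised in agarose with one eye 1 mm from a miniature
OLED display, watches a small cross-shaped glyph (5 lit pixels, 0.63 mm outer
extent) shuttle along a horizontal 6.3 mm track at 2.1 mm/s — the speed
follows from the animation advancing one 0.21 mm pixel pitch every 0.1 s.
Calcium activity in the optic tectum is recorded through a genetically
encoded indicator (GCaMP-class) at one frame per 50 ms (20 ms exposure +
30 ms gap). Each approach of the glyph evokes one fluorescence transient
once the glyph comes close enough to be seen.

The quantity of interest is the **detection distance (DD)**: the
eye-to-stimulus distance at the moment the first tectal response appears.
Because the screen is parallel to the fish, the eye, the point on the screen
opposite the eye, and the glyph form a right triangle, and

    DD = sqrt((x_onset - b)^2 + d_es^2)

where `x_onset` is the glyph's lateral track position at response onset, `b`
the lateral coordinate opposite the eye (default 0 — the track terminates
opposite the eye; configurable) and `d_es` the eye–screen distance (1 mm).
Three further peak-shape parameters are measured per transient: duration
(onset to offset), FWHM (width at half the amplitude above baseline) and the
inter-peak interval (offset of one transient to onset of the next). All four
are compared across three temperature treatments (18, 23, 28 °C).

## Stimulus trajectory model

The glyph follows a triangular wave: approach (decreasing lateral position
`x` at constant speed), a dwell at the near end, recede, a dwell at the far
end, for 10 cycles. Ten cycles in a 2-minute presentation imply a 12 s cycle
period, while a 6.3 mm round trip at 2.1 mm/s takes only 6 s; the remaining
6 s per cycle is modelled as dwell, split equally between the two track ends
(configurable via `dwell_per_cycle`). The discrete 0.1 s pixel jumps are
treated as continuous motion, consistent with deriving the 2.1 mm/s speed
from pitch/jump-interval in the first place.

`first_time_within(dd, cycle)` inverts the trajectory analytically: on an
approach leg starting at `x_start`, distance ≤ `dd` is first reached at
`x = b + sqrt(dd^2 - d_es^2)`, hence at
`t = t_leg_start + (x_start - x)/speed`. No grid search is involved; a
0.1 ms grid-scan oracle confirms it in the tests.

The display's printed angular quantities are documented but not used in any
computation: a 0.63 mm glyph at 1 mm subtends ~35°, not 2.22° (2.22° arises
at ~16.3 mm viewing distance), and 2.1 mm/s lateral motion at 1 mm reaches
120°/s at closest approach, not 20°/s. `angular_size` and `angular_speed`
implement the standard formulas (`2*atan(w/2d)`; `v*d_es/(d_es^2 + (x-b)^2)`).

## Synthetic recordings

The generator is the package's test bed and its default data source; no
recordings ship with it.

* **Kernel.** Each transient is a double-exponential impulse response
  `(1 - exp(-t/tau_r)) * exp(-t/tau_d)`, normalised so its maximum equals the
  requested peak ΔF/F; the peak time has the closed form
  `tau_r * ln(1 + tau_d/tau_r)`. Defaults: `tau_r` = 0.05 s; `tau_d` = 0.7 s
  at 28 °C, scaled up at lower temperature (1.0 s at 23 °C, 1.4 s at 18 °C) so
  transient widths sit on the seconds scale.
* **Events.** One event per approach leg, at the analytic first-crossing
  time of the trial's ground-truth DD, plus an optional detection-to-
  fluorescence latency (default 0; exposed so its bias — every millisecond of
  latency shrinks the estimated DD by `speed * latency` — can be studied).
  No response on receding legs.
* **Amplitude and noise.** Baseline 100 a.u.; amplitudes 0.25/0.16/0.15
  ΔF/F at 18/23/28 °C put F_max/F_base in the 1.15–1.26 range; additive
  Gaussian noise with SD 2% of baseline. Shot (Poisson) noise, bleaching and
  motion artifacts are deliberately not modelled — they are not identifiable
  from the study design this emulates — so passing tests demonstrate
  correctness of the measurement chain, not robustness to every nuisance of
  real microscopy data.
* **Treatment model.** Per-fish DD drawn from a treatment Normal (means
  5.5/4.8/3.5 mm, SD 0.6 mm) truncated to the geometrically attainable
  [1, 6.38] mm. The means encode the qualitative finding the defaults are
  meant to reproduce: DD and transient duration fall, inter-peak interval
  rises, with temperature.
* **Image stacks.** `render_stack` paints the trace onto a ring annulus
  (expected pixel value = trace value) over a flat background with optional
  Gaussian read noise, giving an exact extract→trace round trip at zero
  noise.

Everything stochastic is driven by a `numpy.random.default_rng(seed)`;
identical seeds give bit-identical outputs.

## ROI extraction

The ROI is a ring (default 10 µm outer diameter, 1 pixel thick — thickness
is not constrained by the acquisition description, so it is configurable) and
a pixel belongs to it when its centre distance from the ring centre lies in
`[r - t/2, r + t/2]`. Note this band admits diagonal neighbours for small
rings. The trace is the per-frame mean over ring pixels (linear in the
stack). ROI placement maximises the F_max/F_base response score over a
candidate grid — an exhaustive, deterministic stand-in for the manual
screening of the responsive tectal region; ties break toward the smallest
(row, col).

## Peak detection and metrics

Detection is two-pass and parameter-light:

1. Provisional baseline: rolling 20th percentile (15 s window); robust noise
   `sigma = 1.4826 * MAD` of the residuals.
2. Candidate maxima: topographic prominence ≥ `5 * sigma` (configurable),
   minimum separation 1 s (the stimulus cycle is 12 s).
3. Onset/offset: threshold crossings of `f_base + k * sigma` (default
   `k = 2`) nearest each maximum, linearly interpolated between frames. The
   beginning/end of a transient has no canonical definition in this kind of
   data; `k` is the single most influential convention in the pipeline and
   is deliberately prominent in the API. Crossing searches are confined
   between neighbouring maxima; if the trace never returns to threshold the
   inter-peak valley serves as the boundary, which keeps transients
   non-overlapping by construction.
4. Final baseline: median of all samples outside the provisional transients;
   crossings are re-derived against it.

At zero noise the threshold degenerates to `f_base` exactly; since the
kernel never re-crosses its own baseline, zero-noise offsets sit at the
inter-peak valleys and durations span nearly the whole cycle. Onsets — and
therefore DD — are unaffected (error ≤ one frame). DD estimates carry a
small positive bias bound of `speed * frame_period` (0.105 mm at defaults):
onset interpolation lands within one frame before the true crossing.

Double tops (two maxima closer than 1 s whose valley stays above half the
lower amplitude) are merged into one transient. Artifact rules, each
switchable: duration under 2 frames; amplitude above 5× the trial's median
peak amplitude (a robust gross-spike criterion); onset before stimulus
motion. After flagging and merging, only the first five transients enter the
analysis, mirroring the trial design of ten evoked peaks of which the first
five are scored. Peaks whose onset falls on a receding leg or dwell
contribute shape metrics but no DD — detection is only defined on an
approach.

No smoothing is applied by default; all metrics except F_max/F_base are
invariant under affine rescaling of the fluorescence axis (the ratio is
invariant under pure scaling only).

## Statistics

Per parameter, with the peak as the default statistical unit (per-trial
means are also emitted):

* skewness screen per group (adjusted Fisher–Pearson, the SPSS convention);
  any group with |skewness| ≥ 2 routes the parameter to the nonparametric
  path;
* parametric path: Levene's test (mean-centred; median optional), then
  one-way ANOVA under homogeneity or the Brown–Forsythe robust F*
  (Satterthwaite df) otherwise; pairwise Scheffé (pooled variance, p from
  `F_{k-1,N-k}` of `t²/(k-1)`) under homogeneity, Tamhane T2 (Welch t,
  Šidák-corrected) otherwise. A `posthoc_assignment="as_published"` switch
  swaps the pairing for comparison purposes;
* nonparametric path: Kruskal–Wallis with mid-rank tie correction and Dunn's
  z-tests (tie-corrected variance), Bonferroni-adjusted by default (Šidák or
  none optional);
* α = 0.05 throughout.

Under the null (three Normal groups, n = 20), both omnibus tests reject at
4–5% over 2000 replicates — inside the [0.035, 0.065] calibration band the
tests enforce.

## Problem sizes

The defaults everywhere are the study's own scale: 3200-frame trials
(160 s at 50 ms), 10 cycles, 20 trials per treatment, 100 Monte-Carlo
replicates for the ordering checks, 2000 for null calibration, 50 random
configurations for DD recovery and FWHM oracles. The whole acceptance
computation runs in about half a minute on one CPU.

## Known limitations

* Real recordings include motion, bleaching, focal drift and shot noise the
  generator omits; results on synthetic data bound the measurement chain's
  error, not biological variability.
* The onset convention (`k = 2` noise SDs) is an assumption, not a
  reconstruction of the original analysis, whose findpeaks parameters are
  unknown; DD shifts by up to `speed * (time for a transient to climb from
  0 to k*sigma)` for other conventions.
* Neural/indicator latency is not corrected by default; the latency
  parameter exists precisely to quantify that confound.
* `fmax_fbase` uses the global inter-transient baseline, so slow drifts
  would bias it; a drift hook is out of scope.
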