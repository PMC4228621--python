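# Methods

## The problem

Acoustic surveys identify bat species from their echolocation. With
zero-crossing (frequency-division) detectors a recording is a series of
time–frequency points ("dots"): one point per N cycles of the signal
(division ratio N, conventionally 8), with no amplitude information. A run
of dots from one emission is a *pulse*; pulses separated by less than one
second form a *pulse sequence*, the unit that carries a species label.

The identification chain this package implements is:

1. **Filtering.** A filter is a rule set that both selects sounds and
   triggers their measurement. Pulse-level rules test smoothness, a
   high-frequency start, per-dot frequency-change bounds, parameter ranges
   and linear guards in feature planes ("synthetic lines"); sequence-level
   rules require a minimum number of calls within a time window, minimum
   spacing between calls, and reject call pairs separated by tiny gaps.
   Four presets (BM, BCID, WEST1, WEST2) span permissive to strict
   behaviour. Filter output is accepted in toto — no manual vetting.
2. **Measurement.** The *body* of a pulse is its flattest contiguous
   portion, found by minimizing the absolute endpoint slope (octaves/s)
   over all dot segments at least `Body Over` microseconds long (ties:
   longer, then earlier). The classifier covariates are pulse duration
   (Dur, ms), total bandwidth (Sweep = Fmax − Fmin, kHz), frequency at the
   end of the body (Fc, kHz), body slope (Sc, octaves/s, positive for
   down-sweeps), and duration after the body (Tail, ms). Because the body
   search depends on `Body Over`, different filters measure the *same*
   pulse differently — one of the central effects the package exposes.
3. **Classification.** A quadratic discriminant model: each species k gets
   a Gaussian N(mu_k, Sigma_k) over the covariates (unbiased per-class
   covariances) with equalized priors. A pulse is assigned by highest
   posterior; a sequence is assigned to the species winning a *strict*
   majority (>50%) of its pulses' votes, else labelled UNKNOWN. Covariates
   are pre-screened so no pair has Pearson R² ≥ 0.5 (drop the member of
   the worst pair with more correlated partners; ties drop the later
   column).
4. **Validation.** Internal: sequence-level leave-one-out (remove all of a
   sequence's pulses, refit, classify it). External: fit on one library,
   classify an independently collected one. Rates per species i over N_i
   sequences: correct n_i/N_i, incorrect n_j/N_i, unknown
   (N_i − n_i − n_j)/N_i; overall rates are the *unweighted* mean across
   species. 90% confidence intervals come from resampling sequences with
   replacement (default B = 1000 here; smaller B where noted) and taking
   the 5th/95th quantiles of the replicate rates; non-overlapping
   intervals are read as significant. Filter measurement differences are
   compared per parameter with Kruskal–Wallis, then pairwise two-sided
   rank-sum tests under a Holm adjustment, summarized as compact letters.

## Operational stand-ins

The vendor software that popularized several rule names does not publish
its algorithms. The following are documented, swappable predicates, named
for what they do:

- **Smoothness**: for each dot from the third onward, predict its
  frequency by linear (time-aware) extrapolation of the previous two dots;
  the score is the maximum relative deviation in percent, and a pulse
  passes the rule `s` iff score ≤ s. Pulses with <3 dots score 0.
- **High Start**: the first dot attains Fmax within 2 kHz (tolerance for
  zero-crossing quantization jitter).
- **Max Change** "+2, −4": per-dot frequency increase ≤ 2 kHz and decrease
  ≤ 4 kHz.
- **PMC**: body duration as a percentage of pulse duration.
- **S1**: endpoint slope between the first dot and the dot nearest 25% of
  pulse duration (at least the second dot).
- **Synthetic line**: value = y_measured − ŷ, where ŷ interpolates the
  line through the two anchor points at the measured x; pass iff the value
  lies in [min, max].
- **Time for Calls** is read as a sliding window: the sequence survives if
  some window of that length contains the minimum number of countable
  calls (calls counted greedily from the earliest, subject to the minimum
  spacing). Pulses closer than the reject gap are removed pairwise first.
- **Dot-to-pulse grouping** (undefined upstream): dots split where the
  inter-dot gap exceeds 1000 µs (≥5 inter-dot periods of a 40 kHz signal
  at division ratio 8); join-fragments is applied before ignore-fragments
  so fragments that together form a valid pulse are not discarded.

The WEST2 preset's S1 lower bound is 30 octaves/s (WEST1: −30), entered as
specified with no correction; whether that asymmetry is intentional in the
source material is unknowable here, and it is preserved.

Consensus pulses are identified across filters by (file, first-dot time,
last-dot time): filters with different join settings may delimit pulses
differently, and only identically delimited pulses count as the same
pulse. A file's consensus sequences are re-assembled from its consensus
pulses, and only files retained by every filter contribute.

## The synthetic generator

The call libraries this kind of analysis is trained on are not publicly
deposited, so every stage is exercised against a generator that emulates
their statistical structure. What it emulates: per-species distributions
of the five measured parameters (the Indiana bat model uses the published
consensus statistics — Dur 3.2±0.6 ms, Fc 43.8±2.7 kHz, Sc 158.2±40.8
octaves/s, Tail 0.4±0.3 ms, Sweep 24.5±8.8 kHz; the other ten species are
plausibility presets spanning Fc ≈ 20–46 kHz, not measured values);
sequences of ≥5 pulses with interpulse intervals of 60–400 ms; paired
"early/late" sub-libraries whose feature means differ by a configurable
δ in SD units; and three noise classes (broadband clutter, wind-like
low-frequency gust trains, insect-like chirp trains).

**Trajectory solve.** Each pulse is built backwards from drawn targets.
(Dur, Fc, Sc, Tail) are drawn from truncated normals (symmetric clipping
at ±2 SD, narrowed at physical floors, so configured means are preserved
exactly; slope and duration are drawn with correlation −0.6 — independent
draws at realistic SDs frequently describe impossible pulses). The
descent over [0, Dur−Tail] spans Sc·(Dur−Tail) + X octaves, where the
curvature excess X goes into a start-heavy slope profile (polynomial
exponent p = 2) whose *average* slope over the final `design_body_over`
window is exactly the drawn Sc; a terminal drop of duration Tail is made
steep enough (≥1.3× the window-start slope) that the flattest-window
search cannot slide into it. Bandwidth is therefore induced:
Sweep = Fc·(2^Ω − 1) + drop. A one-time fixed-seed Monte-Carlo solve per
model picks the mean and spread of X so the induced Sweep matches the
configured mean and SD; this calibration is a deterministic design
constant, independent of user seeds. Start and tail slopes are capped at
600 and 700 octaves/s: at division ratio 8 a slope s produces per-dot
steps of ≈5.5·s Hz, and steeper trains are not trackable dot sequences.

Dots are placed by the frequency-division recursion
t_{k+1} = t_k + N/f(t_k) on the jittered trajectory (relative frequency
jitter 0.15%), with times rounded to integer microseconds. Two
quantization-centering constants keep measurement unbiased: the trajectory
is extended by half a dot period at the tail-end frequency (so the last
dot lands, on average, at the designed duration), and the designed body
end is pushed a quarter dot period into the tail (the discrete flattest
window ends at the last dot at or before the designed body end). With
these, extracted sample means recover the configured statistics within a
few percent at n = 2000 (the acceptance suite checks 5%).

**The library shift.** The δ knob shifts each feature mean by δ SDs with
alternating signs (Dur +, Fc −, Sc +, Tail −, Sweep +). A same-signed
offset is close to a common translation of the whole community, to which
a discriminant classifier is largely invariant; alternating signs emulate
a genuine change of recording protocol (different detectors, personnel,
sites) that reshapes the feature space. At δ = 1 this degrades external
validation relative to internal cross-validation by ≈10–15 percentage
points on the default community, qualitatively matching what independent
validation libraries show in practice.

**Noise.** Wind files are trains of ~15 decelerating low-frequency gusts
(terminal frequency 10.5–15.8 kHz, bandwidth ~7 kHz, 3% roughness): smooth
and broad enough to pass a permissive filter, but their characteristic
frequency falls below the 15 kHz bound and their roughness above the 10%
smoothness bound of the strict preset. Insect files are long regular
trains of narrowband *up*-gliding chirps at 17–24 kHz: they pass the BCID
rule set but fail high-start and the S1 bound. Clutter is i.i.d. dots over
10–120 kHz, rejected by smoothness or per-dot change bounds everywhere.
The default mix reproduces the qualitative noise-admission ordering
BM ≫ BCID > WEST1 > WEST2 ≈ 0.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: amplitude effects and echo/fragment artefacts of
real zero-crossing hardware; within-sequence adaptation (approach-phase
shortening); geographic, habitat and behavioural covariates; call-library
label errors; the supplementary per-species parameter tables that were
never available (ten species are plausibility presets). Conclusions about
*relative* filter behaviour and validation design transfer; absolute rates
do not.

## Numerical choices and degenerate inputs

- Body-search ties are resolved by longer duration then earlier start; two
  slopes within a relative 1e-9 are treated as tied, so exactly log-linear
  pulses resolve to the whole sweep.
- Pulses shorter than `Body Over` take the whole pulse as body rather than
  erroring (a 240 µs and a 2000 µs setting must both run on short pulses).
- Posterior computation works in log space with per-class Cholesky
  factors; posteriors are normalized by a log-sum-exp shift. Pulse-level
  posterior ties resolve to the earlier species in the fixed species
  order.
- Covariances use the unbiased (n−1) estimator; a class needs more pulses
  than features + 1, and a singular class covariance raises an error
  naming the species.
- Bootstrap replicates whose evaluation fails (a species stratum vanished
  under resampling) are skipped and counted; more than 10% skipped is an
  error. For external validation only the test library is resampled by
  default.
- Wilcoxon rank-sum tests use the two-sided normal approximation with tie
  correction; Holm adjustment via statsmodels. Compact letters are the
  maximal cliques of the non-significance graph (exact enumeration; the
  group count here is four).
- Fragments reduced to a single dot are always dropped: they carry no
  duration or frequency-change information.

## Problem sizes

The shipped test and acceptance runs use deliberately small designs chosen
to estimate each property well: 11 species × 8 sequences for the pipeline
demonstration; 2000 pulses for parameter recovery; 50 seeds for the
internal-vs-external comparison; 200 worlds × B = 120 bootstrap replicates
(3 species, 12 sequences × 8 pulses, pairwise Mahalanobis distance 1.5)
for interval calibration, with the long-run truth estimated from 300
independent worlds. Bootstrap defaults remain B = 1000 for real use.

## Known limitations

- Ten of the eleven species models are configuration defaults, not
  measured statistics; only the Indiana bat model tracks published values.
- The strict preset's S1 ≥ 30 bound excludes genuinely shallow-sloped
  pulses (and the insect noise) by construction; if the bound is a typo in
  the source material, WEST2 results would change.
- Consensus sequence re-assembly can, for adversarial filter combinations,
  split what a single filter kept as one sequence; under the shipped
  presets and single-burst files this cannot occur.
- The generator's induced-bandwidth calibration matches means tightly and
  SDs approximately; heavily constrained models (quasi-constant-frequency
  species) end up with a narrower bandwidth spread than configured.
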