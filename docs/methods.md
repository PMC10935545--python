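# Methods

`trenchox` simulates *Escherichia coli* growing in mother-machine trenches
under hydrogen-peroxide stress and reimplements the single-cell analyses that
such experiments support: feature extraction, random-forest prediction of
response magnitude, concentration calibration and shielding inference,
cross-correlation lag estimation, lineage-memory statistics, fate
classification and mutagenesis rates.  This note documents the model, its
assumptions, the measurement designs the analyses rely on, and the known
limitations.

## The mechanistic model

A trench is a one-dimensional stack of rod-shaped cells between a closed end
(index 0, the mother cell) and an open end facing the flow channel.  External
H2O2 at concentration `c0(t)` (the treatment schedule) enters at the open
end.

**Shielding.** Scavenging is diffusion-limited: the Damkoehler number for
catalase turnover (5.4e4 s^-1) against envelope permeation (1.6e-5 m/s) over
a 1.2 um cell is ~4e3, so a cell's protective effect scales with its surface
area.  Each live scavenging cell j removes a fraction

    f_j = 1 - exp(-sigma * S_j * E_j)

of the incoming flux, where `S_j` is the envelope area of a hemisphere-capped
cylinder (exactly 2*pi*r*L for this geometry, r = trench width / 2) and
`E_j` in [0, 1] is its scavenging-enzyme level.  The local concentration at a
cell is `c0` times the product of `(1 - f_j)` over every cell between it and
the opening; concentrations therefore decay geometrically with barrier
count.  `sigma` (default 0.055 um^-2) is calibrated so that a wild-type cell
at treatment steady state (S ~ 9.7 um^2, E ~ 0.8) removes about a third of
the incoming H2O2, matching the reported ~32% per-cell attenuation.  Inert
(chemically fixed) and dead cells have E = 0 and do not shield.  Wider
trenches open a disproportionately larger bypass gap around the cells; the
attenuation scale falls as `(1.2 / width)^5`, an exponent estimated from the
ratio of free to cell cross-section area at 1.2 versus 1.4 um and exposed in
the config.

**Intracellular concentration.** `c_int` relaxes quickly (rate 4 min^-1)
toward `c_local / (1 + theta * E)` with theta = 40: induced cells keep their
internal concentration roughly forty-fold below the local one, the negative
feedback through which induction deactivates the response.

**Gene expression.** Enzyme induction senses `c_int` delayed by 2 min
(OxyR oxidation and enzyme synthesis are fast) with a sharp Hill activation
(K = 0.08 uM, n = 2) saturating the steady-state enzyme level; it is diluted
by growth and clamped at a constitutive basal level of 0.15 (Ahp-like
scavenging, which also gives untreated cells a small but non-zero shielding
capacity).  A delta-oxyR cell never induces and stays at the basal level.
The transcriptional reporter is produced per unit cell area at
`basal + max_rate * H(c_int)` (K = 8 uM, n = 1) but senses a concentration
delayed by 12 min -- the extra 10 min is fluorophore maturation, and it
matters: reporter production reflects concentrations *after* the shielding
gradient has formed, which is what makes mother-cell peak amplitudes depend
on their barriers rather than on the uniform pre-gradient transient.  The
reporter is a stable protein: removed only by growth dilution and division
partitioning, so after stress removal its intensity decays exponentially at
the growth rate (half-life = doubling time).  A constitutive marker channel
is produced at a constant per-area rate.  Severe stress collapses protein
synthesis through a saturating damage factor `1/(1 + (c_int/15)^3)`; this is
what prevents naive cells from out-inducing a 500 uM step.

**Growth, size and division.** Cells elongate exponentially,
`dL/dt = beta * L * g(c_int)` with Hill inhibition `g = 1/(1 + (c_int/2)^2)`.
Because `g` acts on the feedback-reduced internal concentration, shielded
interior cells keep near-normal growth while fully exposed cells at the
opening stay strongly slowed, reproducing the position-graded elongation
profiles seen during sustained treatment.  Per-cell elongation rates are
drawn at birth (SD 0.004 min^-1) with a mother-daughter heritability of 0.5,
the carrier of multi-generation growth memory.  Division is an anchored
sizer: a cell divides when it reaches twice the configured mean birth length
(1.88 um) times lognormal noise (CV 0.12).  Anchoring to the configured
birth size rather than the cell's own birth length is deliberate: the
literal "2x own birth length" rule is a geometric random walk whose cell
sizes diverge over tens of generations.  The division threshold also scales
with `g^0.6` -- stressed cells divide smaller, the growth-rate/size coupling
that writes the ambient concentration into cell morphology (and is what a
morphology-only classifier of the external concentration can exploit).
Daughters split length equally; reporter, marker and enzyme content are
partitioned with a fraction drawn around one half (SD 0.015, the scale of
binomial partitioning for thousands of molecules); content sums are
conserved exactly.  Cells are restacked contiguously from the closed end and
a cell whose far edge passes the opening is swept away by the flow.  With a
2.6 um mean cell length this exit rule gives 9.0 +/- 1.6 cells per 25 um
trench, inside the reported 8 +/- 2 band (removing cells only when their
near edge passes the opening would give ~10).

**Trench geometry.** The effective trench length varies between trenches
(SD 4 um, fabrication and field-of-view variability).  This is the source of
*persistent* occupancy differences between trenches; within one geometry,
occupancy fluctuations are single-division events that are too fast for the
dilution-limited reporter to track.

**Death and priming.** A cell dies when `c_int` exceeds
`20 uM + 100 uM * E` continuously for 5 min.  Induced cells therefore
tolerate roughly six-fold higher concentrations (priming).  Death is
absorbing: the cell stops growing but remains in the trench as
non-scavenging mass until pushed out.  Under a sudden 500 uM step, naive
cells die before induction can rescue them (the damage factor stalls enzyme
synthesis); under a gradual 25 -> 100 -> 500 uM ramp, cells induce during
the mild phases and survive.  At the default parameters a 1 h 500 uM step
kills most mothers (survival rises steeply with barrier count), the ramp
kills almost none, and 100 uM kills nobody.

**Mutagenesis.** DNA-mismatch foci are emitted as a Poisson process with
rate `2e-4 + 1e-3 * c_int * (1 - E)` per cell per minute: a burst right
after treatment onset that subsides as induction raises `E`, graded by the
(basal) shielding of the cell's barriers.

**Integration.** Explicit Euler with 0.25 min sub-steps inside each imaging
frame (3 min default; 0.75 min for dedicated lag-analysis runs).  All
kinetics are smooth and slow on that scale; the concentration relaxation and
elongation use exact exponential updates.  One root seed; each trench
evolves under its own child stream, so trench k is unchanged when the trench
count changes.  Non-finite state aborts the run naming the trench.

## Measurement designs

**Calibration.** The intensity-to-concentration line is fitted on the
steady-state (1-3 h) intensities of fully exposed cells in *sparsely loaded*
trenches.  Sparse loading matters: the reporter integrates production with a
~1/growth-rate memory (about 36 min), so cells moving quickly through a full
trench report concentrations from positions they occupied half an hour
earlier, compressing the apparent response.  Near-static cells read
faithfully.

**Shielding inference.** The per-barrier-cell attenuation is fitted as
`ln c = ln c0 + B ln(1 - f)` over *mother cells only* (they are static),
using their baseline-subtracted steady intensities converted through the
calibration slope -- baseline subtraction makes the fit insensitive to the
calibration intercept.  Persistent spread in barrier count comes from
simulating trenches of several lengths (10/15/20/25 um, stable occupancies
of ~3-9 cells); regressing on the time-averaged count within a single
geometry is hopeless because occupancy fluctuations are faster than the
reporter's response (regression dilution drives the slope toward zero, which
we verified directly).  On planted fixed attenuation fractions of
0.2/0.3/0.4 the protocol recovers 0.20/0.29/0.37; on the mechanistic default
it reads ~0.28-0.30, slightly below the true per-cell fraction (~0.33)
because barrier count is a noisy proxy for the barrier mass that actually
does the scavenging and enzyme levels vary with depth.

**Cross-correlation lag.** The generic operation correlates two series as
given.  The pipeline estimator, however, correlates the *per-frame intensity
increment* of the mother against the barrier count: the intensity itself is
an integral of production, and correlating it directly would place the
extremum at the dilution timescale rather than at the sensing delay.
Increments are centred half a frame before their stamp and the reported lag
corrects for that.  Planted reporter delays of 2/6/12 frames (0.75 min
sampling) are recovered within half a frame.

**Fate.** A mother is dead if its rolling length growth rate stays below
0.012 min^-1 for 10 h after stress removal; regrowth time is the first
frame whose instantaneous rate exceeds the threshold with the following
45 min window confirming it.

**Mismatch burst.** Per-frame rates are total foci / total cells / frame
interval; the burst amplitude per barrier-count stratum is the mean rate
over the first 15 min of treatment minus the pre-treatment mean (a mean, not
a maximum: sparse strata would otherwise be ranked by their sampling noise).

## The feature matrix and model

One row per mother cell: 7 statistics (kurtosis, nonparametric skewness,
median, mean, min, max, range) x 9 series (mother length, area, per-frame
length and area rates, surface-area-to-volume ratio; barrier count and
cumulative barrier length, area and SA/V) x 2 epochs (135 min before and
after treatment) = 126 features, plus the label: the reporter peak within
the first hour of treatment minus the pre-treatment mean.  Two printed
renderings of the SA/V expressions in the source material are typographically
inconsistent; both the per-cell metric and the feature series use the exact
geometric SA/V of a hemisphere-capped cylinder, `12 L^3 / (A (3 L^2 - A))`
with `A = 2 r L`.  Kurtosis is the standard population kurtosis (not excess)
and skewness the nonparametric `(mean - median)/SD`; constant windows return
zero for both by convention.  The per-frame rate series use simple first
differences (the log-difference elongation rate is exposed separately).

The regressor is a 100-tree random forest with a depth cap of 3000
(effectively unconstrained) on a seeded, shuffled 80:20 split by mother
cell.  Feature subsetting follows scikit-learn's defaults: all features per
split for regression, sqrt(p) for the concentration classifier.  Accuracy is
`A = 1 - mean(|pred - obs| / obs)` on the held-out mothers; importances are
mean decrease in impurity normalised to sum to one and aggregated into
mother/barrier group shares through the feature manifest.  The coefficient
of variation is SD/mean (the two printed definitions disagree; the standard
one is used).  The induction threshold defaults to 1,480 a.u., 20% of the
~7,400 a.u. steady-state intensity of a fully exposed cell at 100 uM.

## Problem sizes

Default analysis runs: 170 trenches per concentration across
{37.5, 50, 62.5, 75, 100} uM (~850 mothers) for the model; 120 trenches over
9 h (3 h burn-in discarded) for occupancy; 30-40 trenches per geometry for
shielding inference; 200 trenches per schedule for the step/ramp survival
comparison; 250 trenches per width for the mutagenesis gradient.  These are
the sizes the test suite and the reproduction script use.

## What the generator does and does not emulate

The simulator reproduces the study conditions structurally: trench geometry
(25 x 1.2 um, 1.4 um wide variant), 3-min imaging, ~8 +/- 2 cells of
2.6 +/- 0.7 um, induction threshold crossing ~13 min after onset, a
transient response peak followed by a lower steady state, an exponential
intensity gradient along the trench, priming under ramped schedules, and a
pre-induction mutagenesis burst.  It does not model: continuous
reaction-diffusion inside the trench (shielding is a per-cell flux
attenuation), flow-channel hydrodynamics, agarose-pad colonies, cell-to-cell
variation in reporter plasmid copy number, photobleaching or segmentation
error beyond additive Gaussian intensity noise (SD 30 a.u.), or death of
barrier cells feeding back on the gradient beyond their becoming inert mass
(how dead barriers transmit H2O2 is not experimentally constrained; treating
them as non-scavenging mass is a documented choice).  Passing tests
therefore show that the analysis pipeline is correct and well-calibrated on
data with this structure, not that the mechanistic parameters are the true
ones for E. coli.

## Known limitations

* The intensity-based shielding readout is biased for moving cells; the
  package works around it by design (static mothers, multi-length panels)
  rather than by deconvolution.
* The mechanistically measured attenuation (~0.29) sits at the lower edge of
  the reported band even though the underlying per-cell fraction is ~0.33;
  see the shielding-inference notes above.
* Lineage-memory correlations are dominated by the shared trench environment;
  the sister > cousin > unrelated ordering is reproduced, but the absolute
  correlation values are much higher than in real data because all cells in
  a simulated trench share one deterministic concentration history.
* The delta-oxyR strain retains the basal scavenging level, so a long run of
  mutant barriers attenuates weakly (~7% per cell) where the experiments
  report no detectable reduction.
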