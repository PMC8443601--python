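# Methods

## The kinetic-locking model

The probe is modeled as a continuous-time Markov chain over labeled states,
each carrying a hairpin phase (open/closed) and a binder occupancy flag.
The free hairpin is the two-state chain C ⇌ O with closing rate k_f and
opening rate k_u (both ~100 s⁻¹ at the working force, i.e. ~10 ms dwells).
Binding is pseudo-first-order: an edge with rate b = c·k_on, concentration
c in nM and k_on in nM⁻¹ s⁻¹; unbinding has rate d = k_off.  Two scheme
topologies cover the experiments:

* **Open-state locking** (oligonucleotide hybridization; protein binding
  to the fluctuating strand of a no-fork probe): states {C, O, O·B} with
  binding only from O.  A bound state has no phase-changing edge — binding
  locks the hairpin open.
* **Gapped-fork probe**: states {C, O, C·B, O·B}; the single-stranded gap
  is available in both phases, so binding proceeds from C and O alike and
  locks whichever phase it finds.  Long *closed* dwells are the signature.

Dwell times of a lockable phase are absorption times of the transient
two-state chain {free, bound}, a phase-type distribution that reduces to a
two-exponential mixture with eigenvalues λ± = ½[(a+b+d) ± √((a+b+d)²−4ad)]
and weight w = (a−λ₋)/(λ₊−λ₋), where a is the escape rate (k_f for open
dwells, k_u for the fork probe's closed dwells).  λ₋ is evaluated through
the product identity λ₊λ₋ = ad to avoid cancellation.  The mean is
T̄(c) = (1 + c·K_A)/a with K_A = k_on/k_off, so mean dwell versus
concentration is a straight line whose slope measures the binding free
energy ΔG⁰ = −kT ln(K_A c⁰), c⁰ = 1 M (concentrations are nM throughout
the API; conversion to molar happens only in the thermodynamic
conversions, with R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K by
default).  When binding exchange is much faster than the frame time the
mixture collapses: the dwell distribution is single-exponential with rate
k_f/(1 + c·K_A) and only the product K_A remains identifiable, which is
exactly how sub-frame (5/6-mer-like) binders behave.

The simulator is an exact Gillespie algorithm (exponential holding times at
the state exit rate, jump probabilities proportional to edge rates),
rendered onto a uniform camera grid (default 1300 Hz) at two extension
levels 10 nm apart with i.i.d. Gaussian noise (default 1.5 nm).  The noise
model deliberately omits exposure averaging, drift and tether elasticity;
passing tests therefore validate the analysis chain against the stated
two-level model, not against instrument artifacts.  A force change ΔF
rescales the opening rate by 2^(ΔF/0.7 pN); by default the closing rate
receives the inverse factor (symmetric tilt of the folding landscape, which
preserves the force-dependence of the equilibrium constant), configurable
to opening-only.  Binding rates are force-independent by default.  One
top-level seed feeds a SeedSequence tree; state path and camera noise use
independent child streams so either can be regenerated alone.

## Trace idealization

Transitions are detected by the summed-monotonous-change rule: a
transition is declared when the summed extension change over a monotonous
section of the trace exceeds 8 nm (against the ~10 nm step).  On sampled
noisy data, strict sample-level monotonicity is meaningless, so a
monotonous section is implemented as a turning-point ("zigzag") scan: a
rising section ends at its running maximum once the trace has retreated
more than a tolerance (default 1.5 nm, one noise sigma) below it, and the
section's summed change is its extremum-to-extremum amplitude.  A
single-frame excursion of full step height forms its own section, so the
minimum detectable dwell is one frame; an optional moving-average window
(default 1 = off) can trade dead time for robustness at worse
signal-to-noise.  Transitions are timestamped at the first frame where the
cumulative change crosses half the threshold, chosen because it biases
opening and closing events symmetrically.
Detections that fail to alternate are merged (first kept).  First and last
dwells of a record are censored (window-truncated) and excluded from all
statistics.

Measured behavior at the standard conditions (10 ms dwells, 1300 Hz,
1.5 nm noise): >99% of dwells longer than 5 frames are recovered as
episodes of the right phase; the mean detected dwell exceeds the true mean
by ~9%, an additive ~0.85 ms dead-time inflation caused by sub-frame
dwells — ~4% of exponential dwells are shorter than one frame, often leave
no sample in the rendered trace, and merge their neighbors.  No dead-time
correction is applied.  Pure-noise false events occur at ~0.5 s⁻¹ and are
negligible against ~100 s⁻¹ genuine transition rates.  The inner scan is
numba-compiled with a pure-python fallback.

## Inference

Dwell histograms use geometrically growing bins (default ratio 1.4, within
the conventional 1.2–2 band; t_min at the smallest dwell, t_max just above
the largest), with densities normalized so the histogram integrates to 1.
The global fit shares (k_f, k_on, k_off) across all concentration series
and minimizes density residuals weighted by the per-bin counting error
(relative error 1/√n), in log-parameter space for positivity; a
binning-free maximum-likelihood mode is available and agrees within
uncertainties.  Initialization is method-of-moments: an EM two-exponential
mixture fit of the highest-concentration series is inverted through
a = f(0) = (1−w_long)λ₊ + w_long·λ₋, d = λ₊λ₋/a, b = λ₊+λ₋−a−d, which
avoids eigenvalue label switching.  Series with <50 events are excluded,
<500 down-weighted; a c = 0-only input degrades gracefully to a
single-exponential fit with the binding rates flagged unidentifiable.
Uncertainties come from resampling each series with replacement (default
100 resamples) and refitting; reported values are bootstrap means, errors
bootstrap standard deviations.  The EM cross-check is a standard
two-component exponential mixture EM with deterministic median-split
initialization; rate ratios below 1.5 are flagged degenerate
(single-exponential).

The titration fit regresses T̄(c)/T̄(0) on c by weighted least squares with
effective-variance treatment of concentration uncertainty (default 5%
relative, one re-weighting iteration) and reports K_A = slope/intercept —
the ratio form cancels any detection bias that rescales all means by a
common factor.  The c = 0 point anchors the intercept by default; a
documented option drops it from the line (using it only as normalizer),
which also cancels biases common to the finite concentrations only at the
cost of about twice the K_A variance.  ΔG⁰ errors propagate from the fit
covariance.  For slow binders, k_on is also estimated directly as
N_long/(T_unbound·c), where long events (above a threshold taken from the
mixture-component crossing) are excluded from the unbound time; on the
gapped-fork probe, long dwells of both phases count as events and unbound
time pools both phases, matching a binding site exposed in either phase.

## Nearest-neighbor thermodynamics

Duplex ΔH°/ΔS° are assembled from the ten unified Watson-Crick stack
parameters plus per-terminal initiation terms (G·C: +0.1 kcal/mol,
−2.8 e.u.; A·T: +2.3, +4.1), shipped as a plain-text table with two
corrected entropies: ΔS°(TA/AT) = −21.3 e.u. and ΔS°(GG/CC) = −19.9 e.u.
(older copies of the table circulate with −20.4 and −19.0).  The 1 M
reference entropy is moved to the working buffer by
ΔS° += 0.368·(N_bp−1)·ln[mon⁺]_eff.  Because no closed-form mapping of
Mg²⁺ into this entropic correction is universally agreed for short
duplexes, two schemes are implemented — monovalent-only, and
[mon⁺]_eff(mM) = [K⁺+Na⁺](mM) + f·√([Mg²⁺](mM)) — and the default
(f = 140) was selected by calibrating against reference predictions for
CAGAG/CCAGAG/GCCAGAG at 25 °C in 100 mM KCl + 3 mM MgCl₂, which it
reproduces to ≤0.012 kcal/mol (`scripts/salt_calibration.py`; the common
f = 120 variant is ~0.05 kcal/mol off and remains selectable).  Terminal
dye/intercalator corrections are supported only through a user-supplied
(ΔΔH°, ΔΔS°) table keyed by the 5′-terminal dinucleotide — none is
bundled, a missing table raises, and re-application is guarded.
Dangling ends, mismatches and melting temperatures are out of scope.

## Reference experiments and problem sizes

The desk-scale experiments in `kinlock.experiments` fix the study
conditions: a 7000-s stationary recording (k_f = k_u = 100 s⁻¹, 1300 Hz,
1.5 nm noise) cut into twenty 350-s chunks for the stability metrics;
10⁵ Gillespie open dwells per rate triple for the KS comparison of the
dwell law; rate recovery at the no-fork operating point
(k_off = 10.9 s⁻¹, k_on = 10⁻² nM⁻¹ s⁻¹) from 15,000 open dwells at each
of 0/200/800 nM — concentrations chosen so the slow mixture component
carries enough events for the dissociation rate to be identifiable — with
a replicate ensemble (50 replicates of 5000 dwells, 50 bootstrap
resamples) for error-bar calibration; and an end-to-end free-energy
recovery at ΔG⁰ = −8.45 kcal/mol (k_off = 4 s⁻¹, i.e. ~250 ms locked
episodes) titrated at 0–800 nM with 400 s per condition.  At these sizes
the known ~+0.045 kcal/mol dead-time bias plus statistical scatter keeps
the recovered ΔG⁰ within ±0.1 kcal/mol of truth.

## Known limitations

* The dead-time inflation of mean dwells (~9% at 10 ms dwells / 1300 Hz)
  is inherent to threshold idealization of sampled two-state signals; it
  largely cancels in titration ratios but not in absolute rate estimates.
* The fork-probe scheme forbids phase changes of the bound hairpin
  entirely; a binder that clamps the fork only after closure would need an
  extra edge (O·B → C·B) not modeled here.
* Camera exposure averaging, drift, and elastic (WLC) rendering are not
  simulated; detector performance on real traces may differ at the margins.
* The salt correction is calibrated for the single buffer family above;
  extrapolation to very different ionic strengths should re-run the
  calibration against measured data.
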