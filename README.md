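# kinlock

Kinetic-locking analysis of fluctuating DNA hairpin probes.

A short DNA hairpin held at ~10 pN with magnetic tweezers flickers between
its closed (duplex) and open (single-stranded) states every ~10 ms, and the
~10 nm extension difference between the two states is directly trackable at
camera rates.  A ligand — an oligonucleotide hybridizing to the exposed
strand, or a protein such as the *E. coli* RecQ helicase core binding its
DNA substrate — cannot bind without transiently *locking* the hairpin in
one state, so every binding event appears as an anomalously long dwell.
This turns a plain force clamp into a label-free single-molecule binding
assay.  `kinlock` implements the full analysis chain for such experiments,
for people who run them (or want to model them):

* **`kinlock.synthetic_data`** — labeled CTMC schemes for the probe with
  open-state locking (oligonucleotide / no-fork protein binding) or
  two-sided locking (gapped replication-fork probe); exact Gillespie
  simulation; rendering to camera-like traces (1300 Hz, Gaussian noise);
  force rescaling of the hairpin rates (opening rate doubles per 0.7 pN).
* **`kinlock.state_detection`** — trace idealization by the
  summed-monotonous-change rule (8 nm threshold), dwell extraction, and the
  chunked stationarity analysis with bootstrap errors.
* **`kinlock.dwell_models`** — the kinetic laws.  With escape rate *a*
  (= k_f for open dwells), binding rate *b* = c·k_on and unbinding rate
  *d* = k_off, the locked-phase dwell time is phase-type distributed:

      f(t) = w λ₊ e^(−λ₊ t) + (1 − w) λ₋ e^(−λ₋ t),
      λ± = ½[(a+b+d) ± √((a+b+d)² − 4ad)],   w = (a − λ₋)/(λ₊ − λ₋),

  with mean T̄(c) = (1 + c·K_A)/a, K_A = k_on/k_off.  The titration slope
  therefore measures the standard binding free energy
  ΔG⁰ = −kT·ln(K_A·c⁰), c⁰ = 1 M.  The fast-exchange limit (sub-frame
  binders) keeps the mean law while the distribution stays
  single-exponential.
* **`kinlock.inference`** — geometric dwell binning (ratio a ∈ [1.2, 2]),
  a single global double-exponential fit across all concentrations
  (weighted least squares on binned densities with √N errors, or
  binning-free maximum likelihood), bootstrap uncertainties, an EM
  exponential-mixture cross-check, the weighted titration-line fit, and a
  direct k_on estimator from long-event counting.
* **`kinlock.nn_thermo`** — nearest-neighbor prediction of short-duplex
  ΔG⁰(25 °C) with the unified parameter set (including the corrected
  entropies ΔS°(TA/AT) = −21.3 e.u., ΔS°(GG/CC) = −19.9 e.u.) and a
  calibrated salt correction for Mg²⁺-containing buffers.
* **`kinlock.pipeline_io` / `kinlock.cli`** — validated run configurations,
  TSV/CSV/JSON formats, and the `kinlock` command
  (`simulate`, `detect`, `fit-dwells`, `fit-titration`, `nn-predict`,
  `acceptance`).

## Worked example

Predict the hybridization free energies of three short duplexes at 25 °C
in 100 mM KCl + 3 mM MgCl₂:

```sh
$ kinlock nn-predict CAGAG CCAGAG GCCAGAG
```

prints (abridged):

```
sequence   dH (kcal/mol)  dS (e.u.)  dG (kcal/mol)
CAGAG      -32.10          -94.08     -4.05
CCAGAG     -40.10         -114.37     -6.00
GCCAGAG    -49.90         -139.17     -8.41
```

i.e. each added G/C base pair deepens the duplex free energy by roughly
2 kcal/mol, which is what makes 5/6/7-mer binders distinguishable through
their locking times.

Simulate a full titration of a 7-mer-like binder (k_off = 4 s⁻¹, so
~250 ms locked episodes against 10 ms free dwells), idealize the traces and
fit the titration line:

```python
from kinlock import RunConfig, run_titration_pipeline

cfg = RunConfig.model_validate({
    "scheme": "oligo",
    "rates": {"k_f": 100.0, "k_u": 100.0, "k_on": 6.25e-3, "k_off": 4.0},
    "concentrations_nM": [0.0, 200.0, 400.0, 600.0, 800.0],
    "duration_s": 100.0,
    "seed": 12,
})
report = run_titration_pipeline(cfg, with_bootstrap=False)
```

With this seed the report contains

```
mean open dwell (ms): [10.97, 14.80, 17.75, 18.68, 23.88]   # vs 10 ms at c = 0
Ka = 1.398e-03 /nM,  dG0 = -8.38 +/- 0.05 kcal/mol
```

the mean open time grows linearly with binder concentration while closed
times stay put, and the slope converts to a binding free energy — here
within 0.1 kcal/mol of the ΔG⁰ = −8.45 kcal/mol used to generate the data
(the k_on in the config is K_A·k_off for that ΔG⁰).

`kinlock acceptance --seed 1` runs the whole battery of desk-scale checks
(NN predictions, probe stability, dwell-law exactness, rate and
free-energy recovery) and prints a pass/fail table.

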