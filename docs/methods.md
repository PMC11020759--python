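# Methods

`cardiomap` analyzes dual voltage–calcium optical-mapping recordings of
paced, perfused hearts and ships a simulator that generates such
recordings with known ground truth.  This note documents the models,
the estimators, the tunable parameters that matter, and the choices
made where the design was genuinely open.

## The tissue simulator

### Membrane model

Excitation is the two-variable Mitchell–Schaeffer model on a regular
grid (camera pixels, default 0.25 mm pitch):

    dv/dt = h v²(1−v)/τ_in − v/τ_out + I_stim + D ∇²v
    dh/dt = (1−h)/τ_open   if v < v_gate
          = −h/τ_close     if v ≥ v_gate

with forward-Euler integration (internal step ≤ 0.6·dx²/4D, about
0.09 ms at camera pitch), a 5-point Laplacian, no-flux outer
boundaries, and scar cells removed from the medium (internal no-flux
walls).  Output is sampled at the camera's 2 ms frames.  This model was
chosen because the two quantities the tests lean on are analytic:

* **Plane-wave speed.**  With the gate at rest (h = 1) the v-equation
  is a cubic bistable reaction–diffusion front with roots
  0 < v− < v+ (the roots of v² − v + τ_in/τ_out), whose speed is
  c = √(D/2τ_in)·(v+ − 2v−).  Defaults (τ_in 0.3 ms, τ_out 6 ms,
  D 0.1 mm²/ms) give 0.34 mm/ms, a realistic ventricular velocity.
  The closed form holds for the *first* beat from rest; on subsequent
  beats the partially recovered gate (h < 1) slows the front by
  10–20%, so speed oracles always track the first wavefront.  At
  0.25 mm pitch the under-resolved front runs ~4–5% slow; speed
  accuracy tests use a 0.125 mm grid, where the error is ~2%.

* **APD restitution.**  During an action potential h decays with
  τ_close; an AP ends near h_min = 4τ_in/τ_out, giving
  APD ≈ τ_close·ln(h₀/h_min) with h₀ set by the preceding diastolic
  interval through τ_open.

The default τ_close = 70 ms was calibrated once so that the measured
optical APD80 at a 300 ms pacing cycle length is ≈123 ms, the scale of
diseased rabbit ventricle this package's synthetic studies emulate.

### Calcium subsystem

Ca is a driven relaxation, dCa/dt = g·s(v) − Ca/τ_Ca, with s(v) a
sigmoid upstroke gate re-based to be exactly zero at rest.  Diastolic
decay is therefore monoexponential with the configured τ_Ca (default
50.3 ms) by construction, which makes the decay-fit stage exactly
verifiable.  A small residual influx while v is still repolarizing
gives the optically measured τ a 1–3% downward offset relative to the
model constant; it is identical across conditions and cancels in
paired comparisons.

### Drug effect

The intervention is purely parametric, with no kinetics or washout:
`drug_apd_factor` (>1) multiplies τ_close, prolonging APD and
refractoriness; `drug_ca_factor` (<1) multiplies τ_Ca, accelerating
calcium reuptake.  The study default `drug_apd_factor = 1.107` was set
so the *measured* APD80 increase is ≈8%: the realized increase is
sub-linear in the factor because (a) a longer APD shortens the next
diastolic interval, partially offsetting itself through restitution,
and (b) the terminal v-collapse phase scales with τ_out, not τ_close.

### Fluorescence and noise

F_vm = 1 − 0.8·v + ε (inverted polarity, the voltage-dye convention),
F_ca = 0.1 + 0.8·Ca + ε; scar pixels emit baseline + noise only.
Noise is i.i.d. Gaussian per pixel-frame; SNR in dB is peak-to-peak
signal over noise SD (20 dB ⇒ σ = 0.08 on a 0.8 swing), the regime in
which the recovery guarantees below were measured.  An optional
exponential photobleaching drift can be enabled and is removed by the
`detrend="exponential"` preprocessing mode.

### Refractory-period measurement

The S1 drive train is simulated once and checkpointed at the last S1;
each premature interval is then replayed from the checkpoint.  Capture
is *tissue-wide re-activation*: at least half of the medium (outside
the electrode) must repolarize below 0.45 and then cross 0.5 again
within 150 ms of the S2.  A single distal probe was tried first and
abandoned: near the refractory boundary the model can produce local
re-excitation blips that fool a point detector but never spread.
Besides the bench-style descending scan, a bisection strategy finds the
same grid point in O(log) trials and is used inside studies.

### Restitution surrogate (cable and independent sites)

The exponential restitution map
APD_{n+1} = A − a·exp(−DI_n/τ_r) has its period-doubling onset in
closed form (slope 1 at the fixed point ⇒
PCL* = A − τ_r + τ_r·ln(a/τ_r)), which anchors the alternans-threshold
scan.  Two spatial variants:

* a **conducting cable** with DI-dependent velocity
  (cv(DI) = cv_max(1 − cv_amp·e^{−DI/cv_tau})); gentle, slow CV
  restitution (cv_amp ≈ 0.15, cv_tau ≈ 100 ms) yields spatially
  discordant alternans with a *single* mid-cable node — stronger or
  faster CV restitution shortens the discordance wavelength and packs
  in several nodes.  A premature beat on this substrate conducts
  through the short-APD region and blocks near the node, the
  reentry-initiation geometry the mapping stage must recover.
* **independent heterogeneous sites** (per-site additive spread on A,
  SD 5 ms): the exponential map's alternation amplitude explodes to
  2:1 block within ~5 ms of onset, so on a homogeneous medium a 10 ms
  decremental scan can step over the alternans window entirely.  Real
  mapped fields are heterogeneous — the protocol of reading the *site
  of maximum alternans* presumes it — and the spread of per-site
  onsets makes the threshold detectable on the scan grid.

### Ectopy

Spontaneous ectopic beats are a Poisson process (rate in events/min)
with refractory suppression; in rendered ambient recordings the
surviving events fire early in the cycle (refractory end plus a short
exponential), as border-zone triggered activity does.

## The analysis pipeline

* **Preprocessing** — polarity flip, optional linear/exponential
  detrend (the linear slope is fitted to the lower envelope so the
  beat shape cannot leak into it), zero-phase moving-average filters
  (no frame shifts, so activation times are unbiased), per-pixel
  normalization to [0,1] by 2nd/98th percentiles (robust to spikes);
  zero-range pixels are flagged, never divided by.
* **Quality mask** — per-pixel SNR = beat-band variance over
  first-difference residual variance (dB).  The estimator assumes
  unfiltered input (temporal smoothing correlates the noise and
  inflates it): build the mask from `preprocess(movie, 1, 1)` and
  apply it to the filtered movie.  At 20 dB recording SNR, scar reads
  ≈ −6 dB and tissue ≥ ≈7 dB, so the study threshold of 3 dB
  separates them with margin on both channels; fewer than 25
  surviving sites is a hard failure, mirroring the ≥25
  non-infarcted-site rule.
* **Features** — activation = maximal upstroke slope with parabolic
  sub-frame refinement and an amplitude gate (slow-rise channels
  otherwise admit noise spikes); durations to a fractional
  repolarization level (APD80/CaTD80) with per-beat baseline (median
  of the 20 ms pre-upstroke) and linear crossing interpolation;
  diastolic intervals from the previous beat's end.
* **Calcium τ** — monoexponential least squares from the
  20%-repolarization crossing to 95% recovery (window chosen on a
  smoothed copy, plus a margin so the end never chases a noise
  excursion), with the offset anchored to the recovered trace tail:
  letting the offset float biases τ upward, and a pre-upstroke
  baseline is contaminated by the previous transient's tail.  Under
  these choices the 200-seed mean at 20 dB is within 2% of truth, and
  site-averaged estimates from full recordings sit within ~3%.
* **Alternans** — signed Δ = mean over consecutive beat pairs of
  (even − odd); significant when |Δ| exceeds 10 ms (APD) or 5% of the
  pair-mean amplitude (Ca).  Discordance requires both parity signs
  with ≥10 px each (suppresses speckle); the nodal line is the zero
  contour of the 3-px-smoothed signed map.  The threshold scan
  descends in 10 ms steps from 300 ms, judges the max-alternans site,
  and stops on loss of 1:1 capture.
* **Maps** — isochrones relative to the earliest activation; local
  5×5 plane fits give slowness ∇T and velocity ∇T/|∇T|²; block =
  |ΔT| > 4 ms/px between neighbours or the boundary of
  unactivated-but-valid regions, split into fixed (scar-adjacent,
  2-px dilation) vs functional (nodal-line-adjacent when an alternans
  map is supplied).  Phase by Hilbert transform of mean-subtracted
  traces (delay embedding available); singularities by ±2π winding on
  2×2 plaquettes, linked at ≤3 px/frame, tracks <2 frames dropped.
* **Rhythm** — beats from a Gaussian envelope (σ 26 ms) of the
  rectified ECG with refractory guard; paced = within −10..+40 ms of a
  stimulus.  PVB = non-paced with coupling <85% of the running median
  cycle.  VT = ≥3 consecutive organized rapid beats (rapid = cycle
  <80% of baseline; organized = sliding 5-beat cycle-length CV ≤0.15);
  rapid disorganized activity = VF; ≥30 s = sustained.  The
  organized/disorganized words are qualitative in the source protocol;
  these numeric readings are configurable and echoed in reports.
* **Statistics** — paired Student t (p via the regularized incomplete
  beta) and Fisher's exact test (exact integer hypergeometric
  enumeration, two-sided by the point-probability convention), no
  multiple-testing correction, α = 0.05.

## The synthetic paired study

14 hearts, each measured at baseline and under the drug factors.
Heart-level draws: τ_close ~ N(70, 6) ms, τ_Ca ~ N(50.3, 4.8) ms,
restitution-map shifts on A (SD 6 ms) and τ_r (SD 9 ms), shared CV
restitution strength ~ N(0.115, 0.05), per-site A spread (SD 5 ms),
gamma-distributed baseline PVB rate (mean 0.55, SD 0.74 events/min)
scaled by 0.22 under drug.  Surrogate-map centers put the detected
alternans thresholds near 127 ms (baseline) and 115 ms (drug).

Inducibility is mechanistic: the heart's conducting cable is paced one
scan step below its own alternans onset and challenged with a
premature beat; reentry starts iff the substrate is discordant *and*
the premature beat blocks mid-cable.  The heart-level steepness and CV
restitution draws make ~70% of baseline hearts and ~14% of drugged
hearts meet that condition; the resulting episodes are rendered into
the pseudo-ECG and the rhythm classifier — not the mechanism flag —
decides the reported outcome.  Fisher's test then compares conditions.

Problem sizes: the default configuration uses a 50×50 grid (≈8 min on
one CPU); the test suite and acceptance script run the same study at
28×28 with 8 paced beats per recording and a 16×28 refractory strip
(≈2 min per replicate), sizes at which every endpoint's direction and
significance are stable.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis depends on —
paced wavefronts with restitution, scar silence, discordant alternans
with nodal lines, premature-beat block, post-pacing VT/VF runs, Poisson
ectopy, channel noise at stated SNR.  It does not model real dye
spectra, motion artifact, heterogeneous fiber orientation, true
transmembrane currents, or drug kinetics; passing tests therefore
validate the *estimators and their wiring*, not any pharmacological
claim about real tissue.

## Known limitations

* The v-level APD80 ratio under `drug_apd_factor` is sub-linear (see
  above); studies calibrate the factor to the measured effect.
* Optical τ carries the small paired-invariant offset noted above, and
  the tail-anchored baseline assumes the fitted beat is the final one
  of its train (the protocol guarantees this).
* The refractory-period scan reports values ≈35–40 ms above APD80;
  the margin is set by gate recovery (τ_open) and stimulus strength
  and is longer than typical bench values, so only within-study
  orderings of ERP are meaningful.
* CaTD80 of the synthetic calcium waveform (~165 ms) is longer than
  typical rabbit values; it is internally consistent across conditions.
* The charge detector resolves singularities no closer than ~2 px;
  counter-rotating pairs inside that radius annihilate.
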