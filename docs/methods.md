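# Methods

## The model

`astrowave` simulates networks of astrocytes in which each cell is a
single well-mixed compartment with five state variables: cytosolic calcium
C, ER calcium C_ER, the IP3 receptor (IP3R) inactivation gate h, IP3
concentration I, and — shared across the network — the extracellular ATP
field A(x, t) on a 2D grid.

Per cell (concentrations in μM, time in s):

    dC/dt    = β (j_IP3R − j_SERCA + j_lER − j_PCA + j_lext)
    dh/dt    = k_off (k_on − (C + k_on) h)
    dC_ER/dt = R_vol (j_SERCA − j_IP3R − j_lER)
    dI/dt    = r_h (G*_ATP + G*_glu) − k_deg I  + σ √dt η(t)

with fluxes

    j_lext  = k_l_ext (1 − C/C_ext)                        external leak
    j_PCA   = V1 C^1.7/(k1^1.7 + C^1.7)
            + V2 C^4.4/(k2^4.4 + C^4.4)                    PM Ca-ATPase
    j_IP3R  = j_max [C/(C+k_C) · I/(I+k_I) · h]^3 (1 − C/C_ER)
    j_SERCA = v_s C²/(C² + k_s²)                           ER re-uptake
    j_lER   = k_lER (1 − C/C_ER)                           ER leak

The G-protein activities are the steady-state occupancy responses of the
purinergic (ATP) and metabotropic glutamate receptors,

    G*_ATP = (ρ_ATP + δ)/(k_d/k_a + δ + ρ_ATP),  ρ_ATP = A/(k_ATP + A)
    G*_glu = ρ_glu/(k_d/k_a + ρ_glu),  ρ_glu = glu^0.7/(k_glu^0.7 + glu^0.7)

where δ is the residual activity of agonist-free receptors, pinned by
requiring the basal IP3 level I0 to be the zero-stimulus fixed point:
δ = (k_d/k_a)·k_deg I0/(r_h − k_deg I0).

The extracellular ATP field obeys ∂A/∂t = D∇²A − αA + Σ_i δ(x−x_i) j_ATP,i
with calcium-gated release j_ATP = j_max,ATP (C − C_min)/(k_rel + C) for
C > C_min and zero otherwise: cells release nothing at rest and release
during calcium transients, which is the paracrine coupling that lets a
local burst of activity recruit neighbors (the positive-feedback
nucleation of intercellular calcium waves, ICW).

Noise enters only through IP3: a per-cell Gaussian white-noise term
representing the stochastic opening of small IP3R clusters, integrated as
an Euler–Maruyama increment σ√dt·N(0,1) per step so its stationary effect
is independent of the step size. Gap-junctional coupling is not modeled;
glutamate is a spatially uniform bath concentration.

## Numerics

- Forward Euler for the cell ODEs and an explicit FTCS
  (forward-time/centered-space) scheme for the field, on a shared step dt.
  The FTCS stability bound dt ≤ h²/(4D) is enforced at configuration time.
- The grid covers the bounding box of the cells plus a 50 μm margin, with
  zero-flux boundaries. Waves terminate by ATP degradation and store
  exhaustion well before the boundary matters.
- Cells are point sources and point sensors: release is distributed over
  the four enclosing grid nodes with bilinear (cloud-in-cell) weights, and
  the sensed concentration is the bilinear interpolation with the same
  weights. A release j_ATP adds concentration j_ATP·dt/h² split over the
  stencil (mass j_ATP·dt per unit depth).
- After every step, C, C_ER, I are clamped at 0 and h to [0, 1]; the field
  is clamped at 0 (the stochastic IP3 increment can otherwise drive I
  negative).
- Production resolution is h = 2 μm, dt = 5 ms; the desk-scale resolution
  used for sweep-style experiments is h = 4 μm, dt = 10 ms. A
  refinement-equivalence test (halving h and dt on a fixed-source problem)
  bounds the difference at < 5% RMS in cell-sampled concentrations.
- Initial conditions: a single isolated, noise-free cell is relaxed for
  2000 s (ER store initialized at 400 μM); the relaxed state seeds every
  cell. If the deterministic dynamics oscillate, the minimum-calcium state
  of the final quarter of the relaxation is used (a quiescent phase).
  Stimuli (bath glutamate; fractional leak increase for the amyloid-β
  protocol) switch on as a step at t = 0.
- One seeded `numpy` Generator per run; per-cell noise is drawn in fixed
  cell order, so trajectories are bit-reproducible for a given seed and
  backend. The integrator has a numba-compiled kernel and a pure-numpy
  fallback with identical arithmetic (tested to 1e-10 relative agreement).

## Calibration of the fitted constants

The literature-derived constants (receptor/channel/pump kinetics,
diffusivity, degradation) are used exactly as tabulated. Four constants
are declared fits of the original model and are calibrated here; their
values live in the *working parameterization* used by the experiment
presets (`astrowave.config.working_params`), while the bare `ModelParams`
defaults keep the published table values.

1. **k_l_ext (external calcium leak).** Pinned by the model's own resting
   self-consistency: the resting calcium must be half the ATP-release
   threshold (C_rest = C_min/2 = 0.01 μM, so that the release current
   vanishes at rest with a factor-two safety margin), and at rest the
   plasma-membrane fluxes balance: k_l_ext = j_PCA(0.01 μM) ≈ 0.0462
   μM/s. A smaller leak cannot sustain repeated transients: each calcium
   spike expels tens of μM (cytosol-equivalent) through the PCA pump, and
   the leak is the only re-entry path, so the leak rate sets the ISI
   budget (≈ hundreds of seconds at this value, matching the observed ISI
   scale).
2. **I0 (basal IP3).** The basal IP3 level sets the resting IP3R open
   probability and hence the nucleation rate. The working value
   I0 = 0.002 μM leaves cells silent without stimulation while
   sub-to-suprathreshold glutamate (5–13 μM) moves the spontaneous
   transient rate across the range where network recruitment percolates.
3. **Receptor domain area (gpcr_area).** The PLCβ production constant is
   tabulated per unit membrane area (μM·μm⁻²·s⁻¹); the compartment rate is
   r_h = r_h*·area with the working area 9 μm², an effective IP3R/PLCβ
   domain size. This sets both the glutamate sensitivity and the dynamic
   range of the ATP response.
4. **j_ATP,max (release strength).** Controls how strongly a transient in
   one cell raises IP3 production in its neighbors. Calibrated so the
   probability of observing an ICW in 1000 s crosses 1/2 near 9 μM bath
   glutamate on the standard 100-cell field.

## Statistical protocols

- Stimulus-sweep comparisons (wave probability vs. glutamate or leak
  increase) reuse the same seeds — hence the same cell-field geometries
  and noise paths — at every stimulus level (common random numbers).
  Field geometry is the dominant run-to-run variance source (dense local
  patches percolate more easily), and sharing it across levels isolates
  the stimulus dependence of the transition.
- The between-transient calcium baseline is read in an early window
  (50–350 s after stimulus onset): over longer horizons the ER store
  re-equilibrates a tonic IP3 elevation away and the baseline relaxes
  back to the leak/pump balance point.
- ISI moments and the exponential-tail check pool intervals across seeds
  at a fixed stimulus, because the calcium budget (store refill through
  the external leak) limits any single 3000-s run to a handful of
  transients.
- Wavefront speeds are measured on the first wave per run whose
  radius–time regression is meaningful (positive slope, R² ≥ 0.3);
  stimulus-onset coincidence clusters have no coherent front and R² ≈ 0.

## What the synthetic data emulate — and what they do not

The random cell fields (default 100 cells in 400×400 μm with a 20 μm
hard-core minimum distance, ≈ 625 cells/mm²) emulate the density and
nearest-neighbor spacing of sparse dissociated astrocyte cultures; real
imaged fields can be loaded from two-column coordinate tables instead.
The model does not represent: spatially resolved intracellular calcium
(microdomains are collapsed into the IP3 noise term), dynamic calcium
buffering (β is constant), store-operated calcium entry, gap-junctional
IP3 exchange, or glutamate diffusion. Passing tests therefore demonstrate
the network-level consequences of the modeled pathway set, not a complete
account of astrocyte physiology.

## Known limitations

- **Slow store rundown.** Because the stochastic IP3R opening is convex in
  I, the noise produces a small net ER efflux even at the resting balance;
  combined with the open-cell pump stoichiometry this depletes the ER over
  ~10³–10⁴ s. Statistics are therefore quoted over the 1000–1500 s windows
  that the underlying experiments use, and long ISI ensembles are pooled
  over seeds rather than taken from a single very long run.
- **Amyloid-β leak protocol.** Raising the external leak raises basal
  calcium and release (the modeled Aβ effect), but in this pathway the
  leak-to-nucleation coupling is far weaker than the glutamate route: the
  working model requires leak increases well above 20% before waves become
  certain, unless the baseline is placed close to the tonic-release
  threshold. The `network-abeta` preset therefore uses its own baseline
  leak (see the preset docstring); the sensitivity of this protocol to the
  baseline choice is intrinsic to the model.
- The wave detector (single-linkage clustering, 40 μm / 20 s linking,
  ≥ 8 cells) is a post-processing convention; at subthreshold stimulus
  levels chance chains of up to ~7 activations occur and are deliberately
  not counted as waves. Wavefront speeds are quoted from waves whose
  radius-time regression is meaningful (positive slope, R² ≥ 0.3).
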