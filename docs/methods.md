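# Methods

## Scientific scope

`eadsim` studies how early afterdepolarizations (EADs) — reversals of the
action-potential repolarization before it completes — organize into
tissue-level excitation patterns when the repolarization reserve of human
ventricular cells is reduced. The reserve is reduced along two axes:
scaling down the rapid delayed-rectifier potassium conductance G_Kr and
scaling up the L-type calcium conductance G_CaL. Sweeping the two
multipliers produces a two-parameter plane on which the package can
simulate, and then classify, the excitation regimes:

* **EE** — excitation ends after the last stimulus (no EADs, no pattern);
* **B** — bi-excitable fibrillation: sodium-mediated waves that still
  repolarize fully coexist with slower calcium-mediated EAD waves;
* **A** — calcium-wave fibrillation: cells no longer return below the
  sodium-recovery threshold, activity is carried by Ca waves alone;
* **O** — oscillatory regime: each cell is an autonomous oscillator around
  a depolarized equilibrium; apparent waves are phase waves;
* **S / MS / SB** — stable, meandering, and breaking-up spirals (labels
  supported by the classifier; their dynamics are not studied here).

## Cell model

The ionic model is the ten Tusscher–Panfilov 2006 (TP06) human ventricular
endocardial cell: twelve membrane currents (I_Na, I_K1, I_to, I_Kr, I_Ks,
I_CaL, I_NaCa, I_NaK, I_pCa, I_pK, I_bCa, I_bNa), Hodgkin–Huxley gating,
and the TP06 intracellular calcium cycle (SR release with a quenching
gate, SERCA uptake, leak, subspace diffusion, instantaneous buffering).
Membrane potential evolves as dV/dt = −(I_ion + I_stim) with currents in
pA/pF.

Two structural modifications define the *default* model of this package:
the time constant of the voltage-dependent L-type inactivation gate f is
halved (`f_tau_scale = 0.5`), which widens the window for I_CaL
reactivation during the plateau and hence for EADs, and G_CaL is doubled
(`gcal_base_scale = 2.0`) to compensate, leaving the baseline AP close to
the original model (APD90 ≈ 262 ms at the first paced beat).

The sweep multipliers `gkr_mult` and `gcal_mult` act **on this modified
default**: effective G_CaL = 2.0 · gcal_mult · G_CaL(TP06), effective
G_Kr = gkr_mult · G_Kr(TP06). Under this convention the single-cell
behaviour at fixed gkr_mult = 0.6 passes through the expected sequence
normal AP → EAD-deformed AP (≈ gcal_mult 3.5–5) → non-repolarizing
oscillation (≳ 6.0), which anchors the regime taxonomy (B at 4.0, A at
6.0, O at 6.5).

### Integration

Gates advance by the Rush–Larsen exponential update; V and the ionic
concentrations by forward Euler; dt = 0.02 ms by default. The
voltage-dependent gate steady states and exp(−dt/τ) factors, and all
voltage-only current factors, are precomputed on a uniform 25 µV grid
(−100…+100 mV) and linearly interpolated inside the compiled kernel; the
I_K1 rectification factor is tabulated on a (V − E_K) grid because E_K
drifts with intracellular K⁺. Table interpolation error is far below the
time-discretization error.

Correctness of the production stepper is established against an
independent reference implementation (tests/tp06_reference.py): the same
model typed separately, with no tables and plain forward Euler for every
variable at dt = 0.001 ms. At (1.0, 1.0) and (0.6, 4.0) the two agree to
≲ 0.1 mV RMS over 2 s (bound asserted: 1 mV). At the oscillatory point
(0.6, 6.5) the EAD oscillation is phase-unstable, so any two integrators
decorrelate after a few cycles; equivalence is asserted over the first
500 ms (RMS 0.13 mV) together with agreement on the non-repolarizing
character. Two resting states are provided: the published TP06 initial
condition (`resting_state`, the standard starting point for paced
protocols) and the true quiescent equilibrium of the modified model
(`equilibrium_state`, obtained by 60 s of unpaced settling; the published
state relaxes by ≈ 0.3 mV when left unpaced because it is a paced steady
state).

## Tissue model

Monodomain reaction–diffusion on regular 1D/2D/3D lattices:
∂V/∂t = −I_ion + ∇·(D∇V), with the transversely isotropic tensor

    D = D_t I + (D_l − D_t) α αᵀ,

α the local fiber unit vector, D_l = 0.00154 cm²/ms and D_l : D_t = 4 : 1
(a 2 : 1 conduction-velocity anisotropy). Note the tensor is implemented
in this standard form; a published variant that places D_l on the
isotropic term would give 2D_l − D_t along the fiber, contradicting the
role of D_l as the longitudinal diffusivity.

Spatial discretization is a conservative face-flux scheme: axis terms use
second-order central differences with face-averaged D_ii on the lattice
links; when fibers are off-axis (e.g. the wedge's −60°→+60° transmural
rotation) the mixed derivatives ∂_i(D_ij ∂_j V) + ∂_j(D_ij ∂_i V) are
added in face-flux form as well — the flux through each face is the
face-averaged D_ij times the face-averaged transverse centered
derivative — so the spatial mean of V is conserved exactly (to machine
precision) with reaction off, including at boundaries. No-flux boundaries,
mask edges and severed links are zero-flux faces (mirrored ghosts).
The discrete maximum principle is guaranteed for axis-aligned fibers; with
strong off-axis anisotropy centered mixed terms can violate it slightly,
as for all 9/19-point schemes of this type.

Impermeable walls (`insert_walls`) sever every node–node link crossing an
axis-aligned plane; nodes stay active, so decoupled compartments keep
their membrane dynamics.

### Numerics and calibration

Default dx = 0.04 cm (0.4 mm) and dt = 0.02 ms. The explicit scheme
requires dt ≤ dx²/(2 ΣD_ii); `run_simulation` warns when violated. At the
default resolution the calibration cable (8 cm, 200 nodes) gives:

* planar CV along fibers ≈ 67 cm/s (activation = first −20 mV upstroke
  crossing, probes at 2 and 6 cm), consistent with the ~70 cm/s target of
  human ventricular tissue. CV at this coarse dx carries a real
  discretization bias: 76 cm/s at dx = 0.02 cm and ≈ 80 cm/s at 0.01 cm,
  i.e. a 13 % gap between the 0.4 mm and 0.2 mm grids. Physics checks that
  concern scaling laws rather than the study's working resolution
  (CV ∝ √D) are therefore run on a resolved lattice (dx = 0.005 cm with a
  CFL-safe dt per diffusivity), where the ratios come out 2.02 and 2.00
  across a 16-fold range of D.
* electrotonic space constant λ ≈ 825 µm, from a sustained subthreshold
  current at one cable end, steady state (drift < 0.01 mV/ms), and an
  ln(ΔV)-versus-distance fit over the 10–90 % deflection range, with the
  deflection referenced to the simultaneous far-end potential (the whole
  cable drifts slowly, so the t = 0 potential is not a valid reference).
  λ is dominated by the I_K1 rectification knee at rest (V − E_K ≈
  +0.4 mV) and is therefore strongly probe-dependent: ≈ 815 µm for
  vanishing depolarizing probes, ≈ 1000 µm near the −70 mV limit, ≈
  740 µm for hyperpolarizing probes, and steeply smaller if the operating
  point sits 1–2 mV lower relative to E_K. Reported experimental/model
  values of ~0.5 mm fall inside this sensitivity range; this package
  reports what its stated protocol measures.

## Protocols

**Burst pacing.** An S1 (−52 pA/pF, 2 ms, an edge strip 0.2 cm deep) is
delivered every time a probe node just outside the strip falls below
−60 mV during the first 4 s; the pattern then evolves freely to 6 s. Two
guards make the trigger behave like its intent ("pacing frequency set by
the APD"): the probe must have been above −60 mV since the last stimulus,
and a lockout (default 100 ms) bounds the retry rate — an S1 into
partially recovered tissue often fails to capture, and with a shorter
lockout the resulting graded responses re-trigger the rule every ~25 ms.
With these defaults the delivered pulse count decreases monotonically as
the AP lengthens across the sweep (25 → 3 pulses from gcal_mult 1.0 to
6.5 at gkr_mult 0.6), and in the oscillatory regime the threshold is never
reached again after onset, so pacing stops by itself. A 1 ms S1 (the
single-cell convention) frequently failed to capture tissue that had just
recovered to −60 mV, hence the 2 ms tissue default; both are configurable.

**S1S2.** A plane wave from one edge, then an S2 over the lower-left
quarter-plane inside the S1 wake; when the timing is not given, the wake
is scanned in 20 ms steps. Success is declared when the phase mapping
finds a singularity that survives one rotation. At desk scale the TP06
wavelength (CV × APD ≈ 20 cm) exceeds any affordable sheet, so spiral
initiation is marginal; the test suite verifies the mechanism underneath
instead — unidirectional block inside the vulnerable window — plus the
too-early and too-late failure branches.

**Decoupling.** From a running pattern's final state, walls are inserted
along orthogonal mid-planes and the simulation continues ≥ 1 s (optionally
once more without walls as a lag control). *Real* (diffusion-mediated)
waves are absorbed: a compartment without a source falls silent, so the
pattern fails the all-compartments-active test. *Phase* waves — apparent
propagation across autonomous oscillators with a spatial phase gradient —
continue unchanged, with cross-wall activation lags within one sample
interval of the control.

## Pattern characterization

* **Average spectrum** — per-node mean-subtracted amplitude spectra over
  the last second (1 Hz resolution), averaged over up to 2983 equidistant
  nodes; peaks ranked by prominence. The two most prominent sub-6.5 Hz
  peaks are labelled β (the lower frequency, the AP-to-AP beat) and α (the
  higher, the EAD-to-EAD oscillation); a single low peak is labelled α
  (pure oscillation).
* **η index** — η = x/(2n), with x the total number of −60 ± 1 mV band
  transits over the window across n nodes; the hysteresis band (a transit
  requires crossing from below −61 to above −59 mV or back) prevents
  double-counting sampling jitter, and the ÷2 counts one AP (upstroke +
  downstroke) as one event. A fully repolarizing cell with five APs in 1 s
  scores exactly 5; a non-repolarizing oscillator scores 0.
* **Classifier** — decision ladder EE (no activity) → O (η = 0 plus phase
  waves, or no node below −60 mV) → S/MS/SB (filament count and core
  displacement) → A vs B (α-vs-β prominence and η against a configured
  fraction, default 0.5, of the β-implied beat count). Conflicting
  ingredients return a best-effort label flagged low-confidence.

## Phase mapping

EAD-deformed APs make isopotential-crossing definitions of a spiral core
ambiguous, so phase is reconstructed per node as: Savitzky–Golay smoothing
(3rd order, 102 ms frame — 103 samples at the 1 ms analysis rate), minima
and maxima of the smoothed trace joined by monotone PCHIP envelopes, the
envelope midline subtracted from the raw trace, and the angle of the
analytic signal (trace, Hilbert transform) taken in [−π, π]. Every AP and
every EAD oscillation then contributes one full 2π cycle (verified on
stylized traces: 3 APs × (1 + 2 EADs) = 9 cycles). Traces with fewer than
two extrema fall back to mean subtraction, flagged.

Singularities are lattice plaquettes whose wrapped phase circulation is
±2π (|charge| ≥ 0.9 reported with sign); in 3D, slices along the three
lattice directions every 5 nodes are combined. Per-frame points are
clustered (radius 2 nodes), linked across frames (nearest neighbour ≤ 3
nodes, gaps ≤ 10 ms), and only tracks outliving one rotation (200 ms)
inside the [200, 800] ms interior of the final second are kept (the edges
are excluded against Hilbert end effects). On analytic spiral fixtures the
detected core sits within one node of the true core at every frame, total
charge is conserved, and a 150 ms transient defect is rejected while a
300 ms one is kept.

## Pseudo-ECG

A torso-free far-field surrogate: φ(e, t) = −Σ D∇V · ∇(1/|x−e|) dV over
the tissue, per electrode (default: nine points on a spherical cap 4 cm
above the tissue center; the layout echoes a 9-lead concept but has no
anatomical meaning). The signal is linear in V, vanishes for uniform
fields, gives a positive deflection for a wave approaching an electrode,
and decays as 1/r² for a compact front (a voltage step across one cable
link behaves as a two-node current dipole; verified to 1 % at 10–40 node
spacings). This surrogate reproduces rhythm and relative-amplitude
contrasts between regimes, not clinical lead morphology.

## Synthetic fixtures

`eadsim.synthetic` generates movies with exact ground truth so every
analysis is testable without tissue runs: Archimedean-spiral phase fields
with known (optionally drifting) cores and chirality equal to the detected
charge; plane waves; independent-oscillator fields with a linear phase
gradient (period 200 ms, floor above −59 mV — the O-regime structure, and
by construction unaffected by decoupling); and stylized AP traces built
from C¹ chains of half-cosine segments with exact AP and EAD counts
(rest −86 mV, peak +30 mV, EAD swings −30…−5 mV, EAD half-period 65 ms —
slow enough for the 102 ms smoothing frame). All generators are
deterministic; a seed drives only optional jitter. What the fixtures do
not emulate: TP06 AP morphology, conduction-velocity restitution, or any
coupling between nodes — so fixture-based tests validate the *analysis*
stages, not tissue dynamics; the simulated anchors do that.

## Scaled-down study conditions, and what they show

The source study ran on anatomically accurate ventricles (~10 cm, 3D) on
GPUs. This package reproduces at desk scale (minutes on one CPU):

* the two printed tissue calibrations on a 1D cable (CV; λ with the
  caveat above);
* the single-cell regime anchors and their order along the sweep;
* the O-regime signature on a single cell or small sheet: dominant
  last-second frequency 6 Hz (printed value 5 Hz, the ±1 Hz bin), η = 0;
* the B-regime spectral signature on a burst-paced 4×4 cm anisotropic
  sheet: the two most prominent sub-6 Hz peaks at 2.0 Hz (AP-to-AP) and
  4.0 Hz (EAD-to-EAD) with η ≈ 1.0 > 0, measured over the final paced
  second (3–4 s). A desk-scale 2D sheet cannot self-sustain the B pattern
  once pacing stops: the sodium-wave transit (~60 ms across 4 cm) keeps
  the sheet phase-synchronized relative to the ~250 ms EAD cycle, so it
  repolarizes globally a few hundred ms after the last stimulus
  (edge-paced 4×4, corner-paced 6×6 and cross-fiber-paced 8×4 cm sheets
  all behave this way). Self-sustained B/A fibrillation and filament
  statistics at the printed values therefore remain organ-scale results;
  the package's filament machinery is validated on analytic fixtures
  instead.

One distinction inverts at this scale: in the organ-scale study the B
regime's AP (β) peak dominates the EAD (α) peak, while on the desk-scale
paced sheet α dominates — with η > 0 still separating B from A. The
classifier flags such mixed evidence as low-confidence rather than hiding
it. The A anchor (0.6, 6.0) is not distinguishable from O at desk scale
(isolated cells there are already autonomous oscillators, and the Ca-wave
structure that defines A needs domains beyond the Ca wavelength).

## Known limitations

* Endocardial TP06 only; no transmural heterogeneity, no Markov channel
  models, no restitution tuning.
* Bidomain effects, anatomical meshes, torso lead fields and Purkinje
  activation are out of scope; the pseudo-ECG is a volume-conductor
  surrogate.
* The coarse working resolution (0.4 mm) underestimates CV by ~13–16 %
  relative to converged values — the same operating point as the source
  study, kept deliberately.
* 3D filament tracking counts singular points per slice; it does not
  reconstruct connected filament curves.
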