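# Methods

## The measurement chain

A cardiac-gated three-direction phase-contrast (PC) acquisition yields, per
cardiac phase, one magnitude volume and three velocity-encoded phase
volumes. The phase is linear in velocity, `φ_d = π v_d / VENC_d`, wrapped to
(−π, π]; decoding inverts this map. The study conditions emulated throughout
are 32 cardiac phases per cycle, 10 axial slices, isotropic voxels, and
VENC 5 cm/s for healthy volunteers versus 30 cm/s for iNPH/AD patients.

From the decoded field the pressure gradient is obtained pointwise from the
incompressible Navier–Stokes momentum balance,

    ∇p = μ∇²v − ρ ∂v/∂t − ρ (v·∇)v ,

and rotation as the curl ∇×v. The three terms (viscosity, acceleration,
convection) are returned separately; the identity ∇p = viscosity −
acceleration − convection holds exactly elementwise by construction.

## Discretization

- **Space**: 2nd-order central differences; the Laplacian is the 7-point
  stencil; convection uses the non-conservative form v·∇v without upwinding
  (the flows are smooth and laminar, so this keeps all terms at the same
  2nd-order accuracy).
- **Time**: central difference with periodic wrap — the cine covers exactly
  one cardiac cycle, so phase 0 neighbors phases N−1 and 1. At 32 phases the
  derivative of a fundamental-frequency waveform carries a fixed amplitude
  factor sin(ωΔt)/(ωΔt) ≈ 0.9936 (−0.6%).
- **Walls**: voxels whose 6-neighborhood is not fully inside the CSF mask
  are flagged invalid and excluded from ROI statistics. One-sided stencils
  at the lumen wall manufacture spurious gradients; exclusion is the
  conservative choice.
- **Units**: velocities are carried in cm/s and geometry in mm everywhere;
  conversion to SI happens only inside the fluid-mechanics module, which
  emits Pa/m and rad/s (cycles/s = rad/s / 2π).

## Phantoms and ground truth

Womersley's solution for oscillatory laminar flow in a rigid circular tube
driven by −∂p/∂z = Re{G e^{i(kωt+φ)}} per harmonic k,

    u(r,t) = Re{ (G e^{iφ} / iρkω) · [1 − J₀(i^{3/2} α_k r/R) / J₀(i^{3/2} α_k)] · e^{ikωt} },
    α_k = R √(kω ρ/μ),

is sampled at voxel centers (optionally averaged over a 4×4 in-voxel grid to
emulate partial volume). The generator returns the exact axial dp/dz time
series, which the Navier–Stokes stage must recover: for this flow convection
vanishes identically and ρ∂u/∂t − μ∇²u equals the driving gradient. At the
defaults (R = 2 mm, 60 bpm, CSF ≈ water: ρ = 1000 kg/m³, μ = 1.0×10⁻³ Pa·s,
the standard assumption in PC-MRI pressure-gradient work)
α ≈ 5, the physiologic regime of the aqueduct. Poiseuille and rigid-rotation
fields provide closed-form benchmarks for which central differences are
exact (quadratic and linear fields respectively).

The encoding model forms two interleaved complex acquisitions A·e^{±iφ/2}
plus independent complex Gaussian noise of SD 1/SNR per channel (unit
template intensity), and takes the phase of their product — so noiseless
encoding inverts exactly, super-VENC velocities alias naturally, and at high
SNR the velocity noise SD is √2·VENC/(π·SNR). The magnitude template has
three intensity classes (background 0.1, brain 0.5, CSF 1.0) so the
segmentation stage sees realistic contrast.

## Cohort simulation: the hyperdynamic condition

The study-scale simulator draws 19 controls, 10 iNPH and 7 AD subjects.
Per-subject amplitude G and tube radius are log-normal (σ_log 0.25 and 0.05;
medians below), heart rate ~ N(65, 5²) bpm, SNR 30. Controls: G median
100 Pa/m at the cardiac fundamental, VENC 5 cm/s. Patients: same tube
radius (unchanged aqueduct morphology), VENC 30 cm/s, and their driving
gradient concentrated in the **4th cardiac harmonic** — a stylized sharp,
accelerated waveform. Because Womersley velocity scales as G/(ρkω), a
~4-fold pressure-gradient amplitude at k = 4 leaves the velocity amplitude
at control level: elevated acceleration, not velocity, carries the elevated
pressure gradient. The patient median was calibrated by paired simulation
(common random numbers, 1200 control/patient pairs) to 354.5 Pa/m so that
*measured* velocity-metric medians coincide with controls to ~0.3%
(matching also absorbs the small magnitude-noise bias that the higher
patient VENC introduces); it is fixed in the defaults.

With these conditions a default cohort run (seed 1) yields group medians of
1.8/1.8/1.8 cm/s for velocity (control/iNPH/AD), 125/599/594 Pa/m for the
pressure-gradient metric and 0.95/3.5/3.5 cycles/s for rotation — the same
order and separation structure as reported aqueductal values, with velocity
indistinguishable across groups. (The measured pressure-gradient metric
exceeds the driving amplitude because the peak of the noisy ROI-mean
magnitude is taken; group separation, not absolute accuracy, is the point
of the noisy cohort — absolute accuracy is validated noiselessly.)

What the phantom does **not** model: brain anatomy, background phase from
eddy currents or Maxwell terms, trigger jitter of the peripheral-pulse
gating, k-space/Bloch physics, or compliant (non-rigid) walls. Passing
tests therefore demonstrate correctness of the numerics and the claimed
statistical behaviour under the stated flow model, not robustness to every
in-vivo artifact.

## Segmentation

Spatial fuzzy c-means with membership weighting u′ ∝ u^p·h^q, where h is
the neighborhood (3×3×3) sum of memberships; p = q = 1, fuzzifier m = 2,
c = 3 classes, tol 1e-5 on centroid motion, ≤ 200 iterations. With q = 0 the
update is classic FCM. Initialization is deterministic (10th/50th/90th
intensity percentiles); empty clusters are re-seeded from data quantiles
with a warning. The CSF class is the highest-intensity centroid (T2-bright
CSF); the lumen mask is the largest 6-connected component above membership
0.5. Segmentation runs on the time-averaged magnitude volume.

## ROI metrics

ROIs sit on two axial slices (aqueduct entry and outlet; defaults z = 2 and
z = −3) at the in-plane center of mass of the lumen, taking the nearest 7
lumen pixels for velocity/pressure gradient and 16 for rotation — inside
the contracts of 4–8 and 12–20 pixels, which are enforced as errors. Per
phase the vector magnitude is averaged over valid ROI voxels; the waveform
is reduced to its **peak** by default (PC-MRI convention; time-mean and
median are selectable and recorded in provenance). Entry and outlet metrics
are averaged arithmetically. Rotation is reported in cycles/s; a per-area
variant (cycles/s per cm² of nominal ROI cross-section) is provided for
comparability with per-area reporting conventions but is labelled
non-canonical, since that normalization is not standard.

## Statistics

Two-sided Mann–Whitney U (midranks for ties; exact enumeration when
n+m ≤ 20 and tie-free, otherwise normal approximation with tie and
continuity corrections) and two-sample Kolmogorov–Smirnov (exact when
n+m ≤ 16, otherwise the Kolmogorov distribution at effective size
nm/(n+m)). No multiplicity adjustment is applied, and both facts are
stamped into the output. Box-plot summaries use Tukey hinges; outside
values lie beyond 1.5·IQR from a hinge, far-out values beyond 3·IQR and are
not double-counted.

For the qualitative pattern check, a pairwise difference is *claimed* only
when both tests agree at p < 0.05 — the conservative rule for an analysis
that reports two tests side by side without designating a primary one. The
type-I calibration experiment pools Mann–Whitney p-values (the standard
two-sample location test) across the three pairwise null comparisons.

One structural consequence: the velocity comparisons of a matched cohort
are true nulls, so even perfect matching leaves a few-percent chance per
run that some velocity comparison is claimed significant by both tests;
the cohort pattern-reproduction rate therefore saturates near — not at —
100%, and its empirical value over 100 runs carries binomial noise of
about two runs.

## Validation experiment sizes

The validation suite uses problem sizes chosen for desk-scale runtimes:
Womersley recovery on a 24×24×10 grid at 0.5 mm and 32 phases; convergence
at 0.8/0.4/0.2 mm with 128 phases (the finer time axis keeps the fixed
−0.6% temporal bias from masking the spatial order, and the error is
measured on the fixed core region r < R/2 so the shrinking boundary-layer
voxels do not contaminate the slope); statistical exactness over all
tie-free rank configurations with n+m ≤ 10; type-I calibration over 1000
null cohorts; pattern reproduction over 100 full cohort runs of 36 subjects
on a 20×20×10 grid at 0.4 mm (finer than the acquisition's 1.96 mm voxels,
which cannot hold a full interior stencil inside a 2 mm-radius tube — with
wall voxels excluded, pressure-gradient evaluation needs the lumen resolved
by several voxels).

## Known limitations

- The convective term is retained but is negligible for the axial phantom
  flows (it vanishes identically for fully developed tube flow); its
  discretization is exercised by dedicated shear-field tests instead.
- Temporal unwrapping resolves single wraps with smooth waveforms; a true
  adjacent-phase jump exceeding VENC is indistinguishable from a wrap, and
  such voxels are invalidated, not guessed.
- The per-area rotation variant divides by nominal ROI area; it is a
  labelled convenience, not a physically derived quantity.
- Segmentation operates on phantom magnitude images whose classes are
  well-separated by construction; performance on clinical T2-weighted
  contrast is outside what these tests can show.
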