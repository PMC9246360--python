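# Methods

## Scattering models

All models are orientationally averaged single-particle form factors in
the dilute limit: the structure factor is taken as S(q) = 1 throughout.
This is a deliberate simplification — at the amphiphile concentrations
of a drying crystallization matrix (5–15%) interparticle interference is
not strictly negligible, but it does not change which particle shape
fits a curve, only the apparent structural parameters.  Units are fixed
package-wide: q in Å⁻¹, lengths in Å, scattering length densities (SLD)
in Å⁻².

### Bicelle (core–shell circular cylinder)

A disc with three nested homogeneous solids: a hydrophobic lipid core
(radius `r_core`, height `h_tail`), polar-head faces of thickness
`h_head` above and below the core, and a detergent belt of thickness
`delta_r` spanning the full particle height.  With h = h_tail/2,
sinc(x) = sin x/x and B(x) = 2J₁(x)/x, the amplitude at angle α between
the cylinder axis and **q** is a contrast-weighted sum of solid-cylinder
amplitudes:

    F(q, α) = (ρ_core − ρ_face)·V_A·sinc(qh cos α)·B(qR sin α)
            + (ρ_face − ρ_rim)·V_B·sinc(q(h+h_head) cos α)·B(qR sin α)
            + (ρ_rim − ρ_solv)·V_C·sinc(q(h+h_head) cos α)·B(q(R+ΔR) sin α)

with V_A, V_B, V_C the volumes of the three nested solids, and

    I(q) = (scale/V_C) ∫₀^{π/2} F²(q, α) sin α dα + background.

The full-height belt keeps the nested-solid decomposition exact.  The
quantities usually quoted for a bicelle are exposed as `total_radius`
(= r_core + delta_r) and `total_height` (= h_tail + 2 h_head); the
default geometry gives 50 Å and 45 Å with h_tail fixed at 28.8 Å (the
DMPC hydrophobic-core thickness from the three-slab bilayer model, with
area per lipid 61.8 Å²) and delta_r fixed at 11.4 Å (the CHAPSO
molecular extent).

### Ribbon (core–shell elliptical cylinder)

An elongated aggregate with a flattened hydrophobic core (semi-axes
`r_minor` ≤ `r_major`, length `length`) and a hydrophilic shell of
uniform thickness `t_shell` on all faces.  The cross-section enters
through the effective radius r_eff(ψ) = √(r_minor² cos²ψ + r_major²
sin²ψ), and the intensity is a double average over α and the
cross-section azimuth ψ:

    I(q) = (scale/V_out)·(2/π) ∫∫ F²(q, α, ψ) sin α dα dψ + background.

When ribbons form from bicelles, lipid heads and detergent redistribute
into one hydrophilic shell; its thickness follows
t_shell = max(h_head, ΔR), which is 11.4 Å for this system.  The
default core geometry is 20 × 43 Å semi-axes with length 330 Å.

### Quadrature and its verification

Both averages use fixed-order Gauss–Legendre quadrature, 76 nodes per
angle (76 × 76 for the ribbon).  Doubling the order changes intensities
by < 1e-5 relative over the instrument q-range (tested).  The
deterministic quadrature is cross-checked against a Monte-Carlo
orientation average (cos α uniform on [0, 1], ψ uniform on [0, π/2])
that shares only the amplitude kernels: agreement within 3 Monte-Carlo
standard errors at 10⁵ samples is enforced in the test suite, alongside
two exact limits — the bicelle with h_head = ΔR = 0 equals the uniform
cylinder to 1e-8 relative, and the circular ribbon with merged face/rim
SLD equals the bicelle model to 1e-6 relative.

Polydispersity and resolution smearing are not modeled: the fits are
monodisperse and no resolution function is assumed.

## SLD module

X-ray SLD is n_electrons·r_e/V with r_e = 2.8179403e-5 Å; neutron SLD is
Σb/V; mixtures combine by volume fraction.  The shipped composition
table (water, heavy water, DMPC head/tail moieties, CHAPSO) contains
physically derived fixtures — electron counts from molecular formulas
and literature-scale molecular volumes, with the DMPC tail volume tied
to the geometric fixture A_L × H_tail/2 = 889.92 Å³ — not fitted
instrument values.  Default model SLDs (tail 6.65e-6, head 1.44e-5, belt
1.16e-5, water 9.42e-6 Å⁻²) follow from that table; the buffer SLD at
each crystallization step is a configuration input.

## Fitting

The objective is the reduced chi-square over the fit window.  The
optimizer is scipy's bounded trust-region least squares (`trf`) on the
weighted residuals, tolerances 1e-8, at most 2000 residual evaluations.
Curves without uncertainties (synthetic noise-free data) can opt into a
relative sigma surrogate (`sigma_fallback`, default 1% when enabled).
`multistart_fit` restarts from Latin-hypercube points drawn one per
restart from a seed-stable stream, so the restart sequence for n starts
is a prefix of the sequence for n+1; the best chi-square wins.
`compare_models` ranks fits with ties (within 1e-12) broken by fewer
free parameters, then input order.  An optional q⁴ weighting multiplies
data and model by q⁴ in the residuals to emphasize wide-angle features.

Verified recovery behavior: on noise-free bicelle/ribbon curves with
±30% perturbed starting values all free parameters return within 0.1%;
with 2% multiplicative Gaussian noise the median error over 20 seeds
stays below 5%.

## Peak analysis

**Baseline.** A lower-envelope estimate by clipped smoothing in
(log q, log I): on a uniform log-q grid, a grey-scale opening
(min-filter then max-filter, window 2·half_width+1 = 25 samples by
default) followed by moving-average smoothing, clipped from above by the
data; boundary windows see a straight-line continuation of the edge
slope rather than replicated samples.  A pure power law (linear in
log-log) is reproduced exactly; smoothly curved peak-free regions are
followed to a single chord sagitta; peaks narrower than the window are
removed.  This is an empirical baseline — the model-based alternative
(subtract a fitted ribbon curve) is available by fitting and
subtracting explicitly.

**Peaks.** Local maxima above a prominence threshold seed Gaussian
refinement; maxima within 8 samples are fitted jointly as a sum of
Gaussians plus a shared linear term, each center constrained to one grid
step around its raw maximum and each width capped by the distance to its
nearest neighbour, so overlapping reflections stay distinct and no
component can swallow the cluster.  Amplitudes are capped at 1.8× the
largest sample in the window (the most a sampled Gaussian at the minimum
accepted width can exceed its largest sample), widths below half the
local grid spacing are rejected as single-point spikes, and, when the
curve carries uncertainties, peaks below 5 local sigma are rejected.

**Series.** d = 2π/q.  Order grouping is greedy: each unassigned peak
(ascending q) seeds a series as order 1 and absorbs peaks at n·q₁ within
a relative tolerance (default 3%, order cap 4).  The 3% default is
chosen so that a pair at position ratio 1.886 (spacings 660 and 350 Å)
is *not* classified as a 1:2 series — that ratio genuinely differs from
2 — while true lamellar orders are grouped.  The order cap keeps a
long-period fundamental from swallowing unrelated peaks at large
multiples.

**Slopes and differences.** Low-q slope is ordinary least squares of
log₁₀I on log₁₀q (exact for pure power laws).  Difference intensity
I_sys − c·I_ref propagates both uncertainty columns in quadrature and
requires matching grids unless interpolating re-binning is requested.

## Crystal indexing

Bragg positions use the monoclinic formula (unique axis b, β between a
and c).  Enumeration covers both signs of h (q(h,k,l) ≠ q(−h,k,l) in
general, while q(h,k,l) = q(−h,k,−l) exactly, so k, l ≥ 0 suffice);
degenerate positions are collapsed before assignment so multiplicity
never enters 1D matching.  The 2₁ screw-axis absences (0k0, k odd) are
off by default and available behind a flag.

Refinement alternates nearest-reflection assignment with bounded least
squares on the relative discrepancies until the assignment map is a
fixed point.  Because a wrong assignment map is its own fixed point, the
alternation restarts from a deterministic list of perturbed cells (an
angle grid to ±10% crossed with random edge jitters — the angle
dominates basin selection), keeps the solution explaining the most peaks
at the lowest objective, and stops early on an exact indexing.  An
optional low-q warm-up first anchors the cell on the sparse low-order
region (with outlier trimming); it is used for standalone peak lists and
disabled inside the stage classifier, whose low-q region contains
lamellar peaks that are not lattice reflections.  Peaks whose final
relative residual exceeds 2% are reported as unindexed; those with
spacings in a 60–70 Å window are flagged as candidate crystal-bound
lamellar (L_cryst) reflections.  Convergence is reliable for random ±5%
starting errors (exercised in the tests); simultaneous worst-case ±5%
excursions on all four parameters can still land in a neighbouring
basin — ab initio indexing is out of scope.

## Stage classification

A rule cascade over features computed by the other modules:

1. ≥ 5 wide-angle peaks indexable on the candidate monoclinic cell
   (more peaks than the 4 refined parameters) with the refined cell
   within 10% of the candidate → CRYSTAL;
2. any peak at d ∈ [450, 750] Å → TRANSIENT_ORDERED;
3. a lamellar series (order 2 present) with d ∈ [60, 90] Å and a
   ribbon-model best fit → RIBBON_LAMELLAR;
4. ribbon chi-square at most half the bicelle chi-square → RIBBON;
5. low-q log-log slope ≤ −1.5 (extended-sheet signature) → BICELLE_PM;
   otherwise BICELLE_CONCENTRATED.

The model comparison masks all extracted peaks (±3.5σ) and adds a free
q⁻² amplitude to both candidates so residual sheet scattering cannot
decide the shape question; classification fits run at reduced quadrature
order (32 nodes) with a capped iteration budget, which is ample for
model discrimination.  Evidence peaks must rise ≥ 30% above the local
baseline and be narrower than 16% of their own position — Bragg peaks
are resolution-limited, while baseline artifacts and noise humps are
broad and shallow.  A genuine lamellar stack must show its second order;
a fundamental paired only with an accidental higher multiple does not
qualify (this distinction matters: a crystal-bound lamellar peak at
64 Å and the (2,0,0) reflection sit near a 1:3 ratio).

`track_series` audits that stage labels are non-decreasing in time; the
transient ordered phase is exempt (it appears and disappears), and
violations are flagged, never corrected.

## Synthetic data

The generator encodes the study conditions: a 150-point log grid over
0.006–0.8 Å⁻¹ (the combined range of the two instrument geometries),
lipid:detergent molar ratio Q = 2.69, 5.6% total amphiphile.  Stage
composites are built from: a q⁻² power law for membrane sheets (the
sheet amplitude is set so the composite low-q slope of the first stage
is ≈ −1.8, the extended-sheet signature of the crystallizing mixture);
the bicelle and ribbon form factors at their default geometries;
Gaussian lamellar orders at 2πn/73 Å⁻¹ (ratio exactly 1:2); a transient
pair at d = 660 and 350 Å (ratio 1.886, deliberately not 1:2);
monoclinic reflections of the a = 43.91, b = 109.33, c = 53.4 Å,
β = 104.63° cell with a q⁻² amplitude envelope; and a crystal-bound
lamellar peak at d = 64 Å (precursor spacing 68 Å available as a
parameter).  The seven default reflections are chosen pairwise separated
by ≥ 0.02 Å⁻¹ and clear of the lamellar orders so the 150-point grid
resolves each as its own maximum; peak widths (lamellar 0.008/0.014,
crystal 0.012, L_cryst 0.007, transient 0.0012/0.0022 Å⁻¹ FWHM) span
several grid samples, as real detector data do.

Noise is a counting-statistics surrogate: Gaussian with
σᵢ = max(floor, level·√Iᵢ) or max(floor, level·Iᵢ), the applied σ stored
on the curve, bit-reproducible per seed.  What the generator does *not*
emulate: interparticle interference, resolution smearing, polydispersity,
detector artifacts, incoherent background drift and the continuous (as
opposed to staged) evolution of a real sample.  Passing tests therefore
demonstrate the correctness of the analysis chain on curves with the
right structure, not instrument-grade robustness.

## Known limitations

* Stage classification at 5% multiplicative noise is ≈ 92% accurate
  over seeded timelines (100% noise-free); the residual errors are
  crystal-stage curves whose weak high-q reflections lose peak-center
  accuracy, and ribbon-vs-bicelle calls where the chi-square contrast
  falls under the 2× threshold.
* The log-spaced instrument grid under-samples narrow wide-angle peaks
  (Δq/q ≈ 3.3%); real linear-detector data are denser there.
* Cell refinement needs an initial cell; basin convergence is tested for
  random ±5% errors, not guaranteed beyond.
* The finite thickness of a 49 Å sheet steepens its apparent low-q
  slope beyond −2 once q approaches 1/thickness; the −2 asymptote is
  only reached on windows with q ≪ 1/L (see the slope tests).
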