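# Methods

## Scope and units

`cryopeel` models the low-temperature, quasi-static peeling of a short
single-stranded DNA oligomer off a corrugated metal surface by a stiff AFM
tip, and the analysis of the resulting stiffness–distance record.  All
lengths are nm, forces nN, energies nN·nm; a stiffness in nN/nm is
numerically equal to N m⁻¹, so fitted values compare directly with
stiffnesses quoted for sensors and molecules.

## Coarse-grained energy model

One bead per nucleotide; a 20-mer has 19 backbone links.  Each
phosphodiester linkage carries one negative unit charge, so charge
neutrality fixes the counterion count at n_bases − 1 (19 Na⁺ for the
20-mer).  The total energy is

E = Σ ½·k₁·(|r_{i+1} − r_i| − b)²                    (backbone bonds)
  + Σ V_adh(z_i) + V_corr(x_i, y_i, z_i)              (surface)
  + ½·k_tip·|r_att − r_tip|²                          (tip spring)

* **Bonds.** Harmonic with stiffness k₁ = 32.6 nN/nm per repeat, the
  stiffness per repeat of fully stretched ssDNA, so that under end force F
  (adhesion off) every repeat elongates by F/k₁.  Repeat length b defaults
  to 0.63 nm, making the 19-link contour ≈ 12 nm.  Both are configurable.
* **Adhesion.** Per-bead, height-only:
  a Morse contact well D[(1 − e^{−az})² − 1] of depth D = 0.22 nN·nm and
  inverse width a = 8 nm⁻¹ (maximum holding force aD/2 ≈ 0.9 nN), plus a
  Gaussian *shelf* of depth 0.08 nN·nm centred at 0.2 nm (width 0.18 nm) —
  a metastable partially-detached state in which the base has peeled but the
  backbone still binds.  A repeat therefore leaves the surface in stages
  (peel, lift, detach), each an abrupt force drop, which is what produces
  dip spacings well below the projected repeat length.  The depths are
  effective values — they absorb base adhesion plus unfolding work — and
  are calibrated so the simulated peeling tension is in the nN range.
* **Corrugation.** Separable sinusoid with the surface lattice period
  (0.28 nm), amplitude 0.08 nN·nm peak-to-valley per base, windowed in
  height by Gaussians at the contact *and* shelf heights: the lattice
  registry acts on adsorbed and partially-detached bases.  Maximum lateral
  holding force ≈ 0.45 nN.  Energy is invariant under in-plane translation
  by one lattice period.
* **Tip.** A 3-D harmonic spring (k_tip = 35 nN/nm) between a virtual tip
  point and the attachment bead.  The tip point sits vertically above the
  attachment bead's starting position and moves only in z.  The reported
  force F = k_tip (Z − Z_P) — Z the tip displacement, Z_P the vertical
  displacement of the pulled bead — is exactly the vertical spring-force
  component.  The default attachment bead is index 1, the node closest to
  the backbone phosphate between the first two nucleotides; the terminal
  base hangs below the grip, so the lifted span to the far end is
  n_bases − 2 repeats.

## Folded starting conformations

`build_chain` draws a self-avoiding planar walk with step b, minimum
non-bonded separation 0.35 nm, confined to a disc of diameter 4 nm so the
folded oligomer's in-plane extent stays well below its contour length.  The
walk starts on the disc *edge* and drifts monotonically away from the start
(the probe grips the oligomer at one extremity of the folded blob), so
successive bases lie progressively farther from the pulling axis.  That
growing offset keeps the lifted segment inclined — declining slowly from
≈ 35° to ≈ 15° as the segment lengthens against the bounded blob radius,
about 20° on average over the second half of the peel — which in turn makes
full detachment occur below the backbone contour length.  The atomistic
folding pathway is not reproduced — only the compact footprint and edge
pick-up geometry of the adsorbed state.

## Quasi-static retraction

The tip anchor rises in steps dz (default 0.002 nm, well below a quarter
lattice period).  At each step all bead coordinates are relaxed to a local
minimum (L-BFGS with analytic gradients, target gradient 10⁻⁶ nN), warm
started from the previous step.  Warm starting makes the system ride
metastable branches until they vanish — that hysteresis *is* the stick-slip:
base detachments, shelf hops and lattice slips appear as discontinuous force
drops.  At 5 K thermal energy is negligible against the nN·nm barriers, so
this zero-temperature limit replaces thermostatted steered pulling; pulling
speed is carried as metadata only.  An optional Gaussian coordinate jitter
(default 0, i.e. strictly deterministic) emulates small finite-temperature
perturbations before each relaxation.

Energy bookkeeping: moving the tip with frozen beads does external work
equal to the tip-spring energy change, which exceeds the reversible work by
exactly ½·k_tip·dz²; relaxation then releases the step's dissipation.  The
recorded work integral ∫F dZ matches ΔE + Σ dissipation to well under 1%
at the default step (the residual is pure quadrature error, checked by
`work_energy_residual`).

Smoothing of F uses a centred running average with symmetrically shrunken
end windows (linear segments are reproduced exactly).  The default window,
0.02 nm, plays the role of the thermal averaging interval of a steered
simulation; the simulator has no physical clock, so the window is expressed
in distance.  The effective stiffness is k = d⟨F⟩/dZ by central finite
differences (one-sided at the ends), with negative excursions preserved.

The retraction has two regimes.  The *initial unfolding* phase (roughly the
first 1–1.5 nm) lifts the folded pick-up end through correlated,
geometry-dependent rearrangements: the required force rises above the later
peeling level and partly relaxes continuously, so the load is not monotone
between events there — this is the regime in which the corresponding
experiments end by premature rupture of the tip–molecule bond.  In the
subsequent *sequential peeling* regime the load builds monotonically between
discrete drops up to small reversible softening (an order of magnitude below
the ~0.5 nN event drops), and full detachment occurs slightly before the
chain is fully stretched because the lifted segment stays inclined.

Degenerate and failure behaviour: relaxation residuals up to 5×10⁻³ nN are
accepted (an order below the detachment force floor; the post-detachment
dangling chain has nearly flat modes), anything worse raises a step error
carrying Z and the residual.  Ties when two bases could detach in one step
are left to the relaxer; events may merge.

## Sensor conversion and artifacts

For a sub-ångström oscillation amplitude the frequency shift of the
tuning-fork sensor is proportional to the force gradient; the package treats
k = 2k₀Δf/f₀ as exact, with k₀ = 1800 N m⁻¹ and f₀ = 26 kHz defaults.
Measurement noise is Gaussian white on the k channel (the experimental noise
spectrum is not modelled).  Premature rupture of the tip–molecule bond
truncates the trace at the first sample where F reaches the rupture force
and zeroes the signal channels after it; the rupture threshold is a free
parameter (only the rupture position, not the force, is constrained by
experiments).

## Envelope fit

In the reciprocal domain the springs-in-series envelope is linear in the
repeat count: 1/k = 1/k_ends + n/k₁ with n = ⌊Z/(b cosθ)⌋.  The fit is a
grid search over b cosθ (default 0.40–0.90 nm, step 0.005) with an exact
linear least-squares solve per candidate; k_tip is held fixed and k_pin is
recovered from the fitted intercept via 1/k_ends = 1/k_tip + 1/k_pin.
θ is not a separate parameter — only the product b cosθ is identifiable
from peak positions.

Candidate selection needed two refinements beyond "smallest residual":

1. **Peak retention first.** A candidate period whose assignment pushes
   peaks outside the fitted n-range (default 1–18) discards data and
   trivially shrinks its residual sum; candidates retaining more peaks win
   outright.
2. **Plateau alignment.** The height residual is nearly flat in b cosθ over
   whole intervals of equivalent integer assignments (and under noise the
   argmin over these intervals is essentially random), while the peak
   *positions* do identify the period: the model predicts every k maximum to
   lie inside its plateau [n·c, (n+1)·c).  The selection score is therefore
   RSS·(1 + P) with the dimensionless misalignment
   P = 12·mean((Z/c − n − ½)²), normalised by the variance of a uniform
   within-plateau spread (1/12 in plateau units); exact ties resolve to the
   smallest P.  For peaks at plateau centres P = 0 and the criterion reduces
   to the plain residual.

Assignment ties at exact multiples of b cosθ go to the lower n (floor).
Uncertainties on k₁ and k_pin come from the regression covariance propagated
through the reciprocals (delta method); the grid step is reported as the
b cosθ uncertainty.  Degenerate inputs (fewer than four positive peaks, or
all peaks on one n) raise fit errors, and an intercept at or below 1/k_tip
raises an error naming the inconsistent k_tip.

Derived quantities: k_DNA = k₁/(n_bases − 1), and, when a trace is supplied,
the average tension as the mean of ⟨F⟩ over the Z span of the fitted peaks.

## What the generator emulates — and what it does not

The synthetic pipeline reproduces the *study conditions*: a 20-cytosine
chain with 19 repeats and 19 neutralising counterions, folded ~4-nm adsorbed
starting structures, nN-scale peeling tension, stiffness dips every
0.2–0.3 nm from staged detachment plus 0.28-nm stick-slip, a decaying
envelope consistent with the springs-in-series model, an inclined straight
lifted segment, and full detachment slightly before full extension.  It does
not contain atomistic structure (base orientation, backbone dihedrals,
explicit counterions or water), sequence heterogeneity, finite-temperature
kinetics, or instrument dynamics beyond the small-amplitude gradient
relation.  Passing tests therefore validate the analysis machinery and the
coarse-grained phenomenology, not atomistic energetics: the fitted k_pin of
a simulated trace, for instance, reflects the calibrated wells of this
model, and only the self-consistency refits are compared against printed
reference values.

## Problem sizes and numerical choices

The reference run retracts the default 20-mer over 13.5 nm in 0.002-nm
steps (~6800 relaxations, about a minute on one core); tests share one such
run per session.  Oracle checks use a 3-bead chain against exhaustive
grid-plus-polish minimization on a smooth (corrugation-free, shallow-well)
landscape where the warm-started branch coincides with the global minimum,
and a 5-peak envelope against a zooming 3-parameter grid search sharing the
selection objective.  Trace files store 17 significant digits so read/write
round trips are bit-exact.
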