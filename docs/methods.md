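# Methods

This note records the physics model implemented in `carbonmc`, the choices
made where the published parameterization leaves latitude, and what the
test suite does and does not establish.

## Geometry and materials

Right-handed coordinates, beam default along +z, world origin at the
center of the phantom entrance face; voxels are half-open intervals
indexed from 0. Water is 2:1 H:O by number (mass fractions 0.1119/0.8881,
density 1 g/cm³). Number fractions are stored explicitly because
target-nucleus sampling weights cross-sections by element occurrence, not
mass. CT numbers convert to density through a piecewise-linear
monotone calibration; the packaged default is a two-knot air/water curve
because no clinical curve ships with the model — anything quantitative in
heterogeneous media needs a user-supplied calibration. HU-to-composition
segmentation is out of scope: all voxels share one composition and differ
only in density.

## Continuous processes

* **Stopping power**: Bethe formula, no shell/density corrections, with the
  Barkas effective charge z_eff = z(1 − e^(−125β z^(−2/3))). Water's mean
  excitation energy is pinned to I = 78 eV; other materials use Bragg
  additivity over elemental I values. Tables are built per (species,
  material) on a 600-point log grid over 0.05–450 MeV/u and interpolated
  linearly; the CSDA range is the cumulative integral of A·dE/S. This
  reproduces a 26.2 g/cm² proton range at 200 MeV (reference tabulations:
  26.0) and places the 200 MeV/u carbon dose maximum at 8.7 cm.
* **Straggling**: Gaussian per step with the Bohr variance
  0.1569·z_eff²·(Z/A)·ρ·Δs MeV², times the relativistic factor
  (1 − β²/2)/(1 − β²). Variance is additive over sub-steps by
  construction. Integrated over a full carbon track this gives a range
  spread σ_R ≈ 0.29% of range, consistent with published carbon values.
* **Multiple Coulomb scattering**: Highland's projected sigma
  (14.1 MeV/pβc)·z·√(t)·(1 + log₁₀(t)/9), t = step/X₀, applied as two
  independent projected Gaussian deflections, multiplied by f_mcs.
  Published per-species tunings for light ions span 1.29 (alpha, 200
  MeV/u) to 1.43 (oxygen, 300 MeV/u); lacking the reference full-MC to
  retune against, ions default to the midpoint 1.37 (protons 1.0) and the
  factor is configurable per species. The printed tunings are also
  depth-dependent (15% vs 90% of range); this implementation applies one
  constant factor per species.

## Nuclear cross-sections

The carbon–carbon non-elastic cross-section is the four-parameter fit
given in the README (total projectile kinetic energy in MeV). Other
targets scale it by the ratio of Kox geometric cross-sections evaluated at
the same energy per nucleon. The Kox form used is the standard published
parameterization σ_R = π r₀² [A_p^⅓ + A_t^⅓ + a·A_p^⅓A_t^⅓/(A_p^⅓+A_t^⅓)
− c(E)]² (1 − B_c/E_cm) with r₀ = 1.1 fm, a = 1.85, Coulomb radius 1.3 fm,
and a smooth monotone transparency table c(E) rising from 0 at 10 MeV/u to
a 2.1 saturation above 300 MeV/u. Because the model only consumes the
*ratio* to carbon–carbon, the absolute normalization and the exact c(E)
interpolation have suppressed influence.

Hydrogen targets use a packaged fit table
(`data/c_on_h_xs_synthetic.tsv`). The measured knots behind the original
fit are not published numerically, so this table is a **synthetic
stand-in** built from proton–carbon reaction-cross-section systematics,
constructed to be nearly constant above 250 MeV/u (the documented property
of the original). It affects the hydrogen/oxygen target split and the
water attenuation length (22 cm at 95 MeV/u, within the expected
10–50 cm decade).

Elastic scattering exists only for carbon on hydrogen: isotropic cos θ_c
in the CM frame, exact two-body energy sharing, and a configurable
elastic/non-elastic branching fraction on hydrogen (default 0.25, exposed
because the underlying evaluated-data tabulation is not reproduced here).
The printed recoil-angle relation reduces to φ_l = θ_c/2, the mirror image
of the conventional recoil law (π − θ_c)/2; it is implemented as printed.
Only the direction of elastic recoil protons is affected.

## Fragmentation model

* **Target choice**: P_i = n_i σ_i / Σ n_j σ_j over the material's
  elements (data-fit σ for H and C, Kox-scaled fit otherwise). Elements
  without a measured emission table map to the nearest packaged target by
  mass number (N→O, Ca→O) while keeping their own σ in the probability.
* **Species draws**: one cumulative table per target (packaged from the
  95 MeV/u thin-target measurements; cells the experiment could not see —
  neutrons everywhere, species heavier than ⁷Be on hydrogen — carry a
  `fluka-filled` source tag, filled from a full-MC simulation by the
  original authors). Probabilities are per-draw species frequencies.
* **Multiplicity rule** (the published description leaves this open):
  projectile-side species are drawn sequentially; the set closes either
  when the 12-nucleon budget is exhausted or at the first draw that would
  overshoot the remaining mass/charge budget, the leftover nucleons
  forming an untracked bound residual. The alternative rule — rejecting
  overshooting draws until ΣA = 12 exactly — was implemented and measured
  first: it yields a 45% energy-conservation resample rate and suppresses
  accepted fragment energies ~12% below the scaled table means, breaking
  the model's design property that projectile fragments keep the beam's
  mean energy per nucleon. The adopted rule gives a 27% resample rate,
  mean charged multiplicity 3.4, and mean-energy preservation within
  4–9%. One target-side fragment is drawn per event (subject to the
  target's own A/Z limits): drawing a full target-side set until the
  target's mass is exhausted pushes the charged multiplicity to 5–7,
  far outside the 2–4 fragments/event the model is known to produce.
* **Energy–angle sampling**: the two-component distribution is printed
  with Gaussian denominators "2σ"; it is implemented as 2σ² (σ a standard
  deviation — the dimensionally consistent reading, matching the printed
  units of σ_E in MeV/u). The exponential component is implemented
  decaying (the printed exponent lacks the minus sign but would otherwise
  be non-normalizable), truncated to E ∈ (0, 95] MeV/u at calibration (a
  target fragment cannot exceed the projectile's energy per nucleon; some
  printed α_E are too small for an unbounded support) and θ ∈ (0°, 180°].
  Gaussians truncate to E > 0, θ ∈ [0°, 180°]. In the tables for carbon
  and oxygen targets the sixth column is read as σ_θ (the printed header
  repeats α_θ; symmetry with the hydrogen table fixes the meaning).
  Hydrogen-like fragments (n, ¹H, ²H, ³H) draw from the full mixture with
  component weights proportional to the integrated A₁/A₂ terms.
* **Rescaling**: projectile fragments E_i = E₉₅·(E_proj/95)·(1 − c(1−R)),
  c = 0.4, where R is the A-weighted mean per-nucleon energy of the
  *previously scaled projectile* fragments over E_proj (first fragment:
  R = 1). Hydrogen-like projectile-side draws that came from the
  exponential component are treated as target-fragmentation contributions:
  scaled linearly and excluded from the R chain (including them drags R to
  ~0.7 and breaks mean preservation). Target fragments scale linearly with
  no correlation. Angles scale by √(95/E_proj) except protons and neutrons
  (energy-independent emission angles).
* **Conservation**: an event is redrawn in full (species and kinematics)
  until the summed fragment kinetic energy does not exceed the projectile
  kinetic energy; ΣA ≤ 12 and ΣZ ≤ 6 hold on the projectile side by
  construction. More than 1000 redraws raises an error (indicates table
  corruption).

Neutrons enter the conservation sums and the energy ledger but are not
transported and deposit no dose, matching the charged-fragment tracking
scope.

## Transport engine

Tracks advance in vectorized cohorts; steps are limited by the voxel
crossing and a 2% maximum fractional energy loss; charged particles below
0.5 MeV/u (sub-millimeter residual range) deposit locally. Free paths are
drawn once per track in mean-free-path units and decremented against the
local μρ·ρ each step, which handles density changes exactly. Secondaries
are transported with the same EM physics; their own nuclear interactions
are off by default (their fragmentation contributes negligibly to dose) or
available as attenuation-only removal. Non-elastic events log the kinetic
energy they do not hand to fragments as a `nuclear_deficit` ledger sink, so
the run ledger (deposited + escaped + neutron + deficit + secondary
absorption = injected) closes to float precision.

RNG: one child `SeedSequence` stream per primary batch (default 10
batches), giving bit-identical reproducibility for a fixed seed, primary
count and batch count in the single-threaded engine. Per-primary
counter-based streams (which would decouple reproducibility from
scheduling) are unnecessary here and were not implemented; a per-track
scalar engine would consume the stream differently, so no draw-for-draw
batched-vs-scalar equivalence is asserted — determinism and physics
invariants are tested instead. Statistical uncertainty is the standard
error of the per-batch mean dose (batch statistics, not
history-by-history).

## QA observables

Depth dose is the transversally integrated dose vs depth; the Bragg peak
is the global maximum refined by a three-point parabola. SOBP weights are
fitted by non-negative least squares on per-layer kernels, followed by
Lawson-style residual reweighting toward the minimax-flat plateau
(plain NNLS leaves ±3.5% edge ripple; the reweighted solution is within
±3%). The default kernels are analytic: stopping power along the CSDA
slowing-down blurred by the integrated range straggling plus a 0.3%
fractional beam energy spread — the latter emulates the momentum spread /
ripple filter of a real delivery system, without which carbon peaks are
too sharp (σ_R ≈ 0.3%) for practical layer spacings.

The γ-index uses global dose-difference normalization (percent of the
reference maximum) and a low-dose cutoff evaluated on the reference grid.
The search scans all voxel-lattice offsets within 3×DTA and optionally
refines around the best coarse offset on a trilinear-interpolated
sub-voxel lattice; with refinement disabled the scan is exactly an
exhaustive voxel-center search, which is the correctness gate against a
brute-force oracle in the tests.

## What the tests establish — and what they do not

The suite verifies the implementation against the packaged
parameterization: table recovery, distribution recovery, closed-form
scaling factors, kinematic exactness, conservation properties, ledger
closure, γ reference cases, and the 8.6 ± 0.2 cm peak position of a 200
MeV/u beam. It does **not** validate dose accuracy against a full Monte
Carlo or measured data: the published model was tuned and benchmarked
against a general-purpose MC that is not reproduced here, so quantities
that depended on that tuning (per-species f_mcs, the elastic branching
fraction, absolute fragment yields far from 95 MeV/u) carry the defaults
documented above. Desk-scale statistics (10⁵ primaries vs 10⁸ in the
published benchmarks) leave ~1% statistical noise in profile tails.

## Known limitations

* Single-composition phantoms (density may vary per voxel; composition may
  not) — consistent with the HU→density-only calibration scope.
* No fragmentation of fragments beyond optional attenuation-only removal;
  no de-excitation photons; no delta rays; no neutron transport.
* The hydrogen-target cross-section table is a synthetic stand-in (above).
* Emission tables exist for H, C, O targets only; other elements are
  mapped by nearest mass number.
* The elastic recoil-angle convention follows the printed relation (see
  above); elastic recoil protons are emitted at its mirror angle.
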