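# Methods

## The physical model

At the 40 Hz stimulation frequency the ratio of displacement to ohmic
current, 2πf·ε₀·ε_r/σ, is far below one for every tissue in the default
property table (the largest is ≈ 1.8 × 10⁻² for white matter;
`check_quasistatic` reports the ratio per tissue and flags anything at or
above 0.1).  The field problem therefore reduces to steady current flow,

    ∇·(σ∇φ) = 0,   E = −∇φ,   J = σE,

with zero normal current on the outer surface and the injected current
prescribed at the electrode contacts.

**Discretization.**  The equation is discretized with a cell-centred
7-point finite-volume stencil on the label grid.  The conductance of the
face between voxels a and b is

    g = [2 σ_a σ_b / (σ_a + σ_b)] · h,

the harmonic mean of the two conductivities times face area over spacing
(area h², spacing h).  The harmonic mean makes the scheme exact for 1-D
piecewise-constant media, which is the regime that matters for a layered
head model; the test suite verifies the layered-slab potential drops
against the series-resistance closed form to 1e-8 and the near field of a
point source against I/(4πσr) to better than 2%.  Background voxels are
excluded from the domain, which realizes the zero-flux outer boundary.

**Electrode model.**  Each contact is the set of dura-surface voxels whose
column centre lies strictly within the contact radius (half-open,
centre-based rasterization; a 1.5 mm disc at 100 μm voxels covers 177
columns).  Within each column the topmost dura voxel is used, so contacts
ride on the curved dura and never touch parenchyma.  The montage current
is split equally across source electrodes and, within an electrode,
equally across its contact voxels (a uniform-flux model).  This is linear
and simple; its price is that the field within a voxel or two of a contact
is discretization-dominated, and that the physical edge concentration of a
disc electrode is represented only at the grid scale.  An equipotential
(complete-electrode) contact model is out of scope.

**Solve.**  The assembled operator is symmetric positive definite after
one sink-contact voxel is pinned to 0 V (the gauge; potentials are
reported relative to it).  The default solver is Jacobi-preconditioned
conjugate gradients to a relative residual of 1e-8 — on the 200 μm default
grid (~80 k unknowns) this takes ~500 iterations and about one second, and
the 100 μm grid (~570 k unknowns) solves in well under a minute.  A sparse
LU (`method="direct"`) is available and is used for the small closed-form
oracle systems.  Everything is deterministic; a repeated solve returns
bit-identical potentials.

**Differentiation and conserved currents.**  E uses central differences
where both axial neighbours are conductive and one-sided differences at
tissue surfaces.  Cell-centred J = σE is what the ROI statistics and the
safety check consume, but it is only O(h²) conservative; whenever a
current must balance exactly (conservation checks, contact currents), the
face fluxes g·(φ_a − φ_b) of the discretization are summed instead
(`surface_current`), for which Kirchhoff's law holds to solver precision.

## The phantom

The MRI/Nissl atlas behind the published model is not redistributable, so
the phantom is parametric: an ellipsoidal brain (semi-axes 7.5 × 4.5 ×
3.25 mm, C57BL/6 scale) with a 1 mm gray-matter cortical shell over white
matter; paired CSF-filled lateral-ventricle ellipsoids (1.8 × 0.45 ×
0.8 mm, centred 1.4 mm anterior, ±1.2 mm lateral, 0.9 mm dorsal of the
brain centre); a one-voxel SVZ shell computed as the parenchymal voxels
6-adjacent to ventricle; and paired hippocampi (1.5 × 0.9 × 0.8 mm at
−1.3, ±2.2, +0.8 mm) between ventricle and cortex.  A 43 μm CSF film and
a 300 μm dura cover are grown outward by morphological dilation; a film
thinner than one voxel is painted one voxel thick with conductivity scaled
by t/h, which preserves its tangential sheet conductance (the normal
conductance is scaled the same way — an isotropic compromise; anisotropic
thin-layer tensors are a non-goal).  The grid matches the published
dimensions (189 × 236 × 152 at 100 μm) and is scaled by ceiling division
at coarser resolutions; 200 μm is the working default.  The brain centre
sits 2 mm caudal of bregma; geometry is exactly mirror-symmetric about
the midline, and so are solved field magnitudes (to ~1e-9 relative).

Default conductivities (S/m at 40 Hz): CSF 1.79, gray matter 0.276, white
matter 0.126, dura 0.16 — the values in common use for low-frequency
volume-conductor models, with CSF > gray > white enforced when a table is
loaded.  Relative permittivities are order-of-magnitude low-frequency
values and feed only the quasi-static validity report.  All properties
are overridable via CSV.

What the phantom deliberately does not model: the 39-segment atlas
anatomy, skull and scalp (the contacts sit on the dura), vasculature,
white-matter anisotropy, and the glymphatic system.  Conclusions that
depend on exact segment geometry — in particular the absolute voxelwise
field pattern of the published figures — are out of reach; the phantom is
built to carry the conductivity contrasts that drive the qualitative
physics (CSF film under dura, CSF-filled ventricles wrapped by the SVZ,
hippocampus between ventricle and cortex).

## Field metrics

ROI statistics are unweighted voxel means and maxima of |E| and |J| per
label.  Montages are ranked by a maximin coverage score — the minimum over
target regions (hippocampus and SVZ shell) of the region's mean |E| — so
a montage scores well only if it reaches *both* targets; ties break by the
summed target mean |E|, then input order.  The safety check takes the
maximum |J| over parenchyma only (gray, white, hippocampus, SVZ shell):
dura and CSF are not lesion-relevant tissue, and contact voxels plus a
one-voxel neighbourhood are excluded because the uniform-flux contact
model dominates them.  `lesion_threshold_current` exploits linearity to
convert the measured maximum into the injected current that would reach
the bound.

**Known limitation — the contact-rim maximum.**  On the default phantom at
100 μA the deep-target fields sit comfortably in the expected ranges
(hippocampal mean |E| ≈ 12.3 V/m, SVZ mean |J| ≈ 2.3 A/m²), but the
parenchymal maximum is ≈ 21 A/m² at 200 μm (≈ 25 A/m² at 100 μm), in the
first cortical voxels under the contact rim — slightly above the 20 A/m²
lesion bound.  This is the expected physics of the electrode model: a
uniform-flux 1.5 mm disc passes ~57 A/m² through the contact plane, and a
half-space estimate puts the shallow-cortex density at I/(πa²)/2 ≈
28 A/m²; the 43 μm CSF film spreads current over a lateral length of only
σ_CSF·t/σ_gray ≈ 0.3 mm and cannot defuse the rim.  The excess is
confined to a thin ring at the contact edge and sharpens under grid
refinement, as edge concentrations do.  A model with the real
subarachnoid geometry, a complete-electrode contact, or the atlas cortex
may well stay below the bound; this phantom, with its defaults chosen on
anatomical grounds, does not, and the package reports the measured value
rather than adjusting the geometry to meet it.

## Statistics

For a one-way layout the F statistic is a function of per-group
(mean, SD, n) only: SSB = Σ n_g(m_g − m̄)² about the n-weighted grand
mean, MSW = Σ(n_g − 1)s_g²/(N − k) with s_g = SEM_g·√n_g, and
F = MSB/MSW with (k−1, N−k) degrees of freedom.  `anova_from_summary` and
`anova_from_counts` agree to 1e-10 relative on exact summaries; against
printed (rounded-SEM) summaries, reconstructed F values carry a few
percent of rounding noise, so comparisons with published F use a 5%
relative tolerance and p-values ±0.02.  Zero within-group variance with
unequal means yields an infinite-F flagged result rather than an
exception.  No multiple-testing correction is applied across the six
ANOVAs, matching the original analysis.

The studentized-range CDF needed by Tukey's HSD is evaluated from its
classical double integral,

    P(Q ≤ q) = E_S [ k ∫ φ(z) (Φ(z) − Φ(z − qS))^{k−1} dz ],

with S = √(χ²_ν/ν), using fixed-order Gauss–Legendre rules (128 outer ×
256 inner nodes) over the essential support of S and z ∈ [−9, 9].  The
implementation matches scipy's distribution to ~1e-6 absolute and
published 5% critical values (k ∈ {2,3,4}, ν ∈ {6,12,20}) to well within
0.01; for k = 2 it reduces to the two-sided t-test, which the tests
verify.  Tukey assumes equal group sizes (the study design has n = 5
throughout); Tukey–Kramer is out of scope.

**Aggregation convention.**  Per-animal values are the *sum* of counts
over the up-to-18 sampled views.  The published magnitudes (hundreds to
thousands of cells per animal) are consistent with totals rather than
per-view means; a `convention="mean"` switch is provided.

**The DCX/SVZ discrepancy.**  The published F = 78.2 for DCX in the SVZ
cannot be obtained from its own published summaries, which imply F ≈ 40.7
(both well past any significance threshold).  The reconstruction flags
this cell as inconsistent; no attempt is made to force agreement.

## Synthetic data

`generate_animal_counts` draws per-animal totals from a normal
distribution truncated at zero and rounds to integers; at the published
means (all ≫ SD) truncation bias is negligible.
`generate_view_counts` adds the within-animal level: a latent total θ per
animal and Poisson view counts with rate θ/(sections·views), so summing
the views recovers θ in expectation.  The split of variance between the
animal and view levels is a modelling choice (the published summaries
constrain only the between-animal variance); overdispersion beyond
Poisson is not modelled.  Generators are deterministic given a seed.
Passing the published Ki67/SVZ effect sizes through this generator and
the ANOVA pipeline at n = 5 per group rejects the null in > 99% of 2000
seeded replicates, confirming the pipeline detects effects of the
published magnitude — it says nothing about features of real data the
generator does not emulate (between-section structure, counting error,
non-normal animal effects).

The toy phantoms (uniform cube, layered slab, point-source box) exist so
that every solver path is checked against a closed form: J = I/A and the
series-resistance drops are exact identities of the discretization, and
the point-source box uses a centred source with the sink spread uniformly
over the boundary, whose interior correction field has only high-order
cubic harmonics and is negligible at the probed radii (5 voxels to a
quarter of the domain).

## Numerical choices and problem sizes

Solver tolerance 1e-8 relative residual (1e-10 for the point-source
oracle); potential differences rather than raw potentials are compared in
oracles, removing the gauge constant.  Face-potential reconstruction in
the slab tests uses the exact 1-D half-cell resistance I·(h/2)/(σA).
Disc rasterization is half-open and centre-based, which fixes contact
voxel counts deterministically.  Structure collisions (ventricle
intersecting hippocampus) and shells that would be clipped by the grid
raise invalid-spec errors rather than producing silently broken phantoms.
The routine test and acceptance runs use the 200 μm grid (≈ 80 k
unknowns, ~1 s per solve), chosen so a full suite run stays interactive;
the 100 μm published-scale grid is available everywhere via
`PhantomSpec.default(100.0)` or `--resolution 100` and changes the
deep-target means by ~3%.
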