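# Methods

`darcyparam` parameterises a multi-compartment Darcy continuum model of
tissue perfusion directly from a discrete vessel-centreline network, and
quantifies how well the resulting continuum pressure reproduces the
spatially averaged discrete (Poiseuille) pressure. This note records the
model, the numerical choices, and what the synthetic test conditions do and
do not establish.

## Discrete vascular model

A network is a set of nodes (position, radius, both mm) joined by straight
segments oriented in the flow direction. A vessel's radius is the mean of
its endpoint nodal radii and is treated as constant along the vessel; its
volume is `pi r^2 l`. Flow in each vessel follows Poiseuille's law,
`Q = C (p_a - p_b)` with conductance `C = pi r^4 / (8 mu l)` and dynamic
viscosity `mu = 0.0035 Pa s` throughout. Mass conservation at the junctions
yields a weighted graph-Laplacian system for the nodal pressures, solved by
sparse direct factorisation after eliminating the Dirichlet (terminal)
pressures; terminals without an imposed pressure are free unknowns and so
carry zero flux naturally. The solver records the worst junction mass
residual; on the study networks it sits at roundoff (<= 1e-10 of the peak
flux).

## Synthetic networks

**Volume-filling tree.** The test tree is built by recursive alternating-axis
bisection of the domain box `[-1, 1]^3 mm`: each subdomain receives one
bifurcation point at its centroid, jittered by a uniform fraction (default
0.3) of the subdomain half-size, and the recursion runs to a fixed depth, so
`levels = L` gives exactly `2^L` terminals distributed through the box and
`2^(L+1) - 1` vessels. Terminal vessels carry a flow of 1 mm^3/s (the unit
is a convention; only pressure *patterns* matter after the min-max
normalisation below) and parent fluxes are daughter sums, so all fluxes are
exact integers. Radii follow the power law `r = (q / a1)^(1/a2) * a3` with
defaults `(1, 3, 0.001)`, i.e. Murray-type cube-root scaling giving 1 um
terminal radii per unit flow. Relation radii are stored on the distal node
of each vessel (the root node inherits the root vessel's value) and vessel
radii are then re-derived as endpoint-nodal means, keeping the generator
consistent with the file-reading convention. The tree is deterministic
given its seed.

This generator is deliberately *balanced*: every terminal sits at the same
bifurcation depth, so radii take one value per generation and the vessel
population is close to spatially homogeneous and isotropic. Real arterial
trees (and the imaged networks the method targets) are strongly asymmetric,
with heavy-tailed length and radius distributions. Consequences are noted
under "What the tests show" below.

**Aligned capillary lattice.** The anisotropy experiments use a lattice of
near-parallel fibres spanning the box along one axis (radii from a clipped
normal, default 5.3 +/- 2.3 um, as reported for capillary-scale vessels),
with sparse anastomoses: each transversally adjacent fibre pair is linked at
one random interior rung with a configurable probability, and a minimal set
of extra links guarantees a single connected component. An isotropic
control merges three orthogonal fibre families and stitches them at their
nearest node pairs. Fibre endpoints lie exactly on the two faces normal to
the fibre axis so face pressure boundary conditions can be imposed.

## Hierarchy and compartments

The hierarchic parameter `zeta` orders the network from inlet to periphery:
at a node it is the total length of all vessels distal to that node divided
by the network's total vessel length, so the root has `zeta = 1` and distal
terminals `zeta = 0`; a vessel's value is the mean of its endpoints.
Networks with loops are rejected (a pressure-based hierarchy would be
required). An ordered vector `Z` (descending, from 1 to 0) cuts the vessel
population into `N` compartments: compartment `i` holds vessels with
`zeta in [Z[i], Z[i-1])`, values of exactly 1 going to compartment 1.

When target compartment mean radii are given, the interior entries of `Z`
are found by minimising the rms mismatch of compartment mean radii over the
observed `zeta` values — a deterministic coarse grid over candidate cuts
followed by coordinate-wise refinement, ties broken toward larger `Z`.
When no targets are given, defaults are derived from the network itself:
the vessels are ranked by radius and split into blocks of 4% / 46% / 50%
(the proportions typical of an arterial/arteriolar/capillary-scale split in
a three-compartment parameterisation), and each block's mean radius becomes
the target. This keeps the partition meaningful across network sizes; the
classical 30/6/3 um targets remain available as explicit inputs.

## RVE averaging

All continuum fields are obtained by averaging over a sphere of fixed
radius `R` centred at the evaluation point, clipped to the domain box.
Defaults: `R = 0.2667 mm`, about 13% of the domain length.

* Vessels partially inside the ball are weighted by the fraction of their
  centreline length inside it (exact segment-sphere intersection). This
  rule is continuous in `R`, unlike midpoint inclusion.
* Averaged pressure: lumen-volume-weighted mean of per-vessel mean nodal
  pressures; undefined (NaN) when the ball holds no vessel of the queried
  compartment, and then filled from the nearest defined grid point, with a
  warning.
* Porosity: lumen volume inside the ball over the clipped ball volume;
  0 for an empty ball. Compartment porosities add exactly to the total.
* Clipped ball volumes: analytic `4/3 pi R^3` when the ball is interior,
  otherwise seeded Monte Carlo with 1e5 samples in the ball; estimates are
  cached by the per-axis clipping signature, so a regular grid costs only a
  handful of distinct estimates.
* Inter-compartment flux `Q_ik` (i > k): the Poiseuille flux `C dp` summed
  over "connector" vessels — compartment-k vessels sharing a node with a
  compartment-i vessel — inside the ball, inside-fraction weighted, with
  `dp` the signed proximal-minus-distal drop.
* Coupling coefficient `beta_ik = |Q_ik| / |pbar_i - pbar_k|`
  (mm^3 Pa^-1 s^-1), symmetric in (i, k) by construction. Two degenerate
  branches: when no connector lies in the ball the transfer is zero and
  `beta = 0` regardless of the averaged pressures; when the averaged
  pressures coincide (compared with a 1e-12 relative tolerance so solver
  roundoff cannot manufacture a pressure drop) `beta = 0` as well. The
  zero-transfer branch matters in practice: proximal compartments occupy a
  small part of the domain, and treating "no connectors" as missing data
  rather than zero coupling would smear strong coupling into regions with
  no proximal vessels at all.

## Permeability tensors

Three constructions, each a symmetric positive semi-definite 3x3 tensor per
grid node in mm^2 Pa^-1 s^-1, floored to SPD by an eigenvalue floor of
1e-6 x trace:

1. **Porosity-scaled isotropic** — `K = phi(x) I`. A reference method: it
   carries density information but no directionality.
2. **Huyghe–Van Campen (HvC)** — the entrywise sum
   `K_ij = pi / (128 vol_RVE dx0 mu) * sum_v d_v^4 dx_i dx_j / l_v`
   over the ball's compartment vessels (`d` diameter, `dx` endpoint
   coordinate differences), inside-fraction weighted — equivalent to
   clipping each vessel's chord to the ball. `dx0` is the width of the
   compartment's hierarchic interval by default; since every field is
   subsequently rescaled by a fitted constant, it affects only the
   pre-scale magnitude.
3. **Projected PCA** — each vessel contributes a datum: its unit direction
   (oriented away from the endpoint nearest the evaluation point) scaled by
   its conductance; the set is reflected through the origin to zero the
   mean; the covariance (population normaliser) is eigendecomposed; each
   vessel's conductance is then split across the eigendirections in
   proportion to its absolute direction projections, accumulating the
   eigenvalues. The trace therefore equals the summed conductance exactly,
   a property the tests exploit.

Both directional methods are rotation-equivariant (`K -> R K R^T` under a
rigid rotation of the network), verified to 1e-8 in the tests. Grid nodes
whose ball is empty are filled from the nearest populated node (logged).

## Continuum problem and test protocol

The multi-compartment Darcy system couples co-located porous continua
through pressure-difference source terms:
`w_i = -K_i grad p_i`, `div w_i = -sum_k beta_ik (p_i - p_k)`
(no external source field). The test protocol solves only the middle
compartment: compartments 1 and 3 are imposed across the domain as their
RVE-averaged discrete pressures, so the unknown `p_2` satisfies

    -div(K_2 grad p_2) + (b12 + b23) p_2 = b12 pbar_1 + b23 pbar_3

with zero normal flux on the boundary, where `b = beta / vol_RVE(x)` is the
coupling per unit volume — the conversion that gives the exchange term the
units of `div w` (s^-1). The RVE volume enters locally (clipped at the
boundary); any global factor is absorbed by the fitted scale below.

Discretisation: uniform hexahedral mesh (default 16^3 elements on
`[-1,1]^3`, 0.125 mm spacing), trilinear elements, 2x2x2 Gauss quadrature,
nodal coefficient fields interpolated trilinearly to quadrature points,
sparse direct solve. The manufactured-solution test (`p = cos(pi x)` with
unit permeability and coupling) confirms second-order L2 convergence. A
global balance check verifies that the exchange integral plus boundary flux
vanishes to solver precision, and that constant imposed pressures are
reproduced exactly. The anisotropic-lattice protocol instead fixes face
pressures (2 kPa in, 1 kPa out) on the two faces normal to the fibre axis
with zero flux elsewhere, a single compartment, and no exchange term.

## Comparison metrics and the fitted scale

Fields are compared with a min-max-normalised rms: the averaged pressure is
affinely mapped to [0, 1], the *same* transform is applied to the other
field, and the rms of the differences is taken — so the metric is invariant
to the absolute pressure level but not to over/under-shooting. The
comparison points are the mesh nodes for Darcy-vs-averaged, and a seeded
sample of 1000 compartment vessel nodes for discrete-vs-averaged.

None of the three constructions lands on the optimal magnitude, so each
permeability field is rescaled by the constant minimising the rms error:
the assembled system is affine in the scale (`s S + M`), and a bracketed
1-D search on `log10 s` (21-point coarse grid over +/-8 decades, then
bounded scalar minimisation to ~1e-3 relative) is cheap and deterministic.
For the pure-Dirichlet lattice protocol a uniform rescale leaves the
solution unchanged, so no fit is performed there.

A grid "unsmoothness" score Psi accompanies the rms: the absolute response
of the 5-point discrete Laplacian stencil summed over the three axis-aligned
slice families (the 2D stencil applied slice-wise; constants and linear
fields score zero, a lone interior spike of height h scores 24h).

## What the tests show, and what they do not

The study conditions are seeded 10-level trees (2047 vessels), a 16^3 mesh,
and `R = 0.2667 mm`. Under these conditions the pipeline reproduces the
expected qualitative physics: the continuum-vs-averaged error falls as the
averaging window grows while the averaged field simultaneously departs
from the raw discrete pressures (the window-size trade-off); the coupling
fields derived per unit pressure difference are insensitive to the outlet
pressures used to derive them (re-solving with outlet pressures moved from
8 to 9 kPa changes the error by well under 10% with parameters frozen); and
on the aligned capillary lattice the direction-aware methods clearly beat
the isotropic one (HvC best, projected PCA second), with near-parity
restored on the isotropic control.

One caveat is recorded honestly rather than engineered away: on the
*balanced* volume-filling tree the three permeability methods differ by
under 1% rms, and projected PCA tends to edge out HvC there, because a
balanced tree is nearly homogeneous and isotropic by construction — exactly
the regime where the constructions coincide after rescaling. The clear
HvC-first ordering reported for strongly asymmetric networks emerges in
this package on the anisotropic lattice, not on the balanced tree; an
asymmetric tree generator would be required to probe it in a branching
topology, at the cost of the exact terminal-count contract the balanced
generator provides.

Other known limitations: loops are unsupported in the hierarchy (so imaged
arterial arcades need pre-processing); the empty-ball nearest-neighbour
fill is first-order and logged rather than silent; the Monte Carlo clipped
volumes carry ~0.3% noise (cached, hence perfectly reproducible per run);
and the lattice generator only supports axis-aligned fibre directions.
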