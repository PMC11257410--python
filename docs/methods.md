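# Methods

## The transport problem

Oxygen in brain parenchyma diffuses from vessel cross-sections into the
tissue, where it is consumed by oxidative metabolism.  In a 2D tissue
section the vessels appear as disjoint circular disks; the steady
concentration field φ [nmol·cm⁻³] satisfies

    D ∇²φ = M φ / (φ + K)            in the tissue,
    −n·(D∇φ) = q_j / (2π R_j)        on each vessel wall j,
    q_j = K_eff (⟨C_v⟩_j − φ̄_j),

with Dirichlet, zero-flux or periodic conditions on the outer square
boundary.  Here q_j is the wall flux per unit depth, ⟨C_v⟩_j the
cross-section averaged intravascular concentration (an input in 2D,
since the sections are disconnected), φ̄_j the perimeter-averaged tissue
concentration on the wall, and K_eff the effective wall exchange
coefficient combining wall permeability K_m and intravascular diffusion
D_β, K_eff = 8π D_β / (1 + 4 D_β/(K_m R)).  Azimuthal variations of the
*flux* around a wall are neglected (uniform flux density q_j/2πR_j);
azimuthal variations of the concentration are retained.

## Operator splitting

The field is split as φ = s + r.  The rapid part r carries the
logarithmic perivascular gradients analytically: in each coarse cell k,
r_k = Σ_{j∈E(V̂_k)} q_j g_j with the single-layer potential per unit
flux

    g_j(x) = ln(R_j/‖x−x_j‖)/(2πD)   outside the disk,  0 inside.

E(V̂_k) is the set of sources whose n×n cell block contains cell k, so n
controls both the sparsity of the coupled system and the localization
error (∝ 1/(n−1)²).  The additive wall-average constant that formally
belongs to the single-layer potential is absorbed into the slow field;
this keeps the wall-average closure non-circular and makes the retained
potential vanish identically on its own disk — the code relies on this
convention throughout (e.g. self-terms drop automatically from wall
averages).

The slow part s is piecewise per cell and discretized by a two-point
flux approximation on the coarse Cartesian grid.  Because neighboring
cells carry different rapid terms, s jumps across faces; the face
functional

    J_km = ½∫ n·(∇r_m − ∇r_k) dl + (1/h)∫ (r_m − r_k) dl

(with each row using its own outward normal) restores the continuity of
φ and of its flux in the discrete balance −4 s̃_k + Σ_m (s̃_m + J_km) = 0.
Dirichlet faces impose the face-averaged s̃ = φ_D − r_k at half-cell
distance; zero-flux faces impose a slow-term flux opposite to the
face-integrated rapid flux; periodic faces are interior faces whose two
sides evaluate the rapid terms with the appropriate periodic images
(each cell sees the image of a neighborhood source nearest to its own
center).

## Wall closure and sub-grid reconstruction

The wall average φ̄_j is obtained from the mean-value property of
harmonic functions: every contribution to φ other than source j's own
retained potential is harmonic across disk j, so its wall average equals
its value at the center, φ̄_j = I_φ(x_j).  I_φ is a bilinear
interpolation on the dual mesh joining the FV cell centers, with each
corner contributing its nodal slow value plus its cell's rapid field
*continued analytically* to the evaluation point:

    I_φ(x) = Σ_i γ_i(x) (s̃_i + r_i^c(q; x)).

The continuation removes the localization jumps, so I_φ is globally
continuous, interpolates the cell-center values exactly, and meets the
Dirichlet data at boundary nodes.  Boundary dual cells use nodes
projected onto the boundary: Dirichlet nodes carry φ_D − r, zero-flux
nodes extrapolate the slow term linearly with the face gradient implied
by the zero-total-flux closure.  A "nearest-cell" closure (host-cell
value without sub-grid interpolation) is kept as a switchable variant
for the closure-quality benchmark.

Assembling the cell balances and the S wall closures gives a sparse
(F+S)×(F+S) system — A has ≤5 and C ≤4 nonzeros per row, while the
density of B and D grows with n — solved directly (SuperLU).

## Metabolism

Michaelis–Menten consumption enters the cell balance as the tensor
Simpson integral (11×11 nodes per cell by default) of
M φ/(φ+K) with φ = s̃_k + r_k(x), differentiated analytically for the
exact Newton Jacobian.  Newton starts from the nonreactive solution,
damps by step halving (≤8 halvings) and stops at a relative residual of
1e-10 (≤50 iterations); at M = 0 it returns the linear solution
bit-for-bit.  Concentrations at or below −K in any cell abort with a
diagnostic naming the cell (pole of the saturation integrand).

## Resolved reference

Errors are measured against an in-package resolved solution of the
original wall-flux BVP that fully resolves the azimuthal variations of
the concentration around every wall.  It writes φ = H + W, where W sums
exact exterior harmonics per source (log monopole + azimuthal
multipoles, plus nearest periodic images on periodic domains) and the
globally smooth remainder H is solved on a fine uniform grid (default
~1 µm cells).  Collocation on each wall fixes the coefficients: the
monopole carries the Robin exchange and the higher harmonics cancel the
azimuthal flux components so the wall carries a uniform flux density.
The fixed point is relaxed (adaptive damping; the free level of pure
periodic/zero-flux problems is updated implicitly from the global Robin
balance, which otherwise has a destabilizing feedback gain).  The
nonlinear reference runs a damped Newton iteration on H inside the
collocation loop, with the reaction restricted to the tissue by a
per-cell area fraction mask.

The oracle is validated against closed-form solutions before being
trusted: a uniform-flux monopole field (optionally with a
zero-radial-derivative wall harmonic) imposed through the Dirichlet
data, reproduced to ~1e-8 relative in the wall flux; and an exact
x-periodic strip Green's-function field for the periodic machinery.
Wall fluxes change by <0.1% under grid refinement in the benchmark
configurations.

## Baselines and error metrics

The coarse-grid FV baseline shares the grid and BC machinery but uses
the well-mixed closure q_j = K_eff(⟨C_v⟩_j − φ̃_k) with no rapid term.
The Peaceman well-model flux q = K_eff(C_v−φ̃_k)/(1 + K_eff/(2πD)·ln(R/0.2h))
is provided for comparison; at R = 0.2h its correction denominator is
exactly one, which is why the baseline error has a local minimum at
h = 5R.  Errors are relative: per source |q−q_ref|/|q_ref|, per cell
|φ̃_k − φ_ref(x_k)|/|φ_ref(x_k)| (point evaluation at centers, Gauss
mean-value rationale; centers inside a disk are excluded), and global
errors are arithmetic means.

## Benchmark configurations

All error benchmarks use an L = 240 µm square with R = 4.8 µm vessels —
deliberately small, so the reported errors are upper bounds.  Units are
µm, s, nmol·cm⁻³ internally (D = 2×10³ µm²/s, K_eff = 2×10³ µm²/s,
φ_max = 137, K = 13.7, M ≤ 40 nmol·cm⁻³·s⁻¹).

* **Grid sweep** (single source): the published schematic combines all
  three boundary kinds without printing the assignment or the Dirichlet
  value; this package uses periodic lateral sides, a zero-flux bottom
  and a Dirichlet top held at a baseline tissue concentration φ_max/2
  (≈49 mmHg).  A zero Dirichlet value would make *relative*
  concentration errors meaningless next to that side (reference values
  ~2% of φ_max).  The source sits at the cell center nearest the domain
  center of each grid; h/L ∈ {1/12…1/3} and the neighborhood extent is
  held at ≈30R (odd n with n·h closest to 144 µm, ties to the smaller n).
* **Boundary sweep**: 5×5 grid, n = 3, source wall approaching the
  zero-flux bottom (gap d from 0 to 1.2h; at tangency the wall is offset
  inward by 1e-2 R), Dirichlet 0 on the top, periodic lateral sides.
* **Position sweep**: 5×5 grid, n = 3, all-Dirichlet(0) box; the source
  moves diagonally from a cell center onto a grid-cell corner; both
  wall closures are compared.
* **Dipole**: source and sink along the domain diagonal (so d up to
  ~60R fits), grid-sweep boundary set, n ∈ {3, 5}.
* **Multi-vessel**: 17 vessels of R = 4.8 µm placed by seeded hard-core
  sampling (25 µm minimum torus separation) in the fully periodic box;
  one third sources at φ_max, two thirds sinks at 0; 16×16 grid,
  n ∈ {3,5,7,9}, averaged over ≥10 seeds.

## Periarteriolar study

A 400 µm box (20×20 grid, h = 20 µm, periodic) holds a central
penetrating arteriole (R = 20 µm) inside a capillary-free cylinder of
radius 100 µm; capillaries are hard-core sampled outside it at the
layer-specific equivalent 2D source density (count = density × available
area), with wall concentrations drawn from N(ratio·φ_PA, 0.1 φ_PA)
truncated below at 0.05 φ_PA.  Wall exchange uses an asymptotically
large K_eff (10³ × the capillary value; a further ×10 changes the
profiles by <0.1%), n = 10 and M = 40 nmol·cm⁻³·s⁻¹ (2.4 µmol·cm⁻³·min⁻¹).
Radial profiles average 360 rays in 2 µm bins; points inside a disk take
its wall value.  The laminar regression fits the spatial mean of
φ/φ_PA outside the cylinder against the layer density in mm⁻² (the only
dimensionally consistent scale for the published coefficients), with
spreads from per-realization refits.

## What the generators do and do not emulate

The hard-core sampler reproduces vessel counts, minimum spacing and
statistical homogeneity, but not the spatial clustering of real
capillary-bed cross-sections; clustered beds supply tissue less
efficiently per vessel, so the uniform stand-in biases the absolute
oxygenation level slightly upward (the laminar regression's slope is
reproduced within its realization spread; the intercept is shifted up).
The Gaussian wall-concentration draw ignores correlations between
neighboring capillaries.  Passing benchmarks therefore validate the
numerical method (splitting, localization, reconstruction, metabolism)
and the qualitative laminar physiology, not a quantitative prediction
of absolute tissue PO2 in any particular animal.

## Numerical choices

* Face and wall integrals: composite Simpson, starting at
  2⌈h/R_min⌉+1 (≥11) nodes with panel doubling until successive values
  agree to 1e-9 relative — near-tangent source/face geometries need the
  refinement, smooth faces stop immediately.
* Cell ownership is half-open ([x, x+h)); a source centered exactly on
  a face belongs to the +x/+y cell, and n ≥ 3 guarantees its disk stays
  well inside its block either way.
* n may be any integer ≥ 3; odd blocks center on the host cell, even
  blocks take the n×n window whose center is nearest the source.
* Direct sparse solves throughout (problem sizes ≤ a few hundred
  unknowns for the model; ≤ ~10⁵ for the reference fine grid, with the
  constant operator factorized once per configuration).
* Reported problem sizes: grid sweeps use a 256²–320² reference grid;
  stochastic benchmarks use 10 placement seeds and the laminar study 30
  realizations per layer (6 in the test suite).

## Known limitations

Square domains and grids only; 2D only (no intravascular transport
coupling — ⟨C_v⟩ are inputs); the localized image convention assumes the
neighborhood extent does not exceed the domain period; relative error
metrics degrade near zero-concentration regions (a property of the
metric, not the solver); the reference collocation can need strong
damping for walls nearly tangent to boundaries.
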