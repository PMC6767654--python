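# Methods

## Transport model

The package solves the linear convection–diffusion–reaction equation
∂c/∂t + ∇·(vc) − ∇·(D*∇c) + rc = 0 for the tracer concentration
c (mol/m³) in the brain parenchyma, starting from c = 0. The convective
term is kept in divergence form as written; this matters once the velocity
field is interpolated onto the mesh and acquires a small spurious
divergence (the assembled convection operator's interior row sums report
that error; its column sums vanish identically by partition of unity,
which is what makes the discrete mass accounting exact).

Boundary conditions: the SAS interface carries the Dirichlet value
g = c_CSF(t)·h(t, x₃) with the arctan front profile h (a = 20 m⁻¹,
z₀ = −0.2 m as an absolute z-coordinate, u_{x₃} = 1.5×10⁻⁵ m/s); the
ventricular interface has zero diffusive flux, and the convective term
v·n c arising from integration by parts is retained there (configurable)
— tracer convected into the ventricles is returned to the CSF pool, since
the 140 mL CSF volume includes the ventricles.

## SAS budget coupling

c_CSF(t) is not prescribed; it follows from conservation of the injected
dose: parenchymal content + c_CSF·V_CSF + cumulative drained amount = n₀.
One time step of the discrete transport problem is affine in the scalar
c_CSF applied over the step, so the solver computes the step response to a
unit boundary profile (one extra back-substitution on the same LU
factorization) and closes the budget identity at the end of the step
exactly — a semi-implicit coupling. A purely explicit update (freeze
c_CSF at the start of the step) is also available, but it is unstable
whenever the lumped mass of the SAS boundary layer, roughly
surface area × edge length / 4, exceeds V_CSF — which is the case for any
mesh coarser than a few millimetres. At 1 cm resolution the explicit
feedback gain is ≈ 3 and runs diverge within hours of model time; the
semi-implicit closure is unconditionally stable and keeps the scheme first
order in time (the spatial front profile h is still averaged
trapezoidally over the step).

Conservation is verified rather than assumed: independently of the
rearranged identity, the SAS amount is integrated from the consistent
Dirichlet constraint forces (lumped mass × Δc/Δt + transport operator
applied to the midpoint state, summed over boundary rows) plus the
ventricular convective return. The reported budget residual — the
deviation of parenchymal + SAS + drained amounts from n₀ under that flux
accounting — is at machine precision (≈10⁻¹⁵ relative) for all models, a
structural property of the divergence-form P1 scheme with row-sum mass
lumping. The first-order-in-time behaviour of the coupled scheme is
checked separately by Richardson ratios of the c_CSF trace under Δt
halving (observed order ≈ 1.0–1.4).

## Discretization

Continuous piecewise-linear (P1) elements on tetrahedra; row-sum mass
lumping; implicit midpoint in time with Δt = 900 s by default. All element
integrals of P1 products use the exact formula V(1+δᵢⱼ)/20, so regional
amounts, the lumped mass and the budget terms share one quadrature.
Dirichlet rows are enforced by row replacement; vertices shared between
SAS and ventricular facets count as Dirichlet. Linear systems are solved
by a sparse LU factorization computed once per coefficient sample and
reused across all steps — at desk-scale mesh sizes (10³–10⁵ vertices) this
is faster and bit-reproducible compared with Krylov iteration.

Verified orders: spatial L2 error of a decaying heat-equation eigenmode
drops at rate ≈ 2 per mesh halving; the coupled scheme converges at first
order in Δt.

Stabilization. The transport solver defaults to no stabilization. The
Monte Carlo driver, however, enables a streamline-diffusion (SUPG-type)
term for the velocity models: at the default 1 cm resolution the cell
Péclet number reaches ~20–80 for the directional field and for far-tail
inflow draws, and unstabilized central discretization then oscillates hard
enough to pump spurious mass through the Dirichlet boundary (a Gamma-tail
inflow sample breached the budget by 5 %; white-matter amounts went
negative). The stabilization parameter is the classical
τ = h/(2|v|)·min(1, Pe_cell/3). On meshes fine enough that Pe_cell = O(1)
— the regime the model was designed for — the unstabilized default is
appropriate and the two agree.

## Synthetic geometry

The synthetic stand-in for an anatomical mesh is a pair of concentric
ellipsoids (outer semi-axes 7×9×8 cm) with the shell (2 cm) labeled gray
matter, the core white, and a central spherical cavity (2 cm radius) whose
staircase surface is the ventricular interface; the outer surface is the
SAS interface. z = 0 passes through the cavity center, matching the
convention that the foramen magnum, Sylvian fissure and precentral sulcus
sit near z = −0.1, 0 and +0.1 m. Meshes come from Kuhn subdivision of a
regular grid (six tetrahedra per cube, conforming, deterministic), keeping
cells whose centroid lies in the domain; the total volume matches the
closed form within 0.2 % at 1 cm edge length.

What this geometry reproduces: two compartments, two boundary types, the
z-stratified SAS exposure, and domain dimensions. What it does not:
cortical folding (gyri bring white matter within millimetres of the SAS in
a real brain; here the white core is uniformly ~2 cm deep), the cerebellum,
and realistic gray/white volume fractions (59/41 here). Consequently
white-matter quantities respond much more slowly than they would on an
anatomical mesh — with pure diffusion the 10 %-of-dose white activation
threshold is typically not reached in 24 h on this geometry — and the V3
drainage model, whose parenchymal residence times are geometry-dependent,
drains ~50–75 % of the dose in 48 h rather than the ~40 % seen on
anatomical meshes. Passing tests therefore validate the machinery
(samplers, solver, estimators, conservation), not anatomical numbers.

The default regions of interest are 4 mm spheres, S_g placed 3 mm beneath
the SAS surface at z = 0 and S_w mid-way through the white core at z = 0
(their exact anatomical positions are a free choice; both are
configurable). On meshes coarser than 4 mm the radius is floored at the
edge length so the region always contains at least one cell.

## Random coefficients

Matérn fields. Smoothness is fixed at ν = 1/2 (exponential covariance) and
the correlation length λ is the distance at which correlation decays to
1/e; both are configurable, and for general ν the range parameter is
solved so the 1/e convention still holds. Sampling uses circulant
embedding on a regular auxiliary box grid: the covariance is embedded on a
torus of twice the grid size, its FFT gives the eigenvalues, negative
eigenvalues (rare, small) are clipped and the marginal variance rescaled
to be exact; one realization costs one complex FFT. Fields are
interpolated trilinearly to mesh vertices. The grid must resolve λ
(spacing ≤ λ/3, enforced unless explicitly overridden).

Diffusivity. D1 draws 0.25·D_Gad + Gamma(k = 3, θ = 0.75·D_Gad/3) once per
realization: mean 1.2×10⁻¹⁰ m²/s, hard lower bound 0.3×10⁻¹⁰. D2 maps a
standard Matérn field (λ = 1 cm) through the Gaussian copula Φ → gamma
quantile function, preserving the D1 marginal exactly at every point while
the induced spatial correlation is only approximately Matérn. Trilinear
interpolation would shrink the Gaussian variance off-grid, so interpolated
values are divided by their exact pointwise standard deviation
(wᵀCw)^{1/2} computed from the cell-corner covariance — the correction is
continuous across cells and keeps the marginal exact (verified by
per-node variance and Kolmogorov–Smirnov tests).

Glymphatic velocity (V1). v = v_avg·η·10^(−ℰ)·∇×ψ with ψ three i.i.d.
standard Matérn fields (λ = 1020 µm, the arteriole–venule spacing scale)
and ℰ ~ Exponential(mean 0.2) drawn once per realization from its own
seed substream. The curl uses centred differences on the grid, so the
matching discrete divergence vanishes identically in the grid interior.
η is calibrated so E[‖v‖²]^{1/2} = v_avg = 0.17 µm/s:
η = (E[10^(−2ℰ)]·E[‖∇×ψ‖²])^(−1/2), the exponential factor in closed form
(5/(5+2·ln10) ≈ 0.5206) and the curl moment by seeded Monte Carlo. Because
the potential has exponential covariance, E[‖∇×ψ‖²] grows like 1/(hλ) as
the grid spacing h shrinks: η is tied to the grid it was calibrated on and
is recalibrated whenever the sampling grid changes. When the field will be
interpolated to a mesh, the calibration can measure the curl moment at the
mesh vertices instead — at the default production spacing of 2.3 mm
(which deliberately under-resolves λ = 1020 µm, trading small-scale detail
for a tractable grid) interpolation smooths away ≈ 38 % of the RMS, and
mesh-aware calibration restores the intended 0.17 µm/s in the field the
solver actually sees.

Directional field (V2). The closed-form field v_dir (v_f = 2×10⁻⁶ m/s) is
evaluated componentwise exactly as defined and added to a V1 sample. Its
sign convention gives downward flow on the brain-stem axis below
z ≈ 0.067 m; the field is implemented as defined without adjustment. Its
net volumetric outflow through the synthetic domain's surface is
≈ 0.47 mL/min (this number is geometry-specific; on anatomical meshes it
is far smaller).

Radial inflow (V3). v = v̄(ω)·exp(−3(R−d)²/(R²−(R−d)²))·(x_c−x) with
d = ‖x−x_c‖, R = 8 cm, x_c the ventricle center; the profile's limit 0 is
used at d = 0 and the field is zero for d ≥ 2R where the expression is
undefined. v̄ ~ Gamma(k = 2, θ) with θ set so the volume-averaged
E[‖v‖²]^{1/2} equals v_avg, using E[v̄²] = k(k+1)θ² and midpoint mesh
quadrature of the squared profile. Drainage r = 10⁻⁵ s⁻¹ accompanies this
model only.

## Quantities of interest and Monte Carlo summaries

Regional amounts Q_g, Q_w integrate c over the gray/white compartments
(exact P1 quadrature; their sum is bitwise the budget's parenchymal term);
q_g, q_w are volume averages over S_g, S_w; all at τ ∈ {3, 5, 8, 24} h.
Activation times are the infimum of {t : f(t) > threshold} under linear
interpolation of the hourly outputs — strict inequality, so a trajectory
that only touches the threshold never activates — with X = 10 % of n₀ for
the white-matter time F_w and Y = 10⁻³ mol/m³ for the subregion time f_w.
Realizations that never cross are carried as an explicit censored flag,
excluded from means and intervals, and surface as the gap between the CDF's
terminal value and 1.

Summaries per QoI: sample mean with standard error (V̂/N)^{1/2}; 99.73 %
prediction interval as the empirical 0.135 %/99.865 % quantiles
(linear-interpolation order statistics); Freedman–Diaconis histograms and
Scott-bandwidth Gaussian KDEs scaled by the uncensored fraction; and the
sample-size criterion 3(V̂/N)^{1/2} < 0.01·Q̂, reported as a diagnostic
rather than enforced — at the desk-scale default N = 16–64 it holds for
the large, low-variance amounts and correctly fails for small or highly
variable ones.

Reproducibility: per-sample seeds derive deterministically from the base
seed (SeedSequence), each realization draws from its own generator with
separate substreams for the scalar factors, so runs are bit-reproducible
and order-independent; calibration runs are seeded and recorded in the
run metadata.

## Problem sizes and defaults

Default experiments use the synthetic geometry at 1 cm edge length
(~2,700 vertices, 12,500 tetrahedra), N = 16 Monte Carlo samples, Δt =
15 min over 24 h, and a 2.3 mm auxiliary sampling box for the velocity
fields; the distributional test suites use small boxes that resolve their
correlation lengths at λ/3. These sizes keep a full five-model study
within minutes on one CPU while exercising every code path; all of them
are parameters, and anatomical-scale studies (10⁶ vertices, N in the
thousands) use the same interfaces.

## Known limitations

- The synthetic geometry's deep white core makes white-matter quantities
  systematically slower than anatomical values; activation times for pure
  diffusion are typically censored at 24 h here.
- At 1 cm resolution the velocity models rely on streamline-diffusion
  stabilization; residual oscillation can still leave tiny negative
  white-matter amounts (|Q_w| ≲ 0.2 % of n₀) for the directional model.
- The copula field's spatial correlation is only approximately Matérn;
  the marginal is exact.
- The explicit SAS coupling mode reproduces the textbook scheme but is
  usable only on meshes with sub-millimetre boundary resolution.
- Tensor diffusivity, pulsatile flow, SAS hydrodynamics and additional
  efflux routes are out of scope.
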