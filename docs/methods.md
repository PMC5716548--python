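# Methods

## Flux estimation from plane crossings

The estimator treats a first-passage folding ensemble as a stationary flow:
each consecutive frame pair (g′, g″) of every trajectory defines a straight
segment, and each crossing of a node plane g_k = const is assigned to the
transverse elementary cell containing the intersection point and counted
with the sign of the motion along axis k.  Component k of the flux at node
g is (n₊ − n₋)/(M t̄_f ΔA), with ΔA the transverse cell measure.  In 2D the
planes and cells become node lines and elementary segments.

Sub-cell conventions are a free choice the data cannot fix, so they are
declared once and used everywhere (the brute-force oracle in the tests
reimplements them independently):

- planes pass through grid nodes; the transverse cell of a node is the
  half-open box [g − Δg/2, g + Δg/2), and a crossing landing exactly on a
  transverse boundary belongs to the lower-index cell;
- an upward segment crosses the integer planes in (u′, u″] (index units),
  a downward one those in [u″, u′); a frame sitting exactly on a plane is
  therefore counted once per passage, and a segment lying inside a plane
  contributes nothing;
- a long segment contributes one signed count per crossed plane — required
  for the conservation identities below;
- the visit probability p uses the same half-open cell assignment,
  normalized over all frames; t̄_f defaults to the ensemble-mean
  first-passage time and can be overridden.

These conventions make two properties exact (to float round-off, ~1e-15
relative): the net flow through any plane separating all starts from all
ends is 1/t̄_f, and the net crossing flux through the boundary of any box
containing neither a source nor a sink point is zero.  The box check
(`box_net_outflow`) counts segment crossings of the box faces directly
rather than summing the binned field: a cell-aligned box is not a closed
surface of node planes (its transverse edges cut cells), so only the
segment-level count closes exactly.

## Geometry of the flow

Passive tracers integrate dg/dτ = j(g) with fixed-step classical
Runge–Kutta (RK4) over a trilinear interpolant of the node field —
convergence is verified by step-halving (error ratio ≈ 2⁴) rather than by
appeal to any reference integrator.  Stops: entering the target ball,
leaving the node hull, |j| below a stagnation floor (10⁻⁹ of the field RMS
over visited cells), or the step cap.

In 2D the stream function Ψ is the per-column cumulative trapezoid of J_G1
along G₂ (Ψ = 0 at the lower boundary); streamlines are marching-squares
contours of Ψ with linear edge interpolation (scikit-image).  Stream-tube
fractions divide consecutive contour levels by the total flow Π through a
reference G₁ = const section (grid midpoint by default).  When J_G1 ≥ 0 on
the section, Π equals the Ψ span and the fractions tile [Ψ_min, Ψ_max]
exactly; for noisy estimated fields with sign-changing J_G1 the span
exceeds Π and the strict identity cannot hold, so the pipeline divides by
the span instead (`normalization="span"`), keeping a partition of unity by
construction.  Vorticity ω = ∂J_G2/∂G₁ − ∂J_G1/∂G₂ uses central
differences (one-sided at edges), exact for quadratic fields; negative ω is
clockwise motion.

## Collective variables

PCA is performed on the pooled frames of the contact-distance features:
centered, never standardized (all features share Å units), eigenpairs of
the sample covariance sorted by decreasing eigenvalue, each eigenvector's
sign fixed so its largest-magnitude component is positive.  The 2D
reduction takes G₁ = g₁ and G₂ = (λ₂g₂ + λ₃g₃)/(λ₂ + λ₃).
Eigenvalue-proportional (λ, not √λ) weights are a declared reading of
"weighted according to the eigenvalues"; the weights always sum to 1 and
the λ₃ → 0 limit degenerates gracefully to G₂ = g₂.  Consensus native
contacts require the Cα–Cα distance below the cutoff (default 6.5 Å) in
*every* model, with sequence-neighbor exclusion j − i ≥ 2 by default
(configurable; the exclusion window of the reference protocol is not
documented, so the extractor reports whatever window it is given).

## Turbulence statistics

**Coarse-graining.**  Cross-sections perpendicular to axis k are tiled with
non-overlapping L×L squares anchored at the lower corner of the (optionally
g₁-restricted) region; G_k(L) averages |Σ j_k| / RMS(j_k) over tiles that
contain visited cells, and D_k comes from a log-log fit over L (default
1…5 Å, matching the narrow transverse extent of folding flows).  The RMS
runs over the *visited* cells of the tile: this is the only reading under
which the three limiting cases agree (uniform flow D = 2 exactly, one
visited cell per tile D = 0, random fractal support of box dimension D*
recovering D ≈ D*).  Default g₁ regions (10, 30], (30, 50], (50, 70] Å
follow the standard unfolded-to-native partition.

**Structure functions.**  δj_∥ = [j(g+l) − j(g)]·l/|l| over pairs of
visited nodes, binned by |l| rounded to the nearest Δg, isotropic in
direction; δj_∥ is invariant under swapping the endpoints, so unordered
pairs are well defined and the sign of C_lll is intrinsic (a directed
channel feeding a stochastic region gives C_lll < 0 from either side).
Unvisited cells are excluded rather than treated as zero flux — zero is an
estimate of absence, not an observed flux.  Pairs are enumerated
exhaustively below 10⁶ pairs, otherwise 2×10⁶ pairs are sampled with a
fixed seed; with a direction restriction, pairs are enumerated along grid
lines (random sampling would almost never draw an aligned pair).

**Prefactor scaling.**  A_n(L) is the mean ratio of the structure function
of the block-summed field (component k summed over L×L transverse cells at
stride-L planes) to the L₀ = 1 Å baseline over a common l range; exponents
are fitted over L.  For a smooth field block-summing multiplies j by L²
exactly (the D = 2 case: A_ll = L⁴, A_lll = L⁶, exact for linear shear); a
strictly uniform field has zero increments and an undefined ratio, so the
smooth field is the right fixture for that closed form.  The D = 1 fixture
uses deterministic parallel-line support (box dimension exactly 1 below
the line spacing) with a linear ramp magnitude, for which block sums scale
exactly as L·value and A_ll = L², A_lll = L³.

**Variance spectrum.**  Averaged one-sided periodograms of evenly sampled
1D transects (length ≥ 256), power-law fit over wavenumber indices
[4, length/8].  If a single mode carries over half the band power the fit
is refused (a sinusoid has no power-law band).  Hurst-1/3 transects give
slope −5/3.

**Time-resolved flux variance.**  Trajectories aligned at initiation are
cut into tumbling windows of 5 frames; the flux inside window w is
estimated from the same crossing counts normalized by M, the window
duration and the cell area.  σ²_pf(τ) is the spatial variance of the flux
components over occupied cells divided by V(τ), the occupied-cell count as
a fraction of its maximum over windows (the absolute normalization of V is
not recoverable from the protocol; only the linearity of Δσ²(Δt) and the
/6 relation are treated as quantitative).  Δσ²(Δt) is the mean forward
increment over window pairs, ε_pf the slope of a linear fit restricted to
Δt below the 95th percentile of the first-passage times (beyond which few
trajectories survive and the statistics degrade), and the diffusion
coefficient is ε_pf/6 identically — the 3D Brownian relation
d⟨r²⟩/dt = 6D, verified explicitly on simulated walkers.

## Synthetic data: what it does and does not emulate

The funnel generator is an overdamped Langevin process with a
constant-speed radial pull toward the native point plus isotropic noise,
absorbing on a native ball.  Defaults: pull 550 Å/μs, noise 60 Å/√μs,
native radius 2 Å, start 10 Å from the native center, frames every 2×10⁻⁵
μs (the 20 ps storage interval of the reference protocol), M = 100.  The
drift/noise balance puts the quasi-stationary search cloud (≈ D/v ≈ 4 Å)
outside the absorbing radius and makes relaxation fast relative to
absorption, so first passage is approximately Poissonian: the
first-passage distribution is near exponential (Kolmogorov–Smirnov p ≈ 0.3
at the defaults) with a mean of ~0.03–0.05 μs, the order of fast-folding
miniprotein simulations.  It reproduces exactly the two structural facts
the analysis consumes — first-passage termination and near-exponential
kinetics — and nothing else: no energetics, no metastable intermediates,
no multiple pathways, no anisotropic landscape.  Passing tests on it
validate the estimators' bookkeeping and statistics, not any biological
claim.

Self-similar fields use spectral synthesis on a 1.5×-padded periodic grid
(cropped to suppress wrap-around correlations) with the discrete-Laplacian
symbol 4 sin²(πf) per axis in place of the continuum (2πf)²: the lattice
symbol matches lattice increments below the Nyquist scale and removes the
small-separation smoothness bias of plain |k|^−(2H+3) synthesis.  Fractal
supports use an exact-count dyadic cascade (exactly round(2^(D*ℓ)) squares
survive at level ℓ), so grid-aligned box counts follow s^D* by
construction; an independent box-counting routine in the tests confirms
the dimension to ±0.1.  Every generator takes one seeded NumPy generator
per call and is bit-identical under a fixed seed.

## Numerical choices and limitations

- Units are fixed: Å and μs; flux in Å⁻² μs⁻¹ (3D) or Å⁻¹ μs⁻¹ (2D).
- Grids are regular with per-axis origin/spacing; frames outside the grid
  either raise or grow the grid to cover the data (config flag).
- Power-law fits are least squares in log-log space; non-positive points
  are excluded with a warning, fewer than 3 surviving points is an error.
- Problem sizes in the test-suite and benchmark runs (64³ synthesis grids,
  2×10⁶ sampled pairs, 10⁴ walkers, M = 100 trajectories) are chosen so
  every statistical tolerance is met with margin on a single CPU core.
- The estimator needs complete first-passage trajectories for its exact
  conservation identities; truncated or equilibrium trajectories produce
  sources/sinks the diagnostics will flag but not repair.
- Statistics assume the grid resolves the flow (Δg well below the flow
  width); no adaptive or kernel density estimation is provided.
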