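# Methods

This note records the modeling conventions, numerical choices, and known
limitations of `phyllosim`. Everything quantitative stated here is computed
by the test suite or the acceptance script; nothing is quoted from
elsewhere.

## Lattices and state layout

Cells sit on a 1D ring of N cells (K = 2 neighbors) or a 2D hexagonal
torus in rhombic axial coordinates (K = 6; cell (u, v) neighbors
(u±1, v), (u, v±1), (u+1, v−1), (u−1, v+1) modulo the sheet size). The
torus wrapping convention is this package's choice; any 6-regular periodic
embedding is equivalent for the questions asked here. Rings need N ≥ 3 and
tori nx, ny ≥ 3, otherwise interfaces would collapse into double edges.

Each cell–cell interface carries one well-mixed apoplast compartment,
indexed by an undirected edge id; on rings, edge i is the interface
(i, i+1), so the apoplast compartments form a ring of their own — that
adjacency is what the apoplast-diffusion variants use, and it is defined
in 1D only, matching where those variants are deployed. PIN1 is directed:
`p[i, s]` is the density on cell i's membrane facing its s-th neighbor, so
each interface is flanked by two PIN1 values while apoplast concentrations
are stored once per edge (the a′_ij = a′_ji symmetry is structural).

## Model variants

The `models` module implements one `rhs` per variant family:

* **O** — direct cell–cell transport; flux f_ij = E_p(p_ij a_i − p_ji a_j)
  is antisymmetric by construction. An optional saturating flux
  (`kappa_T`) reproduces the flux form of an earlier published variant for
  the equivalence test; it is off by default.
* **A** — efflux E_p p_ij a_i minus influx E_q q a′_ij across each
  membrane; apoplast balance carries 1/V and D_a/V factors (V = apoplast
  to cytoplasm volume ratio), which makes Σ_i a_i + V Σ_edges a′ the
  conserved total when synthesis/turnover are off. Optional symplast
  (D_a1, cell–cell) or apoplast (D_a2, interface–interface) auxin
  diffusion.
* **B1–B6** — the mediator X is synthesized at rate G_x θ(a_i), degraded
  everywhere at G_x, and moves by one of three routes: `simple`
  (cytoplasm↔apoplast, coefficient D_x), `symplast` (cell–cell, D_x1;
  the apoplast X pool then only decays and its equilibrium is exactly 0),
  or `apoplast` (secretion S into the interfaces plus interface–interface
  diffusion D_x2). The feedback target distinguishes the six variants:
  influx-carrier amount (B1), PIN1 amount (B2), auxin synthesis (B3),
  influx efficiency (B4), efflux efficiency (B5), PIN1 polarization (B6).

PIN1 either relaxes at rate G_p toward its normalized allocation
K p w_ij / Σ_j w_ij (dynamic PIN1) or is set to that allocation directly
(`pin_qss`), the quasi-steady simplification valid for fast PIN1 turnover.
The allocation row-sum is exactly K p, so the per-cell PIN1 pool obeys
dP_i/dt = G_p(K p − P_i) in every variant whose allocation is not itself
rescaled by the mediator (B2 rescales the target by ψ1(x_i)).

Closed-form uniform equilibria exist for every variant and are verified to
zero the right-hand side to ≤ 1e−12 in the tests.

## Regulatory functions

Polarization uses power laws (φ0, φa exponent n; φx exponent m), X
synthesis the normalized Hill form θ(a) = 2aʳ/(a_eqʳ + aʳ) with
θ(a_eq) = 1. The mediator modulation functions ψ1/ψ2 have no canonical
printed form; the package default is the normalized Hill shape referenced
at the corresponding X equilibrium, which keeps the feedback-free
equilibria exact fixed points of B1–B5 (the alternative normalized power
form (c/c_ref)^m is selectable, and the tests check both leave the
equilibrium invariant). Two consequences of this convention:

* B4/B5 with symplast X diffusion are rejected at configuration time: the
  apoplast X equilibrium is 0 there, and a modulation normalized at zero
  is undefined.
* B6 with symplast X diffusion applies φx to the *neighboring cell's*
  cytosolic X rather than the (empty) apoplast pool — in that mode the
  mediator's information physically travels through cells.

An optional saturating polarization form c^e/(1 + (c/R)^e) is available
behind an explicit ceiling flag for 2D runs; all shipped defaults leave it
off.

## Numerical integration

Explicit Euler with fixed Δt = 0.001 time units (configurable), periodic
boundaries, initial state = uniform equilibrium with independent
multiplicative fluctuation of ±1% per value (uniform by default, Gaussian
selectable), deterministic per seed. Euler preserves linear invariants
exactly, so the conservation checks above hold to ~1e−12 relative over
1e5 steps. Runs stop at `max_time` (default 1000 time units; the shipped
experiments use 200–300, by which point every 1D run here has either
reached `steady_tol` = 1e−8 or settled into slow coarsening) or when
max |d/dt| < `steady_tol`. Negative or non-finite concentrations abort
with a diagnostic rather than being clamped — clamping would silently
change the dynamics; the fix is a smaller Δt.

## Linear stability

`dispersion_coefficients` evaluates the analytic coefficients at the
uniform 1D equilibrium using the regulatory functions' analytic
derivatives:

* Model O: c₁ = E_p p + D_a, c₂ = −E_p p a_eq φ0′(a_eq)/2φ0(a_eq),
  c₀ = −(G_a + 2c₁ + 2c₂); λ(ν) = 4c₂ν² + 2c₁ν + c₀ − 2c₂. The identity
  λ(1) = −G_a (total auxin relaxes at the turnover rate) holds to machine
  precision. For power-law polarization the instability region re-derives
  to D_a < (2n−1)E_p p − √(2n G_a E_p p) with ν\* = (1+R_a)/2n,
  R_a = D_a/E_p p.
* Model A: λ(ν) = 2c₁ν + c₀ with c₁ = (α−β)/2,
  c₀ = α + β − (2(E_q q + D_a)/V + G_a). This affine form is *exact* for
  the doubly reduced system (QSS PIN1 plus adiabatic elimination of the
  fast cytosolic auxin): β simplifies to
  E_p p a_eq φa′(a′_eq)/(V φa(a′_eq)) via the equilibrium identity
  2(E_q q + D_a)a′_eq + G_a A = a_eq(2E_p p + 2D_a + G_a), and the oracle
  confirms it to ≤ 1e−6 relative. For the full two-field QSS system only
  sign and argmax agreement are asserted — and observed.
* Model B6 (φa ≡ 1): the quadratic form returns with
  c₁ = γ(E_p p + D_a), c₂ = −γκ E_p p a_eq θ′(a_eq) φx′(x′_eq)/2φx(x′_eq),
  γ = (E_q q + D_a)/(2E_q q + 2D_a + VG_a),
  κ = D_x G_x/((2D_x + G_x)(2D_x + VG_x)). These coefficients are an
  *approximation*: they match no clean adiabatic reduction exactly
  (slaving everything to cell auxin leaves 15–30% error at typical
  parameters), and near and beyond their predicted boundary they
  *understate* instability — at the shipped D_x transect the full QSS
  linearization stays unstable (with growing preferred wavelength) where
  the approximate ν\* exceeds 1. They serve as the qualitative summary
  (the closed form of ν\* and its V→0 limit are verified algebraically),
  while quantitative statements defer to the oracle. The
  oracle-agreement test samples the scale-separated regime (V ≤ 0.1, fast
  X turnover) where the approximation predicts robust instability.

The oracle, `reduced_jacobian_spectrum`, differentiates the (QSS-reduced)
right-hand side by complex-step (step 1e−100, machine-precision
derivatives; the regulatory functions pass complex arguments through their
domain checks for exactly this purpose), then projects the Jacobian onto
per-wavenumber plane-wave subspaces (cell fields at integer positions,
edge fields offset by ½). The projection residual certifies translation
invariance (≤ 1e−8, typically ~1e−14). `measure_mode_growth` validates
the dispersion from the simulation side: it seeds a 1e−5-relative cosine
on cell auxin, integrates at Δt = 2e−4, and fits log-amplitude against
time inside the linear window (< 1% of equilibrium), after discarding the
first 20% of samples; agreement within 5% is verified for the QSS model,
whose single-field dynamics have no projection transient.

## Pattern metrics

On a length-N periodic series: L1 = N/k1 with k1 the spectral-power
argmax over k ∈ [1, N/2] (near-ties within 1e−9 relative break toward the
smallest k and are flagged); L2 = (#above-mean positions)/(#cyclically
contiguous runs of them). Strictly constant series — dominant mode
amplitude below 1e−6 of the mean — return an explicit undefined flag;
ties *at* the mean count as non-spots. Both metrics are invariant under
rotation and positive affine rescaling (property-tested). Metrics are
recorded for both the cell and the apoplast series; the apoplast series is
the informative one for Model A (where the alternation lives), the cell
series for Models O and B.

In 2D, above-mean masks percolate on 6-neighbor lattices (Model A's
interface-scale speckle connects into one giant component near the 50%
occupancy threshold), so cluster counting alone cannot separate "many
fine-grained speckles" from "a few maxima". Two complementary summaries
are used instead: the number of strict local maxima above the mean, and
the Pearson correlation between each cell and its neighbor mean. Isolated
macroscopic maxima give a handful of peaks with coherence ≈ 0.8–1.0;
interface-scale patterns give peaks on the order of every tenth cell with
coherence ≲ 0.3.

## Study conditions and scaling

The shipped experiment sizes are desk-scale: 40-cell rings for single-run
reproductions (200 for the analytic wavenumber grids), 8×8 sweep grids
(32×32 in the `full` presets), and a 14×14 hexagonal torus for the 2D
comparison. Sweep seeds derive from a master seed counter-wise per grid
point, so any single cell reproduces in isolation.

Parameter defaults follow the published figure legends. Three points were
genuinely open and are package decisions:

* The 2D mediator legend omits the X-synthesis exponent; r = 2, the
  standard value of the 1D mediator analyses, is used (r = 1 leaves the
  2D uniform state linearly stable — leading eigenvalue −0.18 versus
  +0.30 at r = 2 — so no comparison would be possible).
* The D_x transect of the 1D mediator experiments is read against the
  D_x–D_a panel base (G_x = 1, D_a = 1, r = 2, m = 6, V = 1, p = q = 10);
  the printed cross-reference is internally inconsistent about which
  panel supplies the base.
* Wavelength-tracking comparisons between simulation and the analytic L\*
  run the QSS-PIN1 form of the model, because the analytic prediction *is*
  the QSS dispersion: with dynamic PIN1 at G_p = 1 and strong pumping the
  full linearization's fastest mode genuinely shifts (k = 4 versus the QSS
  k = 8 at p = 40, D_a = 10 on 40 cells — shown by the oracle), and steady
  patterns coarsen accordingly.

## What the synthetic conditions do and do not show

All inputs are generated internally: perturbed uniform equilibria and
synthetic periodic series for the metric tests. Passing tests therefore
demonstrate the internal consistency of the model family — equilibria,
conservation, dispersion/oracle/simulation agreement, and the qualitative
pattern phenomenology (tunable spacing; its collapse to interface-scale
alternation; its mediator-dependent recovery) — not agreement with
measured plant tissue. Real meristems grow, divide, and curve; none of
that is modeled (fixed lattice, no growth, no mechanics, deterministic
dynamics apart from the initial fluctuation).

Two quantitative cautions from the package's own experiments:

* Steady 1D patterns coarsen beyond the linear prediction and freeze with
  phase defects. At the interface-scale (Model A) conditions, N = 40 runs
  end with 17–19 alternating spots instead of 20, so the measured L1 lies
  in [2.0, 2.36] rather than exactly 2 (L2 stays exactly 1); the
  wavelength-2 statement is exact only for the analytic fastest mode.
* The B6 closed-form condition is conservative far from the
  scale-separated regime; use the oracle (or simulation) near and beyond
  its predicted boundary.

## Limitations

1D-only analytic stability (the 2D results are assessed by simulation and
summary statistics); fixed-step explicit Euler as the production
integrator (chosen to honor the reference Δt; the oracle and mode-growth
measurements provide the accuracy cross-checks); no stochastic reaction
dynamics; no growing or irregular meshes.
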