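# Methods

## Physical model

`b850sim` simulates excitation energy transfer in arrays of B850 rings —
the 16-pigment bacteriochlorophyll circles of the LH2 antenna complex of
purple bacteria — with a Holstein-type Frenkel-exciton Hamiltonian

    H = Σ_{jl} J_jl a†_j a_l
      + Σ_{r,q} ω_q b†_{rq} b_{rq}
      − (1/√Ns) Σ_{r,n,q} g_q ω_q a†_{rn} a_{rn} (e^{iqn} b_{rq} + e^{−iqn} b†_{rq}),

where j, l run over all pigments (ring r, site n), each ring carries an
independent, identical set of Ns discrete phonon modes labelled by the ring
momentum q = 2π n_q/Ns, and the exciton couples diagonally (site-energy
modulation) to its own ring's modes. ħ = 1 throughout; energies are in
cm⁻¹, lengths in nm, times in fs (1 cm⁻¹ = 1.883652·10⁻⁴ rad/fs).

Assumptions baked into the model:

- single-excitation manifold (one exciton in the whole array);
- zero temperature — phonons start in the vacuum;
- no static disorder: all site energies equal;
- rings are rigid, coplanar translated copies of one idealized template.

## Geometry and couplings

A ring places 16 pigments uniformly on a circle of radius 2.3 nm, which
puts adjacent pigments ≈0.9 nm apart as in the LH2 crystal structure.
Transition dipoles are unit vectors, nearly tangential, with alternating
in-plane offsets (+12° for α-type, 180°−12° for β-type sites), so adjacent
dipoles are nearly antiparallel (head-to-tail) and the total ring dipole
vanishes. This reproduces the characteristic B850 exciton structure: the
lowest ring eigenstate is optically dark and the second-lowest is a
degenerate pair carrying essentially all the oscillator strength
(≈ Ns/2 = 8 monomer units each). The offset angle is a documented
approximation; the exact α/β dipole orientations would require the
underlying crystal structure.

Couplings use the point-dipole approximation
J_mn = C [d_m·d_n − 3(d_m·r̂)(d_n·r̂)]/r³ for **all** pigment pairs, with
one scale C = 117.5707 cm⁻¹·nm³ calibrated (helper
`calibrate_dipole_strength`) so the intra-ring nearest-neighbor coupling is
+300 cm⁻¹; together with the default site energy 12 396.2 cm⁻¹ this puts
the bright band at 850.0 nm. A config hook can replace the intra-ring
nearest/next-nearest couplings with fixed values. At the default 8 nm
center-to-center spacing the largest inter-ring coupling is ≈2.6 cm⁻¹ —
consistent with the ≈0.1 ps⁻¹ Förster transfer rate measured for LH2 — so
inter-ring transfer in the quantum model is slow compared to studies that
use structure-derived coupling tables several times larger. Consequences
are noted under *Limitations*.

## Phonon baths

Three parameterizations of (ω_q, g_q):

1. **linear_dispersion** (default): ω_q = ω₀[1 + W(2|q|/π − 1)] on the
   16-point grid n_q = −7…8, with ω₀ = 1670 cm⁻¹ (≈20 fs period) and
   bandwidth W = 0.1. Couplings are uniform, g_q ≡ g, fixed by the
   Huang-Rhys sum rule (1/Ns) Σ_q g²ω_q = S ω₀ with S = 0.5 (only the sum
   rule, not the per-mode split, is physically constrained; the uniform
   split is our choice). For the symmetric default grid this gives g² = S.
2. **drude**: density-weighted discretization of
   J(ω) = 2λ_D ω γ_D/(ω² + γ_D²) at equal reorganization-energy slices,
   preserving the total reorganization energy to the cutoff (50 γ_D by
   default; the quadrature test checks 1%).
3. **mode_table**: two-column text file (frequency cm⁻¹, Huang-Rhys
   factor), for effective-mode sets taken from spectroscopy literature.

## Davydov D1 dynamics

The trial state assigns every pigment a complex amplitude α_{rn} and its
own coherent-state displacement field λ_{rnq} over its ring's modes
(Nr·Ns + Nr·Ns² parameters). Equations of motion are the Euler–Lagrange
equations of the Dirac–Frenkel Lagrangian
L = (i/2)(⟨Ψ|Ψ̇⟩ − c.c.) − ⟨Ψ|H|Ψ⟩. Because components with different
exciton sites are orthogonal, the Gram matrix is diagonal and the equations
close explicitly:

    i α̇_j = Σ_l J_jl S_jl α_l + α_j Σ_q [ω_q|λ_jq|² − ω_q(γ*_jq λ_jq + c.c.)]
             − (i/2) α_j Σ_q (λ*_jq λ̇_jq − c.c.),
    i λ̇_jq = ω_q (λ_jq − γ_jq)
             + (1/|α_j|²) Σ_l J_jl α*_j α_l S_jl (λ̃_lq − λ_jq),

with γ_jq = (g_q/√Ns) e^{−iq n_j}, S_jl the Debye-Waller coherent-state
overlap (cross term only within a ring, Gaussian damping always), and
λ̃_lq = λ_lq if l shares j's ring, else 0. The phonon equation is singular
at unoccupied sites; |α_j|² is regularized by an additive floor ε = 10⁻¹²
(config-exposed). Two exact limits pin the implementation down: g = 0
reduces to free-exciton unitary evolution (checked against the matrix
exponential to 10⁻⁶), and J = 0 to the independent-boson closed form
λ_nq(t) = γ_nq(1 − e^{−iω_q t}) (checked to 10⁻⁸).

**Integration.** Fixed-step classical Runge-Kutta (RK4), default
dt = 0.05 fs (the fastest phonon period is ≈18 fs; dt must resolve it by a
factor ≥40 or the propagator refuses). Fixed stepping keeps trajectories
bit-reproducible; there is no randomness anywhere in the quantum pipeline.
The uniform site energy only contributes a global phase, so the mean
diagonal is removed during propagation (recorded in the archive; the
absorption module restores the phase). Norm and variational energy are
monitored at every snapshot — never re-imposed; a norm drift beyond 10⁻³
aborts with a pointer at dt. Typical drifts at default settings are ~10⁻⁹
(norm) and ~10⁻⁸ relative (energy) over 2 ps; halving dt reduces the
integrator energy error ≈16-fold, confirming 4th-order convergence.
Snapshots are strided (default every 1 fs) and store the full (α, λ), so
any observable can be recomputed offline from the archive.

## Observables

- **Reduced density matrix** ρ_mn = α*_m α_n S_mn; the diagonal is exactly
  |α_n|².
- **Ring populations and MSD**: ρ_r = Σ_{n∈r} ρ_nn;
  MSD(t) = Σ_r d_r² ρ_r(t) with d_r ring-center distances from the
  initially excited ring (ring-resolved, not pigment-resolved).
- **Diffusion exponent** γ: least-squares slope of log MSD vs log t. The
  default window starts at 20 fs (one phonon period) to skip the ballistic
  transient and is always reported with the fit. The superdiffusive
  duration comes from a continuous two-segment piecewise-linear fit in
  log-log space, scanning every interior breakpoint for the least total
  squared residual.
- **Coherence size** L_ρ = (Σ|ρ_mn|)²/(N Σ|ρ_mn|²) ∈ (0, N]: N for a
  uniform fully coherent state, 1/N for a single occupied pigment.
- **Superradiance enhancement** L_s = Σ M_mn ρ_mn with M_mn = d_m·d_n, the
  aggregate-to-monomer radiative-rate ratio. The bright initial state gives
  L_s(0) = 7.69 ≈ 8 with the default geometry; the dark state gives 0 and a
  single pigment exactly 1.
- **Absorption spectrum**: wavepacket autocorrelation
  A(ω) ∝ Re ∫₀^T dt e^{iωt−t/τ} F(t), with F(t) the overlap of the
  dipole-projected initial state (phonon vacuum) with its D1-propagated
  image, summed over the three lab polarizations; τ defaults to 50 fs and
  is a documented knob, so only qualitative band shapes are claimed. A
  trapezoid rule in t keeps the oscillator-strength sum rule to <2% on
  wide grids.

## Classical hopping model

Treating each ring as one aggregate, excitation hops between neighboring
rings at rate k, decays locally at rate K, and is injected by a Gaussian
laser A_i = A₀ exp(−[(i−i₀)a]²/2σ²):

    dp_i/dt = r_a A_i − (K + 2k) p_i + k p_{i−1} + k p_{i+1}   (chain).

The stationary chain solution is evaluated through the lattice Green's
function with decay constant λ = arccosh[(K+2k)/2k] and virtual absorbing
rings just outside the chain; the printed hyperbolic-cosine closed form is
typeset ambiguously in parts of the literature, so the coded expression is
derived from the sinh-product Green's function and validated against
direct integration of the rate equations (LSODA, banded Jacobian) to
≈10⁻¹³. All hyperbolics are exponentially scaled so 4001-ring chains do
not overflow. Laser-free relaxation uses the modified-Bessel propagator
p_i(t) = e^{−(K+2k)t} Σ_m p_m(0) I_{i−m}(2kt) with exponentially scaled
Bessel functions (`scipy.special.ive`); on the hexagonally coordinated 2D
lattice (axial coordinates, neighbors (i±1,j), (i,j±1), (i∓1,j±1)) the
analogous triple Bessel sum carries prefactor e^{−(K+6k)t} and an adaptive
truncation (scaled-Bessel tail < 10⁻¹² of the retained sum). The 2D
stationary problem is solved as a sparse linear system on a rhombic patch
with reflecting (missing-neighbor) boundaries. The normalized stationary
distribution p̃_i = p_i/p_{i₀} depends only on K/k and the laser; the
diffusion length is L_d = σ_s − σ with σ_s the moment standard deviation
of the normalized stationary field. The analytic propagators are for the
infinite lattice; finite-patch checks (e.g. K = 0 conservation) are sized
so no probability reaches the boundary on the test horizon.

## Adaptive fractal analysis

The AFA trend fits order-M polynomials (M = 1 by default) in overlapping
windows of odd length w = 2n+1 stepping by n; the n+1 shared points of two
neighboring windows are blended with linearly varying weights
w₁ = 1 − (l−1)/n, w₂ = (l−1)/n, giving a globally continuous trend (the
final window is shifted to end at the last sample, with the actual overlap
length used for the weights). The fluctuation function
F(w) = sqrt[(1/N_f) Σ (u−ν)²] uses the full trend length N_f; windows
whose residual is at the machine-precision scale of the data are excluded
with a warning. H is the slope of log₂F vs log₂w, fitted either in one
segment, in two segments split at a configured window (257 samples for
1 fs sampled traces), or with an automatically detected breakpoint
(continuous two-line least squares). Population traces are analyzed on a
uniform 1 fs grid so window sizes map directly to fs. The duration of an
H > 1 regime is operationalized as the largest dyadic window w such that
the cumulative fit over all windows ≤ w still has slope > 1 for every
monitored trace.

The estimator is calibrated against exact fractional Brownian motion from
a Davies–Harte circulant-embedding generator (deterministic under a fixed
seed): mean fitted H over 20 paths is within ±0.05 of the target for
H ∈ {0.3, 0.5, 0.8}, and Var[B(t)] scales as t^{2H} within 10%.

## Problem sizes and defaults used in the shipped analyses

The packaged tests and the reproduction script run: 3-ring and 11-ring
chains and the 7-ring hexagonal array at dt = 0.05 fs for 0.7–2 ps
(48–176 pigments, 16 modes/ring); the hopping model on 4001-ring chains
and ≈50×50 hexagonal patches. These sizes fully develop the short-time
transport regimes under study (the MSD crossover sits near 0.6 ps) while
keeping a complete run on one CPU core in minutes.

## Limitations

- Zero temperature and a single D1 trial state: no thermal fluctuations,
  and strong-coupling/fast-exciton regimes would need multiple-Davydov
  extensions.
- Point-dipole couplings with one calibrated scale: intra-ring physics
  (dark/bright structure, band position) is quantitatively reasonable, but
  inter-ring couplings at 8 nm come out at the Förster-consistent few-cm⁻¹
  level. Compared to structure-derived coupling tables this makes
  inter-ring quantum transfer slow: on small chains the exciton largely
  remains on the initially excited ring for ~ps, so long-time
  delocalization measures (late-time L_s, L_ρ) reflect one ring's
  coherence pool rather than a chain-wide equilibrium. Short-time
  exponents and crossovers are robust to this.
- No B800 ring, carotenoids, protein electrostatics, or structural/energetic
  disorder.
- The absorption lineshape scheme (autocorrelation with exponential
  damping) is a pragmatic choice; lineshape theory refinements (cumulant
  expansions, inhomogeneous broadening) are out of scope.
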