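# b850sim

Fully quantum exciton–phonon dynamics in mesoscale arrays of B850 pigment
rings, the circular bacteriochlorophyll aggregates of the LH2 antenna of
purple photosynthetic bacteria — plus a classical master-equation picture
of incoherent inter-ring hopping and adaptive fractal analysis (AFA) of
exciton population time series.

**Who it is for.** Researchers in photosynthetic light harvesting and
molecular-aggregate photophysics who want desk-scale, reproducible
simulations of exciton transport across multiple antenna complexes: how
fast an excitation spreads (anomalous-diffusion exponents), how delocalized
it is (coherence size, superradiance enhancement), and how far it travels
before dissipating (diffusion lengths).

## The model in brief

Pigments are two-level chromophores with uniform site energies, coupled by
point-dipole interactions J_mn = C[d_m·d_n − 3(d_m·r̂)(d_n·r̂)]/r³ and each
coupled diagonally to its own ring's discrete phonon modes (Holstein
Hamiltonian; linear phonon dispersion around ω₀ = 1670 cm⁻¹, Huang-Rhys
factor S = 0.5 by default). The wavefunction is the Davydov D1 Ansatz —
one complex amplitude α per pigment and one coherent-state phonon
displacement field λ per pigment — propagated by the Dirac–Frenkel
time-dependent variational principle with fixed-step RK4. Phonons are
treated on the same footing as the exciton; nothing is traced out or
assumed Markovian. The classical layer models each ring as one aggregate
with nearest-neighbor hopping rate k and dissipation rate K, with analytic
stationary (lattice Green's function) and time-dependent (modified-Bessel
propagator) solutions on chains and hexagonally coordinated 2D lattices.

Key observables:

- MSD(t) = Σ_r d_r² ρ_r(t) and its power-law exponent γ (γ>1:
  superdiffusion);
- coherence size L_ρ = (Σ|ρ_mn|)²/(N Σ|ρ_mn|²);
- superradiance enhancement L_s = Σ_mn (d_m·d_n) ρ_mn;
- diffusion length L_d = σ_s − σ of the stationary hopping distribution
  against the driving laser width.

See `docs/methods.md` for the full model, equations of motion, numerical
choices and limitations.

## Worked example

Bright-state excitation of the central ring of a three-ring chain
(16 pigments/ring, 8 nm spacing), 2 ps at dt = 0.05 fs:

```python
import numpy as np
from b850sim import protocols
from b850sim.geometry import ring_center_distances
from b850sim.observables import (
    crossover_fit, diffusion_exponent, mean_square_displacement)

geom, traj = protocols.run_case("chain", n_rings=3, case=2, t_end_fs=2000.0)

d = ring_center_distances(geom, geom.central_ring)
msd = mean_square_displacement(traj, d)
gamma = diffusion_exponent(traj.times, msd, window=(20.0, 600.0))
gs, gl, t_cross = crossover_fit(traj.times, msd, window=(20.0, 1000.0))
Ls = protocols.superradiance_time_series(geom, traj)

print(f"gamma(20-600 fs) = {gamma:.3f}")
print(f"crossover at {t_cross:.0f} fs (slopes {gs:.2f} -> {gl:.2f})")
print(f"Ls(0) = {Ls[0]:.3f}")
```

prints

```
gamma(20-600 fs) = 1.833
crossover at 609 fs (slopes 1.83 -> 0.42)
Ls(0) = 7.689
```

i.e. the exciton spreads superdiffusively (γ ≈ 1.8) for about 0.6 ps
before the spread flattens, and the optically bright initial state starts
with a superradiance enhancement of ≈8 (cooperative emission of half the
ring). The dark-state run (`case=1`) keeps the exciton on the central ring
and its coherence size oscillates around ≈5 pigments.

The classical layer, from the command line:

```
$ b850sim master-eq --preset stationary --K 0.001 --k 0.1 --sigma 169.86
L_d = 34.23 nm
```

— the stationary excitation profile of a 4001-ring chain under a Gaussian
laser of σ = 169.86 nm (FWHM 400 nm) broadens by 34 nm at K/k = 0.01; the
sweep preset (`--preset ld_sweep`) tabulates L_d against K/k, growing
without bound as K/k → 0.

Other entry points: `b850sim simulate CONFIG.yaml` (full quantum pipeline
to a self-describing HDF5 archive + TSV tables), `b850sim afa SERIES.tsv`
(Hurst exponents of any single-column series), `b850sim spectrum`,
`b850sim fixtures`, `b850sim info`.

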