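"""Measurement layer on top of D1 trajectories.

Implements the reduced single-exciton density matrix (with Debye-Waller
damping of inter-site coherences), ring populations, mean square
displacement and its power-law diffusion exponent, the coherence size
L_rho, the superradiance enhancement factor L_s, and a wavepacket
autocorrelation absorption spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .davydov import D1State, Trajectory, debye_waller_matrix, initial_state, propagate
from .hamiltonian import ExcitonHamiltonian, PhononBath
from .units import CM1_TO_RAD_FS

__all__ = [
    "DensityMatrix",
    "dipole_metric",
    "reduced_density_matrix",
    "ring_populations",
    "mean_square_displacement",
    "diffusion_exponent",
    "crossover_fit",
    "coherence_size",
    "superradiance",
    "coherence_size_series",
    "superradiance_series",
    "absorption_spectrum",
]


@dataclass(frozen=True)
class DensityMatrix:
    """Reduced single-exciton density matrix in the (ring, site) basis."""

    rho: np.ndarray  # (N, N) complex, Hermitian
    n_rings: int
    n_sites_per_ring: int
    time: float = 0.0

    def __post_init__(self):
        rho = np.asarray(self.rho)
        N = self.n_rings * self.n_sites_per_ring
        if rho.shape != (N, N):
            raise ValueError(f"rho must be {N}x{N}")
        if not np.allclose(rho, rho.conj().T, atol=1e-10):
            raise ValueError("rho must be Hermitian")
        if np.any(np.real(np.diag(rho)) < -1e-12):
            raise ValueError("negative population on the diagonal")

    @property
    def trace(self) -> float:
        return float(np.real(np.trace(self.rho)))


def reduced_density_matrix(state: D1State) -> DensityMatrix:
    """rho_mn = alpha_m^* alpha_n S_mn with S the Debye-Waller overlap.

    Diagonal overlaps are exactly 1, so diag(rho) = |alpha|^2; cross-ring
    elements carry only the Gaussian damping exp(-(|l_m|^2 + |l_n|^2)/2).
    """
    Nr, Ns = state.alpha.shape
    N = Nr * Ns
    a = state.alpha.reshape(N)
    S = debye_waller_matrix(state.lam)
    rho = np.conj(a)[:, None] * a[None, :] * S
    return DensityMatrix(rho=rho, n_rings=Nr, n_sites_per_ring=Ns, time=state.time)


def dipole_metric(dipoles: np.ndarray) -> np.ndarray:
    """M_mn = d_m . d_n for unit transition dipoles (N x N, symmetric)."""
    dipoles = np.asarray(dipoles, dtype=float)
    return dipoles @ dipoles.T


def ring_populations(traj: Trajectory) -> np.ndarray:
    """Exciton population per ring, shape (T, Nr)."""
    return np.sum(np.abs(traj.alpha) ** 2, axis=2)


def mean_square_displacement(traj: Trajectory, distances: np.ndarray) -> np.ndarray:
    """MSD(t) = sum_r d_r^2 rho_r(t), nm^2.

    ``distances`` are ring-center distances from the initially excited ring.
    """
    distances = np.asarray(distances, dtype=float)
    pops = ring_populations(traj)
    if pops.shape[1] != len(distances):
        raise ValueError("distance vector does not match ring count")
    return pops @ distances**2


def _loglog_window(times, msd, window):
    times = np.asarray(times, dtype=float)
    msd = np.asarray(msd, dtype=float)
    t_min, t_max = window
    sel = (times >= t_min) & (times <= t_max) & (msd > 0) & (times > 0)
    if sel.sum() <= 3:
        raise ValueError("fewer than 4 usable points in the fit window")
    return np.log(times[sel]), np.log(msd[sel])


def diffusion_exponent(times, msd, window=(20.0, 600.0)) -> float:
    """Least-squares slope gamma of log MSD vs log t on the window.

    gamma = 1 is Fickian diffusion, gamma > 1 superdiffusion, gamma < 1
    subdiffusion.  The first ~20 fs (one phonon period) are excluded by the
    default window as a ballistic/transient regime.
    """
    x, y = _loglog_window(times, msd, window)
    gamma = np.polyfit(x, y, 1)[0]
    return float(gamma)


def crossover_fit(times, msd, window=(20.0, 1000.0), margin: int = 4):
    """Continuous two-segment power-law fit of the MSD in log-log space.

    Scans every interior data point as a candidate breakpoint, fits the
    continuous piecewise-linear model y = a + b x + c (x - xb)_+ by least
    squares, and keeps the breakpoint minimizing the total squared residual.

    Returns ``(gamma_short, gamma_long, t_cross_fs)``.
    """
    x, y = _loglog_window(times, msd, window)
    if len(x) < 2 * margin + 2:
        raise ValueError("too few points for a two-segment fit")
    best = None
    for i in range(margin, len(x) - margin):
        xb = x[i]
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - xb, 0.0)])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((X @ coef - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, coef, xb)
    _, coef, xb = best
    gamma_short = float(coef[1])
    gamma_long = float(coef[1] + coef[2])
    return gamma_short, gamma_long, float(np.exp(xb))


def coherence_size(rho: DensityMatrix | np.ndarray) -> float:
    """L_rho = (sum_mn |rho_mn|)^2 / (N sum_mn |rho_mn|^2), in (0, N].

    N is the total pigment count; a fully coherent uniform state gives N,
    a single occupied pigment gives 1/N.
    """
    r = rho.rho if isinstance(rho, DensityMatrix) else np.asarray(rho)
    absr = np.abs(r)
    denom = np.sum(absr**2)
    if denom == 0:
        raise ValueError("all-zero density matrix")
    return float(np.sum(absr) ** 2 / (r.shape[0] * denom))


def superradiance(rho: DensityMatrix | np.ndarray, M: np.ndarray) -> float:
    """L_s = sum_mn M_mn rho_mn, the aggregate-to-monomer radiative ratio."""
    r = rho.rho if isinstance(rho, DensityMatrix) else np.asarray(rho)
    if r.shape != M.shape:
        raise ValueError("shape mismatch between rho and dipole metric")
    val = np.sum(M * r)
    return float(np.real(val))


def _rho_snapshots(traj: Trajectory):
    T, Nr, Ns = traj.alpha.shape[:3]
    N = Nr * Ns
    for i in range(T):
        a = traj.alpha[i].reshape(N)
        S = debye_waller_matrix(traj.lam[i])
        yield np.conj(a)[:, None] * a[None, :] * S


def coherence_size_series(traj: Trajectory) -> np.ndarray:
    """L_rho(t) along a trajectory."""
    out = np.empty(traj.n_snapshots)
    N = traj.alpha.shape[1] * traj.alpha.shape[2]
    for i, rho in enumerate(_rho_snapshots(traj)):
        absr = np.abs(rho)
        out[i] = np.sum(absr) ** 2 / (N * np.sum(absr**2))
    return out


def superradiance_series(traj: Trajectory, M: np.ndarray) -> np.ndarray:
    """L_s(t) along a trajectory (real part)."""
    out = np.empty(traj.n_snapshots)
    for i, rho in enumerate(_rho_snapshots(traj)):
        out[i] = np.real(np.sum(M * rho))
    return out


def absorption_spectrum(
    H: ExcitonHamiltonian,
    bath: PhononBath,
    dipoles: np.ndarray | None = None,
    damping_fs: float = 50.0,
    t_end: float = 500.0,
    dt: float = 0.1,
    omega_grid: np.ndarray | None = None,
    normalize: bool = True,
):
    """Absorption spectrum from the dipole-prepared wavepacket
    autocorrelation,

        A(w) ~ Re int_0^T dt exp(i w t - t / tau) F(t),

    with F(t) the overlap of the initial state (exciton amplitudes
    proportional to the dipole projections along each lab axis, phonons in
    vacuum) with its D1-propagated image, summed over the three
    polarizations.  Returns ``(omega_cm1, A)``.
    """
    if damping_fs <= 0:
        raise ValueError("damping time must be positive")
    if dipoles is None:
        if H.geometry is None:
            raise ValueError("dipoles required when H carries no geometry")
        dipoles = H.geometry.all_dipoles()
    Nr, Ns = H.n_rings, H.n_sites_per_ring
    N = Nr * Ns

    F = None
    times = None
    shift = 0.0
    for axis in range(3):
        proj = dipoles[:, axis]
        w_pol = float(np.sum(proj**2))
        if w_pol < 1e-14:
            continue
        a0 = (proj / np.sqrt(w_pol)).astype(complex).reshape(Nr, Ns)
        lam0 = np.zeros((Nr, Ns, bath.n_modes), dtype=complex)
        st0 = D1State(alpha=a0, lam=lam0)
        traj = propagate(st0, H, bath, t_end=t_end, dt=dt, snapshot_stride=1)
        shift = traj.config["energy_shift_cm1"]
        vac = np.exp(-0.5 * np.sum(np.abs(traj.lam) ** 2, axis=3))
        f = np.sum(
            np.conj(a0)[None, :, :] * traj.alpha * vac, axis=(1, 2)
        )
        F = w_pol * f if F is None else F + w_pol * f
        times = traj.times
    if F is None:
        raise ValueError("all dipole projections vanish")

    # restore the site-energy phase removed by the propagation gauge
    F = F * np.exp(-1j * shift * CM1_TO_RAD_FS * times)

    if omega_grid is None:
        omega_grid = np.arange(shift - 2000.0, shift + 2000.0, 2.0)
    wt = np.exp(
        1j * np.outer(omega_grid * CM1_TO_RAD_FS, times)
        - times[None, :] / damping_fs
    )
    dt_grid = times[1] - times[0]
    weights = np.full(len(times), dt_grid)
    weights[0] = weights[-1] = 0.5 * dt_grid  # trapezoid rule in time
    A = np.real(wt @ (F * weights))
    if normalize and np.max(np.abs(A)) > 0:
        A = A / np.max(A)
    return omega_grid, A
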