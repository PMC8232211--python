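"""Frenkel-exciton coupling matrix and discrete phonon baths.

The exciton Hamiltonian is an N x N real symmetric matrix ``J`` (cm^-1)
whose diagonal holds the (uniform) pigment site energies and whose
off-diagonal elements are excitonic couplings.  By default couplings are
computed in the point-dipole approximation,

    J_mn = C * [d_m . d_n - 3 (d_m . r_hat)(d_n . r_hat)] / r^3,

with ``C`` a dipole-strength scale in cm^-1 nm^3; an optional override
table can replace the intra-ring nearest and next-nearest neighbor
couplings with fixed values.

Each ring carries an independent, identical set of discrete phonon modes.
Three parameterizations are supported: a linear dispersion on the discrete
ring momentum grid, a density-weighted discretization of a Drude spectral
density, and a user-supplied frequency/Huang-Rhys mode table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import NanoarrayGeometry

__all__ = [
    "ExcitonHamiltonian",
    "PhononBath",
    "coupling_matrix",
    "exciton_eigenstates",
    "make_bath",
    "calibrate_dipole_strength",
]

#: default point-dipole scale (cm^-1 nm^3); calibrated so that the
#: intra-ring nearest-neighbor coupling of the default ring is +300 cm^-1,
#: which together with the default site energy puts the bright band near
#: 850 nm (see calibrate_dipole_strength and scripts in the docs).
DEFAULT_DIPOLE_STRENGTH = 117.5707


@dataclass(frozen=True)
class ExcitonHamiltonian:
    """N x N exciton coupling matrix with array bookkeeping."""

    J: np.ndarray  # (N, N) cm^-1, symmetric
    n_rings: int
    n_sites_per_ring: int
    geometry: NanoarrayGeometry | None = None

    def __post_init__(self):
        J = np.asarray(self.J, dtype=float)
        N = self.n_rings * self.n_sites_per_ring
        if J.shape != (N, N):
            raise ValueError(f"J must be {N}x{N}")
        if not np.allclose(J, J.T, atol=1e-10):
            raise ValueError("J must be symmetric")

    @property
    def n_pigments(self) -> int:
        return self.n_rings * self.n_sites_per_ring

    def ring_block(self, r: int) -> np.ndarray:
        """Intra-ring block of ``J`` for ring ``r``."""
        Ns = self.n_sites_per_ring
        return self.J[r * Ns : (r + 1) * Ns, r * Ns : (r + 1) * Ns]


@dataclass(frozen=True)
class PhononBath:
    """Discrete phonon modes of one ring (identical across rings)."""

    q: np.ndarray  # mode momenta, rad (2*pi*n_q/Ns)
    omega: np.ndarray  # frequencies, cm^-1
    g: np.ndarray  # dimensionless couplings
    scheme: str
    n_sites: int  # Ns entering the 1/sqrt(Ns) coupling normalization

    def __post_init__(self):
        if not (len(self.q) == len(self.omega) == len(self.g)):
            raise ValueError("q, omega, g must have equal length")
        if np.any(np.asarray(self.omega) <= 0):
            raise ValueError("all mode frequencies must be positive")

    @property
    def n_modes(self) -> int:
        return len(self.omega)

    def huang_rhys(self) -> float:
        """S = (1/Ns) sum_q g_q^2 omega_q / omega_ref with omega_ref the
        coupling-weighted mean frequency; for the linear-dispersion scheme
        this returns the Huang-Rhys factor used at construction."""
        return float(np.sum(self.g**2 * self.omega) / (self.n_sites * self._omega0()))

    def _omega0(self) -> float:
        return float(np.mean(self.omega))

    def reorganization_energy(self) -> float:
        """lambda = (1/Ns) sum_q g_q^2 omega_q (cm^-1)."""
        return float(np.sum(self.g**2 * self.omega) / self.n_sites)

    def site_phase(self, n_sites: int | None = None) -> np.ndarray:
        """exp(-i q n) phase matrix, shape (n_sites, n_modes)."""
        ns = self.n_sites if n_sites is None else n_sites
        n = np.arange(ns)
        return np.exp(-1j * np.outer(n, self.q))


def coupling_matrix(
    geom: NanoarrayGeometry,
    dipole_strength: float = DEFAULT_DIPOLE_STRENGTH,
    site_energy: float | None = None,
    nn_override: float | None = None,
    nnn_override: float | None = None,
) -> ExcitonHamiltonian:
    """Assemble the point-dipole exciton Hamiltonian for a nanoarray.

    ``nn_override``/``nnn_override`` optionally replace the intra-ring
    nearest- and next-nearest-neighbor couplings by fixed values (cm^-1).
    """
    if dipole_strength <= 0:
        raise ValueError("dipole_strength must be positive")
    pos = geom.all_positions()
    dip = geom.all_dipoles()
    N = len(pos)
    rvec = pos[None, :, :] - pos[:, None, :]
    r = np.linalg.norm(rvec, axis=-1)
    np.fill_diagonal(r, np.inf)
    if np.any(r == 0.0):
        raise ValueError("coincident pigments (zero separation)")
    rhat = rvec / r[..., None]
    dd = dip @ dip.T
    proj = np.einsum("id,ijd->ij", dip, rhat)  # d_i . r_hat(i->j)
    # d_j . r_hat(i->j) = -proj[j, i] by antisymmetry of rvec
    kappa = dd - 3.0 * proj * (-proj.T)
    J = dipole_strength * kappa / r**3
    np.fill_diagonal(J, 0.0)
    J = 0.5 * (J + J.T)  # kill rounding asymmetry

    Ns = geom.n_sites_per_ring
    if nn_override is not None or nnn_override is not None:
        for rblk in range(geom.n_rings):
            o = rblk * Ns
            for n in range(Ns):
                if nn_override is not None:
                    J[o + n, o + (n + 1) % Ns] = nn_override
                    J[o + (n + 1) % Ns, o + n] = nn_override
                if nnn_override is not None:
                    J[o + n, o + (n + 2) % Ns] = nnn_override
                    J[o + (n + 2) % Ns, o + n] = nnn_override

    if site_energy is None:
        site_energy = geom.rings[0].site_energy
    np.fill_diagonal(J, site_energy)
    return ExcitonHamiltonian(
        J=J,
        n_rings=geom.n_rings,
        n_sites_per_ring=Ns,
        geometry=geom,
    )


def exciton_eigenstates(H: ExcitonHamiltonian, dipoles: np.ndarray | None = None):
    """Eigen-decomposition of ``J`` plus per-state transition dipoles.

    Returns ``(energies, vectors, mu, strengths)`` with energies ascending,
    ``vectors[:, k]`` the k-th orthonormal eigenvector, ``mu[k]`` the
    transition-dipole vector ``sum_n c_k(n) d_n`` and ``strengths[k] =
    |mu[k]|^2`` (monomer units, i.e. unit pigment dipoles).
    """
    if dipoles is None:
        if H.geometry is None:
            raise ValueError("dipoles required when H carries no geometry")
        dipoles = H.geometry.all_dipoles()
    energies, vectors = np.linalg.eigh(H.J)
    mu = vectors.T @ dipoles
    strengths = np.sum(mu**2, axis=1)
    return energies, vectors, mu, strengths


def calibrate_dipole_strength(
    geom: NanoarrayGeometry,
    target_nn_coupling: float = 300.0,
) -> float:
    """Dipole scale ``C`` such that the intra-ring nearest-neighbor coupling
    of ring 0 equals ``target_nn_coupling`` (cm^-1)."""
    H1 = coupling_matrix(geom, dipole_strength=1.0, site_energy=0.0)
    j1 = H1.ring_block(0)[0, 1]
    if j1 == 0:
        raise ValueError("degenerate geometry: zero nearest-neighbor coupling")
    return target_nn_coupling / j1


# ---------------------------------------------------------------------------
# phonon baths


def _linear_dispersion_bath(omega0: float, W: float, S: float, Ns: int) -> PhononBath:
    """Linear dispersion omega_q = omega0 [1 + W (2|q|/pi - 1)] on the ring
    momentum grid q = 2 pi n_q / Ns, n_q = -(Ns/2 - 1) .. Ns/2, with uniform
    couplings g fixed by the Huang-Rhys sum rule
    (1/Ns) sum_q g^2 omega_q = S omega0."""
    if Ns % 2:
        raise ValueError("linear-dispersion bath needs an even mode count")
    n_q = np.arange(-(Ns // 2 - 1), Ns // 2 + 1)
    q = 2.0 * np.pi * n_q / Ns
    omega = omega0 * (1.0 + W * (2.0 * np.abs(q) / np.pi - 1.0))
    if np.any(omega <= 0):
        raise ValueError("bandwidth W too large: nonpositive frequencies")
    g2 = S * omega0 * Ns / np.sum(omega)
    g = np.full(Ns, np.sqrt(g2))
    return PhononBath(q=q, omega=omega, g=g, scheme="linear_dispersion", n_sites=Ns)


def _drude_bath(
    lambda_D: float, gamma_D: float, n_modes: int, Ns: int, omega_max: float | None = None
) -> PhononBath:
    """Density-weighted discretization of the Drude spectral density
    J(w) = 2 lambda_D w gamma_D / (w^2 + gamma_D^2).

    Modes are placed at equal slices of the reorganization-energy integral
    lambda(w) = (2 lambda_D / pi) arctan(w / gamma_D), so the total
    reorganization energy (1/Ns) sum g^2 omega = lambda_D (up to the cutoff)
    is preserved.
    """
    if lambda_D <= 0 or gamma_D <= 0:
        raise ValueError("Drude parameters must be positive")
    if omega_max is None:
        omega_max = 50.0 * gamma_D
    # cumulative reorganization energy fraction up to omega_max
    total = (2.0 / np.pi) * np.arctan(omega_max / gamma_D)
    frac = (np.arange(n_modes) + 0.5) / n_modes * total
    omega = gamma_D * np.tan(np.pi * frac / 2.0)
    lam_per_mode = lambda_D * total / n_modes
    # (1/Ns) g^2 omega = lam_per_mode  =>  g = sqrt(Ns * lam / omega)
    g = np.sqrt(Ns * lam_per_mode / omega)
    q = np.zeros(n_modes)  # no momentum structure for a sampled bath
    return PhononBath(q=q, omega=omega, g=g, scheme="drude", n_sites=Ns)


def _mode_table_bath(path, Ns: int) -> PhononBath:
    """Read a two-column table (frequency cm^-1, Huang-Rhys factor s_j);
    '#' starts a comment.  Couplings follow from g^2 = Ns * s_j."""
    omegas, gs = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: row {lineno}: expected 2 columns")
            try:
                w, s = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from None
            if w <= 0 or s < 0:
                raise ValueError(
                    f"{path}: row {lineno}: frequency must be > 0, HR factor >= 0"
                )
            omegas.append(w)
            gs.append(np.sqrt(Ns * s))
    if not omegas:
        raise ValueError(f"{path}: empty mode table")
    return PhononBath(
        q=np.zeros(len(omegas)),
        omega=np.array(omegas),
        g=np.array(gs),
        scheme="mode_table",
        n_sites=Ns,
    )


def make_bath(scheme: str, **params) -> PhononBath:
    """Construct a phonon bath.

    scheme='linear_dispersion': params omega0, W, S, Ns
    scheme='drude': params lambda_D, gamma_D, n_modes, Ns [, omega_max]
    scheme='mode_table': params path, Ns
    """
    if scheme == "linear_dispersion":
        return _linear_dispersion_bath(
            omega0=params.get("omega0", 1670.0),
            W=params.get("W", 0.1),
            S=params.get("S", 0.5),
            Ns=params.get("Ns", 16),
        )
    if scheme == "drude":
        return _drude_bath(
            lambda_D=params["lambda_D"],
            gamma_D=params["gamma_D"],
            n_modes=params.get("n_modes", 100),
            Ns=params.get("Ns", 16),
            omega_max=params.get("omega_max"),
        )
    if scheme == "mode_table":
        return _mode_table_bath(params["path"], Ns=params.get("Ns", 16))
    raise ValueError(f"unknown bath scheme {scheme!r}")
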