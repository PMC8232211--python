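"""Idealized B850 rings and their 1D/2D nanoarray arrangements.

A B850 ring is modeled as ``n_sites`` pigments equally spaced on a circle,
each carrying a unit transition-dipole vector.  The default dipole pattern
mimics the alpha/beta alternation of the bacteriochlorophylls: dipoles are
nearly tangential, with adjacent pigments pointing in nearly opposite
directions (head-to-tail), so the total ring dipole nearly vanishes and the
lowest exciton state of the ring is optically dark.

Arrays of rings are either a 1D chain or a 2D triangular (hexagonally
coordinated) lattice; all rings are coplanar with the membrane normal along
z.  Lengths are in nm, site energies in cm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RingGeometry",
    "NanoarrayGeometry",
    "DipolePattern",
    "build_b850_ring",
    "build_nanoarray",
    "ring_center_distances",
    "save_geometry_tsv",
    "load_geometry_tsv",
]

#: default pigment-circle radius (nm).  The LH2 outer diameter is ~7.5 nm;
#: the Mg-Mg circle of the B850 pigments is considerably smaller, and 2.3 nm
#: keeps adjacent-pigment separations just below 1 nm as in the crystal
#: structure.
DEFAULT_RING_RADIUS_NM = 2.3

#: default number of pigments per B850 ring
DEFAULT_N_SITES = 16


@dataclass(frozen=True)
class DipolePattern:
    """Alternating in-plane dipole pattern for alpha/beta pigments.

    The dipole of site ``n`` is the local tangent rotated in-plane by
    ``offset_alpha`` (even sites) or ``offset_beta`` (odd sites) degrees,
    then tilted out of plane by ``tilt`` degrees.  With the default
    ``offset_beta`` of 180 - offset_alpha the adjacent dipoles are nearly
    antiparallel (head-to-tail alternation).
    """

    offset_alpha_deg: float = 12.0
    offset_beta_deg: float = 168.0
    tilt_deg: float = 0.0

    @property
    def alternating(self) -> bool:
        return not math.isclose(self.offset_alpha_deg, self.offset_beta_deg)


@dataclass(frozen=True)
class RingGeometry:
    """Pigment positions and transition-dipole unit vectors of one ring."""

    n_sites: int
    positions: np.ndarray  # (n_sites, 3), nm
    dipoles: np.ndarray  # (n_sites, 3), unit vectors
    ring_center: np.ndarray  # (3,), nm
    site_energy: float  # cm^-1
    radius: float  # nm

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        dip = np.asarray(self.dipoles, dtype=float)
        if pos.shape != (self.n_sites, 3) or dip.shape != (self.n_sites, 3):
            raise ValueError("positions/dipoles must have shape (n_sites, 3)")
        norms = np.linalg.norm(dip, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("dipole vectors must have unit norm")
        radii = np.linalg.norm(pos - np.asarray(self.ring_center), axis=1)
        if not np.allclose(radii, self.radius, atol=1e-9):
            raise ValueError("pigments must lie on the ring circle")

    def translated(self, shift) -> "RingGeometry":
        shift = np.asarray(shift, dtype=float)
        return RingGeometry(
            n_sites=self.n_sites,
            positions=self.positions + shift,
            dipoles=self.dipoles.copy(),
            ring_center=np.asarray(self.ring_center) + shift,
            site_energy=self.site_energy,
            radius=self.radius,
        )

    def rotated_about_axis(self, angle_rad: float) -> "RingGeometry":
        """Rigid rotation about the ring axis (z through the center)."""
        c, s = math.cos(angle_rad), math.sin(angle_rad)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        center = np.asarray(self.ring_center)
        return RingGeometry(
            n_sites=self.n_sites,
            positions=(self.positions - center) @ R.T + center,
            dipoles=self.dipoles @ R.T,
            ring_center=center,
            site_energy=self.site_energy,
            radius=self.radius,
        )


@dataclass(frozen=True)
class NanoarrayGeometry:
    """A chain or hexagonal arrangement of identical B850 rings."""

    rings: tuple  # tuple[RingGeometry, ...]
    layout: str  # "chain" | "hexagonal"
    spacing: float  # center-to-center distance, nm
    lattice_index: tuple  # per-ring int (chain) or (i, j) axial pair (hex)
    central_ring: int  # index of the ring used for initial excitation

    def __post_init__(self):
        if self.layout not in ("chain", "hexagonal"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if len(set(self.lattice_index)) != len(self.lattice_index):
            raise ValueError("ring lattice indices must be unique")

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    @property
    def n_sites_per_ring(self) -> int:
        return self.rings[0].n_sites

    @property
    def n_pigments(self) -> int:
        return sum(r.n_sites for r in self.rings)

    def all_positions(self) -> np.ndarray:
        """(N, 3) pigment positions in ring-major order."""
        return np.concatenate([r.positions for r in self.rings], axis=0)

    def all_dipoles(self) -> np.ndarray:
        """(N, 3) unit dipole vectors in ring-major order."""
        return np.concatenate([r.dipoles for r in self.rings], axis=0)

    def ring_centers(self) -> np.ndarray:
        return np.array([r.ring_center for r in self.rings])

    def translated(self, shift) -> "NanoarrayGeometry":
        return NanoarrayGeometry(
            rings=tuple(r.translated(shift) for r in self.rings),
            layout=self.layout,
            spacing=self.spacing,
            lattice_index=self.lattice_index,
            central_ring=self.central_ring,
        )


def build_b850_ring(
    n_sites: int = DEFAULT_N_SITES,
    radius: float = DEFAULT_RING_RADIUS_NM,
    pattern: DipolePattern | None = None,
    center=(0.0, 0.0, 0.0),
    site_energy: float = 12396.2,
) -> RingGeometry:
    """Build one idealized B850 ring.

    Pigments sit at angles ``2*pi*n/n_sites``; the dipole of pigment ``n``
    is the local tangent rotated in-plane by the alternating alpha/beta
    offset and tilted out of plane by ``pattern.tilt_deg``.
    """
    if pattern is None:
        pattern = DipolePattern()
    if n_sites < 2:
        raise ValueError("need at least 2 sites per ring")
    if n_sites % 2 and pattern.alternating:
        raise ValueError(
            "an alternating alpha/beta dipole pattern requires an even "
            f"number of sites, got n_sites={n_sites}"
        )
    if radius <= 0:
        raise ValueError("radius must be positive")

    center = np.asarray(center, dtype=float)
    theta = 2.0 * np.pi * np.arange(n_sites) / n_sites
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros(n_sites)], axis=1)
    tangent = np.stack([-np.sin(theta), np.cos(theta), np.zeros(n_sites)], axis=1)
    positions = center + radius * radial

    offsets = np.where(
        np.arange(n_sites) % 2 == 0,
        math.radians(pattern.offset_alpha_deg),
        math.radians(pattern.offset_beta_deg),
    )
    tilt = math.radians(pattern.tilt_deg)
    in_plane = np.cos(offsets)[:, None] * tangent + np.sin(offsets)[:, None] * radial
    dipoles = math.cos(tilt) * in_plane
    dipoles[:, 2] += math.sin(tilt)
    dipoles /= np.linalg.norm(dipoles, axis=1)[:, None]

    return RingGeometry(
        n_sites=n_sites,
        positions=positions,
        dipoles=dipoles,
        ring_center=center,
        site_energy=site_energy,
        radius=radius,
    )


def _chain_centers(n_rings: int, spacing: float) -> tuple[np.ndarray, list]:
    # centered on the middle ring for odd counts, symmetric about 0 otherwise
    idx = np.arange(n_rings) - (n_rings - 1) / 2.0
    centers = np.zeros((n_rings, 3))
    centers[:, 0] = idx * spacing
    return centers, [int(i) for i in range(n_rings)]


def _hex_centers(n_shells: int, spacing: float) -> tuple[np.ndarray, list]:
    """Axial-coordinate triangular lattice out to ``n_shells`` shells."""
    coords = []
    for i in range(-n_shells, n_shells + 1):
        for j in range(-n_shells, n_shells + 1):
            if max(abs(i), abs(j), abs(i + j)) <= n_shells:
                coords.append((i, j))
    # sort by shell then angle for a stable, readable order
    def key(c):
        i, j = c
        x = spacing * (i + 0.5 * j)
        y = spacing * (math.sqrt(3.0) / 2.0) * j
        return (max(abs(i), abs(j), abs(i + j)), math.atan2(y, x) % (2 * math.pi))

    coords.sort(key=key)
    centers = np.zeros((len(coords), 3))
    for n, (i, j) in enumerate(coords):
        centers[n, 0] = spacing * (i + 0.5 * j)
        centers[n, 1] = spacing * (math.sqrt(3.0) / 2.0) * j
    return centers, coords


def build_nanoarray(
    layout: str,
    n_rings: int | None = None,
    n_shells: int | None = None,
    spacing: float = 8.0,
    ring_template: RingGeometry | None = None,
) -> NanoarrayGeometry:
    """Arrange copies of a template ring on a chain or hexagonal lattice.

    ``layout='chain'`` places ``n_rings`` centers on the x axis at the given
    spacing; ``layout='hexagonal'`` builds ``n_shells`` shells around a
    central ring (1 shell -> 7 rings).  The central ring (index of the ring
    at the origin) is recorded for initial-excitation protocols.
    """
    if ring_template is None:
        ring_template = build_b850_ring()
    if spacing <= 2.0 * ring_template.radius:
        raise ValueError(
            f"spacing {spacing} nm would overlap rings of radius "
            f"{ring_template.radius} nm"
        )

    if layout == "chain":
        if n_rings is None or n_rings < 1:
            raise ValueError("chain layout needs n_rings >= 1")
        centers, indices = _chain_centers(n_rings, spacing)
        central = int(np.argmin(np.linalg.norm(centers, axis=1)))
    elif layout == "hexagonal":
        if n_shells is None:
            if n_rings == 1:
                n_shells = 0
            elif n_rings == 7:
                n_shells = 1
            elif n_rings is None:
                raise ValueError("hexagonal layout needs n_shells")
            else:
                raise ValueError("hexagonal layout is specified by n_shells")
        centers, indices = _hex_centers(n_shells, spacing)
        central = int(np.argmin(np.linalg.norm(centers, axis=1)))
    else:
        raise ValueError(f"unknown layout {layout!r}")

    rings = tuple(
        ring_template.translated(c - np.asarray(ring_template.ring_center))
        for c in centers
    )
    return NanoarrayGeometry(
        rings=rings,
        layout=layout,
        spacing=spacing,
        lattice_index=tuple(indices),
        central_ring=central,
    )


def ring_center_distances(geom: NanoarrayGeometry, origin_ring: int) -> np.ndarray:
    """Euclidean distance (nm) from each ring center to ``origin_ring``."""
    if not 0 <= origin_ring < geom.n_rings:
        raise IndexError(f"origin_ring {origin_ring} out of range")
    centers = geom.ring_centers()
    return np.linalg.norm(centers - centers[origin_ring], axis=1)


def hex_neighbor_counts(geom: NanoarrayGeometry, rtol: float = 1e-6) -> np.ndarray:
    """Number of rings at (approximately) one lattice spacing from each ring."""
    centers = geom.ring_centers()
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    near = np.abs(d - geom.spacing) < rtol * geom.spacing
    return near.sum(axis=1)


def save_geometry_tsv(geom: NanoarrayGeometry, path) -> None:
    """One row per pigment: ring, site, x, y, z, dx, dy, dz (nm, unit vec)."""
    with open(path, "w") as fh:
        fh.write(
            f"# layout={geom.layout} spacing={geom.spacing} "
            f"central_ring={geom.central_ring} "
            f"radius={geom.rings[0].radius} "
            f"site_energy={geom.rings[0].site_energy}\n"
        )
        fh.write("ring\tsite\tx\ty\tz\tdx\tdy\tdz\n")
        for r, ring in enumerate(geom.rings):
            for n in range(ring.n_sites):
                x, y, z = ring.positions[n]
                dx, dy, dz = ring.dipoles[n]
                fh.write(
                    f"{r}\t{n}\t{x:.12g}\t{y:.12g}\t{z:.12g}"
                    f"\t{dx:.12g}\t{dy:.12g}\t{dz:.12g}\n"
                )


def load_geometry_tsv(path) -> NanoarrayGeometry:
    """Inverse of :func:`save_geometry_tsv`."""
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            if line.startswith("ring\t"):
                continue
            rows.append(line.split("\t"))
    data = np.array(rows, dtype=float)
    ring_ids = data[:, 0].astype(int)
    rings = []
    radius = float(meta.get("radius", DEFAULT_RING_RADIUS_NM))
    site_energy = float(meta.get("site_energy", 12396.2))
    for r in sorted(set(ring_ids)):
        sel = data[ring_ids == r]
        sel = sel[np.argsort(sel[:, 1])]
        pos = sel[:, 2:5]
        dip = sel[:, 5:8]
        dip = dip / np.linalg.norm(dip, axis=1)[:, None]
        rings.append(
            RingGeometry(
                n_sites=len(sel),
                positions=pos,
                dipoles=dip,
                ring_center=pos.mean(axis=0),
                site_energy=site_energy,
                radius=radius,
            )
        )
    layout = meta.get("layout", "chain")
    spacing = float(meta.get("spacing", 8.0))
    central = int(meta.get("central_ring", 0))
    if layout == "chain":
        indices = tuple(range(len(rings)))
    else:
        # recover axial indices from positions
        indices = []
        for ring in rings:
            x, y = ring.ring_center[0], ring.ring_center[1]
            j = round(y / (spacing * math.sqrt(3.0) / 2.0))
            i = round(x / spacing - 0.5 * j)
            indices.append((int(i), int(j)))
        indices = tuple(indices)
    return NanoarrayGeometry(
        rings=tuple(rings),
        layout=layout,
        spacing=spacing,
        lattice_index=indices,
        central_ring=central,
    )
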