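"""Shrake-Rupley solvent-accessible surface area and the buried-area statistic.

SASA is computed with the classic sphere-point (Shrake-Rupley) method:
each atom is expanded by the probe radius (1.4 Å water by default) and
sampled with a deterministic golden-section spiral lattice; a test point
is accessible when it lies outside every other atom's expanded sphere.
The per-atom area is the accessible point fraction times the expanded
sphere area, so the result is bit-reproducible (no RNG) and converges to
the exact area as the lattice is refined.

The association statistic is the buried area

    dA = < A1 + A2 - A12 >

where A1 and A2 are the SASA of each monomer computed on its in-complex
coordinates with the partner removed, A12 is the SASA of the dimer, and
the brackets denote the time average over the trajectory.  dA is zero
for non-interacting chains and grows with the contact interface.

Heavy atoms only; Bondi-derived radii C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80 Å (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import Frame, Trajectory, chain_view

__all__ = [
    "DEFAULT_RADII",
    "SasaSeries",
    "UnknownElementError",
    "sphere_lattice",
    "shrake_rupley",
    "delta_sasa",
]

#: Bondi-derived van der Waals radii (Å) for peptide heavy atoms.
DEFAULT_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}


class UnknownElementError(KeyError):
    """Atom element has no entry in the radius table."""


@dataclass
class SasaSeries:
    """Per-frame monomer and dimer areas (Å^2) plus the lattice parameters."""

    a1: np.ndarray
    a2: np.ndarray
    a12: np.ndarray
    probe_radius: float
    n_sphere_points: int
    radii_set: Mapping[str, float]

    @property
    def buried(self) -> np.ndarray:
        return self.a1 + self.a2 - self.a12

    @property
    def delta_a(self) -> float:
        return float(self.buried.mean())

    def __len__(self) -> int:
        return len(self.a12)


def sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic golden-section spiral of ``n_points`` on the unit sphere."""
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    theta = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def _atom_radii(frame: Frame, radii: Mapping[str, float]) -> np.ndarray:
    out = np.empty(len(frame.atoms))
    for i, atom in enumerate(frame.atoms):
        try:
            out[i] = radii[atom.element]
        except KeyError:
            raise UnknownElementError(
                f"no radius for element {atom.element!r} "
                f"(atom {atom.atom_name!r}, chain {atom.chain_id} "
                f"residue {atom.residue_index})"
            ) from None
    return out


def shrake_rupley(
    frame: Frame,
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
):
    """Total and per-atom SASA (Å^2) of a heavy-atom frame.

    Raises :class:`UnknownElementError` for elements absent from the
    radius table (including hydrogen: SASA is defined on heavy atoms
    here) and ``ValueError`` for fewer than 32 lattice points.
    """
    if n_points < 32:
        raise ValueError("n_points must be >= 32 for a usable lattice")
    radii = DEFAULT_RADII if radii is None else radii
    coords = frame.coords
    r = _atom_radii(frame, radii) + probe
    n = len(coords)
    per_atom = np.zeros(n)
    if n == 0:
        return 0.0, per_atom

    unit = sphere_lattice(n_points)
    tree = cKDTree(coords)
    r_max = r.max()
    for i in range(n):
        pts = coords[i] + r[i] * unit
        # Any occluder's center lies within r_i + r_max of atom i.
        neighbors = [j for j in tree.query_ball_point(coords[i], r[i] + r_max)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 >= r[j] ** 2
        per_atom[i] = 4.0 * np.pi * r[i] ** 2 * accessible.sum() / n_points
    return float(per_atom.sum()), per_atom


def delta_sasa(
    traj: Trajectory,
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
    stride: int = 1,
):
    """Buried-area statistic for a two-chain heavy-atom trajectory.

    For every frame computes A12 on the full frame and A1/A2 on each
    chain's in-complex coordinates with the partner deleted, then returns
    ``(delta_a, series)`` with ``delta_a`` the time average of
    A1 + A2 - A12.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = traj.frames[::stride]
    chain_a, chain_b = traj.chain_ids
    a1 = np.empty(len(frames))
    a2 = np.empty(len(frames))
    a12 = np.empty(len(frames))
    for f, frame in enumerate(frames):
        a12[f], _ = shrake_rupley(frame, probe, n_points, radii)
        a1[f], _ = shrake_rupley(chain_view(frame, chain_a), probe, n_points, radii)
        a2[f], _ = shrake_rupley(chain_view(frame, chain_b), probe, n_points, radii)
    series = SasaSeries(
        a1=a1, a2=a2, a12=a12, probe_radius=probe,
        n_sphere_points=n_points,
        radii_set=dict(DEFAULT_RADII if radii is None else radii),
    )
    return series.delta_a, series


def two_sphere_sasa(r1: float, r2: float, d: float, probe: float) -> float:
    """Closed-form SASA of two spheres (vdW radii ``r1``, ``r2``) at
    center distance ``d`` -- the analytic oracle for the two-atom case.

    Each expanded sphere (radius ``ri + probe``) loses the spherical cap
    buried inside the other; for concentric containment the smaller
    sphere is fully buried.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4.0 * np.pi * (R1**2 + R2**2)
    if d <= abs(R1 - R2):
        return 4.0 * np.pi * max(R1, R2) ** 2
    # cap height on sphere 1 buried inside sphere 2, and vice versa
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2.0 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2.0 * d)
    area1 = 4.0 * np.pi * R1**2 - 2.0 * np.pi * R1 * h1
    area2 = 4.0 * np.pi * R2**2 - 2.0 * np.pi * R2 * h2
    return area1 + area2
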