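"""Solvent accessible surface area by the Shrake–Rupley method.

Each atom is inflated by the probe radius and sampled with a deterministic
golden-spiral point lattice; a sample point is accessible when it lies
outside every neighbouring inflated sphere.  The per-atom area is the
accessible fraction of the sphere area 4π(r_vdw + probe)².

ΔASA of a residue is its area in the isolated protein (nucleic atoms
removed) minus its area in the full complex; a positive value means the
nucleic acid occludes the residue.  The van der Waals radii default to a
NACCESS/Chothia-style table and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, ComplexStructure

__all__ = [
    "SasaParams",
    "ResidueAsa",
    "DEFAULT_RADII",
    "golden_spiral_points",
    "atom_sasa",
    "sasa_from_coords",
    "residue_delta_asa",
]

# Chothia-style heavy-atom radii (Å); "*" is the fallback for anything else.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "H": 1.00,
    "D": 1.00,
    "*": 1.80,
}


class RadiusError(KeyError):
    """An atom's element has no radius and no fallback is configured."""


@dataclass
class SasaParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.n_sphere_points < 12:
            raise ValueError("n_sphere_points must be >= 12")

    def radius_of(self, element: str) -> float:
        table = self.radii_table
        if element in table:
            return table[element]
        if "*" in table:
            return table["*"]
        raise RadiusError(f"no van der Waals radius for element {element!r} "
                          "and no '*' fallback in the radii table")


@dataclass
class ResidueAsa:
    residue_key: tuple[str, int, str]
    asa_apo: float
    asa_complex: float

    @property
    def delta_asa(self) -> float:
        return self.asa_apo - self.asa_complex


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the sphere (n, 3).

    Fibonacci/golden-angle lattice: z descends linearly, azimuth advances
    by the golden angle.  Fully deterministic — no RNG — so labels built
    on SASA are bit-reproducible.
    """
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa_from_coords(
    coords: np.ndarray,
    radii: np.ndarray,
    params: SasaParams | None = None,
) -> np.ndarray:
    """Per-atom accessible area (Ų) for coordinates (n,3) and vdW radii (n,)."""
    params = params or SasaParams()
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    probe = params.probe_radius
    eff = radii + probe  # inflated radii
    unit = golden_spiral_points(params.n_sphere_points)

    tree = cKDTree(coords)
    r_max = float(eff.max())
    areas = np.empty(n)
    m = params.n_sphere_points
    for i in range(n):
        # candidate occluders: centers within r_i + r_j + 2*probe
        cand = tree.query_ball_point(coords[i], eff[i] + r_max)
        cand = [j for j in cand if j != i]
        sphere_area = 4.0 * np.pi * eff[i] ** 2
        if not cand:
            areas[i] = sphere_area
            continue
        neigh = np.array(cand, dtype=int)
        d = np.linalg.norm(coords[neigh] - coords[i], axis=1)
        close = neigh[d < eff[i] + eff[neigh]]
        if close.size == 0:
            areas[i] = sphere_area
            continue
        pts = coords[i] + eff[i] * unit  # (m, 3)
        diff = pts[:, None, :] - coords[close][None, :, :]
        dist2 = np.einsum("ijk,ijk->ij", diff, diff)
        blocked = (dist2 < (eff[close] ** 2)[None, :]).any(axis=1)
        areas[i] = sphere_area * (m - int(blocked.sum())) / m
    return areas


def atom_sasa(atoms: Sequence[Atom], params: SasaParams | None = None) -> np.ndarray:
    """Per-atom accessible areas (Ų) for a list of atoms."""
    params = params or SasaParams()
    if not atoms:
        raise ValueError("atom_sasa requires at least one atom")
    coords = np.array([a.coord for a in atoms], dtype=float)
    radii = np.array([params.radius_of(a.element) for a in atoms])
    return sasa_from_coords(coords, radii, params)


def residue_delta_asa(
    structure: ComplexStructure,
    params: SasaParams | None = None,
) -> list[ResidueAsa]:
    """Per-residue ΔASA between the isolated protein and the complex.

    The apo state is all protein chains with nucleic atoms removed; the
    complex state adds the RNA/DNA atoms.  Ions and other non-polymer
    chains are excluded from both states.
    """
    params = params or SasaParams()
    if not structure.protein_chains:
        raise ValueError(f"{structure.id}: no protein chain; cannot compute ΔASA")
    if not structure.nucleic_chains:
        raise ValueError(
            f"{structure.id}: no RNA/DNA chain — this structure cannot be "
            "annotated for nucleic-acid binding"
        )

    prot_atoms: list[Atom] = []
    res_slices: list[tuple[tuple[str, int, str], int, int]] = []
    for res in structure.protein_residues():
        start = len(prot_atoms)
        prot_atoms.extend(res.atoms)
        res_slices.append((res.key, start, len(prot_atoms)))
    nuc_atoms = structure.nucleic_atoms()

    all_atoms = prot_atoms + nuc_atoms
    coords_all = np.array([a.coord for a in all_atoms], dtype=float)
    radii_all = np.array([params.radius_of(a.element) for a in all_atoms])
    n_prot = len(prot_atoms)

    asa_complex = sasa_from_coords(coords_all, radii_all, params)[:n_prot]
    asa_apo = sasa_from_coords(coords_all[:n_prot], radii_all[:n_prot], params)

    return [
        ResidueAsa(
            residue_key=key,
            asa_apo=float(asa_apo[a:b].sum()),
            asa_complex=float(asa_complex[a:b].sum()),
        )
        for key, a, b in res_slices
    ]
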