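"""Solvent-accessible surface area and derived per-residue exposure.

The SASA engine is a Shrake–Rupley quadrature over a deterministic
golden-spiral point set on each probe-expanded atom sphere, with a 3-D
cell-list neighbor search.  Relative exposure normalizes residue SASA by
theoretical Gly-X-Gly maxima; the surface partition splits total area into
hydrophobic (C, S) and hydrophilic (N, O) contributions.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .structure_io import ProteinStructure

__all__ = [
    "SasaResult",
    "ResidueSurface",
    "SurfacePartition",
    "golden_spiral_points",
    "sasa_from_arrays",
    "shrake_rupley",
    "residue_exposure",
    "surface_partition",
    "load_max_asa",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_N_POINTS",
    "DEFAULT_EXPOSURE_THRESHOLD",
]

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
DEFAULT_EXPOSURE_THRESHOLD = 0.20
MIN_N_POINTS = 92


def load_max_asa() -> dict[str, float]:
    """Reference maximum ASA (Å²) per residue type, from packaged data."""
    with resources.files("modlys.data").joinpath("max_asa.json").open() as fh:
        return {k: float(v) for k, v in json.load(fh)["values"].items()}


@dataclass
class SasaResult:
    per_atom: np.ndarray            # Å², aligned with structure.atoms
    per_residue: dict               # residue key -> Å²
    total: float
    probe_radius: float
    n_quadrature_points: int


@dataclass
class ResidueSurface:
    residue_key: tuple
    sasa: float
    max_reference: float | None
    relative_sasa: float | None
    exposure_class: str             # "exposed" | "buried" | "unscored"


@dataclass
class SurfacePartition:
    hydrophobic_area: float
    hydrophilic_area: float
    ratio_hydrophilic_to_hydrophobic: float  # inf when hydrophobic area is 0


def golden_spiral_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic, no RNG)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _cell_index(coords: np.ndarray, cell: float) -> dict[tuple, list[int]]:
    grid: dict[tuple, list[int]] = {}
    keys = np.floor(coords / cell).astype(int)
    for i, key in enumerate(map(tuple, keys)):
        grid.setdefault(key, []).append(i)
    return grid


def sasa_from_arrays(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom SASA (Å²) for raw coordinate/radius arrays.

    A quadrature point on atom i's expanded sphere is accessible when it
    lies outside every neighbor's expanded sphere; the atom area is
    4π(r_i+probe)² times the accessible fraction.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    if coords.shape[0] != radii.shape[0]:
        raise ValueError("coords/radii length mismatch")
    if n_points < MIN_N_POINTS:
        raise ValueError(f"n_points must be ≥ {MIN_N_POINTS}")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    n = coords.shape[0]
    if n == 0:
        return np.zeros(0)

    expanded = radii + probe_radius
    unit = golden_spiral_points(n_points)
    cell = 2.0 * float(expanded.max())
    grid = _cell_index(coords, cell)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    cell_keys = np.floor(coords / cell).astype(int)

    areas = np.empty(n)
    for i in range(n):
        ck = cell_keys[i]
        neighbors: list[int] = []
        for off in offsets:
            neighbors.extend(grid.get((ck[0] + off[0], ck[1] + off[1], ck[2] + off[2]), []))
        nb = np.array([j for j in neighbors if j != i], dtype=int)
        if nb.size:
            d = np.linalg.norm(coords[nb] - coords[i], axis=1)
            nb = nb[d < expanded[i] + expanded[nb]]
        if nb.size == 0:
            areas[i] = 4.0 * math.pi * expanded[i] ** 2
            continue
        pts = coords[i] + expanded[i] * unit
        diff = pts[:, None, :] - coords[nb][None, :, :]
        d2 = np.einsum("pnk,pnk->pn", diff, diff)
        accessible = (d2 >= (expanded[nb] ** 2)[None, :]).all(axis=1)
        areas[i] = 4.0 * math.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def shrake_rupley(
    structure: ProteinStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Atomistic SASA of a structure at the given probe radius."""
    if len(structure) == 0:
        raise ValueError("empty structure")
    per_atom = sasa_from_arrays(
        structure.coordinates(), structure.radii(), probe_radius, n_points
    )
    per_residue: dict[tuple, float] = {}
    for atom, area in zip(structure.atoms, per_atom):
        per_residue[atom.residue_key] = per_residue.get(atom.residue_key, 0.0) + area
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        total=float(per_atom.sum()),
        probe_radius=probe_radius,
        n_quadrature_points=n_points,
    )


def residue_exposure(
    sasa: SasaResult,
    reference_table: dict[str, float] | None = None,
    threshold: float = DEFAULT_EXPOSURE_THRESHOLD,
) -> list[ResidueSurface]:
    """Classify residues as exposed (relative SASA ≥ threshold) or buried.

    Residues with no (or zero) reference area are marked "unscored" rather
    than dropped.
    """
    ref = load_max_asa() if reference_table is None else reference_table
    out: list[ResidueSurface] = []
    for key, area in sasa.per_residue.items():
        max_ref = ref.get(key[2])
        if not max_ref:
            out.append(ResidueSurface(key, float(area), None, None, "unscored"))
            continue
        rel = float(area) / float(max_ref)
        out.append(
            ResidueSurface(
                key,
                float(area),
                float(max_ref),
                rel,
                "exposed" if rel >= threshold else "buried",
            )
        )
    return out


def surface_partition(
    sasa: SasaResult,
    structure: ProteinStructure,
    hydrophobic_elements: tuple[str, ...] = ("C", "S"),
    hydrophilic_elements: tuple[str, ...] = ("N", "O"),
    default_side: str = "hydrophilic",
) -> SurfacePartition:
    """Split total SASA into hydrophobic (C,S) and hydrophilic (N,O) area.

    Elements outside both sets are counted on ``default_side`` with a warning.
    """
    hydrophobic = 0.0
    hydrophilic = 0.0
    for atom, area in zip(structure.atoms, sasa.per_atom):
        if atom.element in hydrophobic_elements:
            hydrophobic += area
        elif atom.element in hydrophilic_elements:
            hydrophilic += area
        else:
            warnings.warn(
                f"element {atom.element!r} outside hydrophobicity classes; "
                f"counted as {default_side}",
                stacklevel=2,
            )
            if default_side == "hydrophilic":
                hydrophilic += area
            else:
                hydrophobic += area
    ratio = hydrophilic / hydrophobic if hydrophobic > 0 else math.inf
    return SurfacePartition(float(hydrophobic), float(hydrophilic), float(ratio))
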