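"""Generators for test inputs with known ground truth.

Toy structures place minimal side-chain fragments (key atom plus a couple
of supports) at caller-controlled coordinates so that exposure, bridge and
crosslink geometry is known by construction.  Decay series and standard
curves are forward simulations of the models the analysis modules invert.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .structure_io import AtomRecord, DEFAULT_VDW_RADII, ProteinStructure
from .surface_analysis import golden_spiral_points
from .stability_kinetics import DecaySeries, StandardCurve
from .lysine_triage import ACIDIC_SIDECHAIN_ATOMS, BASIC_SIDECHAIN_ATOMS

__all__ = [
    "Placement",
    "StructureSpec",
    "StructureTruth",
    "DecaySpec",
    "SynthesisError",
    "make_structure",
    "random_structure_spec",
    "simulate_decay",
    "simulate_tnbs",
]

MIN_ATOM_SEPARATION = 0.5  # Å; closer placements are rejected as collisions

# Side-chain fragments as offsets (Å) from the key atom.  The key atom is
# the chemically operative one (NZ for Lys, a carboxylate O for Asp/Glu).
_TEMPLATES: dict[str, tuple[str, list[tuple[str, str, tuple[float, float, float]]]]] = {
    "LYS": ("NZ", [
        ("NZ", "N", (0.0, 0.0, 0.0)),
        ("CB", "C", (0.0, 0.0, 1.8)),
        ("CA", "C", (0.0, 0.0, 3.3)),
    ]),
    "ASP": ("OD1", [
        ("OD1", "O", (0.0, 0.0, 0.0)),
        ("CG", "C", (1.30, 0.0, 0.0)),
        ("OD2", "O", (1.95, 1.06, 0.0)),
        ("CB", "C", (1.95, -1.06, 0.0)),
        ("CA", "C", (3.45, -1.06, 0.0)),
    ]),
    "GLU": ("OE1", [
        ("OE1", "O", (0.0, 0.0, 0.0)),
        ("CD", "C", (1.30, 0.0, 0.0)),
        ("OE2", "O", (1.95, 1.06, 0.0)),
        ("CG", "C", (1.95, -1.06, 0.0)),
        ("CA", "C", (3.45, -1.06, 0.0)),
    ]),
    "ARG": ("NH1", [
        ("NH1", "N", (0.0, 0.0, 0.0)),
        ("CZ", "C", (1.15, 0.7, 0.0)),
        ("NH2", "N", (0.8, 2.0, 0.0)),
        ("NE", "N", (2.5, 0.4, 0.0)),
        ("CA", "C", (4.2, 0.9, 0.0)),
    ]),
    "HIS": ("ND1", [
        ("ND1", "N", (0.0, 0.0, 0.0)),
        ("NE2", "N", (2.15, 0.0, 0.0)),
        ("CE1", "C", (1.1, 0.85, 0.0)),
        ("CA", "C", (1.1, -2.3, 0.0)),
    ]),
    "GLY": ("CA", [
        ("CA", "C", (0.0, 0.0, 0.0)),
    ]),
    "ALA": ("CB", [
        ("CB", "C", (0.0, 0.0, 0.0)),
        ("CA", "C", (1.5, 0.0, 0.0)),
    ]),
}


class SynthesisError(ValueError):
    """Raised on invalid structure specs (collisions, duplicate numbering)."""


@dataclass(frozen=True)
class Placement:
    residue_name: str
    residue_number: int
    chain: str
    key_atom_position: tuple[float, float, float]
    # (count, radius): occluding carbon shell centered on each residue atom
    decoy_shell: tuple[int, float] | None = None


@dataclass
class StructureSpec:
    placements: list[Placement]
    seed: int = 0


@dataclass
class StructureTruth:
    """Ground-truth annotations emitted alongside a synthetic structure."""

    buried_lysines: set = field(default_factory=set)
    bridges: list = field(default_factory=list)   # (basic key, acidic key, dist)
    nz_distances: dict = field(default_factory=dict)  # frozenset(pair) -> Å


@dataclass
class DecaySpec:
    kd_true: float          # min^-1
    A0: float
    times: np.ndarray       # minutes
    noise_sd_fraction: float = 0.0
    seed: int = 0
    temperature: str = ""


def _residue_atoms(placement: Placement) -> list[tuple[str, str, np.ndarray]]:
    if placement.residue_name not in _TEMPLATES:
        raise SynthesisError(f"no template for residue {placement.residue_name!r}")
    _, atoms = _TEMPLATES[placement.residue_name]
    origin = np.asarray(placement.key_atom_position, dtype=float)
    if not np.isfinite(origin).all():
        raise SynthesisError("non-finite key atom position")
    return [(name, elem, origin + np.asarray(off)) for name, elem, off in atoms]


def make_structure(
    spec: StructureSpec,
    bridge_cutoff: float = 4.0,
) -> tuple[ProteinStructure, StructureTruth]:
    """Build a toy structure and its ground-truth annotations.

    Annotations mark lysines buried by decoy shells, basic–acidic contacts
    within ``bridge_cutoff`` (brute-force over all relevant atom pairs),
    and all pairwise NZ–NZ distances.
    """
    seen_numbers: set[tuple[str, int]] = set()
    placed: list[tuple[str, str, str, int, np.ndarray]] = []
    for p in spec.placements:
        if (p.chain, p.residue_number) in seen_numbers:
            raise SynthesisError(
                f"duplicate residue number {p.residue_number} in chain {p.chain}"
            )
        seen_numbers.add((p.chain, p.residue_number))
        for name, elem, xyz in _residue_atoms(p):
            placed.append((name, elem, p.chain, p.residue_number, xyz))

    coords = np.array([t[4] for t in placed])
    for i, j in combinations(range(len(placed)), 2):
        if np.linalg.norm(coords[i] - coords[j]) < MIN_ATOM_SEPARATION:
            raise SynthesisError(
                f"atom collision (<{MIN_ATOM_SEPARATION} Å) between "
                f"{placed[i][:4]} and {placed[j][:4]}"
            )

    # decoy shells: occluding carbons on a sphere around every residue atom;
    # points landing on already-placed atoms are dropped, not errors
    shell_atoms: list[tuple[str, str, str, int, np.ndarray]] = []
    next_number = max((p.residue_number for p in spec.placements), default=0) + 1
    all_xyz = [t[4] for t in placed]
    for p in spec.placements:
        if p.decoy_shell is None:
            continue
        count, radius = p.decoy_shell
        unit = golden_spiral_points(count)
        serial = 1
        for name, _elem, center in _residue_atoms(p):
            for u in unit:
                xyz = center + radius * u
                if any(
                    np.linalg.norm(xyz - q) < MIN_ATOM_SEPARATION + 0.1
                    for q in all_xyz
                ):
                    continue
                shell_atoms.append((f"C{serial}", "C", p.chain, next_number, xyz))
                all_xyz.append(xyz)
                serial += 1
        next_number += 1

    atoms: list[AtomRecord] = []
    for i, (name, elem, chain, number, xyz) in enumerate(placed + shell_atoms, 1):
        atoms.append(
            AtomRecord(
                serial=i,
                name=name,
                element=elem,
                residue_name=_resname_for(name, spec, chain, number),
                residue_number=number,
                chain=chain,
                altloc="",
                occupancy=1.0,
                position=tuple(float(v) for v in xyz),
                vdw_radius=DEFAULT_VDW_RADII[elem],
            )
        )
    structure = ProteinStructure(atoms)

    truth = StructureTruth()
    for p in spec.placements:
        if p.decoy_shell is not None and p.residue_name == "LYS":
            truth.buried_lysines.add((p.chain, p.residue_number, "LYS"))

    charged = {"basic": [], "acidic": []}
    nz_positions: dict[tuple, np.ndarray] = {}
    for p in spec.placements:
        key = (p.chain, p.residue_number, p.residue_name)
        for name, _elem, xyz in _residue_atoms(p):
            if name in BASIC_SIDECHAIN_ATOMS.get(p.residue_name, ()):
                charged["basic"].append((key, xyz))
            if name in ACIDIC_SIDECHAIN_ATOMS.get(p.residue_name, ()):
                charged["acidic"].append((key, xyz))
            if p.residue_name == "LYS" and name == "NZ":
                nz_positions[key] = xyz
    best: dict[tuple, float] = {}
    for bkey, bxyz in charged["basic"]:
        for akey, axyz in charged["acidic"]:
            d = float(np.linalg.norm(bxyz - axyz))
            if d <= bridge_cutoff:
                pair = (bkey, akey)
                if d < best.get(pair, math.inf):
                    best[pair] = d
    truth.bridges = sorted((b, a, d) for (b, a), d in best.items())
    for ka, kb in combinations(sorted(nz_positions), 2):
        truth.nz_distances[frozenset((ka, kb))] = float(
            np.linalg.norm(nz_positions[ka] - nz_positions[kb])
        )
    return structure, truth


def _resname_for(atom_name: str, spec: StructureSpec, chain: str, number: int) -> str:
    for p in spec.placements:
        if p.chain == chain and p.residue_number == number:
            return p.residue_name
    return "SHL"  # decoy shell pseudo-residue


def random_structure_spec(
    n_residues: int,
    seed: int,
    box_size: float = 40.0,
    kinds: tuple[str, ...] = ("LYS", "ASP", "GLU", "GLY"),
    min_separation: float = 6.0,
) -> StructureSpec:
    """Random well-separated placements for property tests."""
    rng = np.random.default_rng(seed)
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < n_residues:
        cand = rng.uniform(0.0, box_size, size=3)
        if all(np.linalg.norm(cand - q) >= min_separation for q in positions):
            positions.append(cand)
        attempts += 1
        if attempts > 100_000:
            raise SynthesisError("could not place residues; enlarge the box")
    placements = [
        Placement(
            residue_name=str(rng.choice(kinds)),
            residue_number=i + 1,
            chain="A",
            key_atom_position=tuple(float(v) for v in positions[i]),
        )
        for i in range(n_residues)
    ]
    return StructureSpec(placements=placements, seed=seed)


def simulate_decay(spec: DecaySpec) -> DecaySeries:
    """Forward-simulate A(t) = A0·exp(−kd·t)·(1+ε), ε ~ N(0, noise fraction)."""
    if spec.kd_true <= 0:
        raise ValueError("kd_true must be positive")
    times = np.asarray(spec.times, dtype=float)
    clean = spec.A0 * np.exp(-spec.kd_true * times)
    if spec.noise_sd_fraction > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = clean * (1.0 + rng.normal(0.0, spec.noise_sd_fraction, times.size))
        clean = np.clip(noisy, 0.0, None)
    return DecaySeries(times=times, activities=clean, temperature=spec.temperature)


def simulate_tnbs(
    n_free_lys_mM: float,
    curve: StandardCurve,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> float:
    """Absorbance of a free-amine assay read off a linear standard curve."""
    if curve.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    value = curve.slope * n_free_lys_mM + curve.intercept
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        value += rng.normal(0.0, noise_sd)
    return float(value)
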