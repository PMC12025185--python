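"""Candidate-site triage for lysine chemical modification.

Combines pKa-based reactivity (10^(pH − pKa), the Henderson–Hasselbalch
fraction-deprotonated ratio), salt-bridge membership, solvent exposure and
crosslinker distance feasibility into a ranked per-lysine profile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import PkaTable, ProteinStructure, residue_sort_key
from .surface_analysis import ResidueSurface

__all__ = [
    "ReactivityScore",
    "SaltBridge",
    "CrosslinkPair",
    "LysineProfile",
    "lys_reactivity",
    "detect_salt_bridges",
    "crosslink_pairs",
    "triage_sites",
    "DEFAULT_REACTIVITY_THRESHOLDS",
    "DEFAULT_SALT_BRIDGE_CUTOFF",
    "DEFAULT_AGENT_SPANS",
    "MONOFUNCTIONAL_AGENTS",
    "AGENT_MODIFICATION_PH",
    "BASIC_SIDECHAIN_ATOMS",
    "ACIDIC_SIDECHAIN_ATOMS",
]

DEFAULT_REACTIVITY_THRESHOLDS = (0.1, 1.0)
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0  # Å, charged N to carboxylate O

# NZ–NZ span windows (Å) for bifunctional amine-reactive crosslinkers.
# Glutaraldehyde in its polymeric forms can bridge wider gaps; the window
# here is the monomer/short-oligomer range and is configurable per call.
DEFAULT_AGENT_SPANS: dict[str, tuple[float, float]] = {
    "GA": (4.0, 11.0),
    "EGNHS": (4.0, 18.0),
}

# Agents that react with a single amino group (or couple at zero length,
# as carbodiimide does): pair-distance analysis does not apply.
MONOFUNCTIONAL_AGENTS = {"CA", "N-HSP", "CDI", "PS"}

# Buffer pH used during each modification protocol.
AGENT_MODIFICATION_PH: dict[str, float] = {
    "EGNHS": 7.4,
    "CA": 9.0,
    "GA": 5.5,
    "CDI": 5.5,
    "GA-CDI": 5.5,
    "N-HSP": 8.0,
    "PS": 8.0,
}

BASIC_SIDECHAIN_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}
ACIDIC_SIDECHAIN_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

_CLASS_RANK = {"high": 3, "semi": 2, "low": 1}


@dataclass(frozen=True)
class ReactivityScore:
    residue_key: tuple | None
    pH: float
    pKa: float
    lys_re: float
    reactivity_class: str  # "low" | "semi" | "high"


@dataclass(frozen=True)
class SaltBridge:
    basic_key: tuple
    acidic_key: tuple
    min_distance: float


@dataclass(frozen=True)
class CrosslinkPair:
    lysine_a: tuple
    lysine_b: tuple
    nz_nz_distance: float
    ca_ca_distance: float
    compatible_agents: tuple[str, ...]


@dataclass
class LysineProfile:
    residue_key: tuple
    relative_sasa: float | None
    exposure_class: str
    pKa: float | None = None
    lys_re: float | None = None
    reactivity_class: str | None = None
    in_salt_bridge: bool = False
    salt_bridge_partners: list = field(default_factory=list)
    candidate: bool = False
    rank_score: float = 0.0
    has_pka: bool = True


def lys_reactivity(
    pKa: float,
    pH: float,
    thresholds: tuple[float, float] = DEFAULT_REACTIVITY_THRESHOLDS,
    residue_key: tuple | None = None,
) -> ReactivityScore:
    """Reactivity index 10^(pH − pKa) with class boundaries inclusive to semi.

    low < thresholds[0] ≤ semi ≤ thresholds[1] < high.
    """
    if not (math.isfinite(pKa) and math.isfinite(pH)):
        raise ValueError("pKa and pH must be finite")
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must be ordered")
    score = 10.0 ** (pH - pKa)
    if score < lo:
        cls = "low"
    elif score <= hi:
        cls = "semi"
    else:
        cls = "high"
    return ReactivityScore(residue_key, pH, pKa, score, cls)


def _charged_atoms(structure: ProteinStructure, table: dict[str, tuple[str, ...]]):
    """(residue key, coordinate) pairs for the named side-chain atoms."""
    keys, coords = [], []
    for res_key, atoms in structure.residues.items():
        wanted = table.get(res_key[2])
        if wanted is None:
            continue
        found = [a for a in atoms if a.name in wanted]
        if not found:
            warnings.warn(
                f"residue {res_key} lacks side-chain atoms {wanted}; skipped",
                stacklevel=3,
            )
            continue
        for a in found:
            keys.append(res_key)
            coords.append(a.position)
    return keys, np.asarray(coords, dtype=float).reshape(-1, 3)


def detect_salt_bridges(
    structure: ProteinStructure,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
) -> list[SaltBridge]:
    """Salt bridges: basic side-chain N within ``cutoff`` of carboxylate O.

    Each (basic, acidic) residue pair is listed once with the minimum
    distance over its relevant atom pairs.
    """
    basic_keys, basic_xyz = _charged_atoms(structure, BASIC_SIDECHAIN_ATOMS)
    acidic_keys, acidic_xyz = _charged_atoms(structure, ACIDIC_SIDECHAIN_ATOMS)
    if not basic_keys or not acidic_keys:
        return []
    tree = cKDTree(acidic_xyz)
    best: dict[tuple[tuple, tuple], float] = {}
    for i, bkey in enumerate(basic_keys):
        for j in tree.query_ball_point(basic_xyz[i], cutoff):
            akey = acidic_keys[j]
            if akey == bkey:
                continue
            d = float(np.linalg.norm(basic_xyz[i] - acidic_xyz[j]))
            pair = (bkey, akey)
            if d <= cutoff and d < best.get(pair, math.inf):
                best[pair] = d
    return sorted(
        (SaltBridge(b, a, d) for (b, a), d in best.items()),
        key=lambda sb: (residue_sort_key(sb.basic_key), residue_sort_key(sb.acidic_key)),
    )


def crosslink_pairs(
    structure: ProteinStructure,
    agents: dict[str, tuple[float, float]] | None = None,
) -> list[CrosslinkPair]:
    """All unordered lysine pairs with NZ–NZ and Cα–Cα distances.

    An agent is compatible when its span window contains the NZ–NZ
    distance; pairs outside every window are still listed.
    """
    spans = DEFAULT_AGENT_SPANS if agents is None else agents
    lysines = []
    for key in structure.residues_named("LYS"):
        nz = structure.atom(key, "NZ")
        ca = structure.atom(key, "CA")
        if nz is None or ca is None:
            warnings.warn(f"lysine {key} lacks NZ or CA; skipped", stacklevel=2)
            continue
        lysines.append((key, np.asarray(nz.position), np.asarray(ca.position)))
    lysines.sort(key=lambda t: residue_sort_key(t[0]))
    out = []
    for (ka, nza, caa), (kb, nzb, cab) in combinations(lysines, 2):
        d_nz = float(np.linalg.norm(nza - nzb))
        d_ca = float(np.linalg.norm(caa - cab))
        compatible = tuple(
            sorted(name for name, (lo, hi) in spans.items() if lo <= d_nz <= hi)
        )
        out.append(CrosslinkPair(ka, kb, d_nz, d_ca, compatible))
    return out


def triage_sites(
    exposures: list[ResidueSurface],
    pka_table: PkaTable | dict,
    bridges: list[SaltBridge],
    pH: float,
    thresholds: tuple[float, float] = DEFAULT_REACTIVITY_THRESHOLDS,
) -> list[LysineProfile]:
    """Rank lysines and mark modification candidates.

    A lysine is a candidate iff it is exposed and not a salt-bridge member.
    Ranking: candidates first, then reactivity class, score, relative SASA,
    with a deterministic (chain, residue number) tie-break.  Lysines absent
    from the pKa table are flagged and ranked by exposure alone.
    """
    entries = pka_table.entries if isinstance(pka_table, PkaTable) else dict(pka_table)
    partner_map: dict[tuple, list] = {}
    for sb in bridges:
        partner_map.setdefault(sb.basic_key, []).append(sb.acidic_key)
        partner_map.setdefault(sb.acidic_key, []).append(sb.basic_key)

    profiles: list[LysineProfile] = []
    for surf in exposures:
        key = surf.residue_key
        if key[2] != "LYS":
            continue
        pka = entries.get(key)
        partners = partner_map.get(key, [])
        profile = LysineProfile(
            residue_key=key,
            relative_sasa=surf.relative_sasa,
            exposure_class=surf.exposure_class,
            in_salt_bridge=bool(partners),
            salt_bridge_partners=sorted(partners, key=residue_sort_key),
        )
        if pka is not None:
            score = lys_reactivity(pka, pH, thresholds, residue_key=key)
            profile.pKa = pka
            profile.lys_re = score.lys_re
            profile.reactivity_class = score.reactivity_class
            profile.rank_score = score.lys_re
        else:
            profile.has_pka = False
            profile.rank_score = surf.relative_sasa or 0.0
        profile.candidate = (
            surf.exposure_class == "exposed" and not profile.in_salt_bridge
        )
        profiles.append(profile)

    def sort_key(p: LysineProfile):
        return (
            0 if p.candidate else 1,
            -_CLASS_RANK.get(p.reactivity_class or "", 0),
            -(p.lys_re if p.lys_re is not None else -math.inf),
            -(p.relative_sasa if p.relative_sasa is not None else -math.inf),
            residue_sort_key(p.residue_key),
        )

    profiles.sort(key=sort_key)
    return profiles
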