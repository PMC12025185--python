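"""Reading and writing of protein structures and tabular assay inputs.

PDB coordinate files are reduced at load time to the heavy-atom model used
by the downstream surface and geometry operators: hydrogens, waters and
(by default) HETATM records are dropped, only the first MODEL is kept, and
alternate locations are resolved to the highest-occupancy conformer.
Van der Waals radii are assigned per element from a configurable table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "PkaTable",
    "AssayTable",
    "PDBParseError",
    "TableError",
    "DEFAULT_VDW_RADII",
    "parse_pdb",
    "write_pdb",
    "read_pka_table",
    "read_assay_table",
    "read_long_assay_table",
    "extract_sequence",
    "residue_sort_key",
]

# Heavy-atom united radii (hydrogens are absorbed); overridable per call.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
FALLBACK_VDW_RADIUS = 1.70

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"}
_TWO_LETTER_ELEMENTS = {"SE", "CL", "BR", "FE", "ZN", "MG", "MN", "CU"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class PDBParseError(ValueError):
    """Raised on malformed or empty PDB input."""


class TableError(ValueError):
    """Raised on malformed tabular (TSV) input."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: object  # int, or "52A"-style string when an icode is present
    chain: str
    altloc: str
    occupancy: float
    position: tuple[float, float, float]
    vdw_radius: float

    @property
    def residue_key(self) -> tuple:
        return (self.chain, self.residue_number, self.residue_name)


def residue_sort_key(key: tuple) -> tuple:
    """Deterministic ordering for (chain, number, name) residue keys.

    Numbers may carry an insertion-code suffix ("52A"); those sort after
    the bare number.
    """
    chain, number, name = key
    if isinstance(number, int):
        return (chain, number, "", name)
    digits = "".join(c for c in str(number) if c.isdigit() or c == "-")
    icode = "".join(c for c in str(number) if c.isalpha())
    return (chain, int(digits) if digits else 0, icode, name)


class ProteinStructure:
    """Ordered heavy-atom model with a residue index.

    ``residues`` maps (chain, residue_number, residue_name) to the list of
    member :class:`AtomRecord` objects, preserving file order.
    """

    def __init__(self, atoms: list[AtomRecord]):
        self.atoms = list(atoms)
        self.residues: dict[tuple, list[AtomRecord]] = {}
        seen: set[tuple] = set()
        for atom in self.atoms:
            ident = (atom.chain, atom.residue_number, atom.name)
            if ident in seen:
                raise PDBParseError(
                    f"duplicate atom {atom.name} in residue "
                    f"{atom.chain}/{atom.residue_number}"
                )
            seen.add(ident)
            self.residues.setdefault(atom.residue_key, []).append(atom)

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def chains(self) -> list[str]:
        out: list[str] = []
        for key in self.residues:
            if key[0] not in out:
                out.append(key[0])
        return out

    def atom(self, residue_key: tuple, name: str) -> AtomRecord | None:
        for a in self.residues.get(residue_key, []):
            if a.name == name:
                return a
        return None

    def residues_named(self, residue_name: str) -> list[tuple]:
        return [k for k in self.residues if k[2] == residue_name]


@dataclass
class PkaTable:
    """Per-residue pKa values keyed by (chain, residue_number, residue_name)."""

    entries: dict[tuple, float] = field(default_factory=dict)

    def get(self, key: tuple) -> float | None:
        return self.entries.get(key)

    def lysines(self) -> dict[tuple, float]:
        return {k: v for k, v in self.entries.items() if k[2] == "LYS"}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AssayTable:
    """Condition labels with matching non-negative activities."""

    condition_labels: list
    activities: list[float]
    metadata: str = ""

    def __post_init__(self):
        if len(self.condition_labels) != len(self.activities):
            raise TableError("condition/activity length mismatch")
        if any(a < 0 for a in self.activities):
            raise TableError("activities must be non-negative")


def _element_from_name(name: str, raw_line_name: str) -> str:
    s = name.strip().lstrip("0123456789")
    if not s:
        raise ValueError("empty atom name")
    two = s[:2].upper()
    if two in _TWO_LETTER_ELEMENTS:
        return two
    # names filling all four columns starting left of the element column
    # (e.g. "HG21") are hydrogens in standard amino acids
    if len(raw_line_name) == 4 and raw_line_name[0] not in " 0123456789":
        if s[0].upper() == "H":
            return "H"
    return s[0].upper()


def _parse_residue_number(field_num: str, icode: str):
    num = int(field_num.strip())
    icode = icode.strip()
    return f"{num}{icode}" if icode else num


def parse_pdb(
    text: str,
    *,
    keep_hetatm: bool = False,
    keep_hydrogens: bool = False,
    vdw_radii: dict[str, float] | None = None,
) -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Only the first MODEL is read.  Waters are always dropped; HETATM and
    hydrogens are dropped unless explicitly kept.  For alternate locations
    the highest-occupancy conformer wins (ties resolve to altloc 'A').
    """
    radii = dict(DEFAULT_VDW_RADII)
    if vdw_radii:
        radii.update(vdw_radii)

    candidates: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    models_seen = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            models_seen += 1
            if models_seen > 1:
                break
            continue
        if rec == "ENDMDL":
            break
        if rec not in ("ATOM", "HETATM"):
            continue
        if rec == "HETATM" and not keep_hetatm:
            continue
        if len(line) < 54:
            raise PDBParseError(f"truncated coordinate record at line {lineno}")
        raw_name = line[12:16]
        name = raw_name.strip()
        altloc = line[16].strip()
        residue_name = line[17:20].strip()
        chain = line[21].strip() or " "
        try:
            residue_number = _parse_residue_number(line[22:26], line[26:27])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(
                f"malformed coordinate field at line {lineno}: {line!r}"
            ) from exc
        try:
            occupancy = float(line[54:60])
        except (ValueError, IndexError):
            occupancy = 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            try:
                element = _element_from_name(name, raw_name)
            except ValueError as exc:
                raise PDBParseError(f"cannot infer element at line {lineno}") from exc

        if residue_name in _WATER_NAMES:
            continue
        if element in ("H", "D") and not keep_hydrogens:
            continue
        if not all(math.isfinite(v) for v in (x, y, z)):
            raise PDBParseError(f"non-finite coordinate at line {lineno}")

        vdw = radii.get(element)
        if vdw is None:
            warnings.warn(
                f"no van der Waals radius for element {element!r}; "
                f"using {FALLBACK_VDW_RADIUS} Å",
                stacklevel=2,
            )
            vdw = FALLBACK_VDW_RADIUS

        atom = AtomRecord(
            serial=int(line[6:11].strip() or 0),
            name=name,
            element=element,
            residue_name=residue_name,
            residue_number=residue_number,
            chain=chain,
            altloc=altloc,
            occupancy=occupancy,
            position=(x, y, z),
            vdw_radius=vdw,
        )
        ident = (chain, residue_number, residue_name, name)
        if ident not in candidates:
            order.append(ident)
            candidates[ident] = atom
        else:
            incumbent = candidates[ident]
            if (atom.occupancy, _altloc_rank(atom.altloc)) > (
                incumbent.occupancy,
                _altloc_rank(incumbent.altloc),
            ):
                candidates[ident] = atom

    if not candidates:
        raise PDBParseError("no ATOM records found")
    return ProteinStructure([candidates[i] for i in order])


def _altloc_rank(altloc: str) -> int:
    # higher is preferred; 'A' beats any other label on an occupancy tie
    if altloc == "A":
        return 2
    if altloc == "":
        return 1
    return -ord(altloc)


def _split_number(residue_number) -> tuple[int, str]:
    if isinstance(residue_number, int):
        return residue_number, ""
    digits = "".join(c for c in str(residue_number) if c.isdigit() or c == "-")
    icode = "".join(c for c in str(residue_number) if c.isalpha())
    return int(digits), icode


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize to canonical single-model PDB text (ends with END)."""
    lines = []
    for i, atom in enumerate(structure.atoms, start=1):
        num, icode = _split_number(atom.residue_number)
        name = atom.name
        if len(name) < 4:
            name = f" {name:<3}" if len(atom.element) == 1 else f"{name:<4}"
        x, y, z = atom.position
        lines.append(
            f"ATOM  {i:>5} {name:<4}{atom.altloc or ' ':1}{atom.residue_name:>3} "
            f"{atom.chain:1}{num:>4}{icode or ' ':1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _data_rows(text: str, n_min_cols: int, what: str):
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        cols = [c.strip() for c in line.rstrip("\n").split("\t")]
        if len(cols) < n_min_cols:
            raise TableError(f"{what}: expected ≥{n_min_cols} columns at line {lineno}")
        rows.append((lineno, cols))
    return rows


def read_pka_table(text: str) -> PkaTable:
    """Read a tab-separated pKa table: chain, residue number, residue name, pKa.

    A header row is required; '#' comment lines are ignored.  Rows for
    non-lysine residues are retained (the triage step filters).
    """
    rows = _data_rows(text, 4, "pKa table")
    if not rows:
        raise TableError("pKa table: missing header row")
    entries: dict[tuple, float] = {}
    for lineno, cols in rows[1:]:
        chain, num_s, resname, pka_s = cols[0], cols[1], cols[2], cols[3]
        try:
            icode = "".join(c for c in num_s if c.isalpha())
            digits = "".join(c for c in num_s if c.isdigit() or c == "-")
            number = f"{int(digits)}{icode}" if icode else int(digits)
            pka = float(pka_s)
        except ValueError as exc:
            raise TableError(f"pKa table: unparsable row at line {lineno}") from exc
        if not (0.0 < pka < 20.0):
            raise TableError(f"pKa table: pKa {pka} out of range at line {lineno}")
        key = (chain, number, resname.upper())
        if key in entries:
            raise TableError(f"pKa table: duplicate residue key {key} at line {lineno}")
        entries[key] = pka
    return PkaTable(entries)


def _maybe_float(label: str):
    try:
        return float(label)
    except ValueError:
        return label


def read_assay_table(text: str, metadata: str = "") -> AssayTable:
    """Read a tab-separated assay table: condition, activity[, replicate]."""
    rows = _data_rows(text, 2, "assay table")
    if not rows:
        raise TableError("assay table: missing header row")
    labels: list = []
    activities: list[float] = []
    for lineno, cols in rows[1:]:
        try:
            activity = float(cols[1])
        except ValueError as exc:
            raise TableError(f"assay table: bad activity at line {lineno}") from exc
        labels.append(_maybe_float(cols[0]))
        activities.append(activity)
    return AssayTable(labels, activities, metadata=metadata)


def read_long_assay_table(text: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a long-format kinetics table: variant, time_min, activity.

    Returns {variant: (times, activities)} preserving row order per variant.
    """
    rows = _data_rows(text, 3, "long assay table")
    if not rows:
        raise TableError("long assay table: missing header row")
    out: dict[str, tuple[list[float], list[float]]] = {}
    for lineno, cols in rows[1:]:
        try:
            t = float(cols[1])
            a = float(cols[2])
        except ValueError as exc:
            raise TableError(f"long assay table: bad number at line {lineno}") from exc
        out.setdefault(cols[0], ([], []))[0].append(t)
        out[cols[0]][1].append(a)
    return {
        v: (np.asarray(ts, dtype=float), np.asarray(acts, dtype=float))
        for v, (ts, acts) in out.items()
    }


def extract_sequence(structure: ProteinStructure, chain: str) -> str:
    """One-letter sequence for a chain, in residue order; unknown names → 'X'."""
    if chain not in structure.chains():
        raise KeyError(f"unknown chain {chain!r}")
    return "".join(
        THREE_TO_ONE.get(key[2], "X")
        for key in structure.residues
        if key[0] == chain
    )
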