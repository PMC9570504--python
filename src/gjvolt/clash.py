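"""Van der Waals steric-overlap screening on PDB coordinates.

Detects clashes and contacts between two residue selections — typically
the pore-lining amino-terminal (NT) helix (residues ~4-17) and the second
transmembrane helix TM2 (residues ~85-95) of a connexin subunit — after a
residue has been exchanged on a template structure. A pair of heavy atoms
clashes when their distance falls below the sum of their van der Waals
radii minus a tolerance (0.4 A by default); pairs within the radii sum
plus 0.5 A are contacts. Atoms separated by one or two covalent bonds are
never counted. Neighbor search uses a uniform 3-D grid so cost scales with
the number of contacts, not with all atom pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ClashReport",
    "VDW_RADII",
    "read_structure",
    "parse_selection",
    "clash_scan",
    "interface_profile",
]

#: van der Waals radii (A) used for overlap screening
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70

#: covalent radii (A) for bond detection (bond if d <= rc1 + rc2 + 0.4)
_COVALENT_RADII = {"C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07, "H": 0.31}
_COVALENT_SLACK = 0.4

DEFAULT_TOLERANCE = 0.4  # A subtracted from the radii sum for a clash call
CONTACT_MARGIN = 0.5  # A added to the radii sum for a contact call
SCAN_CUTOFF = 5.0  # A, pairs farther apart are not evaluated

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    resnum: int  # author numbering, as in the PDB file
    resname: str
    atom: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def vdw(self) -> float:
        return VDW_RADII.get(self.element, DEFAULT_VDW)


def _prevalidate_pdb(path) -> int:
    """Check fixed-column ATOM/HETATM records before handing off to gemmi,
    so truncated or corrupt lines are reported with their line number.
    Returns the number of coordinate records seen."""
    n = 0
    with open(path, encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            n += 1
            stripped = line.rstrip("\n")
            if len(stripped) < 54:
                raise ValueError(
                    f"line {lineno}: truncated {rec} record "
                    f"({len(stripped)} < 54 columns)"
                )
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ValueError(
                        f"line {lineno}: unparsable {what} coordinate "
                        f"{line[lo:hi]!r}"
                    ) from None
    return n


def read_structure(path) -> list[AtomRecord]:
    """Read ATOM/HETATM records from a PDB-format file.

    Waters are skipped; for alternate locations only the highest-occupancy
    conformer of each atom is kept; unknown elements get the default radius
    with a warning. A file without coordinate records is an error.
    """
    if _prevalidate_pdb(path) == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    st = gemmi.read_pdb(str(path))
    best: dict[tuple, tuple[float, AtomRecord]] = {}
    order: list[tuple] = []
    for model in st:
        for chain in model:
            for res in chain:
                if res.name.strip().upper() in _WATER_NAMES:
                    continue
                for atom in res:
                    elem = atom.element.name.upper()
                    if elem not in VDW_RADII and elem != "X":
                        warnings.warn(
                            f"unknown element {elem!r} for atom "
                            f"{chain.name}/{res.seqid.num}/{atom.name}; "
                            f"using default radius {DEFAULT_VDW} A",
                            RuntimeWarning,
                            stacklevel=2,
                        )
                    rec = AtomRecord(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        atom=atom.name,
                        element=elem if elem != "X" else "",
                        xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                    key = (chain.name, res.seqid.num, res.name, atom.name)
                    occ = float(atom.occ)
                    if key not in best:
                        best[key] = (occ, rec)
                        order.append(key)
                    elif occ > best[key][0]:
                        best[key] = (occ, rec)
        break  # first model only
    atoms = [best[k][1] for k in order]
    if not atoms:
        raise ValueError(f"{path}: no usable (non-water) atoms")
    return atoms


def parse_selection(expr: str) -> set[tuple[str, int]]:
    """Parse 'CHAIN:RESNUM[-RESNUM]' (comma-separated) into a residue set."""
    out: set[tuple[str, int]] = set()
    for token in expr.split(","):
        token = token.strip()
        if not token:
            continue
        chain, _, rng = token.partition(":")
        if not chain or not rng:
            raise ValueError(f"bad selection token {token!r}; expected CHAIN:NUM[-NUM]")
        lo, _, hi = rng.partition("-")
        lo_i = int(lo)
        hi_i = int(hi) if hi else lo_i
        for r in range(lo_i, hi_i + 1):
            out.add((chain, r))
    return out


def _as_residue_set(sel) -> set[tuple[str, int]]:
    if isinstance(sel, str):
        return parse_selection(sel)
    return {(str(c), int(r)) for c, r in sel}


@dataclass(frozen=True)
class ClashReport:
    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float
    radii_sum: float
    overlap: float  # radii_sum - distance - tolerance; clash iff > 0
    classification: str  # 'clash' | 'contact' | 'none'


def _grid_index(coords: np.ndarray, cell: float) -> dict[tuple, list[int]]:
    cells: dict[tuple, list[int]] = {}
    keys = np.floor(coords / cell).astype(int)
    for i, key in enumerate(map(tuple, keys)):
        cells.setdefault(key, []).append(i)
    return cells


def _neighbor_pairs(
    coords_a: np.ndarray, idx_a: np.ndarray, coords_b: np.ndarray,
    idx_b: np.ndarray, cutoff: float
):
    """Yield (i, j, distance) over pairs within ``cutoff`` using a cell grid."""
    grid = _grid_index(coords_b, cutoff)
    offsets = list(product((-1, 0, 1), repeat=3))
    keys_a = np.floor(coords_a / cutoff).astype(int)
    for ia, key in enumerate(map(tuple, keys_a)):
        for off in offsets:
            cell = (key[0] + off[0], key[1] + off[1], key[2] + off[2])
            for jb in grid.get(cell, ()):
                d = math.dist(coords_a[ia], coords_b[jb])
                if d <= cutoff:
                    yield int(idx_a[ia]), int(idx_b[jb]), d


def _bond_exclusions(atoms: list[AtomRecord]) -> list[set[int]]:
    """For each atom, the set of atoms within <= 2 covalent bonds."""
    coords = np.array([a.xyz for a in atoms])
    idx = np.arange(len(atoms))
    max_bond = 2 * max(_COVALENT_RADII.values()) + _COVALENT_SLACK
    bonded: list[set[int]] = [set() for _ in atoms]
    for i, j, d in _neighbor_pairs(coords, idx, coords, idx, max_bond):
        if j <= i:
            continue
        rc = _COVALENT_RADII.get(atoms[i].element, 0.77) + _COVALENT_RADII.get(
            atoms[j].element, 0.77
        )
        if d <= rc + _COVALENT_SLACK:
            bonded[i].add(j)
            bonded[j].add(i)
    excluded: list[set[int]] = []
    for i in range(len(atoms)):
        ex = set(bonded[i])
        for j in bonded[i]:
            ex |= bonded[j]
        ex.discard(i)
        excluded.append(ex)
    return excluded


def _classify(d: float, radii_sum: float, tolerance: float) -> str:
    if d < radii_sum - tolerance:
        return "clash"
    if d < radii_sum + CONTACT_MARGIN:
        return "contact"
    return "none"


def clash_scan(
    atoms: list[AtomRecord],
    selection_a,
    selection_b,
    tolerance: float = DEFAULT_TOLERANCE,
    cutoff: float = SCAN_CUTOFF,
) -> list[ClashReport]:
    """Evaluate all inter-selection heavy-atom pairs within ``cutoff`` A.

    Selections are residue sets (``{(chain, resnum), ...}`` or a
    'CHAIN:NUM-NUM' string). Pairs separated by at most two covalent bonds
    are excluded; pair order is canonicalized so the report is symmetric in
    swapping the selections. Results are sorted by decreasing overlap.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    sel_a = _as_residue_set(selection_a)
    sel_b = _as_residue_set(selection_b)
    if not sel_a or not sel_b:
        raise ValueError("both selections must be non-empty")
    heavy = [i for i, a in enumerate(atoms) if a.element != "H"]
    ia = np.array(
        [i for i in heavy if (atoms[i].chain, atoms[i].resnum) in sel_a], dtype=int
    )
    ib = np.array(
        [i for i in heavy if (atoms[i].chain, atoms[i].resnum) in sel_b], dtype=int
    )
    if len(ia) == 0 or len(ib) == 0:
        return []
    coords = np.array([a.xyz for a in atoms])
    excluded = _bond_exclusions(atoms)
    seen: set[tuple[int, int]] = set()
    reports: list[ClashReport] = []
    for i, j, d in _neighbor_pairs(coords[ia], ia, coords[ib], ib, cutoff):
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        if j in excluded[i]:
            continue
        a1, a2 = atoms[key[0]], atoms[key[1]]
        radii_sum = a1.vdw + a2.vdw
        reports.append(
            ClashReport(
                atom_a=a1,
                atom_b=a2,
                distance=d,
                radii_sum=radii_sum,
                overlap=radii_sum - d - tolerance,
                classification=_classify(d, radii_sum, tolerance),
            )
        )
    reports.sort(key=lambda r: (-r.overlap, r.atom_a.chain, r.atom_a.resnum))
    return reports


def interface_profile(
    atoms: list[AtomRecord],
    nt_range: tuple[int, int] = (4, 17),
    tm2_range: tuple[int, int] = (85, 95),
    include_inter: bool = True,
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """NT x TM2 residue contact table, per subunit.

    For every subunit (chain) and every (NT position, TM2 position) pair,
    reports the minimal heavy-atom distance and its classification, pairing
    each chain's NT with its own TM2 and, when ``include_inter`` is set,
    with the TM2 of the adjacent chain (cyclic order, as in a hexamer).
    Residues absent from the model are reported as missing, not fatal.
    """
    chains = sorted({a.chain for a in atoms})
    by_res: dict[tuple[str, int], list[AtomRecord]] = {}
    for a in atoms:
        if a.element != "H":
            by_res.setdefault((a.chain, a.resnum), []).append(a)

    pairings: list[tuple[str, str]] = [(c, c) for c in chains]
    if include_inter and len(chains) > 1:
        for i, c in enumerate(chains):
            pairings.append((c, chains[(i + 1) % len(chains)]))

    rows = []
    for nt_chain, tm2_chain in pairings:
        for nt_res in range(nt_range[0], nt_range[1] + 1):
            for tm2_res in range(tm2_range[0], tm2_range[1] + 1):
                a_atoms = by_res.get((nt_chain, nt_res))
                b_atoms = by_res.get((tm2_chain, tm2_res))
                row = {
                    "nt_chain": nt_chain,
                    "nt_res": nt_res,
                    "tm2_chain": tm2_chain,
                    "tm2_res": tm2_res,
                }
                if not a_atoms or not b_atoms:
                    row.update(
                        min_distance=np.nan, classification="missing",
                        atom_a="", atom_b="",
                    )
                    rows.append(row)
                    continue
                best = None
                for aa in a_atoms:
                    for bb in b_atoms:
                        if (aa.chain, aa.resnum, aa.atom) == (
                            bb.chain, bb.resnum, bb.atom,
                        ):
                            continue
                        d = math.dist(aa.xyz, bb.xyz)
                        if best is None or d < best[0]:
                            best = (d, aa, bb)
                d, aa, bb = best
                row.update(
                    min_distance=d,
                    classification=_classify(d, aa.vdw + bb.vdw, tolerance),
                    atom_a=aa.atom,
                    atom_b=bb.atom,
                )
                rows.append(row)
    return pd.DataFrame(rows)
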