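"""Antigen structure handling: parsing, solvent accessibility, surface
residues, patch enumeration and the geometric patch attributes.

A *surface residue* is one whose side-chain relative solvent accessibility
exceeds 6% at probe radius 1.2 Angstrom; a *surface patch* is a central
surface residue together with its 19 nearest surface neighbours in space.
These definitions are the substrate for every downstream attribute.
"""

from __future__ import annotations

import io
import logging
import math
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.StructureBuilder import StructureBuilder

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
WATER_NAMES = {"HOH", "WAT", "DOD"}

DEFAULT_PROBE_RADIUS = 1.2   # Angstrom
DEFAULT_SURFACE_THRESHOLD = 0.06
DEFAULT_PATCH_SIZE = 20
DEFAULT_CONTACT_CUTOFF = 10.0  # Angstrom, residue representative points
SASA_N_POINTS = 960


class PDBFormatError(ValueError):
    """Raised when PDB-format input cannot be parsed."""


class ChainNotFoundError(KeyError):
    """Raised when a requested chain is absent from the structure."""


class EmptyStructureError(ValueError):
    """Raised when chain filtering leaves no residues."""


class ResidueId(NamedTuple):
    chain: str
    resnum: int
    icode: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chain}{self.resnum}{self.icode}"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class Residue:
    id: ResidueId
    restype: str
    atoms: list[Atom]

    def atom_coords(self, names: Iterable[str] | None = None) -> np.ndarray:
        if names is None:
            sel = self.atoms
        else:
            names = set(names)
            sel = [a for a in self.atoms if a.name in names]
        return np.array([a.xyz for a in sel], dtype=float)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def sidechain_atoms(self) -> list[Atom]:
        """Side-chain atoms; glycine's CA stands in for its absent side chain."""
        sc = [a for a in self.atoms if a.name not in BACKBONE_ATOMS]
        if not sc:
            ca = self.get_atom("CA")
            if ca is not None:
                return [ca]
            return list(self.atoms)
        return sc


@dataclass
class AntigenStructure:
    """Parsed antigen restricted to the chains selected for prediction."""

    residues: list[Residue]
    chains: list[str] = field(default_factory=list)
    selected_chains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chains:
            seen: list[str] = []
            for r in self.residues:
                if r.id.chain not in seen:
                    seen.append(r.id.chain)
            self.chains = seen
        if not self.selected_chains:
            self.selected_chains = list(self.chains)
        self._index = {r.id: r for r in self.residues}
        if len(self._index) != len(self.residues):
            raise PDBFormatError("duplicate residue identifiers within a chain")

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in self._index

    def residue(self, rid: ResidueId) -> Residue:
        return self._index[rid]

    def residue_ids(self) -> list[ResidueId]:
        return [r.id for r in self.residues]

    def sequence(self, chain: str | None = None) -> str:
        from .constants import THREE_TO_ONE

        return "".join(
            THREE_TO_ONE.get(r.restype, "X")
            for r in self.residues
            if chain is None or r.id.chain == chain
        )


def parse_structure(pdb_source, chain_selection: str | Iterable[str] = "all",
                    keep_hetero: bool = False) -> AntigenStructure:
    """Parse PDB-format text (or a path/handle) into an ``AntigenStructure``.

    Only the first model is read. Hydrogens are dropped; for disordered
    atoms the highest-occupancy location is kept; waters (and, by default,
    non-water HETATM ligands) are ignored. Chains outside ``chain_selection``
    are removed entirely so they play no part in accessibility or features.
    """
    if hasattr(pdb_source, "read"):
        handle = pdb_source
    elif isinstance(pdb_source, str) and "\n" in pdb_source:
        handle = io.StringIO(pdb_source)
    else:
        handle = open(pdb_source)

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure("antigen", handle)
    except Exception as exc:  # Bio.PDB raises assorted exceptions on bad input
        raise PDBFormatError(f"cannot parse PDB input: {exc}") from exc
    finally:
        if handle is not pdb_source:
            handle.close()

    try:
        model = next(bio_structure.get_models())
    except StopIteration:
        raise PDBFormatError("no model found in PDB input")

    available = [ch.id for ch in model]
    if chain_selection == "all":
        wanted = available
    else:
        if isinstance(chain_selection, str):
            wanted = list(chain_selection)
        else:
            wanted = list(chain_selection)
        missing = [c for c in wanted if c not in available]
        if missing:
            raise ChainNotFoundError(
                f"chain(s) {missing} not in structure (available: {available})")

    residues: list[Residue] = []
    for ch in model:
        if ch.id not in wanted:
            continue
        for res in ch:
            hetflag, resnum, icode = res.id
            if res.resname.strip() in WATER_NAMES:
                continue
            if hetflag.strip() and not keep_hetero:
                continue
            atoms = []
            for atom in res.get_atoms():  # selected altloc child for disordered
                if atom.element == "H" or atom.element == "D":
                    continue
                coord = atom.get_coord()
                if not np.all(np.isfinite(coord)):
                    raise PDBFormatError(
                        f"non-finite coordinates for atom {atom.get_name()}")
                atoms.append(Atom(atom.get_name(),
                                  atom.element if atom.element else "C",
                                  tuple(float(x) for x in coord)))
            if atoms:
                residues.append(Residue(
                    ResidueId(ch.id, int(resnum), icode.strip()),
                    res.resname.strip(), atoms))

    if not residues:
        raise EmptyStructureError("no residues left after chain/record filtering")
    return AntigenStructure(residues, chains=wanted, selected_chains=wanted)


# ---------------------------------------------------------------------------
# solvent accessibility

@dataclass(frozen=True)
class AccessibilityRecord:
    residue_id: ResidueId
    restype: str
    sasa_total: float       # A^2
    sasa_sidechain: float   # A^2
    rel_acc: float          # side-chain SASA / extended-tripeptide reference
    probe_radius: float


def _to_biopdb(structure: AntigenStructure):
    builder = StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    builder.init_seg("    ")
    current_chain = None
    for res in structure.residues:
        if res.id.chain != current_chain:
            builder.init_chain(res.id.chain)
            current_chain = res.id.chain
        builder.init_residue(res.restype, " ", res.id.resnum, res.id.icode or " ")
        for i, atom in enumerate(res.atoms):
            builder.init_atom(atom.name, np.asarray(atom.coord, dtype=float),
                              0.0, 1.0, " ", atom.name, i, atom.element)
    return builder.get_structure()


@lru_cache(maxsize=8)
def reference_sidechain_areas(probe_radius: float = DEFAULT_PROBE_RADIUS,
                              n_points: int = SASA_N_POINTS) -> dict[str, float]:
    """Side-chain SASA of each residue type X in an extended Gly-X-Gly
    tripeptide, computed with the same sphere-sampling algorithm used for
    antigens so the 6% surface rule is self-consistent.

    The tripeptides carry backbone + C-beta atoms (glycine: backbone only,
    its CA standing in for the side chain), matching the atom complement
    the synthetic structures use.
    """
    from .constants import STANDARD_RESIDUES
    from .geometry import PHI_PSI, build_backbone, format_pdb

    phi, psi = PHI_PSI["strand"]
    backbone = build_backbone([(phi, psi)] * 3)
    out: dict[str, float] = {}
    for rtype in STANDARD_RESIDUES:
        text = format_pdb(backbone, ["A"] * 3, [1, 2, 3], ["GLY", rtype, "GLY"])
        tri = parse_structure(text)
        recs = _raw_sasa(tri, probe_radius, n_points)
        out[rtype] = recs[ResidueId("A", 2, "")][1]
    return out


def _raw_sasa(structure: AntigenStructure, probe_radius: float,
              n_points: int) -> dict[ResidueId, tuple[float, float]]:
    """Per-residue (total, side-chain) SASA via Shrake-Rupley sampling."""
    entity = _to_biopdb(structure)
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(entity, level="A")
    out: dict[ResidueId, tuple[float, float]] = {}
    bio_residues = list(entity.get_residues())
    for res, bio_res in zip(structure.residues, bio_residues):
        total = 0.0
        sidechain = 0.0
        per_atom = {a.get_name(): float(a.sasa) for a in bio_res.get_atoms()}
        sc_names = {a.name for a in res.sidechain_atoms()}
        for name, area in per_atom.items():
            total += area
            if name in sc_names:
                sidechain += area
        out[res.id] = (total, sidechain)
    return out


def compute_sasa(structure: AntigenStructure,
                 probe_radius: float = DEFAULT_PROBE_RADIUS,
                 n_points: int = SASA_N_POINTS) -> dict[ResidueId, AccessibilityRecord]:
    """Per-residue solvent accessible surface areas and relative side-chain
    accessibility (side-chain SASA over the extended Gly-X-Gly reference)."""
    if len(structure) == 0:
        raise EmptyStructureError("cannot compute SASA of an empty structure")
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    refs = reference_sidechain_areas(probe_radius, n_points)
    default_ref = float(np.median(list(refs.values())))
    raw = _raw_sasa(structure, probe_radius, n_points)
    records: dict[ResidueId, AccessibilityRecord] = {}
    for res in structure.residues:
        total, sidechain = raw[res.id]
        ref = refs.get(res.restype)
        if ref is None:
            logger.warning("no reference side-chain area for %s; using median "
                           "of standard residues", res.restype)
            ref = default_ref
        records[res.id] = AccessibilityRecord(
            res.id, res.restype, total, sidechain,
            sidechain / ref if ref > 0 else 0.0, probe_radius)
    return records


def identify_surface_residues(records: dict[ResidueId, AccessibilityRecord],
                              threshold: float = DEFAULT_SURFACE_THRESHOLD,
                              ) -> list[ResidueId]:
    """Residues whose relative side-chain accessibility is strictly greater
    than the threshold (default 6%), in structure order."""
    return [rid for rid, rec in records.items() if rec.rel_acc > threshold]


# ---------------------------------------------------------------------------
# patches and geometric attributes

@dataclass(frozen=True)
class SurfacePatch:
    center: ResidueId
    members: tuple[ResidueId, ...]
    patch_size: int = DEFAULT_PATCH_SIZE

    def __post_init__(self) -> None:
        if self.center not in self.members:
            raise ValueError("patch center must be a member")

    def __len__(self) -> int:
        return len(self.members)


def representative_point(residue: Residue, metric: str = "sidechain_center",
                         ) -> np.ndarray:
    """Residue representative point for inter-residue distances.

    ``sidechain_center``: geometric centre of side-chain atoms (CA for
    glycine); ``ca``: the alpha carbon.
    """
    if metric == "ca":
        ca = residue.get_atom("CA")
        if ca is not None:
            return ca.xyz
        return residue.atom_coords().mean(axis=0)
    if metric == "sidechain_center":
        return np.array([a.xyz for a in residue.sidechain_atoms()]).mean(axis=0)
    raise ValueError(f"unknown distance metric: {metric}")


def enumerate_patches(structure: AntigenStructure,
                      surface_residues: list[ResidueId],
                      patch_size: int = DEFAULT_PATCH_SIZE,
                      metric: str = "sidechain_center") -> list[SurfacePatch]:
    """One patch per surface residue: the centre plus its patch_size-1
    nearest surface neighbours (all surface residues if fewer exist).

    Distance ties are broken by residue identifier so enumeration is
    deterministic.
    """
    if len(surface_residues) < 3:
        raise EmptyStructureError(
            f"need at least 3 surface residues, got {len(surface_residues)}")
    pts = np.array([representative_point(structure.residue(rid), metric)
                    for rid in surface_residues])
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    patches = []
    for i, center in enumerate(surface_residues):
        order = sorted(range(len(surface_residues)),
                       key=lambda j: (d[i, j], surface_residues[j]))
        take = order[:min(patch_size, len(surface_residues))]
        members = tuple(sorted(surface_residues[j] for j in take))
        patches.append(SurfacePatch(center, members, patch_size))
    return patches


def contact_number(structure: AntigenStructure, rid: ResidueId,
                   cutoff: float = DEFAULT_CONTACT_CUTOFF,
                   metric: str = "sidechain_center") -> int:
    """Number of other residues whose representative point lies within
    ``cutoff`` of this residue's representative point (residues, not atoms)."""
    p0 = representative_point(structure.residue(rid), metric)
    count = 0
    for res in structure.residues:
        if res.id == rid:
            continue
        if np.linalg.norm(representative_point(res, metric) - p0) < cutoff:
            count += 1
    return count


def planarity_score(structure: AntigenStructure, patch: SurfacePatch,
                    metric: str = "sidechain_center") -> float:
    """RMS deviation (Angstrom) of the patch members' representative points
    from their least-squares plane. Small values mean a flat patch."""
    pts = np.array([representative_point(structure.residue(rid), metric)
                    for rid in patch.members])
    return plane_rmsd(pts)


def plane_rmsd(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        logger.warning("planarity undefined for <3 points; returning 0")
        return 0.0
    centered = pts - pts.mean(axis=0)
    evals = np.linalg.eigvalsh(centered.T @ centered)
    if evals[1] < 1e-12:  # collinear: no unique plane
        logger.warning("collinear points; planarity degenerate, returning 0")
        return 0.0
    return float(math.sqrt(max(evals[0], 0.0) / len(pts)))


# ---------------------------------------------------------------------------
# secondary structure

HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -90.0)
STRAND_PSI = (90.0, 180.0)
MIN_HELIX_RUN = 4
MIN_STRAND_RUN = 3
PEPTIDE_BOND_MAX = 2.5  # C(i)-N(i+1) distance for chain continuity


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(structure: AntigenStructure,
                       ) -> dict[ResidueId, tuple[float | None, float | None]]:
    """Per-residue (phi, psi); None where undefined (termini, chain breaks,
    missing backbone atoms)."""
    out: dict[ResidueId, tuple[float | None, float | None]] = {}
    residues = structure.residues
    for i, res in enumerate(residues):
        phi = psi = None
        n = res.get_atom("N")
        ca = res.get_atom("CA")
        c = res.get_atom("C")
        if n and ca and c:
            if i > 0 and residues[i - 1].id.chain == res.id.chain:
                prev_c = residues[i - 1].get_atom("C")
                if prev_c is not None and \
                        np.linalg.norm(prev_c.xyz - n.xyz) < PEPTIDE_BOND_MAX:
                    phi = _dihedral(prev_c.xyz, n.xyz, ca.xyz, c.xyz)
            if i + 1 < len(residues) and residues[i + 1].id.chain == res.id.chain:
                next_n = residues[i + 1].get_atom("N")
                if next_n is not None and \
                        np.linalg.norm(c.xyz - next_n.xyz) < PEPTIDE_BOND_MAX:
                    psi = _dihedral(n.xyz, ca.xyz, c.xyz, next_n.xyz)
        out[res.id] = (phi, psi)
    return out


def _in_window(value, window) -> bool:
    return value is not None and window[0] <= value <= window[1]


def assign_secondary_structure(structure: AntigenStructure,
                               method: str = "auto",
                               ) -> dict[ResidueId, str]:
    """Three-class (helix/strand/coil) assignment for every residue.

    ``auto`` uses mkdssp when it is on PATH, otherwise the built-in
    deterministic phi/psi heuristic (helix and strand torsion windows with
    minimum run lengths 4 and 3). Residues lacking backbone atoms are coil.
    """
    if method == "auto":
        method = "dssp" if shutil.which("mkdssp") else "heuristic"
    if method == "dssp":
        try:
            return _assign_dssp(structure)
        except Exception as exc:  # pragma: no cover - depends on external tool
            logger.warning("DSSP failed (%s); falling back to heuristic", exc)
            method = "heuristic"
    if method != "heuristic":
        raise ValueError(f"unknown secondary-structure method: {method}")

    dihedrals = backbone_dihedrals(structure)
    raw: list[str] = []
    for res in structure.residues:
        phi, psi = dihedrals[res.id]
        if _in_window(phi, HELIX_PHI) and _in_window(psi, HELIX_PSI):
            raw.append("H")
        elif _in_window(phi, STRAND_PHI) and _in_window(psi, STRAND_PSI):
            raw.append("E")
        else:
            if res.get_atom("CA") is None or res.get_atom("N") is None \
                    or res.get_atom("C") is None:
                logger.warning("residue %s lacks backbone atoms; assigned coil",
                               res.id)
            raw.append("C")
    # enforce minimum element lengths
    final = list(raw)
    i = 0
    while i < len(raw):
        j = i
        while j < len(raw) and raw[j] == raw[i] \
                and structure.residues[j].id.chain == structure.residues[i].id.chain:
            j += 1
        run = j - i
        if raw[i] == "H" and run < MIN_HELIX_RUN:
            final[i:j] = ["C"] * run
        elif raw[i] == "E" and run < MIN_STRAND_RUN:
            final[i:j] = ["C"] * run
        i = j
    classes = {"H": "helix", "E": "strand", "C": "coil"}
    return {res.id: classes[s] for res, s in zip(structure.residues, final)}


def _assign_dssp(structure: AntigenStructure) -> dict[ResidueId, str]:
    """mkdssp-based assignment, collapsed to three classes."""
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        fh.write(write_pdb(structure))
        path = fh.name
    result = subprocess.run(["mkdssp", path], capture_output=True, text=True,
                            check=True)
    mapping3 = {"H": "helix", "G": "helix", "I": "helix",
                "E": "strand", "B": "strand"}
    assignments = {res.id: "coil" for res in structure.residues}
    in_table = False
    for line in result.stdout.splitlines():
        if line.startswith("  #  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 17 or line[13] == "!":
            continue
        chain = line[11].strip()
        try:
            resnum = int(line[5:10])
        except ValueError:
            continue
        icode = line[10].strip()
        rid = ResidueId(chain, resnum, icode)
        if rid in assignments:
            assignments[rid] = mapping3.get(line[16], "coil")
    return assignments


def write_pdb(structure: AntigenStructure) -> str:
    """Round-trip a parsed structure back to minimal ATOM records."""
    lines = []
    serial = 1
    prev_chain = None
    for res in structure.residues:
        if prev_chain is not None and res.id.chain != prev_chain:
            lines.append("TER")
        prev_chain = res.id.chain
        for atom in res.atoms:
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:>5} {atom.name:^4} {res.restype:>3} "
                f"{res.id.chain}{res.id.resnum:>4}{res.id.icode or ' ':1}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element:>2}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def accessibility_table(records: dict[ResidueId, AccessibilityRecord],
                        surface: list[ResidueId]) -> pd.DataFrame:
    """Tabular per-residue accessibility report."""
    surface_set = set(surface)
    rows = [{
        "chain": rid.chain, "resnum": rid.resnum, "icode": rid.icode,
        "restype": rec.restype, "sasa_total": rec.sasa_total,
        "sasa_sidechain": rec.sasa_sidechain, "rel_acc": rec.rel_acc,
        "is_surface": rid in surface_set,
    } for rid, rec in records.items()]
    return pd.DataFrame(rows)
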