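"""Synthetic inputs with known ground truth.

Generates every input the pipeline consumes — toy antigen structures with
known surface/epitope truth, ASCII PSSM files with planted conservation
offsets, multi-target training corpora with a planted feature-label signal,
and simulated ranked predictor outputs — so the whole pipeline is testable
without external data or servers.

Structures carry backbone + C-beta atoms only. Glycine is deliberately
absent from the type pools: with this atom complement every non-glycine
type has the same side-chain geometry, so re-labelling residue types after
the surface has been computed cannot change the surface set. Coordinates
are emitted at PDB precision (3 decimals) and all ground truth is computed
from the re-parsed rounded coordinates, so oracles and pipeline see
identical input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import BLOSUM62_DIAGONAL, PSSM_ALPHABET
from .features import PssmProfile, parse_pssm
from .geometry import PHI_PSI, build_backbone, format_pdb
from .meta import ServerRanking
from .structure import (AccessibilityRecord, AntigenStructure, ResidueId,
                        compute_sasa, identify_surface_residues,
                        parse_structure)

GEOMETRIES = ("helix", "sheet", "globule", "two_chain")

# residue-type pools (no glycine: see module docstring)
EPITOPE_TYPES = ("LYS", "ARG", "ASN", "ASP", "GLU")
BACKGROUND_TYPES = ("LEU", "VAL", "ILE", "ALA", "THR", "SER")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic antigen. Identical spec + seed gives
    byte-identical PDB text."""

    seed: int = 0
    geometry: str = "helix"
    n_residues: int = 30
    epitope_radius: float = 9.0          # A, CA-CA from the seed residue
    epitope_types: tuple[str, ...] = EPITOPE_TYPES
    background_types: tuple[str, ...] = BACKGROUND_TYPES
    enrichment: float = 0.8              # P(type drawn from the matching pool)
    lattice_spacing: float = 4.3         # A, globule only
    jitter: float = 0.25                 # A, globule lattice noise

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if "GLY" in self.epitope_types + self.background_types:
            raise ValueError("glycine not allowed in fixture type pools")


@dataclass
class StructureFixture:
    spec: FixtureSpec
    pdb_text: str
    structure: AntigenStructure
    records: dict[ResidueId, AccessibilityRecord]
    surface: list[ResidueId]
    epitope: set[ResidueId]
    ss_truth: dict[ResidueId, str]
    atoms_emitted: int


def _helix_coords(n: int):
    return build_backbone([PHI_PSI["helix"]] * n), ["A"] * n, list(range(1, n + 1))


def _sheet_coords(n: int):
    m = n // 2
    s1 = build_backbone([PHI_PSI["strand"]] * m)
    s2 = build_backbone([PHI_PSI["strand"]] * (n - m))
    # antiparallel partner: flip and offset by a typical inter-strand spacing
    flip = np.diag([-1.0, 1.0, -1.0])
    shift = np.array([0.0, 4.8, 0.0])
    end = s1[-1]["CA"]
    for res in s2:
        for k in res:
            res[k] = flip @ res[k] + shift + end * np.array([1.0, 0, 0])
    return s1 + s2, ["A"] * n, list(range(1, n + 1))


def _globule_coords(n: int, spacing: float, jitter: float,
                    rng: np.random.Generator):
    """Residues snaked through a compact cubic lattice so an interior core
    is solvent-inaccessible; local atom frames are randomly oriented."""
    w = math.ceil(n ** (1 / 3))
    sites = []
    for z in range(w):
        for y in range(w):
            xs = range(w) if y % 2 == 0 else range(w - 1, -1, -1)
            xs = xs if z % 2 == 0 else reversed(list(xs))
            for x in xs:
                sites.append((x, y, z))
                if len(sites) == n:
                    break
            if len(sites) == n:
                break
        if len(sites) == n:
            break
    template = build_backbone([(-120.0, 130.0)])[0]
    ca0 = template["CA"]
    local = {k: v - ca0 for k, v in template.items()}
    residues = []
    rots = Rotation.random(n, rng=rng)
    for i, site in enumerate(sites):
        center = np.array(site, dtype=float) * spacing \
            + rng.uniform(-jitter, jitter, size=3)
        rot = rots[i].as_matrix()
        residues.append({k: center + rot @ v for k, v in local.items()})
    return residues, ["A"] * n, list(range(1, n + 1))


def _two_chain_coords(n: int):
    m = n // 2
    h1 = build_backbone([PHI_PSI["helix"]] * m)
    h2 = build_backbone([PHI_PSI["helix"]] * (n - m))
    shift = np.array([0.0, 12.0, 0.0])
    for res in h2:
        for k in res:
            res[k] = res[k] + shift
    chains = ["A"] * m + ["B"] * (n - m)
    numbers = list(range(1, m + 1)) + list(range(1, n - m + 1))
    return h1 + h2, chains, numbers


def _ss_truth(spec: FixtureSpec, chains, numbers) -> list[str]:
    n = spec.n_residues
    if spec.geometry == "helix":
        return ["coil"] + ["helix"] * (n - 2) + ["coil"]
    if spec.geometry == "two_chain":
        out = []
        for ch in ("A", "B"):
            m = chains.count(ch)
            out += ["coil"] + ["helix"] * (m - 2) + ["coil"]
        return out
    if spec.geometry == "sheet":
        m = n // 2
        out = ["coil"] + ["strand"] * (m - 2) + ["coil"]
        out += ["coil"] + ["strand"] * (n - m - 2) + ["coil"]
        return out
    return ["coil"] * n  # globule: incoherent backbone


def generate_structure(spec: FixtureSpec) -> StructureFixture:
    """Emit a toy antigen and its ground truth.

    The epitope is a spatial cluster of surface residues (within
    ``epitope_radius`` of a randomly chosen surface seed) enriched in
    ``epitope_types``; the rest of the protein is enriched in
    ``background_types``. Surface truth is what the accessibility pipeline
    computes on the emitted (rounded) coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    if spec.geometry == "helix":
        coords, chains, numbers = _helix_coords(n)
    elif spec.geometry == "sheet":
        coords, chains, numbers = _sheet_coords(n)
    elif spec.geometry == "globule":
        coords, chains, numbers = _globule_coords(
            n, spec.lattice_spacing, spec.jitter, rng)
    else:
        coords, chains, numbers = _two_chain_coords(n)

    # pass 1: uniform types, to locate the surface on the final coordinates
    draft = format_pdb(coords, chains, numbers, ["ALA"] * n)
    structure = parse_structure(draft)
    records = compute_sasa(structure)
    surface = identify_surface_residues(records)
    if len(surface) < 3:
        raise ValueError("fixture has fewer than 3 surface residues; "
                         "increase n_residues")

    seed_rid = surface[int(rng.integers(len(surface)))]
    seed_ca = structure.residue(seed_rid).get_atom("CA").xyz
    epitope = set()
    for rid in surface:
        ca = structure.residue(rid).get_atom("CA").xyz
        if np.linalg.norm(ca - seed_ca) <= spec.epitope_radius:
            epitope.add(rid)

    # pass 2: plant the residue-type enrichment (surface set is invariant
    # to the re-labelling because all pool types share the CB-only side chain)
    types = []
    for rid in structure.residue_ids():
        in_epi = rid in epitope
        pool = spec.epitope_types if in_epi else spec.background_types
        other = spec.background_types if in_epi else spec.epitope_types
        chosen = pool if rng.uniform() < spec.enrichment else other
        types.append(chosen[int(rng.integers(len(chosen)))])

    pdb_text = format_pdb(coords, chains, numbers, types)
    final = parse_structure(pdb_text)
    final_records = compute_sasa(final)
    final_surface = identify_surface_residues(final_records)
    ss = dict(zip(final.residue_ids(), _ss_truth(spec, chains, numbers)))
    n_atoms = sum(len(r.atoms) for r in final.residues)
    return StructureFixture(spec, pdb_text, final, final_records,
                            final_surface, epitope, ss, n_atoms)


# ---------------------------------------------------------------------------
# synthetic PSSM files

def generate_pssm(sequence: str, offsets) -> str:
    """ASCII PSSM text whose per-position self-score is the BLOSUM62
    diagonal plus the planted offset; off-diagonal scores follow BLOSUM62."""
    from .constants import _BLOSUM62

    offsets = list(offsets)
    if len(offsets) != len(sequence):
        raise ValueError("profile length must match sequence length")
    lines = ["",
             "Last position-specific scoring matrix computed, weighted "
             "observed percentages rounded down, information per position, "
             "and relative weight of gapless real matches to pseudocounts"]
    header = "           " + "".join(f"{aa:>3}" for aa in PSSM_ALPHABET) \
        + "  " + "".join(f"{aa:>4}" for aa in PSSM_ALPHABET)
    lines.append(header)
    for i, (aa, off) in enumerate(zip(sequence, offsets), start=1):
        if aa not in BLOSUM62_DIAGONAL:
            raise ValueError(f"non-standard residue {aa!r} in sequence")
        row = [int(_BLOSUM62[aa, col]) for col in PSSM_ALPHABET]
        row[PSSM_ALPHABET.index(aa)] = BLOSUM62_DIAGONAL[aa] + int(off)
        scores = "".join(f"{v:>3}" for v in row)
        pcts = "".join(f"{0:>4}" for _ in PSSM_ALPHABET)
        lines.append(f"{i:>5} {aa}  {scores}  {pcts}  0.00 0.00")
    lines += ["", "                      K         Lambda",
              "Standard Ungapped    0.1337     0.3176"]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# training corpus with a planted feature-label signal

@dataclass
class CorpusTarget:
    target_id: str
    fixture: StructureFixture
    pssm_texts: dict[str, str]
    pssm_profiles: dict[str, PssmProfile] = field(default_factory=dict)

    @property
    def structure(self) -> AntigenStructure:
        return self.fixture.structure

    @property
    def epitope(self) -> set[ResidueId]:
        return self.fixture.epitope

    @property
    def surface(self) -> list[ResidueId]:
        return self.fixture.surface


def child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2 ** 31) for s in state]


def generate_training_corpus(n_targets: int, seed: int = 0,
                             template: FixtureSpec | None = None,
                             shuffle_labels: bool = False,
                             id_prefix: str = "T",
                             ) -> list[CorpusTarget]:
    """Targets whose epitopes carry a planted, recoverable signal: a spatial
    surface cluster enriched in charged/polar types (propensity signal) with
    depressed PSSM self-scores (conservation signal).

    ``shuffle_labels`` keeps structures and profiles but replaces each
    epitope with a random surface subset of the same size — the permutation
    null for recovery experiments.
    """
    template = template or FixtureSpec(geometry="globule", n_residues=96,
                                       epitope_radius=11.0)
    targets = []
    for i, sub_seed in enumerate(child_seeds(seed, n_targets)):
        fixture = generate_structure(replace(template, seed=sub_seed))
        rng = np.random.default_rng(sub_seed + 1)
        pssm_texts = {}
        pssm_profiles = {}
        for chain in fixture.structure.chains:
            chain_rids = [r.id for r in fixture.structure.residues
                          if r.id.chain == chain]
            sequence = fixture.structure.sequence(chain)
            offsets = [int(rng.integers(-6, -1)) if rid in fixture.epitope
                       else int(rng.integers(1, 4)) for rid in chain_rids]
            text = generate_pssm(sequence, offsets)
            pssm_texts[chain] = text
            pssm_profiles[chain] = parse_pssm(text)
        if shuffle_labels:
            # permute labels only after every feature input is fixed, so the
            # planted residue-type and conservation signals decouple from them
            surface = fixture.surface
            k = len(fixture.epitope)
            pick = rng.choice(len(surface), size=k, replace=False)
            fixture.epitope = {surface[j] for j in sorted(pick)}
        targets.append(CorpusTarget(f"{id_prefix}{i:03d}", fixture, pssm_texts,
                                    pssm_profiles))
    return targets


def as_prepared_target(target: CorpusTarget, patch_size: int = 20,
                       metric: str = "sidechain_center"):
    """Bridge a corpus target into the regression pipeline's prepared form,
    reusing the fixture's accessibility records."""
    from .structure import assign_secondary_structure, enumerate_patches
    from .svr import PreparedTarget

    patches = enumerate_patches(target.structure, target.fixture.surface,
                                patch_size, metric)
    ss = assign_secondary_structure(target.structure, method="heuristic")
    return PreparedTarget(target.target_id, target.structure,
                          target.fixture.records, list(target.fixture.surface),
                          patches, ss, target.pssm_profiles,
                          set(target.epitope))


# ---------------------------------------------------------------------------
# simulated predictor rankings

def generate_server_rankings(surface, epitope: set[ResidueId],
                             lambdas, seed: int = 0,
                             names=None) -> dict[str, ServerRanking]:
    """One ranking per server: score = lambda * label + (1 - lambda) * noise.

    lambda = 1 ranks all epitopic residues first; lambda = 0 is pure noise;
    intermediate values tune each simulated server's AUC monotonically.
    """
    lambdas = list(lambdas)
    if any(not 0 <= lam <= 1 for lam in lambdas):
        raise ValueError("every lambda must lie in [0, 1]")
    if names is None:
        names = [f"S{i + 1}" for i in range(len(lambdas))]
    surface = list(surface)
    rng = np.random.default_rng(seed)
    out = {}
    for name, lam in zip(names, lambdas):
        noise = rng.uniform(size=len(surface))
        scores = {rid: lam * (1.0 if rid in epitope else 0.0)
                  + (1 - lam) * float(noise[i])
                  for i, rid in enumerate(surface)}
        out[name] = ServerRanking.from_scores(name, scores)
    return out
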