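"""The six patch attributes and their assembly into scaled feature vectors.

Per-residue terms (epitope propensity, conservation, side-chain environment
energy) are averaged over the patch; the contact number belongs to the
patch centre; planarity and secondary-structure composition are patch-level.
All six are min-max scaled to [0, 1] with a scaler fitted on the training
patches, mirroring the scaling applied to the epitopic-count label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import BLOSUM62_DIAGONAL, PSSM_ALPHABET
from .structure import (AccessibilityRecord, AntigenStructure, ResidueId,
                        SurfacePatch, contact_number, planarity_score)

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("propensity", "conservation", "side_chain_energy",
                 "contact_number", "planarity", "ss_composition")

DEFAULT_PSEUDOCOUNT = 1.0  # A^2 added to every (type, class) area sum

# relative-accessibility bins for the burial-environment energy term
BURIAL_BIN_EDGES = (0.05, 0.25, 0.5)


class ProvenanceError(RuntimeError):
    """A training-derived table was used on a target it was derived from."""


class MappingError(ValueError):
    """An annotation or profile references residues absent from the structure."""


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# residue epitope propensity

@dataclass(frozen=True)
class PropensityTable:
    """Per-residue-type log-ratio of epitopic to non-epitope surface area.

    ``values[t] = ln( f_epi(t) / f_rest(t) )`` where f are the
    pseudocounted side-chain-area fractions of type t on epitopic versus
    remaining surface residues of the training targets.
    """

    values: Mapping[str, float]
    epitope_areas: Mapping[str, float]
    rest_areas: Mapping[str, float]
    pseudocount: float
    provenance: tuple[str, ...] = ()

    def __getitem__(self, restype: str) -> float:
        return self.values[restype]

    def __contains__(self, restype: str) -> bool:
        return restype in self.values


def derive_propensity_table(
        targets: Iterable[tuple[str, Mapping[ResidueId, AccessibilityRecord],
                                Sequence[ResidueId], set[ResidueId]]],
        pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PropensityTable:
    """Pool side-chain surface area by residue type over epitopic and
    non-epitopic surface residues of the training targets.

    Each target is ``(target_id, accessibility records, surface residues,
    epitope residue set)``. The pseudocount keeps every log-ratio finite
    even for types absent from one class.
    """
    from .constants import STANDARD_RESIDUES

    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be non-negative")
    epi_area = {t: 0.0 for t in STANDARD_RESIDUES}
    rest_area = {t: 0.0 for t in STANDARD_RESIDUES}
    provenance = []
    for target_id, records, surface, epitope in targets:
        provenance.append(target_id)
        for rid in surface:
            rec = records[rid]
            if rec.restype not in epi_area:
                continue
            bucket = epi_area if rid in epitope else rest_area
            bucket[rec.restype] += rec.sasa_sidechain
    total_epi = sum(epi_area.values()) + pseudocount * len(epi_area)
    total_rest = sum(rest_area.values()) + pseudocount * len(rest_area)
    if total_epi <= 0 or total_rest <= 0:
        raise ConfigurationError("zero total area even after pseudocounting")
    values = {}
    for t in STANDARD_RESIDUES:
        f_epi = (epi_area[t] + pseudocount) / total_epi
        f_rest = (rest_area[t] + pseudocount) / total_rest
        values[t] = float(np.log(f_epi / f_rest))
    return PropensityTable(values, epi_area, rest_area, pseudocount,
                           tuple(provenance))


def epitope_propensity(restype: str, record: AccessibilityRecord,
                       table: PropensityTable) -> float:
    """Relative side-chain accessibility times the type's log-ratio."""
    if restype not in table:
        logger.warning("residue type %s not in propensity table; score 0",
                       restype)
        return 0.0
    return record.rel_acc * table[restype]


# ---------------------------------------------------------------------------
# conservation (PSSM self-score minus BLOSUM62 diagonal)

@dataclass(frozen=True)
class PssmProfile:
    """Parsed PSI-BLAST ASCII position-specific scoring matrix."""

    sequence: str                 # one-letter, one char per position
    scores: np.ndarray            # (n_positions, 20) integer substitution scores
    alphabet: str = PSSM_ALPHABET

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.sequence), len(self.alphabet)):
            raise MappingError("PSSM score block does not match sequence length")

    def self_score(self, position: int) -> int:
        aa = self.sequence[position]
        return int(self.scores[position, self.alphabet.index(aa)])


def parse_pssm(text: str) -> PssmProfile:
    """Read the ``-out_ascii_pssm`` dialect: header, a column line of
    amino-acid letters, then one row per position (index, residue, scores)."""
    lines = text.splitlines()
    alphabet = None
    seq = []
    rows = []
    for line in lines:
        tokens = line.split()
        if alphabet is None:
            if len(tokens) >= 20 and all(len(t) == 1 and t.isalpha()
                                         for t in tokens[:20]):
                alphabet = "".join(tokens[:20])
            continue
        if len(tokens) >= 22 and tokens[0].lstrip("-").isdigit() \
                and len(tokens[1]) == 1 and tokens[1].isalpha():
            try:
                scores = [int(t) for t in tokens[2:22]]
            except ValueError:
                continue
            seq.append(tokens[1])
            rows.append(scores)
        elif rows:
            break  # trailing statistics block
    if alphabet is None or not rows:
        raise MappingError("not a recognisable ASCII PSSM")
    return PssmProfile("".join(seq), np.array(rows, dtype=int), alphabet)


def map_pssm_to_chain(profile: PssmProfile, structure: AntigenStructure,
                      chain: str) -> dict[ResidueId, int]:
    """Map PSSM positions onto the chain's ATOM-record residues by exact
    substring match (either sequence may be the longer one). Residues left
    unmapped are reported by the caller and score 0."""
    chain_ids = [r.id for r in structure.residues if r.id.chain == chain]
    chain_seq = structure.sequence(chain)
    pssm_seq = profile.sequence
    mapping: dict[ResidueId, int] = {}
    if chain_seq and chain_seq in pssm_seq:
        offset = pssm_seq.index(chain_seq)
        for i, rid in enumerate(chain_ids):
            mapping[rid] = offset + i
    elif pssm_seq and pssm_seq in chain_seq:
        offset = chain_seq.index(pssm_seq)
        for j in range(len(pssm_seq)):
            mapping[chain_ids[offset + j]] = j
    else:
        logger.warning("PSSM sequence does not match chain %s; "
                       "no positions mapped", chain)
    return mapping


def conservation_score(profile: PssmProfile, position: int) -> float:
    """PSSM self-substitution score minus the BLOSUM62 diagonal entry.

    Negative values flag positions less conserved than the background —
    the hallmark the conservation attribute exploits (epitopes are less
    conserved than average surface).
    """
    aa = profile.sequence[position]
    if aa not in BLOSUM62_DIAGONAL:
        logger.warning("non-standard residue %s in PSSM; conservation 0", aa)
        return 0.0
    return float(profile.self_score(position) - BLOSUM62_DIAGONAL[aa])


# ---------------------------------------------------------------------------
# side-chain environment energy (burial-class log-odds)

@dataclass(frozen=True)
class EnergyTable:
    """Statistical side-chain environment score.

    For each residue type the training corpus supplies counts over four
    burial classes (relative accessibility bins). The score of a residue in
    class b is ``-ln( P(b | type) / P(b) )`` with one pseudocount per cell:
    positive (unfavourable) when the type is rarely seen that buried or
    exposed, zero under flat statistics.
    """

    counts: Mapping[str, tuple[float, ...]]   # type -> per-bin counts
    pseudocount: float = 1.0
    provenance: tuple[str, ...] = ()

    def score(self, restype: str, rel_acc: float) -> float:
        if restype not in self.counts:
            logger.warning("residue type %s not in energy table; score 0",
                           restype)
            return 0.0
        b = burial_bin(rel_acc)
        n_bins = len(BURIAL_BIN_EDGES) + 1
        row = self.counts[restype]
        type_total = sum(row) + self.pseudocount * n_bins
        bin_total = sum(c[b] for c in self.counts.values()) \
            + self.pseudocount * len(self.counts)
        grand = sum(sum(c) for c in self.counts.values()) \
            + self.pseudocount * len(self.counts) * n_bins
        p_bin_given_type = (row[b] + self.pseudocount) / type_total
        p_bin = bin_total / grand
        return float(-np.log(p_bin_given_type / p_bin))


def burial_bin(rel_acc: float) -> int:
    for i, edge in enumerate(BURIAL_BIN_EDGES):
        if rel_acc < edge:
            return i
    return len(BURIAL_BIN_EDGES)


def derive_energy_table(
        targets: Iterable[tuple[str, Mapping[ResidueId, AccessibilityRecord]]],
        pseudocount: float = 1.0) -> EnergyTable:
    """Count burial classes per residue type over all residues of the
    training targets (buried and surface alike)."""
    from .constants import STANDARD_RESIDUES

    n_bins = len(BURIAL_BIN_EDGES) + 1
    counts = {t: [0.0] * n_bins for t in STANDARD_RESIDUES}
    provenance = []
    for target_id, records in targets:
        provenance.append(target_id)
        for rec in records.values():
            if rec.restype in counts:
                counts[rec.restype][burial_bin(rec.rel_acc)] += 1.0
    return EnergyTable({t: tuple(v) for t, v in counts.items()},
                       pseudocount, tuple(provenance))


# ---------------------------------------------------------------------------
# patch-level assembly

def ss_composition(patch: SurfacePatch,
                   assignment: Mapping[ResidueId, str]) -> float:
    """Fraction of patch members assigned to the coil class."""
    missing = [rid for rid in patch.members if rid not in assignment]
    if missing:
        raise MappingError(f"patch members without secondary structure: {missing}")
    coil = sum(1 for rid in patch.members if assignment[rid] == "coil")
    return coil / len(patch.members)


def patch_label(patch: SurfacePatch, epitope: set[ResidueId]) -> float:
    """Observed epitopic residues in the patch, scaled by the nominal patch
    size (20): the regression target."""
    count = sum(1 for rid in patch.members if rid in epitope)
    return count / patch.patch_size


def validate_annotation(epitope: set[ResidueId],
                        structure: AntigenStructure) -> None:
    unknown = sorted(rid for rid in epitope if rid not in structure)
    if unknown:
        raise MappingError(f"annotation references unknown residues: {unknown}")


class FeatureScaler:
    """Per-attribute min-max scaling to [0, 1], fitted on training patches.

    Values outside the training range are clamped; an attribute constant in
    training maps to 0.5.
    """

    def __init__(self) -> None:
        self.mins: np.ndarray | None = None
        self.maxs: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mins is not None

    def fit(self, raw: np.ndarray) -> "FeatureScaler":
        raw = np.asarray(raw, dtype=float)
        self.mins = raw.min(axis=0)
        self.maxs = raw.max(axis=0)
        return self

    def transform(self, raw: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("scaler must be fitted before use")
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        span = self.maxs - self.mins
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = (raw - self.mins) / span
        scaled = np.where(span > 0, scaled, 0.5)
        return np.clip(scaled, 0.0, 1.0)

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("scaler must be fitted before use")
        span = self.maxs - self.mins
        return np.atleast_2d(scaled) * span + self.mins

    def to_dict(self) -> dict:
        return {"mins": list(map(float, self.mins)),
                "maxs": list(map(float, self.maxs))}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        sc = cls()
        sc.mins = np.array(d["mins"], dtype=float)
        sc.maxs = np.array(d["maxs"], dtype=float)
        return sc


@dataclass(frozen=True)
class PatchFeatureVector:
    patch: SurfacePatch
    raw: np.ndarray       # six raw attribute values, FEATURE_NAMES order
    scaled: np.ndarray | None = None
    label: float | None = None


def assemble_patch_features(patch: SurfacePatch,
                            residue_scores: Mapping[ResidueId,
                                                    tuple[float, float, float]],
                            contact: float, planarity: float,
                            ss_frac: float,
                            scaler: FeatureScaler | None = None,
                            ) -> PatchFeatureVector:
    """Average the residue-level terms over the patch and join the
    patch-level geometry into the six-component attribute vector."""
    per_res = np.array([residue_scores[rid] for rid in patch.members])
    prop, cons, energy = per_res.mean(axis=0)
    raw = np.array([prop, cons, energy, contact, planarity, ss_frac],
                   dtype=float)
    scaled = scaler.transform(raw)[0] if scaler is not None else None
    return PatchFeatureVector(patch, raw, scaled)


# ---------------------------------------------------------------------------
# whole-target featurisation

@dataclass
class FeaturizedTarget:
    """Everything the regressor needs for one antigen."""

    target_id: str
    structure: AntigenStructure
    surface: list[ResidueId]
    patches: list[SurfacePatch]
    raw_features: np.ndarray            # (n_patches, 6)
    labels: np.ndarray | None = None    # scaled epitopic counts, if annotated
    epitope: set[ResidueId] = field(default_factory=set)

    def feature_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.raw_features, columns=list(FEATURE_NAMES))
        df.insert(0, "center", [str(p.center) for p in self.patches])
        if self.labels is not None:
            df["label"] = self.labels
        return df


def featurize_target(target_id: str,
                     structure: AntigenStructure,
                     records: Mapping[ResidueId, AccessibilityRecord],
                     surface: Sequence[ResidueId],
                     patches: Sequence[SurfacePatch],
                     ss_assignment: Mapping[ResidueId, str],
                     propensity_table: PropensityTable,
                     energy_table: EnergyTable,
                     pssm_profiles: Mapping[str, PssmProfile] | None = None,
                     epitope: set[ResidueId] | None = None,
                     contact_cutoff: float = 10.0,
                     metric: str = "sidechain_center",
                     allow_self: bool = False) -> FeaturizedTarget:
    """Compute the raw six-vector for every patch of one antigen.

    Cross-validation hygiene is enforced here: a propensity or energy table
    whose provenance includes ``target_id`` is rejected unless the caller
    explicitly opts in (final-model evaluation on its own training set).
    """
    if not allow_self:
        for table, name in ((propensity_table, "propensity"),
                            (energy_table, "energy")):
            if target_id in table.provenance:
                raise ProvenanceError(
                    f"{name} table was derived from target {target_id!r}; "
                    "refusing to score it (leave-one-out hygiene)")

    pssm_maps: dict[str, dict[ResidueId, int]] = {}
    if pssm_profiles:
        for chain, profile in pssm_profiles.items():
            pssm_maps[chain] = map_pssm_to_chain(profile, structure, chain)

    residue_scores: dict[ResidueId, tuple[float, float, float]] = {}
    for rid in surface:
        res = structure.residue(rid)
        rec = records[rid]
        prop = epitope_propensity(res.restype, rec, propensity_table)
        cons = 0.0
        if rid.chain in pssm_maps and rid in pssm_maps[rid.chain]:
            cons = conservation_score(pssm_profiles[rid.chain],
                                      pssm_maps[rid.chain][rid])
        energy = energy_table.score(res.restype, rec.rel_acc)
        residue_scores[rid] = (prop, cons, energy)

    raw = np.empty((len(patches), 6), dtype=float)
    for i, patch in enumerate(patches):
        contact = contact_number(structure, patch.center, contact_cutoff, metric)
        planarity = planarity_score(structure, patch, metric)
        ss_frac = ss_composition(patch, ss_assignment)
        fv = assemble_patch_features(patch, residue_scores, contact,
                                     planarity, ss_frac)
        raw[i] = fv.raw

    labels = None
    if epitope is not None:
        validate_annotation(epitope, structure)
        labels = np.array([patch_label(p, epitope) for p in patches])
    return FeaturizedTarget(target_id, structure, list(surface), list(patches),
                            raw, labels, epitope or set())
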