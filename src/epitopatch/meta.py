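"""Tiered minimum-vote consensus over ranked predictor outputs.

Several epitope predictors each rank the antigen's surface residues. A
residue is accepted when at least two of the currently active predictors
include it in their growing top lists. Predictors are admitted in tiers:
the most reliable three handle requests up to 25% of the surface; as the
requested prediction size E grows past 25/50/75% of the surface, a fourth,
fifth and sixth predictor join the vote, each tier seeded with the residues
already accepted at the previous boundary (R25/R50/R75).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .evaluate import RocCurve, curve_from_sets
from .structure import ResidueId


class MetaConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ServerRanking:
    """One predictor's output: residues ordered best-first.

    ``coverage`` is the set of residues the predictor scored at all; it may
    be a strict subset of the surface when a predictor skips part of the
    structure.
    """

    name: str
    order: tuple[ResidueId, ...]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise MetaConfigError(f"duplicate residues in ranking {self.name!r}")

    @property
    def coverage(self) -> set[ResidueId]:
        return set(self.order)

    def top(self, k: int) -> set[ResidueId]:
        return set(self.order[:max(0, k)])

    @classmethod
    def from_scores(cls, name: str,
                    scores: Mapping[ResidueId, float]) -> "ServerRanking":
        order = sorted(scores, key=lambda rid: (-scores[rid], rid))
        return cls(name, tuple(order))


@dataclass(frozen=True)
class MetaConfig:
    boundaries: tuple[float, ...] = (0.25, 0.50, 0.75, 1.0)
    tier_servers: tuple[tuple[str, ...], ...] = (
        ("S1", "S2", "S3"),
        ("S1", "S2", "S3", "S4"),
        ("S1", "S2", "S3", "S4", "S5"),
        ("S1", "S2", "S3", "S4", "S5", "S6"),
    )
    vote_threshold: int = 2
    step_fraction: float = 0.01

    def __post_init__(self) -> None:
        if len(self.boundaries) != len(self.tier_servers):
            raise MetaConfigError("one server list per tier required")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise MetaConfigError("tier boundaries must be strictly increasing")
        if abs(self.boundaries[-1] - 1.0) > 1e-9:
            raise MetaConfigError("last tier boundary must be 1.0")
        for lo, hi in zip(self.tier_servers, self.tier_servers[1:]):
            if tuple(hi[:len(lo)]) != tuple(lo):
                raise MetaConfigError("tier server lists must be nested")
        if self.vote_threshold < 2:
            raise MetaConfigError("vote threshold must be at least 2")


@dataclass
class MetaResult:
    predicted: set[ResidueId]
    tier: int                                  # 1-based
    checkpoints: dict[int, set[ResidueId]]     # boundary percent -> Rp set
    acquisition: dict[ResidueId, tuple[int, float, int]] = field(
        default_factory=dict)                  # rid -> (tier, fraction, votes)
    shortfall: bool = False


def vote_collect(server_sets: Sequence[set[ResidueId]],
                 threshold: int = 2) -> set[ResidueId]:
    """Residues predicted by at least ``threshold`` of the servers."""
    if len(server_sets) < threshold:
        raise MetaConfigError(
            f"{len(server_sets)} server sets cannot reach {threshold} votes")
    counts: dict[ResidueId, int] = {}
    for s in server_sets:
        for rid in s:
            counts[rid] = counts.get(rid, 0) + 1
    return {rid for rid, c in counts.items() if c >= threshold}


def predictor(rp: set[ResidueId], e: int,
              rankings: Sequence[ServerRanking], n: int,
              threshold: int = 2, step_fraction: float = 0.01,
              tier: int = 0,
              acquisition: dict | None = None,
              ) -> tuple[set[ResidueId], bool]:
    """Grow every server's top list in steps of 1% of the surface, voting at
    each step, until the seed set plus the consensus reaches E residues.

    Returns the final set and a shortfall flag (set when even full-length
    server lists cannot reach E, e.g. with incomplete coverage).
    """
    if e <= len(rp):
        return set(rp), False
    step = max(1, math.ceil(step_fraction * n))
    max_k = math.ceil(n / step)
    collected: set[ResidueId] = set()
    result = set(rp)
    k = 0
    while len(result) < e and k < max_k:
        k += 1
        sets = [r.top(k * step) for r in rankings]
        new_collected = vote_collect(sets, threshold)
        if acquisition is not None:
            counts: dict[ResidueId, int] = {}
            for s in sets:
                for rid in s:
                    counts[rid] = counts.get(rid, 0) + 1
            for rid in new_collected - collected:
                if rid not in acquisition and rid not in rp:
                    acquisition[rid] = (tier, k * step / n, counts[rid])
        collected = new_collected
        result = rp | collected
    return result, len(result) < e


def select_tier(e: int, n: int, config: MetaConfig) -> int:
    """1-based tier index for a request of E residues out of N; each tier's
    upper boundary is inclusive (floor of fraction * N)."""
    if not 0 <= e <= n:
        raise MetaConfigError(f"E={e} outside [0, N={n}]")
    for i, b in enumerate(config.boundaries):
        if e <= math.floor(b * n):
            return i + 1
    return len(config.boundaries)


def meta_predict(rankings: Mapping[str, ServerRanking], e: int, n: int,
                 config: MetaConfig = MetaConfig()) -> MetaResult:
    """Run the tiered consensus for a request of E of N surface residues.

    The tier is chosen by E/N; lower tiers are applied recursively at their
    boundary sizes to build the seed checkpoints (R25, R50, R75), then the
    selected tier's servers vote until the request is met.
    """
    tier = select_tier(e, n, config)
    needed = config.tier_servers[tier - 1]
    missing = [s for s in needed if s not in rankings]
    if missing:
        raise MetaConfigError(f"missing rankings for required servers: {missing}")

    acquisition: dict[ResidueId, tuple[int, float, int]] = {}
    checkpoints: dict[int, set[ResidueId]] = {}
    seed: set[ResidueId] = set()
    shortfall = False
    for t in range(1, tier):
        boundary_e = math.floor(config.boundaries[t - 1] * n)
        servers = [rankings[s] for s in config.tier_servers[t - 1]]
        seed, fell_short = predictor(seed, boundary_e, servers, n,
                                     config.vote_threshold,
                                     config.step_fraction, t, acquisition)
        shortfall = shortfall or fell_short
        checkpoints[round(config.boundaries[t - 1] * 100)] = set(seed)
    servers = [rankings[s] for s in config.tier_servers[tier - 1]]
    predicted, fell_short = predictor(seed, e, servers, n,
                                      config.vote_threshold,
                                      config.step_fraction, tier, acquisition)
    return MetaResult(predicted, tier, checkpoints, acquisition,
                      shortfall or fell_short)


def meta_roc(rankings: Mapping[str, ServerRanking],
             epitope: set[ResidueId],
             surface: Sequence[ResidueId],
             config: MetaConfig = MetaConfig()) -> RocCurve:
    """Sweep the requested prediction size E over 1%..100% of the surface
    and trace the consensus ROC (the swept sets are nested across tiers)."""
    n = len(surface)
    sets = []
    for k in range(1, 101):
        e = min(n, math.ceil(k * n / 100))
        sets.append(meta_predict(rankings, e, n, config).predicted)
    return curve_from_sets(sets, epitope, surface)
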