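"""Epsilon-SVR scoring of surface patches and aggregation to residue scores.

The regression target is the scaled count of epitopic residues in a patch
(count / 20). Hyperparameters follow the LIBSVM convention: ``c`` is the
cost, ``g`` the RBF kernel gamma, ``p`` the epsilon-insensitive tube, each
searched over powers of two with per-target leave-one-out evaluation.
Predicted patch scores are averaged over all patches containing a residue
to give residue scores, and the top-ranked residues are the epitope call.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from . import evaluate
from .features import (DEFAULT_PSEUDOCOUNT, EnergyTable, FeatureScaler,
                       FeaturizedTarget, PropensityTable, PssmProfile,
                       derive_energy_table, derive_propensity_table,
                       featurize_target)
from .structure import (DEFAULT_CONTACT_CUTOFF, DEFAULT_PATCH_SIZE,
                        DEFAULT_PROBE_RADIUS, DEFAULT_SURFACE_THRESHOLD,
                        AccessibilityRecord, AntigenStructure, ResidueId,
                        SurfacePatch, assign_secondary_structure, compute_sasa,
                        enumerate_patches, identify_surface_residues)

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SVRConfig:
    """LIBSVM-style epsilon-SVR hyperparameters (RBF kernel)."""

    c: float = 2.0 ** -6
    g: float = 2.0 ** -5
    p: float = 2.0 ** -3

    def __post_init__(self) -> None:
        if min(self.c, self.g, self.p) <= 0:
            raise ValueError("c, g and p must all be positive")


def default_grid(c_exps: Sequence[int] = range(-10, 0),
                 g_exps: Sequence[int] = range(-12, -2),
                 p_exps: Sequence[int] = range(-5, -1)) -> list[SVRConfig]:
    """Power-of-two grid: c in 2^-10..2^-1, g in 2^-12..2^-3, p in 2^-5..2^-2."""
    return [SVRConfig(2.0 ** a, 2.0 ** b, 2.0 ** c)
            for a, b, c in itertools.product(c_exps, g_exps, p_exps)]


@dataclass
class SVRModel:
    """Self-contained trained model: support vectors, dual coefficients and
    bias plus the fitted scaler and the training-derived score tables, so a
    serialized model predicts stand-alone."""

    support_vectors: np.ndarray     # (n_sv, 6), scaled feature space
    dual_coef: np.ndarray           # (n_sv,)
    intercept: float
    config: SVRConfig
    scaler: FeatureScaler
    propensity_table: PropensityTable
    energy_table: EnergyTable
    patch_size: int = DEFAULT_PATCH_SIZE
    probe_radius: float = DEFAULT_PROBE_RADIUS
    surface_threshold: float = DEFAULT_SURFACE_THRESHOLD
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    metric: str = "sidechain_center"

    def predict(self, scaled_features: np.ndarray) -> np.ndarray:
        """RBF kernel expansion: sum_i alpha_i exp(-g ||x - sv_i||^2) + b."""
        x = np.atleast_2d(np.asarray(scaled_features, dtype=float))
        if x.shape[1] != self.support_vectors.shape[1] and \
                self.support_vectors.size:
            raise ValueError(
                f"expected {self.support_vectors.shape[1]} features, "
                f"got {x.shape[1]}")
        if self.support_vectors.size == 0:
            return np.full(len(x), self.intercept)
        d2 = ((x[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(-1)
        return np.exp(-self.config.g * d2) @ self.dual_coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "config": {"c": self.config.c, "g": self.config.g, "p": self.config.p},
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "scaler": self.scaler.to_dict(),
            "propensity_table": {
                "values": dict(self.propensity_table.values),
                "epitope_areas": dict(self.propensity_table.epitope_areas),
                "rest_areas": dict(self.propensity_table.rest_areas),
                "pseudocount": self.propensity_table.pseudocount,
                "provenance": list(self.propensity_table.provenance),
            },
            "energy_table": {
                "counts": {t: list(v) for t, v in self.energy_table.counts.items()},
                "pseudocount": self.energy_table.pseudocount,
                "provenance": list(self.energy_table.provenance),
            },
            "patch_size": self.patch_size,
            "probe_radius": self.probe_radius,
            "surface_threshold": self.surface_threshold,
            "contact_cutoff": self.contact_cutoff,
            "metric": self.metric,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        pt = d["propensity_table"]
        et = d["energy_table"]
        return cls(
            np.array(d["support_vectors"], dtype=float).reshape(-1, 6),
            np.array(d["dual_coef"], dtype=float),
            float(d["intercept"]),
            SVRConfig(**d["config"]),
            FeatureScaler.from_dict(d["scaler"]),
            PropensityTable(pt["values"], pt["epitope_areas"], pt["rest_areas"],
                            pt["pseudocount"], tuple(pt["provenance"])),
            EnergyTable({t: tuple(v) for t, v in et["counts"].items()},
                        et["pseudocount"], tuple(et["provenance"])),
            int(d["patch_size"]), float(d["probe_radius"]),
            float(d["surface_threshold"]), float(d["contact_cutoff"]),
            d["metric"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SVRModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_svr_arrays(features: np.ndarray, labels: np.ndarray,
                   config: SVRConfig) -> tuple[np.ndarray, np.ndarray, float]:
    """LIBSVM epsilon-SVR fit (via scikit-learn); returns the kernel
    expansion (support vectors, dual coefficients, intercept)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(features) != len(labels):
        raise ValueError("features and labels disagree in length")
    if np.ptp(labels) == 0:
        logger.warning("constant labels: returning a constant predictor")
        return (np.empty((0, features.shape[1])), np.empty(0),
                float(labels[0]) if len(labels) else 0.0)
    est = SVR(kernel="rbf", C=config.c, gamma=config.g, epsilon=config.p)
    est.fit(features, labels)
    return (est.support_vectors_.copy(), est.dual_coef_.ravel().copy(),
            float(est.intercept_[0]))


# ---------------------------------------------------------------------------
# target preparation and the training corpus

@dataclass
class PreparedTarget:
    """One antigen with all table-independent computations done once:
    accessibility, surface set, patches and secondary structure."""

    target_id: str
    structure: AntigenStructure
    records: Mapping[ResidueId, AccessibilityRecord]
    surface: list[ResidueId]
    patches: list[SurfacePatch]
    ss: Mapping[ResidueId, str]
    pssm_profiles: Mapping[str, PssmProfile] = field(default_factory=dict)
    epitope: set[ResidueId] = field(default_factory=set)


def prepare_target(target_id: str, structure: AntigenStructure,
                   pssm_profiles: Mapping[str, PssmProfile] | None = None,
                   epitope: set[ResidueId] | None = None,
                   probe_radius: float = DEFAULT_PROBE_RADIUS,
                   surface_threshold: float = DEFAULT_SURFACE_THRESHOLD,
                   patch_size: int = DEFAULT_PATCH_SIZE,
                   metric: str = "sidechain_center",
                   ss_method: str = "auto") -> PreparedTarget:
    records = compute_sasa(structure, probe_radius)
    surface = identify_surface_residues(records, surface_threshold)
    patches = enumerate_patches(structure, surface, patch_size, metric)
    ss = assign_secondary_structure(structure, ss_method)
    return PreparedTarget(target_id, structure, records, surface, patches, ss,
                          pssm_profiles or {}, epitope or set())


def derive_tables(targets: Sequence[PreparedTarget],
                  pseudocount: float = DEFAULT_PSEUDOCOUNT,
                  ) -> tuple[PropensityTable, EnergyTable]:
    prop = derive_propensity_table(
        [(t.target_id, t.records, t.surface, t.epitope) for t in targets],
        pseudocount)
    energy = derive_energy_table(
        [(t.target_id, t.records) for t in targets])
    return prop, energy


def _featurize(target: PreparedTarget, prop: PropensityTable,
               energy: EnergyTable, contact_cutoff: float, metric: str,
               with_labels: bool, allow_self: bool) -> FeaturizedTarget:
    return featurize_target(
        target.target_id, target.structure, target.records, target.surface,
        target.patches, target.ss, prop, energy, target.pssm_profiles,
        target.epitope if with_labels else None,
        contact_cutoff, metric, allow_self)


def train_model(targets: Sequence[PreparedTarget],
                config: SVRConfig = SVRConfig(),
                pseudocount: float = DEFAULT_PSEUDOCOUNT,
                contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                metric: str = "sidechain_center") -> SVRModel:
    """Fit the final model on every training target pooled (tables, scaler
    and SVR all derived from the full corpus)."""
    prop, energy = derive_tables(targets, pseudocount)
    feats = [_featurize(t, prop, energy, contact_cutoff, metric,
                        with_labels=True, allow_self=True) for t in targets]
    raw = np.vstack([f.raw_features for f in feats])
    labels = np.concatenate([f.labels for f in feats])
    scaler = FeatureScaler().fit(raw)
    sv, coef, b = fit_svr_arrays(scaler.transform(raw), labels, config)
    probe = next(iter(targets)).records[targets[0].surface[0]].probe_radius
    return SVRModel(sv, coef, b, config, scaler, prop, energy,
                    patch_size=targets[0].patches[0].patch_size,
                    probe_radius=probe, contact_cutoff=contact_cutoff,
                    metric=metric)


def predict_patch_scores(model: SVRModel,
                         raw_features: np.ndarray) -> np.ndarray:
    """Scale raw patch attributes with the model's own scaler, evaluate the
    SVR, and clamp to [0, 1]: the predicted fraction of epitopic residues."""
    raw_features = np.atleast_2d(np.asarray(raw_features, dtype=float))
    if raw_features.shape[1] != 6:
        raise ValueError(f"expected 6 features, got {raw_features.shape[1]}")
    return np.clip(model.predict(model.scaler.transform(raw_features)), 0.0, 1.0)


# ---------------------------------------------------------------------------
# residue aggregation and ranking

@dataclass
class ResidueScoreTable:
    """Per surface residue: mean score over containing patches, patch count
    and rank (1 = best). Sorted by descending score with deterministic
    lexicographic tie-breaking."""

    table: pd.DataFrame  # columns residue, score, n_patches, rank

    @property
    def ranking(self) -> list[ResidueId]:
        return list(self.table["residue"])

    def score(self, rid: ResidueId) -> float:
        row = self.table.loc[self.table["residue"] == rid, "score"]
        return float(row.iloc[0])


def residue_scores(patches: Sequence[SurfacePatch],
                   patch_scores: np.ndarray) -> ResidueScoreTable:
    """Average patch scores over all patches containing each residue."""
    if len(patches) != len(patch_scores):
        raise ValueError("one score per patch required")
    sums: dict[ResidueId, float] = {}
    counts: dict[ResidueId, int] = {}
    for patch, score in zip(patches, patch_scores):
        for rid in patch.members:
            sums[rid] = sums.get(rid, 0.0) + float(score)
            counts[rid] = counts.get(rid, 0) + 1
    rids = sorted(sums, key=lambda r: (-sums[r] / counts[r], r))
    df = pd.DataFrame({
        "residue": rids,
        "score": [sums[r] / counts[r] for r in rids],
        "n_patches": [counts[r] for r in rids],
        "rank": np.arange(1, len(rids) + 1),
    })
    return ResidueScoreTable(df)


def rank_and_select(table: ResidueScoreTable,
                    fraction_of_surface: float) -> set[ResidueId]:
    """Top ceil(fraction * N) residues of the ranking."""
    if not 0 <= fraction_of_surface <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    n = len(table.ranking)
    k = math.ceil(fraction_of_surface * n)
    return set(table.ranking[:k])


def predict_target(model: SVRModel, target: PreparedTarget,
                   allow_self: bool = False) -> ResidueScoreTable:
    """Full prediction path for one antigen: featurize with the model's
    tables, score patches, aggregate to residue scores."""
    feats = _featurize(target, model.propensity_table, model.energy_table,
                       model.contact_cutoff, model.metric,
                       with_labels=False, allow_self=allow_self)
    scores = predict_patch_scores(model, feats.raw_features)
    return residue_scores(feats.patches, scores)


# ---------------------------------------------------------------------------
# leave-one-out grid search

def loo_fold_data(targets: Sequence[PreparedTarget],
                  pseudocount: float = DEFAULT_PSEUDOCOUNT,
                  contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                  metric: str = "sidechain_center"):
    """Precompute, for each held-out target, the fold's training matrix,
    fitted scaler and held-out features (tables re-derived without the
    held-out target). Shared by every grid point."""
    folds = []
    for i, held_out in enumerate(targets):
        train = [t for j, t in enumerate(targets) if j != i]
        prop, energy = derive_tables(train, pseudocount)
        # training members are in the tables' provenance by construction;
        # hygiene only forbids scoring the held-out target with them
        train_feats = [_featurize(t, prop, energy, contact_cutoff, metric,
                                  True, allow_self=True) for t in train]
        raw = np.vstack([f.raw_features for f in train_feats])
        labels = np.concatenate([f.labels for f in train_feats])
        scaler = FeatureScaler().fit(raw)
        test_feat = _featurize(held_out, prop, energy, contact_cutoff, metric,
                               False, allow_self=False)
        folds.append({
            "held_out": held_out,
            "x_train": scaler.transform(raw),
            "y_train": labels,
            "scaler": scaler,
            "x_test": scaler.transform(test_feat.raw_features),
            "patches": test_feat.patches,
        })
    return folds


def _fold_auc(fold, config: SVRConfig,
              step_fraction: float = 0.01) -> float | None:
    held_out: PreparedTarget = fold["held_out"]
    positives = held_out.epitope & set(held_out.surface)
    if not positives or len(positives) == len(held_out.surface):
        logger.warning("target %s has no epitopic (or no non-epitopic) "
                       "surface residues; excluded", held_out.target_id)
        return None
    sv, coef, b = fit_svr_arrays(fold["x_train"], fold["y_train"], config)
    model_like = SVRModel(sv, coef, b, config, fold["scaler"],
                          PropensityTable({}, {}, {}, 1.0),
                          EnergyTable({}))
    scores = np.clip(model_like.predict(fold["x_test"]), 0.0, 1.0)
    table = residue_scores(fold["patches"], scores)
    curve = evaluate.roc_from_ranking(table.ranking, held_out.epitope,
                                      step_fraction)
    return curve.auc


def loo_mean_auc(targets: Sequence[PreparedTarget] | list,
                 config: SVRConfig,
                 folds=None, step_fraction: float = 0.01,
                 **fold_kwargs) -> float:
    """Per-target leave-one-out mean AUC at one hyperparameter point."""
    if folds is None:
        folds = loo_fold_data(targets, **fold_kwargs)
    aucs = [_fold_auc(f, config, step_fraction) for f in folds]
    return evaluate.mean_auc(aucs, undefined="exclude")


def grid_search_loo(targets: Sequence[PreparedTarget],
                    grid: Sequence[SVRConfig] | None = None,
                    step_fraction: float = 0.01,
                    **fold_kwargs) -> tuple[SVRConfig, pd.DataFrame]:
    """Evaluate every grid point by per-target leave-one-out mean AUC and
    return the winner (ties broken by smallest c, then g, then p) together
    with the full results table."""
    if grid is None:
        grid = default_grid()
    if len(targets) < 2:
        raise ValueError("leave-one-out needs at least two targets")
    folds = loo_fold_data(targets, **fold_kwargs)
    rows = []
    for cfg in grid:
        mean = loo_mean_auc(targets, cfg, folds=folds,
                            step_fraction=step_fraction)
        rows.append({"c": cfg.c, "g": cfg.g, "p": cfg.p, "mean_auc": mean})
    df = pd.DataFrame(rows)
    best_idx = df.sort_values(["mean_auc", "c", "g", "p"],
                              ascending=[False, True, True, True]).index[0]
    best = grid[int(best_idx)]
    return best, df
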