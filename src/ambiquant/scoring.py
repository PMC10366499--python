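"""The overall contamination score: a PCA-weighted feature combination.

Five bounded features — empty-droplet scaled slope sum, inverted max
secant distance, *doubled* inverted secant sd (so its [0, 0.5] range
maps to [0, 1]), inverted AUC percentage, and average percent counts
ambient as a fraction — are combined linearly into a single score in
[0, 1]: 0 is perfect signal-to-noise, 1 is all noise.  The weights are
derived once from a simulated calibration sweep spanning ambient levels
5-4900: the six standardized metrics (the five features plus the number
of ambient genes) are decomposed by PCA, and the absolute first-PC
loadings of the five combined features, renormalized to sum 1, become
the weights.  The number of ambient genes informs the PCA but carries no
weight in the combination (it is unbounded and depth-sensitive).

A versioned default model derived at 10 levels x 50 replicates ships
with the package; ``derive_weights`` reproduces or re-derives it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .ambient import MetricSet
from .errors import DegenerateSweepError, ParameterError

__all__ = [
    "ScoreModel",
    "FEATURE_NAMES",
    "transform_features",
    "derive_weights",
    "overall_score",
    "default_model",
]

FEATURE_NAMES = (
    "empty_droplet_slope_sum",
    "inverted_max_secant",
    "inverted_secant_sd_x2",
    "inverted_auc_pct",
    "frac_counts_ambient",
)

_PCA_FEATURE_NAMES = FEATURE_NAMES + ("n_ambient_genes",)


@dataclass
class ScoreModel:
    """Non-negative weights (sum 1) over the five combined features."""

    weights: np.ndarray
    provenance: dict
    pca_explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.pca_explained_variance = np.asarray(self.pca_explained_variance, dtype=float)
        if self.weights.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} weights")
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")

    def to_dict(self) -> dict:
        return {
            "feature_names": list(FEATURE_NAMES),
            "weights": self.weights.tolist(),
            "pca_explained_variance": self.pca_explained_variance.tolist(),
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=1)
        return path

    @classmethod
    def from_dict(cls, record: dict) -> "ScoreModel":
        return cls(
            weights=np.asarray(record["weights"], dtype=float),
            provenance=record.get("provenance", {}),
            pca_explained_variance=np.asarray(
                record.get("pca_explained_variance", []), dtype=float
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ScoreModel":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))


def default_model() -> ScoreModel:
    """The packaged default score model (versioned JSON)."""
    text = resources.files("ambiquant.data").joinpath("default_score_model.json").read_text()
    return ScoreModel.from_dict(json.loads(text))


def transform_features(metrics: MetricSet) -> np.ndarray:
    """The 5 combined features of a MetricSet, each bounded in [0, 1].

    The inverted secant sd is doubled and the average percent counts
    ambient divided by 100 so that every feature shares the [0, 1]
    range.
    """
    vec = np.array(
        [
            metrics.empty_droplet_slope_sum,
            metrics.inverted_max_secant,
            2.0 * metrics.inverted_secant_sd,
            metrics.inverted_auc_pct,
            metrics.avg_pct_counts_ambient / 100.0,
        ]
    )
    if (vec < -1e-9).any() or (vec > 1 + 1e-9).any():
        raise ValueError(f"transformed features outside [0, 1]: {vec}")
    return np.clip(vec, 0.0, 1.0)


def _pca_feature_matrix(metric_sets) -> np.ndarray:
    rows = [
        np.concatenate([transform_features(ms), [float(ms.n_ambient_genes)]])
        for ms in metric_sets
    ]
    return np.asarray(rows)


def derive_weights(metric_sets, ambient_levels=None, provenance: dict | None = None) -> ScoreModel:
    """Derive score weights by PCA over a simulated metric matrix.

    ``metric_sets`` should come from a calibration sweep spanning a wide
    ambient range (5-4900); at least 100 datasets and two distinct
    levels are required.  The standardized 6-feature matrix is
    decomposed; if the first component's loadings on the five combined
    features do not share a sign the sweep is too degenerate (all
    metrics co-increase with ambient level on any informative sweep) and
    an error suggests widening the ambient-level span.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    metric_sets = list(metric_sets)
    if len(metric_sets) < 100:
        raise ParameterError(
            f"need at least 100 simulated datasets to derive weights, got {len(metric_sets)}"
        )
    if ambient_levels is not None and len(set(np.asarray(ambient_levels).tolist())) < 2:
        raise DegenerateSweepError(
            "calibration sweep uses a single ambient level; widen the ambient-level span"
        )
    X = _pca_feature_matrix(metric_sets)
    stds = X.std(axis=0)
    if (stds < 1e-12).any():
        flat = [_PCA_FEATURE_NAMES[i] for i in np.nonzero(stds < 1e-12)[0]]
        raise DegenerateSweepError(
            f"degenerate covariance: feature(s) {flat} constant across the sweep; "
            "widen the ambient-level span"
        )
    Z = StandardScaler().fit_transform(X)
    pca = PCA(n_components=X.shape[1])
    pca.fit(Z)
    loadings = pca.components_[0]
    five = loadings[: len(FEATURE_NAMES)]
    if not ((five > 0).all() or (five < 0).all()):
        raise DegenerateSweepError(
            "first-PC loadings of the combined features do not share a sign; "
            "the sweep is too noisy or narrow — widen the ambient-level span"
        )
    weights = np.abs(five)
    weights /= weights.sum()
    return ScoreModel(
        weights=weights,
        provenance=dict(provenance or {}, n_datasets=len(metric_sets)),
        pca_explained_variance=pca.explained_variance_ratio_,
    )


def overall_score(metrics: MetricSet, model: ScoreModel) -> float:
    """Weighted combination of the transformed features, clamped to [0, 1]."""
    raw = float(model.weights @ transform_features(metrics))
    clamped = min(max(raw, 0.0), 1.0)
    if abs(clamped - raw) > 1e-6:
        warnings.warn(
            f"overall score {raw} clamped to {clamped}", UserWarning, stacklevel=2
        )
    return clamped
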