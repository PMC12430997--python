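"""Unsupervised seedling-health assessment with a one-class SVM.

Most seedlings in a paddy are healthy, so health assessment is framed
as novelty detection: a one-class SVM (OCSVM) encloses the bulk of the
15-dimensional feature cloud and flags seedlings outside the boundary
as anomalies (label −1).  ``ν`` upper-bounds the fraction of training
points allowed outside the boundary; ``γ`` sets the kernel bandwidth.

Because no labels exist, hyperparameters are chosen by an internal
clustering criterion: every (kernel, ν, γ) combination in the grid is
fitted, the silhouette score of the resulting {inlier, outlier}
partition is computed in the same standardized feature space the SVM
saw, and the best-silhouette combination wins.  Combinations that
produce a single class have no defined silhouette and can never win.

Separability diagnostics accompany the labels: a per-feature
Bhattacharyya distance between the two groups (univariate-Gaussian
closed form, on raw feature values so magnitudes are interpretable) and
a seeded 2-D t-SNE projection for visual inspection.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from sklearn.svm import OneClassSVM

from .features import FeatureTable

__all__ = [
    "GridSearchSpace",
    "AnomalyResult",
    "standardize",
    "fit_ocsvm",
    "bhattacharyya",
    "silhouette",
    "embed_2d",
]

_VAR_FLOOR = 1e-12
_POLY_DEGREE = 3   # fixed; recorded in every grid_log entry
_POLY_COEF0 = 1.0  # inhomogeneous kernel: (γ⟨x,y⟩ + 1)³ stays well
                   # conditioned at small γ, unlike the homogeneous form
_MAX_ITER = 2_000_000
_NU_SLACK = 0.05  # documented tolerance on the trained-outlier fraction


def _outlier_labels(nu: float, dec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels from decision values, with the ν-property enforced.

    The ν-property of the one-class SVM upper-bounds the training
    outlier fraction by ν, but that holds at the *exact* dual optimum;
    at solver precision, support vectors sit numerically on the
    boundary and a raw sign read of the decision values can flag far
    more than ν·n points (grossly so for degenerate fits, e.g. a linear
    kernel on z-scored features, which surround the origin the SVM
    separates from).  Outliers are therefore the most negative decision
    values, at most ⌊(ν + 0.05)·n⌋ of them — ν plus a fixed, documented
    tolerance that admits boundary support vectors without letting a
    degenerate fit flag an arbitrary fraction.  A degenerate fit then
    yields a small arbitrary partition with a poor silhouette that the
    model selection discards on its own.

    Decision values of trimmed points are snapped to 0 so
    sign(decision) agrees with the label for every seedling.
    """
    n = dec.shape[0]
    budget = int(np.floor((nu + _NU_SLACK) * n))
    labels = np.ones(n, dtype=int)
    neg = np.nonzero(dec < 0)[0]
    if neg.size > budget:
        keep = neg[np.argsort(dec[neg])[:budget]]
    else:
        keep = neg
    labels[keep] = -1
    adjusted = dec.copy()
    adjusted[(labels == 1) & (dec < 0)] = 0.0
    return labels, adjusted


@dataclass
class GridSearchSpace:
    """OCSVM hyperparameter grid.

    Defaults are the full automated grid: all three kernels,
    ν ∈ {0.01, 0.05, 0.1} and γ ∈ {0.01, 0.1, auto, scale}.  γ has no
    effect on the linear kernel; those duplicates are fitted once and
    logged as collapsed.
    """

    kernels: tuple[str, ...] = ("linear", "rbf", "poly")
    nus: tuple[float, ...] = (0.01, 0.05, 0.1)
    gammas: tuple = (0.01, 0.1, "auto", "scale")

    def combinations(self):
        for kernel in self.kernels:
            for nu in self.nus:
                for gamma in self.gammas:
                    yield kernel, nu, gamma


@dataclass
class AnomalyResult:
    """Labels (+1 inlier / −1 outlier), decision values and the search log."""

    labels: np.ndarray
    decision_values: np.ndarray
    best_params: dict
    silhouette: float
    grid_log: list[dict] = field(default_factory=list)

    @property
    def outlier_fraction(self) -> float:
        return float((self.labels == -1).mean())

    def to_frame(self, instance_ids=None) -> pd.DataFrame:
        n = len(self.labels)
        ids = instance_ids if instance_ids is not None else np.arange(1, n + 1)
        return pd.DataFrame({"instance_id": ids, "label": self.labels,
                             "decision_value": self.decision_values})


def standardize(table: FeatureTable) -> FeatureTable:
    """Per-column z-score (population sd); constant columns pass
    through unchanged and are flagged.  Column (mean, sd) are stored on
    the returned table for the inverse mapping."""
    if table.scaling_state != "raw":
        raise ValueError("table is already standardized")
    if table.n < 2:
        raise ValueError("standardization needs at least 2 rows")
    df = table.df.copy()
    stats: dict[str, dict] = {}
    for name in table.feature_names:
        col = df[name].to_numpy(dtype=np.float64)
        mean, sd = float(col.mean()), float(col.std(ddof=0))
        if sd == 0.0:
            stats[name] = {"mean": mean, "sd": sd, "constant": True}
            continue
        df[name] = (col - mean) / sd
        stats[name] = {"mean": mean, "sd": sd, "constant": False}
    return FeatureTable(df=df, feature_names=list(table.feature_names),
                        scaling_state="standardized", column_stats=stats,
                        glcm_config=table.glcm_config)


def fit_ocsvm(table: FeatureTable, space: GridSearchSpace | None = None,
              seed: int = 0) -> AnomalyResult:
    """Silhouette-guided grid search over one-class SVMs.

    Every grid combination is fitted on all rows; the silhouette score
    of its {+1, −1} partition (Euclidean, in the standardized feature
    space) ranks the combinations.  One-class outcomes score −inf.
    Ties keep the earlier combination in grid order (kernels as listed,
    then ν ascending, then γ as listed).  The fit itself is
    deterministic; ``seed`` is recorded for provenance of downstream
    stochastic steps.
    """
    space = space or GridSearchSpace()
    if table.scaling_state != "standardized":
        raise ValueError("fit_ocsvm expects a standardized FeatureTable")
    X = table.matrix()
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 seedlings, got {n}")

    best = None
    grid_log: list[dict] = []
    seen_linear_nu: dict[float, dict] = {}
    for kernel, nu, gamma in space.combinations():
        entry = {"kernel": kernel, "nu": nu, "gamma": gamma,
                 "degree": _POLY_DEGREE if kernel == "poly" else None}
        if kernel == "linear" and nu in seen_linear_nu:
            # gamma is inert for the linear kernel: reuse the first fit
            prev = seen_linear_nu[nu]
            entry.update(silhouette=prev["silhouette"],
                         n_outliers=prev["n_outliers"], collapsed=True)
            grid_log.append(entry)
            continue
        model = OneClassSVM(kernel=kernel, nu=nu, gamma=gamma,
                            degree=_POLY_DEGREE, coef0=_POLY_COEF0,
                            max_iter=_MAX_ITER)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X)
            dec = model.decision_function(X).ravel()
        labels, dec = _outlier_labels(nu, dec)
        n_out = int((labels == -1).sum())
        if n_out == 0 or n_out == n:
            sil = -math.inf
        else:
            sil = float(silhouette_score(X, labels, metric="euclidean"))
        entry.update(silhouette=sil, n_outliers=n_out, collapsed=False)
        grid_log.append(entry)
        if kernel == "linear":
            seen_linear_nu[nu] = entry
        if sil > -math.inf and (best is None or sil > best["silhouette"]):
            best = {"kernel": kernel, "nu": nu, "gamma": gamma,
                    "silhouette": sil, "labels": labels,
                    "decision_values": dec}

    if best is None:
        raise RuntimeError(
            "every grid combination produced a single class; no separation "
            "found — consider a larger ν"
        )
    return AnomalyResult(
        labels=best["labels"].astype(int),
        decision_values=best["decision_values"],
        best_params={"kernel": best["kernel"], "nu": best["nu"],
                     "gamma": best["gamma"],
                     "degree": _POLY_DEGREE if best["kernel"] == "poly" else None,
                     "seed": seed},
        silhouette=best["silhouette"],
        grid_log=grid_log,
    )


def bhattacharyya(table: FeatureTable, labels: np.ndarray) -> pd.DataFrame:
    """Per-feature Bhattacharyya distance between the two label groups.

    Univariate-Gaussian closed form per feature, computed on RAW
    (unstandardized) values so the distances reflect the features'
    native scales:

        D = ¼·ln(¼·(σ₁²/σ₂² + σ₂²/σ₁² + 2)) + ¼·(μ₁−μ₂)²/(σ₁²+σ₂²)

    Variances are floored at 1e−12.  If either group has fewer than two
    members the distance is undefined: NaN with the ``undefined`` column
    set.
    """
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {-1, 1}:
        raise ValueError("labels must be +1/-1")
    X = table.matrix()
    a, b = X[labels == 1], X[labels == -1]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be nonempty")
    undefined = len(a) < 2 or len(b) < 2
    records = []
    for j, name in enumerate(table.feature_names):
        if undefined:
            records.append({"feature": name, "distance": np.nan,
                            "undefined": True})
            continue
        m1, m2 = a[:, j].mean(), b[:, j].mean()
        v1 = max(a[:, j].var(ddof=0), _VAR_FLOOR)
        v2 = max(b[:, j].var(ddof=0), _VAR_FLOOR)
        d = (0.25 * math.log(0.25 * (v1 / v2 + v2 / v1 + 2.0))
             + 0.25 * (m1 - m2) ** 2 / (v1 + v2))
        records.append({"feature": name, "distance": d, "undefined": False})
    return pd.DataFrame.from_records(records)


def silhouette(table: FeatureTable, labels: np.ndarray) -> float:
    """Mean silhouette of the label partition, Euclidean distances in
    the table's feature space (use the standardized table to score what
    the SVM saw).  Singleton-class samples score 0 per convention."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs two nonempty classes")
    if len(labels) < 3:
        raise ValueError("silhouette needs at least 3 samples")
    return float(silhouette_score(table.matrix(), labels, metric="euclidean"))


def embed_2d(table: FeatureTable, seed: int = 0) -> np.ndarray | None:
    """Seeded 2-D t-SNE projection of the standardized features.

    Perplexity is min(30, (n−1)/3).  Purely for visualization/export —
    no decision feeds off it.  Returns None (with a warning) for n < 5.
    """
    n = table.n
    if n < 5:
        warnings.warn(f"too few samples for a 2-D embedding (n={n}); skipped")
        return None
    perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(table.matrix())
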