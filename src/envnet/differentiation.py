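"""Feature assembly, PCA embedding and the three differentiation criteria.

The differentiation question — can antagonistic and mutualistic networks
be told apart? — is operationalized on a feature table of the three
null-corrected architecture metrics, optionally joined by the
environmental covariate, through three tests:

* **separability** — cross-validated accuracy of a Gaussian discriminant
  on the scaled features, with a label-permutation p-value and the
  overlap of the per-class 68% coverage ellipses on the PC1–PC2 plane.
  The default discriminant is quadratic (class-specific covariances):
  opposite-sign environment–architecture couplings make the two classes
  differ primarily in covariance structure, which no linear boundary can
  exploit; a linear discriminant remains available for comparison.
* **scalability** — whether sub-class centroids in PC space sit closer to
  other sub-classes of their own interaction class than to those of the
  other class.
* **specificity** — the separability analysis repeated on ER-randomized
  architectures (metrics recomputed with fresh null ensembles).  The
  scaler is fit on the randomized feature table, never the empirical one:
  randomization makes the class label a collider between environment and
  metrics, and importing the empirical scaling effectively conditions on
  it, manufacturing a spurious environment–metric association.  The
  scaling reference is therefore an explicit, mandatory field of the
  scaler so the mistake cannot happen silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.decomposition import PCA as _SKPCA
from sklearn.model_selection import RepeatedStratifiedKFold, cross_val_score

from envnet.errors import ParameterError, ValidationError
from envnet.network_io import DEFAULT_ENV_VAR, NetworkSet
from envnet.null_models import er_randomize, null_corrected_metrics
from envnet.spectral import ArchitectureMetrics

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("rel_err_l1_cm", "rel_err_l1_er", "rel_err_l2_er")

_SEED_MAX = 2**31 - 1


@dataclass
class FeatureTable:
    """Feature matrix (id-indexed) plus class and sub-class labels."""

    data: pd.DataFrame
    class_labels: pd.Series
    sub_class_labels: pd.Series
    env_var: str | None = None  # None when environment not included
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValidationError("feature table must not contain missing values")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


def assemble_features(network_set: NetworkSet,
                      metrics: dict[str, ArchitectureMetrics],
                      include_environment: bool = True,
                      env_var: str = DEFAULT_ENV_VAR) -> FeatureTable:
    """Build the feature table from per-network metrics.

    Networks with an undefined λ2 relative error (NaN) are excluded and
    the count logged.  With ``include_environment`` a missing environment
    value is an error listing the offending ids.
    """
    rows, classes, subs, excluded, missing_env = [], [], [], [], []
    for net in network_set:
        am = metrics[net.id]
        vals = [am.rel_err_l1_cm, am.rel_err_l1_er, am.rel_err_l2_er]
        if any(np.isnan(v) for v in vals):
            excluded.append(net.id)
            continue
        if include_environment:
            if env_var not in net.env:
                missing_env.append(net.id)
                continue
            vals.append(net.env[env_var])
        rows.append(pd.Series(vals, name=net.id))
        classes.append(net.interaction_class)
        subs.append(net.sub_class)
    if missing_env:
        raise ValidationError(f"missing {env_var!r} for networks: {missing_env}")
    if not rows:
        raise ValidationError("no networks left after exclusions")
    if excluded:
        logger.info("excluded %d networks with undefined metrics: %s",
                    len(excluded), excluded)
    cols = list(METRIC_COLUMNS) + ([env_var] if include_environment else [])
    data = pd.DataFrame(rows)
    data.columns = cols
    idx = data.index
    return FeatureTable(
        data=data,
        class_labels=pd.Series(classes, index=idx, name="interaction_class"),
        sub_class_labels=pd.Series(subs, index=idx, name="sub_class"),
        env_var=env_var if include_environment else None,
        n_excluded=len(excluded),
    )


# ---------------------------------------------------------------------------
# Scaling


@dataclass
class Scaler:
    """Column-wise standardization (sample sd, ddof=1) with a declared reference."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    reference: str  # "empirical" or "randomized"


def fit_scaler(table: FeatureTable | pd.DataFrame, reference: str = "empirical") -> Scaler:
    df = table.data if isinstance(table, FeatureTable) else table
    if len(df) < 2:
        raise ValidationError("need at least 2 rows to fit a scaler")
    if reference not in ("empirical", "randomized"):
        raise ParameterError("reference must be 'empirical' or 'randomized'")
    means = df.mean(axis=0).to_numpy(dtype=float)
    sds = df.std(axis=0, ddof=1).to_numpy(dtype=float)
    bad = [c for c, s in zip(df.columns, sds) if not s > 0]
    if bad:
        raise ValidationError(f"constant column(s): {bad}")
    return Scaler(columns=list(df.columns), means=means, sds=sds, reference=reference)


def apply_scaler(scaler: Scaler, table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    df = table.data if isinstance(table, FeatureTable) else table
    if list(df.columns) != scaler.columns:
        raise ValidationError("column mismatch between scaler and table")
    return (df - scaler.means) / scaler.sds


# ---------------------------------------------------------------------------
# PCA embedding


@dataclass
class Embedding:
    scores: pd.DataFrame  # networks x components (PC1, PC2, ...)
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray


def pca(scaled: pd.DataFrame, n_components: int = 2) -> Embedding:
    """PCA of an already-scaled table; component signs are fixed by making
    each component's largest-magnitude loading positive."""
    if n_components > scaled.shape[1]:
        raise ParameterError("n_components exceeds the number of columns")
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(scaled.to_numpy(dtype=float))
    load = model.components_.T.copy()  # features x components
    for k in range(load.shape[1]):
        j = int(np.argmax(np.abs(load[:, k])))
        if load[j, k] < 0:
            load[:, k] *= -1.0
            scores[:, k] *= -1.0
    names = [f"PC{i + 1}" for i in range(n_components)]
    return Embedding(
        scores=pd.DataFrame(scores, index=scaled.index, columns=names),
        loadings=pd.DataFrame(load, index=scaled.columns, columns=names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# Coverage ellipses


@dataclass
class EllipseParams:
    """Mean-centered covariance ellipse at a chi-square(2) coverage level."""

    center: np.ndarray
    semi_axes: np.ndarray  # major, minor
    angle: float  # radians, orientation of the major axis
    level: float

    def to_polygon(self, n_vertices: int = 256):
        from shapely.geometry import Polygon

        t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        xy = np.column_stack([self.semi_axes[0] * np.cos(t), self.semi_axes[1] * np.sin(t)])
        c, s = np.cos(self.angle), np.sin(self.angle)
        R = np.array([[c, -s], [s, c]])
        return Polygon(xy @ R.T + self.center)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test for an (n, 2) array of points."""
        P = np.asarray(points, dtype=float) - self.center
        c, s = np.cos(self.angle), np.sin(self.angle)
        R = np.array([[c, s], [-s, c]])
        Q = P @ R.T
        return (Q[:, 0] / self.semi_axes[0]) ** 2 + (Q[:, 1] / self.semi_axes[1]) ** 2 <= 1.0


def coverage_ellipse(scores: np.ndarray, level: float = 0.68) -> EllipseParams:
    """Bivariate-normal coverage ellipse of a 2-column score matrix.

    Radius scale is the chi-square(2 df) quantile of ``level``, so for
    normal scores the ellipse contains ≈ level of the points.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValidationError("scores must be an (n, 2) matrix")
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 points")
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12:
        raise ValidationError("degenerate (singular-covariance) ellipse")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    r2 = chi2.ppf(level, df=2)
    return EllipseParams(
        center=center,
        semi_axes=np.sqrt(evals * r2),
        angle=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        level=level,
    )


def ellipse_overlap(e1: EllipseParams, e2: EllipseParams) -> float:
    """Jaccard overlap (intersection area / union area) of two ellipses."""
    p1, p2 = e1.to_polygon(), e2.to_polygon()
    union = p1.union(p2).area
    return float(p1.intersection(p2).area / union) if union > 0 else 0.0


# ---------------------------------------------------------------------------
# Separability


@dataclass
class SeparabilityReport:
    cv_accuracy: float
    p_value: float
    ellipse_overlap: float
    ellipses: dict[str, EllipseParams]
    classifier: str
    n_permutations: int
    seed: int
    scaler_reference: str
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.array([]))

    def summary(self) -> str:
        return (f"cv_accuracy={self.cv_accuracy:.3f} p={self.p_value:.4f} "
                f"ellipse_overlap={self.ellipse_overlap:.3f} "
                f"classifier={self.classifier} scaling={self.scaler_reference}")


def _make_classifier(name: str):
    if name == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=0.01)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    raise ParameterError(f"unknown classifier {name!r}")


def _cv_accuracy(X, y, classifier: str, n_splits: int, random_state: int,
                 n_repeats: int = 3) -> float:
    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats,
                                 random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QDA collinearity warnings on permuted labels
        return float(cross_val_score(_make_classifier(classifier), X, y, cv=cv).mean())


def separability(table: FeatureTable, seed: int = 0, classifier: str = "qda",
                 n_splits: int = 5, n_permutations: int = 199,
                 scaler: Scaler | None = None, level: float = 0.68) -> SeparabilityReport:
    """Quantified class separability of a feature table.

    Stratified k-fold cross-validated accuracy of a Gaussian discriminant
    on the scaled features; permutation p-value from label shuffles; 68%
    coverage-ellipse overlap on the PC1–PC2 plane.  Deterministic under
    ``seed``.  If no ``scaler`` is given one is fit on ``table`` itself
    (reference "empirical").
    """
    y = table.class_labels.to_numpy()
    levels, counts = np.unique(y, return_counts=True)
    if len(levels) < 2:
        raise ValidationError("separability needs both interaction classes")
    if counts.min() < 5:
        raise ValidationError("each class needs at least 5 networks")
    if scaler is None:
        scaler = fit_scaler(table)
    scaled = apply_scaler(scaler, table)
    X = scaled.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(_SEED_MAX))
    obs = _cv_accuracy(X, y, classifier, n_splits, cv_seed)
    n_hits = 0
    for _ in range(n_permutations):
        y_perm = rng.permutation(y)
        acc = _cv_accuracy(X, y_perm, classifier, n_splits, int(rng.integers(_SEED_MAX)))
        if acc >= obs:
            n_hits += 1
    p_value = (1 + n_hits) / (1 + n_permutations)
    emb = pca(scaled, n_components=2)
    ellipses = {}
    for cls in levels:
        pts = emb.scores.to_numpy()[y == cls]
        ellipses[str(cls)] = coverage_ellipse(pts, level=level)
    ov = ellipse_overlap(*[ellipses[str(c)] for c in levels[:2]])
    return SeparabilityReport(
        cv_accuracy=obs, p_value=float(p_value), ellipse_overlap=ov,
        ellipses=ellipses, classifier=classifier, n_permutations=n_permutations,
        seed=seed, scaler_reference=scaler.reference,
        explained_variance_ratio=emb.explained_variance_ratio,
    )


# ---------------------------------------------------------------------------
# Scalability


@dataclass
class ScalabilityReport:
    table: pd.DataFrame  # per sub-class: class, n, same_class_dist, other_class_dist
    passes: bool
    degenerate: bool = False  # single sub-class per class: class-level distances only


def scalability_report(table: FeatureTable, min_members: int = 3,
                       scaler: Scaler | None = None) -> ScalabilityReport:
    """Centroid geometry of sub-classes on the PC1–PC2 plane.

    Passes when every sub-class centroid is on average closer to
    same-class sub-class centroids than to other-class ones.
    """
    if scaler is None:
        scaler = fit_scaler(table)
    emb = pca(apply_scaler(scaler, table), n_components=2)
    df = emb.scores.copy()
    df["sub_class"] = table.sub_class_labels.to_numpy()
    df["interaction_class"] = table.class_labels.to_numpy()
    counts = df.groupby("sub_class").size()
    small = counts[counts < min_members].index.tolist()
    if small:
        warnings.warn(f"sub-classes excluded with < {min_members} members: {small}",
                      stacklevel=2)
        df = df[~df["sub_class"].isin(small)]
    cent = df.groupby(["interaction_class", "sub_class"])[["PC1", "PC2"]].mean()
    cls_of = {sub: cls for cls, sub in cent.index}
    degenerate = any(
        sum(1 for s in cls_of.values() if s == c) < 2 for c in set(cls_of.values())
    )
    rows = []
    for (cls, sub), xy in cent.iterrows():
        same, other = [], []
        for (cls2, sub2), xy2 in cent.iterrows():
            if sub2 == sub:
                continue
            dist = float(np.linalg.norm(xy.to_numpy() - xy2.to_numpy()))
            (same if cls2 == cls else other).append(dist)
        rows.append({
            "sub_class": sub, "interaction_class": cls,
            "n": int(counts[sub]),
            "same_class_dist": float(np.mean(same)) if same else np.nan,
            "other_class_dist": float(np.mean(other)) if other else np.nan,
        })
    out = pd.DataFrame(rows).set_index("sub_class")
    with_both = out.dropna(subset=["same_class_dist", "other_class_dist"])
    passes = bool(len(with_both) > 0 and
                  (with_both["same_class_dist"] < with_both["other_class_dist"]).all())
    if degenerate:
        warnings.warn("single sub-class per class: report degenerates to "
                      "class-level distances", stacklevel=2)
        passes = bool((out["other_class_dist"].notna()).all())
    return ScalabilityReport(table=out, passes=passes, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Specificity


def randomized_metrics(network_set: NetworkSet, R: int = 100,
                       seed: int = 0) -> dict[str, ArchitectureMetrics]:
    """One ER randomization per network, metrics with fresh null ensembles."""
    ss = np.random.SeedSequence(seed)
    out = {}
    for net, child in zip(network_set, ss.spawn(len(network_set))):
        s1, s2 = (int(x) for x in child.generate_state(2) % _SEED_MAX)
        B_rand = er_randomize(net.incidence, seed=s1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[net.id] = null_corrected_metrics(B_rand, R=R, seed=s2)
    return out


def specificity_test(network_set: NetworkSet, R: int = 100, seed: int = 0,
                     env_var: str = DEFAULT_ENV_VAR, classifier: str = "qda",
                     n_permutations: int = 199,
                     scaling_reference: str = "randomized") -> SeparabilityReport:
    """Separability of ER-randomized architectures (expected ≈ chance).

    Metrics are recomputed on one ER replicate per network with fresh
    null ensembles, joined with the (unchanged) environment values, and
    scaled on the randomized table itself.  ``scaling_reference=
    "empirical"`` is accepted only as a documented anti-pattern flag for
    demonstrating the collider artefact; it scales the randomized table
    with a scaler fit on the *empirical* metrics.
    """
    rng = np.random.default_rng(seed)
    s_metrics, s_sep = (int(x) for x in rng.integers(_SEED_MAX, size=2))
    metrics = randomized_metrics(network_set, R=R, seed=s_metrics)
    rand_table = assemble_features(network_set, metrics, include_environment=True,
                                   env_var=env_var)
    if scaling_reference == "randomized":
        scaler = fit_scaler(rand_table, reference="randomized")
    elif scaling_reference == "empirical":
        warnings.warn(
            "scaling randomized features on the empirical table conditions on a "
            "collider and can manufacture spurious separation; provided for "
            "demonstration only", stacklevel=2)
        s_emp = int(rng.integers(_SEED_MAX))
        emp_metrics = {net.id: null_corrected_metrics(net, R=R, seed=s_emp + k)
                       for k, net in enumerate(network_set)}
        emp_table = assemble_features(network_set, emp_metrics,
                                      include_environment=True, env_var=env_var)
        scaler = fit_scaler(emp_table, reference="empirical")
    else:
        raise ParameterError("scaling_reference must be 'randomized' or 'empirical'")
    return separability(rand_table, seed=s_sep, classifier=classifier,
                        n_permutations=n_permutations, scaler=scaler)
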