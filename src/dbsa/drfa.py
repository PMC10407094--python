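"""Decorrelated ranked feature analysis: phenotype separation and rescue.

Behavioral features are heavily inter-correlated, so group separation is
measured in a decorrelated space: features are standardized on the pooled
reference data, the pooled covariance is eigendecomposed, and samples are
expressed in whitened component coordinates (each retained component scaled
to unit pooled variance).  In that space

* the **Discrimination Index** is the mean held-out accuracy of a
  nearest-centroid classifier over repeated stratified subsamples, expressed
  on a 50–100% scale (50 = indistinguishable groups), with a group-label
  permutation p-value;
* the **Recovery Index** locates a treated test group on the axis joining the
  model and wild-type centroids: each sample is orthogonally projected to a
  scalar coordinate scaled so the model mean sits at 0 and the wild-type mean
  at 1, and recovery is the clamped mean test coordinate as a percentage,
  with a one-sided Welch t-test (test vs model projections) as its p-value.

Whitening makes the recovery coordinate invariant under invertible affine
maps of the raw features (when no component is discarded), so the index
measures biology, not units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import FeatureMatrix, Selector
from .signatures import welch_t

_EIGVAL_TOL = 1e-10


@dataclass
class DRFSpace:
    """Standardization + decorrelating transform fitted on two reference groups.

    ``transform`` rows are orthonormal eigenvectors of the pooled covariance
    of standardized features; ``component_variances`` are the matching
    eigenvalues.  :meth:`project` returns whitened coordinates (unit pooled
    variance per component).  ``discriminant_order`` re-ranks the retained
    components by |between-group Welch t| descending, for display.
    """

    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    transform: np.ndarray
    component_variances: np.ndarray
    n_components: int
    discriminant_order: np.ndarray

    def project(self, values: np.ndarray) -> np.ndarray:
        """Whitened decorrelated coordinates of raw feature rows."""
        z = (np.atleast_2d(values) - self.center) / self.scale
        return (z @ self.transform.T) / np.sqrt(self.component_variances)

    def project_matrix(self, matrix: FeatureMatrix, selector: Selector | None = None) -> np.ndarray:
        values = matrix.values if selector is None else matrix.group_values(selector)
        if list(matrix.feature_names) != self.feature_names:
            raise ValueError("matrix feature names do not match the fitted space")
        return self.project(values)


def fit_drf_space(
    matrix: FeatureMatrix,
    group_a: Selector,
    group_b: Selector,
    variance_kept: float = 0.95,
) -> DRFSpace:
    """Fit the decorrelated feature space on two reference groups.

    Standardizes per feature on the pooled samples of both groups,
    eigendecomposes the pooled covariance, keeps the smallest number of
    components whose eigenvalues reach ``variance_kept`` of the non-null
    spectrum, and re-ranks the retained components by between-group
    separation.
    """
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must be in (0, 1]")
    mask_a = matrix.select(group_a)
    mask_b = matrix.select(group_b)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each reference group needs at least 3 samples")
    if np.any(mask_a & mask_b):
        raise ValueError("reference groups overlap")
    pooled = matrix.values[mask_a | mask_b]
    center = pooled.mean(axis=0)
    scale = pooled.std(axis=0, ddof=1)
    scale = np.where(scale == 0, 1.0, scale)  # constant features carry no variance anyway
    z = (pooled - center) / scale
    cov = np.cov(z, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals > _EIGVAL_TOL * max(evals[0], 1.0)
    if not positive.any():
        raise ValueError("all features are constant; no decorrelated space exists")
    evals, evecs = evals[positive], evecs[:, positive]
    cum = np.cumsum(evals) / evals.sum()
    k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    k = min(k, evals.size)
    space = DRFSpace(
        feature_names=list(matrix.feature_names),
        center=center,
        scale=scale,
        transform=evecs[:, :k].T,
        component_variances=evals[:k],
        n_components=k,
        discriminant_order=np.arange(k),
    )
    scores_a = space.project(matrix.values[mask_a])
    scores_b = space.project(matrix.values[mask_b])
    t, _ = welch_t(scores_a, scores_b)
    space.discriminant_order = np.argsort(-np.abs(t), kind="stable")
    return space


@dataclass
class GroupCloud:
    """2D summary of one group on two chosen decorrelated components.

    ``sd_axes`` are the principal SD half-axes of the group's 2D scatter,
    ``orientation_rad`` the angle of the first axis; ``sem_axes`` are the
    same axes divided by sqrt(n).  A single-sample group has undefined
    spread (``single_sample`` flag, NaN axes).
    """

    label: str
    mean_2d: np.ndarray
    sd_axes: np.ndarray
    orientation_rad: float
    sem_axes: np.ndarray
    n: int
    single_sample: bool = False


def cloud_summary(
    matrix: FeatureMatrix,
    group: Selector,
    space: DRFSpace,
    display_components: tuple[int, int] = (0, 1),
    label: str = "",
) -> GroupCloud:
    """Mean and SD/SEM ellipses of a group on two discriminant-ranked components."""
    coords = space.project_matrix(matrix, group)
    if coords.shape[0] == 0:
        raise ValueError("group selector matched no samples")
    comp = [space.discriminant_order[c] for c in display_components]
    if max(display_components) >= space.n_components:
        raise ValueError("display component index out of range")
    xy = coords[:, comp]
    n = xy.shape[0]
    mean = xy.mean(axis=0)
    if n < 2:
        return GroupCloud(label, mean, np.array([np.nan, np.nan]), 0.0,
                          np.array([np.nan, np.nan]), n, single_sample=True)
    cov2 = np.cov(xy, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov2))
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    sd_axes = np.sqrt(evals)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return GroupCloud(label, mean, sd_axes, angle, sd_axes / np.sqrt(n), n)


@dataclass
class DiscriminationResult:
    """Held-out separability of two groups in the decorrelated space."""

    index_percent: float
    p_value: float | None
    n_subsamples: int
    holdout_fraction: float
    classifier_spec: str
    seed: int
    clouds: tuple[GroupCloud, GroupCloud]


def _holdout_accuracies(
    ya: np.ndarray,
    yb: np.ndarray,
    n_subsamples: int,
    holdout_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Nearest-centroid held-out accuracy per stratified random split."""
    na, nb = ya.shape[0], yb.shape[0]
    ta = min(max(1, round(na * holdout_fraction)), na - 1)
    tb = min(max(1, round(nb * holdout_fraction)), nb - 1)
    if na < 2 or nb < 2:
        raise ValueError("holdout needs at least 2 samples per group")
    accs = np.empty(n_subsamples)
    for i in range(n_subsamples):
        pa = rng.permutation(na)
        pb = rng.permutation(nb)
        ca = ya[pa[ta:]].mean(axis=0)
        cb = yb[pb[tb:]].mean(axis=0)
        test = np.vstack([ya[pa[:ta]], yb[pb[:tb]]])
        da = ((test - ca) ** 2).sum(axis=1)
        db = ((test - cb) ** 2).sum(axis=1)
        pred_a = da < db
        correct = pred_a[:ta].sum() + (~pred_a[ta:]).sum()
        accs[i] = correct / (ta + tb)
    return accs


def discrimination_index(
    matrix: FeatureMatrix,
    group_a: Selector,
    group_b: Selector,
    space: DRFSpace,
    n_subsamples: int = 200,
    holdout_fraction: float = 0.5,
    seed: int = 0,
) -> DiscriminationResult:
    """Mean held-out nearest-centroid accuracy between two groups, as 50–100%.

    For each subsample a stratified ``holdout_fraction`` is held out, group
    centroids are fitted on the remaining samples in decorrelated
    coordinates, and the held-out samples are classified by the nearer
    centroid.  The index is ``max(50, 100 * mean accuracy)``.
    """
    if n_subsamples < 1:
        raise ValueError("n_subsamples must be >= 1")
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    ya = space.project_matrix(matrix, group_a)
    yb = space.project_matrix(matrix, group_b)
    rng = np.random.default_rng(seed)
    accs = _holdout_accuracies(ya, yb, n_subsamples, holdout_fraction, rng)
    index = max(50.0, 100.0 * float(accs.mean()))
    two_d = space.n_components >= 2
    clouds = (
        cloud_summary(matrix, group_a, space, (0, 1) if two_d else (0, 0), label="group_a"),
        cloud_summary(matrix, group_b, space, (0, 1) if two_d else (0, 0), label="group_b"),
    )
    return DiscriminationResult(
        index_percent=index,
        p_value=None,
        n_subsamples=n_subsamples,
        holdout_fraction=holdout_fraction,
        classifier_spec="nearest-centroid (Euclidean) on whitened decorrelated components",
        seed=seed,
        clouds=clouds,
    )


def discrimination_pvalue(
    matrix: FeatureMatrix,
    group_a: Selector,
    group_b: Selector,
    variance_kept: float = 0.95,
    n_subsamples: int = 200,
    holdout_fraction: float = 0.5,
    n_label_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, DiscriminationResult]:
    """Permutation p for the Discrimination Index under label exchange.

    Group labels are shuffled over the pooled samples (group sizes fixed) and
    the full index is recomputed per permutation.  The pooled
    standardization/eigendecomposition does not depend on the labels, so the
    fitted space is shared across permutations.
    ``p = (1 + #{perm >= observed}) / (n_label_permutations + 1)``.
    """
    if n_label_permutations < 1:
        raise ValueError("n_label_permutations must be >= 1")
    space = fit_drf_space(matrix, group_a, group_b, variance_kept)
    observed = discrimination_index(
        matrix, group_a, group_b, space, n_subsamples, holdout_fraction, seed
    )
    ya = space.project_matrix(matrix, group_a)
    yb = space.project_matrix(matrix, group_b)
    pooled = np.vstack([ya, yb])
    na = ya.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    exceed = 0
    for _ in range(n_label_permutations):
        perm = rng.permutation(pooled.shape[0])
        pa, pb = pooled[perm[:na]], pooled[perm[na:]]
        accs = _holdout_accuracies(pa, pb, n_subsamples, holdout_fraction, rng)
        if max(50.0, 100.0 * accs.mean()) >= observed.index_percent:
            exceed += 1
    p = (1 + exceed) / (n_label_permutations + 1)
    observed.p_value = p
    return p, observed


@dataclass
class RecoveryResult:
    """Position of a treated test group on the model-to-wild-type axis.

    ``projections`` maps group role -> scalar coordinates (model mean at 0,
    wild-type mean at 1 exactly); ``segment`` holds the two group means in
    decorrelated coordinates.
    """

    recovery_percent: float
    p_value: float | None
    projections: dict[str, np.ndarray]
    segment: tuple[np.ndarray, np.ndarray]


def recovery_index(
    matrix: FeatureMatrix,
    model_group: Selector,
    wt_group: Selector,
    test_group: Selector,
    space: DRFSpace,
) -> RecoveryResult:
    """Recovery of a test group along the model-to-wild-type axis.

    Every sample is orthogonally projected onto the segment joining the two
    reference centroids in whitened decorrelated coordinates;
    ``recovery_percent = 100 * clamp(mean test coordinate, 0, 1)``.
    """
    y_model = space.project_matrix(matrix, model_group)
    y_wt = space.project_matrix(matrix, wt_group)
    y_test = space.project_matrix(matrix, test_group)
    for name, y in (("model", y_model), ("wt", y_wt), ("test", y_test)):
        if y.shape[0] == 0:
            raise ValueError(f"{name} group matched no samples")
    mu_model = y_model.mean(axis=0)
    mu_wt = y_wt.mean(axis=0)
    axis = mu_wt - mu_model
    norm2 = float(axis @ axis)
    if norm2 == 0:
        raise ValueError("model and wild-type group means coincide; recovery axis undefined")

    def coord(y: np.ndarray) -> np.ndarray:
        return (y - mu_model) @ axis / norm2

    projections = {"model": coord(y_model), "wt": coord(y_wt), "test": coord(y_test)}
    recovery = 100.0 * float(np.clip(projections["test"].mean(), 0.0, 1.0))
    result = RecoveryResult(
        recovery_percent=recovery,
        p_value=None,
        projections=projections,
        segment=(mu_model, mu_wt),
    )
    if y_test.shape[0] >= 2 and y_model.shape[0] >= 2:
        result.p_value = recovery_pvalue(result)
    return result


def recovery_pvalue(result: RecoveryResult) -> float:
    """One-sided Welch t-test of test vs model projections, toward wild-type."""
    test = result.projections["test"]
    model = result.projections["model"]
    if test.size < 2 or model.size < 2:
        raise ValueError("recovery p-value needs >= 2 samples in test and model groups")
    if test.var(ddof=1) == 0 and model.var(ddof=1) == 0:
        # degenerate projections: identical means are the exact null
        if np.isclose(test.mean(), model.mean()):
            return 1.0
        return 1.0 if test.mean() < model.mean() else float(np.finfo(float).tiny)
    p = stats.ttest_ind(test, model, equal_var=False, alternative="greater").pvalue
    return float(max(p, np.finfo(float).tiny))  # keep p in (0, 1] under underflow
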