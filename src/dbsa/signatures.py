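"""Differential behavioral profiles and disease target signatures.

A contrast profile is one Welch t statistic per behavioral feature for a
two-group comparison (disease model vs wild-type control, or drug-treated vs
vehicle).  The disease signature is the ordered pair of feature sets most
increased and most decreased in the model relative to control — the "target
phenotype" that library compounds are screened against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import FeatureMatrix, Selector


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch (unequal-variance) t per column, ``a`` minus ``b``.

    Returns ``(t, zero_variance)``: columns with zero variance in *both*
    groups get ``t = 0`` and a raised flag instead of an undefined statistic.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("Welch t needs at least 2 samples per group")
    se2 = a.var(axis=0, ddof=1) / na + b.var(axis=0, ddof=1) / nb
    degenerate = se2 == 0.0
    t = np.where(
        degenerate,
        0.0,
        (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(np.where(degenerate, 1.0, se2)),
    )
    return t, degenerate


@dataclass
class ContrastProfile:
    """Per-feature Welch t-scores for a two-group contrast.

    Positive t means higher in ``group_a`` (the case: model or drug-treated).
    ``zero_variance`` flags features constant within both groups, which are
    assigned ``t = 0`` rather than an undefined value.
    """

    feature_names: list[str]
    t_scores: np.ndarray
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.feature_names = [str(f).strip() for f in self.feature_names]
        self.t_scores = np.asarray(self.t_scores, dtype=float)
        if self.zero_variance is None:
            self.zero_variance = np.zeros(len(self.feature_names), dtype=bool)
        self.zero_variance = np.asarray(self.zero_variance, dtype=bool)
        if self.t_scores.shape != (len(self.feature_names),):
            raise ValueError("t_scores length must match feature_names")
        if not np.all(np.isfinite(self.t_scores)):
            raise ValueError("t_scores must be finite")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("each group needs at least 2 samples")

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a_label,
            "group_b": self.group_b_label,
            "n_a": int(self.n_a),
            "n_b": int(self.n_b),
            "features": self.feature_names,
            "t_scores": [float(t) for t in self.t_scores],
            "zero_variance": [bool(z) for z in self.zero_variance],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ContrastProfile":
        return cls(
            feature_names=list(payload["features"]),
            t_scores=np.asarray(payload["t_scores"], dtype=float),
            group_a_label=payload["group_a"],
            group_b_label=payload["group_b"],
            n_a=int(payload["n_a"]),
            n_b=int(payload["n_b"]),
            zero_variance=np.asarray(payload.get("zero_variance", []), dtype=bool)
            if payload.get("zero_variance") is not None
            else None,
        )


def _selector_label(selector: Selector, fallback: str) -> str:
    if isinstance(selector, dict):
        return ",".join(f"{k}={v}" for k, v in selector.items()) or fallback
    return fallback


def compute_feature_tscores(
    matrix: FeatureMatrix,
    group_a: Selector,
    group_b: Selector,
    label_a: str | None = None,
    label_b: str | None = None,
) -> ContrastProfile:
    """One Welch t statistic per feature, ``group_a`` minus ``group_b``.

    Both selectors must match at least 2 samples and be disjoint.  Features
    with zero variance in both groups receive ``t = 0`` with a flag.
    """
    mask_a = matrix.select(group_a)
    mask_b = matrix.select(group_b)
    for name, mask in (("group_a", mask_a), ("group_b", mask_b)):
        if mask.sum() == 0:
            raise ValueError(f"{name} selector matched no samples")
        if mask.sum() < 2:
            raise ValueError(f"{name} has fewer than 2 samples ({int(mask.sum())})")
    if np.any(mask_a & mask_b):
        raise ValueError("group selections overlap")
    t, flags = welch_t(matrix.values[mask_a], matrix.values[mask_b])
    return ContrastProfile(
        feature_names=list(matrix.feature_names),
        t_scores=t,
        group_a_label=label_a or _selector_label(group_a, "group_a"),
        group_b_label=label_b or _selector_label(group_b, "group_b"),
        n_a=int(mask_a.sum()),
        n_b=int(mask_b.sum()),
        zero_variance=flags,
    )


@dataclass
class DiseaseSignature:
    """Ordered increased/decreased feature sets of the target phenotype.

    ``increased`` holds (feature, t) pairs with t > 0, most increased first;
    ``decreased`` holds pairs with t < 0, most decreased first.  Both are
    ordered by |t| descending and are disjoint.  ``selection`` records the
    rule used (``k_per_tail`` and ``min_abs_t``).
    """

    increased: list[tuple[str, float]]
    decreased: list[tuple[str, float]]
    selection: dict

    def __post_init__(self) -> None:
        self.increased = [(str(f).strip(), float(t)) for f, t in self.increased]
        self.decreased = [(str(f).strip(), float(t)) for f, t in self.decreased]
        inc_names = {f for f, _ in self.increased}
        dec_names = {f for f, _ in self.decreased}
        if inc_names & dec_names:
            raise ValueError(f"increased/decreased overlap: {sorted(inc_names & dec_names)}")
        if any(t <= 0 for _, t in self.increased):
            raise ValueError("increased set contains non-positive t-scores")
        if any(t >= 0 for _, t in self.decreased):
            raise ValueError("decreased set contains non-negative t-scores")
        for pairs in (self.increased, self.decreased):
            mags = [abs(t) for _, t in pairs]
            if any(x < y for x, y in zip(mags, mags[1:])):
                raise ValueError("signature sets must be ordered by |t| descending")

    @property
    def increased_names(self) -> list[str]:
        return [f for f, _ in self.increased]

    @property
    def decreased_names(self) -> list[str]:
        return [f for f, _ in self.decreased]

    def to_dict(self) -> dict:
        return {
            "increased": [{"feature": f, "t": t} for f, t in self.increased],
            "decreased": [{"feature": f, "t": t} for f, t in self.decreased],
            "selection": dict(self.selection),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DiseaseSignature":
        return cls(
            increased=[(e["feature"], e["t"]) for e in payload["increased"]],
            decreased=[(e["feature"], e["t"]) for e in payload["decreased"]],
            selection=dict(payload.get("selection", {})),
        )


def build_disease_signature(
    profile: ContrastProfile,
    k_per_tail: int = 20,
    min_abs_t: float = 0.0,
) -> DiseaseSignature:
    """Extract the top increased and decreased features of a contrast.

    Up to ``k_per_tail`` features per tail, requiring t >= ``min_abs_t`` for
    the increased set and t <= -``min_abs_t`` for the decreased set (features
    with t exactly 0 never qualify).  Raises if both sets come out empty.
    """
    if k_per_tail < 1:
        raise ValueError("k_per_tail must be >= 1")
    if min_abs_t < 0:
        raise ValueError("min_abs_t must be non-negative")
    t = profile.t_scores
    order = np.argsort(-np.abs(t), kind="stable")
    increased: list[tuple[str, float]] = []
    decreased: list[tuple[str, float]] = []
    for idx in order:
        score = float(t[idx])
        if score > 0 and score >= min_abs_t and len(increased) < k_per_tail:
            increased.append((profile.feature_names[idx], score))
        elif score < 0 and -score >= min_abs_t and len(decreased) < k_per_tail:
            decreased.append((profile.feature_names[idx], score))
    if not increased and not decreased:
        raise ValueError("no features qualify for the signature (both tails empty)")
    return DiseaseSignature(
        increased=increased,
        decreased=decreased,
        selection={
            "rule": "top-k per tail by |t|",
            "k_per_tail": int(k_per_tail),
            "min_abs_t": float(min_abs_t),
            "contrast": f"{profile.group_a_label} vs {profile.group_b_label}",
        },
    )
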