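"""Two-tailed enrichment scoring of drug profiles against a disease signature.

The core statistic is a weighted Kolmogorov–Smirnov running sum (the GSEA
enrichment score) evaluated, in a single pass over one ranked drug profile,
for both the disease-increased and disease-decreased feature sets.  A drug
that pushes disease-increased features to the bottom of its own ranking and
disease-decreased features to the top gets a positive *reversal score*

    reversal = (ES_decreased - ES_increased) / 2

when the two extrema have opposite signs (the same-sign rule zeroes the score
when both sets pile up on the same end of the ranking, which indicates a
global shift rather than a reversal).  Significance is non-parametric: random
feature-set pairs of the same sizes are drawn from the ranked features and
the observed reversal is compared against that permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .signatures import ContrastProfile, DiseaseSignature


@dataclass
class DrugRanking:
    """A drug-dose profile as features ranked by drug-vs-vehicle t-score.

    ``ordered_scores`` is non-increasing; ties keep the original feature
    order (the enrichment score depends on rank order, so the tie-break is
    part of the contract).
    """

    drug_id: str
    dose_mg_per_kg: float
    ordered_features: list[str]
    ordered_scores: np.ndarray

    def __post_init__(self) -> None:
        self.ordered_features = [str(f).strip() for f in self.ordered_features]
        self.ordered_scores = np.asarray(self.ordered_scores, dtype=float)
        if len(self.ordered_features) != self.ordered_scores.size:
            raise ValueError("ordered_features and ordered_scores must have equal length")
        if len(set(self.ordered_features)) != len(self.ordered_features):
            raise ValueError(f"duplicate features in ranking for {self.drug_id}")
        if np.any(np.diff(self.ordered_scores) > 0):
            raise ValueError("ordered_scores must be non-increasing")

    @classmethod
    def from_profile(cls, profile: ContrastProfile, drug_id: str, dose: float) -> "DrugRanking":
        order = np.argsort(-profile.t_scores, kind="stable")
        return cls(
            drug_id=drug_id,
            dose_mg_per_kg=float(dose),
            ordered_features=[profile.feature_names[i] for i in order],
            ordered_scores=profile.t_scores[order],
        )

    @property
    def n(self) -> int:
        return len(self.ordered_features)


@dataclass
class EnrichmentCurve:
    """Running enrichment score along the ranking, with its upper envelope.

    ``theoretical_max`` is the curve the same feature set would trace if its
    members occupied the top ranks with their own weights (largest first) —
    the best-case enrichment for that set on this profile.
    """

    running_es: np.ndarray
    theoretical_max: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.running_es.size + 1)


@dataclass
class EnrichmentResult:
    drug_id: str
    dose_mg_per_kg: float
    es_increased: float
    es_decreased: float
    reversal_score: float
    p_value: float | None = None
    curve_increased: EnrichmentCurve | None = None
    curve_decreased: EnrichmentCurve | None = None
    n_permutations: int | None = None
    seed: int | None = None


def _batch_enrichment(weights: np.ndarray, hits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Running sums and signed extrema for a batch of hit masks.

    ``weights`` is ``|score|^p`` per rank (length n); ``hits`` is a boolean
    ``(B, n)`` membership mask.  A hit at rank i adds its weight share, a
    miss subtracts ``1/(n - m)``; the extremum is the running value of
    largest magnitude (first occurrence on ties, which pins the sign by
    position in the degenerate case where the curve maximum and minimum tie
    in magnitude).  When every hit weight is zero the hits fall back to
    uniform shares.
    """
    hits = np.atleast_2d(hits)
    n = weights.size
    m = hits.sum(axis=1)
    if np.any(m == 0):
        raise ValueError("empty feature set")
    denom = hits @ weights
    uniform = hits / m[:, None]
    weighted = hits * (weights / np.where(denom == 0, 1.0, denom)[:, None])
    hit_steps = np.where((denom == 0)[:, None], uniform, weighted)
    n_miss = n - m
    miss_steps = np.where(hits, 0.0, -1.0 / np.where(n_miss == 0, 1, n_miss)[:, None])
    running = np.cumsum(hit_steps + miss_steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    extrema = running[np.arange(running.shape[0]), idx]
    return running, extrema


def running_enrichment_score(
    ranking: DrugRanking,
    feature_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[EnrichmentCurve, float]:
    """Weighted KS running sum of one feature set over one drug ranking.

    Returns the curve (running score and theoretical-maximum envelope) and
    the signed extremum.  ``weight_exponent = 0`` gives the classic
    unweighted KS form; ``1`` weights hits by |t-score|.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be non-negative")
    members = {str(f).strip() for f in feature_set}
    if not members:
        raise ValueError("empty feature set")
    positions = {f: i for i, f in enumerate(ranking.ordered_features)}
    missing = sorted(members - positions.keys())
    if missing:
        raise KeyError(f"feature set members absent from ranking: {missing}")
    hits = np.zeros(ranking.n, dtype=bool)
    hits[[positions[f] for f in members]] = True
    weights = np.abs(ranking.ordered_scores) ** weight_exponent
    running, extrema = _batch_enrichment(weights, hits[None, :])

    # Best case: the set's own weights at the top ranks, largest first.
    m = int(hits.sum())
    top_weights = np.sort(weights[hits])[::-1]
    denom = top_weights.sum()
    top_steps = top_weights / denom if denom > 0 else np.full(m, 1.0 / m)
    if m < ranking.n:
        miss = np.full(ranking.n - m, -1.0 / (ranking.n - m))
        envelope = np.cumsum(np.concatenate([top_steps, miss]))
    else:
        envelope = np.cumsum(top_steps)
    curve = EnrichmentCurve(running_es=running[0], theoretical_max=envelope)
    return curve, float(extrema[0])


def _resolve_sets(
    ranking: DrugRanking, signature: DiseaseSignature
) -> tuple[list[str], list[str]]:
    present = set(ranking.ordered_features)
    inc = [f for f in signature.increased_names if f in present]
    dec = [f for f in signature.decreased_names if f in present]
    dropped = sorted(
        (set(signature.increased_names) | set(signature.decreased_names)) - present
    )
    if dropped:
        warnings.warn(
            f"{len(dropped)} signature features absent from ranking of "
            f"{ranking.drug_id} and dropped: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=3,
        )
    if not inc and not dec:
        raise ValueError("no signature feature resolves in the drug ranking")
    return inc, dec


def combine_reversal(es_increased: float, es_decreased: float, same_sign_zero: bool = True) -> float:
    """Symmetric reversal statistic from the two set extrema."""
    if same_sign_zero and es_increased * es_decreased > 0:
        return 0.0
    return (es_decreased - es_increased) / 2.0


def gsea2_reversal_score(
    ranking: DrugRanking,
    signature: DiseaseSignature,
    weight_exponent: float = 1.0,
    same_sign_zero: bool = True,
) -> EnrichmentResult:
    """Two-tailed enrichment of a disease signature in one drug profile.

    Both signature sets are scored on the same ranking in one pass; a
    positive reversal score means the drug moves disease-increased features
    down and disease-decreased features up.  Signature features missing from
    the ranking are dropped with a warning.
    """
    inc, dec = _resolve_sets(ranking, signature)
    es_inc = 0.0
    es_dec = 0.0
    curve_inc = curve_dec = None
    if inc:
        curve_inc, es_inc = running_enrichment_score(ranking, inc, weight_exponent)
    if dec:
        curve_dec, es_dec = running_enrichment_score(ranking, dec, weight_exponent)
    return EnrichmentResult(
        drug_id=ranking.drug_id,
        dose_mg_per_kg=ranking.dose_mg_per_kg,
        es_increased=es_inc,
        es_decreased=es_dec,
        reversal_score=combine_reversal(es_inc, es_dec, same_sign_zero),
        curve_increased=curve_inc,
        curve_decreased=curve_dec,
    )


def permuted_reversal_scores(
    ranking: DrugRanking,
    size_increased: int,
    size_decreased: int,
    n_permutations: int,
    rng: np.random.Generator,
    weight_exponent: float = 1.0,
    same_sign_zero: bool = True,
) -> np.ndarray:
    """Reversal scores for random disjoint set pairs of the given sizes."""
    n = ranking.n
    k1, k2 = size_increased, size_decreased
    if k1 + k2 > n:
        raise ValueError(
            f"cannot draw disjoint sets of sizes {k1}+{k2} from {n} ranked features"
        )
    weights = np.abs(ranking.ordered_scores) ** weight_exponent
    # random permutations: first k1 ranks -> increased stand-in, next k2 -> decreased
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    rows = np.arange(n_permutations)[:, None]
    inc_hits = np.zeros((n_permutations, n), dtype=bool)
    dec_hits = np.zeros((n_permutations, n), dtype=bool)
    if k1:
        inc_hits[rows, order[:, :k1]] = True
    if k2:
        dec_hits[rows, order[:, k1 : k1 + k2]] = True
    scores = np.zeros(n_permutations)
    es_inc = np.zeros(n_permutations)
    es_dec = np.zeros(n_permutations)
    if k1:
        _, es_inc = _batch_enrichment(weights, inc_hits)
    if k2:
        _, es_dec = _batch_enrichment(weights, dec_hits)
    scores = (es_dec - es_inc) / 2.0
    if same_sign_zero:
        scores[es_inc * es_dec > 0] = 0.0
    return scores


def permutation_pvalue(
    ranking: DrugRanking,
    signature: DiseaseSignature,
    observed: EnrichmentResult,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    weight_exponent: float = 1.0,
    same_sign_zero: bool = True,
) -> float:
    """One-sided permutation p toward reversal, with the add-one estimator.

    Random disjoint feature-set pairs of the observed sizes are drawn
    uniformly from the ranked features and scored identically; the drug
    ranking stays fixed so the null reflects signature membership only.
    ``p = (1 + #{perm >= observed}) / (n_permutations + 1)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inc, dec = _resolve_sets(ranking, signature)
    null = permuted_reversal_scores(
        ranking, len(inc), len(dec), n_permutations, rng, weight_exponent, same_sign_zero
    )
    return float((1 + np.sum(null >= observed.reversal_score)) / (n_permutations + 1))


@dataclass
class ScreenSettings:
    """Knobs of a library screen; every stochastic step derives from ``seed``."""

    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    same_sign_zero: bool = True


SCREEN_COLUMNS = [
    "drug_id",
    "dose_mg_per_kg",
    "stratum",
    "es_increased",
    "es_decreased",
    "reversal_score",
    "p_value",
    "fdr_q",
    "rank",
]


@dataclass
class ScreenTable:
    """Ranked screen of one stratum: one row per drug-dose with scores and p.

    Rows are ordered by rank: reversal score descending, permutation p
    ascending, then drug id / dose lexicographic as the final tie-break.
    ``fdr_q`` is the Benjamini–Hochberg adjusted p within the stratum.
    """

    table: pd.DataFrame
    stratum: str

    def __post_init__(self) -> None:
        missing = [c for c in SCREEN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"screen table missing columns {missing}")
        ranks = np.sort(self.table["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.table) + 1)):
            raise ValueError("rank must be a permutation of 1..n_rows")


def screen_library(
    library: Sequence[DrugRanking],
    signature: DiseaseSignature,
    settings: ScreenSettings | None = None,
    stratum: str = "all",
) -> ScreenTable:
    """Score and rank every drug-dose profile against the disease signature.

    Deterministic given ``settings.seed``: per-profile permutation streams
    are spawned from one seed sequence in library order.
    """
    if not library:
        raise ValueError("empty drug library")
    settings = settings or ScreenSettings()
    keys = [(r.drug_id, r.dose_mg_per_kg) for r in library]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (drug_id, dose) in stratum {stratum!r}: {dupes}")

    children = np.random.SeedSequence(settings.seed).spawn(len(library))
    rows = []
    for ranking, child in zip(library, children):
        result = gsea2_reversal_score(
            ranking, signature, settings.weight_exponent, settings.same_sign_zero
        )
        result.n_permutations = settings.n_permutations
        p = permutation_pvalue(
            ranking,
            signature,
            result,
            settings.n_permutations,
            np.random.default_rng(child),
            settings.weight_exponent,
            settings.same_sign_zero,
        )
        rows.append(
            {
                "drug_id": ranking.drug_id,
                "dose_mg_per_kg": ranking.dose_mg_per_kg,
                "stratum": stratum,
                "es_increased": result.es_increased,
                "es_decreased": result.es_decreased,
                "reversal_score": result.reversal_score,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr_q"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values(
        by=["reversal_score", "p_value", "drug_id", "dose_mg_per_kg"],
        ascending=[False, True, True, True],
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ScreenTable(table=table[SCREEN_COLUMNS], stratum=stratum)


@dataclass
class ConsistencyResult:
    """Cross-stratum agreement of a screen: which drug-doses replicate.

    ``kept`` are the (drug_id, dose) pairs called in *every* stratum;
    ``flags`` is the per-stratum significance grid behind that call.
    """

    kept: list[tuple[str, float]]
    flags: pd.DataFrame
    alpha: float
    use_q: bool


def consistency_filter(
    tables: Mapping[str, ScreenTable],
    alpha: float = 0.05,
    use_q: bool = False,
) -> ConsistencyResult:
    """Keep drug-doses predicted as reversers in every stratum.

    A pair passes a stratum when its reversal score is positive and its
    permutation p (or BH q with ``use_q``) is at most ``alpha``; the filter
    intersects the calls across strata.  Pairs absent from some stratum are
    dropped with a warning.
    """
    if len(tables) < 2:
        raise ValueError("consistency filter needs at least 2 strata")
    sig_col = "fdr_q" if use_q else "p_value"
    per_stratum: dict[str, pd.Series] = {}
    for name, screen in tables.items():
        t = screen.table.set_index(["drug_id", "dose_mg_per_kg"])
        per_stratum[name] = (t[sig_col] <= alpha) & (t["reversal_score"] > 0)
    flags = pd.DataFrame(per_stratum)
    incomplete = flags.index[flags.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"{len(incomplete)} drug-dose pairs absent from some strata were dropped: "
            f"{sorted(incomplete.tolist())[:5]}",
            stacklevel=2,
        )
        flags = flags.dropna()
    kept_mask = flags.astype(bool).all(axis=1)
    kept = sorted((str(d), float(dose)) for d, dose in flags.index[kept_mask])
    return ConsistencyResult(kept=kept, flags=flags.astype(bool), alpha=alpha, use_q=use_q)
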