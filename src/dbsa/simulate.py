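"""Synthetic behavioral cohorts and drug libraries with known ground truth.

The generator emulates the shape of a high-content phenotyping dataset: many
correlated numeric features per animal, a disease effect on a subset of
features in the model group, and a multi-dose drug library screened in
wild-type animals against a shared vehicle group.  Features follow a
low-rank Gaussian factor model: feature j loads on factor ``j mod
n_factors`` with a common loading, plus independent noise, so the expected
correlation between two features sharing a factor is
``factor_strength^2 / (factor_strength^2 + noise_sd^2)`` and 0 otherwise.
The disease effect shifts affected features by ``effect_size`` marginal
standard deviations, alternating sign so that half the affected features
increase and half decrease (latency-like features flip sign in real data).

Drug archetypes, before noise:

* ``reverser``  — ``-strength x`` the disease effect on affected features;
* ``mimic``     — ``+strength x`` the disease effect;
* ``partial``   — reversal restricted to a fraction of the affected features;
* ``null``      — no effect.

Dose scales the archetype strength linearly up to the largest dose listed
for the drug, so higher doses give stronger (not qualitatively different)
profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import FeatureMatrix
from .enrichment import DrugRanking
from .signatures import welch_t

ARCHETYPES = ("reverser", "mimic", "null", "partial")


@dataclass
class DrugSpec:
    """One library drug: archetype, doses and effect strength."""

    drug_id: str
    doses: list[float]
    archetype: str = "null"
    reversal_strength: float = 1.0
    partial_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}; choose from {ARCHETYPES}")
        if not self.doses:
            raise ValueError(f"drug {self.drug_id} lists no doses")
        if not 0 <= self.reversal_strength <= 1:
            raise ValueError("reversal_strength must be in [0, 1]")
        if not 0 < self.partial_fraction <= 1:
            raise ValueError("partial_fraction must be in (0, 1]")


def default_library_spec() -> list[DrugSpec]:
    """A small screening library: planted reversers among mimics and nulls."""
    lib = [
        DrugSpec("reverser_full", [10.0, 30.0], "reverser", 1.0),
        DrugSpec("reverser_partial", [10.0, 30.0], "partial", 1.0, partial_fraction=0.5),
        DrugSpec("mimic_full", [10.0, 30.0], "mimic", 1.0),
    ]
    lib += [DrugSpec(f"null_{i:02d}", [10.0], "null") for i in range(1, 13)]
    return lib


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic screen.

    Defaults emulate a single-age, single-sex behavioral cohort: a few
    hundred correlated features, a disease effect of one marginal SD on a
    subset of them, and mid-teens group sizes.
    """

    n_features: int = 300
    n_affected: int = 40
    effect_size: float = 1.0
    n_factors: int = 10
    factor_strength: float = 0.5
    n_per_group: int = 20
    noise_sd: float = 1.0
    library: list[DrugSpec] = field(default_factory=default_library_spec)
    seed: int = 0
    sex: str = "F"
    age_months: float = 6.0

    def __post_init__(self) -> None:
        if self.n_affected > self.n_features:
            raise ValueError("n_affected cannot exceed n_features")
        if self.n_factors >= self.n_features:
            raise ValueError("infeasible correlation spec: n_factors must be < n_features")
        if min(self.n_features, self.n_affected, self.n_factors, self.n_per_group) < 1:
            raise ValueError("all sizes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0 or self.factor_strength < 0:
            raise ValueError("effect_size and factor_strength must be non-negative")

    @property
    def feature_names(self) -> list[str]:
        return [f"feat_{i:04d}" for i in range(self.n_features)]

    @property
    def marginal_sd(self) -> float:
        return math.sqrt(self.factor_strength**2 + self.noise_sd**2)


@dataclass
class SyntheticTruth:
    """Planted ground truth behind a synthetic cohort and library."""

    affected_features: list[str]
    true_effects: np.ndarray  # signed raw-unit shift per feature (0 off the affected set)
    drug_effects: dict[tuple[str, float], np.ndarray]
    archetypes: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "affected_features": self.affected_features,
            "true_effects": [float(v) for v in self.true_effects],
            "archetypes": dict(self.archetypes),
            "drug_effects": {
                f"{drug}@{dose:g}": [float(v) for v in vec]
                for (drug, dose), vec in self.drug_effects.items()
            },
        }


def _factor_samples(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Correlated Gaussian draws under the block factor model."""
    factors = rng.standard_normal((n, config.n_factors))
    assignment = np.arange(config.n_features) % config.n_factors
    common = factors[:, assignment] * config.factor_strength
    return common + config.noise_sd * rng.standard_normal((n, config.n_features))


def disease_effect_vector(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Signed raw-unit disease shift: ``effect_size`` marginal SDs, alternating sign."""
    affected = rng.choice(config.n_features, size=config.n_affected, replace=False)
    affected.sort()
    effects = np.zeros(config.n_features)
    signs = np.where(np.arange(config.n_affected) % 2 == 0, 1.0, -1.0)
    effects[affected] = signs * config.effect_size * config.marginal_sd
    return effects


def generate_cohort(config: SimulationConfig) -> tuple[FeatureMatrix, SyntheticTruth]:
    """Simulate a model-vs-wild-type cohort; deterministic per ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    effects = disease_effect_vector(config, rng)
    n = config.n_per_group
    wt = _factor_samples(config, n, rng)
    model = _factor_samples(config, n, rng) + effects
    values = np.vstack([model, wt])
    ids = [f"model_{i:03d}" for i in range(n)] + [f"wt_{i:03d}" for i in range(n)]
    metadata = pd.DataFrame(
        {
            "group": ["model"] * n + ["WT"] * n,
            "sex": config.sex,
            "age_months": config.age_months,
            "treatment": "none",
            "dose_mg_per_kg": 0.0,
        },
        index=pd.Index(ids),
    )
    matrix = FeatureMatrix(ids, metadata, values, config.feature_names)
    names = config.feature_names
    truth = SyntheticTruth(
        affected_features=[names[i] for i in np.nonzero(effects)[0]],
        true_effects=effects,
        drug_effects={},
        archetypes={},
    )
    return matrix, truth


def drug_effect_vector(
    spec: DrugSpec, dose: float, truth: SyntheticTruth, rng: np.random.Generator
) -> np.ndarray:
    """Planted raw-unit drug effect for one drug-dose (before sampling noise)."""
    scale = spec.reversal_strength * dose / max(spec.doses)
    base = np.asarray(truth.true_effects)
    if spec.archetype == "null":
        return np.zeros_like(base)
    if spec.archetype == "reverser":
        return -scale * base
    if spec.archetype == "mimic":
        return scale * base
    # partial: reversal on the leading fraction of affected features only
    affected_idx = np.nonzero(base)[0]
    k = max(1, math.ceil(spec.partial_fraction * affected_idx.size))
    effect = np.zeros_like(base)
    effect[affected_idx[:k]] = -scale * base[affected_idx[:k]]
    return effect


def generate_library(
    config: SimulationConfig,
    truth: SyntheticTruth,
    seed: int | None = None,
) -> list[DrugRanking]:
    """Simulate the drug library screen in wild-type animals.

    One vehicle group is shared by every drug-dose (the screening design uses
    a single vehicle per stratum); each drug-dose gets its own treated group
    of ``n_per_group`` animals, and the profile is the per-feature Welch t of
    treated vs vehicle.  Ground-truth effect vectors and archetypes are
    recorded on ``truth``.
    """
    root = np.random.SeedSequence(config.seed + 1 if seed is None else seed)
    n_cells = sum(len(spec.doses) for spec in config.library)
    children = root.spawn(n_cells + 1)
    vehicle = _factor_samples(config, config.n_per_group, np.random.default_rng(children[0]))
    rankings: list[DrugRanking] = []
    cell = 1
    for spec in config.library:
        truth.archetypes[spec.drug_id] = spec.archetype
        for dose in spec.doses:
            rng = np.random.default_rng(children[cell])
            cell += 1
            effect = drug_effect_vector(spec, dose, truth, rng)
            truth.drug_effects[(spec.drug_id, float(dose))] = effect
            treated = _factor_samples(config, config.n_per_group, rng) + effect
            t, _ = welch_t(treated, vehicle)
            order = np.argsort(-t, kind="stable")
            rankings.append(
                DrugRanking(
                    drug_id=spec.drug_id,
                    dose_mg_per_kg=float(dose),
                    ordered_features=[config.feature_names[i] for i in order],
                    ordered_scores=t[order],
                )
            )
    return rankings
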