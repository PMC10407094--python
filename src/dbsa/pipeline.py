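"""Serialization and the end-to-end reproducible screening pipeline.

The pipeline ties the stages together per stratum (sex x age cohort):
disease signature -> library screen -> cross-stratum consistency filter ->
optional decorrelated-space validation (discrimination of the model and
recovery of a designated test group).  All randomness derives from the one
top-level seed; identical config + seed gives byte-identical output files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import FeatureMatrix, read_feature_matrix
from .drfa import discrimination_pvalue, fit_drf_space, recovery_index
from .enrichment import (
    SCREEN_COLUMNS,
    ConsistencyResult,
    DrugRanking,
    ScreenSettings,
    ScreenTable,
    consistency_filter,
    screen_library,
)
from .signatures import ContrastProfile, DiseaseSignature, build_disease_signature, compute_feature_tscores

_FLOAT_FORMAT = "%.10g"

LIBRARY_COLUMNS = ["drug_id", "dose_mg_per_kg", "feature", "t_score"]


# ---------------------------------------------------------------------------
# serialization helpers


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_signature(signature: DiseaseSignature, path: str | Path) -> None:
    write_json(signature.to_dict(), path)


def read_signature(path: str | Path) -> DiseaseSignature:
    return DiseaseSignature.from_dict(read_json(path))


def write_library(library: Sequence[DrugRanking], path: str | Path) -> None:
    """Long-format library TSV: drug_id, dose_mg_per_kg, feature, t_score."""
    rows = []
    for ranking in library:
        for feature, score in zip(ranking.ordered_features, ranking.ordered_scores):
            rows.append((ranking.drug_id, ranking.dose_mg_per_kg, feature, score))
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FORMAT
    )


def read_library(path: str | Path) -> list[DrugRanking]:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in LIBRARY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"library table missing columns {missing}")
    rankings = []
    for (drug, dose), block in table.groupby(["drug_id", "dose_mg_per_kg"], sort=True):
        block = block.sort_values("t_score", ascending=False, kind="stable")
        rankings.append(
            DrugRanking(
                drug_id=str(drug),
                dose_mg_per_kg=float(dose),
                ordered_features=block["feature"].tolist(),
                ordered_scores=block["t_score"].to_numpy(),
            )
        )
    return rankings


def write_screen_table(screen: ScreenTable, path: str | Path) -> None:
    screen.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_screen_table(path: str | Path) -> ScreenTable:
    table = pd.read_csv(path, sep="\t")
    strata = table["stratum"].unique()
    if len(strata) != 1:
        raise ValueError(f"screen table must hold one stratum, found {list(strata)}")
    return ScreenTable(table=table[SCREEN_COLUMNS], stratum=str(strata[0]))


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class StratumPaths:
    name: str
    cohort: str
    library: str


@dataclass
class RunConfig:
    """Full configuration of one reproducible screening run."""

    strata: list[StratumPaths]
    out_dir: str
    seed: int = 0
    metadata_columns: list[str] | None = None
    model_selector: dict = field(default_factory=lambda: {"group": "model"})
    wt_selector: dict = field(default_factory=lambda: {"group": "WT"})
    k_per_tail: int = 20
    min_abs_t: float = 0.0
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    same_sign_zero: bool = True
    alpha: float = 0.05
    use_q: bool = False
    drfa_enabled: bool = False
    drfa_test_selector: dict | None = None
    variance_kept: float = 0.95
    n_subsamples: int = 200
    holdout_fraction: float = 0.5
    n_label_permutations: int = 1000

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["strata"] = [asdict(s) for s in self.strata]
        return payload

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RunConfig":
        payload = dict(payload)
        payload["strata"] = [StratumPaths(**s) for s in payload["strata"]]
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# pipeline


def derive_seeds(seed: int, n: int) -> list[int]:
    """n independent child seeds (deterministic) from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute signature -> screen -> consistency (-> DRFA) for every stratum.

    Writes, under ``config.out_dir``: per-stratum ``signature_<s>.json`` and
    ``screen_<s>.tsv``, ``consistency.tsv``, optional ``drfa_<s>.json``, and
    a plain-text ``summary.txt`` recording versions, seeds and thresholds.
    Returns the in-memory results keyed like the files.
    """
    if not config.strata:
        raise ValueError("run config lists no strata")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    child_seeds = derive_seeds(config.seed, 2 * len(config.strata))
    results: dict[str, object] = {}
    screens: dict[str, ScreenTable] = {}
    lines = [
        f"dbsa {__version__}",
        f"seed: {config.seed}",
        f"signature: k_per_tail={config.k_per_tail} min_abs_t={config.min_abs_t}",
        f"screen: weight_exponent={config.weight_exponent} "
        f"n_permutations={config.n_permutations} same_sign_zero={config.same_sign_zero}",
        f"consistency: alpha={config.alpha} use_q={config.use_q}",
    ]

    for i, stratum in enumerate(config.strata):
        stage = f"signature[{stratum.name}]"
        try:
            matrix = read_feature_matrix(stratum.cohort, config.metadata_columns)
            profile = compute_feature_tscores(
                matrix, config.model_selector, config.wt_selector
            )
            signature = build_disease_signature(profile, config.k_per_tail, config.min_abs_t)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"stage {stage} failed on {stratum.cohort}: {exc}") from exc
        write_signature(signature, out / f"signature_{stratum.name}.json")
        results[f"signature_{stratum.name}"] = signature

        stage = f"screen[{stratum.name}]"
        try:
            library = read_library(stratum.library)
            settings = ScreenSettings(
                weight_exponent=config.weight_exponent,
                n_permutations=config.n_permutations,
                seed=child_seeds[i],
                same_sign_zero=config.same_sign_zero,
            )
            screen = screen_library(library, signature, settings, stratum=stratum.name)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage {stage} failed on {stratum.library}: {exc}") from exc
        write_screen_table(screen, out / f"screen_{stratum.name}.tsv")
        screens[stratum.name] = screen
        lines.append(
            f"stratum {stratum.name}: n_drugs={len(screen.table)} "
            f"screen_seed={settings.seed} top={screen.table.iloc[0]['drug_id']}"
        )

        if config.drfa_enabled:
            stage = f"drfa[{stratum.name}]"
            try:
                payload = _run_drfa_stage(
                    matrix, config, seed=child_seeds[len(config.strata) + i]
                )
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"stage {stage} failed on {stratum.cohort}: {exc}") from exc
            write_json(payload, out / f"drfa_{stratum.name}.json")
            results[f"drfa_{stratum.name}"] = payload

    if len(screens) >= 2:
        consistency = consistency_filter(screens, config.alpha, config.use_q)
    else:
        only = next(iter(screens.values()))
        sig_col = "fdr_q" if config.use_q else "p_value"
        mask = (only.table[sig_col] <= config.alpha) & (only.table["reversal_score"] > 0)
        kept = sorted(
            (str(r.drug_id), float(r.dose_mg_per_kg))
            for r in only.table[mask].itertuples()
        )
        consistency = ConsistencyResult(
            kept=kept,
            flags=only.table.set_index(["drug_id", "dose_mg_per_kg"])[[sig_col]].le(config.alpha),
            alpha=config.alpha,
            use_q=config.use_q,
        )
    results["screens"] = screens
    results["consistency"] = consistency
    pd.DataFrame(consistency.kept, columns=["drug_id", "dose_mg_per_kg"]).to_csv(
        out / "consistency.tsv", sep="\t", index=False, float_format=_FLOAT_FORMAT
    )
    lines.append(f"consistency kept {len(consistency.kept)} drug-dose pairs")
    for drug, dose in consistency.kept:
        lines.append(f"  kept: {drug} @ {dose:g} mg/kg")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return results


def _run_drfa_stage(matrix: FeatureMatrix, config: RunConfig, seed: int) -> dict:
    p, disc = discrimination_pvalue(
        matrix,
        config.model_selector,
        config.wt_selector,
        variance_kept=config.variance_kept,
        n_subsamples=config.n_subsamples,
        holdout_fraction=config.holdout_fraction,
        n_label_permutations=config.n_label_permutations,
        seed=seed,
    )
    payload = {
        "discrimination_index_percent": disc.index_percent,
        "discrimination_p": p,
        "n_subsamples": disc.n_subsamples,
        "holdout_fraction": disc.holdout_fraction,
        "classifier": disc.classifier_spec,
        "seed": seed,
    }
    if config.drfa_test_selector is not None:
        space = fit_drf_space(
            matrix, config.model_selector, config.wt_selector, config.variance_kept
        )
        rec = recovery_index(
            matrix,
            config.model_selector,
            config.wt_selector,
            config.drfa_test_selector,
            space,
        )
        payload["recovery_percent"] = rec.recovery_percent
        payload["recovery_p"] = rec.p_value
    return payload
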