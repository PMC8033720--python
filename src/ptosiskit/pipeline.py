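"""End-to-end orchestration: simulate -> measure -> dataset -> train -> report.

Every stage is a plain function over the library types; the CLI wraps
these one-to-one.  All artifacts are text (OBJ meshes, CSV tables, JSON
models/metrics, YAML config) and every run is reproducible from its
seed: the metrics JSON embeds the seed and a hash of the resolved
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset as ds
from . import decision, gbm, morphometry, synthcohort
from .dataset import FeatureScheme, SplitConfig
from .errors import PtosisKitError
from .gbm import BoostConfig, HyperGrid
from .synthcohort import CohortConfig, CohortEye

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    grid: HyperGrid | None = None
    boost: BoostConfig = field(default_factory=lambda: BoostConfig(eta=0.1, n_rounds=100, max_depth=3))
    schemes: tuple[FeatureScheme, ...] = (
        FeatureScheme.THREE_D,
        FeatureScheme.TWO_D,
        FeatureScheme.BOTH,
    )
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        """Rebase every stage's seed on one master seed."""
        return dataclasses.replace(
            self,
            seed=seed,
            cohort=dataclasses.replace(self.cohort, seed=seed),
            split=dataclasses.replace(self.split, seed=seed + 1),
        )

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "cohort": dataclasses.asdict(self.cohort),
            "split": dataclasses.asdict(self.split),
            "boost": dataclasses.asdict(self.boost),
            "schemes": [s.value for s in self.schemes],
        }
        if self.grid is not None:
            d["grid"] = {
                "params": self.grid.params,
                "validation_fraction": self.grid.validation_fraction,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        if "cohort" in d:
            c = dict(d["cohort"])
            if "class_proportions" in c:
                c["class_proportions"] = tuple(c["class_proportions"])
            cfg.cohort = CohortConfig(**c)
        if "split" in d:
            cfg.split = SplitConfig(**d["split"])
        if "boost" in d:
            cfg.boost = BoostConfig(**d["boost"])
        if "grid" in d and d["grid"]:
            g = d["grid"]
            cfg.grid = HyperGrid(
                params={k: list(v) for k, v in g.get("params", {}).items()},
                validation_fraction=g.get("validation_fraction", 0.25),
            )
        if "schemes" in d:
            cfg.schemes = tuple(FeatureScheme(s) for s in d["schemes"])
        cfg.seed = int(d.get("seed", 0))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# in-memory pipeline


def measure_cohort(cohort: list[CohortEye]) -> pd.DataFrame:
    """Run both measurement paths over a cohort: eye_id + 14 mm columns."""
    rows = {}
    for eye in cohort:
        cal = morphometry.calibrate_scale(eye.landmarks_2d.disc_diameters_px)
        d2 = morphometry.measure_2d(eye.landmarks_2d, cal)
        d3 = morphometry.measure_3d(eye.mesh, eye.landmarks_3d, model_units_per_mm=1.0)
        rows[eye.eye_id] = (d2, d3)
    return morphometry.distances_to_frame(rows)


def cohort_labels(cohort: list[CohortEye]) -> pd.DataFrame:
    return pd.DataFrame(
        {"eye_id": [e.eye_id for e in cohort], "label": [e.label.value for e in cohort]}
    )


def cohort_to_records(cohort: list[CohortEye]) -> pd.DataFrame:
    """Measure a cohort and assemble the 15-field eye records."""
    distances = measure_cohort(cohort)
    d2 = distances[["eye_id", *ds.FEATURE_COLUMNS_2D]]
    d3 = distances[["eye_id", *ds.FEATURE_COLUMNS_3D]]
    return ds.assemble_records(d2, d3, cohort_labels(cohort))


def run_experiment(
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[FeatureScheme, decision.CascadeModel], dict]:
    """Full in-memory run: generate, measure, split, train, evaluate.

    Returns the 3-scheme x 2-task evaluation grid, the trained cascades,
    and a dict of intermediate artifacts (records, split, normalizer).
    """
    cohort = synthcohort.generate_cohort(config.cohort)
    records = cohort_to_records(cohort)
    train, test = ds.split_train_test(records, config.split)
    normalizer = ds.FeatureNormalizer().fit(train)
    train_n, test_n = normalizer.transform(train), normalizer.transform(test)

    models: dict[FeatureScheme, decision.CascadeModel] = {}
    for scheme in config.schemes:
        models[scheme] = decision.train_cascade(
            train_n, scheme, config.grid if config.grid is not None else config.boost,
            seed=config.seed + 10,
        )
    report = decision.build_report(test_n, models)
    artifacts = {
        "cohort": cohort,
        "records": records,
        "train": train,
        "test": test,
        "normalizer": normalizer,
        "models": models,
    }
    return report, models, artifacts


def recovery_experiment(
    seed: int,
    n_eyes: int = 500,
    noise_sd_mm: float = 0.3,
    scheme: FeatureScheme = FeatureScheme.BOTH,
    boost: BoostConfig | None = None,
) -> dict:
    """Parameter-recovery run: can the cascade recover the generating rule?

    Generates a noisy cohort at the default clinical thresholds, runs the
    full measure/assemble/split/normalize/train path for one feature
    scheme, and returns the held-out diagnosis and plan metrics plus the
    training-loss traces of both stages.
    """
    boost = boost or BoostConfig(eta=0.1, n_rounds=60, max_depth=3)
    cohort = synthcohort.generate_cohort(
        CohortConfig(n_eyes=n_eyes, noise_sd_mm=noise_sd_mm, seed=seed)
    )
    records = cohort_to_records(cohort)
    train, test = ds.split_train_test(records, SplitConfig(seed=seed))
    normalizer = ds.FeatureNormalizer().fit(train)
    model = decision.train_cascade(normalizer.transform(train), scheme, boost, seed=seed)
    reports = decision.evaluate_cascade(model, normalizer.transform(test))
    return {
        "seed": seed,
        "n_eyes": n_eyes,
        "diagnosis": reports["diagnosis"],
        "plan": reports["plan"],
        "stage1_loss": list(model.stage1.train_loss),
        "stage2_loss": list(model.stage2.train_loss),
    }


# ---------------------------------------------------------------------------
# on-disk pipeline (used by the CLI)


def _write_normalizer(norm: ds.FeatureNormalizer, path: Path) -> None:
    path.write_text(
        json.dumps(
            {
                "columns": list(norm.columns),
                "mean": [float(norm.mean_[c]) for c in norm.columns],
                "std": [float(norm.std_[c]) for c in norm.columns],
                "constant": norm._constant,
            },
            indent=1,
        )
    )


def _read_normalizer(path: Path) -> ds.FeatureNormalizer:
    d = json.loads(path.read_text())
    norm = ds.FeatureNormalizer(columns=tuple(d["columns"]))
    norm.mean_ = pd.Series(d["mean"], index=d["columns"])
    norm.std_ = pd.Series(d["std"], index=d["columns"])
    norm._constant = list(d["constant"])
    return norm


def run_pipeline(config: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Execute every stage and write all artifacts under ``outdir``.

    Artifacts: ``cohort/`` (OBJ meshes + manifest), ``distances.csv``,
    ``records.csv``, ``split.csv``, ``normalizer.json``,
    ``models/<scheme>_stage<k>.json``, ``report.csv``, ``report.txt`` and
    ``metrics.json`` (seed, config hash, metric grid).  Idempotent for a
    fixed configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    current = {"stage": "simulate"}

    def stage(name: str) -> None:
        current["stage"] = name
        log.info("stage %s", name)

    try:
        stage("simulate")
        cohort = synthcohort.generate_cohort(config.cohort)
        synthcohort.write_cohort(cohort, outdir / "cohort")

        stage("measure")
        distances = measure_cohort(cohort)
        distances.to_csv(outdir / "distances.csv", index=False)

        stage("dataset")
        records = ds.assemble_records(
            distances[["eye_id", *ds.FEATURE_COLUMNS_2D]],
            distances[["eye_id", *ds.FEATURE_COLUMNS_3D]],
            cohort_labels(cohort),
        )
        records.to_csv(outdir / "records.csv", index=False)
        train, test = ds.split_train_test(records, config.split)
        split = pd.concat(
            [
                pd.DataFrame({"eye_id": train["eye_id"], "subset": "train"}),
                pd.DataFrame({"eye_id": test["eye_id"], "subset": "test"}),
            ]
        )
        split.to_csv(outdir / "split.csv", index=False)

        stage("train")
        normalizer = ds.FeatureNormalizer().fit(train)
        _write_normalizer(normalizer, outdir / "normalizer.json")
        train_n, test_n = normalizer.transform(train), normalizer.transform(test)
        (outdir / "models").mkdir(exist_ok=True)
        models: dict[FeatureScheme, decision.CascadeModel] = {}
        for scheme in config.schemes:
            model = decision.train_cascade(
                train_n,
                scheme,
                config.grid if config.grid is not None else config.boost,
                seed=config.seed + 10,
            )
            models[scheme] = model
            gbm.save_model(model.stage1, outdir / "models" / f"{scheme.value}_stage1.json")
            gbm.save_model(model.stage2, outdir / "models" / f"{scheme.value}_stage2.json")

        stage("evaluate")
        report = decision.build_report(test_n, models)
        report.to_csv(outdir / "report.csv", index=False)

        stage("report")
        (outdir / "report.txt").write_text(decision.report_to_text(report) + "\n")
        (outdir / "metrics.json").write_text(
            json.dumps(
                {
                    "seed": config.seed,
                    "config_hash": config.config_hash(),
                    "n_eyes": len(records),
                    "metrics": report.to_dict(orient="records"),
                },
                indent=1,
            )
        )
        return report
    except PtosisKitError as exc:
        raise type(exc)(f"[stage {current['stage']}] {exc}") from exc
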