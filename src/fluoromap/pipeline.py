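"""End-to-end runner: simulate -> ingest -> associate -> fit -> evaluate -> map -> risk.

Each stage writes its artifact under the run directory and is recorded in a
manifest (artifact paths, SHA-256 hashes, timings, the master seed). A
failure in any stage raises :class:`StageError` naming the stage. The whole
run is deterministic under a fixed master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import association, evaluation, exposure, ingest, mapping, simulate
from .forest import ForestConfig, rfe_select, train_balanced_forest, tune_min_node_size
from .grids import write_ascii

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ingest", "associate", "fit", "evaluate", "map", "risk")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One pipeline run: scenario, model settings, evaluation settings, paths."""

    out_dir: str | Path
    scenario: simulate.SyntheticScenario = field(default_factory=simulate.SyntheticScenario)
    threshold: float = ingest.DEFAULT_THRESHOLD
    forest: ForestConfig = field(default_factory=ForestConfig)
    n_repetitions: int = 100
    run_rfe: bool = True
    tune_node_size: bool = False
    node_size_candidates: tuple[int, ...] = (1, 2, 3, 4, 5)
    low_cutoff: float = 0.5
    hybrid_cutoff: float | None = None  # None -> crossover / 2
    seed: int | None = None  # overrides scenario.seed and forest.seed

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.scenario.seed = int(self.seed)
            self.forest.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "scenario" in d:
            d["scenario"] = simulate.SyntheticScenario(**{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in d["scenario"].items()
            })
        if "forest" in d:
            d["forest"] = ForestConfig(**d["forest"])
        if "node_size_candidates" in d:
            d["node_size_candidates"] = tuple(d["node_size_candidates"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.scenario.seed,
        "threshold": config.threshold,
        "stages": {},
    }

    def record(stage: str, artifact: Path, t0: float) -> None:
        manifest["stages"][stage] = {
            "artifact": str(artifact),
            "sha256": _sha256(artifact),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        logger.info("[%s] wrote %s", stage, artifact)

    # -- simulate --------------------------------------------------------
    t0 = time.perf_counter()
    try:
        scn = config.scenario
        stack = simulate.gen_covariate_rasters(scn)
        truth = simulate.gen_truth_surface(stack, scn)
        raw = simulate.gen_measurements(truth, scn)
        rural, urban, countries, usage = simulate.gen_population_and_usage(scn)
        sim_dir = out / "synthetic"
        sim_dir.mkdir(exist_ok=True)
        raw.to_csv(sim_dir / "measurements_raw.csv", index=False)
        usage.to_csv(sim_dir / "usage.csv", index=False)
        write_ascii(truth, sim_dir / "truth.asc")
        record("simulate", sim_dir / "measurements_raw.csv", t0)
    except Exception as e:  # noqa: BLE001 - typed re-raise with stage context
        raise StageError("simulate", e) from e

    # -- ingest ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        table = ingest.build_model_table(raw, stack, threshold=config.threshold)
        table_path = out / "model_table.csv"
        table.to_csv(table_path, index=False)
        record("ingest", table_path, t0)
    except Exception as e:  # noqa: BLE001
        raise StageError("ingest", e) from e

    feature_names = scn.band_names

    # -- associate -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        params = [
            n for n in feature_names
            if stack.bands[n].kind == "continuous"
        ] + [c for c in ("insitu_mono", "insitu_vee") if c in table.columns]
        assoc = association.associate_table(table, params)
        assoc_path = out / "associations.csv"
        assoc.to_csv(assoc_path, index=False)
        record("associate", assoc_path, t0)
    except Exception as e:  # noqa: BLE001
        raise StageError("associate", e) from e

    # -- fit -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        selected = list(feature_names)
        if config.run_rfe:
            trace = rfe_select(table, feature_names, config.forest)
            trace.to_frame().to_csv(out / "rfe_trace.csv", index=False)
            selected = list(trace.chosen)
        fcfg = config.forest
        if config.tune_node_size:
            best = tune_min_node_size(
                table, selected, fcfg, candidates=config.node_size_candidates
            )
            fcfg = ForestConfig(
                n_trees=fcfg.n_trees, features_per_node=fcfg.features_per_node,
                min_node_size=best, balanced_bagging=fcfg.balanced_bagging,
                seed=fcfg.seed,
            )
        model = train_balanced_forest(table, selected, fcfg)
        model.feature_importance(standardize=True).to_csv(out / "importance.csv")
        model_path = out / "model.pkl"
        model.save(model_path)
        record("fit", model_path, t0)
    except Exception as e:  # noqa: BLE001
        raise StageError("fit", e) from e

    # -- evaluate --------------------------------------------------------
    t0 = time.perf_counter()
    try:
        report = evaluation.cross_validate(
            table, selected, fcfg, n_repetitions=config.n_repetitions
        )
        report.per_repetition.to_csv(out / "cv_repetitions.csv", index=False)
        report_path = out / "cv_report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=2))
        record("evaluate", report_path, t0)
    except Exception as e:  # noqa: BLE001
        raise StageError("evaluate", e) from e

    # -- map -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        hazard = mapping.predict_map(model, stack)
        hazard_path = out / "hazard.asc"
        write_ascii(hazard.raster, hazard_path)
        manifest["area_fraction_above_0.5"] = mapping.area_fraction_above(hazard, 0.5)
        record("map", hazard_path, t0)
    except Exception as e:  # noqa: BLE001
        raise StageError("map", e) from e

    # -- risk ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        consuming = exposure.groundwater_population(rural, urban, usage, countries)
        continents = dict(zip(usage["country_id"], usage["continent"]))
        hybrid_cutoff = (
            config.hybrid_cutoff
            if config.hybrid_cutoff is not None
            else report.crossover / 2.0
        )
        country_table, continent_table = exposure.aggregate_exposure(
            consuming, hazard, countries, continents,
            low_cutoff=config.low_cutoff, hybrid_cutoff=hybrid_cutoff,
        )
        country_table.to_csv(out / "exposure_by_country.csv", index=False)
        continent_table.to_csv(out / "exposure_by_continent.csv", index=False)
        totals = {
            "hybrid_cutoff": hybrid_cutoff,
            "crossover_cutoff": report.crossover,
            "exposed_high": float(country_table["exposed_high"].sum()),
            "exposed_low": float(country_table["exposed_low"].sum()),
            "exposed_hybrid": float(country_table["exposed_hybrid"].sum()),
        }
        totals_path = out / "exposure_totals.json"
        totals_path.write_text(json.dumps(totals, indent=2))
        record("risk", totals_path, t0)
    except Exception as e:  # noqa: BLE001
        raise StageError("risk", e) from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
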