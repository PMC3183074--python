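"""End-to-end orchestration: simulate (or load) a cohort, summarize, regress,
dichotomize, build the biomarker network and the time-resolved predictive
curves, and write everything as commented CSV files."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import network as wnetwork
from . import stats as wstats
from . import supplementary
from . import synthetic
from . import temporal
from .types import AnimalRecord, BiomarkerTimecourse

log = logging.getLogger("wormspan")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_csv"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Either ``summaries_path`` points at an existing per-animal summary CSV,
    or a cohort is simulated from the ``cohort`` config (default: the
    paper-like preset).  The seed propagates to every stochastic stage.
    """

    output_dir: str = "results"
    seed: int = 0
    summaries_path: Optional[str] = None
    timecourse_path: Optional[str] = None
    window: Tuple[float, float] = (3.0, 7.0)
    alpha: float = 0.001
    n_animals: int = 463
    run_network: bool = True
    run_curve: bool = True
    curve_biomarkers: Tuple[str, ...] = ("length", "mir71")
    lambda_grid: Optional[Sequence[float]] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def digest(self) -> str:
        # the digest covers the scientific configuration, not where the
        # outputs land
        blob = json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(self).items()
                           if not callable(v) and k != "output_dir"},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    summaries: pd.DataFrame
    regressions: Dict[str, wstats.RegressionResult]
    diagnostic: Optional[wstats.DiagnosticTest]
    network: Optional[wnetwork.PartialCorrelationNetwork]
    curves: Dict[str, temporal.PredictiveCurve]
    outputs: List[Path]


def write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig,
              index: bool = False) -> Path:
    """Write a CSV with a provenance header (config hash + seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# wormspan config={config.digest()} seed={config.seed}\n")
        df.to_csv(fh, index=index)
    return path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the tabular analysis stages and write their outputs.

    Produces: summary CSV, regression report (R-squared, p, l.o.o.,
    standardized weights), diagnostic-test report, network edge list, and
    per-age predictive curves.  With ``summaries_path`` given, the simulation
    stage is skipped and the statistics run on the provided table.
    """
    out = Path(config.output_dir)
    outputs: List[Path] = []

    if config.summaries_path:
        log.info("loading summaries from %s", config.summaries_path)
        summaries = supplementary.read_summary_table(config.summaries_path)
        courses: List[BiomarkerTimecourse] = []
        lifespans = summaries["lifespan_days"].to_dict()
    else:
        cfg = synthetic.paper_like_config(n_animals=config.n_animals,
                                          seed=config.seed)
        cfg.window = tuple(config.window)
        animals, courses = synthetic.generate_cohort(cfg)
        adf, tdf = synthetic.cohort_to_frames(animals, courses)
        outputs.append(write_csv(adf, out / "animals.csv", config))
        outputs.append(write_csv(tdf, out / "timecourses.csv", config))
        summaries = wstats.summary_table(animals, courses,
                                         window=config.window)
        lifespans = {a.animal_id: a.lifespan_days for a in animals
                     if a.lifespan_days is not None}
    outputs.append(write_csv(summaries.reset_index(), out / "summaries.csv",
                             config))

    regressions = supplementary.replicate(summaries)
    rows = []
    for name, res in regressions.items():
        rows.append({
            "model": name, "n": res.n, "r2": res.r2, "p": res.p_value,
            "loo_r2": res.loo_r2,
            "weights": "; ".join(f"{k}={v:+.3f}"
                                 for k, v in res.weights_by_magnitude()),
        })
    outputs.append(write_csv(pd.DataFrame(rows), out / "regressions.csv",
                             config))

    diagnostic = None
    key = "survival_index" if "survival_index" in regressions else \
        next(iter(regressions), None)
    if key is not None:
        cols = list(supplementary.REGRESSION_BATTERY[key])
        sub = summaries[cols + ["lifespan_days"]].dropna()
        res = wstats.ols_predict(sub[cols], sub["lifespan_days"])
        diagnostic = wstats.dichotomize_test(res.predictions,
                                             sub["lifespan_days"])
        outputs.append(write_csv(pd.DataFrame([{
            "model": key, "sensitivity": diagnostic.sensitivity,
            "specificity": diagnostic.specificity,
            "mean_lifespan_ratio": diagnostic.mean_lifespan_ratio,
            "ks_statistic": diagnostic.ks_statistic,
            "ks_p": diagnostic.ks_p,
        }]), out / "diagnostic_test.csv", config))

    net = None
    if config.run_network:
        slope_cols = [c for c in summaries.columns if c.endswith("_slope")]
        data = summaries[slope_cols].copy()
        data["lifespan"] = summaries["lifespan_days"]
        data.columns = [c.replace("_slope", "") for c in data.columns]
        try:
            net = wnetwork.pc_skeleton(data.dropna(), alpha=config.alpha)
            edges = pd.DataFrame(net.edge_list(),
                                 columns=["node_a", "node_b"])
            outputs.append(write_csv(edges, out / "network_edges.csv",
                                     config))
        except ValueError as exc:
            log.warning("network stage skipped: %s", exc)

    curves: Dict[str, temporal.PredictiveCurve] = {}
    if config.run_curve and courses:
        grid = None if config.lambda_grid is None else \
            np.asarray(config.lambda_grid, float)
        for biomarker in config.curve_biomarkers:
            sub = [c for c in courses if c.biomarker == biomarker]
            if not sub:
                continue
            curve = temporal.predictive_curve(sub, lifespans,
                                              lambda_grid=grid)
            curves[biomarker] = curve
            outputs.append(write_csv(curve.as_frame(),
                                     out / f"curve_{biomarker}.csv", config))

    return PipelineResult(summaries=summaries, regressions=regressions,
                          diagnostic=diagnostic, network=net, curves=curves,
                          outputs=outputs)
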