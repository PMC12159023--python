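"""End-to-end orchestration: survey → indicators → GHI levels → level
summaries → diversity thresholds and change rates → Mantel screen.

Every stage runs independently per grassland type (meadow and steppe are
never pooled), writes its tabular output, and the whole run is reproducible
from the configuration and seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import RESPONSE_METRICS, build_plot_indicators
from .errors import InvalidParameterError, StageError
from .ghi import build_ghi
from .spatial import (
    dbmem,
    euclidean_distance_matrix,
    geodesic_distance_matrix,
    mantel_screen,
)
from .synthetic import GeneratorConfig, SurveyDataset, generate_survey
from .thresholds import change_table, diversity_thresholds

log = logging.getLogger("pikathresh")

_CONFIG_KEYS = {
    "schema_version", "generator", "input_dir", "per_type", "loess_span",
    "loess_degree", "grid_size", "adoption_tolerance", "k_levels",
    "n_permutations", "mantel_method", "density_quantile", "seed", "out_dir",
}


@dataclass
class PipelineConfig:
    """Run configuration; either a generator config or an input directory."""

    generator: GeneratorConfig | None = None
    input_dir: str | None = None
    per_type: bool = True
    loess_span: float = 0.75
    loess_degree: int = 2
    grid_size: int = 512
    adoption_tolerance: float = 0.005
    k_levels: int = 4
    n_permutations: int = 999
    mantel_method: str = "pearson"
    density_quantile: float = 0.90
    seed: int = 0
    out_dir: str | None = None
    schema_version: int = 1

    def __post_init__(self):
        if self.k_levels < 2:
            raise InvalidParameterError("k_levels must be >= 2")
        if self.n_permutations < 99:
            raise InvalidParameterError("n_permutations must be >= 99")
        if self.generator is None and self.input_dir is None:
            self.generator = GeneratorConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        return cls(**d)


@dataclass
class RunReport:
    """Machine-readable record of one full analysis run."""

    ghi_summary: dict  # type -> {weights, kmo, bartlett_chi2, bartlett_p}
    level_counts: dict  # type -> {level: n}
    level_summary: list  # rows: type, level, metric, n, mean, se, is_argmax
    thresholds: list  # rows: type, candidates, adopted, principle
    change_rates: dict  # type -> {metric: percent}
    mantel: list  # rows: type, response, predictor, r, p, significance
    provenance: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def level_summary(indicators: pd.DataFrame, levels: pd.Series,
                  metrics: list | None = None) -> pd.DataFrame:
    """Per (type, level, metric): n, mean, standard error, argmax flag.

    The standard error is NaN-marked when a level holds a single plot.  The
    ``is_argmax`` flag marks, within each type and metric, the level whose
    mean is highest — the "which disturbance level maximizes this metric"
    question.
    """
    metrics = metrics or RESPONSE_METRICS
    df = indicators.copy()
    if "plot_id" in df.columns:
        df = df.set_index("plot_id")
    df["level"] = levels.reindex(df.index)
    if df["level"].isna().any():
        raise InvalidParameterError("some plots have no level assignment")
    rows = []
    for (gtype, level), sub in df.groupby(["type", "level"], sort=True):
        for m in metrics:
            vals = sub[m].to_numpy(dtype=float)
            rows.append({
                "type": gtype, "level": level, "metric": m, "n": vals.size,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan"),
            })
    out = pd.DataFrame(rows)
    out["is_argmax"] = False
    for (gtype, m), sub in out.groupby(["type", "metric"], sort=False):
        out.loc[sub["mean"].idxmax(), "is_argmax"] = True
    return out


def _mantel_predictors(sub: pd.DataFrame, mem_frame: pd.DataFrame) -> dict:
    preds = {}
    if not mem_frame.empty:
        preds["MEM"] = euclidean_distance_matrix(
            mem_frame.to_numpy(), labels=list(sub.index), units="mem")
    preds["EH"] = euclidean_distance_matrix(sub["EH"].to_numpy(), labels=list(sub.index))
    for cov, name in (("annual_mean_temp_c", "AT"), ("annual_precip_mm", "AP"),
                      ("TOC", "TOC"), ("pH", "pH")):
        if cov in sub.columns:
            preds[name] = euclidean_distance_matrix(sub[cov].to_numpy(), labels=list(sub.index))
    return preds


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
    return wrap


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and return (and optionally write) a report."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- survey ---
    if config.input_dir:
        dataset = _stage("load")(SurveyDataset.read, config.input_dir)
    else:
        dataset = _stage("generate")(generate_survey, config.generator)
        if out_dir:
            dataset.write(out_dir)
    log.info("survey: %d plots, %d quadrat-species rows, seed=%s",
             len(dataset.plots), len(dataset.quadrats), config.seed)

    # --- indicators ---
    indicators = _stage("indicators")(build_plot_indicators, dataset.quadrats, dataset.plots)
    if out_dir:
        indicators.to_csv(out_dir / "plot_indicators.csv", index=False)

    types = sorted(indicators["type"].unique()) if config.per_type else ["ALL"]
    idx = indicators.set_index("plot_id")

    ghi_summary, level_counts, threshold_rows, mantel_rows = {}, {}, [], []
    all_levels = []
    ghi_frames = []
    for gtype in types:
        sub = idx if gtype == "ALL" else idx[idx["type"] == gtype]
        res = _stage(f"ghi/{gtype}")(build_ghi, sub.reset_index(), k=config.k_levels)
        ghi_summary[gtype] = {
            "weights": {k: float(v) for k, v in res.weights.items()},
            "kmo": res.kmo,
            "bartlett_chi2": res.bartlett_chi2,
            "bartlett_p": res.bartlett_p,
            "dropped": res.dropped,
        }
        level_counts[gtype] = res.levels.value_counts().sort_index().to_dict()
        all_levels.append(res.levels)
        ghi_frames.append(res.to_frame().assign(type=gtype))

        dec = _stage(f"thresholds/{gtype}")(
            diversity_thresholds, indicators, gtype,
            span=config.loess_span, degree=config.loess_degree,
            grid_size=config.grid_size, tolerance=config.adoption_tolerance,
        )
        threshold_rows.append({
            "type": gtype,
            "candidates": {k: float(v) for k, v in dec.candidates.items()},
            "adopted": dec.adopted,
            "principle": dec.principle,
            "boundary_flags": dec.boundary_flags,
        })

        # Mantel screen: responses are the two diversity metrics; the
        # spatial predictor is Euclidean distance in dbMEM coordinates.
        coords = sub[["lat", "lon"]].to_numpy(dtype=float)
        geo = geodesic_distance_matrix(coords, labels=list(sub.index))
        try:
            mem_frame = dbmem(geo).to_frame()
        except InvalidParameterError:
            mem_frame = pd.DataFrame(index=sub.index)
        preds = _mantel_predictors(sub, mem_frame)
        for resp_name in ("SW", "SR"):
            resp = euclidean_distance_matrix(sub[resp_name].to_numpy(), labels=list(sub.index))
            screen = _stage(f"mantel/{gtype}/{resp_name}")(
                mantel_screen, resp, preds,
                n_permutations=config.n_permutations,
                method=config.mantel_method,
                seed=int((config.seed + zlib.crc32(f"{gtype}/{resp_name}".encode())) % 2**31),
            )
            for _, row in screen.iterrows():
                mantel_rows.append({"type": gtype, "response": resp_name, **row.to_dict()})
        if out_dir and not mem_frame.empty:
            mem_frame.assign(type=gtype).to_csv(out_dir / f"mem_basis_{gtype}.csv")

    levels = pd.concat(all_levels)
    summary = _stage("level_summary")(level_summary, indicators, levels)
    rates = _stage("change_rates")(change_table, indicators, levels,
                                   density_quantile=config.density_quantile)

    if out_dir:
        pd.concat(ghi_frames).to_csv(out_dir / "ghi_scores.csv")
        (out_dir / "ghi_model.json").write_text(json.dumps(ghi_summary, indent=2, sort_keys=True))
        pd.DataFrame(threshold_rows).to_csv(out_dir / "thresholds.csv", index=False)
        rates.to_csv(out_dir / "change_rates.csv")
        pd.DataFrame(mantel_rows).to_csv(out_dir / "mantel_results.csv", index=False)
        summary.to_csv(out_dir / "level_summary.csv", index=False)

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
    report = RunReport(
        ghi_summary=ghi_summary,
        level_counts=level_counts,
        level_summary=summary.to_dict(orient="records"),
        thresholds=threshold_rows,
        change_rates={t: {m: float(v) for m, v in row.items()}
                      for t, row in rates.iterrows()},
        mantel=mantel_rows,
        provenance={"config": cfg_dict, "config_hash": cfg_hash,
                    "seed": config.seed, "version": __version__},
    )
    if out_dir:
        (out_dir / "report.json").write_text(report.to_json())
    return report
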