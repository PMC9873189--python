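"""End-to-end orchestration: normalize, fit decay models, summarize.

``run_all`` reproduces the analysis sequence on simulated or user data:
normalization -> log transform -> per-treatment broken-line fits ->
half-life summary -> decay-rate LRTs for configured treatment pairs ->
fold-change table -> Spearman matrix -> PCA, writing every table plus a
provenance log into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ACTD_TREATMENTS, CountMatrix, DataError
from .decay import (
    compare_decay_rates,
    estimate_decay,
    fit_gene_treatment,
    log_transform,
    summarize_half_lives,
)
from .diffstats import fold_change_table, iron_contrast_groups, pca_scores, spearman_matrix
from .io import read_count_matrix, read_titration, write_counts
from .normalization import (
    NormalizationConfig,
    TitrationMeasurement,
    estimate_attenuation_factor,
    normalize_pipeline,
)
from .simulate import HK_PROBE, DesignSpec, default_panel, simulate_experiment

logger = logging.getLogger(__name__)

DEFAULT_LRT_PAIRS = (("rec", "actd"), ("actd", "actd_fe"))


@dataclass
class PipelineConfig:
    """Paths, probe roles and analysis settings for a full run."""

    counts: str | None = None
    probes: str | None = None
    metadata: str | None = None
    titration: str | None = None
    out_dir: str = "ferrodecay_out"
    hk_probe: str = HK_PROBE
    attenuated_treatments: tuple[str, ...] = ("low",)
    rec_attenuation_window_min: float = 30.0
    pool_actd_arms: bool = True
    lrt_pairs: tuple[tuple[str, str], ...] = DEFAULT_LRT_PAIRS
    decay_treatments: tuple[str, ...] = ("rec", "actd", "actd_fe")
    exclude_from_average: tuple[str, ...] = ()
    pseudocount: float = 1.0
    seed: int = 0
    simulate: bool = False

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["lrt_pairs"] = [list(p) for p in self.lrt_pairs]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        if "lrt_pairs" in data:
            data["lrt_pairs"] = tuple(tuple(p) for p in data["lrt_pairs"])
        for key in ("attenuated_treatments", "decay_treatments",
                    "exclude_from_average"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class ResultBundle:
    """In-memory results of a full pipeline run."""

    normalized: CountMatrix
    factors: pd.DataFrame
    half_life_tables: dict[str, pd.DataFrame]
    half_life_averages: dict[str, float]
    lrt_table: pd.DataFrame
    fold_changes: pd.DataFrame
    spearman: pd.DataFrame
    spearman_order: list[str]
    pca: pd.DataFrame
    explained_variance: np.ndarray
    provenance: dict


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        design = DesignSpec(seed=config.seed)
        matrix, titration, _ = simulate_experiment(design, default_panel())
        return matrix, titration
    for name in ("counts", "probes", "metadata"):
        if getattr(config, name) is None:
            raise DataError(f"config is missing the {name!r} path")
    matrix = read_count_matrix(config.counts, config.probes, config.metadata)
    titration: list[TitrationMeasurement] = []
    if config.titration:
        df = read_titration(config.titration)
        titration = [
            TitrationMeasurement(
                probe_id=str(r.probe_id),
                count_unattenuated=float(r.count_unattenuated),
                count_attenuated=float(r.count_attenuated),
            )
            for r in df.itertuples()
        ]
    return matrix, titration


def run_all(config: PipelineConfig, write: bool = True) -> ResultBundle:
    """Execute the full analysis and (optionally) write the result bundle.

    Stage failures abort with the stage name; partially written outputs are
    removed.
    """
    stage = "load"
    try:
        matrix, titration = _load_inputs(config)

        stage = "normalize"
        if config.hk_probe not in matrix.values.index:
            raise DataError(
                f"housekeeping probe {config.hk_probe!r} is not in the count "
                "matrix; set hk_probe in the config"
            )
        norm_config = NormalizationConfig(
            hk_probe=config.hk_probe,
            attenuation_factors=estimate_attenuation_factor(titration),
            attenuated_treatments=frozenset(config.attenuated_treatments),
            rec_attenuation_window_min=config.rec_attenuation_window_min,
            pool_actd_arms=config.pool_actd_arms,
        )
        normalized, audit = normalize_pipeline(matrix, norm_config)

        stage = "log_transform"
        logc = log_transform(normalized, pseudocount=config.pseudocount)

        stage = "fit_decay"
        genes = [p.probe_id for p in normalized.probes
                 if p.probe_class == "endogenous"]
        present = {s.treatment for s in normalized.biological_samples()
                   if s.experiment == "ST"}
        half_tables: dict[str, pd.DataFrame] = {}
        half_avgs: dict[str, float] = {}
        for tr in config.decay_treatments:
            if tr not in present:
                logger.warning("treatment %r absent; decay fits skipped", tr)
                continue
            estimates = []
            for g in genes:
                fit = fit_gene_treatment(logc, normalized, g, tr)
                estimates.append(estimate_decay(g, tr, fit))
            table, avg = summarize_half_lives(
                estimates, exclude=set(config.exclude_from_average) or "auto"
            )
            half_tables[tr] = table
            half_avgs[tr] = avg

        stage = "lrt"
        lrt_rows = []
        for a, b in config.lrt_pairs:
            if a not in present or b not in present:
                logger.warning("LRT pair (%s, %s) absent; skipped", a, b)
                continue
            for g in genes:
                res, free, _tied = compare_decay_rates(
                    logc, normalized, g, a, b
                )
                lrt_rows.append({
                    "gene": g, "treatment_a": a, "treatment_b": b,
                    "beta1_a": free.beta1[a], "beta1_b": free.beta1[b],
                    "statistic": res.statistic, "df": res.df,
                    "p_value": res.p_value,
                })
        lrt_table = pd.DataFrame(lrt_rows)
        if len(lrt_table):
            from statsmodels.stats.multitest import multipletests
            lrt_table["p_adjusted"] = multipletests(
                lrt_table["p_value"], method="fdr_bh"
            )[1]

        stage = "fold_change"
        low, high = iron_contrast_groups(normalized)
        fold = fold_change_table(normalized, low, high)

        stage = "correlation"
        corr, order = spearman_matrix(normalized)

        stage = "pca"
        scores, evr = pca_scores(normalized)

        provenance = {
            "ferrodecay_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "python_version": platform.python_version(),
            "seed": config.seed,
            "pseudocount": config.pseudocount,
            "hk_probe": config.hk_probe,
            "simulated": config.simulate,
            "n_probes": len(matrix.probes),
            "n_samples": len(matrix.samples),
            "stages": list(
                dict.fromkeys(audit.to_frame()["stage"])
            ),
        }

        bundle = ResultBundle(
            normalized=normalized, factors=audit.to_frame(),
            half_life_tables=half_tables, half_life_averages=half_avgs,
            lrt_table=lrt_table, fold_changes=fold,
            spearman=corr, spearman_order=order,
            pca=scores, explained_variance=evr, provenance=provenance,
        )
    except Exception as exc:
        raise DataError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if write:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: ResultBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        written.append(path)

    try:
        emit("normalized_counts.csv",
             lambda p: write_counts(bundle.normalized, p))
        emit("factors.csv", lambda p: bundle.factors.to_csv(p, index=False))
        for tr, table in bundle.half_life_tables.items():
            emit(f"halflives_{tr}.csv", lambda p, t=table: t.to_csv(p, index=False))
        emit("lrt.csv", lambda p: bundle.lrt_table.to_csv(p, index=False))
        emit("fold_changes.csv", lambda p: bundle.fold_changes.to_csv(p, index=False))
        emit("spearman.csv", lambda p: bundle.spearman.to_csv(p))
        emit("pca_scores.csv", lambda p: bundle.pca.to_csv(p))
        summary = {
            "half_life_averages_min": bundle.half_life_averages,
            "explained_variance_ratio": [
                float(v) for v in bundle.explained_variance[:5]
            ],
            "spearman_order": bundle.spearman_order,
        }
        emit("summary.json", lambda p: p.write_text(json.dumps(summary, indent=2)))
        emit("provenance.json",
             lambda p: p.write_text(json.dumps(bundle.provenance, indent=2)))
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
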