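"""End-to-end orchestration: connectivity -> modules -> metrics ->
expression alignment -> PLS -> enrichment, from one configuration with
one master seed.

Stage seeds are derived from the master seed by fixed offsets so that
the stages consume independent but fully reproducible random streams.
A robustness sweep re-runs the topology + PLS stages across a range of
connection densities and both partition resolutions and reports whether
the sign pattern of the component-metric correlations is stable — the
qualitative claim the analysis rests on.
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, synth
from .connectivity import build_graph, group_mean_matrix, wavelet_correlation
from .enrichment import candidate_set_test, ranked_enrichment
from .netmetrics import average_metrics, consensus_partition, nodal_metrics, response_matrix
from .pls import fit_pls, metric_correlations, bootstrap_ranking, permutation_test
from .transcriptome import exclude_outlier_regions, zscore

logger = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {
    "synthesis": 0,
    "partition": 101,
    "pls": 202,
    "bootstrap": 303,
    "permutation": 404,
    "enrichment": 505,
}

SIGN_COLUMNS = ["k_intra", "k_inter", "d"]


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``synthetic`` is set (everything is generated) or the input
    paths are: per-subject time-series TSVs (or a precomputed matrix),
    a region table, a raw expression matrix, and GMT files.
    """

    synthetic: synth.SyntheticConfig | None = None
    time_series_paths: list | None = None
    matrix_path: str | None = None
    region_table_path: str | None = None
    expression_path: str | None = None
    annotation_gmt: str | None = None
    gene_sets_gmt: str | None = None
    scales: tuple = (2, 3)
    density: float = 0.10
    sweep_densities: tuple = (0.10, 0.15, 0.20, 0.25, 0.30)
    gamma: float = 2.0
    sweep_gammas: tuple = (1.0, 2.0)
    n_runs: int = 100
    n_components: int = 3
    n_boot: int = 1000
    n_perm: int = 1000
    scheme: str = "naive"
    metric_aggregation: str = "mean"
    expression_already_zscored: bool = False
    run_sweep: bool = True
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if not (0 < self.density <= 1):
            raise ValueError("density must lie in (0, 1]")
        if self.scheme not in ("naive", "block"):
            raise ValueError("scheme must be 'naive' or 'block'")
        if self.synthetic is None:
            for attr in ("region_table_path", "expression_path"):
                p = getattr(self, attr)
                if p is None:
                    raise ValueError(f"{attr} required for a non-synthetic run")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{attr}: {p}")
            if self.time_series_paths is None and self.matrix_path is None:
                raise ValueError("need time_series_paths or matrix_path")

    def stage_seed(self, stage: str) -> int:
        return int(self.seed + STAGE_SEED_OFFSETS[stage])


@dataclass
class ResultsBundle:
    config: PipelineConfig
    provenance: dict = field(default_factory=dict)
    regions: pd.DataFrame | None = None
    truth: synth.GroundTruth | None = None
    group_matrix: object = None
    partition: object = None
    metrics: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    pls: object = None
    correlations: dict | None = None
    permutation: object = None
    rankings: dict = field(default_factory=dict)
    enrichment: pd.DataFrame | None = None
    candidate_tests: dict = field(default_factory=dict)
    sweep: pd.DataFrame | None = None
    sweep_stable: bool | None = None
    errors: list = field(default_factory=list)
    log: list = field(default_factory=list)

    def note(self, msg: str) -> None:
        logger.info(msg)
        self.log.append(msg)

    def fail(self, stage: str, exc: Exception) -> None:
        record = f"stage {stage} failed: {exc!r}"
        logger.error(record)
        self.errors.append({"stage": stage, "error": repr(exc), "traceback": traceback.format_exc()})


def validate_inputs(
    regions: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    matrix: np.ndarray | None = None,
    annotation: dict | None = None,
) -> list:
    """Fail-fast consistency checks; returns the list of problems found."""
    problems = []
    region_ids = list(regions["region_id"])
    if len(set(region_ids)) != len(region_ids):
        problems.append("duplicate region ids in region table")
    if expression is not None:
        missing = [c for c in expression.columns if c not in set(region_ids)]
        if missing:
            problems.append(f"expression regions absent from region table: {missing}")
    if matrix is not None:
        m = np.asarray(matrix, float)
        if m.shape[0] != m.shape[1]:
            problems.append("connectivity matrix is not square")
        elif np.abs(m - m.T).max() > 1e-8:
            problems.append("connectivity matrix is asymmetric (|r_ij - r_ji| > 1e-8)")
    if annotation is not None:
        for term, rec in annotation.items():
            if not rec.get("genes"):
                problems.append(f"GMT term {term} has no genes")
    return problems


def run_pipeline(cfg: PipelineConfig) -> ResultsBundle:
    """Execute the full analysis; on stage failure the bundle carries the
    partial outputs plus an error record (nothing is silently skipped)."""
    cfg.validate()
    bundle = ResultsBundle(config=cfg)
    bundle.provenance = {
        "seed": cfg.seed,
        "stage_seed_offsets": dict(STAGE_SEED_OFFSETS),
        "density": cfg.density,
        "gamma": cfg.gamma,
        "scales": list(cfg.scales),
    }

    try:
        inputs = _load_inputs(cfg, bundle)
    except Exception as exc:  # noqa: BLE001 - recorded, not silenced
        bundle.fail("inputs", exc)
        return bundle

    try:
        _topology_stage(cfg, bundle, inputs)
    except Exception as exc:  # noqa: BLE001
        bundle.fail("topology", exc)
        return bundle

    try:
        _expression_stage(cfg, bundle, inputs)
    except Exception as exc:  # noqa: BLE001
        bundle.fail("expression", exc)
        return bundle

    try:
        _pls_stage(cfg, bundle)
    except Exception as exc:  # noqa: BLE001
        bundle.fail("pls", exc)
        return bundle

    try:
        _enrichment_stage(cfg, bundle, inputs)
    except Exception as exc:  # noqa: BLE001
        bundle.fail("enrichment", exc)

    if cfg.run_sweep:
        try:
            _sweep_stage(cfg, bundle, inputs)
        except Exception as exc:  # noqa: BLE001
            bundle.fail("sweep", exc)

    if cfg.out_dir:
        try:
            _write_bundle(cfg, bundle)
        except Exception as exc:  # noqa: BLE001
            bundle.fail("write", exc)
    return bundle


def _load_inputs(cfg: PipelineConfig, bundle: ResultsBundle) -> dict:
    inputs: dict = {}
    if cfg.synthetic is not None:
        scfg = cfg.synthetic
        regions, truth = synth.generate_regions(scfg)
        ts = synth.generate_time_series(regions, truth, scfg)
        bundle.regions, bundle.truth = regions, truth
        inputs.update(ts=ts, regions=regions, truth=truth, synthetic=True)
        bundle.note(f"generated synthetic cohort: {scfg.n_subjects} subjects x {scfg.n_regions} regions")
    else:
        regions = io.read_region_table(cfg.region_table_path)
        bundle.regions = regions
        inputs["regions"] = regions
        if cfg.time_series_paths:
            inputs["ts"] = io.read_time_series(cfg.time_series_paths, tr_seconds=2.42, region_ids=regions["region_id"])
        else:
            mat = io.read_matrix(cfg.matrix_path)
            from .connectivity import ConnectivityMatrix

            inputs["matrix"] = ConnectivityMatrix(mat.to_numpy(float), list(mat.index), cfg.scales)
        inputs["expression_raw"] = io.read_matrix(cfg.expression_path)
        if cfg.annotation_gmt:
            inputs["annotation"] = io.read_gmt(cfg.annotation_gmt)
        if cfg.gene_sets_gmt:
            inputs["gene_sets"] = io.read_gmt(cfg.gene_sets_gmt)
        problems = validate_inputs(
            regions,
            expression=inputs.get("expression_raw"),
            matrix=inputs["matrix"].r if "matrix" in inputs else None,
            annotation=inputs.get("annotation"),
        )
        if problems:
            raise ValueError("invalid inputs: " + "; ".join(problems))
    return inputs


def _topology_stage(cfg: PipelineConfig, bundle: ResultsBundle, inputs: dict) -> None:
    regions = inputs["regions"]
    coords = regions[["x", "y", "z"]].to_numpy(float)
    if "ts" in inputs:
        subject_mats = wavelet_correlation(inputs["ts"], scales=cfg.scales)
        group = group_mean_matrix(subject_mats)
    else:
        subject_mats = [inputs["matrix"]]
        group = inputs["matrix"]
    bundle.group_matrix = group
    inputs["subject_mats"] = subject_mats

    group_graph = build_graph(group, cfg.density, coords)
    partition = consensus_partition(group_graph, gamma=cfg.gamma, n_runs=cfg.n_runs, seed=cfg.stage_seed("partition"))
    bundle.partition = partition
    bundle.note(f"consensus partition: {partition.n_modules} modules at gamma={cfg.gamma}")

    per_subject = [
        nodal_metrics(build_graph(m, cfg.density, coords), partition, coords) for m in subject_mats
    ]
    bundle.metrics = average_metrics(per_subject, how=cfg.metric_aggregation)
    inputs["group_graph"] = group_graph


def _expression_stage(cfg: PipelineConfig, bundle: ResultsBundle, inputs: dict) -> None:
    if inputs.get("synthetic"):
        scfg = cfg.synthetic
        expr_raw, truth, sets = synth.generate_expression(inputs["regions"], bundle.metrics, scfg, inputs["truth"])
        bundle.truth = truth
        inputs["annotation"] = sets["annotation"]
        inputs["gene_sets"] = sets["gene_sets"]
        T = zscore(expr_raw)
    else:
        expr_raw = inputs["expression_raw"].loc[:, list(inputs["regions"]["region_id"])]
        T = expr_raw if cfg.expression_already_zscored else zscore(expr_raw)
        T, excluded = exclude_outlier_regions(T)
        if excluded:
            bundle.note(f"excluded outlier regions: {excluded}")
            keep = [r for r in inputs["regions"]["region_id"] if r not in set(excluded)]
            bundle.metrics = bundle.metrics.loc[keep]
    bundle.expression = T
    bundle.note(f"expression matrix T: {T.shape[0]} genes x {T.shape[1]} regions")


def _pls_stage(cfg: PipelineConfig, bundle: ResultsBundle) -> None:
    T = bundle.expression
    C = response_matrix(bundle.metrics.loc[T.columns])
    coords = bundle.regions.set_index("region_id").loc[T.columns, ["x", "y", "z"]].to_numpy(float)
    res = fit_pls(T, C, n_components=cfg.n_components)
    bundle.pls = res
    bundle.correlations = metric_correlations(res, bundle.metrics.loc[T.columns], coords)
    bundle.note(
        "PLS cumulative % response variance: "
        + ", ".join(f"{v:.1f}" for v in res.cumulative_pct_variance)
    )
    blocks = None
    if cfg.scheme == "block":
        if bundle.truth is not None:
            blocks = bundle.truth.block_labels
        elif "block" in bundle.regions.columns:
            blocks = bundle.regions.set_index("region_id").loc[T.columns, "block"].to_numpy()
    bundle.permutation = permutation_test(
        T,
        C,
        n_components=cfg.n_components,
        n_perm=cfg.n_perm,
        seed=cfg.stage_seed("permutation"),
        scheme=cfg.scheme,
        blocks=blocks,
        coords=coords,
    )
    bundle.note(f"permutation test ({cfg.scheme}): p = {bundle.permutation.p:.4g}")
    for comp in (1, 2):
        bundle.rankings[comp] = bootstrap_ranking(
            T, C, component=comp, n_boot=cfg.n_boot, seed=cfg.stage_seed("bootstrap") + comp
        )


def _enrichment_stage(cfg: PipelineConfig, bundle: ResultsBundle, inputs: dict) -> None:
    annotation = inputs.get("annotation")
    if annotation:
        tables = []
        for comp, ranking in bundle.rankings.items():
            t = ranked_enrichment(ranking, annotation)
            t.insert(0, "component", comp)
            tables.append(t)
        bundle.enrichment = pd.concat(tables, ignore_index=True)
    gene_sets = inputs.get("gene_sets")
    if gene_sets:
        for name, rec in gene_sets.items():
            for comp, ranking in bundle.rankings.items():
                bundle.candidate_tests[(name, comp)] = candidate_set_test(
                    ranking, rec, n_perm=cfg.n_perm, seed=cfg.stage_seed("enrichment") + comp
                )


def _sweep_stage(cfg: PipelineConfig, bundle: ResultsBundle, inputs: dict) -> None:
    """Re-run topology + PLS across densities and resolutions; the report
    records the sign of each leading component-metric correlation."""
    regions = inputs["regions"]
    coords = regions[["x", "y", "z"]].to_numpy(float)
    group = bundle.group_matrix
    rows = []
    for gamma in cfg.sweep_gammas:
        for density in cfg.sweep_densities:
            graph = build_graph(group, density, coords)
            part = consensus_partition(graph, gamma=gamma, n_runs=max(10, cfg.n_runs // 4), seed=cfg.stage_seed("partition"))
            per_subject = [
                nodal_metrics(build_graph(m, density, coords), part, coords) for m in inputs["subject_mats"]
            ]
            metrics = average_metrics(per_subject, how=cfg.metric_aggregation)
            C = response_matrix(metrics.loc[bundle.expression.columns])
            res = fit_pls(bundle.expression, C, n_components=min(cfg.n_components, 2))
            corr = metric_correlations(res, metrics.loc[bundle.expression.columns], coords)["r"]
            for comp in corr.index[: 2]:
                row = {"gamma": gamma, "density": density, "component": comp, "n_modules": part.n_modules}
                for col in SIGN_COLUMNS:
                    row[f"sign_{col}"] = int(np.sign(corr.loc[comp, col]))
                rows.append(row)
    sweep = pd.DataFrame(rows)
    signs = sweep.groupby("component")[[f"sign_{c}" for c in SIGN_COLUMNS]].nunique()
    bundle.sweep = sweep
    bundle.sweep_stable = bool((signs == 1).all().all())
    bundle.note(f"robustness sweep sign pattern stable: {bundle.sweep_stable}")


def _write_bundle(cfg: PipelineConfig, bundle: ResultsBundle) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_region_table(bundle.regions, out / "regions.tsv")
    if bundle.partition is not None:
        bundle.partition.to_frame().to_csv(out / "partition.tsv", sep="\t", index=False)
    if bundle.metrics is not None:
        bundle.metrics.to_csv(out / "nodal_metrics.tsv", sep="\t")
    if bundle.pls is not None:
        io.write_json(
            {
                "pct_variance": bundle.pls.pct_variance,
                "cumulative_pct_variance": bundle.pls.cumulative_pct_variance,
                "correlations_r": bundle.correlations["r"].to_dict() if bundle.correlations else None,
                "correlations_p": bundle.correlations["p"].to_dict() if bundle.correlations else None,
                "permutation_p": bundle.permutation.p if bundle.permutation else None,
                "permutation_scheme": bundle.permutation.scheme if bundle.permutation else None,
            },
            out / "pls_report.json",
        )
    for comp, ranking in bundle.rankings.items():
        ranking.to_csv(out / f"gene_ranking_PLS{comp}.tsv", sep="\t", index=False)
    if bundle.enrichment is not None:
        bundle.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if bundle.candidate_tests:
        io.write_json(
            {f"{name}_PLS{comp}": {"observed": r.observed, "p": r.p} for (name, comp), r in bundle.candidate_tests.items()},
            out / "candidate_tests.json",
        )
    if bundle.sweep is not None:
        bundle.sweep.to_csv(out / "robustness_sweep.tsv", sep="\t", index=False)
    io.write_json({"provenance": bundle.provenance, "log": bundle.log, "errors": bundle.errors}, out / "run.json")
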