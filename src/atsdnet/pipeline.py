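"""End-to-end orchestration: filter -> networks -> analysis -> evaluation.

The library entry point is :func:`run`, which takes an in-memory dataset,
a stage design and a :class:`PipelineParams` and returns a
:class:`PipelineResult` with every intermediate artifact.  The file-based
entry point :func:`run_pipeline` reads a YAML config, executes :func:`run`
and writes all artifacts plus a JSON manifest to a run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

from . import __version__
from .data_model import (
    StageDesign,
    TimeSeriesDataset,
    load_dataset,
    validate_design,
)
from .dynamic_network import DynamicNetwork, degree_stats, network_series
from .evaluation import ALPHA, candidate_report, pca_summary, screen_candidates
from .network_analysis import FeatureSubset, combine, dynamic_concentration, topological_structure
from .ratio_dynamics import GAMMA, TAU
from .static_filter import RfeConfig, retained_features

log = logging.getLogger("atsdnet")


@dataclass(frozen=True)
class PipelineParams:
    """Paper-parameterised defaults for a full run.

    tau=0.85 and gamma=1.732 drive network construction; the
    dynamic-concentration window and top-k topology analysis use the
    stage design; subsets combine by intersection with k=1 by default.
    """

    tau: float = TAU
    gamma: float = GAMMA
    k: int = 1
    mode: Literal["concentration", "topology", "both"] = "both"
    combine_mode: Literal["intersection", "union"] = "intersection"
    run_filter: bool = True
    rfe: RfeConfig = field(default_factory=RfeConfig)
    alpha: float = ALPHA
    group: str | None = "model"


def default_design(ds: TimeSeriesDataset, lookback: int = 3) -> StageDesign:
    """Stage design read off the dataset: typical point = last point of each
    stage; onset = typical point of the final stage; N_e defaults to 3."""
    typical = {s: ds.stage_points(s)[-1] for s in ds.stages}
    onset = typical[ds.stages[-1]]
    lookback = min(lookback, onset - 1)
    return StageDesign(typical_points=typical, onset_point=onset, lookback=lookback)


@dataclass
class PipelineResult:
    retained: list[str]
    networks: list[DynamicNetwork]
    degree_table: pd.DataFrame
    subset1: FeatureSubset | None
    subset2: FeatureSubset | None
    combined: FeatureSubset | None
    report: pd.DataFrame | None
    screened: list[str]
    counts: dict

    def candidate_pairs(self) -> list[tuple[str, str]]:
        src = self.combined or self.subset1 or self.subset2
        return src.sorted_pairs() if src else []


def run(
    ds: TimeSeriesDataset,
    design: StageDesign | None = None,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Execute every pipeline stage in order on an in-memory dataset."""
    design = design or default_design(ds)
    validate_design(ds, design)

    if params.run_filter:
        retained = retained_features(ds, design, params.rfe)
    else:
        retained = ds.feature_names
    n_ratios = len(retained) * (len(retained) - 1) // 2
    log.info("retained %d features -> %d feature ratios", len(retained), n_ratios)

    networks = network_series(
        ds, features=retained, tau=params.tau, gamma=params.gamma, group=params.group
    )
    edge_counts = {net.t: net.n_edges for net in networks}
    log.info("edges per network: %s", edge_counts)
    degrees = degree_stats(networks)

    subset1 = subset2 = combined = None
    if params.mode in ("concentration", "both"):
        subset1 = dynamic_concentration(networks, design)
        log.info("dynamic concentration: %d ratios", len(subset1))
    if params.mode in ("topology", "both"):
        subset2 = topological_structure(networks, k=params.k)
        log.info(
            "topological structure: %d ratios from DN-%d",
            len(subset2), subset2.evidence["network_t"],
        )
    if subset1 is not None and subset2 is not None:
        combined = combine(subset1, subset2, params.combine_mode)
        log.info("%s: %d ratios", params.combine_mode, len(combined))

    final = combined or subset1 or subset2
    report = None
    screened: list[str] = []
    if final and len(final) > 0:
        pairs = final.sorted_pairs()
        report = candidate_report(ds, design, pairs, alpha=params.alpha)
        screened = screen_candidates(report, alpha=params.alpha)
        log.info("screened candidates: %d of %d", len(screened), len(pairs))

    counts = {
        "n_features": ds.n_features,
        "n_retained": len(retained),
        "n_ratios": n_ratios,
        "n_networks": len(networks),
        "edges_per_network": edge_counts,
        "subset1_size": len(subset1) if subset1 else None,
        "subset2_size": len(subset2) if subset2 else None,
        "combined_size": len(combined) if combined else None,
        "n_screened": len(screened),
    }
    return PipelineResult(
        retained=retained,
        networks=networks,
        degree_table=degrees,
        subset1=subset1,
        subset2=subset2,
        combined=combined,
        report=report,
        screened=screened,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# file-based runs


def load_run_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path} must be a mapping")
    return cfg


def _params_from_config(cfg: dict) -> PipelineParams:
    sf = cfg.get("static_filter", {})
    rfe = RfeConfig(
        elim_fraction=sf.get("elim_fraction", 0.10),
        n_folds=sf.get("n_folds", 5),
        n_repeats=sf.get("n_repeats", 50),
        selection_threshold=sf.get("selection_threshold", 0.5),
        seed=sf.get("seed", cfg.get("seed", 0)),
        C=sf.get("C", 1.0),
    )
    return PipelineParams(
        tau=cfg.get("tau", TAU),
        gamma=cfg.get("gamma", GAMMA),
        k=cfg.get("k", 1),
        mode=cfg.get("mode", "both"),
        combine_mode=cfg.get("combine_mode", "intersection"),
        run_filter=cfg.get("run_filter", True),
        rfe=rfe,
        alpha=cfg.get("alpha", ALPHA),
        group=cfg.get("group", "model"),
    )


def _design_from_config(cfg: dict, ds: TimeSeriesDataset) -> StageDesign:
    d = cfg.get("design")
    if not d:
        return default_design(ds)
    return StageDesign(
        typical_points={str(k): int(v) for k, v in d["typical_points"].items()},
        onset_point=int(d["onset_point"]),
        lookback=int(d.get("lookback", 3)),
    )


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> PipelineResult:
    """Run from a YAML/dict config and write all artifacts plus a manifest."""
    if not isinstance(config, dict):
        config = load_run_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    input_path = Path(config["input"])
    ds = load_dataset(input_path, config["schema"])
    design = _design_from_config(config, ds)
    params = _params_from_config(config)

    result = run(ds, design, params)

    (outdir / "retained_features.txt").write_text("\n".join(result.retained) + "\n")
    for net in result.networks:
        net.write_edges(outdir / f"dn_{net.t}.edges.tsv")
        net.write_graphml(outdir / f"dn_{net.t}.graphml")
    result.degree_table.to_csv(outdir / "degree_table.tsv", sep="\t")
    for name, subset in (
        ("subset1", result.subset1),
        ("subset2", result.subset2),
        ("combined", result.combined),
    ):
        if subset is not None:
            subset.to_frame().to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    if result.report is not None:
        result.report.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        pairs = result.candidate_pairs()
        if pairs:
            cols = {
                f"{fi}/{fj}": ds.abundance[fi].to_numpy() / ds.abundance[fj].to_numpy()
                for fi, fj in pairs
            }
            mat = pd.DataFrame(cols)
            if mat.shape[1] >= 2:
                pca = pca_summary(mat)
                scores = pca["scores"].copy()
                scores["group"] = ds.meta["group"]
                scores["time"] = ds.meta["time"]
                scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index=False)
                result.counts["pca_explained"] = pca["explained"]
                result.counts["pca_cumulative"] = pca["cumulative"]

    manifest = {
        "atsdnet_version": __version__,
        "input": str(input_path),
        "input_sha256": hashlib.sha256(input_path.read_bytes()).hexdigest(),
        "design": {
            "typical_points": dict(design.typical_points),
            "onset_point": design.onset_point,
            "lookback": design.lookback,
            "window": design.concentration_window(),
        },
        "params": {
            "tau": params.tau,
            "gamma": params.gamma,
            "k": params.k,
            "mode": params.mode,
            "combine_mode": params.combine_mode,
            "run_filter": params.run_filter,
            "alpha": params.alpha,
            "group": params.group,
            "rfe": {
                "elim_fraction": params.rfe.elim_fraction,
                "n_folds": params.rfe.n_folds,
                "n_repeats": params.rfe.n_repeats,
                "selection_threshold": params.rfe.selection_threshold,
                "seed": params.rfe.seed,
                "C": params.rfe.C,
            },
        },
        "counts": result.counts,
        "screened": result.screened,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
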