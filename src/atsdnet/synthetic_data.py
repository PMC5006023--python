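"""Synthetic time-series cohorts with planted ratio-shift biomarkers.

The generator emulates a repeated-measures two-group study design: a
control and a model (diseased) cohort sampled at ``N`` time points that
span contiguous disease stages, with a handful of feature pairs planted to
carry a persistent ratio shift from a disease-onset time point onward.

Abundances are log-normal: on the log scale each cell is

    baseline_i + subject_effect(s, i) + planted_shift(g, i, t) + noise

with the subject effect a per-(subject, feature) random intercept constant
over time.  For each planted pair the numerator feature gains
``log_fold_shift`` *per time step* from ``shift_onset`` onward (a cumulative
monotone ramp) and the partner feature declines by
``partner_log_fold_shift`` per step, mimicking the one-up / one-down lipid
pattern of a disease-progression biomarker ratio; control subjects never
receive the shift.  The ramp makes the planted ratio's effective range
upshift at every post-onset transition, so its edge persists across the
post-onset networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CONTROL, MODEL, TimeSeriesDataset

DISCOVERY_STAGE_MAP = {1: "H", 2: "CIR", 3: "CIR", 4: "CIR", 5: "HCC", 6: "HCC", 7: "HCC"}
VALIDATION_STAGE_MAP = {1: "H", 2: "CIR", 3: "CIR", 4: "CIR", 5: "HCC", 6: "HCC"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and effect-size parameters of the generator.

    Defaults emulate the discovery cohort of a stepwise
    hepatocarcinogenesis design: 10 control + 7 model subjects sampled at
    7 time points over three contiguous stages (H / CIR / HCC), with 4
    planted biomarker pairs whose ratio starts shifting at the HCC onset
    point T_5.  All scales are on the natural-log scale.
    """

    n_control: int = 10
    n_model: int = 7
    n_time: int = 7
    stage_map: dict = field(default_factory=lambda: dict(DISCOVERY_STAGE_MAP))
    m: int = 40
    n_planted_pairs: int = 4
    shift_onset: int = 5
    log_fold_shift: float = 0.8
    partner_log_fold_shift: float = -0.4
    subject_sd: float = 0.10
    noise_sd: float = 0.15
    baseline_log_mean: tuple[float, float] = (0.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.shift_onset <= self.n_time:
            raise ValueError(f"shift_onset must be in 2..{self.n_time}")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if 2 * self.n_planted_pairs > self.m:
            raise ValueError(
                f"{self.n_planted_pairs} disjoint planted pairs need "
                f">= {2 * self.n_planted_pairs} features, have m={self.m}"
            )
        if set(self.stage_map) != set(range(1, self.n_time + 1)):
            raise ValueError("stage_map must cover 1..n_time")


def validation_config(**overrides) -> GeneratorConfig:
    """External-validation cohort design: 6 model subjects, 6 time points."""
    base = dict(
        n_control=0,
        n_model=6,
        n_time=6,
        stage_map=dict(VALIDATION_STAGE_MAP),
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def generate(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[TimeSeriesDataset, dict]:
    """Generate a cohort and its ground-truth manifest, reproducibly from seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m, N = config.m, config.n_time
    features = [f"feat{k:03d}" for k in range(m)]

    # disjoint planted pairs; the lower canonical index is the numerator so
    # the canonical ratio orientation shifts upward by construction
    chosen = rng.choice(m, size=2 * config.n_planted_pairs, replace=False)
    planted = [tuple(sorted(chosen[2 * k: 2 * k + 2])) for k in range(config.n_planted_pairs)]

    baselines = rng.uniform(*config.baseline_log_mean, size=m)

    subjects = [f"c{k + 1}" for k in range(config.n_control)] + [
        f"m{k + 1}" for k in range(config.n_model)
    ]
    groups = [CONTROL] * config.n_control + [MODEL] * config.n_model
    subject_effects = rng.normal(0.0, config.subject_sd, size=(len(subjects), m))

    # cumulative post-onset ramp: 0 before onset, +delta per step from onset on
    steps = np.array([max(0, t - config.shift_onset + 1) for t in range(1, N + 1)])
    shift = np.zeros((N, m))
    for i, j in planted:
        shift[:, i] += config.log_fold_shift * steps
        shift[:, j] += config.partner_log_fold_shift * steps

    rows_meta = []
    rows_log = []
    for s_idx, (subj, grp) in enumerate(zip(subjects, groups)):
        for t in range(1, N + 1):
            log_f = baselines + subject_effects[s_idx]
            if grp == MODEL:
                log_f = log_f + shift[t - 1]
            log_f = log_f + rng.normal(0.0, config.noise_sd, size=m)
            rows_meta.append((subj, grp, t))
            rows_log.append(log_f)

    abundance = pd.DataFrame(np.exp(np.vstack(rows_log)), columns=features)
    meta = pd.DataFrame(rows_meta, columns=["subject", "group", "time"])
    ds = TimeSeriesDataset(
        abundance=abundance,
        subject_id=meta["subject"],
        group=meta["group"],
        time_index=meta["time"],
        stage_map=config.stage_map,
    )
    manifest = {
        "planted_pairs": [[features[i], features[j]] for i, j in planted],
        "planted_features": sorted({features[i] for p in planted for i in p}),
        "config": {**asdict(config), "baseline_log_mean": list(config.baseline_log_mean)},
        "seed": int(config.seed if seed is None else seed),
    }
    return ds, manifest


def write_cohort(
    ds: TimeSeriesDataset, manifest: dict, outdir: str | Path, name: str = "cohort"
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.write(outdir / f"{name}.csv")
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2))


def recovery_experiment(
    config: GeneratorConfig,
    pipeline_params=None,
    seeds=range(10),
) -> pd.DataFrame:
    """Run the full pipeline over generated cohorts; report planted-pair recovery.

    For each seed the cohort is regenerated, the pipeline is run, and each
    planted pair is checked for membership in feature subset 1 (dynamic
    concentration), feature subset 2 (topological structure), their
    combination, and the final univariate screen.  Returns one row per
    (seed, planted pair).

    By default the static filter is skipped (all features enter the
    networks): the recovery question addresses the network stage, and a
    planted pair whose ratio shift is large enough to form edges separates
    the stage classes so widely that the filter's best-accuracy rule keeps
    only one of its two features.  Pass ``pipeline_params`` with
    ``run_filter=True`` to study the filtered pipeline.
    """
    from .errors import AtsdnetError
    from .pipeline import PipelineParams, default_design, run

    params = pipeline_params or PipelineParams(run_filter=False)
    rows = []
    for seed in seeds:
        ds, manifest = generate(replace(config, seed=int(seed)))
        design = default_design(ds)
        try:
            result = run(ds, design, params)
        except AtsdnetError:
            # e.g. every network empty at zero effect: nothing is recovered
            result = None
        screened = set(result.screened) if result else set()
        for fi, fj in manifest["planted_pairs"]:
            pair = (fi, fj)

            def _member(subset):
                return bool(result and subset and pair in subset.pairs)

            rows.append(
                {
                    "seed": int(seed),
                    "pair": f"{fi}/{fj}",
                    "in_subset1": _member(result.subset1 if result else None),
                    "in_subset2": _member(result.subset2 if result else None),
                    "in_combined": _member(result.combined if result else None),
                    "in_screened": f"{fi}/{fj}" in screened,
                }
            )
    return pd.DataFrame(rows)
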