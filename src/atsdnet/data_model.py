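"""Domain types and tabular I/O for repeated-measures time-series omics data.

The single input object of the pipeline is :class:`TimeSeriesDataset`: a
wide sample-by-feature table of strictly positive relative abundances,
annotated per sample with a subject identifier, a group label
(``control`` / ``model``) and a 1-based time-point index, plus a mapping
from time points to disease stages.  :class:`StageDesign` captures the
stage-level structure used downstream: the typical (last) time point of
each stage, the onset point ``T_s`` of the stage whose early-warning
signal is sought, and the number of pre-onset points ``N_e`` examined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, SchemaError, ValidationError

CONTROL = "control"
MODEL = "model"

#: Default column roles for wide-format CSV/TSV tables.
DEFAULT_SCHEMA = {"subject_col": "subject", "group_col": "group", "time_col": "time"}


class TimeSeriesDataset:
    """Samples x features x time points with subject/group/stage annotations.

    Parameters
    ----------
    abundance:
        Sample-by-feature table of strictly positive relative abundances.
        Column order defines the canonical feature order that drives all
        downstream ``i < j`` ratio orientation.
    subject_id, group, time_index:
        Per-sample annotations, aligned with the rows of ``abundance``.
        ``group`` values must be ``"control"`` or ``"model"``;
        ``time_index`` is 1-based (``T_1 .. T_N``).
    stage_map:
        Mapping from every time index in ``1..N`` to a stage label.
    """

    def __init__(
        self,
        abundance: pd.DataFrame,
        subject_id: Sequence[str],
        group: Sequence[str],
        time_index: Sequence[int],
        stage_map: Mapping[int, str],
        validate: bool = True,
    ) -> None:
        self.abundance = abundance.reset_index(drop=True)
        self.meta = pd.DataFrame(
            {
                "subject": list(subject_id),
                "group": list(group),
                "time": [int(t) for t in time_index],
            }
        )
        self.stage_map = {int(t): str(s) for t, s in stage_map.items()}
        if validate:
            self._validate()

    # -- invariants ------------------------------------------------------

    def _validate(self) -> None:
        if len(self.meta) != len(self.abundance):
            raise ValidationError(
                f"{len(self.abundance)} abundance rows but {len(self.meta)} metadata rows"
            )
        bad_group = set(self.meta["group"]) - {CONTROL, MODEL}
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")

        values = self.abundance.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite abundance for sample {self._sample_label(r)!r}, "
                f"feature {self.abundance.columns[c]!r}"
            )
        if np.any(values <= 0):
            r, c = np.argwhere(values <= 0)[0]
            raise ValidationError(
                f"non-positive abundance ({values[r, c]}) for sample "
                f"{self._sample_label(r)!r}, feature {self.abundance.columns[c]!r}"
            )

        dup = self.meta.duplicated(subset=["subject", "time"], keep=False)
        if dup.any():
            row = self.meta[dup].iloc[0]
            raise ValidationError(
                f"subject {row['subject']!r} appears more than once at time point {row['time']}"
            )

        times = set(self.meta["time"])
        mapped = set(self.stage_map)
        expected = set(range(1, self.n_timepoints + 1))
        if mapped != expected:
            raise ValidationError(
                f"stage_map must cover time indices {sorted(expected)}, got {sorted(mapped)}"
            )
        if not times <= expected:
            raise ValidationError(
                f"time indices {sorted(times - expected)} outside 1..{self.n_timepoints}"
            )

    def _sample_label(self, row: int) -> str:
        m = self.meta.iloc[row]
        return f"{m['subject']}@T{m['time']}"

    # -- basic properties ------------------------------------------------

    @property
    def feature_names(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.abundance)

    @property
    def n_timepoints(self) -> int:
        """N: the number of time points (highest index in the stage map or data)."""
        return max(max(self.stage_map, default=0), int(self.meta["time"].max()))

    @property
    def stages(self) -> list[str]:
        """Distinct stage labels in time order of first appearance."""
        seen: list[str] = []
        for t in range(1, self.n_timepoints + 1):
            s = self.stage_map[t]
            if s not in seen:
                seen.append(s)
        return seen

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    # -- selection helpers ----------------------------------------------

    def mask(self, time: int | None = None, group: str | None = None) -> np.ndarray:
        m = np.ones(len(self.meta), dtype=bool)
        if time is not None:
            m &= (self.meta["time"] == int(time)).to_numpy()
        if group is not None:
            m &= (self.meta["group"] == group).to_numpy()
        return m

    def values_at(self, time: int, group: str | None = None) -> np.ndarray:
        """Abundance matrix (n_t x m) of the samples at one time point."""
        return self.abundance.to_numpy(dtype=float)[self.mask(time, group)]

    def subjects_at(self, time: int, group: str | None = None) -> list[str]:
        return list(self.meta.loc[self.mask(time, group), "subject"])

    def counts(self) -> pd.DataFrame:
        """Per-(group, time) sample counts, times as columns."""
        return (
            self.meta.groupby(["group", "time"]).size().unstack(fill_value=0)
        )

    def stage_points(self, stage: str) -> list[int]:
        return sorted(t for t, s in self.stage_map.items() if s == stage)

    # -- I/O -------------------------------------------------------------

    def to_frame(self, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
        schema = {**DEFAULT_SCHEMA, **(schema or {})}
        out = pd.DataFrame(
            {
                schema["subject_col"]: self.meta["subject"],
                schema["group_col"]: self.meta["group"],
                schema["time_col"]: self.meta["time"],
            }
        )
        return pd.concat([out, self.abundance], axis=1)

    def write(self, path: str | Path, schema: Mapping[str, str] | None = None) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        self.to_frame(schema).to_csv(path, sep=sep, index=False)


def load_dataset(
    path: str | Path,
    schema: Mapping[str, object],
) -> TimeSeriesDataset:
    """Read a wide CSV/TSV table into a validated :class:`TimeSeriesDataset`.

    ``schema`` must provide ``subject_col``, ``group_col``, ``time_col`` and
    ``stage_map`` (time index -> stage label; string keys are accepted so the
    mapping can come straight from YAML/JSON).  Optional ``feature_cols``
    restricts and orders the feature columns; by default every remaining
    column is a feature, in file order.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep)
    return dataset_from_frame(table, schema)


def dataset_from_frame(
    table: pd.DataFrame, schema: Mapping[str, object]
) -> TimeSeriesDataset:
    for key in ("subject_col", "group_col", "time_col"):
        if key not in schema:
            raise SchemaError(f"schema is missing required key {key!r}")
        if schema[key] not in table.columns:
            raise SchemaError(f"column {schema[key]!r} ({key}) not found in table")
    if "stage_map" not in schema:
        raise SchemaError("schema is missing required key 'stage_map'")
    stage_map = {int(k): str(v) for k, v in dict(schema["stage_map"]).items()}

    meta_cols = [schema["subject_col"], schema["group_col"], schema["time_col"]]
    feature_cols = schema.get("feature_cols")
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in meta_cols]
    missing = [c for c in feature_cols if c not in table.columns]
    if missing:
        raise SchemaError(f"feature columns not found: {missing}")

    return TimeSeriesDataset(
        abundance=table[list(feature_cols)],
        subject_id=table[schema["subject_col"]].astype(str),
        group=table[schema["group_col"]].astype(str),
        time_index=table[schema["time_col"]].astype(int),
        stage_map=stage_map,
    )


@dataclass(frozen=True)
class StageDesign:
    """Stage-level analysis design.

    ``typical_points`` maps each stage to its typical (representative) time
    point — by convention the last point of the stage.  ``onset_point`` is
    the typical point ``T_s`` of the disease stage whose early-warning
    signal is sought, and ``lookback`` is ``N_e``, the number of pre-onset
    time points examined by dynamic-concentration analysis.
    """

    typical_points: Mapping[str, int]
    onset_point: int
    lookback: int

    def __post_init__(self) -> None:
        if self.onset_point <= 1:
            raise DesignError(f"onset point T_s={self.onset_point} must exceed 1")
        if self.lookback <= 0:
            raise DesignError(f"lookback N_e={self.lookback} must be positive")
        if self.onset_point - self.lookback < 1:
            raise DesignError(
                f"T_s - N_e = {self.onset_point - self.lookback} reaches before T_1"
            )

    def concentration_window(self) -> list[int]:
        """Indices t of the networks DN-t examined before onset.

        The window is ``s - N_e <= t < s - 1`` (upper bound exclusive), so
        for ``T_s = 7`` and ``N_e = 3`` it is ``[4, 5]``: networks DN-4
        (T4–T5) and DN-5 (T5–T6), built from the three pre-onset-window
        time points T4, T5 and T6.
        """
        return list(range(self.onset_point - self.lookback, self.onset_point - 1))

    def onset_stage(self, ds: TimeSeriesDataset) -> str:
        return ds.stage_map[self.onset_point]

    def disease_points(self, ds: TimeSeriesDataset) -> list[int]:
        """All time points belonging to the onset stage."""
        return ds.stage_points(self.onset_stage(ds))

    def reference_point(self, ds: TimeSeriesDataset) -> int:
        """Typical point of the stage immediately preceding the onset stage."""
        stages = ds.stages
        idx = stages.index(self.onset_stage(ds))
        if idx == 0:
            raise DesignError("onset stage has no preceding stage")
        return self.typical_points[stages[idx - 1]]


@dataclass
class DesignReport:
    """Outcome of checking a design against a dataset."""

    counts: pd.DataFrame
    stage_spans: dict[str, list[int]]
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return True  # construction fails (raises) before an invalid report exists


def validate_design(ds: TimeSeriesDataset, design: StageDesign) -> DesignReport:
    """Check stage contiguity and design bounds; report per-point counts.

    Raises :class:`DesignError` for structural problems (non-contiguous
    stage, typical point outside its stage, window out of range); records
    soft issues (unbalanced sampling) as warnings.
    """
    n = ds.n_timepoints
    spans: dict[str, list[int]] = {}
    for stage in ds.stages:
        pts = ds.stage_points(stage)
        if pts != list(range(pts[0], pts[-1] + 1)):
            raise DesignError(f"stage {stage!r} spans non-consecutive time points {pts}")
        spans[stage] = pts

    for stage, tp in design.typical_points.items():
        if stage not in spans:
            raise DesignError(f"typical point declared for unknown stage {stage!r}")
        if tp not in spans[stage]:
            raise DesignError(
                f"typical point T_{tp} of stage {stage!r} lies outside its span {spans[stage]}"
            )
    for stage in spans:
        if stage not in design.typical_points:
            raise DesignError(f"stage {stage!r} has no typical point declared")

    if design.onset_point > n:
        raise DesignError(f"onset point T_{design.onset_point} exceeds N={n}")
    window = design.concentration_window()
    if not window:
        raise DesignError(
            f"empty concentration window for T_s={design.onset_point}, N_e={design.lookback}"
        )
    if window[0] < 1 or window[-1] > n - 1:
        raise DesignError(f"concentration window {window} outside networks 1..{n - 1}")

    counts = ds.counts()
    report = DesignReport(counts=counts, stage_spans=spans)
    for group in counts.index:
        per_t = counts.loc[group]
        observed = per_t[per_t > 0]
        if len(observed.unique()) > 1:
            msg = f"group {group!r} is unbalanced across time points: {per_t.to_dict()}"
            report.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    return report
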