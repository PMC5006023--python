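import numpy as np
import pandas as pd
import pytest

from atsdnet.data_model import StageDesign, TimeSeriesDataset
from atsdnet.synthetic_data import GeneratorConfig, generate

DISCOVERY_STAGES = {1: "H", 2: "CIR", 3: "CIR", 4: "CIR", 5: "HCC", 6: "HCC", 7: "HCC"}


def make_dataset(values, stage_map, groups=None):
    """Build a small dataset from {feature: {time: [per-subject values]}}.

    Every time point must list the same number of subjects; subject k is
    ``s{k}`` and belongs to ``groups[k]`` (default: all model).
    """
    features = list(values)
    times = sorted(next(iter(values.values())))
    n_sub = len(values[features[0]][times[0]])
    groups = groups or ["model"] * n_sub
    rows, meta = [], []
    for t in times:
        for k in range(n_sub):
            rows.append([values[f][t][k] for f in features])
            meta.append((f"s{k}", groups[k], t))
    m = pd.DataFrame(meta, columns=["subject", "group", "time"])
    return TimeSeriesDataset(
        abundance=pd.DataFrame(rows, columns=features),
        subject_id=m["subject"],
        group=m["group"],
        time_index=m["time"],
        stage_map=stage_map,
    )


@pytest.fixture(scope="session")
def discovery_design():
    return StageDesign(typical_points={"H": 1, "CIR": 4, "HCC": 7}, onset_point=7, lookback=3)


@pytest.fixture(scope="session")
def discovery_cohort():
    """Default synthetic discovery cohort with its ground-truth manifest."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def single_pair_cohort():
    """Discovery-design cohort with a single planted biomarker pair."""
    return generate(GeneratorConfig(n_planted_pairs=1, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
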