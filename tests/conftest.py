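import numpy as np
import pandas as pd
import pytest

from segmem.pipeline import outcome_model_data
from segmem.scoring import score_dataset
from segmem.segmentation import compute_all_agreements
from segmem.simulate import SimConfig, simulate_study
from segmem.videos import default_videos


@pytest.fixture(scope="session")
def videos():
    return default_videos()


@pytest.fixture(scope="session")
def small_config():
    """10 + 10 participants, fixed seed: the standing small-study fixture."""
    return SimConfig(seed=7, group_sizes={"gyoza": 10, "taichi": 10})


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_outcomes(small_study):
    return score_dataset(small_study.survey, small_study.trials, small_study.recall)


@pytest.fixture(scope="session")
def small_agreement(small_study):
    return compute_all_agreements(small_study)


@pytest.fixture(scope="session")
def model_tables(small_study, small_outcomes, small_agreement):
    """Complete-case model tables for the small fixture, keyed by outcome."""
    return {
        name: outcome_model_data(
            name, small_outcomes, small_agreement, small_study.design
        )
        for name in (
            "survey",
            "recognition",
            "order",
            "recall",
            "segmentation_count",
            "segmentation_agreement",
        )
    }


def fast_sim_config(**kwargs) -> SimConfig:
    """Config with the press-log generator silenced (no presses), for
    simulation studies that only consume the graded outcomes."""
    cfg = SimConfig(**kwargs)
    cfg.segmentation.detection_coarse = {"gyoza": 0.0, "taichi": 0.0}
    cfg.segmentation.detection_fine = {"gyoza": 0.0, "taichi": 0.0}
    cfg.segmentation.false_alarm_rate = 0.0
    return cfg


def recognition_table(dataset) -> pd.DataFrame:
    """Fast aggregated recognition proportions (equivalent to twoafc_score,
    whose arithmetic is covered by the scoring tests)."""
    rec = dataset.trials[dataset.trials["task"] == "recognition"]
    agg = (
        rec.groupby(["participant", "session", "activity"], sort=False)["correct"]
        .agg(successes="sum", trials="size")
        .reset_index()
    )
    agg["proportion"] = agg["successes"] / agg["trials"]
    return agg.merge(dataset.design[["participant", "group"]], on="participant")
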