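"""Shared fixtures: analyzed synthetic scenes reused across test modules.

The four canonical case days and the multi-day deployment are rendered and
analyzed once per session; several modules (soundscape, pipeline,
acceptance) assert different properties of the same runs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from seachorus.ordinal import OrdinalWarning
from seachorus.pipeline import RunConfig, analyze_audio
from seachorus.soundscape import deployment_config, render_scene, scene_presets

SCENE_SEED = 1


@pytest.fixture(autouse=True)
def _quiet_short_series_warning():
    # hourly windows of compressed scenes are legitimately < 100·d! samples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OrdinalWarning)
        yield


def _analyze_scene(cfg) -> tuple[pd.DataFrame, pd.DataFrame]:
    audio, truth = render_scene(cfg)
    run = RunConfig(seconds_per_hour=cfg.seconds_per_hour)
    results = analyze_audio(audio, run, stem="scene")
    return results, truth


@pytest.fixture(scope="session")
def case_days() -> dict:
    """The four case presets (seed fixed), analyzed hourly.

    Returns {case: {"results": tidy df, "wide": wide df, "truth": df}}.
    """
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for case, cfg in scene_presets(seed=SCENE_SEED).items():
            results, truth = _analyze_scene(cfg)
            wide = results.pivot_table(
                index=["window_id", "clock_hour"], columns="measure", values="value", sort=False
            ).reset_index()
            out[case] = {"results": results, "wide": wide, "truth": truth, "config": cfg}
    return out


@pytest.fixture(scope="session")
def deployment_run() -> dict:
    """A six-day deployment with recurring nightly choruses, analyzed hourly."""
    cfg = deployment_config(days=6, seed=SCENE_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results, truth = _analyze_scene(cfg)
    wide = results.pivot_table(
        index=["window_id", "clock_hour"], columns="measure", values="value", sort=False
    ).reset_index()
    return {"results": results, "wide": wide, "truth": truth, "config": cfg}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
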