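import numpy as np
import pytest

from vrgaze import classify as clf
from vrgaze import kinematics
from vrgaze.io import PipelineConfig
from vrgaze.paradigm import WorldLayout, build_schedule
from vrgaze.simulate import SimulationParams, simulate_session


@pytest.fixture(scope="session")
def layout():
    return WorldLayout()


@pytest.fixture()
def cfg():
    return PipelineConfig()


def make_session(layout, trial_slice, seed=0, **param_overrides):
    """Simulate a (sub)session and classify it; shared across test modules."""
    schedule = build_schedule(layout, seed=seed)
    schedule.trials = schedule.trials[trial_slice]
    params = SimulationParams(seed=seed, **param_overrides)
    rec, events, truth = simulate_session(schedule, layout, params)
    config = PipelineConfig()
    speeds = kinematics.compute_speeds(rec, config)
    segments = clf.classify_recording(rec, config)
    return {"rec": rec, "events": events, "truth": truth, "speeds": speeds,
            "segments": segments, "schedule": schedule, "params": params,
            "cfg": config}


@pytest.fixture(scope="session")
def small_session(layout):
    """12 trials, default noise: static block head-fixed trials plus VOR."""
    return make_session(layout, slice(48, 60), seed=0)


@pytest.fixture(scope="session")
def dynamic_session(layout):
    """One dynamic block (48 trials), default noise."""
    return make_session(layout, slice(96, 144), seed=0)


@pytest.fixture(scope="session")
def full_session(layout):
    """The complete 288-trial session under the default study conditions."""
    return make_session(layout, slice(None), seed=0)


@pytest.fixture(scope="session")
def noiseless_session(layout):
    """96 mixed static/dynamic trials with noise and dropout disabled."""
    schedule = build_schedule(WorldLayout(), seed=0)
    schedule.trials = schedule.trials[48:144]
    return make_session(layout, slice(48, 144), seed=0,
                        fixation_noise_sd=0.0, dropout_rate=0.0)
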