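import numpy as np
import pytest

from organoquant import synthetic as syn
from organoquant.ktr import aggregate_per_organoid, analyze_movie

#: the live-imaging schedule: 13 frames at 10-min spacing (T0..T12 = 120 min)
FRAME_TIMES = np.arange(13) * 10.0


@pytest.fixture(scope="session")
def step_movie():
    """20-cell reporter movie, step stimulation at T0, default noise."""
    scene = syn.ktr_scene(20, FRAME_TIMES, seed=1)
    params = syn.KineticsParams()
    stack, truth = syn.render_movie(scene, params, syn.step_activity(FRAME_TIMES),
                                    r0=params.r_min)
    return scene, params, stack, truth


@pytest.fixture(scope="session")
def step_movie_noise_free():
    scene = syn.ktr_scene(20, FRAME_TIMES, seed=1)
    params = syn.KineticsParams(noise_sd=0.0)
    stack, truth = syn.render_movie(scene, params, syn.step_activity(FRAME_TIMES),
                                    r0=params.r_min)
    return scene, params, stack, truth


@pytest.fixture(scope="session")
def cohort_trace(step_movie):
    """Pipeline-recovered per-cell records and cohort-mean trace."""
    _, _, stack, _ = step_movie
    records = analyze_movie(stack)
    return records, aggregate_per_organoid(records)


def normalized_truth(truth):
    """Ground-truth cohort-mean normalized trace (percent of T0 mean)."""
    gt = truth.groupby("time_min")["true_ratio"].mean().sort_index()
    return (gt / gt.iloc[0] * 100.0).to_numpy(), gt.index.to_numpy()
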