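"""Shared fixtures: simulated cohorts at the study's default conditions.

The heavy cohorts are session-scoped so the recovery, accuracy and
acceptance tests all reuse one simulation per motion mode.
"""
from __future__ import annotations

import numpy as np
import pytest

from cellodyn import kinetics, segment, sim


@pytest.fixture(scope="session")
def default_params() -> segment.SegmentationParams:
    return segment.SegmentationParams()


@pytest.fixture(scope="session")
def duration_cohort(default_params):
    """Duration-mode cohort at study defaults: 6000 molecules, 1.5 nm noise."""
    cfg = sim.SimConfig(n_molecules=6000, rng_seed=123)
    trajs, truths = sim.simulate_experiment(cfg)
    movie_length = cfg.n_frames * cfg.frame_interval
    segmented = [segment.segment_trajectory(t, default_params, movie_length) for t in trajs]
    kept, report = segment.apply_filters(segmented, default_params)
    return {
        "config": cfg,
        "trajectories": trajs,
        "truths": truths,
        "segmented": segmented,
        "kept": kept,
        "filter_report": report,
        "movie_length": movie_length,
    }


@pytest.fixture(scope="session")
def duration_cohort_fits(duration_cohort, default_params):
    samples = kinetics.collect_dwell_samples(duration_cohort["kept"], default_params)
    fits = {}
    for label, s in samples.items():
        try:
            fits[label] = kinetics.fit_exponential_mle(s, boot_iterations=1000, seed=7)
        except ValueError:
            pass
    counts = kinetics.branching_fractions(duration_cohort["kept"])
    return {"samples": samples, "fits": fits, "counts": counts}


@pytest.fixture(scope="session")
def runlength_cohort(default_params):
    """Run-length-mode cohort: exponential detected run lengths, mean 38.6 nm."""
    cfg = sim.SimConfig(n_molecules=3000, rng_seed=456, motion_mode="runlength")
    trajs, truths = sim.simulate_experiment(cfg)
    movie_length = cfg.n_frames * cfg.frame_interval
    segmented = [segment.segment_trajectory(t, default_params, movie_length) for t in trajs]
    kept, _ = segment.apply_filters(segmented, default_params)
    return {"config": cfg, "truths": truths, "kept": kept, "segmented": segmented}


def processive_segments(segmented):
    return [sg for st in segmented for sg in st.segments if sg.kind == segment.PROCESSIVE]
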