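import numpy as np
import pytest

from whitefront import (
    ScenarioParams,
    TrackConfig,
    build_rcurve,
    modulus_from_record,
    sync_frames,
    synth_video,
    track,
)


@pytest.fixture(scope="session")
def default_scenario():
    """Default synthetic fracture test rendered once for the whole session."""
    params = ScenarioParams(seed=0)
    frames, truth = synth_video(params)
    return params, frames, truth


@pytest.fixture(scope="session")
def tracked_scenario(default_scenario):
    """Full pipeline run (sync -> track) on the default scenario."""
    params, frames, truth = default_scenario
    synced = sync_frames(frames, truth.mech)
    cfg = TrackConfig(roi=params.roi(), reg_window=params.reg_window())
    trajectory = track(frames, synced, params.notch_tip_px, params.calibration, cfg)
    return params, frames, truth, synced, trajectory


@pytest.fixture(scope="session")
def recovered_rcurve(tracked_scenario):
    """Pipeline and reference resistance curves for the default scenario."""
    params, frames, truth, synced, trajectory = tracked_scenario
    force = np.array([s.force_N for s in synced if s.synced])
    disp = np.array([s.disp_mm for s in synced if s.synced])
    E, fit = modulus_from_record(force, disp, params.geometry)
    pipeline = build_rcurve(trajectory, params.geometry, E, m=fit.m)
    reference = truth.reference_rcurve(frames)
    return pipeline, reference
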