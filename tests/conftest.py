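import numpy as np
import pytest

from flightmaneuvers.pipeline import extract_from_trajectory
from flightmaneuvers.synthetic import gen_bout, standard_bouts


def overlaps(t_start, t_end, a, b) -> bool:
    return min(t_end, b) - max(t_start, a) > 0


def match_detections(truth, found, times):
    """Map each planted maneuver to same-class detections overlapping it."""
    out = []
    for t in truth:
        cands = [
            m
            for m in found
            if m.maneuver_class == t.maneuver_class
            and overlaps(t.t_start, t.t_end, times[m.start_frame], times[m.end_frame])
        ]
        out.append((t, cands))
    return out


@pytest.fixture(scope="session")
def clean_bout_results():
    """Noise-free standard bouts run through extraction (no smoothing)."""
    results = []
    for k, plan in enumerate(standard_bouts()):
        traj, truth = gen_bout(plan, object_id=f"bout{k}")
        kin, found = extract_from_trajectory(traj, smooth=False)
        results.append((traj, truth, kin, found))
    return results


@pytest.fixture(scope="session")
def noisy_bout_results():
    """Standard bouts with tracking noise, smoothed before extraction.

    Position noise matches the tracker's observation SD (12 mm), the
    orientation noise the orientation observation SD, and the body-axis
    sign is flipped at random per frame.
    """
    results = []
    for seed in range(6):
        rng = np.random.default_rng(seed)
        plans = standard_bouts(noise_sd=0.012, ori_noise_sd=0.0012, sign_flip_p=0.5)
        for k, plan in enumerate(plans):
            traj, truth = gen_bout(plan, rng=rng, object_id=f"bout{k}")
            kin, found = extract_from_trajectory(traj, smooth=True)
            results.append((traj, truth, kin, found))
    return results
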