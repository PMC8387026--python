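import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ilexys_params():
    from lexykit.presets import live_preset

    return live_preset("live-iLEXYs")


@pytest.fixture(scope="session")
def constant_trace():
    """A flat model trace (dark steady state held) for rendering tests."""
    from lexykit.photocycle import StateTrace

    t = np.array([0.0, 1000.0])
    return StateTrace(times=t, u=np.zeros(2), N=np.full(2, 0.75), C=np.full(2, 0.25))


@pytest.fixture(scope="session")
def induction_run():
    """Default live induction pipeline run (iLEXYs preset), shared read-only."""
    from lexykit.pipeline import run_live_experiment

    return run_live_experiment("live-iLEXYs", phase="induction", n_cells=10,
                               frame_interval_min=0.5, duration_min=10.0, seed=1)


def detection_f1(gt_labels, pred_labels, iou_threshold=0.5):
    """Detection F1 between two label masks by greedy IoU matching."""
    gt_ids = [int(v) for v in np.unique(gt_labels) if v > 0]
    pred_ids = [int(v) for v in np.unique(pred_labels) if v > 0]
    matched_gt, matched_pred = set(), set()
    pairs = []
    for g in gt_ids:
        gm = gt_labels == g
        for p in pred_ids:
            pm = pred_labels == p
            inter = np.logical_and(gm, pm).sum()
            if inter == 0:
                continue
            iou = inter / np.logical_or(gm, pm).sum()
            if iou >= iou_threshold:
                pairs.append((iou, g, p))
    for _, g, p in sorted(pairs, reverse=True):
        if g not in matched_gt and p not in matched_pred:
            matched_gt.add(g)
            matched_pred.add(p)
    tp = len(matched_gt)
    fp = len(pred_ids) - tp
    fn = len(gt_ids) - tp
    return 2 * tp / max(2 * tp + fp + fn, 1)
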