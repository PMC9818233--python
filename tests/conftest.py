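import numpy as np
import pytest
from hypothesis import settings

import pvcnet as pv
from pvcnet.nn import build_model, resnet_tiny_spec

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


TINY_RENDER = pv.RenderConfig(height=64, width=64)


def match_detections(detected, truth, tolerance):
    """Greedy one-to-one matching of detections to ground-truth R indices.

    Returns (sensitivity, positive predictivity)."""
    truth = np.asarray(truth)
    used = set()
    tp = 0
    for p in detected:
        d = np.abs(truth - p)
        j = int(np.argmin(d))
        if d[j] <= tolerance and j not in used:
            used.add(j)
            tp += 1
    sens = tp / len(truth) if len(truth) else 0.0
    ppv = tp / len(detected) if len(detected) else 0.0
    return sens, ppv


def make_dataset(
    n_subjects: int,
    beats_per_subject: int,
    pvc_fraction: float = 0.2,
    noise_sd: float = 0.02,
    seed: int = 0,
    prefix: str = "S",
) -> pv.BeatDataset:
    """Synthetic multi-subject beat-image dataset at desk scale (64x64)."""
    spec = pv.RhythmSpec(
        n_beats=beats_per_subject + 2,  # endpoints are dropped at segmentation
        pvc_fraction=pvc_fraction,
        noise_sd=noise_sd,
        seed=seed,
    )
    recs = pv.generate_dataset(n_subjects, spec, record_prefix=prefix)
    return pv.build_dataset([r for r, _ in recs], TINY_RENDER)


@pytest.fixture(scope="session")
def trained_tiny():
    """A tiny residual network trained on clearly separated synthetic beats.

    Shared across tests that need any trained classifier; returns
    (model, dataset, history)."""
    ds = make_dataset(n_subjects=4, beats_per_subject=40, seed=5)
    cfg = pv.TrainConfig(max_epochs=6, seed=0)
    model = build_model(resnet_tiny_spec(), seed=0)
    model, hist = pv.fit(model, ds, cfg)
    return model, ds, hist
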