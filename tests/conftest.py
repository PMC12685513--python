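"""Shared fixtures.

The trained six-type classifier and the marker-correlation contexts are
expensive to build, so they are session-scoped and shared between the
unit tests and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import dpcscreen as d
from dpcscreen import classifier as C
from dpcscreen import experiments
from dpcscreen.markers import feature_marker_regression, select_correlated
from dpcscreen.morphometry import extract_features
from dpcscreen.phantoms import sample_population_at_fraction
from dpcscreen.pipeline import segmentation_params
from dpcscreen.segmentation import segment_cells


@pytest.fixture(scope="session")
def trained_model():
    """The default six-type classifier trained at study conditions."""
    model, curves = experiments.train_default_classifier(seed=7)
    return model, curves


def _tiny_separable_dataset(n_per_class=20, size=48, seed=0, shuffle_labels=False):
    """Six trivially separable synthetic classes.

    Class k carries 4k + 2 bright disks of radius 2 + 0.4k on a noisy
    background, so the classes differ in bright-area fraction, blob
    count and blob size — structure that survives per-image
    normalization.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    step = size // 5
    slots = [(step // 2 + i * step, step // 2 + j * step) for i in range(5) for j in range(5)]
    data = []
    for lbl in range(6):
        for _ in range(n_per_class):
            img_f = rng.normal(1000.0, 40.0, (size, size))
            chosen = rng.choice(len(slots), size=4 * lbl + 2, replace=False)
            for s in chosen:
                cy, cx = slots[s]
                img_f += 3000.0 * (np.hypot(yy - cy, xx - cx) < 2.0 + 0.4 * lbl)
            c2 = img_f.clip(0, 65535).astype(np.uint16)
            c1 = rng.normal(1000.0, 40.0, (size, size)).clip(0, 65535).astype(np.uint16)
            img = d.FieldImage(channels={"brightfield": c1, "dpc": c2})
            data.append(C.LabeledImage(image=img, type_label=lbl))
    if shuffle_labels:
        # i.i.d. random labels: the canonical chance-level control
        labels = rng.integers(0, 6, size=len(data))
        data = [
            C.LabeledImage(image=it.image, type_label=int(lbl))
            for it, lbl in zip(data, labels)
        ]
    return data


@pytest.fixture(scope="session")
def separable_dataset():
    return _tiny_separable_dataset()


@pytest.fixture(scope="session")
def shuffled_dataset():
    return _tiny_separable_dataset(n_per_class=130, shuffle_labels=True, seed=1)


@pytest.fixture(scope="session")
def marker_contexts():
    """Feature/marker regressions in three experimental contexts.

    Context profiles are per-condition mean features from segmented
    phantom fields: a stimulus dose series at 24 h, a time series at the
    model dose, and an inhibitor strength series at the model dose.
    """
    am = d.ActivationModel()
    params = segmentation_params(0.5)

    def profile(frac, seed):
        cells = sample_population_at_fraction(
            frac, 150, am, seed, canvas=(512, 512), render_scale=0.5
        )
        img = d.render_field(cells, 512, 512, ("dpc",), seed=seed + 1)
        feats = extract_features(img, segment_cells(img, "dpc", **params), "dpc")
        marker = float(np.mean([c.marker_intensity for c in cells]))
        return feats.iloc[:, 4:].mean(), marker

    f_model = am.activated_fraction_at(10.0, 24.0)
    context_fracs = {
        "dose": [am.activated_fraction_at(dd, 24.0) for dd in (0, 1.25, 2.5, 5, 10, 25)],
        "time": [am.activated_fraction_at(10.0, t) for t in (4, 8, 12, 16, 20, 24)],
        "inhibitor": [0.05 + (f_model - 0.05) * (1 - e) for e in (0.95, 0.8, 0.6, 0.4, 0.2, 0.0)],
    }
    out = {}
    for ci, (name, fracs) in enumerate(context_fracs.items()):
        rows, markers = [], []
        for j, f in enumerate(fracs):
            prof, mk = profile(f, 1000 + 10 * ci + j)
            rows.append(prof)
            markers.append(mk)
        results = feature_marker_regression(pd.DataFrame(rows), markers)
        out[name] = {
            "results": results,
            "selected": select_correlated(results, 0.3),
            "markers": markers,
        }
    return out
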