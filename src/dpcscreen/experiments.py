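"""Canonical desk-scale study conditions.

The fixed experiment recipes the package's validation studies run:
assay-quality plates, the seeded six-class training run, and the
planted-truth recovery screen.  Tests and the reproduction script call
these so that every report is recomputed from the same conditions.

Problem sizes are desk-scale by design: plates image two 512 x 512
fields per well at render scale 0.3 (about 500 cells per well), the
classifier trains on 200 images per class at 96 x 96, and screens use 96
compounds across two 96-well plates with one classification field and
three readout fields per well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classifier as clf
from .phantoms import PlateLayout, ProliferationModel, simulate_screen
from .pipeline import ScreenResult, compute_well_readouts, run_plate_qc, run_screen
from .qc import PlateQc

#: proliferation model for plate-level simulations: the same growth
#: parameters as the per-field default, with the carrying capacity
#: scaled to the larger imaged area
PLATE_PROLIFERATION = ProliferationModel(carrying_capacity=5000.0)

QC_PLATE_KWARGS = dict(
    plate_layout=PlateLayout(n_wells=96, n_control=8, n_model=8),
    canvas=(512, 512),
    render_scale=0.3,
    n_initial=250.0,
    duration_h=24.0,
    interval_h=24.0,
    proliferation=PLATE_PROLIFERATION,
    readout_canvas=None,
)

SCREEN_KWARGS = dict(
    plate_layout=PlateLayout(n_wells=96, n_control=12, n_model=12),
    canvas=(128, 128),
    render_scale=0.267,
    n_initial=45.0,
    duration_h=24.0,
    interval_h=24.0,
    readout_canvas=(256, 256),
    readout_fields=3,
)


def qc_plate_study(seed: int, n_plates: int = 3) -> list[PlateQc]:
    """Simulate reference plates and compute per-plate Z'/CV.

    Each plate carries 8 control and 8 model wells; the readout is the
    relative cell count at 24 h obtained through segmentation.
    """
    out: list[PlateQc] = []
    children = np.random.SeedSequence(seed).spawn(n_plates)
    for i, child in enumerate(children):
        plate_seed = int(child.generate_state(1)[0] % (2**31))
        ds = simulate_screen(0, 0.0, 0.0, seed=plate_seed, **QC_PLATE_KWARGS)
        qcs = run_plate_qc(compute_well_readouts(ds))
        for q in qcs:
            out.append(
                PlateQc(
                    plate_id=f"plate{i + 1}",
                    z_prime=q.z_prime,
                    cv_control=q.cv_control,
                    cv_model=q.cv_model,
                    pass_flag=q.pass_flag,
                )
            )
    return out


def train_default_classifier(
    seed: int, n_per_class: int = 200, epochs: int = 120
) -> tuple[clf.TrainedClassifier, dict]:
    """The seeded six-class training run.

    Generates the phantom dataset at the class anchor conditions, applies
    four-fold rotation augmentation, splits 4:1 (stratified) and trains
    the default backend.
    """
    data = clf.make_labeled_dataset(n_per_class=n_per_class, size=96, seed=seed)
    aug = clf.augment_rotations(data)
    train, val = clf.split_dataset(aug, train_fraction=0.8, seed=seed)
    return clf.train_classifier(train, val, epochs=epochs, seed=seed)


@dataclass
class RecoveryMetrics:
    """Pooled planted-truth recovery of the two-step screen."""

    true_positives: int = 0
    n_inhibitors: int = 0
    n_hits: int = 0
    funnels: list = None

    @property
    def sensitivity(self) -> float:
        return self.true_positives / self.n_inhibitors if self.n_inhibitors else float("nan")

    @property
    def precision(self) -> float:
        return self.true_positives / self.n_hits if self.n_hits else float("nan")


def screen_recovery_study(
    model: clf.TrainedClassifier,
    seed: int,
    n_replicates: int = 10,
    n_compounds: int = 96,
    inhibitor_fraction: float = 0.1,
    toxic_fraction: float = 0.05,
) -> tuple[RecoveryMetrics, list[ScreenResult]]:
    """Run replicate synthetic screens and pool final-hit recovery."""
    metrics = RecoveryMetrics(funnels=[])
    results = []
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for child in children:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        ds = simulate_screen(
            n_compounds, inhibitor_fraction, toxic_fraction, seed=rep_seed, **SCREEN_KWARGS
        )
        res = run_screen(ds, model)
        ev = res.evaluate(ds.truth_labels())
        metrics.true_positives += ev["true_positives"]
        metrics.n_inhibitors += ev["n_inhibitors"]
        metrics.n_hits += ev["n_hits"]
        metrics.funnels.append(res.funnel)
        results.append(res)
    return metrics, results
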