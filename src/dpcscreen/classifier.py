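"""Six-state cell-activation image classifier.

Images of stimulated fibroblast cultures are labeled into six activation
types anchored on dose and time: vehicle-treated fields are type 0,
low-dose fields around 12 h are types 1-3, and high-dose fields after
20 h are types 4-5.  Types group into three phenotypes: {0,1} normal,
{2,3} alternative, {4,5} fibrotic.

Preprocessing follows a fixed contract: each of the two input channels
(bright-field, DPC) is resized and min-max normalized, and a third
channel equal to the element-wise mean of the two resized channels is
appended, giving a ``target x target x 3`` array in [0, 1] (default
target 299).

The default training backend is a compact multilayer perceptron
(scikit-learn ``MLPClassifier``) over a fixed, untrained front end of
translation- and rotation-invariant image statistics, trained with
softmax cross-entropy loss and the Adam optimizer under an epoch cap
(default 120).  The backend is pluggable behind
:func:`train_classifier`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .errors import LabelingError, NotFittedError, TrainingError
from .io import FieldImage
from .phantoms import (
    ActivationModel,
    CellGeometry,
    ProliferationModel,
    _lognormal_factor,
    render_field,
    sample_population_at_fraction,
)

PHENOTYPE_GROUPS = {0: "normal", 1: "normal", 2: "alternative", 3: "alternative",
                    4: "fibrotic", 5: "fibrotic"}

N_TYPES = 6


@dataclass
class LabeledImage:
    """A two-channel field image with its activation-type label."""

    image: FieldImage
    type_label: int
    dose: float = 0.0
    time_h: float = 0.0
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.type_label not in range(N_TYPES):
            raise ValueError("type_label must be in 0..5")


@dataclass
class PreprocessedImage:
    """H x W x 3 float array in [0, 1]."""

    values: np.ndarray


@dataclass
class ClassifierMetrics:
    """Cross-validation metrics: per-fold macro precision/recall/F1."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    confusion: np.ndarray

    @property
    def precision_mean(self) -> float:
        return float(self.precision.mean())

    @property
    def precision_sd(self) -> float:
        return float(self.precision.std(ddof=1)) if self.precision.size > 1 else 0.0

    @property
    def recall_mean(self) -> float:
        return float(self.recall.mean())

    @property
    def recall_sd(self) -> float:
        return float(self.recall.std(ddof=1)) if self.recall.size > 1 else 0.0

    @property
    def f1_mean(self) -> float:
        return float(self.f1.mean())

    @property
    def f1_sd(self) -> float:
        return float(self.f1.std(ddof=1)) if self.f1.size > 1 else 0.0


# --------------------------------------------------------------------------
# preprocessing


def resize_channels(image: FieldImage, target_size: int = 299) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear-resize the two input channels (pre-normalization)."""
    names = image.channel_names
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 channels, got {len(names)}")
    out = []
    for n in names:
        ch = image.channels[n].astype(np.float64)
        if ch.shape != (target_size, target_size):
            ch = resize(ch, (target_size, target_size), order=1, anti_aliasing=False,
                        preserve_range=True)
        out.append(ch)
    return out[0], out[1]


def _minmax(ch: np.ndarray) -> np.ndarray:
    lo, hi = float(ch.min()), float(ch.max())
    if hi == lo:  # degenerate zero-range channel normalizes to 0
        return np.zeros_like(ch)
    return (ch - lo) / (hi - lo)


def preprocess_image(image: FieldImage, target_size: int = 299) -> PreprocessedImage:
    """Resize, append the averaged third channel, min-max normalize.

    The third channel is the element-wise mean of the two resized
    channels, computed before normalization; each of the three channels
    is then independently min-max scaled to [0, 1] (a zero-range channel
    maps to 0).
    """
    c1, c2 = resize_channels(image, target_size)
    c3 = (c1 + c2) / 2.0
    stack = np.stack([_minmax(c1), _minmax(c2), _minmax(c3)], axis=-1)
    return PreprocessedImage(values=stack)


# --------------------------------------------------------------------------
# labeling


@dataclass(frozen=True)
class LabelAnchor:
    """Half-open dose band (lo, hi] x time band [lo, hi) -> type."""

    dose_lo: float
    dose_hi: float
    time_lo: float
    time_hi: float
    type_label: int


#: Default anchor table. Vehicle (dose 0) is always type 0; low-dose
#: bands around 12 h map to types 1-3 and high-dose bands after 20 h to
#: types 4-5 (the model dose at mid time fills the type-3 band).
DEFAULT_ANCHORS: tuple[LabelAnchor, ...] = (
    LabelAnchor(0.0, 1.875, 6.0, 18.0, 1),
    LabelAnchor(1.875, 5.0, 6.0, 18.0, 2),
    LabelAnchor(5.0, 20.0, 6.0, 18.0, 3),
    LabelAnchor(20.0, 37.5, 18.0, 36.0001, 4),
    LabelAnchor(37.5, 400.0, 18.0, 36.0001, 5),
)


def assign_label(
    dose: float, time_h: float, anchor_table: tuple[LabelAnchor, ...] = DEFAULT_ANCHORS
) -> int:
    """Dose/time-anchored type label; vehicle (dose 0) is always type 0."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if dose == 0:
        return 0
    for a in anchor_table:
        if a.dose_lo < dose <= a.dose_hi and a.time_lo <= time_h < a.time_hi:
            return a.type_label
    raise LabelingError(f"(dose={dose}, time={time_h} h) outside the anchor table coverage")


#: Generating (dose ng/mL, time h) condition per type for the phantom
#: labeled dataset; each condition maps to its type via DEFAULT_ANCHORS.
DEFAULT_CLASS_CONDITIONS: tuple[tuple[float, float], ...] = (
    (0.0, 12.0),
    (1.25, 12.0),
    (2.5, 12.0),
    (10.0, 12.0),
    (25.0, 24.0),
    (50.0, 24.0),
)


def make_labeled_dataset(
    n_per_class: int = 200,
    size: int = 96,
    seed: int = 7,
    *,
    conditions: tuple[tuple[float, float], ...] = DEFAULT_CLASS_CONDITIONS,
    activation: ActivationModel = ActivationModel(),
    proliferation: ProliferationModel = ProliferationModel(),
    geometry: CellGeometry = CellGeometry(),
    render_scale: float = 0.2,
    n_initial: float = 45.0,
    count_jitter_cv: float = 0.04,
    effect_scale: float = 1.0,
) -> list[LabeledImage]:
    """Generate the seeded 6-class phantom dataset.

    Each image is one field of a culture held at its class's anchor
    condition: the cell count follows the dose-modulated logistic
    expectation (with a small per-field lognormal jitter) and the
    activated fraction follows the dose Hill curve with the first-order
    onset ramp.  ``effect_scale`` in [0, 1] shrinks all dose effects
    toward the vehicle condition (used to study accuracy vs effect
    size); 1.0 is the study condition.
    """
    rng = np.random.default_rng(seed)
    out: list[LabeledImage] = []
    f0 = activation.baseline_activated_fraction
    for dose, t in conditions:
        label = assign_label(dose, t)
        f = activation.activated_fraction_at(dose, t)
        f = f0 + (f - f0) * effect_scale
        mult = proliferation.rate_multiplier(dose)
        mult = 1.0 + (mult - 1.0) * effect_scale
        expected = proliferation.expected_count(n_initial, dose, t, rate_multiplier=mult)
        for _ in range(n_per_class):
            n = max(1, int(round(expected * _lognormal_factor(rng, count_jitter_cv))))
            cells = sample_population_at_fraction(
                f, n, activation, rng, canvas=(size, size),
                render_scale=render_scale, geometry=geometry,
            )
            img = render_field(
                cells, width=size, height=size, channels=("brightfield", "dpc"),
                seed=rng.integers(2**31), time_h=t,
            )
            out.append(LabeledImage(image=img, type_label=label, dose=dose, time_h=t))
    return out


# --------------------------------------------------------------------------
# augmentation / splitting


def augment_rotations(dataset: list[LabeledImage]) -> list[LabeledImage]:
    """Replace each image by its four right-angle rotations (labels kept)."""
    out: list[LabeledImage] = []
    for item in dataset:
        for k in range(4):
            if k == 0:
                out.append(item)
                continue
            channels = {n: np.rot90(c, k).copy() for n, c in item.image.channels.items()}
            img = FieldImage(
                channels=channels,
                well_id=item.image.well_id,
                field_index=item.image.field_index,
                time_h=item.image.time_h,
            )
            out.append(replace(item, image=img))
    return out


def split_dataset(
    dataset: list[LabeledImage],
    train_fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Random train/validation split (default 4:1), stratified by type.

    ``len(train) == round(train_fraction * N)``; the partition is
    deterministic per seed, disjoint and exhaustive.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    n_train = int(round(train_fraction * n))
    idx = np.arange(n)
    if stratified:
        labels = np.array([d.type_label for d in dataset])
        train_idx: list[int] = []
        order = []
        for lbl in np.unique(labels):
            cls = idx[labels == lbl]
            rng.shuffle(cls)
            order.append(cls)
            take = int(round(train_fraction * cls.size))
            train_idx.extend(cls[:take])
        # fix rounding drift while preserving stratification as closely as possible
        train_set = set(train_idx)
        leftovers = [i for cls in order for i in cls if i not in train_set]
        while len(train_set) < n_train and leftovers:
            train_set.add(leftovers.pop(0))
        while len(train_set) > n_train:
            train_set.discard(next(iter(train_set)))
        train_idx = sorted(train_set)
    else:
        rng.shuffle(idx)
        train_idx = sorted(idx[:n_train].tolist())
    train_set = set(train_idx)
    train = [dataset[i] for i in train_idx]
    val = [dataset[i] for i in range(n) if i not in train_set]
    return train, val


# --------------------------------------------------------------------------
# training backend


@dataclass
class TrainedClassifier:
    """Handle to a fitted 6-type classifier."""

    backend: str
    model: MLPClassifier | None
    input_size: int
    classes: tuple[int, ...] = tuple(range(N_TYPES))
    seed: int = 0
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def is_fitted(self) -> bool:
        return self.model is not None and hasattr(self.model, "coefs_")

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return x
        return (x - self.feature_mean) / self.feature_scale


def _featurize_one(arr: np.ndarray) -> np.ndarray:
    """Fixed (untrained) multiscale feature front end for one image.

    Translation-invariant statistics of the preprocessed H x W x 3 array:
    per-channel intensity histograms and supra-threshold areas, band-pass
    energy statistics of the DPC channel at three spatial scales (small
    scales respond to thin resting cells, large scales to spread
    activated cells), texture and composition summaries.  The trained
    part of the backend is only the MLP softmax head.
    """
    feats: list[np.ndarray] = []
    bins = np.linspace(0.0, 1.0, 17)
    for c in range(arr.shape[-1]):
        ch = arr[..., c]
        hist, _ = np.histogram(ch, bins=bins)
        feats.append(hist / ch.size)
        feats.append(np.array([(ch > t).mean() for t in (0.2, 0.35, 0.5, 0.65, 0.8)]))
        feats.append(np.array([ch.mean(), ch.std()]))
    dpc = arr[..., 1]
    # binary morphology proxies: total foreground, thin-structure area
    # (resting spindles vanish under opening; spread bodies survive) and
    # component counts approximating the cell count
    for t in (0.25, 0.4, 0.55):
        fgm = dpc > t
        opened = ndi.binary_opening(fgm, structure=np.ones((3, 3)))
        thin = fgm & ~opened
        n_comp = ndi.label(fgm)[1]
        n_comp_open = ndi.label(opened)[1]
        feats.append(
            np.array(
                [fgm.mean(), thin.mean(), opened.mean(),
                 n_comp / 100.0, n_comp_open / 100.0]
            )
        )
    # nucleus-scale blob count (determinant-of-Hessian maxima) and the
    # skeleton length of the foreground: together they estimate how many
    # cells there are and how much of the population is thin spindles
    from skimage.morphology import h_maxima, skeletonize

    doh = None
    for s in (0.8, 1.6):
        ixx = ndi.gaussian_filter(dpc, s, order=(0, 2))
        iyy = ndi.gaussian_filter(dpc, s, order=(2, 0))
        ixy = ndi.gaussian_filter(dpc, s, order=(1, 1))
        det = (ixx * iyy - ixy**2) * s**4
        det = np.where(ixx + iyy < 0, det, 0.0)
        doh = det if doh is None else np.maximum(doh, det)
    top = float(np.percentile(doh, 99.5))
    if top > 0:
        blobs = h_maxima(doh, 0.15 * top) & (doh > 0.3 * top)
        n_blobs = ndi.label(blobs)[1]
    else:
        n_blobs = 0
    fg03 = dpc > 0.3
    skel = skeletonize(fg03)
    thin03 = fg03 & ~ndi.binary_opening(fg03, structure=np.ones((3, 3)))
    feats.append(
        np.array(
            [n_blobs / 100.0, skel.mean() * 10.0, (skel & thin03).mean() * 10.0]
        )
    )
    # orientation-pooled spot/edge/ridge energies: ridge responses track
    # thin resting spindles, spot responses the compact nuclei/bodies
    from .morphometry import texture_responses

    tex = texture_responses(dpc, scales=(1, 2))
    feats.append(np.array([resp.mean() for resp in tex.values()]))
    feats.append(np.array([float(np.percentile(resp, 95)) for resp in tex.values()]))
    for s in (1.0, 2.0, 4.0):
        band = ndi.gaussian_filter(dpc, s) - ndi.gaussian_filter(dpc, 2.0 * s)
        a = np.abs(band)
        feats.append(
            np.array(
                [
                    a.mean(),
                    a.std(),
                    float(np.percentile(a, 90)),
                    float(np.percentile(a, 99)),
                    np.maximum(band, 0).mean(),
                    np.maximum(-band, 0).mean(),
                ]
            )
        )
    return np.concatenate(feats)


def _robust_morphology(dpc_raw: np.ndarray) -> np.ndarray:
    """Area-composition features on a robustly scaled raw DPC channel.

    Robust scaling (median to 98th-percentile) keeps thresholds
    comparable across images regardless of how bright the densest
    overlap is; thin-structure area tracks the resting-spindle share of
    the population, opened area the spread activated share.
    """
    med = float(np.median(dpc_raw))
    hi = float(np.percentile(dpc_raw, 98))
    if hi <= med:
        return np.zeros(12)
    r = (dpc_raw - med) / (hi - med)
    feats = []
    for t in (0.15, 0.3, 0.5):
        fgm = r > t
        opened = ndi.binary_opening(fgm, structure=np.ones((5, 5)))
        thin = fgm & ~ndi.binary_opening(fgm, structure=np.ones((3, 3)))
        denom = max(fgm.mean(), 1e-6)
        feats.append([fgm.mean(), thin.mean(), opened.mean(), thin.mean() / denom])
    return np.asarray(feats).ravel()


def _segmentation_features(dpc_raw: np.ndarray) -> np.ndarray:
    """Cell-level composition statistics from the package's segmentation.

    The per-image label-mask object count and log-area histogram encode
    how many cells there are and how the population splits between thin
    resting spindles (small areas) and spread activated cells (large
    areas); at high confluency the statistics become biased but remain
    consistent within a condition, which is all a classifier needs.
    """
    from skimage.measure import regionprops

    from .segmentation import segment_cells

    scale = dpc_raw.shape[0] / 480.0  # relative to the native render scale
    mask = segment_cells(
        dpc_raw, min_area=max(4, int(round(60 * scale**2))),
        smoothing_scale=max(0.6, 2.0 * scale),
    )
    if mask.n_objects == 0:
        return np.zeros(10, dtype=np.float64)
    regions = regionprops(mask.labels)
    areas = np.array([r.area for r in regions], dtype=float)
    aspect = np.array(
        [max(r.axis_major_length, 1.0) / max(r.axis_minor_length, 1.0) for r in regions]
    )
    edges = np.array([0, 8, 16, 32, 64, 128, np.inf])
    hist, _ = np.histogram(areas, bins=edges)
    return np.concatenate(
        [
            [mask.n_objects / 100.0, np.median(areas) / 100.0, float(np.median(aspect)) / 4.0],
            hist / max(1, len(areas)),
            [0.0],
        ]
    )


def _featurize(images: list[FieldImage], input_size: int) -> np.ndarray:
    """Preprocess images and apply the fixed feature front end."""
    out = []
    for img in images:
        arr = preprocess_image(img, target_size=input_size).values
        dpc_raw = list(img.channels.values())[-1].astype(np.float64)
        vec = np.concatenate(
            [
                _featurize_one(arr),
                _robust_morphology(dpc_raw),
                _segmentation_features(dpc_raw),
            ]
        )
        out.append(vec)
    return np.asarray(out, dtype=np.float32)


def train_classifier(
    train: list[LabeledImage],
    val: list[LabeledImage],
    backend: str = "mlp",
    epochs: int = 120,
    seed: int = 0,
    *,
    input_size: int = 96,
    hidden: tuple[int, ...] = (128,),
) -> tuple[TrainedClassifier, dict]:
    """Train the default MLP backend with softmax cross-entropy + Adam.

    Returns the fitted handle and the learning curves (per-epoch training
    loss plus final train/validation accuracy).
    """
    if backend != "mlp":
        raise ValueError(f"unknown backend {backend!r}; available: 'mlp'")
    if not train or not val:
        raise TrainingError("both training and validation sets must be non-empty")
    y_train = np.array([d.type_label for d in train])
    if set(np.unique(y_train)) != set(range(N_TYPES)):
        missing = sorted(set(range(N_TYPES)) - set(np.unique(y_train)))
        raise TrainingError(f"training set is missing classes {missing}")
    x_train = _featurize([d.image for d in train], input_size)
    x_val = _featurize([d.image for d in val], input_size)
    y_val = np.array([d.type_label for d in val])
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd[sd == 0] = 1.0
    x_train = (x_train - mu) / sd
    x_val = (x_val - mu) / sd
    clf = MLPClassifier(
        hidden_layer_sizes=hidden,
        solver="adam",
        alpha=1e-4,
        batch_size=min(32, len(train)),
        learning_rate_init=2e-3,
        max_iter=epochs,
        random_state=seed,
        tol=1e-6,
        n_iter_no_change=max(10, epochs // 6),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        clf.fit(x_train, y_train)
    handle = TrainedClassifier(
        backend="mlp", model=clf, input_size=input_size, seed=seed,
        feature_mean=mu, feature_scale=sd,
        meta={"epochs": epochs, "hidden": hidden},
    )
    curves = {
        "loss": list(map(float, clf.loss_curve_)),
        "train_accuracy": float(clf.score(x_train, y_train)),
        "val_accuracy": float(clf.score(x_val, y_val)),
    }
    return handle, curves


def classify(model: TrainedClassifier, image: FieldImage) -> tuple[int, np.ndarray]:
    """Predict the activation type and class probabilities for one field."""
    if model is None or not model.is_fitted():
        raise NotFittedError("classifier handle is not trained")
    x = model.transform(_featurize([image], model.input_size))
    probs = model.model.predict_proba(x)[0]
    full = np.zeros(N_TYPES)
    for cls, p in zip(model.model.classes_, probs):
        full[int(cls)] = p
    return int(np.argmax(full)), full


def plan_folds(labels, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Stratified fold memberships (sizes floor(N/k) with remainder spread).

    This is the fold plan :func:`cross_validate` executes; exposed so the
    dataset-protocol arithmetic can be checked without training.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k < 2 or k > n:
        raise ValueError("k must satisfy 2 <= k <= N")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros((n, 1)), labels)]


def cross_validate(
    dataset: list[LabeledImage],
    k: int = 5,
    seed: int = 0,
    epochs: int = 60,
    **train_kwargs,
) -> ClassifierMetrics:
    """Stratified k-fold cross-validation with macro-averaged metrics."""
    n = len(dataset)
    if k < 2 or k > n:
        raise ValueError("k must satisfy 2 <= k <= N")
    labels = np.array([d.type_label for d in dataset])
    input_size = train_kwargs.pop("input_size", 96)
    hidden = train_kwargs.pop("hidden", (128,))
    x = _featurize([d.image for d in dataset], input_size)
    folds = plan_folds(labels, k=k, seed=seed)
    precisions, recalls, f1s = [], [], []
    confusion = np.zeros((N_TYPES, N_TYPES), dtype=int)
    import warnings

    for te in folds:
        tr = np.setdiff1d(np.arange(n), te)
        mu = x[tr].mean(axis=0)
        sd = x[tr].std(axis=0)
        sd[sd == 0] = 1.0
        clf = MLPClassifier(
            hidden_layer_sizes=hidden, solver="adam", alpha=1e-4,
            batch_size=min(32, len(tr)), learning_rate_init=2e-3, max_iter=epochs,
            random_state=seed, tol=1e-6, n_iter_no_change=max(10, epochs // 6),
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            clf.fit((x[tr] - mu) / sd, labels[tr])
        pred = clf.predict((x[te] - mu) / sd)
        p, r, f1, _ = precision_recall_fscore_support(
            labels[te], pred, average="macro", zero_division=0
        )
        precisions.append(p)
        recalls.append(r)
        f1s.append(f1)
        confusion += confusion_matrix(labels[te], pred, labels=list(range(N_TYPES)))
    return ClassifierMetrics(
        precision=np.array(precisions),
        recall=np.array(recalls),
        f1=np.array(f1s),
        confusion=confusion,
    )


def group_type(type_label: int) -> str:
    """Map a type label to its phenotype: {0,1} normal, {2,3} alternative, {4,5} fibrotic."""
    if type_label not in PHENOTYPE_GROUPS:
        raise ValueError(f"type label {type_label!r} out of range 0-5")
    return PHENOTYPE_GROUPS[type_label]
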