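"""Synthetic DPC phantom generator.

Generates two-channel (bright-field + DPC, optionally marker and nuclei)
time-series images of a fibroblast activation assay with known ground
truth.  The generative model is deliberately simple:

* **Activation.**  The probability that a cell is in the activated
  (myofibroblast) state follows a Hill curve in the stimulus dose,
  ``f(d) = f0 + (fmax - f0) d^h / (d^h + d50^h)``.  In time-resolved
  simulations the activated fraction approaches this asymptote with a
  first-order onset, ``f(d, t) = f0 + (f(d) - f0)(1 - exp(-t/tau))``,
  emulating the hours-scale induction of the activation marker.
* **Marker.**  Per-cell activation-marker intensity (an alpha-SMA
  surrogate) is ``baseline + gain * activated + N(0, sd)``.
* **Geometry.**  Resting cells are thin spindles; activated cells are
  enlarged and spread (larger area, lower elongation).
* **Proliferation.**  Well cell number follows logistic growth whose rate
  is modulated by a unimodal function of dose: maximal at the model dose
  and suppressed at high doses (biphasic response).  Well counts track the
  logistic expectation with a small lognormal well-level rate jitter;
  per-field counts add a small lognormal sampling jitter.

Determinism: every public operation takes a seed (or an
``numpy.random.Generator``) and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigurationError
from .io import FieldImage

# --------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class ActivationModel:
    """Dose -> activation-state response of the cell population.

    ``onset_time_h`` is the first-order time constant with which the
    activated fraction approaches its dose asymptote in time-resolved
    simulations; operations that take no time argument use the asymptote.
    """

    baseline_activated_fraction: float = 0.05
    max_activated_fraction: float = 0.9
    half_effect_dose: float = 2.5  # ng/mL
    hill_coefficient: float = 1.5
    marker_gain: float = 100.0  # intensity units per activation state
    marker_noise_sd: float = 8.0
    marker_baseline: float = 20.0
    onset_time_h: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_activated_fraction <= self.max_activated_fraction <= 1.0:
            raise ValueError("need 0 <= baseline <= max <= 1")
        if self.half_effect_dose <= 0 or self.hill_coefficient <= 0:
            raise ValueError("half_effect_dose and hill_coefficient must be > 0")
        if self.marker_noise_sd < 0:
            raise ValueError("marker_noise_sd must be >= 0")

    def activated_fraction(self, dose: float) -> float:
        """Asymptotic activated fraction at a given dose (Hill curve)."""
        if dose < 0:
            raise ValueError("dose must be non-negative")
        f0, fm = self.baseline_activated_fraction, self.max_activated_fraction
        if dose == 0:
            return f0
        dh = dose**self.hill_coefficient
        return f0 + (fm - f0) * dh / (dh + self.half_effect_dose**self.hill_coefficient)

    def activated_fraction_at(self, dose: float, time_h: float) -> float:
        """Activated fraction at a given dose and time since stimulation."""
        f0 = self.baseline_activated_fraction
        ramp = 1.0 - math.exp(-max(time_h, 0.0) / self.onset_time_h)
        return f0 + (self.activated_fraction(dose) - f0) * ramp


@dataclass(frozen=True)
class ProliferationModel:
    """Dose-modulated logistic growth of the per-field cell count.

    The growth-rate multiplier is 1 at dose zero, unimodal with its
    maximum at ``peak_dose``, and suppressed by ``high_dose_suppression``
    at doses >= 10x the peak (biphasic dose response).
    """

    base_doubling_time: float = 24.0  # hours
    peak_dose: float = 10.0  # ng/mL
    peak_rate_multiplier: float = 1.6
    high_dose_suppression: float = 0.5
    carrying_capacity: float = 500.0  # cells per field
    log_width: float = 0.5  # width of the unimodal bump in log10 dose

    def __post_init__(self) -> None:
        if self.peak_rate_multiplier < 1.0:
            raise ValueError("peak_rate_multiplier must be >= 1")
        if not 0.0 <= self.high_dose_suppression <= 1.0:
            raise ValueError("high_dose_suppression must be in [0, 1]")

    def rate_multiplier(self, dose: float) -> float:
        """Growth-rate multiplier as a function of dose."""
        if dose < 0:
            raise ValueError("dose must be non-negative")
        if dose == 0:
            return 1.0
        x = math.log10(dose / self.peak_dose)
        bump = math.exp(-((x / self.log_width) ** 2))
        # smooth suppression ramp over one decade above the peak
        u = min(1.0, max(0.0, (x - self.log_width) / (1.0 - self.log_width)))
        s = 3 * u * u - 2 * u * u * u
        return 1.0 + (self.peak_rate_multiplier - 1.0) * bump - self.high_dose_suppression * s

    def base_rate(self) -> float:
        return math.log(2.0) / self.base_doubling_time

    def expected_count(
        self, n_initial: float, dose: float, time_h: float, rate_multiplier: float | None = None
    ) -> float:
        """Closed-form logistic expectation of the cell count."""
        m = self.rate_multiplier(dose) if rate_multiplier is None else rate_multiplier
        r = self.base_rate() * m
        k = self.carrying_capacity
        if n_initial <= 0:
            return 0.0
        if r >= 0:
            e = math.exp(r * time_h)
            return k / (1.0 + (k / n_initial - 1.0) / e)
        # declining wells: plain exponential decay (capacity irrelevant)
        return n_initial * math.exp(r * time_h)


@dataclass(frozen=True)
class CellGeometry:
    """Axis-length distributions (px, at render scale 1) per state."""

    resting_major: tuple[float, float] = (40.0, 8.0)  # mean, sd
    resting_minor: tuple[float, float] = (8.0, 2.0)
    activated_major: tuple[float, float] = (45.0, 10.0)
    activated_minor: tuple[float, float] = (25.0, 6.0)


@dataclass
class CellPhantom:
    """Ground-truth record of a single rendered cell."""

    centroid: tuple[float, float]  # (row, col) px
    orientation: float  # radians
    major_axis: float  # px
    minor_axis: float  # px
    activated: bool
    marker_intensity: float
    nucleus_centroid: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.major_axis >= self.minor_axis > 0:
            raise ValueError("need major_axis >= minor_axis > 0")


@dataclass
class FrameTruth:
    time_h: float
    cells: list[CellPhantom]

    @property
    def true_count(self) -> int:
        return len(self.cells)

    @property
    def activated_count(self) -> int:
        return sum(c.activated for c in self.cells)


@dataclass
class GroundTruth:
    """Per-frame phantom records for one simulated well/field."""

    dose: float
    frames: list[FrameTruth] = field(default_factory=list)
    planted_effect: str = "none"  # none | inhibitor | toxic

    @property
    def true_counts(self) -> list[int]:
        return [f.true_count for f in self.frames]

    @property
    def times_h(self) -> list[float]:
        return [f.time_h for f in self.frames]

    def mean_marker(self, frame: int = -1) -> float:
        cells = self.frames[frame].cells
        return float(np.mean([c.marker_intensity for c in cells])) if cells else float("nan")


# --------------------------------------------------------------------------
# population sampling


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _sample_axes(rng, mean_sd, scale, lo=0.6):
    mean, sd = mean_sd
    return max(lo, float(rng.normal(mean * scale, sd * scale)))


class _PlacementGrid:
    """Bucket grid for the soft-repulsion placement neighbour search."""

    def __init__(self, h: float, w: float, render_scale: float):
        self.bucket = max(4.0, 40.0 * render_scale)
        self.h, self.w = h, w
        self.cells: dict[tuple[int, int], list[tuple[float, float, float]]] = {}

    def _key(self, y: float, x: float) -> tuple[int, int]:
        return int(y // self.bucket), int(x // self.bucket)

    def add(self, y: float, x: float, major: float) -> None:
        self.cells.setdefault(self._key(y, x), []).append((y, x, major))

    def clearance(self, y: float, x: float, major: float) -> float:
        """Distance margin to the nearest neighbour (soft-overlap metric)."""
        ky, kx = self._key(y, x)
        best = np.inf
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for (py, px, pm) in self.cells.get((ky + dy, kx + dx), ()):
                    d = np.hypot(py - y, px - x) - 0.25 * (pm + major)
                    if d < best:
                        best = d
        return best


def sample_population_at_fraction(
    activated_fraction: float,
    n_cells: int,
    activation: ActivationModel,
    seed,
    *,
    canvas: tuple[int, int] = (512, 512),
    render_scale: float = 1.0,
    geometry: CellGeometry = CellGeometry(),
) -> list[CellPhantom]:
    """Sample ``n_cells`` phantoms with an explicit activated fraction."""
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = _rng(seed)
    h, w = canvas
    cells: list[CellPhantom] = []
    states = rng.random(n_cells) < activated_fraction
    # contact-inhibited placement: fibroblast monolayers avoid piling up,
    # so centres keep a soft minimum separation (best of a few attempts;
    # crowded fields degrade gracefully).  A bucket grid keeps the
    # neighbour search O(1) per attempt.
    grid = _PlacementGrid(h, w, render_scale)
    # far beyond confluency there is no free room to seek; place uniformly
    attempts = 15 if n_cells <= 4 * (h / grid.bucket) * (w / grid.bucket) else 1
    for act in states:
        if act:
            major = _sample_axes(rng, geometry.activated_major, render_scale)
            minor = _sample_axes(rng, geometry.activated_minor, render_scale)
        else:
            major = _sample_axes(rng, geometry.resting_major, render_scale)
            minor = _sample_axes(rng, geometry.resting_minor, render_scale)
        if minor > major:
            major, minor = minor, major
        cy = cx = 0.0
        best = -np.inf
        for _ in range(attempts):
            ty, tx = float(rng.uniform(0, h)), float(rng.uniform(0, w))
            dmin = grid.clearance(ty, tx, major) if attempts > 1 else 1.0
            if dmin > best:
                best, cy, cx = dmin, ty, tx
            if dmin > 0:
                break
        if attempts > 1:
            grid.add(cy, cx, major)
        theta = float(rng.uniform(0, np.pi))
        marker = (
            activation.marker_baseline
            + activation.marker_gain * float(act)
            + float(rng.normal(0.0, activation.marker_noise_sd))
        )
        # nucleus sits near the cell centre with a small offset
        off = rng.normal(0.0, 0.08 * major, size=2)
        cells.append(
            CellPhantom(
                centroid=(cy, cx),
                orientation=theta,
                major_axis=major,
                minor_axis=minor,
                activated=bool(act),
                marker_intensity=marker,
                nucleus_centroid=(cy + float(off[0]), cx + float(off[1])),
            )
        )
    return cells


def sample_population(
    dose: float,
    n_cells: int,
    activation: ActivationModel,
    seed,
    **kwargs,
) -> list[CellPhantom]:
    """Sample a cell population at a stimulus dose.

    The expected activated fraction is the Hill curve
    ``f0 + (fmax - f0) d^h / (d^h + d50^h)``; each cell's state is an
    independent Bernoulli draw at that probability.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    f = activation.activated_fraction(dose)
    return sample_population_at_fraction(f, n_cells, activation, seed, **kwargs)


# --------------------------------------------------------------------------
# rendering


def _add_profiles(canvas: np.ndarray, cells: Sequence[CellPhantom], amplitudes, nucleus_gain=0.0):
    """Accumulate smooth super-Gaussian elliptical profiles onto a canvas."""
    h, w = canvas.shape
    for cell, amp in zip(cells, amplitudes):
        a = cell.major_axis / 2.0
        b = cell.minor_axis / 2.0
        cy, cx = cell.centroid
        ext = 1.1 * cell.major_axis
        r0, r1 = int(max(0, cy - ext)), int(min(h, cy + ext + 1))
        c0, c1 = int(max(0, cx - ext)), int(min(w, cx + ext + 1))
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dy = yy - cy
        dx = xx - cx
        ct, st = np.cos(cell.orientation), np.sin(cell.orientation)
        xr = dx * ct + dy * st
        yr = -dx * st + dy * ct
        r2 = (xr / a) ** 2 + (yr / b) ** 2
        prof = np.exp(-(r2**1.5))
        patch = amp * prof
        if nucleus_gain > 0:
            ny, nx = cell.nucleus_centroid
            sig = max(0.9, 0.18 * cell.minor_axis)
            nd2 = ((yy - ny) ** 2 + (xx - nx) ** 2) / (2 * sig * sig)
            patch = patch + amp * nucleus_gain * np.exp(-nd2) * np.exp(-(r2**1.5))
        canvas[r0:r1, c0:c1] += patch


def render_field(
    cells: Sequence[CellPhantom],
    width: int = 512,
    height: int = 512,
    channels: Iterable[str] = ("brightfield", "dpc"),
    seed=0,
    *,
    well_id: str = "",
    field_index: int = 1,
    time_h: float = 0.0,
    background_level: float = 900.0,
    noise_sd: float = 25.0,
    cell_amplitude: float = 420.0,
    marker_coupling: float = 1.6,
) -> FieldImage:
    """Render a phantom population into a 16-bit multi-channel field.

    The DPC channel draws each cell as a smooth super-Gaussian elliptical
    profile (with a brighter nuclear centre) over a textured noisy
    background; cell amplitude is mildly coupled to the activation-marker
    intensity, emulating the denser optical mass of spread myofibroblasts.
    The optional ``nuclei`` channel renders one blob per nucleus and the
    optional ``marker`` channel scales the cell profile by its marker
    intensity.
    """
    channels = tuple(channels)
    if not channels:
        raise ValueError("channel set must not be empty")
    if width <= 0 or height <= 0:
        raise ValueError("canvas dimensions must be positive")
    rng = _rng(seed)
    out: dict[str, np.ndarray] = {}

    dpc_amp = np.array(
        [
            cell_amplitude * (1.0 + 0.18 * float(rng.normal()))
            + marker_coupling * max(0.0, c.marker_intensity)
            for c in cells
        ]
    )
    cell_sum = np.zeros((height, width), dtype=np.float64)
    _add_profiles(cell_sum, cells, dpc_amp, nucleus_gain=0.9)

    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=(height, width)), 8.0) * 18.0

    for name in channels:
        if name == "dpc":
            img = background_level + texture + rng.normal(0.0, noise_sd, (height, width)) + cell_sum
        elif name == "brightfield":
            img = (
                1000.0
                + 0.4 * texture
                + rng.normal(0.0, noise_sd * 0.8, (height, width))
                - 0.30 * cell_sum
            )
        elif name == "marker":
            m = np.zeros((height, width), dtype=np.float64)
            amps = np.array([4.0 * max(0.0, c.marker_intensity) for c in cells])
            _add_profiles(m, cells, amps)
            img = 120.0 + rng.normal(0.0, 8.0, (height, width)) + m
        elif name == "nuclei":
            m = np.zeros((height, width), dtype=np.float64)
            for c in cells:
                ny, nx = c.nucleus_centroid
                sig = max(0.8, 0.28 * c.minor_axis)
                ext = int(4 * sig) + 1
                r0, r1 = int(max(0, ny - ext)), int(min(height, ny + ext + 1))
                c0, c1 = int(max(0, nx - ext)), int(min(width, nx + ext + 1))
                if r0 >= r1 or c0 >= c1:
                    continue
                yy, xx = np.mgrid[r0:r1, c0:c1]
                m[r0:r1, c0:c1] += 2500.0 * np.exp(
                    -(((yy - ny) ** 2 + (xx - nx) ** 2) / (2 * sig * sig))
                )
            img = 100.0 + rng.normal(0.0, 8.0, (height, width)) + m
        else:
            raise ValueError(f"unknown channel {name!r}")
        out[name] = np.clip(img, 0, 65535).astype(np.uint16)

    return FieldImage(
        channels=out, well_id=well_id, field_index=field_index, time_h=time_h
    )


# --------------------------------------------------------------------------
# time-course simulation


@dataclass(frozen=True)
class WellSpec:
    """Everything needed to simulate one well."""

    dose: float = 0.0
    n_initial: float = 100.0
    activation: ActivationModel = ActivationModel()
    proliferation: ProliferationModel = ProliferationModel()
    geometry: CellGeometry = CellGeometry()
    canvas: tuple[int, int] = (512, 512)
    render_scale: float = 1.0
    channels: tuple[str, ...] = ("brightfield", "dpc")
    well_id: str = "A01"
    rate_jitter_cv: float = 0.01  # well-to-well growth-rate lognormal CV
    rate_multiplier_override: float | None = None
    activation_override: float | None = None  # fixed asymptotic fraction
    planted_effect: str = "none"


def _lognormal_factor(rng, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def simulate_timecourse(
    well: WellSpec,
    duration_h: float,
    interval_h: float,
    seed,
    *,
    render: bool = True,
) -> tuple[list[FieldImage], GroundTruth]:
    """Simulate one field of a well over time.

    Frames are produced at ``0, interval, 2*interval, ...`` up to
    ``duration`` (``floor(duration/interval) + 1`` frames).  Cells persist
    across frames with small positional jitter; the cell count follows
    the dose-modulated logistic expectation with well-level rate jitter;
    the activated fraction follows the dose Hill asymptote with the
    first-order onset ramp.  Resting cells convert to the activated state
    (resampling geometry and marker) as the target fraction rises.
    """
    if interval_h <= 0:
        raise ValueError("interval_h must be positive")
    if duration_h < 0:
        raise ValueError("duration_h must be non-negative")
    rng = _rng(seed)
    n_frames = int(math.floor(duration_h / interval_h + 1e-9)) + 1
    times = [i * interval_h for i in range(n_frames)]

    act, prol = well.activation, well.proliferation
    if well.rate_multiplier_override is not None:
        mult = well.rate_multiplier_override
    else:
        mult = prol.rate_multiplier(well.dose)
    mult *= _lognormal_factor(rng, well.rate_jitter_cv)

    n0 = max(1, int(rng.poisson(well.n_initial)))

    def frac_at(t: float) -> float:
        if well.activation_override is not None:
            f0 = act.baseline_activated_fraction
            ramp = 1.0 - math.exp(-max(t, 0.0) / act.onset_time_h)
            return f0 + (well.activation_override - f0) * ramp
        return act.activated_fraction_at(well.dose, t)

    cells = sample_population_at_fraction(
        frac_at(0.0),
        n0,
        act,
        rng,
        canvas=well.canvas,
        render_scale=well.render_scale,
        geometry=well.geometry,
    )

    truth = GroundTruth(dose=well.dose, planted_effect=well.planted_effect)
    images: list[FieldImage] = []
    h, w = well.canvas
    jitter_sd = 1.2 * well.render_scale

    for fi, t in enumerate(times):
        if fi > 0:
            # positional jitter
            for c in cells:
                dy, dx = rng.normal(0.0, jitter_sd, size=2)
                c.centroid = (
                    float(np.clip(c.centroid[0] + dy, 0, h - 1)),
                    float(np.clip(c.centroid[1] + dx, 0, w - 1)),
                )
                c.nucleus_centroid = (c.nucleus_centroid[0] + dy, c.nucleus_centroid[1] + dx)
            target = prol.expected_count(n0, well.dose, t, rate_multiplier=mult)
            n_t = max(0, int(round(target)))
            while len(cells) > n_t:
                cells.pop(int(rng.integers(len(cells))))
            if len(cells) < n_t and cells:
                f_now = frac_at(t)
                born = sample_population_at_fraction(
                    f_now,
                    n_t - len(cells),
                    act,
                    rng,
                    canvas=well.canvas,
                    render_scale=well.render_scale,
                    geometry=well.geometry,
                )
                # newborn cells settle wherever the monolayer has room
                # (same soft repulsion as the initial seeding, so grown
                # and freshly plated fields share spatial statistics)
                pos = np.array([c.centroid for c in cells])
                majors = np.array([c.major_axis for c in cells])
                for b in born:
                    best, ny, nx = -np.inf, b.centroid[0], b.centroid[1]
                    for _ in range(15):
                        ty = float(rng.uniform(0, h))
                        tx = float(rng.uniform(0, w))
                        dmin = float(
                            np.min(
                                np.hypot(pos[:, 0] - ty, pos[:, 1] - tx)
                                - 0.25 * (majors + b.major_axis)
                            )
                        )
                        if dmin > best:
                            best, ny, nx = dmin, ty, tx
                        if dmin > 0:
                            break
                    shift = (ny - b.centroid[0], nx - b.centroid[1])
                    b.centroid = (ny, nx)
                    b.nucleus_centroid = (
                        b.nucleus_centroid[0] + shift[0],
                        b.nucleus_centroid[1] + shift[1],
                    )
                    pos = np.vstack([pos, [ny, nx]])
                    majors = np.append(majors, b.major_axis)
                cells.extend(born)
            # activation progression toward the rising target fraction
            f_target = frac_at(t)
            n_act = sum(c.activated for c in cells)
            want = int(round(f_target * len(cells)))
            resting_idx = [i for i, c in enumerate(cells) if not c.activated]
            rng.shuffle(resting_idx)
            for i in resting_idx[: max(0, want - n_act)]:
                c = cells[i]
                major = _sample_axes(rng, well.geometry.activated_major, well.render_scale)
                minor = _sample_axes(rng, well.geometry.activated_minor, well.render_scale)
                if minor > major:
                    major, minor = minor, major
                c.major_axis, c.minor_axis = major, minor
                c.activated = True
                c.marker_intensity = (
                    act.marker_baseline
                    + act.marker_gain
                    + float(rng.normal(0.0, act.marker_noise_sd))
                )

        frame_cells = [replace(c) for c in cells]
        truth.frames.append(FrameTruth(time_h=t, cells=frame_cells))
        if render:
            images.append(
                render_field(
                    frame_cells,
                    width=w,
                    height=h,
                    channels=well.channels,
                    seed=rng.integers(2**31),
                    well_id=well.well_id,
                    time_h=t,
                )
            )
    return images, truth


# --------------------------------------------------------------------------
# whole-screen simulation


@dataclass(frozen=True)
class PlateLayout:
    """Template for one plate: reference wells plus compound capacity."""

    n_wells: int = 96
    n_control: int = 8
    n_model: int = 8

    @property
    def n_compound_slots(self) -> int:
        return self.n_wells - self.n_control - self.n_model

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_model < 1:
            raise ConfigurationError("each plate needs control and model wells")
        if self.n_compound_slots < 0:
            raise ConfigurationError("plate too small for the reference wells")


@dataclass
class WellRecord:
    well_id: str
    plate_id: str
    role: str  # control | model | compound
    compound_id: str | None = None
    conc_um: float = 0.0
    dose: float = 0.0  # stimulus dose, ng/mL
    effect: str = "none"  # ground truth: none | inhibitor | toxic
    strength: float = 0.0  # inhibitor strength at the primary dose


@dataclass
class ScreenDataset:
    """A simulated screen: plate map, per-well image series, ground truth.

    Each well carries a classification field (``images``) sized to match
    the classifier's training distribution and, optionally, a larger
    readout field at the same cell density (``readout_images``) from
    which proliferation counts are taken with lower sampling noise.
    """

    wells: list[WellRecord]
    images: dict[str, list[FieldImage]]  # well_id -> frames (one field)
    truth: dict[str, GroundTruth]
    model_dose: float
    primary_conc_um: float
    layout: PlateLayout
    activation: ActivationModel
    proliferation: ProliferationModel
    canvas: tuple[int, int]
    render_scale: float
    n_initial: float
    duration_h: float
    interval_h: float
    seed: int
    inhibitor_ec50_um: float = 5.0
    readout_images: dict[str, list[FieldImage]] | None = None

    @property
    def plate_ids(self) -> list[str]:
        return sorted({w.plate_id for w in self.wells})

    def wells_of(self, plate_id: str | None = None, role: str | None = None) -> list[WellRecord]:
        out = self.wells
        if plate_id is not None:
            out = [w for w in out if w.plate_id == plate_id]
        if role is not None:
            out = [w for w in out if w.role == role]
        return out

    def truth_labels(self) -> dict[str, str]:
        return {
            w.compound_id: w.effect
            for w in self.wells
            if w.role == "compound" and w.compound_id is not None
        }


def inhibitor_effect_at(strength: float, conc_um: float, primary_conc_um: float, ec50_um: float) -> float:
    """Dose-scaled inhibitor effect, normalised to ``strength`` at the primary dose."""
    if conc_um <= 0:
        return 0.0
    norm = primary_conc_um / (primary_conc_um + ec50_um)
    return min(0.99, strength * (conc_um / (conc_um + ec50_um)) / norm)


def _well_spec_for(
    rec: WellRecord,
    ds_params: dict,
    activation: ActivationModel,
    proliferation: ProliferationModel,
) -> WellSpec:
    """Translate a well record (with planted effect) into a WellSpec."""
    model_dose = ds_params["model_dose"]
    base = dict(
        activation=activation,
        proliferation=proliferation,
        canvas=ds_params["canvas"],
        render_scale=ds_params["render_scale"],
        n_initial=ds_params["n_initial"],
        well_id=rec.well_id,
        planted_effect=rec.effect,
    )
    if rec.role == "control":
        return WellSpec(dose=0.0, **base)
    if rec.role == "model":
        return WellSpec(dose=model_dose, **base)
    # compound wells: stimulated at the model dose, modified by the effect
    f_ctrl = activation.baseline_activated_fraction
    f_model = activation.activated_fraction(model_dose)
    m_model = proliferation.rate_multiplier(model_dose)
    if rec.effect == "inhibitor":
        e = inhibitor_effect_at(
            rec.strength, rec.conc_um, ds_params["primary_conc_um"], ds_params["inhibitor_ec50_um"]
        )
        f_eff = f_ctrl + (f_model - f_ctrl) * (1.0 - e)
        m_eff = 1.0 + (m_model - 1.0) * (1.0 - e)
    elif rec.effect == "toxic":
        f_eff = f_model
        m_eff = rec.strength  # negative-to-weak multiplier: cells die off
    else:
        f_eff = f_model
        m_eff = m_model
    return WellSpec(
        dose=model_dose,
        activation_override=f_eff,
        rate_multiplier_override=m_eff,
        **base,
    )


def simulate_wells(
    records: Sequence[WellRecord],
    ds_params: dict,
    activation: ActivationModel,
    proliferation: ProliferationModel,
    duration_h: float,
    interval_h: float,
    seed,
    render: bool = True,
    readout_canvas: tuple[int, int] | None = None,
    readout_fields: int = 2,
) -> tuple[
    dict[str, list[FieldImage]],
    dict[str, GroundTruth],
    dict[str, list[FieldImage]] | None,
]:
    """Simulate each well's classification field (and readout field).

    The well-level growth-rate jitter is drawn once per well and shared
    between its fields, as both image the same culture.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(records))
    images: dict[str, list[FieldImage]] = {}
    truth: dict[str, GroundTruth] = {}
    readout: dict[str, list[FieldImage]] | None = {} if readout_canvas else None
    for rec, child in zip(records, children):
        rng = np.random.default_rng(child)
        spec = _well_spec_for(rec, ds_params, activation, proliferation)
        base_mult = (
            spec.rate_multiplier_override
            if spec.rate_multiplier_override is not None
            else proliferation.rate_multiplier(spec.dose)
        )
        jit = _lognormal_factor(rng, spec.rate_jitter_cv)
        spec = replace(spec, rate_multiplier_override=base_mult * jit, rate_jitter_cv=0.0)
        imgs, gt = simulate_timecourse(spec, duration_h, interval_h, rng, render=render)
        images[rec.well_id] = imgs
        truth[rec.well_id] = gt
        if readout_canvas:
            area_factor = (readout_canvas[0] * readout_canvas[1]) / (
                spec.canvas[0] * spec.canvas[1]
            )
            rspec = replace(
                spec,
                canvas=readout_canvas,
                n_initial=spec.n_initial * area_factor,
                proliferation=replace(
                    spec.proliferation,
                    carrying_capacity=spec.proliferation.carrying_capacity * area_factor,
                ),
                channels=("dpc",),
            )
            frames: list[FieldImage] = []
            for fi in range(readout_fields):
                rimgs, _ = simulate_timecourse(rspec, duration_h, interval_h, rng, render=render)
                for im in rimgs:
                    im.field_index = fi + 1
                frames.extend(rimgs)
            readout[rec.well_id] = frames
    return images, truth, readout


def simulate_screen(
    n_compounds: int,
    planted_inhibitor_fraction: float = 0.1,
    planted_toxic_fraction: float = 0.05,
    plate_layout: PlateLayout = PlateLayout(),
    seed: int = 0,
    *,
    model_dose: float = 10.0,
    primary_conc_um: float = 10.0,
    canvas: tuple[int, int] = (128, 128),
    render_scale: float = 0.3,
    n_initial: float = 50.0,
    duration_h: float = 24.0,
    interval_h: float = 24.0,
    activation: ActivationModel = ActivationModel(),
    proliferation: ProliferationModel = ProliferationModel(),
    render: bool = True,
    readout_canvas: tuple[int, int] | None = (256, 256),
    readout_fields: int = 3,
) -> ScreenDataset:
    """Simulate a primary screen with planted inhibitors and toxic compounds.

    Each plate holds the layout's control wells (dose 0) and model wells
    (model dose, no compound); compound wells receive the model stimulus
    plus the compound at the primary concentration.  Planted inhibitors
    attenuate activation and proliferation toward control values; planted
    toxic compounds drive counts below the control range.  Exactly
    ``round(n * fraction)`` compounds receive each planted effect.
    """
    if planted_inhibitor_fraction < 0 or planted_toxic_fraction < 0:
        raise ValueError("planted fractions must be non-negative")
    if planted_inhibitor_fraction + planted_toxic_fraction > 1:
        raise ValueError("planted fractions must sum to <= 1")
    if plate_layout.n_control < 1 or plate_layout.n_model < 1:
        raise ConfigurationError("plates must contain control and model wells")

    rng = np.random.default_rng(seed)
    n_inh = int(round(n_compounds * planted_inhibitor_fraction))
    n_tox = int(round(n_compounds * planted_toxic_fraction))
    effects = ["inhibitor"] * n_inh + ["toxic"] * n_tox + ["none"] * (n_compounds - n_inh - n_tox)
    rng.shuffle(effects)

    rows = "ABCDEFGH"
    per_plate = plate_layout.n_compound_slots
    n_plates = max(1, math.ceil(n_compounds / per_plate))
    records: list[WellRecord] = []
    ci = 0
    for p in range(n_plates):
        plate_id = f"P{p + 1}"
        n_cols = max(1, plate_layout.n_wells // len(rows))
        well_ids = [f"{plate_id}-{r}{c + 1:02d}" for r in rows for c in range(n_cols)][
            : plate_layout.n_wells
        ]
        roles = (
            ["control"] * plate_layout.n_control
            + ["model"] * plate_layout.n_model
            + ["compound"] * per_plate
        )
        rng.shuffle(roles)
        for wid, role in zip(well_ids, roles):
            if role == "compound":
                if ci >= n_compounds:
                    continue
                eff = effects[ci]
                if eff == "inhibitor":
                    strength = float(rng.uniform(0.85, 0.98))
                elif eff == "toxic":
                    strength = float(rng.uniform(-0.5, 0.4))
                else:
                    strength = 0.0
                records.append(
                    WellRecord(
                        well_id=wid,
                        plate_id=plate_id,
                        role=role,
                        compound_id=f"CPD{ci + 1:04d}",
                        conc_um=primary_conc_um,
                        dose=model_dose,
                        effect=eff,
                        strength=strength,
                    )
                )
                ci += 1
            else:
                records.append(
                    WellRecord(
                        well_id=wid,
                        plate_id=plate_id,
                        role=role,
                        dose=0.0 if role == "control" else model_dose,
                    )
                )

    ds_params = dict(
        model_dose=model_dose,
        primary_conc_um=primary_conc_um,
        canvas=canvas,
        render_scale=render_scale,
        n_initial=n_initial,
        inhibitor_ec50_um=5.0,
    )
    images, truth, readout_images = simulate_wells(
        records,
        ds_params,
        activation,
        proliferation,
        duration_h,
        interval_h,
        np.random.SeedSequence([seed, 1]),
        render=render,
        readout_canvas=readout_canvas,
        readout_fields=readout_fields,
    )
    return ScreenDataset(
        wells=records,
        images=images,
        truth=truth,
        readout_images=readout_images,
        model_dose=model_dose,
        primary_conc_um=primary_conc_um,
        layout=plate_layout,
        activation=activation,
        proliferation=proliferation,
        canvas=canvas,
        render_scale=render_scale,
        n_initial=n_initial,
        duration_h=duration_h,
        interval_h=interval_h,
        seed=seed,
    )


def simulate_confirmation(
    dataset: ScreenDataset,
    compound_ids: Sequence[str],
    concs_um: Sequence[float] = (20.0, 10.0, 5.0, 1.0),
    seed: int | None = None,
) -> tuple[list[WellRecord], dict[str, list[FieldImage]], dict[str, GroundTruth]]:
    """Simulate confirmation-dose wells for selected compounds.

    Each compound keeps its planted ground-truth effect; inhibitor
    strength scales with concentration through a saturating potency
    curve anchored at the primary screening concentration.
    """
    by_id = {w.compound_id: w for w in dataset.wells if w.role == "compound"}
    records: list[WellRecord] = []
    for cid in compound_ids:
        base = by_id[cid]
        for conc in concs_um:
            records.append(
                WellRecord(
                    well_id=f"CONF-{cid}-{conc:g}uM",
                    plate_id="CONF",
                    role="compound",
                    compound_id=cid,
                    conc_um=conc,
                    dose=dataset.model_dose,
                    effect=base.effect,
                    strength=base.strength,
                )
            )
    ds_params = dict(
        model_dose=dataset.model_dose,
        primary_conc_um=dataset.primary_conc_um,
        canvas=dataset.canvas,
        render_scale=dataset.render_scale,
        n_initial=dataset.n_initial,
        inhibitor_ec50_um=dataset.inhibitor_ec50_um,
    )
    images, truth, _ = simulate_wells(
        records,
        ds_params,
        dataset.activation,
        dataset.proliferation,
        dataset.duration_h,
        dataset.interval_h,
        np.random.SeedSequence([dataset.seed if seed is None else seed, 2]),
    )
    return records, images, truth
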