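"""Generator contracts: dose response, rendering, growth, screen layout."""

import numpy as np
import pytest
from scipy import stats

import dpcscreen as d
from dpcscreen.errors import ConfigurationError
from dpcscreen.phantoms import sample_population_at_fraction


def _frac(cells):
    return np.mean([c.activated for c in cells])


class TestActivationModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            d.ActivationModel(baseline_activated_fraction=0.5, max_activated_fraction=0.4)
        with pytest.raises(ValueError):
            d.ActivationModel(half_effect_dose=0.0)
        with pytest.raises(ValueError):
            d.ActivationModel(marker_noise_sd=-1.0)

    @pytest.mark.parametrize(
        "dose,baseline,maximum,expected",
        [
            (0.0, 0.05, 0.9, 0.05),  # Hill curve at zero dose
            (2.5e6, 0.05, 0.9, 0.9),  # saturation at 1e6 x half dose
            (2.5, 0.0, 0.8, 0.40),  # half-maximal point
        ],
    )
    def test_activated_fraction_landmarks(self, dose, baseline, maximum, expected):
        am = d.ActivationModel(
            baseline_activated_fraction=baseline, max_activated_fraction=maximum
        )
        cells = d.sample_population(dose, 10_000, am, seed=1)
        se = np.sqrt(expected * (1 - expected) / 10_000) if 0 < expected < 1 else 0.01
        assert abs(_frac(cells) - expected) <= 3 * se + 1e-9

    def test_dose_monotonicity(self):
        am = d.ActivationModel()
        fr = [am.activated_fraction(x) for x in (0, 0.5, 1.25, 2.5, 5, 10, 25, 50, 200)]
        assert all(b >= a for a, b in zip(fr, fr[1:]))

    def test_negative_dose_rejected(self):
        am = d.ActivationModel()
        with pytest.raises(ValueError):
            d.sample_population(-1.0, 10, am, seed=0)
        with pytest.raises(ValueError):
            d.sample_population(1.0, -5, am, seed=0)

    def test_marker_morphology_coupling(self):
        """Across >=500 cells, marker intensity and cell area correlate."""
        am = d.ActivationModel()
        cells = d.sample_population(2.5, 600, am, seed=3, canvas=(2000, 2000))
        area = [c.major_axis * c.minor_axis for c in cells]
        marker = [c.marker_intensity for c in cells]
        r = stats.pearsonr(area, marker).statistic
        assert r > 0.3

    def test_state_geometry_contract(self):
        """Activated cells: larger area, lower elongation (n >= 200/state)."""
        am = d.ActivationModel()
        act = sample_population_at_fraction(1.0, 250, am, seed=4, canvas=(2000, 2000))
        rest = sample_population_at_fraction(0.0, 250, am, seed=5, canvas=(2000, 2000))
        area = lambda cc: np.mean([c.major_axis * c.minor_axis for c in cc])  # noqa: E731
        elong = lambda cc: np.mean([c.major_axis / c.minor_axis for c in cc])  # noqa: E731
        assert area(act) > area(rest)
        assert elong(act) < elong(rest)


class TestRenderField:
    def test_empty_field_is_background(self):
        img = d.render_field([], 128, 128, ("dpc",), seed=0)
        from dpcscreen.segmentation import count_cells, segment_cells

        assert count_cells(segment_cells(img, "dpc")) == 0

    def test_determinism_bit_identical(self):
        am = d.ActivationModel()
        cells = d.sample_population(5.0, 30, am, seed=9, canvas=(256, 256))
        a = d.render_field(cells, 256, 256, ("brightfield", "dpc"), seed=11)
        b = d.render_field(cells, 256, 256, ("brightfield", "dpc"), seed=11)
        for ch in a.channels:
            assert np.array_equal(a.channels[ch], b.channels[ch])

    def test_empty_channel_set_rejected(self):
        with pytest.raises(ValueError):
            d.render_field([], 64, 64, (), seed=0)

    def test_all_channels_render(self):
        am = d.ActivationModel()
        cells = d.sample_population(10.0, 20, am, seed=2, canvas=(128, 128))
        img = d.render_field(
            cells, 128, 128, ("brightfield", "dpc", "marker", "nuclei"), seed=3
        )
        assert set(img.channel_names) == {"brightfield", "dpc", "marker", "nuclei"}
        for ch in img.channels.values():
            assert ch.dtype == np.uint16


class TestTimecourse:
    def test_half_hour_sampling_gives_48_frames(self):
        spec = d.WellSpec(dose=0.0, n_initial=20, canvas=(64, 64), render_scale=0.2)
        _, truth = d.simulate_timecourse(spec, 23.5, 0.5, seed=0, render=False)
        assert len(truth.frames) == 48

    def test_zero_duration_single_frame(self):
        spec = d.WellSpec(n_initial=10, canvas=(64, 64), render_scale=0.2)
        _, truth = d.simulate_timecourse(spec, 0.0, 0.5, seed=0, render=False)
        assert len(truth.frames) == 1

    def test_bad_interval_rejected(self):
        spec = d.WellSpec()
        with pytest.raises(ValueError):
            d.simulate_timecourse(spec, 10.0, 0.0, seed=0, render=False)

    def test_counts_follow_logistic_prediction(self):
        """Realized peak-dose/control count ratio matches the closed form."""
        pm = d.ProliferationModel()
        ratios = []
        for seed in range(12):
            counts = {}
            for dose in (0.0, pm.peak_dose):
                spec = d.WellSpec(
                    dose=dose, n_initial=100, proliferation=pm, rate_jitter_cv=0.0,
                    canvas=(512, 512),
                )
                _, truth = d.simulate_timecourse(spec, 24, 24, seed=seed, render=False)
                counts[dose] = truth.true_counts[-1] / truth.true_counts[0]
            ratios.append(counts[pm.peak_dose] / counts[0.0])
        predicted = (
            pm.expected_count(100, pm.peak_dose, 24) / 100
        ) / (pm.expected_count(100, 0.0, 24) / 100)
        assert abs(np.mean(ratios) - predicted) / predicted < 0.05

    def test_biphasic_proliferation(self):
        """24-h growth is maximal at the peak dose, weaker at 10x peak."""
        pm = d.ProliferationModel()
        gains = {dose: [] for dose in (0.0, pm.peak_dose, 10 * pm.peak_dose)}
        for seed in range(20):
            for dose in gains:
                spec = d.WellSpec(dose=dose, n_initial=80, canvas=(512, 512), render_scale=0.3)
                _, truth = d.simulate_timecourse(spec, 24, 24, seed=seed, render=False)
                gains[dose].append(truth.true_counts[-1] / truth.true_counts[0])
        mean = {k: np.mean(v) for k, v in gains.items()}
        assert mean[pm.peak_dose] > mean[0.0]
        assert mean[10 * pm.peak_dose] < mean[pm.peak_dose]

    def test_rate_multiplier_shape(self):
        pm = d.ProliferationModel()
        assert pm.rate_multiplier(0.0) == 1.0
        doses = np.geomspace(0.1, 1000, 80)
        mult = np.array([pm.rate_multiplier(x) for x in doses])
        assert abs(doses[mult.argmax()] - pm.peak_dose) / pm.peak_dose < 0.2
        assert pm.rate_multiplier(10 * pm.peak_dose) < pm.rate_multiplier(pm.peak_dose)


class TestSimulateScreen:
    def test_planted_counts_exact(self):
        ds = d.simulate_screen(
            80, 0.1, 0.05, seed=5, render=False, readout_canvas=None
        )
        labels = list(ds.truth_labels().values())
        assert labels.count("inhibitor") == 8
        assert labels.count("toxic") == 4

    def test_full_plate_layout(self):
        ds = d.simulate_screen(
            80, 0.0, 0.0, seed=1, render=False, readout_canvas=None
        )
        assert len(ds.wells) == 96
        roles = [w.role for w in ds.wells]
        assert roles.count("control") == 8
        assert roles.count("model") == 8
        assert roles.count("compound") == 80

    def test_inhibitor_activation_within_control_band(self):
        """A strong planted inhibitor's activated fraction is control-like."""
        ds = d.simulate_screen(
            40, 1.0, 0.0, seed=3, render=False, readout_canvas=None
        )
        am = ds.activation
        ctrl_frac = am.baseline_activated_fraction
        for wid, gt in ds.truth.items():
            if gt.planted_effect == "inhibitor":
                frac = gt.frames[-1].activated_count / gt.frames[-1].true_count
                assert frac < am.activated_fraction(ds.model_dose) / 2
                assert frac == pytest.approx(ctrl_frac, abs=0.25)

    def test_toxic_wells_decline(self):
        ds = d.simulate_screen(
            40, 0.0, 1.0, seed=3, render=False, readout_canvas=None
        )
        rels = [
            gt.true_counts[-1] / gt.true_counts[0]
            for gt in ds.truth.values()
            if gt.planted_effect == "toxic"
        ]
        ctrl = [
            gt.true_counts[-1] / gt.true_counts[0]
            for wid, gt in ds.truth.items()
            if gt.planted_effect == "none" and gt.dose == 0.0
        ]
        assert max(rels) < min(ctrl)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            d.simulate_screen(10, 0.8, 0.5, seed=0, render=False)
        with pytest.raises(ConfigurationError):
            d.PlateLayout(n_wells=96, n_control=0, n_model=8)

    def test_ground_truth_counts_consistent(self):
        ds = d.simulate_screen(8, 0.0, 0.0, seed=2, render=False, readout_canvas=None)
        for gt in ds.truth.values():
            for frame in gt.frames:
                assert frame.true_count == len(frame.cells)
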