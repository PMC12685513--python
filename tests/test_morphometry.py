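"""The 31-feature registry and its geometric/intensity contracts."""

import numpy as np
import pytest
from scipy import stats
from skimage.draw import disk, ellipse

import dpcscreen as d
from dpcscreen.morphometry import (
    FEATURE_NAMES,
    REGISTRY,
    extract_features,
    feature_registry,
)
from dpcscreen.phantoms import sample_population_at_fraction
from dpcscreen.pipeline import segmentation_params
from dpcscreen.segmentation import LabelMask, segment_cells


def _mask_image(shape, fg_coords, intensity=1000.0, background=100.0, noise_seed=0):
    rng = np.random.default_rng(noise_seed)
    img = background + rng.normal(0, 2.0, shape)
    lab = np.zeros(shape, dtype=np.int32)
    lab[fg_coords] = 1
    img[fg_coords] = intensity + rng.normal(0, 2.0, lab.sum())
    return img, LabelMask(labels=lab)


class TestRegistry:
    def test_exactly_31_unique_features(self):
        reg = feature_registry()
        assert len(reg) == 31
        names = [r.name for r in reg]
        assert len(set(names)) == 31
        assert names == list(FEATURE_NAMES)

    def test_required_names_present(self):
        required = {
            "cell_area", "cell_roundness", "cell_width", "cell_length",
            "cell_aspect_ratio", "cell_radial_mean", "ebr_bright",
            "profile_1", "profile_2", "ser_bright_0px", "ser_bright_1px",
            "ser_bright_2px",
        }
        assert required <= set(FEATURE_NAMES)

    def test_group_sizes(self):
        tex = [n for n in FEATURE_NAMES if n.startswith("ser_")]
        assert len(tex) == 12


class TestGeometry:
    def test_disk_features(self):
        """Filled disk radius 20: roundness ~1, aspect ~1, area ~pi r^2."""
        img, mask = _mask_image((128, 128), disk((64, 64), 20))
        row = extract_features(img, mask).iloc[0]
        assert row["cell_roundness"] == pytest.approx(1.0, abs=0.02)
        assert row["cell_aspect_ratio"] == pytest.approx(1.0, abs=0.05)
        assert row["cell_area"] == pytest.approx(np.pi * 400, rel=0.03)

    def test_ellipse_aspect_ratio(self):
        """Ellipse with semi-axes 40x10 px has aspect ratio ~4."""
        img, mask = _mask_image((256, 256), ellipse(128, 128, 10, 40))
        row = extract_features(img, mask).iloc[0]
        assert row["cell_aspect_ratio"] == pytest.approx(4.0, rel=0.05)

    def test_rotation_invariance_90deg(self):
        img, mask = _mask_image((256, 256), ellipse(128, 128, 12, 40, rotation=0.3))
        r0 = extract_features(img, mask).iloc[0][list(FEATURE_NAMES)]
        img_r = np.rot90(img).copy()
        mask_r = LabelMask(labels=np.ascontiguousarray(np.rot90(mask.labels)))
        r1 = extract_features(img_r, mask_r).iloc[0][list(FEATURE_NAMES)]
        for name in FEATURE_NAMES:
            a, b = float(r0[name]), float(r1[name])
            scale = max(abs(a), abs(b), 1e-9)
            assert abs(a - b) / scale <= 0.02, name

    def test_scale_law(self):
        """Scaling a phantom by s scales area ~s^2 and axes ~s."""
        s = 1.5
        img1, m1 = _mask_image((256, 256), ellipse(128, 128, 12, 30))
        img2, m2 = _mask_image((256, 256), ellipse(128, 128, 12 * s, 30 * s))
        a = extract_features(img1, m1).iloc[0]
        b = extract_features(img2, m2).iloc[0]
        assert b["cell_area"] / a["cell_area"] == pytest.approx(s**2, rel=0.03)
        assert b["cell_length"] / a["cell_length"] == pytest.approx(s, rel=0.03)
        assert b["cell_width"] / a["cell_width"] == pytest.approx(s, rel=0.03)
        assert b["cell_roundness"] == pytest.approx(a["cell_roundness"], rel=0.02)
        assert b["cell_aspect_ratio"] == pytest.approx(a["cell_aspect_ratio"], rel=0.02)


class TestIntensityContracts:
    def test_offset_invariance_per_registry(self):
        """Only the intensity/profile features move under +c offsets."""
        # radially structured interior so every intensity feature is live
        coords = ellipse(64, 64, 10, 25)
        img, mask = _mask_image((128, 128), coords)
        yy, xx = coords
        img[coords] += 20.0 * np.hypot(yy - 64, xx - 64)
        r0 = extract_features(img, mask).iloc[0]
        r1 = extract_features(img + 250.0, mask).iloc[0]
        for desc in REGISTRY:
            a, b = float(r0[desc.name]), float(r1[desc.name])
            scale = max(abs(a), abs(b), 1e-9)
            if desc.offset_invariant:
                assert abs(a - b) / scale < 0.05, desc.name
            else:
                assert abs(a - b) / scale > 0.01, desc.name

    def test_all_features_finite_on_phantoms(self):
        am = d.ActivationModel()
        cells = sample_population_at_fraction(
            0.5, 60, am, 0, canvas=(512, 512), render_scale=0.5
        )
        img = d.render_field(cells, 512, 512, ("dpc",), seed=1)
        feats = extract_features(img, segment_cells(img, "dpc", **segmentation_params(0.5)))
        assert len(feats) > 20
        assert np.isfinite(feats[list(FEATURE_NAMES)].to_numpy()).all()
        assert (feats["cell_aspect_ratio"] >= 1).all()
        assert ((feats["cell_roundness"] > 0) & (feats["cell_roundness"] <= 1)).all()

    def test_empty_mask_empty_table(self):
        img = np.zeros((64, 64))
        mask = LabelMask(labels=np.zeros((64, 64), dtype=np.int32))
        feats = extract_features(img, mask)
        assert feats.empty
        assert list(feats.columns)[4:] == list(FEATURE_NAMES)

    def test_dimension_mismatch_raises(self):
        img = np.zeros((64, 64))
        mask = LabelMask(labels=np.zeros((32, 32), dtype=np.int32))
        with pytest.raises(ValueError):
            extract_features(img, mask)


class TestStateSeparability:
    def test_activated_vs_resting_features(self):
        """Measured area/aspect separate the two states at p < 0.01."""
        am = d.ActivationModel()
        params = segmentation_params(0.6)
        tables = {}
        for label, frac, seed in (("act", 1.0, 0), ("rest", 0.0, 1)):
            rows = []
            for rep in range(3):
                cells = sample_population_at_fraction(
                    frac, 80, am, seed + 10 * rep, canvas=(512, 512), render_scale=0.6
                )
                img = d.render_field(cells, 512, 512, ("dpc",), seed=seed + 50 + rep)
                rows.append(
                    extract_features(img, segment_cells(img, "dpc", **params))
                )
            tables[label] = np.concatenate([t[["cell_area", "cell_aspect_ratio"]].to_numpy() for t in rows])
        area_p = stats.ttest_ind(tables["act"][:, 0], tables["rest"][:, 0]).pvalue
        aspect_p = stats.ttest_ind(tables["act"][:, 1], tables["rest"][:, 1]).pvalue
        assert tables["act"][:, 0].mean() > tables["rest"][:, 0].mean()
        assert tables["act"][:, 1].mean() < tables["rest"][:, 1].mean()
        assert area_p < 0.01 and aspect_p < 0.01
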