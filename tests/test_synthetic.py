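"""Exact-oracle and statistical tests for the synthetic carcass generator."""

import io

import numpy as np
import pytest

from ccw.synthetic import (SyntheticCarcassSpec, WeightModel, analytic_areas_cm2,
                           analytic_areas_table, assign_weights, default_spec,
                           generate_carcass, generate_dataset, rasterize_view,
                           _view_shapes, shape_membership)
from ccw.dataset_io import PART_CLASSES


def _small_spec(cid="c0", s=1.0, **kw):
    return default_spec(cid, s=s, canvas=160, sigma_pos=0, sigma_tex=0,
                        sigma_scale=0, **kw)


class TestRasterization:
    @pytest.mark.parametrize("view", ["ventral", "lateral"])
    def test_matches_membership_oracle(self, view):
        """Rasterized labels equal a per-pixel scalar membership evaluation."""
        spec = _small_spec(s=1.0)
        labels = rasterize_view(spec, view)
        shapes = _view_shapes(spec, view, spec.s)
        c = spec.canvas
        # scalar loop over a probe subset plus full vector check
        want = np.zeros((c, c), dtype=int)
        for part, kind, params in shapes:
            ys, xs = np.mgrid[0:c, 0:c]
            inside = shape_membership(kind, params, xs + 0.5, ys + 0.5)
            want[inside] = PART_CLASSES[part]
        np.testing.assert_array_equal(labels, want)
        rng = np.random.default_rng(7)
        for _ in range(200):     # independent scalar spot checks
            i, j = rng.integers(0, c, 2)
            lab = 0
            for part, kind, params in shapes:
                if bool(shape_membership(kind, params,
                                         np.float64(j + 0.5),
                                         np.float64(i + 0.5))):
                    lab = PART_CLASSES[part]
            assert labels[i, j] == lab

    def test_area_scaling_law(self):
        """Doubling the size factor quadruples every part's pixel area."""
        half = dict(torso_semi_axes=(40.0, 55.0), head_radius=16.5,
                    leg_length=46.0, leg_width=12.0, gap=5.0, sigma_pos=0,
                    sigma_tex=0, sigma_scale=0)
        small = SyntheticCarcassSpec(carcass_id="a", s=1.0, canvas=640, **half)
        big = SyntheticCarcassSpec(carcass_id="a", s=2.0, canvas=640, **half)
        for view in ("ventral", "dorsal", "lateral"):
            m_small = rasterize_view(small, view)
            m_big = rasterize_view(big, view)
            for part, lab in PART_CLASSES.items():
                if lab == 0:
                    continue
                ratio = (m_big == lab).sum() / (m_small == lab).sum()
                assert ratio == pytest.approx(4.0, rel=0.02)

    def test_deterministic_replicates_without_jitter(self):
        spec = _small_spec()
        sample = generate_carcass(spec, seed=3, replicates=3)
        for view in spec.views:
            for rep in (2, 3):
                np.testing.assert_array_equal(
                    sample["images"][(view, 1)], sample["images"][(view, rep)])
                np.testing.assert_array_equal(
                    sample["masks"][(view, 1)], sample["masks"][(view, rep)])

    def test_rasterized_area_close_to_analytic(self):
        spec = default_spec("c0", s=0.9, canvas=320, sigma_pos=0,
                            sigma_tex=0, sigma_scale=0)
        for view in ("ventral", "lateral"):
            labels = rasterize_view(spec, view)
            areas = analytic_areas_cm2(spec, view)
            for part, lab in PART_CLASSES.items():
                if lab == 0:
                    continue
                measured = (labels == lab).sum() / spec.px_per_cm**2
                assert measured == pytest.approx(areas[part], rel=0.02)

    def test_dark_background_bright_foreground(self):
        spec = default_spec("c0", canvas=160, sigma_pos=0, sigma_scale=0)
        sample = generate_carcass(spec, seed=1)
        im = sample["images"][("ventral", 1)]
        mask = sample["masks"][("ventral", 1)] > 0
        assert im[mask].mean() > 150 and im[~mask].mean() < 50

    def test_oversized_geometry_rejected_with_dimension_name(self):
        with pytest.raises(ValueError, match="leg_length"):
            SyntheticCarcassSpec(carcass_id="x", canvas=64)


class TestWeightModel:
    def test_noiseless_linear(self):
        model = WeightModel(beta0=0.0, betas={"torso": 1.0, "head": 1.0,
                                              "leg": 1.0},
                            sigma_w=0.0,
                            part_intercepts={"torso": 0, "head": 0, "leg": 0})
        areas = {"torso": {"ventral": 60.0}, "head": {"ventral": 30.0},
                 "leg": {"ventral": 10.0}}
        rec = assign_weights(areas, model, seed=0)
        assert rec.total_g == pytest.approx(100.0)

    def test_intercept_only(self):
        model = WeightModel(beta0=50.0, betas={}, sigma_w=0.0,
                            part_intercepts={})
        rec = assign_weights({"torso": {"ventral": 123.0}}, model, seed=0)
        assert rec.total_g == pytest.approx(50.0)

    def test_negative_area_rejected(self):
        model = WeightModel(sigma_w=0.0)
        with pytest.raises(ValueError, match="negative"):
            assign_weights({"torso": {"ventral": -1.0}}, model, seed=0)

    def test_noise_is_centered(self):
        """Monte-Carlo: mean deviation from the deterministic part ~ 0."""
        sigma = 25.0
        model = WeightModel(sigma_w=sigma)
        areas = {"torso": {"ventral": 280.0}, "head": {"ventral": 38.0},
                 "leg": {"ventral": 60.0}}
        det, _ = model.deterministic_weights(areas)
        n = 1000
        devs = [assign_weights(areas, model, seed=s).total_g - det
                for s in range(n)]
        assert abs(np.mean(devs)) < 4 * sigma / np.sqrt(n)

    def test_ols_recovers_coefficients_on_noiseless_cohort(self):
        """Least squares on noiseless generated data returns the true betas."""
        model = WeightModel(sigma_w=0.0)
        man = generate_dataset(40, seed=3, canvas=160, weight_model=model)
        rows = []
        y = []
        for cid in man.specs:
            areas = man.true_areas(cid)
            rows.append([np.mean(list(areas[p].values()))
                         for p in ("torso", "head", "leg")])
            y.append(float(man.weights.set_index("carcass_id")
                           .loc[cid, "weight_total_g"]))
        x = np.column_stack([np.ones(len(rows)), np.array(rows)])
        coef, *_ = np.linalg.lstsq(x, np.array(y), rcond=None)
        want = [model.beta0, model.betas["torso"], model.betas["head"],
                model.betas["leg"]]
        np.testing.assert_allclose(coef, want, rtol=1e-6)


class TestDataset:
    def test_record_counts(self):
        man = generate_dataset(301, seed=0, canvas=160)
        assert len(man.images) == 2709
        assert len(man.weights) == 301
        assert man.images.carcass_id.nunique() == 301

    def test_single_carcass(self):
        man = generate_dataset(1, seed=0, canvas=160)
        assert len(man.images) == 9

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError, match="at least 1"):
            generate_dataset(0, seed=0)

    def test_manifests_byte_identical_across_runs(self, tmp_path):
        bufs = []
        for _ in range(2):
            man = generate_dataset(20, seed=9, canvas=160)
            a, b = io.StringIO(), io.StringIO()
            man.to_csv(a, b)
            bufs.append((a.getvalue(), b.getvalue()))
        assert bufs[0] == bufs[1]

    def test_noise_calibration_hits_signal_fraction(self):
        """sigma_w is set so the area term explains ~90% of weight variance."""
        man = generate_dataset(200, seed=4, canvas=160, signal_fraction=0.9)
        det = np.array([man.weight_model.deterministic_weights(
            man.true_areas(cid))[0] for cid in man.specs])
        ratio = man.weight_model.sigma_w / det.std(ddof=1)
        assert ratio == pytest.approx(np.sqrt(1 / 0.9 - 1), rel=1e-6)

    def test_analytic_areas_table_layout(self):
        man = generate_dataset(5, seed=2, canvas=160)
        table = analytic_areas_table(man)
        assert set(table.part) == {"torso", "head", "leg"}
        assert len(table) == 5 * 3 * 3  # carcasses x views x parts
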