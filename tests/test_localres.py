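import numpy as np
import pytest

import mapres.localres as localres_mod
from mapres.boxes import BandSpec
from mapres.localres import (
    AuditReport,
    OversharpenConfig,
    ResolutionMap,
    ResolutionSummary,
    audit_sharpening,
    estimate,
    summarize,
)
from mapres.map_io import DensityMap, Mask, ValidationError
from mapres.network import NetworkConfig, build
from mapres.spectral import FilterBankSpec


@pytest.fixture()
def band():
    return BandSpec(voxel_size=1.0, bank=FilterBankSpec(3.0, 12.0, 1.0))


@pytest.fixture()
def reg(band):
    return build(NetworkConfig(seed=0), band=band)


def constant_predictor(value):
    def fake_predict(reg, cubes, batch=16, norm_tol=1e-3):
        return np.full(len(cubes), value, np.float32)

    return fake_predict


class TestEstimate:
    def test_constant_predictor_contract(self, rng, band, reg, monkeypatch):
        """Stub regressor returning 5.0 -> rmap is 5.0 on covered voxels, 0 elsewhere."""
        monkeypatch.setattr(localres_mod, "predict", constant_predictor(5.0))
        dmap = DensityMap(rng.standard_normal((20, 20, 20)).astype(np.float32), voxel_size=1.0)
        mask_data = np.zeros(dmap.shape, np.uint8)
        mask_data[8:12, 8:12, 8:12] = 1
        rmap = estimate(dmap, Mask(mask_data), reg)
        covered = rmap.coverage > 0
        assert covered.sum() == mask_data.sum()  # interior mask: all covered
        assert np.all(rmap.data[covered] == 5.0)
        assert np.all(rmap.data[~covered] == 0.0)

    def test_outside_mask_zero(self, rng, band, reg, monkeypatch):
        monkeypatch.setattr(localres_mod, "predict", constant_predictor(4.0))
        dmap = DensityMap(rng.standard_normal((16, 16, 16)).astype(np.float32), voxel_size=1.0)
        mask_data = np.zeros(dmap.shape, np.uint8)
        mask_data[7, 7, 7] = 1
        rmap = estimate(dmap, Mask(mask_data), reg)
        assert rmap.data.shape == dmap.shape
        assert rmap.data[7, 7, 7] == 4.0
        assert rmap.data.sum() == pytest.approx(4.0)

    def test_resampled_to_band_voxel(self, rng, band, reg, monkeypatch):
        """A 0.5 A/voxel input is worked at the band's 1.0 A/voxel."""
        monkeypatch.setattr(localres_mod, "predict", constant_predictor(6.0))
        dmap = DensityMap(rng.standard_normal((32, 32, 32)).astype(np.float32), voxel_size=0.5)
        mask_data = np.zeros(dmap.shape, np.uint8)
        mask_data[12:20, 12:20, 12:20] = 1
        rmap = estimate(dmap, Mask(mask_data), reg)
        assert rmap.voxel_size == 1.0
        assert rmap.data.shape == (16, 16, 16)
        back = estimate(dmap, Mask(mask_data), reg, return_original_grid=True)
        assert back.data.shape == dmap.shape
        assert back.voxel_size == 0.5

    def test_border_mask_errors(self, rng, band, reg, monkeypatch):
        monkeypatch.setattr(localres_mod, "predict", constant_predictor(4.0))
        dmap = DensityMap(rng.standard_normal((15, 15, 15)).astype(np.float32), voxel_size=1.0)
        mask_data = np.zeros(dmap.shape, np.uint8)
        mask_data[0, 0, 0] = 1
        with pytest.raises(ValidationError, match="window|border"):
            estimate(dmap, Mask(mask_data), reg)


class TestSummarize:
    def _rmap(self, band, values, coverage=None):
        data = np.zeros((15, 15, 15), np.float32)
        cov = np.zeros((15, 15, 15), np.uint8)
        idx = np.unravel_index(np.arange(len(values)), data.shape)
        data[idx] = values
        cov[idx] = 1
        if coverage is not None:
            cov = coverage
        return ResolutionMap(data=data, voxel_size=1.0, band=band, coverage=cov)

    def test_constant_map(self, band):
        rmap = self._rmap(band, np.full(100, 4.2, np.float32))
        s = summarize(rmap)
        assert s.median == pytest.approx(4.2, abs=1e-6)
        assert s.sd == pytest.approx(0.0, abs=1e-5)  # float32 rounding floor

    def test_histogram_counts_sum(self, band, rng):
        values = rng.uniform(3, 12, 500).astype(np.float32)
        s = summarize(self._rmap(band, values))
        assert s.histogram_counts.sum() == s.n_voxels == 500

    def test_percentile_50_equals_median(self, band, rng):
        values = rng.uniform(3, 12, 501).astype(np.float32)
        s = summarize(self._rmap(band, values), percentiles=(50.0,))
        sorted_vals = np.sort(values)
        assert s.percentiles[50.0] == pytest.approx(float(sorted_vals[250]), abs=1e-6)
        assert s.median == pytest.approx(s.percentiles[50.0], abs=1e-9)

    def test_empty_coverage_errors(self, band):
        rmap = ResolutionMap(
            data=np.zeros((15, 15, 15), np.float32),
            voxel_size=1.0,
            band=band,
            coverage=np.zeros((15, 15, 15), np.uint8),
        )
        with pytest.raises(ValidationError):
            summarize(rmap)

    def test_json_round_trip(self, band, tmp_path, rng):
        import json

        s = summarize(self._rmap(band, rng.uniform(3, 12, 64).astype(np.float32)))
        p = tmp_path / "s.json"
        s.to_json(p)
        loaded = json.loads(p.read_text())
        assert loaded["median"] == pytest.approx(s.median)
        assert sum(loaded["histogram_counts"]) == 64


class TestAudit:
    def _stub_estimates(self, monkeypatch, band, values_by_b):
        """Make estimate() yield a constant map per B factor via bfactor identity."""
        calls = iter(values_by_b)

        def fake_estimate(dmap, mask, reg, stride=1, batch=16, return_original_grid=False):
            value = next(calls)
            data = np.full((15, 15, 15), value, np.float32)
            cov = np.ones((15, 15, 15), np.uint8)
            return ResolutionMap(data=data, voxel_size=1.0, band=band, coverage=cov)

        monkeypatch.setattr(localres_mod, "estimate", fake_estimate)

    def test_paper_style_outcome(self, monkeypatch, band, reg, rng):
        """Reference 4.0; candidates {0:4.8,-30:4.4,-60:4.0,-100:3.4} -> pick -60, flag -100."""
        self._stub_estimates(monkeypatch, band, [4.8, 4.4, 4.0, 3.4])
        dmap = DensityMap(rng.standard_normal((15, 15, 15)).astype(np.float32), voxel_size=1.0)
        mask = Mask(np.ones(dmap.shape, np.uint8))
        ref = ResolutionMap(
            data=np.full((15, 15, 15), 4.0, np.float32),
            voxel_size=1.0,
            band=band,
            coverage=np.ones((15, 15, 15), np.uint8),
        )
        cfg = OversharpenConfig(b_grid=[0.0, -30.0, -60.0, -100.0], percentile=20.0)
        report = audit_sharpening(dmap, mask, reg, ref, cfg)
        assert report.recommended_b == -60.0
        flags = {row["b_factor"]: row["oversharpened"] for row in report.rows}
        assert flags == {0.0: False, -30.0: False, -60.0: False, -100.0: True}

    def test_b0_only_self_reference(self, monkeypatch, band, reg, rng):
        self._stub_estimates(monkeypatch, band, [5.0])
        dmap = DensityMap(rng.standard_normal((15, 15, 15)).astype(np.float32), voxel_size=1.0)
        mask = Mask(np.ones(dmap.shape, np.uint8))
        ref = ResolutionMap(
            data=np.full((15, 15, 15), 5.0, np.float32),
            voxel_size=1.0,
            band=band,
            coverage=np.ones((15, 15, 15), np.uint8),
        )
        report = audit_sharpening(dmap, mask, reg, ref, OversharpenConfig(b_grid=[0.0]))
        assert report.recommended_b == 0.0
        assert not report.rows[0]["oversharpened"]

    def test_linear_stub_crossing_point(self, monkeypatch, band, reg, rng):
        """Prediction improves linearly with |B|: recommendation = closed-form crossing."""
        b_grid = [0.0, -20.0, -40.0, -60.0, -80.0]
        slope, intercept = 0.01, 6.0  # value = intercept + slope * B
        self._stub_estimates(monkeypatch, band, [intercept + slope * b for b in b_grid])
        ref_value = 5.5
        crossing = (ref_value - intercept) / slope  # = -50
        expected = min(b_grid, key=lambda b: abs(b - crossing))
        dmap = DensityMap(rng.standard_normal((15, 15, 15)).astype(np.float32), voxel_size=1.0)
        mask = Mask(np.ones(dmap.shape, np.uint8))
        ref = ResolutionMap(
            data=np.full((15, 15, 15), ref_value, np.float32),
            voxel_size=1.0,
            band=band,
            coverage=np.ones((15, 15, 15), np.uint8),
        )
        report = audit_sharpening(dmap, mask, reg, ref, OversharpenConfig(b_grid=b_grid))
        assert report.recommended_b in (-40.0, -60.0)
        assert report.recommended_b == expected

    def test_missing_percentile_errors(self, band, reg, rng):
        summary = ResolutionSummary(
            median=4.0,
            sd=0.1,
            percentiles={50.0: 4.0},
            histogram_edges=np.array([3, 4, 5.0]),
            histogram_counts=np.array([1, 1]),
            n_voxels=2,
        )
        dmap = DensityMap(rng.standard_normal((15, 15, 15)).astype(np.float32), voxel_size=1.0)
        mask = Mask(np.ones(dmap.shape, np.uint8))
        with pytest.raises(ValidationError, match="percentile"):
            audit_sharpening(dmap, mask, reg, summary, OversharpenConfig(b_grid=[0.0]))

    def test_report_csv(self, tmp_path):
        report = AuditReport(
            percentile=20.0,
            reference_value=4.0,
            rows=[{"b_factor": 0.0, "percentile_value": 4.8, "median": 5.0, "oversharpened": False}],
            recommended_b=0.0,
        )
        p = tmp_path / "audit.csv"
        report.to_csv(p)
        assert "b_factor" in p.read_text()
        assert "4.8" in p.read_text()
        assert "recommended" in report.describe()


def test_oversharpen_config_validation():
    with pytest.raises(ValidationError):
        OversharpenConfig(b_grid=[])
    with pytest.raises(ValidationError):
        OversharpenConfig(percentile=0.0)
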