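import numpy as np
import pytest

from songrec.ppf import (
    InterpolationError,
    PhonotaxisRecord,
    PreferenceField,
    dc_transect,
    interpolate_field,
    peak_significance,
    period_transect,
    read_field,
    read_phonotaxis_table,
    write_field,
    write_phonotaxis_table,
)


def rec(d, p, score, n=4, per_female=None):
    return PhonotaxisRecord(pulse_duration=d, pause=p, score=score, n_females=n, per_female_scores=per_female)


def gaussian_bump_field(center_pulse, center_pause, resolution=0.25, extent=20.0, sd=1.0):
    axis = np.arange(0.0, extent + resolution / 2, resolution)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    vals = np.exp(-((gx - center_pulse) ** 2 + (gy - center_pause) ** 2) / (2 * sd**2))
    return PreferenceField(pulse_axis=axis, pause_axis=axis.copy(), values=vals, resolution=resolution)


class TestInterpolateField:
    def test_constant_records_give_constant_field(self):
        records = [rec(2, 2, 0.5), rec(2, 18, 0.5), rec(18, 2, 0.5), rec(18, 18, 0.5)]
        field = interpolate_field(records, resolution=1.0, extent=20.0)
        assert field.value_at(10.0, 10.0) == pytest.approx(0.5)
        np.testing.assert_allclose(field.values, 0.5, atol=1e-12)

    def test_interpolating_property_at_record_coordinates(self):
        records = [rec(2, 2, 0.1), rec(2, 18, 0.4), rec(18, 2, 0.8), rec(18, 18, 0.2), rec(10, 10, 0.6)]
        field = interpolate_field(records, resolution=0.5, extent=20.0)
        for r in records:
            assert field.value_at(r.pulse_duration, r.pause) == pytest.approx(r.score, abs=1e-9)

    def test_negative_plane_region_is_clipped_to_zero(self):
        # plane z = 0.8 - 0.05*(pulse + pause) dips below 0 for pulse+pause > 16
        records = [rec(d, p, 0.8 - 0.05 * (d + p)) for d, p in [(0, 0), (20, 0), (0, 20), (20, 20), (10, 10)]]
        field = interpolate_field(records, resolution=0.5, extent=20.0)
        assert field.value_at(19.0, 19.0) == 0.0
        assert field.value_at(2.0, 2.0) == pytest.approx(0.8 - 0.05 * 4, abs=1e-9)
        assert np.all(field.values >= 0.0)

    def test_outside_hull_uses_nearest_inside_value(self):
        records = [rec(8, 8, 0.2), rec(12, 8, 0.4), rec(10, 12, 0.9)]
        field = interpolate_field(records, resolution=0.5, extent=20.0)
        # far corner nearest to the (10, 12) record
        assert field.value_at(10.0, 20.0) == pytest.approx(0.9)

    def test_idempotent_on_its_own_output_at_record_locations(self):
        records = [rec(2, 2, 0.1), rec(2, 18, 0.4), rec(18, 2, 0.8), rec(18, 18, 0.2)]
        field = interpolate_field(records, resolution=0.5, extent=20.0)
        records2 = [rec(r.pulse_duration, r.pause, float(field.value_at(r.pulse_duration, r.pause))) for r in records]
        field2 = interpolate_field(records2, resolution=0.5, extent=20.0)
        for r in records:
            assert field2.value_at(r.pulse_duration, r.pause) == pytest.approx(
                field.value_at(r.pulse_duration, r.pause), abs=1e-9
            )

    def test_too_few_or_collinear_records_raise(self):
        with pytest.raises(InterpolationError):
            interpolate_field([rec(1, 1, 0.5), rec(2, 2, 0.5)])
        with pytest.raises(InterpolationError):
            interpolate_field([rec(i, i, 0.5) for i in range(1, 6)])


class TestTransects:
    def test_constant_field_gives_flat_transects(self):
        field = interpolate_field(
            [rec(2, 2, 0.7), rec(2, 18, 0.7), rec(18, 2, 0.7), rec(18, 18, 0.7)], resolution=0.5
        )
        _, pv = period_transect(field, 0.5)
        np.testing.assert_allclose(pv, 0.7, atol=1e-9)
        _, dv = dc_transect(field, 17.2)
        np.testing.assert_allclose(dv, 0.7, atol=1e-9)

    def test_period_transect_finds_gaussian_bump(self):
        # bump at (pulse, pause) = (4.3, 4.3): period 8.6, DC 50%
        field = gaussian_bump_field(4.3, 4.3)
        periods, vals = period_transect(field, 0.5)
        assert periods[np.argmax(vals)] == pytest.approx(8.6, abs=field.resolution)

    def test_period_transect_dc50_is_transpose_invariant(self):
        field = gaussian_bump_field(5.0, 5.0)
        _, v1 = period_transect(field, 0.5)
        swapped = PreferenceField(
            pulse_axis=field.pause_axis,
            pause_axis=field.pulse_axis,
            values=field.values.T,
            resolution=field.resolution,
        )
        _, v2 = period_transect(swapped, 0.5)
        np.testing.assert_allclose(v1, v2)

    def test_dc_transect_finds_two_bumps(self):
        f1 = gaussian_bump_field(0.25 * 17.2, 0.75 * 17.2, sd=1.2)
        f2 = gaussian_bump_field(0.90 * 17.2, 0.10 * 17.2, sd=1.2)
        field = PreferenceField(
            pulse_axis=f1.pulse_axis,
            pause_axis=f1.pause_axis,
            values=f1.values + f2.values,
            resolution=f1.resolution,
        )
        dcs, vals = dc_transect(field, 17.2)
        from conftest import local_maxima

        peaks = dcs[local_maxima(vals, floor_fraction=0.3)]
        assert any(abs(p - 0.25) < 0.05 for p in peaks)
        assert any(abs(p - 0.90) < 0.05 for p in peaks)

    def test_zero_field_gives_zero_dc_transect(self):
        field = gaussian_bump_field(5, 5)
        zero = PreferenceField(
            pulse_axis=field.pulse_axis,
            pause_axis=field.pause_axis,
            values=np.zeros_like(field.values),
            resolution=field.resolution,
        )
        _, vals = dc_transect(zero, 17.2)
        assert np.all(vals == 0.0)

    def test_transects_agree_where_query_lines_intersect(self):
        field = gaussian_bump_field(6.0, 4.0, sd=2.0)
        dc, period = 0.6, 10.0  # intersection at (6, 4)
        periods, pv = period_transect(field, dc)
        dcs, dv = dc_transect(field, period)
        v1 = pv[np.argmin(np.abs(periods - period))]
        v2 = dv[np.argmin(np.abs(dcs - dc))]
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_non_negative_fields_give_non_negative_transects(self):
        field = gaussian_bump_field(3.0, 9.0)
        assert np.all(period_transect(field, 0.33)[1] >= 0)
        assert np.all(dc_transect(field, 12.0)[1] >= 0)

    def test_out_of_range_arguments_raise(self):
        field = gaussian_bump_field(5, 5)
        with pytest.raises(ValueError):
            period_transect(field, 1.5)
        with pytest.raises(ValueError):
            dc_transect(field, 100.0)


class TestPeakSignificance:
    def test_identical_scores_give_half(self):
        assert peak_significance([0.5, 0.6, 0.7], [0.5, 0.6, 0.7]) == 0.5

    def test_uniform_positive_shift_degenerates_to_zero(self):
        with pytest.warns(RuntimeWarning):
            p = peak_significance([1.3, 1.1, 1.2], [0.3, 0.1, 0.2])
        assert p == 0.0

    def test_hand_computed_paired_t(self):
        # differences {0.3, 0.1, 0.2, 0.4}: t = 0.25 / (0.1291 / 2) = 3.873, 3 df
        peak = [0.8, 0.6, 0.7, 0.9]
        ref = [0.5, 0.5, 0.5, 0.5]
        assert peak_significance(peak, ref) == pytest.approx(0.015233, abs=1e-5)

    def test_errors_on_bad_input(self):
        with pytest.raises(ValueError):
            peak_significance([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            peak_significance([1.0], [0.5])


class TestIO:
    def test_phonotaxis_table_round_trip(self, tmp_path):
        records = [
            rec(5.0, 3.5, 0.55, 2, per_female=(0.5, 0.6)),
            rec(8.0, 8.0, 0.2, 3, per_female=(0.1, 0.2, 0.3)),
        ]
        path = tmp_path / "table.csv"
        write_phonotaxis_table(records, path)
        back = read_phonotaxis_table(path)
        assert len(back) == 2
        assert back[0].per_female_scores == pytest.approx((0.5, 0.6))
        assert back[1].score == pytest.approx(0.2)
        assert back[1].n_females == 3

    def test_field_round_trip(self, tmp_path):
        field = gaussian_bump_field(4.0, 6.0, resolution=1.0, extent=10.0)
        path = tmp_path / "field.csv"
        write_field(field, path)
        back = read_field(path)
        assert back.resolution == field.resolution
        np.testing.assert_allclose(back.values, field.values, atol=1e-12)
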