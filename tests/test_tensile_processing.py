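"""Force-displacement -> stress-stretch conversion, preload referencing,
resampling and averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tracheamech import (
    ForceDisplacementRecord,
    HyperelasticParams,
    SpecimenGeometry,
    StressStretchCurve,
    average_curves,
    cauchy_stress,
    cauchy_stress_from_force,
    preload_reference,
    record_to_curve,
    resample_to_grid,
    stretch_from_displacement,
    uniform_grid,
)
from tracheamech.tensile_processing import (
    read_record_csv,
    write_curve_csv,
    write_record_csv,
)


def make_record(displacement, force, L0=1.0, A0=1.0, tissue="cartilage"):
    return ForceDisplacementRecord(
        specimen_id="sp1",
        subject_id="s1",
        tissue=tissue,
        displacement=np.asarray(displacement, float),
        force=np.asarray(force, float),
        geometry=SpecimenGeometry(L0=L0, A0=A0),
    )


def model_record(params, L0=1.0, A0=1.0, lambda_max=1.5, tissue="smooth_muscle",
                 preload=0.1, step=0.01):
    """Noiseless record built by inverting the stress equations."""
    grid = uniform_grid(lambda_max, step)
    sig = np.asarray(cauchy_stress(params, grid))
    return make_record((grid - 1) * L0, sig * A0 / grid + preload,
                       L0=L0, A0=A0, tissue=tissue)


class TestPointwiseFormulas:
    @pytest.mark.parametrize(
        "dL, L0, lam", [(0.0, 5.0, 1.0), (1.0, 2.0, 1.5), (0.32, 1.60, 1.2)]
    )
    def test_stretch_from_displacement(self, dL, L0, lam):
        assert stretch_from_displacement(dL, L0) == pytest.approx(lam, rel=1e-12)

    def test_negative_displacement_rejected(self):
        with pytest.raises(ValueError):
            stretch_from_displacement(-0.1, 1.0)
        with pytest.raises(ValueError):
            stretch_from_displacement(0.1, 0.0)

    @pytest.mark.parametrize(
        "T, A0, lam, sig",
        [(0.0, 2.0, 1.3, 0.0), (1.0, 1.0, 1.5, 1.5), (2.0, 4.0, 1.2, 0.6)],
    )
    def test_cauchy_stress_from_force(self, T, A0, lam, sig):
        assert cauchy_stress_from_force(T, A0, lam) == pytest.approx(sig, rel=1e-12)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            cauchy_stress_from_force(1.0, 0.0, 1.2)

    @given(st.floats(0.1, 10.0), st.floats(0.0, 5.0))
    def test_stretch_always_at_least_one(self, L0, dL):
        assert stretch_from_displacement(dL, L0) >= 1.0


class TestPreloadReference:
    def test_by_hand_trace(self):
        rec = make_record([0.0, 0.1, 0.2, 0.5], [0.0, 0.05, 0.1, 0.4])
        out = preload_reference(rec, preload=0.1)
        np.testing.assert_allclose(out.displacement, [0.0, 0.3])
        np.testing.assert_allclose(out.force, [0.1, 0.4])

    def test_already_at_preload_unchanged(self):
        rec = make_record([0.0, 0.2, 0.4], [0.1, 0.3, 0.5])
        out = preload_reference(rec)
        np.testing.assert_allclose(out.displacement, rec.displacement)
        np.testing.assert_allclose(out.force, rec.force)

    def test_never_reaching_preload_rejected(self):
        rec = make_record([0.0, 0.1, 0.2], [0.0, 0.02, 0.05])
        with pytest.raises(ValueError, match="preload"):
            preload_reference(rec)


class TestRecordToCurve:
    def test_neo_hookean_roundtrip(self):
        p = HyperelasticParams("neo_hookean", (1.0,))
        curve = record_to_curve(model_record(p))
        grid = curve.stretch
        np.testing.assert_allclose(
            curve.stress, 2 * (grid**2 - 1 / grid), atol=1e-9
        )

    def test_zero_force_gives_zero_stress(self):
        rec = make_record([0.0, 0.1, 0.2], [0.1, 0.1, 0.1])
        curve = record_to_curve(rec)
        np.testing.assert_allclose(curve.stress, 0.0, atol=1e-12)

    def test_cartilage_slope_matches_tangent_scale(self, cartilage_curve):
        # published-coefficient cartilage record processes to a curve whose
        # linear slope sits near 21 MPa
        from tracheamech import linear_modulus

        p = HyperelasticParams("yeoh", (3.583, -2.534, 12.020))
        rec = model_record(p, L0=4.0, A0=5.0, lambda_max=1.2, tissue="cartilage")
        e, r2 = linear_modulus(record_to_curve(rec), lambda_max=1.2)
        assert e == pytest.approx(20.607, abs=0.05)
        assert r2 > 0.999

    def test_area_scaling_cancels(self):
        """Doubling A0 doubles forces but leaves the stress curve fixed."""
        p = HyperelasticParams("yeoh", (0.063, 0.394, -0.171))
        c1 = record_to_curve(model_record(p, A0=1.0))
        c2 = record_to_curve(model_record(p, A0=2.0))
        np.testing.assert_allclose(c1.stress, c2.stress, atol=1e-12)

    def test_jitter_samples_dropped(self):
        rec = make_record([0.0, 0.1, 0.1, 0.2, 0.15, 0.3],
                          [0.1, 0.2, 0.21, 0.3, 0.29, 0.4])
        curve = record_to_curve(rec)
        assert curve.stretch.size == 4  # two non-increasing samples gone
        assert np.all(np.diff(curve.stretch) > 0)


class TestResampleAndAverage:
    def test_resample_identity_on_own_grid(self, smooth_muscle_curve):
        out = resample_to_grid(smooth_muscle_curve, smooth_muscle_curve.stretch)
        np.testing.assert_allclose(out.stress, smooth_muscle_curve.stress)

    def test_resample_exact_on_lines(self):
        grid = uniform_grid(1.5)
        line = StressStretchCurve(
            stretch=grid, stress=10 * (grid - 1), tissue="connective"
        )
        new = np.array([1.0, 1.123, 1.377, 1.5])
        out = resample_to_grid(line, new)
        np.testing.assert_allclose(out.stress, 10 * (new - 1), atol=1e-12)

    def test_resample_refuses_extrapolation(self, cartilage_curve):
        with pytest.raises(ValueError):
            resample_to_grid(cartilage_curve, [1.0, 1.3])

    def test_average_of_two_lines(self):
        grid = uniform_grid(1.5)
        c1 = StressStretchCurve(stretch=grid, stress=2 * (grid - 1), tissue="connective")
        c2 = StressStretchCurve(stretch=grid, stress=4 * (grid - 1), tissue="connective")
        avg = average_curves([c1, c2], lambda_max=1.5)
        np.testing.assert_allclose(avg.stress, 3 * (grid - 1), atol=1e-12)
        np.testing.assert_allclose(
            avg.stress_sd, np.sqrt(2) * (grid - 1), atol=1e-12
        )
        assert avg.n_samples == 2

    def test_average_identical_curves_sd_zero(self, connective_curve):
        avg = average_curves([connective_curve, connective_curve])
        np.testing.assert_allclose(avg.stress, connective_curve.stress, atol=1e-12)
        np.testing.assert_allclose(avg.stress_sd, 0.0, atol=1e-12)

    def test_average_permutation_invariant(self, smooth_muscle_curve, connective_curve):
        grid = uniform_grid(1.5)
        curves = [
            StressStretchCurve(stretch=grid, stress=k * (grid - 1) ** 2,
                               tissue="connective")
            for k in (1.0, 2.5, 7.0)
        ]
        a = average_curves(curves)
        b = average_curves(curves[::-1])
        np.testing.assert_allclose(a.stress, b.stress)
        np.testing.assert_allclose(a.stress_sd, b.stress_sd)

    def test_single_curve_passthrough(self, cartilage_curve):
        avg = average_curves([cartilage_curve])
        assert avg.n_samples == 1
        np.testing.assert_allclose(avg.stress, cartilage_curve.stress)

    def test_short_curve_excluded(self, caplog):
        grid_long = uniform_grid(1.5)
        grid_short = uniform_grid(1.3)
        long = StressStretchCurve(stretch=grid_long, stress=grid_long - 1,
                                  tissue="connective")
        short = StressStretchCurve(stretch=grid_short, stress=5 * (grid_short - 1),
                                   tissue="connective")
        avg = average_curves([long, short], lambda_max=1.5)
        assert avg.n_samples == 1
        np.testing.assert_allclose(avg.stress, long.stress)

    def test_mixed_tissues_rejected(self, cartilage_curve, connective_curve):
        with pytest.raises(ValueError):
            average_curves([cartilage_curve, connective_curve], lambda_max=1.2)


class TestCsvInterchange:
    def test_record_roundtrip(self, tmp_path):
        p = HyperelasticParams("yeoh", (0.257, 0.483, -0.148))
        rec = model_record(p, L0=1.6, A0=3.0, tissue="connective")
        path = tmp_path / "rec.csv"
        write_record_csv(rec, path)
        back = read_record_csv(path, "sp1", "s1", "connective", rec.geometry)
        np.testing.assert_allclose(back.displacement, rec.displacement, rtol=1e-8)
        np.testing.assert_allclose(back.force, rec.force, rtol=1e-8)

    def test_curve_csv_columns(self, tmp_path, cartilage_curve):
        import pandas as pd

        path = tmp_path / "curve.csv"
        write_curve_csv(cartilage_curve, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["stretch", "stress_MPa"]
        np.testing.assert_allclose(df["stress_MPa"], cartilage_curve.stress,
                                   rtol=1e-8)
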