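"""Synthetic vitals generation: distributions, structure, determinism, I/O."""

import numpy as np
import pytest

from ewsso import synthetic_data as sd
from ewsso.errors import ConfigurationError, DatasetParseError
from ewsso.unit_conversion import AVPU_TO_GCS, fahrenheit_to_celsius

RR_SPEC = sd.VitalDistributionSpec(
    name="rr", unit="breaths/min", value_kind="continuous",
    median=18, q1=16, q3=20, range_min=4, range_max=45, precision=2,
)


class TestSigmaFromIqr:
    def test_standard_normal_quartiles(self):
        q = 0.6744897501960817
        assert sd.sigma_from_iqr(-q, q) == pytest.approx(1.0, abs=1e-12)

    def test_scale_identity(self):
        width = 1.3489795003921634
        assert sd.sigma_from_iqr(10.0, 10.0 + width) == pytest.approx(1.0, abs=1e-12)

    def test_respiratory_rate_example(self):
        assert sd.sigma_from_iqr(16, 20) == pytest.approx(4 / 1.3489795003921634, rel=1e-10)

    def test_degenerate_iqr_rejected(self):
        with pytest.raises(ValueError):
            sd.sigma_from_iqr(20, 16)


class TestTruncatedNormal:
    def test_empty_sample(self):
        assert sd.sample_truncated_normal(RR_SPEC, 0, seed=1).size == 0

    def test_truncation_bounds(self):
        spec = sd.VitalDistributionSpec(
            name="narrow", value_kind="continuous",
            median=18, q1=17.5, q3=18.5, range_min=17, range_max=19, precision=2,
        )
        x = sd.sample_truncated_normal(spec, 5000, seed=2)
        assert x.min() >= 17 and x.max() <= 19

    def test_seed_determinism(self):
        a = sd.sample_truncated_normal(RR_SPEC, 100, seed=7)
        b = sd.sample_truncated_normal(RR_SPEC, 100, seed=7)
        assert np.array_equal(a, b)

    def test_median_and_iqr_recovered_at_scale(self):
        x = sd.sample_truncated_normal(RR_SPEC, 100_000, seed=3)
        assert np.median(x) == pytest.approx(18, abs=0.2)
        assert np.percentile(x, 25) == pytest.approx(16, abs=0.3)
        assert np.percentile(x, 75) == pytest.approx(20, abs=0.3)

    def test_integer_kind_yields_whole_numbers(self):
        spec = sd.VitalDistributionSpec(
            name="hr", value_kind="integer",
            median=84, q1=72, q3=98, range_min=25, range_max=190,
        )
        x = sd.sample_truncated_normal(spec, 500, seed=4)
        assert x.dtype.kind == "i"

    def test_invalid_spec_ordering_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.VitalDistributionSpec(
                name="bad", value_kind="continuous",
                median=10, q1=12, q3=11, range_min=0, range_max=20,
            )


class TestAvpu:
    def test_degenerate_distribution(self):
        assert sd.generate_avpu({"A": 1.0}, 10, seed=1) == ["A"] * 10

    def test_frequencies_approach_probabilities(self):
        probs = {"A": 0.85, "V": 0.08, "P": 0.04, "U": 0.03}
        draws = sd.generate_avpu(probs, 100_000, seed=5)
        for cat, p in probs.items():
            assert draws.count(cat) / len(draws) == pytest.approx(p, abs=0.01)

    def test_seed_determinism(self):
        probs = {"A": 0.5, "V": 0.5}
        assert sd.generate_avpu(probs, 4, seed=9) == sd.generate_avpu(probs, 4, seed=9)

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_avpu({"A": 0.7, "V": 0.7}, 10, seed=1)


@pytest.fixture(scope="module")
def config():
    cfg = sd.load_config()
    cfg.n_patients = 200
    return cfg


class TestVitalsDataset:
    def test_row_count_and_columns(self, config):
        df = sd.generate_vitals_dataset(config, seed=1)
        assert len(df) == 200
        assert list(df.columns) == sd.VITALS_COLUMNS

    def test_zero_missing_rate_leaves_no_blanks(self, config):
        import dataclasses
        cfg = dataclasses.replace(config, missing_rate=0.0)
        df = sd.generate_vitals_dataset(cfg, seed=1)
        assert not df.isna().any().any()
        assert not df.map(lambda v: v is None).any().any()

    def test_gcs_is_pure_function_of_avpu(self, config):
        df = sd.generate_vitals_dataset(config, seed=2)
        both = df[[c is not None for c in df["avpu"]]]
        both = both[[g is not None for g in both["gcs"]]]
        assert all(AVPU_TO_GCS[a] == g for a, g in zip(both["avpu"], both["gcs"]))

    def test_temperature_units_and_range_containment(self, config):
        df = sd.generate_vitals_dataset(config, seed=3)
        spec = config.spec("body_temperature")
        seen_units = set()
        for t, unit in zip(df["body_temperature"], df["body_temperature_unit"]):
            if t is None:
                assert unit is None
                continue
            seen_units.add(unit)
            t_c = fahrenheit_to_celsius(t) if unit == "degF" else t
            # 0.1 degF recording precision allows a ~0.06 degC overshoot
            assert spec.range_min - 0.06 <= t_c <= spec.range_max + 0.06
        assert seen_units == {"degC", "degF"}

    def test_numeric_vitals_stay_in_extreme_range(self, config):
        df = sd.generate_vitals_dataset(config, seed=4)
        for name in ("respiratory_rate", "oxygen_saturation", "systolic_blood_pressure",
                     "heart_rate", "urine_output"):
            spec = config.spec(name)
            vals = [v for v in df[name] if v is not None]
            assert min(vals) >= spec.range_min and max(vals) <= spec.range_max


class TestDistractorDataset:
    def test_superset_with_distractor_columns(self, config):
        df = sd.generate_distractor_dataset(config, seed=1)
        assert len(df) == 200
        extras = [c for c in df.columns if c not in sd.VITALS_COLUMNS]
        assert len(extras) >= 6
        assert set(df.columns[: len(sd.VITALS_COLUMNS)]) == set(sd.VITALS_COLUMNS)

    def test_vitals_portion_identical_to_vitals_dataset(self, config):
        plain = sd.generate_vitals_dataset(config, seed=6)
        with_extras = sd.generate_distractor_dataset(config, seed=6)
        assert plain.equals(with_extras[sd.VITALS_COLUMNS])

    def test_empty_distractor_spec_matches_dataset_one(self, config):
        import dataclasses
        cfg = dataclasses.replace(config, distractors=[])
        assert list(sd.generate_distractor_dataset(cfg, seed=1).columns) == sd.VITALS_COLUMNS

    def test_name_collision_rejected(self, config):
        import dataclasses
        clash = sd.VitalDistributionSpec(
            name="heart_rate", value_kind="integer",
            median=84, q1=72, q3=98, range_min=25, range_max=190,
        )
        cfg = dataclasses.replace(config, distractors=[clash])
        with pytest.raises(ConfigurationError):
            sd.generate_distractor_dataset(cfg, seed=1)


class TestCsvIO:
    def test_round_trip(self, config, tmp_path):
        df = sd.generate_distractor_dataset(config, seed=8)
        path = tmp_path / "ds.csv"
        sd.write_dataset(df, path)
        assert sd.read_dataset(path, config).equals(df)

    def test_byte_identical_determinism(self, config, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        sd.write_dataset(sd.generate_vitals_dataset(config, seed=9), a)
        sd.write_dataset(sd.generate_vitals_dataset(config, seed=9), b)
        assert a.read_bytes() == b.read_bytes()

    def test_blank_cell_reads_as_missing(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "patient_id,body_temperature,body_temperature_unit,heart_rate\nP1,,,70\n"
        )
        df = sd.read_dataset(path)
        assert df.loc[0, "body_temperature"] is None
        assert df.loc[0, "heart_rate"] == 70

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("patient_id,heart_rate\nP1,70\nP2,fast\n")
        with pytest.raises(DatasetParseError, match="row 3"):
            sd.read_dataset(path)
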