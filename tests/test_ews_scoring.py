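"""Band lookup, minimum-data semantics and score computation."""

import pytest
import yaml

from ewsso.errors import DataError, RubricCoverageError
from ewsso.ews_scoring import (
    STATUS_SCORED,
    STATUS_UNAVAILABLE,
    band_score,
    check_minimum_data,
    compute_score,
    load_rubric,
)
from ewsso.semantic_store import MeasurementDatum, NONSCORE


def _iri(model, label):
    return model.term_by_label(label).iri


def _measure(model, label, value, unit=None):
    return MeasurementDatum("http://x/p", _iri(model, label), value, unit)


def _normal_news_row(model):
    """All seven NEWS inputs in their zero-point bands."""
    return [
        _measure(model, "respiratory rate measurement datum", 16),
        _measure(model, "oxygen saturation measurement datum", 98),
        _measure(model, "supplemental oxygen use measurement datum", "no"),
        _measure(model, "body temperature measurement datum", 37.0, "degC"),
        _measure(model, "systolic blood pressure measurement datum", 120),
        _measure(model, "heart rate measurement datum", 70),
        _measure(model, "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum", "A"),
    ]


class TestBandScore:
    @pytest.mark.parametrize(
        "score,datum,value,points",
        [
            ("NEWS", "respiratory rate measurement datum", 12, 0),
            ("NEWS", "respiratory rate measurement datum", 8, 3),
            ("NEWS", "oxygen saturation measurement datum", 92, 2),
            ("qSOFA", "systolic blood pressure measurement datum", 100, 1),
            ("qSOFA", "systolic blood pressure measurement datum", 101, 0),
            ("MEWS6", "urine output measurement datum", 0.0, 3),
            ("MEWS6", "urine output measurement datum", 0.4, 2),
            ("MEWS6", "urine output measurement datum", 0.5, 1),
        ],
    )
    def test_chart_lookups(self, model, rubrics, score, datum, value, points):
        assert band_score(rubrics[score], _iri(model, datum), value).points == points

    def test_categorical_lookup(self, model, rubrics):
        avpu = "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum"
        assert band_score(rubrics["NEWS"], _iri(model, avpu), "A").points == 0
        assert band_score(rubrics["MEWS6"], _iri(model, avpu), "P").points == 2

    def test_unknown_category_is_coverage_error(self, model, rubrics):
        avpu = "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum"
        with pytest.raises(RubricCoverageError):
            band_score(rubrics["NEWS"], _iri(model, avpu), "X")

    def test_overlapping_bands_rejected_at_load(self, model, tmp_path):
        bad = {
            "score": "BAD",
            "label": "national early warning score",
            "parameters": [{
                "datum": "heart rate measurement datum",
                "precision": 0,
                "domain": [0, 10],
                "bands": [[0, 5, 0], [5, 10, 1]],
            }],
        }
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(bad))
        with pytest.raises(RubricCoverageError, match="matches 2 bands"):
            load_rubric(path, model)

    def test_gap_in_bands_rejected_at_load(self, model, tmp_path):
        bad = {
            "score": "BAD",
            "label": "national early warning score",
            "parameters": [{
                "datum": "heart rate measurement datum",
                "precision": 0,
                "domain": [0, 10],
                "bands": [[0, 4, 0], [6, 10, 1]],
            }],
        }
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(bad))
        with pytest.raises(RubricCoverageError, match="matches 0 bands"):
            load_rubric(path, model)


class TestMinimumData:
    def test_full_set_satisfied(self, model, rubrics):
        required = rubrics["NEWS"].required()
        assert check_minimum_data(required, required) == (True, set())

    def test_missing_member_reported(self, model, rubrics):
        required = rubrics["NEWS"].required()
        spo2 = _iri(model, "oxygen saturation measurement datum")
        assert check_minimum_data(required - {spo2}, required) == (False, {spo2})

    def test_empty_requirement_vacuously_satisfied(self):
        assert check_minimum_data(set(), set()) == (True, set())


class TestComputeScore:
    def test_qsofa_all_criteria_met(self, model, rubrics):
        data = [
            _measure(model, "respiratory rate measurement datum", 22),
            _measure(model, "systolic blood pressure measurement datum", 100),
            _measure(model, "Glasgow coma scale measurement datum", 14),
        ]
        res = compute_score(rubrics["qSOFA"], data)
        assert (res.status, res.total) == (STATUS_SCORED, 3)

    def test_news_all_normal_scores_zero(self, model, rubrics):
        res = compute_score(rubrics["NEWS"], _normal_news_row(model))
        assert (res.status, res.total) == (STATUS_SCORED, 0)

    def test_missing_temperature_makes_news_unavailable(self, model, rubrics):
        temp = _iri(model, "body temperature measurement datum")
        data = [m for m in _normal_news_row(model) if m.datum_class_iri != temp]
        res = compute_score(rubrics["NEWS"], data)
        assert res.status == STATUS_UNAVAILABLE
        assert res.total is None
        assert res.missing_inputs == {temp}

    def test_fahrenheit_input_scores_like_celsius(self, model, rubrics):
        temp = _iri(model, "body temperature measurement datum")
        base = [m for m in _normal_news_row(model) if m.datum_class_iri != temp]
        in_f = compute_score(
            rubrics["NEWS"],
            base + [_measure(model, "body temperature measurement datum", 100.3, "degF")],
        )
        in_c = compute_score(
            rubrics["NEWS"],
            base + [_measure(model, "body temperature measurement datum", 37.9, "degC")],
        )
        assert in_f.total == in_c.total
        audit = next(
            c for c in in_f.components if c.datum_class_iri == temp
        ).conversion
        assert audit.conversion_applied
        assert audit.converted_value == pytest.approx((100.3 - 32) * 5 / 9, abs=1e-12)

    def test_avpu_fallback_derives_gcs_for_qsofa(self, model, rubrics):
        data = [
            _measure(model, "respiratory rate measurement datum", 16),
            _measure(model, "systolic blood pressure measurement datum", 120),
            _measure(model, "Alert, Voice, Pain, Unresponsiveness (AVPU) measurement datum", "V"),
        ]
        res = compute_score(rubrics["qSOFA"], data)
        assert (res.status, res.total) == (STATUS_SCORED, 1)  # GCS 12 < 15
        gcs = _iri(model, "Glasgow coma scale measurement datum")
        comp = next(c for c in res.components if c.datum_class_iri == gcs)
        assert comp.conversion.conversion_applied
        assert comp.converted_value == 12

    def test_distractor_measurements_are_ignored(self, model, rubrics):
        extra = MeasurementDatum("http://x/p", str(NONSCORE["Age"]), 60)
        with_extra = compute_score(rubrics["NEWS"], _normal_news_row(model) + [extra])
        without = compute_score(rubrics["NEWS"], _normal_news_row(model))
        assert with_extra.total == without.total == 0

    def test_duplicate_measurement_rejected(self, model, rubrics):
        data = _normal_news_row(model)
        with pytest.raises(DataError):
            compute_score(rubrics["NEWS"], data + [data[0]])

    def test_totals_stay_in_declared_ranges(self, model, rubrics):
        assert rubrics["NEWS"].max_total == 20
        assert rubrics["MEWS6"].max_total == 17
        assert rubrics["qSOFA"].max_total == 3
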