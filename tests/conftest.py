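import pytest

from dietexposome.occurrence import OccurrenceRecord

_COUNTER = {"i": 0}


def make_record(**overrides) -> OccurrenceRecord:
    """A valid quantified record with sensible defaults, overridable per test."""
    _COUNTER["i"] += 1
    base = dict(
        record_id=f"r{_COUNTER['i']:04d}",
        study_id="study-1",
        food="rice",
        cooking_state="unspecified",
        contaminant="cadmium",
        chem_class="heavy_metal",
        stat_type="mean",
        value=5.0,
        unit="ug/kg",
        basis="wet",
        n=10,
        censor="quantified",
        lod=None,
        loq=None,
        sample_flag="normal",
    )
    base.update(overrides)
    return OccurrenceRecord(**base)


@pytest.fixture
def record_factory():
    return make_record
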