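import pytest

from cescore import CountryYearRecord, SeverityLevel, default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


def representative_value(definition, level):
    """A raw value strictly inside the given level's cut-off interval."""
    a, b = definition.level_interval(level)
    return (a + b) / 2


def record_from_levels(config, levels, country="X", date="2015", pin=None, missing=()):
    """Build a record whose raw values classify to the given 8 levels.

    ``levels`` maps indicator name -> SeverityLevel (or a sequence in
    configuration order); names in ``missing`` are set to na instead.
    """
    if not hasattr(levels, "keys"):
        levels = dict(zip(config.names, levels))
    values = {
        name: None if name in missing else representative_value(config[name], levels[name])
        for name in config.names
    }
    return CountryYearRecord(
        country=country, assessment_date=date, values=values, people_in_need_millions=pin
    )


@pytest.fixture(scope="session")
def all_levels():
    return (SeverityLevel.LOW_MEDIUM, SeverityLevel.HIGH, SeverityLevel.EXTREME)
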