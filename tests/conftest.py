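import pytest

from otopanel import build_table_fixtures, load_builtin_panel


@pytest.fixture(scope="session")
def panel():
    return load_builtin_panel()


@pytest.fixture()
def cohort():
    # function-scoped: triage mutates per-variant classification state
    return build_table_fixtures()
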