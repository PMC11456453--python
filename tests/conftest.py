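import logging

import pytest

import fixture_transcripts as ft


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # warnings from missing-value policies are expected in many tests;
    # keep them out of the terminal but available through caplog
    logging.getLogger("speechmarker").setLevel(logging.ERROR)
    yield
    logging.getLogger("speechmarker").setLevel(logging.NOTSET)


@pytest.fixture
def fixture_a():
    return ft.FIXTURES["a"]()


@pytest.fixture(params=sorted(ft.FIXTURES), ids=sorted(ft.FIXTURES))
def any_fixture(request):
    return ft.FIXTURES[request.param]()
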