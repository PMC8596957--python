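import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def paper_batches():
    from fermbal.synthetic import make_paper_fixture

    return {b.spec.reactor_id: b for b in make_paper_fixture()}


@pytest.fixture
def paper_reports(paper_batches):
    from fermbal.stoich import balance_report

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            rid: balance_report(b.spec, b.panel, c_i=b.c_i)
            for rid, b in paper_batches.items()
        }
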