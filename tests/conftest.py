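import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def nursing_instrument():
    from delphiscore import default_instrument

    return default_instrument()


@pytest.fixture(scope="session")
def likert():
    from delphiscore import LIKERT_1_10

    return LIKERT_1_10


def ratings_vector(spec: dict[int, int]) -> list[int]:
    """Expand {rating: count} into a flat rating list."""
    out = []
    for rating, count in spec.items():
        out.extend([rating] * count)
    return out
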