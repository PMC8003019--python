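import pytest
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
def small_cohort():
    """Hand-built mixed cohort: outcomes consistent with n >= 1 for tumors."""
    from dtcfate import ColonizationRecord

    return [
        ColonizationRecord("m1", "outgrowth", 25, 1),
        ColonizationRecord("m2", "outgrowth", 18, 1),
        ColonizationRecord("m3", "outgrowth", 30, 1),
        ColonizationRecord("m4", "outgrowth", 12, 0),
        ColonizationRecord("m5", "indolence", 6, 0),
        ColonizationRecord("m6", "indolence", 9, 1),
        ColonizationRecord("m7", "indolence", 4, 0),
        ColonizationRecord("m8", "indolence", 7, 0),
    ]
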