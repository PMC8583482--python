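import pytest

from climstress import (
    PersonContext,
    PersonProfile,
    activity_profile,
    clothing_catalogue,
)


@pytest.fixture
def reference_person() -> PersonProfile:
    """1.80 m / 80 kg unacclimatised male, the sensitivity-analysis body."""
    return PersonProfile(age=35, height=180.0, weight=80.0, sex="male", acclimatised=False)


@pytest.fixture
def acclimatised_person() -> PersonProfile:
    return PersonProfile(age=35, height=180.0, weight=80.0, sex="male", acclimatised=True)


@pytest.fixture
def moderate_summer_context(reference_person) -> PersonContext:
    return PersonContext(
        person=reference_person,
        activity=activity_profile("moderate", reference_person),
        clothing=clothing_catalogue("summer"),
    )


@pytest.fixture
def low_casual_context(reference_person) -> PersonContext:
    return PersonContext(
        person=reference_person,
        activity=activity_profile("low", reference_person),
        clothing=clothing_catalogue("casual"),
    )
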