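import pytest

import oralsim as o


@pytest.fixture(scope="session")
def evidence():
    return o.load_evidence()


@pytest.fixture(scope="session")
def printed_coeffs():
    return o.CoefficientSet.printed()


@pytest.fixture(scope="session")
def derived_coeffs(evidence):
    return o.CoefficientSet.from_evidence(evidence)


@pytest.fixture(scope="session")
def cohort20k():
    return o.generate_cohort(20_000, seed=101)


@pytest.fixture(scope="session")
def scored20k(cohort20k, printed_coeffs):
    """(profiles, linear predictors, composite scores, decile labels)."""
    lp = o.linear_predictors(cohort20k.profiles, printed_coeffs)
    composite = o.composite_scores(lp)
    deciles = o.assign_deciles(composite)
    return cohort20k.profiles, lp, composite, deciles
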