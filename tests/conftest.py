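import hypothesis
import pytest

import modytree as mt

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the study-group sizes (77/88/99/92)."""
    return mt.simulate_cohort(mt.default_config(seed=1))


@pytest.fixture(scope="session")
def published():
    return mt.published_tree()


def _central(group, c_peptide, bmi, ag15, hscrp):
    return mt.PatientRecord(
        id=f"central-{group.value}",
        group=group,
        c_peptide=c_peptide,
        bmi=bmi,
        ag15=ag15,
        hscrp=hscrp,
    )


@pytest.fixture(scope="session")
def central_records():
    """One record per group at its central marker values (medians / means)."""
    return [
        _central(mt.Group.HNF1A, c_peptide=1.45, bmi=23.9, ag15=4.70, hscrp=0.51),
        _central(mt.Group.GCK, c_peptide=1.43, bmi=23.7, ag15=11.24, hscrp=0.76),
        _central(mt.Group.T1D, c_peptide=0.01, bmi=23.9, ag15=3.77, hscrp=0.75),
        _central(mt.Group.T2D, c_peptide=2.78, bmi=30.3, ag15=6.07, hscrp=1.33),
    ]
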