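import pytest

from crypticex import study
from crypticex.synthetic import LocusSpec, build_toy_locus


@pytest.fixture(scope="session")
def plus_locus():
    return build_toy_locus(LocusSpec(seed=1, strand="+"))


@pytest.fixture(scope="session")
def minus_locus():
    return build_toy_locus(LocusSpec(seed=1, strand="-"))


@pytest.fixture(scope="session")
def wgs_design():
    return study.wgs_cohort_design()


@pytest.fixture(scope="session")
def rna_design():
    return study.rna_cohort_design()


@pytest.fixture(scope="session")
def amp_design():
    return study.amplicon_cohort_design()
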