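import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from isoimpact.align import AlignParams
from isoimpact.pipeline import run_pipeline
from isoimpact.simulate import FixtureSpec, generate_locus, prkacb_template_fixture


@pytest.fixture(scope="session")
def align_params() -> AlignParams:
    return AlignParams()


@pytest.fixture(scope="session")
def template_bundle():
    return prkacb_template_fixture()


@pytest.fixture(scope="session")
def template_result(template_bundle):
    b = template_bundle
    return run_pipeline(
        b.locus,
        domains=b.domains,
        ptms=b.ptms,
        interactions=b.interactions,
        gene_sets=b.gene_sets,
        de_records=b.de_records,
    )


@pytest.fixture(scope="session")
def small_bundle():
    return generate_locus(FixtureSpec(seed=7, canonical_length=120, n_isoforms=3))
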