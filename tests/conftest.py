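import numpy as np
import pytest

from sepfun import io as catalog_io
from sepfun.loci import clump_loci, filter_suggestive
from sepfun.simulate import headline_preset
from sepfun.types import HaplotypePanel


@pytest.fixture(scope="session")
def locus_fixture():
    """(leads, eqtl_records, cytokine_records) from the packaged 39-locus table."""
    return catalog_io.load_locus_qtl_fixture()


@pytest.fixture(scope="session")
def fixture_loci():
    """The 39 fixture leads clumped into (singleton) independent loci."""
    variants = catalog_io.fixture_lead_gwas()
    return clump_loci(filter_suggestive(variants))


@pytest.fixture()
def small_panel():
    """A hand-built 6-haplotype, 4-variant phased panel.

    Columns: rsA and rsB form the classic D'=1 / r2=0.5 pair; rsC is an
    exact copy of rsA; rsD is uncorrelated with rsA (r = 0).
    """
    hap = np.array(
        [
            # rsA rsB rsC rsD
            [1, 1, 1, 1],
            [1, 1, 1, 0],
            [0, 1, 0, 1],
            [0, 0, 0, 0],
            [0, 0, 0, 1],
            [0, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return HaplotypePanel(
        ["rsA", "rsB", "rsC", "rsD"], [1000, 2000, 3000, 4000], "chr1", hap
    )


@pytest.fixture(scope="session")
def preset_study(tmp_path_factory):
    """One shared headline synthetic study (generation is cheap but reused a lot)."""
    out = tmp_path_factory.mktemp("preset")
    return headline_preset(17, out)
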