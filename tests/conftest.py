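import logging
import random

import pytest

import silylib as s
from silylib.synth import synthetic_inchikey

# matchms logs a warning per record for EI spectra without precursor ions
logging.getLogger("matchms").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def registry_bundle():
    """(compounds, TMS derivatives, TBDMS derivatives) from the packaged tables."""
    return s.build_test_registry()


@pytest.fixture(scope="session")
def fixture_library(registry_bundle):
    """A deterministic 10-record library with real registry metadata.

    Peaks are synthetic (the generator's controlled shapes); names, formulas
    and masses come from the packaged TMS derivative records, including the
    Greek-letter and prime-character names that exercise text encoding.
    """
    _, tms, _ = registry_bundle
    rng = random.Random(99)
    records = []
    picks = [d for d in tms if d.parent.iupac_name in (
        "benzoic acid", "estriol", "17β-estradiol", "trans-3′-hydroxycotinine",
        "salicylic acid", "L-serine", "meso-erythritol", "urea",
        "Δ9-tetrahydrocannabinol", "sulfanilamide")]
    for d in picks[:10]:
        sp = s.generate_passing_spectrum("TMS", round(d.derivative_mw), rng,
                                         n_groups=d.n_groups)
        sp.name = f"{d.parent.iupac_name} {d.n_groups}TMS"
        sp.inchikey = synthetic_inchikey(sp.name)
        sp.formula = d.derivative_formula
        sp.mw = float(round(d.derivative_mw))
        sp.exact_mass = d.derivative_exact_mass
        records.append(sp)
    assert len(records) == 10
    return s.LibraryFile(format="MSP", records=records, source_path="<fixture>")


@pytest.fixture()
def default_config():
    return s.FilterConfig()


@pytest.fixture()
def rng():
    return random.Random(1234)
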