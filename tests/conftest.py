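import numpy as np
import pytest

import plf


@pytest.fixture(scope="session")
def small_study():
    """A small single-region 3v3 study with one implanted suppression.

    SYNA carries a 4-fold aged suppression over residues 101-200; SYNB and
    SYNC are effect-free. Abundant proteins so the effect is detectable.
    """
    rng = np.random.default_rng(42)
    proteome = plf.random_proteome(3, rng, (300, 500))
    proteome = [
        plf.ProteinEntry(accession=name, sequence=p.sequence)
        for name, p in zip(("SYNA", "SYNB", "SYNC"), proteome)
    ]
    spec = plf.SyntheticStudySpec(
        proteome=tuple(proteome),
        regions=("r1",),
        baseline_log_mean=float(np.log(2000.0)),
        baseline_log_sd=0.3,
        effects=(plf.Effect("SYNA", 101, 200, "aged", 0.25),),
        seed=43,
    )
    return plf.simulate_counts(spec)


@pytest.fixture(scope="session")
def three_region_study():
    """The bundled showcase scenario: shared, region-specific and
    abundance-only effects across three tissue regions (posterior 3v2)."""
    return plf.simulate_counts(plf.showcase_spec(seed=7, n_proteins=40))
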