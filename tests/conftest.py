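import pytest

from ujat import simulate


@pytest.fixture(scope="session")
def lpl_like_cohort():
    """A moderately sized cohort in the LPL-like default configuration.

    One causal locus, effect-allele frequency 0.429 on the ancestry-2
    background vs 0.689 on the ancestry-0 background, genotype effect
    +0.1 per allele, ancestry effect fully mediated by the genotype.
    """
    cfg = simulate.CohortConfig(n_individuals=4000, n_loci=1, seed=20_230_830)
    return simulate.simulate_admixed_cohort(cfg)
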