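import numpy as np
import pandas as pd
import pytest

from mitovar import (
    GeneAnnotation,
    MtReference,
    default_signature_rates,
    simulate_cohort,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_genome():
    """A 3 kb synthetic circular genome with protein/tRNA/rRNA/D-loop features."""
    return simulate_reference(3000, seed=7)


@pytest.fixture(scope="session")
def rates():
    return default_signature_rates()


@pytest.fixture(scope="session")
def cohort(small_genome, rates):
    ref, ann = small_genome
    return simulate_cohort(
        ref, ann, rates, n_samples=100, mutation_rate=3.0,
        vaf_model=("uniform", 0.05, 1.0), seed=11,
    )


@pytest.fixture()
def toy_gene_genome():
    """Hand-built genome whose single protein gene contains codons with
    known consequences: ATG TGG CGA CTA ... TAA."""
    coding = "ATG" + "TGG" + "CGA" + "CTA" + "GCC" + "TAA"
    pad = "AACCGGTTAACCGGTT"
    ref = MtReference(coding + pad, name="toy")
    ann = [GeneAnnotation(gene="G1", start=1, end=len(coding), feature="protein")]
    return ref, ann
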