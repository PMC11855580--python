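import numpy as np
import pytest

import pepperbsa as pb


@pytest.fixture(scope="session")
def default_dataset():
    """One default simulated study (seed 42), shared across tests."""
    pop, bulks, table = pb.simulate_dataset(seed=42)
    return pop, bulks, table


@pytest.fixture(scope="session")
def filtered_table(default_dataset):
    _, _, table = default_dataset
    return pb.filter_parental_informative(table)


@pytest.fixture()
def toy_table():
    """Five hand-built sites: 2 clean-informative, 1 het parent, 1 same
    allele in both parents, 1 low parental depth."""
    mk = pb.VariantSite
    sites = [
        mk("chr1", 100, "A", "G"),   # clean: P1=A, P2=G
        mk("chr1", 200, "C", "T"),   # clean: P1=C, P2=T
        mk("chr1", 300, "A", "G"),   # P1 heterozygous
        mk("chr1", 400, "A", "G"),   # both parents A
        mk("chr1", 500, "A", "G"),   # P2 depth below threshold
    ]
    d = pb.SampleDepths
    depths = [
        d({"A": 30}, {"G": 28}, {"A": 10, "G": 10}, {"A": 15, "G": 5}),
        d({"C": 25}, {"T": 30}, {"C": 12, "T": 8}, {"C": 9, "T": 11}),
        d({"A": 15, "G": 15}, {"G": 30}, {"A": 10, "G": 10}, {"A": 9, "G": 11}),
        d({"A": 30}, {"A": 28}, {"A": 20}, {"A": 20}),
        d({"A": 30}, {"G": 5}, {"A": 10, "G": 10}, {"A": 10, "G": 10}),
    ]
    return pb.VariantTable(sites, depths, {"chr1": 1000})


@pytest.fixture(scope="session")
def aprr2_like_cds():
    """Synthetic 587-codon CDS (586 aa + stop) with TGG at codon 476,
    mirroring a published premature-stop case: base 1428 is the third
    base of codon 476."""
    return pb.make_synthetic_cds(587, {476: "TGG"}, cds_id="APRR2like", seed=1)
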