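import numpy as np
import pytest

from its2vec import (
    EmbeddingParams,
    SequenceRecord,
    SyntheticConfig,
    TaxonomyLineage,
    build_corpus,
    generate_dataset,
    train_embedding,
)


def make_record(accession="A1", sh="SH001", genus="Gen", species="Gen_sp",
                sequence="ACGTACGTACGT"):
    return SequenceRecord(
        accession=accession,
        sh_code=sh,
        lineage=TaxonomyLineage(kingdom="Fungi", phylum="Ascomycota",
                                class_="X", order="Y", family="Z",
                                genus=genus, species=species),
        sequence=sequence,
    )


def random_sequence(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def tiny_records():
    """Small synthetic barcode set shared by read-only tests."""
    return generate_dataset(
        SyntheticConfig(n_species=8, seqs_per_species=4,
                        length_low=200, length_high=260,
                        substitution_rate_within=0.01, seed=11)
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_records):
    """A small trained embedding (k=6, dim=32) over the tiny record set."""
    corpus = build_corpus(tiny_records, 6)
    return train_embedding(
        corpus, EmbeddingParams(k=6, dim=32, epochs=3, window=4, seed=5)
    )
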