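import numpy as np
import pytest

from msaneff import Msa, MsaFormat, MsaRecord


def make_msa(rows, ids=None, fmt=MsaFormat.FASTA, query_index=0):
    ids = ids or [f"seq_{i + 1}" for i in range(len(rows))]
    return Msa(
        records=[MsaRecord(i, s) for i, s in zip(ids, rows)],
        source_format=fmt,
        query_index=query_index,
    )


def random_rows(
    rng: np.random.Generator,
    n_rows: int,
    n_cols: int,
    alphabet: str = "protein",
    gap_rate: float = 0.15,
    non_standard_rate: float = 0.05,
    lowercase_rate: float = 0.1,
):
    """Random aligned rows exercising gaps, non-standard letters and case.

    Row 0 (the query) is kept gap-free so query-gap removal never empties
    the alignment.
    """
    standard = {"protein": "ACDEFGHIKLMNPQRSTVWY", "dna": "ACGT", "rna": "ACGU"}[alphabet]
    non_standard = {"protein": "BJOUXZ", "dna": "NRYSWKMBDHVX", "rna": "NRYSWKMBDHVX"}[alphabet]
    rows = []
    for r in range(n_rows):
        chars = []
        for _ in range(n_cols):
            u = rng.random()
            if r > 0 and u < gap_rate:
                chars.append("-" if rng.random() < 0.5 else ".")
            elif u < gap_rate + non_standard_rate:
                chars.append(non_standard[rng.integers(len(non_standard))])
            else:
                ch = standard[rng.integers(len(standard))]
                if rng.random() < lowercase_rate:
                    ch = ch.lower()
                chars.append(ch)
        rows.append("".join(chars))
    return rows


@pytest.fixture
def worked_msa():
    """The 4-row example with pair identities {q,s1}=.8 {q,s2}=.6 {q,s3}=1."""
    return make_msa(
        ["ACDEF", "ACDEG", "ACDGG", "ACDEF"], ids=["q", "s1", "s2", "s3"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
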