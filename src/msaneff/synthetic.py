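"""Deterministic synthetic MSA generator for testing and demonstration.

Alignments are built from a root sequence: cluster centers are heavily
mutated copies of the root, and rows are lightly mutated copies of their
center, with optional per-cell gaps.  Within-cluster identity therefore
stays high (≈ 1 − mutation_rate per column) while between-cluster identity
sits near the heavy-mutation level, so with a small mutation rate and the
usual θ = 0.8 threshold the unnormalized NEFF lands close to the number of
clusters.  The query (row 0) is the first cluster's center, kept gap-free so
query-gap removal is a no-op unless gaps are injected deliberately.

Randomness comes from numpy's ``default_rng`` (PCG64), which is explicitly
specified and portable: the same seed yields the same alignment on any
platform.  No phylogenetic realism is attempted — there is no tree, no
indel model, and no position heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabets import Alphabet
from .io import Msa, MsaFormat, MsaRecord
from .multimer import MultimerSpec

#: Divergence applied when deriving cluster centers from the root; far below
#: the 0.8 identity threshold so clusters do not bleed into each other.
CENTER_DIVERGENCE = 0.5


@dataclass
class FixtureSpec:
    """Parameters of one synthetic alignment; output is a pure function of these."""

    n_rows: int
    n_cols: int
    alphabet: Alphabet = field(default_factory=Alphabet.protein)
    mutation_rate: float = 0.1
    gap_rate: float = 0.0
    n_clusters: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.alphabet, str):
            self.alphabet = Alphabet.from_name(self.alphabet)
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be positive")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > self.n_rows:
            raise ValueError(
                f"cannot place {self.n_clusters} clusters in {self.n_rows} rows"
            )
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must be in [0, 1)")


def _mutate(seq: np.ndarray, rate: float, k: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability `rate`, uniformly over the
    other k-1 symbols."""
    out = seq.copy()
    mask = rng.random(seq.shape[0]) < rate
    n = int(mask.sum())
    if n:
        # shift by 1..k-1 modulo k: never the original symbol
        out[mask] = (out[mask] + rng.integers(1, k, size=n)) % k
    return out


def _to_string(codes: np.ndarray, symbols: str, gaps: np.ndarray | None = None) -> str:
    chars = np.array(list(symbols))[codes]
    if gaps is not None:
        chars = np.where(gaps, "-", chars)
    return "".join(chars)


def generate_msa(spec: FixtureSpec) -> Msa:
    """Generate a clustered synthetic alignment.

    Row 0 is the gap-free query (= center of cluster 1); remaining rows are
    assigned to clusters round-robin, mutated from their center at
    ``mutation_rate`` and gapped at ``gap_rate`` per cell.
    """
    rng = np.random.default_rng(spec.seed)
    symbols = spec.alphabet.standard_symbols
    k = len(symbols)
    root = rng.integers(0, k, size=spec.n_cols)

    centers = [root]
    for _ in range(spec.n_clusters - 1):
        centers.append(_mutate(root, CENTER_DIVERGENCE, k, rng))

    records = [MsaRecord("seq_1", _to_string(centers[0], symbols), "query")]
    for r in range(1, spec.n_rows):
        cluster = (r - 1) % spec.n_clusters
        row = _mutate(centers[cluster], spec.mutation_rate, k, rng)
        gaps = rng.random(spec.n_cols) < spec.gap_rate if spec.gap_rate else None
        records.append(
            MsaRecord(f"seq_{r + 1}", _to_string(row, symbols, gaps),
                      f"cluster_{cluster + 1}")
        )
    return Msa(records=records, source_format=MsaFormat.FASTA)


def generate_multimer_msa(
    spec: FixtureSpec,
    chain_lengths: list[int],
    paired_fraction: float,
) -> tuple[Msa, MultimerSpec]:
    """Generate a concatenated multimer alignment with known row classes.

    The query spans every chain gap-free.  Exactly
    ``round(paired_fraction * (n_rows - 1))`` non-query rows carry residues
    in all chains; the rest carry residues in exactly one chain (cycled) and
    gaps elsewhere.  Every intended residue-bearing segment is guaranteed at
    least one residue, so classification counts match the construction
    exactly.  ``spec.n_cols`` is ignored in favour of ``sum(chain_lengths)``.
    """
    if not 0 <= paired_fraction <= 1:
        raise ValueError("paired_fraction must be in [0, 1]")
    if not chain_lengths or any(n < 1 for n in chain_lengths):
        raise ValueError("chain_lengths must be positive")
    rng = np.random.default_rng(spec.seed)
    symbols = spec.alphabet.standard_symbols
    k = len(symbols)
    n_chains = len(chain_lengths)
    roots = [rng.integers(0, k, size=n) for n in chain_lengths]

    def chain_segment(c: int, gapped: bool) -> str:
        row = _mutate(roots[c], spec.mutation_rate, k, rng)
        if gapped and spec.gap_rate:
            gaps = rng.random(chain_lengths[c]) < spec.gap_rate
            if gaps.all():
                gaps[0] = False  # keep the segment residue-bearing
            return _to_string(row, symbols, gaps)
        return _to_string(row, symbols)

    records = [
        MsaRecord("seq_1", "".join(_to_string(r, symbols) for r in roots), "query")
    ]
    n_paired = round(paired_fraction * (spec.n_rows - 1))
    for r in range(1, spec.n_rows):
        if r <= n_paired:
            seq = "".join(chain_segment(c, gapped=True) for c in range(n_chains))
            desc = "paired"
        else:
            home = (r - n_paired - 1) % n_chains
            parts = [
                chain_segment(c, gapped=True) if c == home else "-" * chain_lengths[c]
                for c in range(n_chains)
            ]
            seq = "".join(parts)
            desc = f"unpaired_chain_{home + 1}"
        records.append(MsaRecord(f"seq_{r + 1}", seq, desc))

    msa = Msa(records=records, source_format=MsaFormat.FASTA)
    return msa, MultimerSpec(chain_lengths=list(chain_lengths))
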