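"""The NEFF statistic: sequence weights, preprocessing, normalization.

The number of effective sequences of an alignment M with N rows is

    NEFF(M) = f * sum_n 1 / (1 + #{m != n : S(m,n) >= theta})

i.e. each sequence gets weight 1/n_i where n_i counts the sequences
(including itself) whose similarity to it reaches the threshold theta
(typically 0.8), and f is a normalization factor: 1/L with L the
post-preprocessing column count (the query length under default query-gap
removal), 1/sqrt(L), or 1.

Similarity comes in two flavours:

* symmetric — fraction of columns with identical codes over the common
  alignment length; gap aligned to gap counts as a match, so S(i,j)=S(j,i);
* asymmetric — directional: S(m→n) is the number of columns where the codes
  match and row n holds a residue, divided by row n's non-gap length.  The
  weight of row n then counts rows m with S(m→n) >= theta.

Similarity numerators are exact integer counts; the only floating-point
step is the final division, so the vectorized implementation agrees bit-for-
bit with a naive double loop.

Preprocessing runs in a fixed order: depth cap (first ``depth`` rows, query
always retained), query-gap column removal (on by default), then gappy-column
removal (columns whose gap fraction strictly exceeds ``gap_cutoff``; the
default cutoff of 1.0 disables it since a fraction cannot exceed 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alphabets import (
    Alphabet,
    EncodedMsa,
    NonStandardPolicy,
    encode_msa,
)
from .errors import EmptyAlignmentError, OptionError
from .io import Msa, MsaFormat, resolve_insertions

logger = logging.getLogger("msaneff")

NORM_MODES = ("none", "by_length", "by_sqrt_length")
_NORM_ALIASES = {
    "length": "by_length",
    "sqrt": "by_sqrt_length",
    "sqrt_length": "by_sqrt_length",
}


def _coerce_norm(value: str) -> str:
    key = str(value).lower()
    key = _NORM_ALIASES.get(key, key)
    if key not in NORM_MODES:
        raise OptionError(
            f"unknown normalization {value!r}; expected one of {NORM_MODES}"
        )
    return key


@dataclass
class NeffOptions:
    """All tunable knobs of the NEFF computation.

    theta            similarity threshold in (0, 1]; comparison is inclusive.
    symmetric        symmetric vs directional (asymmetric) similarity.
    norm             "by_length" (1/L), "by_sqrt_length", or "none".
    gap_cutoff       drop columns whose gap fraction exceeds this; 1.0 = off.
    keep_query_gaps  keep columns where the query holds a gap.
    non_standard     how non-standard residues encode (own code vs gap).
    depth            optional cap on the number of rows considered.
    alphabet         protein (default), dna, or rna.
    """

    theta: float = 0.8
    symmetric: bool = True
    norm: str = "by_length"
    gap_cutoff: float = 1.0
    keep_query_gaps: bool = False
    non_standard: NonStandardPolicy = NonStandardPolicy.AS_STANDARD
    depth: Optional[int] = None
    alphabet: Alphabet = field(default_factory=Alphabet.protein)

    def __post_init__(self) -> None:
        self.norm = _coerce_norm(self.norm)
        self.non_standard = NonStandardPolicy.coerce(self.non_standard)
        if isinstance(self.alphabet, str):
            self.alphabet = Alphabet.from_name(self.alphabet)
        if not 0 < self.theta <= 1:
            raise OptionError(f"theta must be in (0, 1], got {self.theta}")
        if not 0 < self.gap_cutoff <= 1:
            raise OptionError(f"gap_cutoff must be in (0, 1], got {self.gap_cutoff}")
        if self.depth is not None and self.depth < 1:
            raise OptionError(f"depth must be >= 1, got {self.depth}")

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "symmetric": self.symmetric,
            "norm": self.norm,
            "gap_cutoff": self.gap_cutoff,
            "keep_query_gaps": self.keep_query_gaps,
            "non_standard": self.non_standard.value,
            "depth": self.depth,
            "alphabet": self.alphabet.name,
        }


@dataclass
class NeffResult:
    """Outcome of one NEFF computation.

    ``weights[i] = 1/n_i``; ``raw_sum`` is their sum (1 <= raw_sum <= N);
    ``neff = raw_sum * f`` for the chosen normalization.  ``columns_removed``
    is (query-gap columns, gappy columns).
    """

    neff: float
    raw_sum: float
    weights: np.ndarray
    n_rows: int
    n_cols: int
    options_used: NeffOptions
    columns_removed: tuple[int, int] = (0, 0)

    def to_dict(self) -> dict:
        return {
            "neff": self.neff,
            "raw_sum": self.raw_sum,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "columns_removed": {
                "query_gap": self.columns_removed[0],
                "gappy": self.columns_removed[1],
            },
            "options": self.options_used.to_dict(),
        }


def preprocess(encoded: EncodedMsa, options: NeffOptions) -> EncodedMsa:
    """Apply depth cap, query-gap removal and gappy-column removal, in order.

    The query row (``encoded.query_row``) is always retained by the depth
    cap.  ``column_map`` tracks surviving columns back to the original
    alignment; ``columns_removed`` records how many columns each stage took.
    """
    matrix = encoded.matrix
    gap = encoded.gap_code
    query_row = encoded.query_row
    if query_row >= matrix.shape[0]:
        raise OptionError("query row index out of range")

    if options.depth is not None:
        depth = options.depth
        if query_row < depth:
            rows = np.arange(min(depth, matrix.shape[0]))
            new_query = query_row
        else:
            rows = np.concatenate([np.arange(depth - 1), [query_row]])
            new_query = depth - 1
        matrix = matrix[rows]
        query_row = new_query

    col_mask = np.ones(matrix.shape[1], dtype=bool)
    n_query_gap = 0
    if not options.keep_query_gaps:
        query_gaps = matrix[query_row] == gap
        n_query_gap = int(query_gaps.sum())
        col_mask &= ~query_gaps

    n_gappy = 0
    if options.gap_cutoff < 1.0:
        gap_frac = (matrix == gap).mean(axis=0)
        gappy = (gap_frac > options.gap_cutoff) & col_mask
        n_gappy = int(gappy.sum())
        col_mask &= ~gappy

    if not col_mask.any():
        raise EmptyAlignmentError(
            "preprocessing removed every column of the alignment"
        )

    column_map = [encoded.column_map[j] for j in np.nonzero(col_mask)[0]]
    return EncodedMsa(
        matrix=np.ascontiguousarray(matrix[:, col_mask]),
        gap_code=gap,
        symbol_map=dict(encoded.symbol_map),
        column_map=column_map,
        query_row=query_row,
        columns_removed=(n_query_gap, n_gappy),
    )


def pairwise_similarity(
    encoded: EncodedMsa, i: int, j: int, symmetric: bool = True
):
    """Similarity between rows i and j.

    Symmetric mode returns one number: matching columns (gap-gap included)
    over the common length.  Asymmetric mode returns the ordered pair
    (S(i→j), S(j→i)); a row with no residues has similarity 0 into it.
    """
    a, b = encoded.matrix[i], encoded.matrix[j]
    if symmetric:
        return float(np.count_nonzero(a == b)) / a.shape[0]
    gap = encoded.gap_code
    eq_nongap = (a == b) & (b != gap)
    num = int(np.count_nonzero(eq_nongap))
    len_j = int(np.count_nonzero(b != gap))
    len_i = int(np.count_nonzero(a != gap))
    num_ji = int(np.count_nonzero((a == b) & (a != gap)))
    s_into_j = num / len_j if len_j else 0.0
    s_into_i = num_ji / len_i if len_i else 0.0
    if len_i == 0 or len_j == 0:
        logger.warning("row with no residues encountered in asymmetric similarity")
    return (s_into_j, s_into_i)


def _equal_count_matrix(matrix: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """C[i, j] = number of columns where rows i and j share a code in `codes`.

    Built as a sum of indicator-matrix products, one per symbol code; each
    product contributes exact small integers, so C is exact in float64.
    """
    n = matrix.shape[0]
    counts = np.zeros((n, n), dtype=np.float64)
    for code in codes:
        ind = (matrix == code).astype(np.float64)
        counts += ind @ ind.T
    return counts


def sequence_weights(
    encoded: EncodedMsa, theta: float = 0.8, symmetric: bool = True
) -> np.ndarray:
    """Per-row weights 1/n_i under the theta-neighbour count.

    Vectorized over symbol-indicator matrix products; similarity values are
    the same exact-count ratios a naive double loop computes, so results
    agree exactly with the O(N^2 L) reference.
    """
    matrix = encoded.matrix
    gap = encoded.gap_code
    n_rows, n_cols = matrix.shape
    codes = np.unique(matrix)

    if symmetric:
        counts = _equal_count_matrix(matrix, codes)
        sims = counts / n_cols
        # diagonal is always 1 >= theta (theta <= 1): subtract self-match
        neighbours = (sims >= theta).sum(axis=1) - 1
    else:
        nongap_codes = codes[codes != gap]
        counts = _equal_count_matrix(matrix, nongap_codes)
        nongap_len = np.count_nonzero(matrix != gap, axis=1)
        empty = nongap_len == 0
        if empty.any():
            logger.warning(
                "%d row(s) contain no residues; asymmetric similarity into "
                "them is 0", int(empty.sum()),
            )
        denom = np.where(empty, 1, nongap_len)
        sims = counts / denom[np.newaxis, :]
        sims[:, empty] = 0.0
        hits = (sims >= theta).sum(axis=0)
        self_hit = (np.diagonal(sims) >= theta).astype(np.int64)
        neighbours = hits - self_hit
    return 1.0 / (1.0 + neighbours.astype(np.float64))


def _norm_factor(norm: str, n_cols: int) -> float:
    if norm == "by_length":
        return 1.0 / n_cols
    if norm == "by_sqrt_length":
        return 1.0 / np.sqrt(n_cols)
    return 1.0


def _prepare(msa: Msa, options: NeffOptions) -> EncodedMsa:
    if msa.source_format in (MsaFormat.A2M, MsaFormat.A3M):
        msa = resolve_insertions(msa, "remove")
    encoded = encode_msa(msa, options.alphabet, options.non_standard)
    return preprocess(encoded, options)


def compute_neff(msa: Msa, options: NeffOptions | None = None) -> NeffResult:
    """Full pipeline: encode → preprocess → weights → normalized NEFF.

    A2M/A3M inputs are first reduced to their match columns.  The
    normalization length L is the post-preprocessing column count, which
    under default query-gap removal equals the query's residue count.
    """
    options = options or NeffOptions()
    encoded = _prepare(msa, options)
    weights = sequence_weights(encoded, options.theta, options.symmetric)
    raw_sum = float(weights.sum())
    neff = raw_sum * _norm_factor(options.norm, encoded.n_cols)
    return NeffResult(
        neff=neff,
        raw_sum=raw_sum,
        weights=weights,
        n_rows=encoded.n_rows,
        n_cols=encoded.n_cols,
        options_used=options,
        columns_removed=encoded.columns_removed,
    )


@dataclass
class PerResidueNeff:
    """Column-wise NEFF: per column, the summed weights of rows holding a residue.

    ``columns`` gives each value's 0-based column in the *original*
    alignment (identity unless preprocessing removed columns).  Values are
    unnormalized by default; ``sequence_result`` carries the global weights
    they were built from.
    """

    values: np.ndarray
    columns: list[int]
    sequence_result: NeffResult

    def to_dict(self) -> dict:
        return {
            "per_residue_neff": [float(v) for v in self.values],
            "columns": list(self.columns),
            **self.sequence_result.to_dict(),
        }


def per_residue_neff(
    msa: Msa, options: NeffOptions | None = None, normalize: bool = False
) -> PerResidueNeff:
    """Per-column NEFF from the global sequence weights (computed once)."""
    options = options or NeffOptions()
    encoded = _prepare(msa, options)
    weights = sequence_weights(encoded, options.theta, options.symmetric)
    residue_mask = encoded.matrix != encoded.gap_code
    values = residue_mask.T.astype(np.float64) @ weights
    if normalize:
        values = values * _norm_factor(options.norm, encoded.n_cols)
    raw_sum = float(weights.sum())
    result = NeffResult(
        neff=raw_sum * _norm_factor(options.norm, encoded.n_cols),
        raw_sum=raw_sum,
        weights=weights,
        n_rows=encoded.n_rows,
        n_cols=encoded.n_cols,
        options_used=options,
        columns_removed=encoded.columns_removed,
    )
    return PerResidueNeff(values=values, columns=list(encoded.column_map), sequence_result=result)
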