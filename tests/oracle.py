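"""Literal reference implementation of NEFF, kept deliberately naive.

Pure-Python double loops over character strings, independent of the
package's encoded-matrix path.  Used by tests as the ground truth the
vectorized implementation must match exactly.
"""

from __future__ import annotations

GAPS = "-."

# Independent copies of the permitted character sets.
PROTEIN_NON_STANDARD = set("BJOUXZ")
NUC_NON_STANDARD = set("NRYSWKMBDHVX")
NON_STANDARD = {
    "protein": PROTEIN_NON_STANDARD,
    "dna": NUC_NON_STANDARD,
    "rna": NUC_NON_STANDARD,
}


def normalize_rows(rows, alphabet="protein", non_standard_as_gap=False):
    """Uppercase, map '.' to '-', optionally map non-standard residues to '-'."""
    ns = NON_STANDARD[alphabet]
    out = []
    for row in rows:
        chars = []
        for ch in row.upper():
            if ch in GAPS:
                chars.append("-")
            elif non_standard_as_gap and ch in ns:
                chars.append("-")
            else:
                chars.append(ch)
        out.append("".join(chars))
    return out


def preprocess_rows(rows, query=0, depth=None, keep_query_gaps=False, gap_cutoff=1.0):
    """Depth cap, query-gap column removal, gappy-column removal, in order."""
    if depth is not None:
        if query < depth:
            idx = list(range(min(depth, len(rows))))
            new_query = query
        else:
            idx = list(range(depth - 1)) + [query]
            new_query = depth - 1
        rows = [rows[i] for i in idx]
        query = new_query
    length = len(rows[0])
    keep = [True] * length
    if not keep_query_gaps:
        for c in range(length):
            if rows[query][c] == "-":
                keep[c] = False
    if gap_cutoff < 1.0:
        for c in range(length):
            if keep[c]:
                frac = sum(1 for r in rows if r[c] == "-") / len(rows)
                if frac > gap_cutoff:
                    keep[c] = False
    if not any(keep):
        raise ValueError("empty: preprocessing removed every column")
    rows = ["".join(r[c] for c in range(length) if keep[c]) for r in rows]
    return rows, query


def pair_similarity(a, b, symmetric=True):
    length = len(a)
    if symmetric:
        return sum(1 for c in range(length) if a[c] == b[c]) / length
    den = sum(1 for c in range(length) if b[c] != "-")
    if den == 0:
        return 0.0
    num = sum(1 for c in range(length) if b[c] != "-" and a[c] == b[c])
    return num / den


def weights(rows, theta=0.8, symmetric=True):
    """w_n = 1 / (1 + #{m != n : S(m, n) >= theta}); asymmetric uses S(m->n)."""
    out = []
    for n in range(len(rows)):
        count = 1
        for m in range(len(rows)):
            if m == n:
                continue
            if pair_similarity(rows[m], rows[n], symmetric) >= theta:
                count += 1
        out.append(1.0 / count)
    return out


def neff(
    rows,
    theta=0.8,
    symmetric=True,
    norm="by_length",
    alphabet="protein",
    non_standard_as_gap=False,
    query=0,
    depth=None,
    keep_query_gaps=False,
    gap_cutoff=1.0,
):
    """Full naive pipeline; returns (neff, raw_sum, weights, n_cols)."""
    rows = normalize_rows(rows, alphabet, non_standard_as_gap)
    rows, _ = preprocess_rows(rows, query, depth, keep_query_gaps, gap_cutoff)
    w = weights(rows, theta, symmetric)
    raw = sum(w)
    length = len(rows[0])
    factor = {"by_length": 1.0 / length, "by_sqrt_length": length ** -0.5, "none": 1.0}[norm]
    return raw * factor, raw, w, length
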