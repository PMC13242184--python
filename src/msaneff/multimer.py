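"""NEFF for multimeric MSAs: chain segmentation and per-block statistics.

A multimer MSA concatenates the per-chain alignments of a complex along the
column axis (the layout AlphaFold-style pipelines emit): the query row spans
every chain, "paired" rows carry residues in two or more chains, and
unpaired rows cover exactly one chain with gaps elsewhere.  Chain boundaries
are given explicitly as column counts — nothing is inferred from gap
structure.

For a homomer (identical query segment in every chain) the chain sub-MSAs
can optionally be stacked and deduplicated into a single per-entity
alignment before computing one NEFF for the entity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .core import NeffOptions, NeffResult, compute_neff
from .errors import MultimerSpecError
from .io import Msa, MsaFormat, MsaRecord, merge_msas

logger = logging.getLogger("msaneff")


@dataclass
class MultimerSpec:
    """Chain layout of a concatenated multimer MSA.

    ``chain_lengths`` are the column counts of the chain segments, in order,
    summing to the alignment length.  ``stoichiometry`` is an optional label
    such as "A2" or "A1B1" used for reporting.
    """

    chain_lengths: list[int]
    stoichiometry: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chain_lengths:
            raise MultimerSpecError("chain_lengths must be non-empty")
        if any(n < 1 for n in self.chain_lengths):
            raise MultimerSpecError("chain lengths must be positive")

    @property
    def n_chains(self) -> int:
        return len(self.chain_lengths)

    def boundaries(self) -> list[tuple[int, int]]:
        """Half-open (start, stop) column spans of each chain."""
        spans = []
        start = 0
        for n in self.chain_lengths:
            spans.append((start, start + n))
            start += n
        return spans


@dataclass
class SegmentedMultimer:
    """Row classification and chain sub-MSAs of one multimer alignment.

    ``row_classes[i]`` labels the i-th *retained* row: "query", "paired", or
    "unpaired:k" (1-based chain).  ``kept_rows`` are their original row
    indices; all-gap rows are dropped (and logged) into ``dropped_rows``.
    """

    row_classes: list[str]
    kept_rows: list[int]
    dropped_rows: list[int]
    chains: list[Msa]
    filtered: Msa  # original alignment minus dropped rows


def segment_multimer(msa: Msa, spec: MultimerSpec) -> SegmentedMultimer:
    """Cut each row at the chain boundaries and classify it.

    A row is paired iff at least two of its chain segments contain a
    residue; otherwise it is unpaired for its single residue-bearing chain.
    The query must carry residues in every chain.  Chain k's sub-MSA is the
    query's segment k followed by segment k of every row with residues
    there, preserving row order.
    """
    if not msa.is_aligned():
        raise MultimerSpecError("multimer MSA must be column-aligned")
    length = msa.n_cols
    if sum(spec.chain_lengths) != length:
        raise MultimerSpecError(
            f"chain lengths {spec.chain_lengths} sum to {sum(spec.chain_lengths)}, "
            f"but the alignment has {length} columns"
        )
    spans = spec.boundaries()
    qi = msa.query_index

    def segments(seq: str) -> list[str]:
        return [seq[a:b] for a, b in spans]

    def has_residue(segment: str) -> bool:
        return any(ch not in "-." for ch in segment)

    query_segs = segments(msa.query.seq)
    for k, seg in enumerate(query_segs, start=1):
        if not has_residue(seg):
            raise MultimerSpecError(
                f"query row has no residues in chain {k}; chain lengths "
                "probably do not match this alignment"
            )

    row_classes: list[str] = []
    kept_rows: list[int] = []
    dropped_rows: list[int] = []
    chain_records: list[list[MsaRecord]] = [[] for _ in spans]

    for i, rec in enumerate(msa.records):
        segs = segments(rec.seq)
        occupied = [k for k, seg in enumerate(segs) if has_residue(seg)]
        if i == qi:
            row_classes.append("query")
            kept_rows.append(i)
        elif not occupied:
            dropped_rows.append(i)
            continue
        elif len(occupied) >= 2:
            row_classes.append("paired")
            kept_rows.append(i)
        else:
            row_classes.append(f"unpaired:{occupied[0] + 1}")
            kept_rows.append(i)
        for k in occupied:
            chain_records[k].append(MsaRecord(rec.id, segs[k], rec.description))

    if dropped_rows:
        logger.warning(
            "dropped %d all-gap row(s) from the multimer MSA", len(dropped_rows)
        )

    chains = []
    for k, records in enumerate(chain_records):
        # query segment always leads (it has residues in every chain)
        chains.append(Msa(records=records, source_format=MsaFormat.FASTA))
    filtered = Msa(
        records=[msa.records[i] for i in kept_rows],
        source_format=msa.source_format,
        annotations=list(msa.annotations),
        query_index=kept_rows.index(qi),
    )
    return SegmentedMultimer(
        row_classes=row_classes,
        kept_rows=kept_rows,
        dropped_rows=dropped_rows,
        chains=chains,
        filtered=filtered,
    )


@dataclass
class MultimerNeffResult:
    """NEFF values for a multimer MSA, per block.

    ``overall`` covers the full concatenated alignment (all retained rows);
    ``paired`` the query plus rows spanning >= 2 chains, at full width;
    ``per_chain[k]`` chain k's columns over rows with residues there.
    ``per_entity`` is set only when homomer chains were merged.
    """

    overall: NeffResult
    paired: NeffResult
    per_chain: list[NeffResult]
    row_classes: list[str]
    spec: MultimerSpec
    per_entity: Optional[NeffResult] = None

    def to_dict(self) -> dict:
        payload = {
            "stoichiometry": self.spec.stoichiometry,
            "chain_lengths": list(self.spec.chain_lengths),
            "overall": self.overall.to_dict(),
            "paired": self.paired.to_dict(),
            "per_chain": [r.to_dict() for r in self.per_chain],
            "row_classes": list(self.row_classes),
        }
        if self.per_entity is not None:
            payload["per_entity"] = self.per_entity.to_dict()
        return payload


def compute_multimer_neff(
    msa: Msa,
    spec: MultimerSpec,
    options: NeffOptions | None = None,
    merge_homomer_chains: bool = False,
) -> MultimerNeffResult:
    """Segment a multimer MSA and compute NEFF per block.

    With ``merge_homomer_chains`` the chain sub-MSAs are stacked row-wise,
    deduplicated, and a single per-entity NEFF computed — meaningful only
    when all chains are copies of one entity (identical query segments).
    """
    options = options or NeffOptions()
    seg = segment_multimer(msa, spec)

    overall = compute_neff(seg.filtered, options)

    paired_records = [
        rec
        for rec, cls in zip(seg.filtered.records, seg.row_classes)
        if cls in ("query", "paired")
    ]
    paired_msa = Msa(records=paired_records, source_format=MsaFormat.FASTA)
    paired = compute_neff(paired_msa, options)

    per_chain = [compute_neff(chain, options) for chain in seg.chains]

    per_entity = None
    if merge_homomer_chains:
        merged = merge_msas(seg.chains)  # requires identical query segments
        per_entity = compute_neff(merged, options)

    return MultimerNeffResult(
        overall=overall,
        paired=paired,
        per_chain=per_chain,
        row_classes=seg.row_classes,
        spec=spec,
        per_entity=per_entity,
    )
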