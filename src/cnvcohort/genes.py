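"""CNV-to-gene mapping and multi-evidence gene prioritization.

A gene is "affected" by a call when their intervals overlap by at least
``min_overlap_bp`` under half-open semantics. Prioritization then ranks
genes by how many independent evidence sets contain them (text-mined
obesity candidates, epidemiological catalogs, curated literature lists,
CNV morbidity maps, ...): membership in two or more sets marks a gene as
prioritized. Gene identity is the trimmed, case-sensitive symbol; alias
resolution is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core import CNVCall, ClinicalClass, GeneRecord
from .intervals import intersect

__all__ = ["genes_overlapped", "GeneEvidence", "prioritize"]


def genes_overlapped(
    calls: Sequence[CNVCall],
    gene_table: Sequence[GeneRecord],
    min_overlap_bp: int = 1,
    class_filter: Optional[set[ClinicalClass]] = None,
) -> dict[CNVCall, list[str]]:
    """Map each call to the gene symbols it overlaps.

    ``class_filter`` optionally restricts which clinical classes of calls
    are scanned (e.g. pathogenic only); filtered-out calls are absent from
    the result.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    out: dict[CNVCall, list[str]] = {}
    for call in calls:
        if class_filter is not None and call.clinical_class not in class_filter:
            continue
        hits = []
        for gene in gene_table:
            overlap = intersect(call.interval, gene.location)
            if overlap is not None and overlap.length >= min_overlap_bp:
                hits.append(gene.symbol)
        out[call] = sorted(hits)
    return out


@dataclass(frozen=True)
class GeneEvidence:
    symbol: str
    n_sets: int
    sets: tuple[str, ...]
    within: tuple[tuple[str, str], ...]  # (patient_id, clinical_class)
    prioritized: bool


def prioritize(
    gene_hits: Mapping[CNVCall, Sequence[str]] | Sequence[str],
    gene_sets: Mapping[str, set[str]] | Sequence[tuple[str, set[str]]],
    min_sets: int = 2,
) -> list[GeneEvidence]:
    """Score genes by evidence-set membership.

    ``gene_hits`` is either the mapping produced by
    :func:`genes_overlapped` (patient context is then carried through) or
    a plain list of symbols. ``gene_sets`` maps unique set names to symbol
    sets (a sequence of pairs is accepted; duplicate names are an error).
    Output is deterministic: alphabetical by symbol; set names listed in
    their given (insertion) order.
    """
    if not isinstance(gene_sets, Mapping):
        names = [name for name, _ in gene_sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene set names")
        gene_sets = dict(gene_sets)
    if len(gene_sets) < 2:
        raise ValueError("need at least two named gene sets")
    carriers: dict[str, list[tuple[str, str]]] = {}
    if isinstance(gene_hits, Mapping):
        for call, symbols in gene_hits.items():
            for sym in symbols:
                carriers.setdefault(sym, []).append(
                    (call.patient_id, call.clinical_class.value)
                )
    else:
        for sym in gene_hits:
            carriers.setdefault(sym, [])
    out = []
    for sym in sorted(carriers):
        members = tuple(name for name, symbols in gene_sets.items() if sym in symbols)
        out.append(
            GeneEvidence(
                symbol=sym,
                n_sets=len(members),
                sets=members,
                within=tuple(sorted(set(carriers[sym]))),
                prioritized=len(members) >= min_sets,
            )
        )
    return out
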