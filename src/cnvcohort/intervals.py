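"""Interval algebra over CNV calls.

Pairwise and n-way intersection (the shortest region of overlap, SRO),
single-linkage clustering of calls into recurrent loci, and assignment of
calls to a genomic-disorder catalog. All semantics are half-open: an
interval is ``[start, end)``, its length is ``end - start``, and touching
intervals (``a.end == b.start``) do not overlap.

Recurrence counting is catalog-based rather than raw-overlap-based: a
terminal and an interstitial deletion of the same disorder region belong
to one locus even when they do not mutually overlap. Raw single-linkage
clustering is available separately via :func:`cluster_by_overlap`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .core import CNVCall, GenomicInterval, LocusCatalogEntry

logger = logging.getLogger("cnvcohort")

__all__ = [
    "intersect",
    "shortest_region_of_overlap",
    "OverlapCluster",
    "cluster_by_overlap",
    "LocusAssignment",
    "assign_to_catalog",
    "recurrent_loci",
]


def intersect(a: GenomicInterval, b: GenomicInterval) -> Optional[GenomicInterval]:
    """Positive-length intersection of two intervals, or None.

    Commutative; intervals on different chromosomes simply do not
    intersect (not an error).
    """
    if a.chrom != b.chrom:
        return None
    start, end = max(a.start, b.start), min(a.end, b.end)
    if end <= start:
        return None
    return GenomicInterval(a.chrom, start, end)


def shortest_region_of_overlap(
    calls: Sequence[CNVCall | GenomicInterval],
) -> Optional[GenomicInterval]:
    """n-way intersection of CNV calls: the shortest region of overlap.

    The SRO is the locus shared by every case and is the standard device
    for narrowing a candidate region from multiple overlapping
    deletions/duplications. Returns None when the common intersection is
    empty. All calls must lie on one chromosome; mixed chromosomes are an
    error (an SRO across chromosomes is meaningless).
    """
    if not calls:
        raise ValueError("shortest_region_of_overlap needs at least one call")
    intervals = [c.interval if isinstance(c, CNVCall) else c for c in calls]
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"calls span multiple chromosomes: {sorted(chroms)}")
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if end <= start:
        return None
    return GenomicInterval(intervals[0].chrom, start, end)


@dataclass(frozen=True)
class OverlapCluster:
    """A connected component of mutually-overlapping calls on one chromosome."""

    cluster_id: str
    members: tuple[CNVCall, ...]
    span: GenomicInterval
    sro: Optional[GenomicInterval]

    @property
    def n_patients(self) -> int:
        return len({m.patient_id for m in self.members})


def cluster_by_overlap(
    calls: Sequence[CNVCall], ignore_type: bool = True
) -> list[OverlapCluster]:
    """Single-linkage clusters of overlapping calls, per chromosome.

    With ``ignore_type=True`` (default) deletions and duplications at one
    locus pool into one cluster, matching how reciprocal del/dup loci are
    counted in cohort reports. Output is order-stable: clusters sorted by
    (chromosome, span start), members by (start, end, patient_id).
    """
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(range(len(calls)))
    by_chrom: dict[tuple, list[int]] = {}
    for idx, call in enumerate(calls):
        key = (
            call.interval.chrom
            if ignore_type
            else (call.interval.chrom, call.cnv_type)
        )
        by_chrom.setdefault(key, []).append(idx)
    for indices in by_chrom.values():
        # sweep in coordinate order; link each call to overlapping successors
        indices = sorted(indices, key=lambda i: (calls[i].interval.start, calls[i].interval.end))
        for pos, i in enumerate(indices):
            for j in indices[pos + 1:]:
                if calls[j].interval.start >= calls[i].interval.end:
                    break
                graph.add_edge(i, j)
    clusters = []
    for component in nx.connected_components(graph):
        members = tuple(
            sorted(
                (calls[i] for i in component),
                key=lambda c: (c.interval.start, c.interval.end, c.patient_id),
            )
        )
        chrom = members[0].interval.chrom
        span = GenomicInterval(
            chrom,
            min(m.interval.start for m in members),
            max(m.interval.end for m in members),
        )
        clusters.append(
            OverlapCluster(
                cluster_id="",
                members=members,
                span=span,
                sro=shortest_region_of_overlap(members),
            )
        )
    clusters.sort(key=lambda c: (c.span.chrom, c.span.start, c.span.end))
    return [
        OverlapCluster(f"C{k + 1:03d}", c.members, c.span, c.sro)
        for k, c in enumerate(clusters)
    ]


@dataclass(frozen=True)
class LocusAssignment:
    call: CNVCall
    locus_id: str
    overlap_bp: int
    overlap_fraction_of_call: float


def assign_to_catalog(
    calls: Sequence[CNVCall],
    catalog: Sequence[LocusCatalogEntry],
    min_overlap_bp: int = 1,
) -> tuple[list[LocusAssignment], list[CNVCall]]:
    """Match calls to catalog regions by >= ``min_overlap_bp`` overlap.

    Returns ``(assignments, unassigned)``. A call may match several
    regions (catalog regions are allowed to overlap); a call with no match
    appears in ``unassigned``.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if not catalog:
        logger.warning("empty locus catalog: all %d calls unassigned", len(calls))
        return [], list(calls)
    assignments: list[LocusAssignment] = []
    unassigned: list[CNVCall] = []
    for call in calls:
        matched = False
        for entry in catalog:
            overlap = intersect(call.interval, entry.region)
            if overlap is not None and overlap.length >= min_overlap_bp:
                matched = True
                assignments.append(
                    LocusAssignment(
                        call=call,
                        locus_id=entry.locus_id,
                        overlap_bp=overlap.length,
                        overlap_fraction_of_call=overlap.length / call.length,
                    )
                )
        if not matched:
            unassigned.append(call)
    return assignments, unassigned


def recurrent_loci(
    assignments: Sequence[LocusAssignment], min_patients: int = 2
) -> list[tuple[str, int]]:
    """Catalog loci hit by >= ``min_patients`` distinct patients.

    Each patient contributes at most once per locus regardless of how many
    of their calls match it. Output sorted by descending count then locus
    id.
    """
    patients_per_locus: dict[str, set[str]] = {}
    for a in assignments:
        patients_per_locus.setdefault(a.locus_id, set()).add(a.call.patient_id)
    out = [
        (locus, len(patients))
        for locus, patients in patients_per_locus.items()
        if len(patients) >= min_patients
    ]
    out.sort(key=lambda item: (-item[1], item[0]))
    return out
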