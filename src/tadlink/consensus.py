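"""Consensus TAD construction from two parent TAD sets.

Two Hi-C-derived TAD annotations (e.g. from two cell types) rarely agree
interval-for-interval. The pipeline's reference TAD set is the consensus of
their overlap. Two constructions are exposed:

``intersect``
    One consensus interval per maximal pairwise-overlap region between an
    interval of parent A and an interval of parent B. Splitting a parent
    interval against several partners can make the consensus *larger* in
    count than either parent.
``merge_chained``
    Overlap regions deriving from the same parent-A TAD are merged into a
    single interval spanning from the first to the last such region — one
    consensus TAD per A-TAD that overlaps anything in B.

Tissue-specific TADs are those with zero overlap bases against the entire
other set; a single shared base disqualifies.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval, IntervalSet, jaccard, read_bed

__all__ = ["TadSet", "ConsensusReport", "build_consensus", "tissue_specific", "consensus_report"]


class TadSet:
    """A validated, per-chromosome disjoint set of TAD intervals.

    Ids are regenerated as stable ordinals ``TAD_<chrom>_<k>`` in coordinate
    order (k starting at 1), so identical coordinates always yield identical
    ids regardless of input naming. Original ids, when present, are kept in
    ``source_ids`` keyed by the new id.
    """

    def __init__(self, intervals: IntervalSet):
        iset = intervals if intervals.is_normalized else intervals.normalize()
        relabelled: list[GenomicInterval] = []
        source_ids: dict[str, str] = {}
        for chrom, ivs in sorted(iset.by_chrom().items()):
            prev_end = None
            for k, iv in enumerate(ivs, start=1):
                if prev_end is not None and iv.start < prev_end:
                    raise ValueError(
                        f"TADs overlap on {chrom}: [...,{prev_end}) and "
                        f"[{iv.start},{iv.end})"
                    )
                prev_end = iv.end
                new_id = f"TAD_{chrom}_{k}"
                relabelled.append(GenomicInterval(chrom, iv.start, iv.end, id=new_id))
                if iv.id is not None:
                    source_ids[new_id] = iv.id
        self.intervals = IntervalSet(relabelled, _sorted=True)
        self.source_ids = source_ids

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def ids_in_order(self) -> dict[str, list[str]]:
        """Coordinate-ordered TAD ids per chromosome (the adjacency used by
        the adjacent-TAD null)."""
        return {
            chrom: [iv.id for iv in ivs]  # type: ignore[misc]
            for chrom, ivs in sorted(self.intervals.by_chrom().items())
        }

    @classmethod
    def from_bed(cls, path) -> "TadSet":
        return cls(read_bed(path))


@dataclass(frozen=True)
class ConsensusReport:
    """Interval counts, tissue-specific counts, and base-level Jaccard for a
    parent pair — the shape of a TAD-set concordance table."""

    n_parent_a: int
    n_parent_b: int
    n_consensus: int
    n_a_only: int
    n_b_only: int
    jaccard: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.jaccard <= 1.0):
            raise ValueError("jaccard outside [0,1]")
        if self.n_a_only > self.n_parent_a or self.n_b_only > self.n_parent_b:
            raise ValueError("tissue-specific counts exceed parent counts")


def _pairwise_overlaps(a: TadSet, b: TadSet) -> list[tuple[GenomicInterval, str]]:
    """All maximal pairwise-overlap regions, each tagged with its parent-A id."""
    out: list[tuple[GenomicInterval, str]] = []
    b_by_chrom = b.intervals.by_chrom()
    for chrom, a_ivs in a.intervals.by_chrom().items():
        b_ivs = b_by_chrom.get(chrom, [])
        i = j = 0
        while i < len(a_ivs) and j < len(b_ivs):
            lo = max(a_ivs[i].start, b_ivs[j].start)
            hi = min(a_ivs[i].end, b_ivs[j].end)
            if hi > lo:
                out.append((GenomicInterval(chrom, lo, hi), a_ivs[i].id))  # type: ignore[arg-type]
            if a_ivs[i].end <= b_ivs[j].end:
                i += 1
            else:
                j += 1
    return out


def build_consensus(a: TadSet, b: TadSet, mode: str = "intersect") -> TadSet:
    """Build the consensus TAD set; see the module docstring for the two modes.

    Both parents being disjoint guarantees a disjoint result in either mode
    (merge_chained spans stay inside their parent-A interval). Ids are
    regenerated ordinals.
    """
    if mode not in ("intersect", "merge_chained"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    regions = _pairwise_overlaps(a, b)
    if mode == "intersect":
        ivs = [iv for iv, _ in regions]
    else:
        # chain regions sharing a parent-A TAD into one spanning interval
        by_parent: dict[str, list[GenomicInterval]] = {}
        for iv, a_id in regions:
            by_parent.setdefault(a_id, []).append(iv)
        ivs = [
            GenomicInterval(group[0].chrom, min(g.start for g in group), max(g.end for g in group))
            for group in by_parent.values()
        ]
    return TadSet(IntervalSet(ivs).normalize())


def tissue_specific(a: TadSet, b: TadSet) -> tuple[list[str], list[str]]:
    """Ids of TADs with zero overlap bases against the whole other set,
    as (a_only_ids, b_only_ids)."""

    def _only(x: TadSet, y: TadSet) -> list[str]:
        y_by_chrom = y.intervals.by_chrom()
        only: list[str] = []
        for chrom, ivs in x.intervals.by_chrom().items():
            others = y_by_chrom.get(chrom, [])
            j = 0
            for iv in ivs:
                while j < len(others) and others[j].end <= iv.start:
                    j += 1
                if j >= len(others) or others[j].start >= iv.end:
                    only.append(iv.id)  # type: ignore[arg-type]
        return only

    return _only(a, b), _only(b, a)


def consensus_report(a: TadSet, b: TadSet, mode: str = "intersect") -> ConsensusReport:
    """Assemble counts and Jaccard into one record (deterministic)."""
    cons = build_consensus(a, b, mode=mode)
    a_only, b_only = tissue_specific(a, b)
    return ConsensusReport(
        n_parent_a=len(a),
        n_parent_b=len(b),
        n_consensus=len(cons),
        n_a_only=len(a_only),
        n_b_only=len(b_only),
        jaccard=jaccard(a.intervals, b.intervals),
    )
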