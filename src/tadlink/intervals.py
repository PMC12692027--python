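"""Genomic-interval data model and the overlap primitives the pipeline builds on.

Coordinates follow the BED dialect throughout: 0-based, half-open ``[start,
end)``. Every consumed and emitted track is BED, so a single convention
avoids off-by-one churn at module boundaries. Strand is carried through I/O
but ignored by all spatial operations — enhancers act independently of
orientation, and promoter/enhancer pairing here is purely positional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_overlapping",
    "overlap_bases",
    "jaccard",
    "assign_to_tads",
]

_STRANDS = {"+", "-", None}


class BedParseError(ValueError):
    """Raised for malformed BED input; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open span ``[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open coordinates in bases; ``start < end`` (empty
        intervals are rejected) and ``start >= 0``.
    id : str, optional
        Feature identifier. When absent, :func:`read_bed` and
        :meth:`IntervalSet.normalize` assign ``"<chrom>:<start>-<end>"``.
    strand : {"+", "-", None}
        Carried for round-tripping; never consulted spatially.
    """

    chrom: str
    start: int
    end: int
    id: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise TypeError("start/end must be integers")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} in {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def default_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def midpoint2(self) -> int:
        """Twice the midpoint (``start + end``): exact integer arithmetic for
        distance comparisons with no float rounding at boundaries."""
        return self.start + self.end


class IntervalSet:
    """A collection of :class:`GenomicInterval` grouped by chromosome.

    ``normalize()`` sorts each chromosome by ``(start, end)``, fills missing
    ids, and enforces id uniqueness. All spatial operations require a
    normalized set and the constructors used by I/O return one.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), *, _sorted: bool = False):
        self._intervals: list[GenomicInterval] = list(intervals)
        self._normalized = _sorted

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, normalized={self._normalized})"

    @property
    def is_normalized(self) -> bool:
        return self._normalized

    def normalize(self) -> "IntervalSet":
        """Return a sorted copy with unique, auto-filled ids."""
        filled = [
            iv if iv.id is not None else replace(iv, id=iv.default_id())
            for iv in self._intervals
        ]
        filled.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        seen: set[str] = set()
        for iv in filled:
            if iv.id in seen:
                raise ValueError(f"duplicate interval id {iv.id!r}")
            seen.add(iv.id)  # type: ignore[arg-type]
        out = IntervalSet(filled, _sorted=True)
        return out

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        groups: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            groups.setdefault(iv.chrom, []).append(iv)
        return groups

    def total_bases(self) -> int:
        """Covered bases counting multiplicity (use after merging for cover size)."""
        return sum(iv.length() for iv in self._intervals)


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6 into a normalized :class:`IntervalSet`.

    track/browser/comment/blank lines are skipped; a 4th field becomes the
    id, a 6th the strand ("." → unstranded). Malformed coordinates raise
    :class:`BedParseError` naming the line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from exc
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
            strand: str | None = None
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            try:
                intervals.append(GenomicInterval(chrom, start, end, id=name, strand=strand))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals).normalize()


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write a normalized set as BED6 (score column fixed to 0, strand "." when
    unset). Round-trips through :func:`read_bed` exactly on coordinates/ids."""
    if not iset.is_normalized:
        raise ValueError("write_bed requires a normalized IntervalSet")
    path = Path(path)
    with path.open("w") as fh:
        for iv in iset:
            strand = iv.strand if iv.strand is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{strand}\n")


def merge_overlapping(iset: IntervalSet) -> IntervalSet:
    """Per chromosome, the minimal set of maximal intervals covering the same
    bases. Bookended intervals ([0,10), [10,20)) merge — the bedtools default.
    Idempotent; merged intervals get fresh coordinate-derived ids."""
    if not iset.is_normalized:
        raise ValueError("merge_overlapping requires a normalized IntervalSet")
    merged: list[GenomicInterval] = []
    for chrom, ivs in sorted(iset.by_chrom().items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or bookended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(merged).normalize()


def overlap_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases; 0 across chromosomes or when merely touching."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _cover_intersection_bases(a: IntervalSet, b: IntervalSet) -> int:
    """Intersection bases of two merged (disjoint, sorted) covers; linear sweep."""
    total = 0
    b_by_chrom = b.by_chrom()
    for chrom, a_ivs in a.by_chrom().items():
        b_ivs = b_by_chrom.get(chrom)
        if not b_ivs:
            continue
        i = j = 0
        while i < len(a_ivs) and j < len(b_ivs):
            lo = max(a_ivs[i].start, b_ivs[j].start)
            hi = min(a_ivs[i].end, b_ivs[j].end)
            if hi > lo:
                total += hi - lo
            if a_ivs[i].end <= b_ivs[j].end:
                i += 1
            else:
                j += 1
    return total


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """Base-level Jaccard of two interval sets: each set is merged internally,
    then intersection bases / union bases. Empty union → 0.0 by convention."""
    am, bm = merge_overlapping(a), merge_overlapping(b)
    inter = _cover_intersection_bases(am, bm)
    union = am.total_bases() + bm.total_bases() - inter
    return inter / union if union > 0 else 0.0


def assign_to_tads(features: IntervalSet, tads: "TadSetLike") -> dict[str, str]:
    """Uniquely assign each feature to the TAD it overlaps most.

    A feature overlapping one TAD by ≥1 bp maps to it; with several
    overlapping TADs the largest overlap wins and ties go to the
    lower-coordinate TAD; no overlap → the feature is absent from the
    mapping. Unique assignment keeps per-TAD aggregation conservative:
    summing over TADs plus unassigned features recovers every count once.

    ``tads`` is anything exposing ``.intervals`` as a normalized, per-chromosome
    disjoint :class:`IntervalSet` (a :class:`~tadlink.consensus.TadSet`).
    """
    tad_iset: IntervalSet = tads.intervals if hasattr(tads, "intervals") else tads
    if not tad_iset.is_normalized or not features.is_normalized:
        raise ValueError("assign_to_tads requires normalized inputs")
    tads_by_chrom = tad_iset.by_chrom()
    assignment: dict[str, str] = {}
    for chrom, feats in features.by_chrom().items():
        tad_ivs = tads_by_chrom.get(chrom, [])
        if not tad_ivs:
            continue
        starts = [t.start for t in tad_ivs]
        import bisect

        for feat in feats:
            # TADs are disjoint & sorted: candidates lie in a narrow window
            lo = bisect.bisect_right(starts, feat.start) - 1
            lo = max(lo, 0)
            best: tuple[int, int, int] | None = None  # (-overlap, start, idx)
            for k in range(lo, len(tad_ivs)):
                t = tad_ivs[k]
                if t.start >= feat.end:
                    break
                ov = overlap_bases(feat, t)
                if ov > 0:
                    key = (-ov, t.start, k)
                    if best is None or key < best:
                        best = key
            if best is not None:
                assignment[feat.id] = tad_ivs[best[2]].id  # type: ignore[index]
    return assignment


# typing helper for assign_to_tads's duck-typed TAD argument
class TadSetLike:  # pragma: no cover - structural typing aid only
    intervals: IntervalSet
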