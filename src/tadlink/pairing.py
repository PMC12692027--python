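"""Enhancer–promoter pair enumeration and differential-expression filtering.

Candidate pairs come from three nested levels of spatial association:
linear proximity (midpoint distance ≤ 500 kb by default), co-localization
within one TAD, and finally the functional filter keeping only pairs whose
both members are significantly differentially expressed (BH FDR strictly
below the threshold). A surviving pair carries a sign pattern — promoter
sign first, enhancer sign second — one of ``++``, ``+-``, ``-+``, ``--``.

Distances are midpoint-to-midpoint, compared exactly in integer arithmetic
(twice-midpoints), so the inclusion boundary never depends on float
rounding. Pair identity is ``(promoter_id, enhancer_id)``; the TAD id is
annotation, which keeps cross-tissue intersection insensitive to
TAD-assignment edge cases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .consensus import TadSet
from .intervals import IntervalSet, assign_to_tads

__all__ = [
    "EPPair",
    "load_de_table",
    "de_sign",
    "pairs_by_proximity",
    "pairs_by_tad",
    "filter_differential",
    "stable_pairs",
    "pairs_to_frame",
]

DEFAULT_MAX_DISTANCE = 500_000
DEFAULT_FDR = 0.05


@dataclass(frozen=True)
class EPPair:
    """One promoter–enhancer pair.

    ``distance`` is the midpoint separation in bases (may end in .5 for
    odd-length spans); ``pattern`` is set only after DE filtering.
    """

    promoter_id: str
    enhancer_id: str
    tad_id: str | None = None
    distance: float = 0.0
    pattern: str | None = None
    prom_log2fc: float | None = None
    enh_log2fc: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.promoter_id, self.enhancer_id)


def load_de_table(path: str | Path) -> pd.DataFrame:
    """Read a per-tissue differential-expression TSV.

    Requires columns ``feature_id``, ``log2fc``, ``fdr``; extra columns are
    kept. Duplicate feature ids or FDR outside [0,1] are validation errors.
    """
    df = pd.read_csv(path, sep="\t")
    return validate_de_table(df)


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = {"feature_id", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"duplicate feature id in DE table: {dup!r}")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("FDR values outside [0,1] in DE table")
    return df


def de_sign(log2fc: float) -> str:
    """Direction of change: '+' for upregulation, '-' for downregulation.
    A zero fold change has no direction and is rejected where a sign is
    required."""
    if log2fc > 0:
        return "+"
    if log2fc < 0:
        return "-"
    raise ValueError("log2fc of exactly 0 carries no sign")


def pairs_by_proximity(
    promoters: IntervalSet,
    enhancers: IntervalSet,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[EPPair]:
    """All same-chromosome pairs with midpoint distance ≤ ``max_distance``
    (inclusive). Sliding window over midpoint-sorted features."""
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    pairs: list[EPPair] = []
    enh_by_chrom = enhancers.by_chrom()
    limit2 = 2 * max_distance  # compare doubled midpoints exactly
    for chrom, proms in promoters.by_chrom().items():
        enhs = sorted(enh_by_chrom.get(chrom, []), key=lambda iv: iv.midpoint2)
        if not enhs:
            continue
        e_mid2 = [e.midpoint2 for e in enhs]
        import bisect

        for p in sorted(proms, key=lambda iv: iv.midpoint2):
            lo = bisect.bisect_left(e_mid2, p.midpoint2 - limit2)
            hi = bisect.bisect_right(e_mid2, p.midpoint2 + limit2)
            for e in enhs[lo:hi]:
                pairs.append(
                    EPPair(
                        promoter_id=p.id,  # type: ignore[arg-type]
                        enhancer_id=e.id,  # type: ignore[arg-type]
                        distance=abs(p.midpoint2 - e.midpoint2) / 2,
                    )
                )
    pairs.sort(key=lambda pr: pr.key)
    return pairs


def pairs_by_tad(
    promoters: IntervalSet, enhancers: IntervalSet, tads: TadSet
) -> list[EPPair]:
    """Pairs whose members are both uniquely assigned to the same TAD.

    Features overlapping no TAD generate no pairs; features straddling a
    boundary follow the largest-overlap assignment rule of
    :func:`tadlink.intervals.assign_to_tads`.
    """
    prom_tad = assign_to_tads(promoters, tads)
    enh_tad = assign_to_tads(enhancers, tads)
    prom_mid2 = {iv.id: iv.midpoint2 for iv in promoters}
    enh_mid2 = {iv.id: iv.midpoint2 for iv in enhancers}
    enh_by_tad: dict[str, list[str]] = {}
    for eid, tid in enh_tad.items():
        enh_by_tad.setdefault(tid, []).append(eid)
    pairs: list[EPPair] = []
    for pid, tid in prom_tad.items():
        for eid in enh_by_tad.get(tid, ()):
            pairs.append(
                EPPair(
                    promoter_id=pid,
                    enhancer_id=eid,
                    tad_id=tid,
                    distance=abs(prom_mid2[pid] - enh_mid2[eid]) / 2,
                )
            )
    pairs.sort(key=lambda pr: pr.key)
    return pairs


def filter_differential(
    pairs: list[EPPair],
    de_prom: pd.DataFrame,
    de_enh: pd.DataFrame,
    fdr_threshold: float = DEFAULT_FDR,
) -> list[EPPair]:
    """Keep pairs where both members pass ``fdr < fdr_threshold`` (strict),
    and stamp the sign pattern (promoter sign first).

    Pairs with a member missing from its DE table are dropped. A passing
    record with log2fc exactly 0 is contradictory (significant but
    directionless) and raises.
    """
    de_prom = validate_de_table(de_prom)
    de_enh = validate_de_table(de_enh)
    prom_idx = de_prom.set_index("feature_id")
    enh_idx = de_enh.set_index("feature_id")
    kept: list[EPPair] = []
    for pair in pairs:
        if pair.promoter_id not in prom_idx.index or pair.enhancer_id not in enh_idx.index:
            continue
        p_row = prom_idx.loc[pair.promoter_id]
        e_row = enh_idx.loc[pair.enhancer_id]
        if not (p_row["fdr"] < fdr_threshold and e_row["fdr"] < fdr_threshold):
            continue
        pattern = de_sign(p_row["log2fc"]) + de_sign(e_row["log2fc"])
        kept.append(
            replace(
                pair,
                pattern=pattern,
                prom_log2fc=float(p_row["log2fc"]),
                enh_log2fc=float(e_row["log2fc"]),
            )
        )
    return kept


def stable_pairs(
    per_tissue_pairs: dict[str, list[EPPair]],
) -> list[tuple[tuple[str, str], dict[str, str | None]]]:
    """Pairs present in every tissue's (filtered) list.

    Identity is ``(promoter_id, enhancer_id)`` regardless of per-tissue
    pattern. Returns each stable key with its per-tissue patterns.
    """
    if not per_tissue_pairs:
        raise ValueError("stable_pairs requires at least one tissue")
    if len(per_tissue_pairs) < 2:
        raise ValueError("stable_pairs requires at least two tissues")
    key_maps = {
        tissue: {p.key: p.pattern for p in plist}
        for tissue, plist in per_tissue_pairs.items()
    }
    tissues = list(key_maps)
    common = set(key_maps[tissues[0]])
    for tissue in tissues[1:]:
        common &= set(key_maps[tissue])
    return [
        (key, {tissue: key_maps[tissue][key] for tissue in tissues})
        for key in sorted(common)
    ]


def pairs_to_frame(pairs: list[EPPair]) -> pd.DataFrame:
    """Tabular view of a pair list (the CLI's pairs.tsv schema)."""
    return pd.DataFrame(
        [
            {
                "promoter_id": p.promoter_id,
                "enhancer_id": p.enhancer_id,
                "tad_id": p.tad_id if p.tad_id is not None else ".",
                "distance": p.distance,
                "pattern": p.pattern if p.pattern is not None else ".",
                "prom_log2fc": p.prom_log2fc,
                "enh_log2fc": p.enh_log2fc,
            }
            for p in pairs
        ],
        columns=[
            "promoter_id",
            "enhancer_id",
            "tad_id",
            "distance",
            "pattern",
            "prom_log2fc",
            "enh_log2fc",
        ],
    )
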