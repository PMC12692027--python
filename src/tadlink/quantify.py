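"""Sign-pattern interaction counting per TAD and per tissue.

The number of putative promoter–enhancer interactions in a TAD is the
plain combinatorial product of its differentially expressed promoters and
enhancers, split into four sign classes: with ``u_p``/``d_p`` up/down
promoters and ``u_e``/``d_e`` up/down enhancers,

    c_++ = u_p·u_e,  c_+- = u_p·d_e,  c_-+ = d_p·u_e,  c_-- = d_p·d_e,

so the class counts always sum to ``(u_p+d_p)·(u_e+d_e)``. A tissue's
profile sums these over its TADs and normalizes the total to 1.0. A TAD
is *consolidated* when all its DE promoters share one sign and all its DE
enhancers share one sign — exactly one class count is then nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .pairing import DEFAULT_FDR, de_sign, validate_de_table

__all__ = [
    "TadPatternCount",
    "TissueInteractionProfile",
    "de_features_by_tad",
    "count_tad_patterns",
    "tissue_profile",
    "profile_from_pairs",
    "consolidated_tads",
    "annotated_subset_profile",
]

PATTERNS = ("++", "+-", "-+", "--")


@dataclass(frozen=True)
class TadPatternCount:
    """Per-TAD DE feature counts and the four interaction class counts."""

    tad_id: str
    n_prom_up: int
    n_prom_down: int
    n_enh_up: int
    n_enh_down: int

    @property
    def c_pp(self) -> int:
        return self.n_prom_up * self.n_enh_up

    @property
    def c_pm(self) -> int:
        return self.n_prom_up * self.n_enh_down

    @property
    def c_mp(self) -> int:
        return self.n_prom_down * self.n_enh_up

    @property
    def c_mm(self) -> int:
        return self.n_prom_down * self.n_enh_down

    @property
    def total(self) -> int:
        return (self.n_prom_up + self.n_prom_down) * (self.n_enh_up + self.n_enh_down)

    def class_counts(self) -> dict[str, int]:
        return {"++": self.c_pp, "+-": self.c_pm, "-+": self.c_mp, "--": self.c_mm}


@dataclass(frozen=True)
class TissueInteractionProfile:
    """Tissue-level interaction totals and class proportions (sum to 1 when
    total > 0; all-zero with ``empty=True`` otherwise)."""

    tissue: str
    total: int
    n_pp: int
    n_pm: int
    n_mp: int
    n_mm: int
    p_pp: float
    p_pm: float
    p_mp: float
    p_mm: float
    empty: bool = False

    def proportions(self) -> dict[str, float]:
        return {"++": self.p_pp, "+-": self.p_pm, "-+": self.p_mp, "--": self.p_mm}


def de_features_by_tad(
    de_table: pd.DataFrame,
    assignment: dict[str, str],
    fdr_threshold: float = DEFAULT_FDR,
) -> dict[str, list[tuple[str, str]]]:
    """Group significant DE features (fdr < threshold, strict) by their TAD.

    Returns ``{tad_id: [(feature_id, sign), ...]}``; unassigned features are
    dropped.
    """
    de_table = validate_de_table(de_table)
    out: dict[str, list[tuple[str, str]]] = {}
    for row in de_table.itertuples(index=False):
        if not row.fdr < fdr_threshold:
            continue
        tad = assignment.get(row.feature_id)
        if tad is None:
            continue
        out.setdefault(tad, []).append((row.feature_id, de_sign(row.log2fc)))
    return out


def count_tad_patterns(
    de_prom_by_tad: dict[str, list[tuple[str, str]]],
    de_enh_by_tad: dict[str, list[tuple[str, str]]],
) -> list[TadPatternCount]:
    """One record per TAD with ≥1 DE promoter and ≥1 DE enhancer; exact
    integer products."""
    counts: list[TadPatternCount] = []
    for tad_id in sorted(set(de_prom_by_tad) & set(de_enh_by_tad)):
        proms = de_prom_by_tad[tad_id]
        enhs = de_enh_by_tad[tad_id]
        if not proms or not enhs:
            continue
        counts.append(
            TadPatternCount(
                tad_id=tad_id,
                n_prom_up=sum(1 for _, s in proms if s == "+"),
                n_prom_down=sum(1 for _, s in proms if s == "-"),
                n_enh_up=sum(1 for _, s in enhs if s == "+"),
                n_enh_down=sum(1 for _, s in enhs if s == "-"),
            )
        )
    return counts


def tissue_profile(counts: list[TadPatternCount], tissue: str) -> TissueInteractionProfile:
    """Sum the four classes over a tissue's TADs and normalize to proportions.
    A tissue with no qualifying TADs gets zero proportions and the
    ``empty`` flag."""
    n_pp = sum(c.c_pp for c in counts)
    n_pm = sum(c.c_pm for c in counts)
    n_mp = sum(c.c_mp for c in counts)
    n_mm = sum(c.c_mm for c in counts)
    total = n_pp + n_pm + n_mp + n_mm
    if total == 0:
        return TissueInteractionProfile(tissue, 0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, empty=True)
    return TissueInteractionProfile(
        tissue=tissue,
        total=total,
        n_pp=n_pp,
        n_pm=n_pm,
        n_mp=n_mp,
        n_mm=n_mm,
        p_pp=n_pp / total,
        p_pm=n_pm / total,
        p_mp=n_mp / total,
        p_mm=n_mm / total,
    )


def profile_from_pairs(pairs, tissue: str) -> TissueInteractionProfile:
    """Tissue profile tallied directly from DE-filtered pairs.

    Enumerated pairs within a TAD *are* the promoter x enhancer products, so
    tallying pattern occurrences reproduces :func:`tissue_profile` exactly;
    this is the entry point used when working from a pairs table.
    """
    tallies = {p: 0 for p in PATTERNS}
    for pair in pairs:
        if pair.pattern is None:
            raise ValueError(f"pair {pair.key} has no sign pattern; run the DE filter first")
        tallies[pair.pattern] += 1
    total = sum(tallies.values())
    if total == 0:
        return TissueInteractionProfile(tissue, 0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, empty=True)
    return TissueInteractionProfile(
        tissue=tissue,
        total=total,
        n_pp=tallies["++"],
        n_pm=tallies["+-"],
        n_mp=tallies["-+"],
        n_mm=tallies["--"],
        p_pp=tallies["++"] / total,
        p_pm=tallies["+-"] / total,
        p_mp=tallies["-+"] / total,
        p_mm=tallies["--"] / total,
    )


def consolidated_tads(
    counts: list[TadPatternCount], *, promoter_only: bool = False
) -> list[tuple[TadPatternCount, str]]:
    """TADs whose DE features respond uniformly, with their sign label.

    By default both promoter and enhancer signs must each be uniform (the
    returned label is ``promoter_sign + enhancer_sign`` and exactly one
    class count is nonzero). ``promoter_only=True`` relaxes the enhancer
    condition; the label's enhancer slot is then ``"."`` when enhancer signs
    are mixed.
    """
    out: list[tuple[TadPatternCount, str]] = []
    for c in counts:
        prom_uniform = (c.n_prom_up == 0) != (c.n_prom_down == 0)
        enh_uniform = (c.n_enh_up == 0) != (c.n_enh_down == 0)
        if not prom_uniform:
            continue
        if not promoter_only and not enh_uniform:
            continue
        p_sign = "+" if c.n_prom_up > 0 else "-"
        e_sign = ("+" if c.n_enh_up > 0 else "-") if enh_uniform else "."
        out.append((c, p_sign + e_sign))
    return out


def annotated_subset_profile(
    de_prom_by_tad: dict[str, list[tuple[str, str]]],
    de_enh_by_tad: dict[str, list[tuple[str, str]]],
    annotation: set[str],
    id_map: dict[str, str] | None = None,
) -> tuple[dict[str, int], int]:
    """Class totals counting only promoters whose gene is in ``annotation``
    (e.g. a transcription-factor/cofactor gene list).

    ``id_map`` maps promoter feature ids to gene ids; unmapped features
    count as unannotated. Returns the four class totals and the number of
    distinct annotated DE genes.
    """
    if not annotation:
        raise ValueError("annotation set is empty")
    id_map = id_map or {}

    def gene_of(fid: str) -> str:
        return id_map.get(fid, fid)

    restricted = {
        tad: [(fid, s) for fid, s in feats if gene_of(fid) in annotation]
        for tad, feats in de_prom_by_tad.items()
    }
    counts = count_tad_patterns(restricted, de_enh_by_tad)
    totals = {p: 0 for p in PATTERNS}
    for c in counts:
        for p, v in c.class_counts().items():
            totals[p] += v
    genes = {
        gene_of(fid)
        for tad, feats in restricted.items()
        if de_enh_by_tad.get(tad)
        for fid, _ in feats
    }
    return totals, len(genes)
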