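"""TAD-aggregated co-expression: correlation/regression battery and the
adjacent-TAD shift null.

Promoter and enhancer read counts are summed per TAD, log2-transformed with
a pseudocount, and compared across TADs: enhancer aggregate on X, promoter
aggregate on Y. The battery reports Pearson's r, Spearman's ρ, Kendall's
τ (tau-b, tie-corrected — ties are common after count aggregation), a
least-squares line (SLR), and the robust Theil–Sen line (slope = median of
all pairwise slopes; intercept = median residual).

The adjacent-TAD null re-pairs each TAD's enhancer aggregate with the
promoter aggregate of the *next* TAD along the chromosome. If TADs really
do confine regulatory contacts, the same-TAD association should survive
and the shifted pairing should not — the null is the negative control for
the claim that the correlation respects TAD boundaries rather than broad
chromosomal trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TadAggregate",
    "AssociationReport",
    "aggregate_by_tad",
    "theil_sen",
    "association_battery",
    "adjacent_tad_null",
    "format_p",
]

P_UNDERFLOW = 1e-300


@dataclass(frozen=True)
class TadAggregate:
    """Summed promoter/enhancer counts for one TAD and their log2(x + pc)
    transforms."""

    tad_id: str
    prom_sum: float
    enh_sum: float
    prom_log2: float
    enh_log2: float


@dataclass(frozen=True)
class AssociationReport:
    """The full correlation/regression battery over a set of TADs.

    Coefficients are NaN (with ``degenerate=True``) when either axis has
    zero variance; p-values are NaN when fewer than 3 points are available.
    """

    n_tads: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    kendall_tau: float
    kendall_p: float
    slr_slope: float
    slr_intercept: float
    theilsen_slope: float
    theilsen_intercept: float
    degenerate: bool = False

    def to_dict(self) -> dict[str, float | int | bool]:
        return {
            "n_tads": self.n_tads,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "kendall_tau": self.kendall_tau,
            "kendall_p": self.kendall_p,
            "slr_slope": self.slr_slope,
            "slr_intercept": self.slr_intercept,
            "theilsen_slope": self.theilsen_slope,
            "theilsen_intercept": self.theilsen_intercept,
            "degenerate": self.degenerate,
        }


def format_p(p: float) -> str:
    """Render a p-value for reports; underflowed values print as '<1e-300'
    rather than a misleading hard zero."""
    if math.isnan(p):
        return "NA"
    if 0 <= p < P_UNDERFLOW:
        return "<1e-300"
    return format(p, ".6g")


def aggregate_by_tad(
    prom_counts: pd.Series,
    enh_counts: pd.Series,
    prom_assignment: dict[str, str],
    enh_assignment: dict[str, str],
    pseudocount: float = 1.0,
) -> list[TadAggregate]:
    """Sum feature counts per TAD and log2-transform.

    ``prom_counts``/``enh_counts`` map feature id → total read count
    (non-negative). Only TADs holding at least one assigned promoter AND one
    assigned enhancer are returned; unassigned features are ignored (the
    unique TAD assignment makes the per-TAD sums conserve total counts).
    """
    for name, counts in (("promoter", prom_counts), ("enhancer", enh_counts)):
        if (counts < 0).any():
            raise ValueError(f"negative {name} counts")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")

    def _sums(counts: pd.Series, assignment: dict[str, str]) -> dict[str, float]:
        sums: dict[str, float] = {}
        for fid, value in counts.items():
            tad = assignment.get(fid)
            if tad is not None:
                sums[tad] = sums.get(tad, 0.0) + float(value)
        return sums

    prom_sums = _sums(prom_counts, prom_assignment)
    enh_sums = _sums(enh_counts, enh_assignment)
    out = []
    for tad in sorted(set(prom_sums) & set(enh_sums)):
        ps, es = prom_sums[tad], enh_sums[tad]
        out.append(
            TadAggregate(
                tad_id=tad,
                prom_sum=ps,
                enh_sum=es,
                prom_log2=math.log2(ps + pseudocount),
                enh_log2=math.log2(es + pseudocount),
            )
        )
    return out


def theil_sen(x, y) -> tuple[float, float]:
    """Theil–Sen line fit.

    slope = median over index pairs i<j with x_i != x_j of
    (y_j - y_i)/(x_j - x_i); intercept = median over points of
    y_i - slope*x_i. Even-cardinality medians average the two central order
    statistics. Requires ≥2 points with ≥2 distinct x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 2:
        raise ValueError("Theil-Sen requires at least 2 points")
    if np.unique(x).size < 2:
        raise ValueError("Theil-Sen is degenerate: all x identical")
    # scipy's 'joint' method is exactly the pairwise-slope-median /
    # median-residual estimator
    res = stats.theilslopes(y, x, method="joint")
    return float(res.slope), float(res.intercept)


def _battery(x: np.ndarray, y: np.ndarray, n_label: int | None = None) -> AssociationReport:
    n = len(x)
    nan = float("nan")
    if n == 0:
        return AssociationReport(0, nan, nan, nan, nan, nan, nan, nan, nan, nan, nan, True)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationReport(n, nan, nan, nan, nan, nan, nan, nan, nan, nan, nan, True)
    if n >= 3:
        pr = stats.pearsonr(x, y)
        sp = stats.spearmanr(x, y)
        kd = stats.kendalltau(x, y)  # tau-b with tie correction
        pearson_r, pearson_p = float(pr.statistic), float(pr.pvalue)
        spearman_rho, spearman_p = float(sp.statistic), float(sp.pvalue)
        kendall_tau, kendall_p = float(kd.statistic), float(kd.pvalue)
    else:
        # 2 points: coefficients are formally defined, p-values are not
        pearson_r = float(np.corrcoef(x, y)[0, 1])
        spearman_rho = pearson_r
        kendall_tau = float(np.sign((x[1] - x[0]) * (y[1] - y[0])))
        pearson_p = spearman_p = kendall_p = nan
    lr = stats.linregress(x, y)
    ts_slope, ts_intercept = theil_sen(x, y)
    return AssociationReport(
        n_tads=n if n_label is None else n_label,
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        spearman_rho=spearman_rho,
        spearman_p=spearman_p,
        kendall_tau=kendall_tau,
        kendall_p=kendall_p,
        slr_slope=float(lr.slope),
        slr_intercept=float(lr.intercept),
        theilsen_slope=ts_slope,
        theilsen_intercept=ts_intercept,
    )


def association_battery(agg: list[TadAggregate]) -> AssociationReport:
    """Same-TAD battery: x = enhancer log2 aggregate, y = promoter log2
    aggregate, one point per TAD."""
    x = np.array([a.enh_log2 for a in agg])
    y = np.array([a.prom_log2 for a in agg])
    return _battery(x, y)


def adjacent_tad_null(
    agg: list[TadAggregate], tad_order: dict[str, list[str]]
) -> AssociationReport:
    """Shifted pairing: enhancer aggregate of each TAD against the promoter
    aggregate of the next usable TAD on the same chromosome.

    ``tad_order`` gives coordinate-sorted TAD ids per chromosome
    (:meth:`tadlink.consensus.TadSet.ids_in_order`). TADs absent from
    ``agg`` are skipped, so adjacency is taken over the usable TADs; the
    last usable TAD of each chromosome pairs with nothing. Requires ≥3
    shifted pairs.
    """
    by_id = {a.tad_id: a for a in agg}
    xs: list[float] = []
    ys: list[float] = []
    for chrom_ids in tad_order.values():
        usable = [tid for tid in chrom_ids if tid in by_id]
        for cur, nxt in zip(usable, usable[1:]):
            xs.append(by_id[cur].enh_log2)
            ys.append(by_id[nxt].prom_log2)
    if len(xs) < 3:
        raise ValueError(
            f"adjacent-TAD null needs >=3 shifted pairs, got {len(xs)}"
        )
    return _battery(np.array(xs), np.array(ys))


def aggregates_to_frame(agg: list[TadAggregate]) -> pd.DataFrame:
    """Per-TAD scatter table (plot-ready: enh_log2 on X, prom_log2 on Y)."""
    return pd.DataFrame(
        [
            {
                "tad_id": a.tad_id,
                "prom_sum": a.prom_sum,
                "enh_sum": a.enh_sum,
                "prom_log2": a.prom_log2,
                "enh_log2": a.enh_log2,
            }
            for a in agg
        ],
        columns=["tad_id", "prom_sum", "enh_sum", "prom_log2", "enh_log2"],
    )
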