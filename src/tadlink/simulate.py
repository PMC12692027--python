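"""Synthetic TAD-structured data with known ground truth.

The generator emulates the statistical skeleton of a CAGE-style two-condition
expression study on a TAD-partitioned genome:

* TADs tile each chromosome end to end; promoters (100 bp) and enhancers
  (400 bp) are placed uniformly at random inside their TAD, non-overlapping
  within a TAD.
* For sample ``s`` and feature ``f`` in TAD ``t`` the read count is
  ``round(2^(b_f + a_t + g_f*c_s + eps_fs))`` with per-TAD activity
  ``a_t ~ N(0, sigma_a^2)`` shared by all features of the TAD (the source of
  same-TAD promoter/enhancer co-expression), per-feature baseline
  ``b_f ~ N(mu_b, sigma_b^2)``, noise ``eps ~ N(0, sigma_e^2)``, and a
  condition effect ``g_f`` that is ``+/- delta`` in DE-carrying TADs.
* A DE-carrying TAD draws one sign pattern from ``pattern_mixture``; every
  promoter in it gets the promoter sign of that pattern, every enhancer the
  enhancer sign — mirroring TAD-level coordinated regulation.

Counts are rounded log-normal rather than negative binomial: simpler, and
sufficient to induce the shared-activity correlation structure and sign
patterns the downstream analysis measures. ``naive_de`` is a deliberately
plain two-sample t-test on log2(count+1) with BH adjustment — it exercises
the FDR-filter contract end to end and makes no claim to model counts the
way a dedicated DE package would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consensus import TadSet
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate",
    "perturb_tads",
    "naive_de",
    "bh_adjust",
]

PATTERNS = ("++", "+-", "-+", "--")
PROMOTER_WIDTH = 100
ENHANCER_WIDTH = 400
_SIGN = {"+": 1.0, "-": -1.0}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Log-scale parameters (``tad_activity_sd``, ``feature_baseline_mean``/``sd``,
    ``noise_sd``, ``effect_size``) are in log2 units; lengths in bases.
    ``de_fraction`` is the fraction of TADs carrying a condition effect and
    ``pattern_mixture`` the (++, +-, -+, --) probabilities for the pattern a
    DE TAD draws.
    """

    n_chromosomes: int = 2
    tads_per_chromosome: int = 60
    tad_length: int = 400_000
    promoters_per_tad: int = 3
    enhancers_per_tad: int = 3
    tad_activity_sd: float = 1.0
    feature_baseline_mean: float = 5.0
    feature_baseline_sd: float = 1.0
    noise_sd: float = 0.5
    n_samples_per_condition: int = 5
    de_fraction: float = 0.5
    pattern_mixture: tuple[float, float, float, float] = (0.55, 0.15, 0.15, 0.15)
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.pattern_mixture) - 1.0) > 1e-12:
            raise ValueError("pattern_mixture must sum to 1")
        if any(q < 0 for q in self.pattern_mixture):
            raise ValueError("pattern_mixture probabilities must be >= 0")
        for name in ("tad_activity_sd", "feature_baseline_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0,1]")
        if self.tad_length <= 0:
            raise ValueError("tad_length must be positive")
        if self.n_samples_per_condition < 1:
            raise ValueError("need >=1 sample per condition")


@dataclass
class SimTruth:
    """Ground truth of one simulation: per-TAD activity and pattern, per-feature
    baseline and signed condition effect."""

    tad_activity: dict[str, float]
    tad_pattern: dict[str, str | None]
    feature_baseline: dict[str, float]
    feature_effect: dict[str, float]


@dataclass
class SimResult:
    tads: TadSet
    promoters: IntervalSet
    enhancers: IntervalSet
    prom_counts: pd.DataFrame  # feature_id index x sample columns
    enh_counts: pd.DataFrame
    condition: pd.Series  # sample -> 0/1
    truth: SimTruth


def _place_features(
    rng: np.random.Generator, tad: GenomicInterval, n: int, width: int, prefix: str
) -> list[GenomicInterval]:
    """Uniform non-overlapping placement inside a TAD by bounded rejection."""
    placed: list[tuple[int, int]] = []
    span = tad.length() - width
    if span < 0:
        raise ValueError(f"TAD {tad.id} shorter than feature width {width}")
    for _ in range(n):
        for _attempt in range(1000):
            start = tad.start + int(rng.integers(0, span + 1))
            end = start + width
            if all(end <= s or start >= e for s, e in placed):
                placed.append((start, end))
                break
        else:
            raise ValueError(
                f"could not place {n} non-overlapping features of width {width} "
                f"in TAD {tad.id}; increase tad_length"
            )
    placed.sort()
    return [
        GenomicInterval(tad.chrom, s, e, id=f"{prefix}_{tad.id}_{k}")
        for k, (s, e) in enumerate(placed, start=1)
    ]


def simulate(config: SimConfig) -> SimResult:
    """Generate one dataset; bit-reproducible for a fixed ``config.seed``."""
    rng = np.random.default_rng(config.seed)

    tad_ivs = []
    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        for k in range(config.tads_per_chromosome):
            tad_ivs.append(
                GenomicInterval(chrom, k * config.tad_length, (k + 1) * config.tad_length)
            )
    tads = TadSet(IntervalSet(tad_ivs).normalize())

    n_samples = 2 * config.n_samples_per_condition
    samples = [f"s{j+1}" for j in range(n_samples)]
    condition = pd.Series(
        [0] * config.n_samples_per_condition + [1] * config.n_samples_per_condition,
        index=samples,
        name="condition",
    )

    proms: list[GenomicInterval] = []
    enhs: list[GenomicInterval] = []
    tad_activity: dict[str, float] = {}
    tad_pattern: dict[str, str | None] = {}
    baselines: dict[str, float] = {}
    effects: dict[str, float] = {}
    rows_p: dict[str, np.ndarray] = {}
    rows_e: dict[str, np.ndarray] = {}

    c_s = condition.to_numpy(dtype=float)
    for tad in tads:
        a_t = rng.normal(0.0, config.tad_activity_sd)
        tad_activity[tad.id] = a_t
        is_de = rng.random() < config.de_fraction
        pattern: str | None = None
        if is_de:
            pattern = PATTERNS[rng.choice(4, p=np.asarray(config.pattern_mixture))]
        tad_pattern[tad.id] = pattern

        p_feats = _place_features(rng, tad, config.promoters_per_tad, PROMOTER_WIDTH, "prom")
        e_feats = _place_features(rng, tad, config.enhancers_per_tad, ENHANCER_WIDTH, "enh")
        proms.extend(p_feats)
        enhs.extend(e_feats)

        for feats, rows, slot in ((p_feats, rows_p, 0), (e_feats, rows_e, 1)):
            for feat in feats:
                b_f = rng.normal(config.feature_baseline_mean, config.feature_baseline_sd)
                g_f = _SIGN[pattern[slot]] * config.effect_size if pattern else 0.0
                baselines[feat.id] = b_f
                effects[feat.id] = g_f
                eps = rng.normal(0.0, config.noise_sd, size=n_samples)
                log2_expr = b_f + a_t + g_f * c_s + eps
                counts = np.rint(np.exp2(log2_expr)).astype(np.int64)
                rows[feat.id] = np.maximum(counts, 0)

    prom_counts = pd.DataFrame.from_dict(rows_p, orient="index", columns=samples)
    enh_counts = pd.DataFrame.from_dict(rows_e, orient="index", columns=samples)
    prom_counts.index.name = enh_counts.index.name = "feature_id"

    return SimResult(
        tads=tads,
        promoters=IntervalSet(proms).normalize(),
        enhancers=IntervalSet(enhs).normalize(),
        prom_counts=prom_counts,
        enh_counts=enh_counts,
        condition=condition,
        truth=SimTruth(tad_activity, tad_pattern, baselines, effects),
    )


def perturb_tads(
    tads: TadSet,
    boundary_sd: float,
    seed: int,
    min_length: int = 1000,
    drop_fraction: float = 0.0,
) -> TadSet:
    """Synthetic second TAD annotation: jitter each internal boundary by a
    rounded Normal(0, boundary_sd) offset (order and disjointness preserved),
    then drop a random ``drop_fraction`` of TADs.

    Emulates the disagreement between two independently derived TAD sets:
    jitter shifts shared boundaries, dropped TADs become tissue-specific on
    the unperturbed side and pull the base-level Jaccard below 1.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0,1)")
    rng = np.random.default_rng(seed)
    new_ivs: list[GenomicInterval] = []
    for chrom, ivs in sorted(tads.intervals.by_chrom().items()):
        # jitter the shared boundaries, clamped to keep every TAD >= min_length
        bounds = [ivs[0].start] + [iv.end for iv in ivs]
        for k in range(1, len(bounds) - 1):
            lo = bounds[k - 1] + min_length
            hi = bounds[k + 1] - min_length
            jit = bounds[k] + int(round(rng.normal(0.0, boundary_sd)))
            bounds[k] = min(max(jit, lo), hi)
        for k in range(len(ivs)):
            if drop_fraction > 0 and rng.random() < drop_fraction:
                continue
            new_ivs.append(GenomicInterval(chrom, bounds[k], bounds[k + 1]))
    return TadSet(IntervalSet(new_ivs).normalize())


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def naive_de(counts: pd.DataFrame, condition: pd.Series) -> pd.DataFrame:
    """Two-sample t-test DE on log2(count+1), BH-adjusted across all features.

    ``counts`` is feature x sample; ``condition`` maps sample -> {0,1} with
    >=2 samples per condition. log2fc is condition 1 minus condition 0.
    Features identical in both conditions get p=1; a zero-variance split with
    unequal means gets p=0 (degenerate t).
    Returns columns feature_id, log2fc, pvalue, fdr.
    """
    condition = condition.reindex(counts.columns)
    if condition.isna().any():
        raise ValueError("condition labels missing for some samples")
    g0 = counts.columns[condition == 0]
    g1 = counts.columns[condition == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("naive_de needs >=2 samples per condition")
    log = np.log2(counts.to_numpy(dtype=float) + 1.0)
    idx0 = [counts.columns.get_loc(c) for c in g0]
    idx1 = [counts.columns.get_loc(c) for c in g1]
    x0, x1 = log[:, idx0], log[:, idx1]
    log2fc = x1.mean(axis=1) - x0.mean(axis=1)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant features are legitimate inputs; their t is handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        tres = stats.ttest_ind(x1, x0, axis=1)
    pvals = np.asarray(tres.pvalue, dtype=float)
    nan_mask = np.isnan(pvals)
    pvals[nan_mask & (log2fc == 0)] = 1.0
    pvals[nan_mask & (log2fc != 0)] = 0.0
    return pd.DataFrame(
        {
            "feature_id": counts.index.to_numpy(),
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        }
    )
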