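"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the implementation's code paths: interval
operations are checked base by base on a small toy genome, rank statistics
by explicit enumeration, and BH by a literal step-up transcription.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from tadlink.intervals import GenomicInterval, IntervalSet

# ---------------------------------------------------------------- oracles


def cover_bases(iset) -> set[tuple[str, int]]:
    """Per-base membership of an interval set's cover."""
    bases: set[tuple[str, int]] = set()
    for iv in iset:
        for pos in range(iv.start, iv.end):
            bases.add((iv.chrom, pos))
    return bases


def jaccard_oracle(a, b) -> float:
    ca, cb = cover_bases(a), cover_bases(b)
    union = ca | cb
    return len(ca & cb) / len(union) if union else 0.0


def theil_sen_oracle(x, y) -> tuple[float, float]:
    slopes = [
        (y[j] - y[i]) / (x[j] - x[i])
        for i in range(len(x))
        for j in range(i + 1, len(x))
        if x[j] != x[i]
    ]
    slope = float(np.median(slopes))
    intercept = float(np.median([yi - slope * xi for xi, yi in zip(x, y)]))
    return slope, intercept


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def ranks_average(v) -> list[float]:
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    return pearson_oracle(ranks_average(x), ranks_average(y))


def kendall_tau_b_oracle(x, y) -> float:
    n = len(x)
    concordant = discordant = 0
    tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    return (concordant - discordant) / math.sqrt((n0 - tx) * (n0 - ty))


def slr_oracle(x, y) -> tuple[float, float]:
    """Least squares via the normal equations."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(a * a for a in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    return slope, (sy - slope * sx) / n


def bh_oracle(p) -> list[float]:
    """Literal step-up: sort ascending, q_i = min_{j>=i} p_j*m/j, restore order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def random_interval_set(
    rand: random.Random, n: int, genome_length: int = 10_000, chroms=("chr1", "chr2")
) -> IntervalSet:
    """Random small interval set over a toy genome (may overlap freely)."""
    ivs = []
    for k in range(n):
        chrom = rand.choice(chroms)
        start = rand.randrange(0, genome_length - 1)
        end = rand.randrange(start + 1, min(start + 1 + rand.randrange(1, 500), genome_length) + 1)
        ivs.append(GenomicInterval(chrom, start, end, id=f"iv{k}"))
    return IntervalSet(ivs).normalize()


def random_disjoint_tads(
    rand: random.Random, n_per_chrom: int, genome_length: int = 10_000, chroms=("chr1",)
):
    """Random disjoint TAD-like tiling with gaps over a toy genome."""
    from tadlink.consensus import TadSet

    ivs = []
    for chrom in chroms:
        cuts = sorted(rand.sample(range(1, genome_length), 2 * n_per_chrom))
        for k in range(n_per_chrom):
            lo, hi = cuts[2 * k], cuts[2 * k + 1]
            if hi > lo:
                ivs.append(GenomicInterval(chrom, lo, hi))
    return TadSet(IntervalSet(ivs).normalize())
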