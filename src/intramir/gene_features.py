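"""Structural gene features and the rank-based cohort comparisons.

Features per gene: total genomic length, intron count, UTR lengths,
AU-rich element (ARE) content of the 3'-UTR — the AUUUA pentamer counted
at every (possibly overlapping) position and normalized per kb — and
5'-UTR GC content. Non-coding transcripts carry no UTR-dependent features
(``None``, excluded from statistics) rather than zeros.

Cohort machinery: chromosome/strand-matched control sampling, 3'-UTR
length-matched resampling sets, Mann-Whitney U (exact by enumeration for
small samples, tie-corrected normal approximation otherwise), and
Kruskal-Wallis with Bonferroni-corrected post-hoc pairwise tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GeneModel, derive_utr_lengths

logger = logging.getLogger(__name__)

EXACT_MWU_MAX_N = 12

FEATURE_NAMES = (
    "total_length",
    "n_introns",
    "utr5_len",
    "utr3_len",
    "are_count",
    "are_per_kb",
    "utr5_gc",
)

_RNA_OK = set("ACGUN")


def count_are(seq: str) -> int:
    """Occurrences of the ARE pentamer AUUUA, overlapping positions counted."""
    bad = set(seq) - _RNA_OK
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    count = 0
    pos = seq.find("AUUUA")
    while pos != -1:
        count += 1
        pos = seq.find("AUUUA", pos + 1)
    return count


def gc_fraction(seq: str) -> float:
    """(G + C) / length of a normalized RNA sequence."""
    bad = set(seq) - _RNA_OK
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    if not seq:
        raise ValueError("empty sequence: GC fraction undefined")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class GeneFeatureRecord:
    gene_id: str
    total_length: int
    n_introns: int
    utr5_len: int | None = None
    utr3_len: int | None = None
    are_count: int | None = None
    are_per_kb: float | None = None
    utr5_gc: float | None = None


def compute_features(gene: GeneModel) -> GeneFeatureRecord:
    """All structural features for one gene; missing pieces stay ``None``."""
    utr5_len = utr3_len = are_count = are_per_kb = utr5_gc = None
    if gene.is_coding:
        utr5_len, utr3_len = derive_utr_lengths(gene)
        if gene.utr3_sequence is not None:
            are_count = count_are(gene.utr3_sequence)
            if utr3_len > 0:
                are_per_kb = are_count * 1000.0 / utr3_len
        if gene.utr5_sequence:
            utr5_gc = gc_fraction(gene.utr5_sequence)
    return GeneFeatureRecord(
        gene_id=gene.gene_id,
        total_length=gene.total_length,
        n_introns=gene.n_introns,
        utr5_len=utr5_len,
        utr3_len=utr3_len,
        are_count=are_count,
        are_per_kb=are_per_kb,
        utr5_gc=utr5_gc,
    )


def features_frame(genes: Iterable[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame([compute_features(g).__dict__ for g in genes])


# ---------------------------------------------------------------------------
# cohort sampling


def sample_matched_controls(
    hosts: Sequence[GeneModel],
    universe: Sequence[GeneModel],
    k_per_host: int = 10,
    seed: int | np.random.Generator | None = None,
) -> list[GeneModel]:
    """Controls matching the hosts' chromosome/strand distribution.

    Per (chrom, strand) stratum, exactly ``k_per_host`` times the host
    count is drawn from non-host universe genes; strata short of
    candidates are sampled with replacement (logged).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    host_ids = {g.gene_id for g in hosts}
    candidates: dict[tuple[str, str], list[GeneModel]] = {}
    for g in universe:
        if g.gene_id in host_ids:
            continue
        candidates.setdefault((g.interval.chrom, g.interval.strand), []).append(g)
    strata: dict[tuple[str, str], int] = {}
    for g in hosts:
        key = (g.interval.chrom, g.interval.strand)
        strata[key] = strata.get(key, 0) + 1
    controls: list[GeneModel] = []
    for key in sorted(strata):
        need = strata[key] * k_per_host
        pool = candidates.get(key, [])
        if not pool:
            raise ValueError(f"no control candidates in stratum {key}")
        if len(pool) < need:
            logger.warning(
                "stratum %s has %d candidates for %d slots; sampling with replacement",
                key, len(pool), need,
            )
            idx = rng.choice(len(pool), size=need, replace=True)
        else:
            idx = rng.choice(len(pool), size=need, replace=False)
        controls.extend(pool[i] for i in idx)
    return controls


def sample_utr3_matched_sets(
    hosts: Sequence[GeneModel],
    universe: Sequence[GeneModel],
    n_sets: int = 1000,
    seed: int | np.random.Generator | None = None,
    n_bins: int = 20,
    p_threshold: float = 0.05,
    max_attempts: int = 50,
) -> list[list[GeneModel]]:
    """Gene sets matching the hosts' 3'-UTR length distribution.

    Stratified over ``n_bins`` quantile bins of host 3'-UTR length; each
    accepted set shows no significant Mann-Whitney difference to the hosts
    (p > ``p_threshold``), resampling up to ``max_attempts`` times.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    host_lens = np.array([_require_utr3(g) for g in hosts], dtype=float)
    uni = [(g, _require_utr3(g)) for g in universe]
    edges = np.quantile(host_lens, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    host_bins = np.searchsorted(edges, host_lens, side="right") - 1
    pools: dict[int, list[tuple[GeneModel, float]]] = {}
    for g, length in uni:
        b = int(np.searchsorted(edges, length, side="right")) - 1
        pools.setdefault(b, []).append((g, length))
    bin_counts = {int(b): int(n) for b, n in zip(*np.unique(host_bins, return_counts=True))}
    for b in bin_counts:
        if b not in pools or not pools[b]:
            raise ValueError(f"no universe candidates in 3'-UTR length bin {b}")
    sets: list[list[GeneModel]] = []
    for _ in range(n_sets):
        best = None
        for attempt in range(max_attempts):
            chosen: list[GeneModel] = []
            lens: list[float] = []
            for b, n in sorted(bin_counts.items()):
                pool = pools[b]
                replace = len(pool) < n
                idx = rng.choice(len(pool), size=n, replace=replace)
                for i in idx:
                    chosen.append(pool[i][0])
                    lens.append(pool[i][1])
            p = mwu_test(lens, host_lens)
            if best is None or p > best[0]:
                best = (p, chosen)
            if p > p_threshold:
                break
        else:
            logger.warning(
                "matched set kept with MWU p=%.3g after %d attempts",
                best[0], max_attempts,
            )
        sets.append(best[1])
    return sets


def _require_utr3(g: GeneModel) -> int:
    utr3 = derive_utr_lengths(g)[1] if g.is_coding else None
    if utr3 is None:
        raise ValueError(f"{g.gene_id}: 3'-UTR length undefined (non-coding)")
    return utr3


# ---------------------------------------------------------------------------
# rank statistics


def mwu_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by enumeration of all label assignments (midranks, so ties are
    handled) when n_a + n_b <= 12, tie-corrected normal approximation with
    continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size + b.size <= EXACT_MWU_MAX_N:
        return _mwu_exact(a, b)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


def _mwu_exact(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = a.size
    n = pooled.size
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    mean_u = na * (n - na) / 2
    dev_obs = abs(u_obs - mean_u)
    extreme = total = 0
    for idx in combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-9:
            extreme += 1
    return extreme / total


@dataclass
class KruskalResult:
    statistic: float
    p_value: float
    cutoff: float
    pairwise: list[tuple[int, int, float, bool]]  # (i, j, p, significant)


def kruskal_pairwise(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> KruskalResult:
    """Kruskal-Wallis plus Bonferroni-corrected pairwise Mann-Whitney tests.

    For three groups the cut-off is alpha/3 ≈ 0.016.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {i} is empty")
    stat, p = stats.kruskal(*groups)
    pairs = list(combinations(range(len(groups)), 2))
    cutoff = alpha / len(pairs)
    pairwise = [
        (i, j, (pij := mwu_test(groups[i], groups[j])), pij < cutoff)
        for i, j in pairs
    ]
    return KruskalResult(float(stat), float(p), cutoff, pairwise)


@dataclass(frozen=True)
class FeatureComparison:
    feature: str
    median_a: float
    range_a: tuple[float, float]
    n_a: int
    median_b: float
    range_b: tuple[float, float]
    n_b: int
    ratio: float | None
    p_value: float
    test: str = "mann-whitney-u"
    n_excluded_a: int = 0
    n_excluded_b: int = 0


def compare_features(
    group_a: Sequence[GeneFeatureRecord],
    group_b: Sequence[GeneFeatureRecord],
    feature: str,
) -> FeatureComparison:
    """Median/range/ratio + Mann-Whitney p for one feature across cohorts."""
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}")
    va = [getattr(r, feature) for r in group_a]
    vb = [getattr(r, feature) for r in group_b]
    a = [v for v in va if v is not None and not (isinstance(v, float) and math.isnan(v))]
    b = [v for v in vb if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not a or not b:
        raise ValueError(f"feature {feature!r} undefined for an entire group")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    ratio = med_a / med_b if med_b > 0 else None
    return FeatureComparison(
        feature=feature,
        median_a=med_a,
        range_a=(float(min(a)), float(max(a))),
        n_a=len(a),
        median_b=med_b,
        range_b=(float(min(b)), float(max(b))),
        n_b=len(b),
        ratio=ratio,
        p_value=mwu_test(a, b),
        n_excluded_a=len(va) - len(a),
        n_excluded_b=len(vb) - len(b),
    )


def comparison_table(
    group_a: Sequence[GeneFeatureRecord],
    group_b: Sequence[GeneFeatureRecord],
    features: Sequence[str] = FEATURE_NAMES,
    label_a: str = "host",
    label_b: str = "control",
) -> pd.DataFrame:
    """Feature-comparison report shaped like a median/range/ratio/p table."""
    rows = []
    for f in features:
        c = compare_features(group_a, group_b, f)
        rows.append(
            {
                "feature": f,
                f"median_{label_a}": c.median_a,
                f"range_{label_a}": f"[{c.range_a[0]:g}-{c.range_a[1]:g}]",
                f"median_{label_b}": c.median_b,
                f"range_{label_b}": f"[{c.range_b[0]:g}-{c.range_b[1]:g}]",
                "ratio": c.ratio,
                "p_value": c.p_value,
            }
        )
    return pd.DataFrame(rows)
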