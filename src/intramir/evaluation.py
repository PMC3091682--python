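"""Evaluation utilities: ROC/AUC against fold changes, host-target
correlation contrasts between sample groups, and conservation proportion
tests.

The AUC of a prediction stratum is computed by the rank-sum identity
(concordant pairs + half ties over all positive x negative pairs); fold
changes are negated before scoring because predicted targets are expected
to be repressed. Conservation comparisons use the 2-sample test for
equality of proportions with continuity correction (Yates-corrected χ² on
the 2x2 table, as in R's ``prop.test``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .target_integration import AgreementMatrix

logger = logging.getLogger(__name__)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC = (concordant + 0.5 x tied) / (n_pos x n_neg), via midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class RocResult:
    stratum: str
    auc: float
    n_pos: int
    n_neg: int


def auc_by_agreement(
    fold_changes: Mapping[tuple[str, str], float],
    matrix: AgreementMatrix,
    mirnas: Iterable[str],
    levels: Sequence[int] | None = None,
) -> list[RocResult]:
    """Pooled AUC per agreement threshold.

    ``fold_changes`` maps (mirna_id, gene_id) to a measured fold change;
    the instances of all supplied miRNAs are pooled, the binary outcome at
    level k is agreement >= k, and the score is the negated fold change
    (predicted targets are expected to be repressed). Levels with a single
    class are skipped with a warning.
    """
    mirnas = set(mirnas)
    items = [(pair, fc) for pair, fc in fold_changes.items() if pair[0] in mirnas]
    if not items:
        raise ValueError("no measured (miRNA, gene) pairs for the supplied miRNAs")
    scores = np.array([-fc for _, fc in items])
    agreement = np.array([matrix.agreement(*pair) for pair, _ in items])
    if levels is None:
        levels = range(1, matrix.n_sources + 1)
    out: list[RocResult] = []
    for k in levels:
        labels = (agreement >= k).astype(int)
        n_pos = int(labels.sum())
        n_neg = labels.size - n_pos
        if n_pos == 0 or n_neg == 0:
            logger.warning("agreement level %d has a single class; skipped", k)
            continue
        out.append(RocResult(f"agreement>={k}", roc_auc(scores, labels), n_pos, n_neg))
    return out


@dataclass(frozen=True)
class ConservationComparison:
    conserved_a: int
    total_a: int
    conserved_b: int
    total_b: int
    chi2: float
    p_value: float


def prop_test_cc(
    conserved_a: int, total_a: int, conserved_b: int, total_b: int
) -> ConservationComparison:
    """2-sample equality of proportions with continuity correction."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("group totals must be positive")
    if conserved_a > total_a or conserved_b > total_b:
        raise ValueError("conserved count exceeds group total")
    table = np.array(
        [
            [conserved_a, total_a - conserved_a],
            [conserved_b, total_b - conserved_b],
        ]
    )
    # degenerate margins (all or none conserved in both groups): no difference
    if (table.sum(axis=0) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        res = stats.chi2_contingency(table, correction=True)
        chi2, p = float(res.statistic), float(res.pvalue)
    return ConservationComparison(conserved_a, total_a, conserved_b, total_b, chi2, p)


@dataclass(frozen=True)
class CorrelationContrast:
    target: str
    r_n: float
    p_n: float
    r_t: float
    p_t: float
    pattern: str


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def correlation_contrast(
    expr: pd.DataFrame,
    host: str,
    targets: Iterable[str],
    groups: Mapping[str, str],
    method: str = "pearson",
    alpha: float = 0.05,
) -> list[CorrelationContrast]:
    """Host-target correlation in group "N" vs group "T", per target.

    ``expr`` is genes x samples; ``groups`` maps sample name to "N" or
    "T". A target is labeled ``negative_in_N_lost_in_T`` when its
    correlation with the host is significantly negative in N and either
    non-significant or significantly positive in T; ``more_negative_in_N``
    when r_N < r_T without meeting that pattern; ``other`` otherwise.
    Targets with constant expression are flagged ``undefined``.
    """
    if host not in expr.index:
        raise ValueError(f"host {host!r} absent from expression matrix")
    samples_n = [s for s in expr.columns if groups.get(s) == "N"]
    samples_t = [s for s in expr.columns if groups.get(s) == "T"]
    if len(samples_n) < 3 or len(samples_t) < 3:
        raise ValueError("need >= 3 samples per group")
    host_n = expr.loc[host, samples_n].to_numpy(float)
    host_t = expr.loc[host, samples_t].to_numpy(float)
    out: list[CorrelationContrast] = []
    for target in targets:
        if target not in expr.index:
            logger.warning("target %s absent from expression matrix; skipped", target)
            continue
        r_n, p_n = _corr(host_n, expr.loc[target, samples_n].to_numpy(float), method)
        r_t, p_t = _corr(host_t, expr.loc[target, samples_t].to_numpy(float), method)
        if np.isnan(r_n) or np.isnan(r_t):
            pattern = "undefined"
        elif r_n < 0 and p_n < alpha and (p_t >= alpha or (r_t > 0 and p_t < alpha)):
            pattern = "negative_in_N_lost_in_T"
        elif r_n < r_t:
            pattern = "more_negative_in_N"
        else:
            pattern = "other"
        out.append(CorrelationContrast(target, r_n, p_n, r_t, p_t, pattern))
    return out


def contrast_frame(
    contrasts: list[CorrelationContrast], host: str
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "host": host,
                "target": c.target,
                "r_N": c.r_n,
                "p_N": c.p_n,
                "r_T": c.r_t,
                "p_T": c.p_t,
                "pattern": c.pattern,
            }
            for c in contrasts
        ]
    )
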