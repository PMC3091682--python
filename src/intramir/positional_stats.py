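"""Positional statistics for intronic miRNAs.

The expected intron-position distribution weights every intron ordinal by
total intron length across host genes:

    E_k = (sum of lengths of intron k over hosts having one)
          / (sum of all intron lengths over hosts),

so ordinals that are both frequent and long attract more expectation.
Observed placements are compared to it by Pearson goodness-of-fit χ²,
either over all ordinals or truncated (renormalized) to ordinals 1–5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GeneModel, derive_introns
from .classification import MirnaPlacement


@dataclass
class IntronPositionDistribution:
    """Observed counts and length-weighted expected proportions per ordinal."""

    observed: dict[int, int]
    expected: dict[int, float]
    total_intron_length: int

    def to_frame(self) -> pd.DataFrame:
        ordinals = sorted(set(self.observed) | set(self.expected))
        total_obs = sum(self.observed.values())
        return pd.DataFrame(
            {
                "intron_ordinal": ordinals,
                "observed": [self.observed.get(k, 0) for k in ordinals],
                "expected_proportion": [self.expected.get(k, 0.0) for k in ordinals],
                "expected_count": [
                    self.expected.get(k, 0.0) * total_obs for k in ordinals
                ],
            }
        )


def expected_intron_distribution(
    hosts: Iterable[GeneModel],
) -> IntronPositionDistribution:
    """Length-weighted expected proportion of miRNAs per intron ordinal."""
    hosts = list(hosts)
    zero = [g.gene_id for g in hosts if g.n_introns == 0]
    if zero:
        raise ValueError(f"hosts without introns: {zero}")
    if not hosts:
        raise ValueError("no host genes supplied")
    length_by_ordinal: dict[int, int] = {}
    total = 0
    for gene in hosts:
        for k, intron in enumerate(derive_introns(gene), start=1):
            length_by_ordinal[k] = length_by_ordinal.get(k, 0) + len(intron)
            total += len(intron)
    expected = {k: v / total for k, v in sorted(length_by_ordinal.items())}
    return IntronPositionDistribution(
        observed={}, expected=expected, total_intron_length=total
    )


def observed_intron_counts(placements: Iterable[MirnaPlacement]) -> dict[int, int]:
    """Number of intronic miRNAs per intron ordinal."""
    counts: dict[int, int] = {}
    for p in placements:
        if p.mirna_class == "intronic":
            counts[p.intron_ordinal] = counts.get(p.intron_ordinal, 0) + 1
    return counts


def chisq_gof(
    observed: Sequence[float], expected_probs: Sequence[float]
) -> tuple[float, float]:
    """Pearson goodness-of-fit χ² with df = len - 1, upper-tail p."""
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != probs.shape:
        raise ValueError("observed and expected vectors differ in length")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"expected probabilities sum to {probs.sum()}, not 1")
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed total must be positive")
    if np.any((probs == 0) & (obs > 0)):
        raise ValueError("expected cell is 0 where observed count is positive")
    keep = probs > 0
    stat, p = stats.chisquare(obs[keep], f_exp=probs[keep] * total)
    # df must reflect the full support even if some zero-prob/zero-obs cells drop
    df = len(obs) - 1
    p = float(stats.chi2.sf(stat, df))
    return float(stat), p


def strand_bias_test(n_same: int, n_opposite: int) -> tuple[float, float]:
    """χ² test of the intragenic strand split against equal proportions."""
    if n_same + n_opposite <= 0:
        raise ValueError("no intragenic miRNAs")
    return chisq_gof([n_same, n_opposite], [0.5, 0.5])


@dataclass(frozen=True)
class FirstFiveMetrics:
    fraction_hosts_first5: float
    fraction_mirnas_first5: float
    chi2: float
    p_value: float


def first_five_metrics(
    placements: Iterable[MirnaPlacement],
    hosts: Mapping[str, GeneModel],
    n_first: int = 5,
) -> FirstFiveMetrics:
    """5'-bias summary over the first ``n_first`` introns.

    Host fraction: hosts of intronic miRNAs with at least one miRNA in
    ordinals 1..n_first over all hosts of intronic miRNAs; miRNA fraction
    analogous. The χ² compares observed counts in ordinals 1..n_first with
    the expected distribution renormalized to that support.
    """
    intronic = [p for p in placements if p.mirna_class == "intronic"]
    if not intronic:
        raise ValueError("no intronic placements")
    host_ids = {p.host_gene_id for p in intronic}
    hosts_first5 = {
        p.host_gene_id for p in intronic if p.intron_ordinal <= n_first
    }
    frac_hosts = len(hosts_first5) / len(host_ids)
    n_mirnas_first5 = sum(1 for p in intronic if p.intron_ordinal <= n_first)
    frac_mirnas = n_mirnas_first5 / len(intronic)

    dist = expected_intron_distribution(hosts[h] for h in sorted(host_ids))
    probs = np.array([dist.expected.get(k, 0.0) for k in range(1, n_first + 1)])
    if probs.sum() <= 0:
        raise ValueError("expected distribution has no mass in the first introns")
    probs = probs / probs.sum()
    obs = np.array(
        [
            sum(1 for p in intronic if p.intron_ordinal == k)
            for k in range(1, n_first + 1)
        ],
        dtype=float,
    )
    if obs.sum() == 0:
        raise ValueError("no intronic miRNAs within the first introns")
    chi2, p = chisq_gof(obs, probs)
    return FirstFiveMetrics(frac_hosts, frac_mirnas, chi2, p)


def position_report(
    placements: Iterable[MirnaPlacement], hosts: Mapping[str, GeneModel]
) -> pd.DataFrame:
    """Observed vs expected intron-position table (TSV-ready)."""
    placements = list(placements)
    intronic = [p for p in placements if p.mirna_class == "intronic"]
    if not intronic:
        raise ValueError("no intronic placements")
    host_ids = sorted({p.host_gene_id for p in intronic})
    dist = expected_intron_distribution(hosts[h] for h in host_ids)
    dist.observed = observed_intron_counts(intronic)
    return dist.to_frame()
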