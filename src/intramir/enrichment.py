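"""Resampling enrichment statistics: pathway target coverage, self-targeting
and hypergeometric gene-set overrepresentation.

For a pathway with gene set S_p, let S_t be the union of predicted targets
(prediction agreement >= 2 by default) of the miRNAs hosted by genes in
S_p. The target coverage is

    C = |S_p ∩ S_t| / |S_p|.

Its null distribution replaces S_p by |S_p| genes sampled without
replacement from the universe; the empirical p-value is the fraction of
1000 resampled coverages C'_i >= C (no smoothing, so p = 0 is reported as
"< 1/n_iter"). Because the random sample only enters through its overlap
with S_t, the null overlap follows the hypergeometric law exactly and is
drawn directly from it. q-values control the FDR (Storey single-λ or
Benjamini-Hochberg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import MirnaPlacement
from .target_integration import AgreementMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set collection: name <tab> description <tab> genes..."""
    collections: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name = fields[0]
            if name in collections:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            collections[name] = set(fields[2:])
    return collections


def write_gmt(collections: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collections.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def target_coverage(s_p: set[str], s_t: set[str]) -> float:
    """C = |S_p ∩ S_t| / |S_p|."""
    if not s_p:
        raise ValueError("pathway gene set S_p is empty")
    return len(s_p & s_t) / len(s_p)


@dataclass
class CoverageResult:
    pathway_id: str
    coverage: float
    null_values: np.ndarray
    p: float
    q: float | None = None
    n_iter: int = 0
    seed: int | None = None


def coverage_pvalue(
    c_obs: float,
    s_t: set[str],
    universe: set[str],
    size: int,
    n_iter: int = 1000,
    seed: int | np.random.Generator | None = None,
    pathway_id: str = "",
    smoothed: bool = False,
) -> CoverageResult:
    """Empirical p for observing coverage >= ``c_obs`` under random gene sets.

    Null coverages are |sample ∩ S_t| / size for ``n_iter`` samples of
    ``size`` genes drawn without replacement from ``universe``; the overlap
    count is drawn from its exact hypergeometric distribution. With
    ``smoothed`` the (+1)/(n+1) estimator replaces the plain fraction.
    """
    if size > len(universe):
        raise ValueError(f"sample size {size} exceeds universe {len(universe)}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_good = len(universe & s_t)
    n_bad = len(universe) - n_good
    overlaps = rng.hypergeometric(n_good, n_bad, size, size=n_iter)
    null = overlaps / size
    hits = int(np.sum(null >= c_obs - _EPS))
    p = (hits + 1) / (n_iter + 1) if smoothed else hits / n_iter
    return CoverageResult(
        pathway_id=pathway_id,
        coverage=c_obs,
        null_values=null,
        p=float(p),
        n_iter=n_iter,
        seed=seed if isinstance(seed, int) else None,
    )


def fdr_qvalues(p_values: Sequence[float], method: str = "storey") -> np.ndarray:
    """q-values from p-values: BH step-up or Storey with the single-λ=0.5 π₀."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError(f"unknown FDR method {method!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    bh = np.empty(m)
    bh[order] = np.minimum(ranked, 1.0)
    if method == "bh":
        return bh
    pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5)
    return np.minimum(pi0 * bh, 1.0)


# ---------------------------------------------------------------------------
# pathway coverage analysis


@dataclass
class PathwayTargetSets:
    pathway_id: str
    s_p: set[str]
    hosts_in_pathway: set[str]
    mirnas: set[str]
    s_t: set[str]


def build_pathway_target_sets(
    pathways: Mapping[str, set[str]],
    placements: Iterable[MirnaPlacement],
    matrix: AgreementMatrix,
    agreement_k: int = 2,
) -> list[PathwayTargetSets]:
    """Link each pathway to its hosted miRNAs and their predicted targets.

    Only pathways containing at least one host gene of an intragenic miRNA
    are returned (the others have no associated miRNAs).
    """
    host_to_mirnas: dict[str, set[str]] = {}
    for p in placements:
        if p.host_gene_id is not None:
            host_to_mirnas.setdefault(p.host_gene_id, set()).add(p.mirna_id)
    targets_by_mirna: dict[str, set[str]] = {}
    for (mirna, gene), c in matrix.counts.items():
        if c >= agreement_k:
            targets_by_mirna.setdefault(mirna, set()).add(gene)
    out = []
    for pid, s_p in pathways.items():
        hosts = {g for g in s_p if g in host_to_mirnas}
        if not hosts:
            continue
        mirnas = set().union(*(host_to_mirnas[h] for h in hosts))
        s_t = set().union(*(targets_by_mirna.get(m, set()) for m in mirnas))
        out.append(PathwayTargetSets(pid, set(s_p), hosts, mirnas, s_t))
    return out


def coverage_analysis(
    pathways: Mapping[str, set[str]],
    placements: Iterable[MirnaPlacement],
    matrix: AgreementMatrix,
    universe: set[str],
    agreement_k: int = 2,
    n_iter: int = 1000,
    seed: int | None = None,
    fdr_method: str = "storey",
    smoothed: bool = False,
) -> pd.DataFrame:
    """Target coverage, empirical p and q-value for every hosted pathway."""
    linked = build_pathway_target_sets(pathways, placements, matrix, agreement_k)
    rng = np.random.default_rng(seed)
    results = []
    for pts in sorted(linked, key=lambda x: x.pathway_id):
        c = target_coverage(pts.s_p, pts.s_t)
        res = coverage_pvalue(
            c, pts.s_t, universe, len(pts.s_p), n_iter=n_iter, seed=rng,
            pathway_id=pts.pathway_id, smoothed=smoothed,
        )
        results.append((pts, res))
    if not results:
        return pd.DataFrame(
            columns=["pathway", "host_genes", "n_genes", "coverage", "p", "q"]
        )
    q = fdr_qvalues([r.p for _, r in results], method=fdr_method)
    df = pd.DataFrame(
        {
            "pathway": [pts.pathway_id for pts, _ in results],
            "host_genes": [";".join(sorted(pts.hosts_in_pathway)) for pts, _ in results],
            "n_genes": [len(pts.s_p) for pts, _ in results],
            "coverage": [r.coverage for _, r in results],
            "p": [r.p for _, r in results],
            "q": q,
        }
    )
    return df.sort_values(["q", "p", "pathway"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# self-targeting


@dataclass
class SelfTargetResult:
    observed: int
    host_count: int
    null_counts: np.ndarray
    p: float
    n_iter: int
    mode: str


def self_target_set(
    placements: Iterable[MirnaPlacement], matrix: AgreementMatrix, k: int = 2
) -> tuple[set[str], set[str]]:
    """miRNAs predicted (agreement >= k) to target their own host, and hosts."""
    mirnas: set[str] = set()
    hosts: set[str] = set()
    for p in placements:
        if p.host_gene_id is None:
            continue
        if matrix.agreement(p.mirna_id, p.host_gene_id) >= k:
            mirnas.add(p.mirna_id)
            hosts.add(p.host_gene_id)
    return mirnas, hosts


def self_target_pvalue(
    observed: int,
    placements: Iterable[MirnaPlacement],
    matrix: AgreementMatrix,
    universe_mode: str = "predicted_targets",
    n_iter: int = 1000,
    seed: int | np.random.Generator | None = None,
    k: int = 2,
    matched_sets: Sequence[Sequence] | None = None,
) -> SelfTargetResult:
    """Null distribution of the self-target count under host exchange.

    Each iteration replaces every host gene by a random surrogate and
    recounts miRNAs whose pair with the surrogate reaches agreement >= k.
    ``predicted_targets`` draws surrogates without replacement from the
    non-redundant set of predicted targets of the hosted miRNAs;
    ``utr3_matched`` walks through caller-supplied 3'-UTR-matched gene
    sets (one per iteration, cycled), assigning hosts to distinct random
    members.
    """
    placements = [p for p in placements if p.host_gene_id is not None]
    hosts = sorted({p.host_gene_id for p in placements})
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if universe_mode == "predicted_targets":
        hosted_mirnas = {p.mirna_id for p in placements}
        pool = sorted(
            {
                gene
                for (mirna, gene), c in matrix.counts.items()
                if c >= k and mirna in hosted_mirnas
            }
        )
        if len(pool) < len(hosts):
            raise ValueError("predicted-target universe smaller than host set")
        draw = lambda i: rng.choice(pool, size=len(hosts), replace=False)
    elif universe_mode == "utr3_matched":
        if not matched_sets:
            raise ValueError("utr3_matched mode requires matched_sets")
        pools = [
            sorted(g.gene_id if hasattr(g, "gene_id") else g for g in s)
            for s in matched_sets
        ]
        def draw(i: int):
            pool = pools[i % len(pools)]
            if len(pool) < len(hosts):
                raise ValueError("matched set smaller than host set")
            return rng.choice(pool, size=len(hosts), replace=False)
    else:
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    null = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        surrogate = dict(zip(hosts, draw(i)))
        null[i] = sum(
            1
            for p in placements
            if matrix.agreement(p.mirna_id, surrogate[p.host_gene_id]) >= k
        )
    p = float(np.mean(null >= observed))
    host_count = len({p_.host_gene_id for p_ in placements
                      if matrix.agreement(p_.mirna_id, p_.host_gene_id) >= k})
    return SelfTargetResult(observed, host_count, null, p, n_iter, universe_mode)


# ---------------------------------------------------------------------------
# hypergeometric overrepresentation


def hypergeom_enrichment(
    query: set[str],
    categories: Mapping[str, set[str]],
    universe: set[str],
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric P(X >= overlap) per category, with FDR."""
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    m = len(universe)
    n = len(query)
    rows = []
    for name, genes in categories.items():
        inside = genes & universe
        dropped = len(genes) - len(inside)
        if dropped:
            logger.warning("category %s: %d genes outside universe dropped",
                           name, dropped)
        k_cat = len(inside)
        overlap = len(inside & query)
        p = float(stats.hypergeom.sf(overlap - 1, m, k_cat, n)) if overlap > 0 else 1.0
        rows.append({"category": name, "size": k_cat, "overlap": overlap, "p": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = fdr_qvalues(df["p"].to_numpy(), method=fdr_method)
    return df.sort_values(["p", "category"], kind="stable").reset_index(drop=True)
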