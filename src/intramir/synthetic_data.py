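"""Synthetic input bundles with ground-truth-annotated, plantable effects.

The generator emulates the statistical structure the analysis assumes so
every stage can be exercised and validated without external downloads:

* gene models with negative-binomial intron counts and log-normal lengths,
  host genes longer (median total-length ratio 2.9 by default) with more
  introns (median 13 vs 8);
* intronic miRNA placement with a 5' positional bias — intron k is chosen
  with weight proportional to ``length x exp(-beta (k-1))`` — and strand
  concordance 0.85;
* host 3'-UTRs longer (ratio 1.4) and denser in AUUUA pentamers (ratio
  2.0); ARE counts are planted exactly (accidental motif hits are
  scrubbed), so motif density reflects the configured rates;
* six conditionally independent prediction catalogs plus a validation
  database generated from a latent true-target set, so prediction
  agreement concentrates on true targets;
* pathway gene sets with optional planted coverage enrichment (a fraction
  gamma of a hosted miRNA's true targets is redirected into its host's
  pathway);
* a two-group expression matrix with planted host-target correlations
  (rho_normal vs rho_tumor), a host-miRNA conservation table and pooled
  fold-change measurements for ROC evaluation.

Everything is reproducible from ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    MirnaLocus,
    derive_introns,
    write_gene_models,
    write_mirna_gff,
    write_utr_fasta,
)
from .target_integration import DEFAULT_SUPPORT_FILTER, PredictionSource

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGU"))
_MOTIF = np.array([0, 3, 3, 3, 0])  # AUUUA over the ACGU alphabet


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults mirror the printed study structure."""

    seed: int = 0
    # genome
    n_genes: int = 1000
    n_chromosomes: int = 5
    host_fraction: float = 0.25
    noncoding_fraction: float = 0.05
    # intron counts (negative binomial) and gene lengths (log-normal)
    intron_count_mean: float = 8.0
    host_intron_count_mean: float = 13.0
    intron_count_size: float = 4.0
    length_meanlog: float = float(np.log(25_000))
    length_sdlog: float = 0.8
    host_length_ratio: float = 2.9
    # UTR/CDS lengths (log-normal)
    utr5_meanlog: float = float(np.log(280))
    utr5_sdlog: float = 0.8
    utr3_meanlog: float = float(np.log(870))
    utr3_sdlog: float = 0.7
    host_utr3_ratio: float = 1.4
    cds_meanlog: float = float(np.log(1300))
    cds_sdlog: float = 0.5
    # ARE planting (pentamers per kb of 3'-UTR) and base composition
    are_per_kb: float = 1.0
    host_are_per_kb: float = 2.0
    utr5_gc: float = 0.58
    utr3_gc: float = 0.42
    # miRNAs
    n_mirnas: int = 700
    class_probs: tuple[float, float, float] = (0.426, 0.053, 0.521)
    same_strand_prob: float = 0.85
    positional_bias_beta: float = 0.15
    mirna_len_min: int = 60
    mirna_len_max: int = 120
    # target predictions
    n_methods: int = 6
    method_sensitivity: tuple[float, ...] = (0.8, 0.75, 0.7, 0.65, 0.6, 0.5)
    fp_per_mirna: int = 25
    true_targets_per_mirna: float = 30.0
    self_target_fraction: float = 0.2
    validation_fraction: float = 0.05
    # pathways
    n_pathways: int = 40
    pathway_size_min: int = 20
    pathway_size_max: int = 60
    host_pathway_prob: float = 0.9
    n_enriched_pathways: int = 4
    coverage_enrichment_gamma: float = 0.5
    # expression
    n_samples_per_group: int = 30
    rho_normal: float = -0.6
    rho_tumor: float = 0.0
    expr_targets_per_host: int = 5
    # conservation
    conserved_prob_self: float = 0.35
    conserved_prob_nonself: float = 0.245
    # fold-change evaluation
    n_eval_mirnas: int = 5
    n_measured_per_mirna: int = 300
    eval_effect: float = 1.0
    eval_noise_sd: float = 0.6

    def validate(self) -> None:
        probs = [
            self.host_fraction, self.noncoding_fraction, self.same_strand_prob,
            self.self_target_fraction, self.validation_fraction,
            self.host_pathway_prob, self.coverage_enrichment_gamma,
            self.conserved_prob_self, self.conserved_prob_nonself,
            *self.class_probs, *self.method_sensitivity,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if self.positional_bias_beta < 0:
            raise ValueError("positional_bias_beta must be >= 0")
        if len(self.method_sensitivity) != self.n_methods:
            raise ValueError("method_sensitivity must have n_methods entries")
        for name in ("length_sdlog", "utr5_sdlog", "utr3_sdlog", "cds_sdlog"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 10 or self.n_mirnas < 1 or self.n_chromosomes < 1:
            raise ValueError("infeasible genome size configuration")


@dataclass
class SyntheticTruth:
    """Ground-truth record of every planted effect."""

    mirna_class: dict[str, str]
    host: dict[str, str]
    intron_ordinal: dict[str, int]
    same_strand: dict[str, bool]
    true_targets: dict[str, list[str]]
    self_targets: list[str]
    enriched_pathways: list[str]
    expression_pairs: list[tuple[str, str]]
    eval_mirnas: list[str]
    planted: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    annotation: GenomeAnnotation
    utr_sequences: dict[tuple[str, str], str]
    prediction_tables: dict[str, pd.DataFrame]
    validation_table: pd.DataFrame
    sources: list[PredictionSource]
    pathways: dict[str, set[str]]
    expression: pd.DataFrame
    groups: dict[str, str]
    homology: pd.DataFrame
    fold_changes: dict[tuple[str, str], float]
    truth: SyntheticTruth

    @property
    def host_pool(self) -> set[str]:
        return {g for g in self.truth.host.values()}


# ---------------------------------------------------------------------------
# helpers


def _nbinom(rng: np.random.Generator, mean: float, size_param: float) -> int:
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def _split_lengths(
    rng: np.random.Generator, total: int, parts: int, minimum: int
) -> np.ndarray:
    """Split ``total`` into ``parts`` integers each >= ``minimum``."""
    if parts == 1:
        return np.array([total])
    extra = total - minimum * parts
    if extra < 0:
        raise ValueError("total too small for the requested split")
    w = rng.dirichlet(np.ones(parts))
    sizes = minimum + np.floor(w * extra).astype(int)
    sizes[0] += total - sizes.sum()
    return sizes


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _find_motifs(seq: np.ndarray) -> np.ndarray:
    if seq.size < 5:
        return np.array([], dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(seq, 5)
    return np.nonzero((windows == _MOTIF).all(axis=1))[0]


def _plant_ares(rng: np.random.Generator, length: int, count: int) -> np.ndarray:
    """Sequence of ``length`` containing exactly ``count`` AUUUA pentamers."""
    seq = _random_seq(rng, length, gc=0.42)
    count = min(count, length // 5)
    planted: list[int] = []
    for _ in range(count):
        for _attempt in range(200):
            pos = int(rng.integers(0, length - 4))
            if all(abs(pos - q) >= 5 for q in planted):
                planted.append(pos)
                break
    covered = np.zeros(length, dtype=bool)
    for pos in planted:
        seq[pos:pos + 5] = _MOTIF
        covered[pos:pos + 5] = True
    # scrub accidental occurrences so the planted count is exact
    for _ in range(20):
        accidental = [i for i in _find_motifs(seq) if i not in planted]
        if not accidental:
            break
        for i in accidental:
            free = [j for j in range(i, i + 5) if not covered[j]]
            if free:
                seq[free[len(free) // 2]] = 2  # G breaks every window through it
    return seq


def _seq_str(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def _exonic_offset_to_coord(exons: Sequence[GenomicInterval], offset: int) -> int:
    """Genomic coordinate of the 0-based ``offset``-th exonic base."""
    for e in exons:
        if offset < len(e):
            return e.start + offset
        offset -= len(e)
    raise ValueError("offset beyond exonic extent")


# ---------------------------------------------------------------------------
# generation stages


def _build_genes(cfg: SyntheticConfig, rng: np.random.Generator):
    n = cfg.n_genes
    host_pool_idx = set(
        rng.choice(n, size=int(round(cfg.host_fraction * n)), replace=False).tolist()
    )
    min_exon, min_intron = 30, 200
    genes: list[GeneModel] = []
    specs = []
    for i in range(n):
        is_host = i in host_pool_idx
        coding = True if is_host else rng.random() >= cfg.noncoding_fraction
        if is_host:
            n_introns = 1 + _nbinom(rng, cfg.host_intron_count_mean - 1,
                                    cfg.intron_count_size)
        else:
            n_introns = _nbinom(rng, cfg.intron_count_mean, cfg.intron_count_size)
        if coding:
            utr5 = max(10, int(rng.lognormal(cfg.utr5_meanlog, cfg.utr5_sdlog)))
            mean3 = cfg.utr3_meanlog + (np.log(cfg.host_utr3_ratio) if is_host else 0.0)
            utr3 = max(30, int(rng.lognormal(mean3, cfg.utr3_sdlog)))
            cds = max(150, int(rng.lognormal(cfg.cds_meanlog, cfg.cds_sdlog)))
            exonic_total = utr5 + cds + utr3
        else:
            utr5 = utr3 = cds = 0
            exonic_total = max(200, int(rng.lognormal(np.log(2000), 0.6)))
        n_introns = min(n_introns, exonic_total // min_exon - 1)
        n_introns = max(n_introns, 1 if is_host else 0)
        mean_len = cfg.length_meanlog + (np.log(cfg.host_length_ratio) if is_host else 0.0)
        total = int(rng.lognormal(mean_len, cfg.length_sdlog))
        total = max(total, exonic_total + n_introns * min_intron)
        if n_introns == 0:
            total = exonic_total
        exon_sizes = _split_lengths(rng, exonic_total, n_introns + 1, min_exon)
        intron_sizes = (
            _split_lengths(rng, total - exonic_total, n_introns, min_intron)
            if n_introns
            else np.array([], dtype=int)
        )
        specs.append(
            dict(is_host=is_host, coding=coding, utr5=utr5, utr3=utr3,
                 exon_sizes=exon_sizes, intron_sizes=intron_sizes, total=total,
                 chrom=f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}",
                 strand="+" if rng.random() < 0.5 else "-")
        )
    # lay out genes chromosome by chromosome
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(specs):
        by_chrom.setdefault(s["chrom"], []).append(i)
    gaps: dict[str, list[tuple[int, int]]] = {c: [] for c in by_chrom}
    for chrom in sorted(by_chrom):
        pos = 10_000
        gaps[chrom].append((1_000, pos))
        for i in by_chrom[chrom]:
            s = specs[i]
            tx_start = pos
            exon_coords = []
            cursor = tx_start
            for j, esize in enumerate(s["exon_sizes"]):
                exon_coords.append((cursor, cursor + int(esize)))
                cursor += int(esize)
                if j < len(s["intron_sizes"]):
                    cursor += int(s["intron_sizes"][j])
            tx_end = cursor
            strand = s["strand"]
            exons = tuple(
                GenomicInterval(chrom, a, b, strand) for a, b in exon_coords
            )
            cds_start = cds_end = None
            if s["coding"]:
                left_utr = s["utr5"] if strand == "+" else s["utr3"]
                right_utr = s["utr3"] if strand == "+" else s["utr5"]
                exonic_total = int(s["exon_sizes"].sum())
                cds_start = _exonic_offset_to_coord(exons, left_utr)
                cds_end = _exonic_offset_to_coord(
                    exons, exonic_total - right_utr - 1
                ) + 1
            gene_id = f"G{i:05d}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=f"SYM{i:05d}",
                    interval=GenomicInterval(chrom, tx_start, tx_end, strand),
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
            gap = int(rng.lognormal(np.log(8_000), 0.8)) + 1_000
            gaps[chrom].append((tx_end + 1, tx_end + gap))
            pos = tx_end + gap
    genes.sort(key=lambda g: g.gene_id)
    host_pool = {f"G{i:05d}" for i in host_pool_idx}
    return genes, host_pool, gaps


def _place_mirnas(cfg, rng, genes_by_id, host_pool, gaps):
    host_ids = sorted(host_pool)
    chroms = sorted(gaps)
    mirnas: list[MirnaLocus] = []
    truth_class: dict[str, str] = {}
    truth_host: dict[str, str] = {}
    truth_ordinal: dict[str, int] = {}
    truth_same: dict[str, bool] = {}
    classes = rng.choice(3, size=cfg.n_mirnas, p=list(cfg.class_probs))
    for i in range(cfg.n_mirnas):
        mid = f"syn-mir-{i:04d}"
        length = int(rng.integers(cfg.mirna_len_min, cfg.mirna_len_max + 1))
        cls = ("intronic", "exonic", "intergenic")[classes[i]]
        if cls == "intergenic":
            chrom = chroms[int(rng.integers(len(chroms)))]
            cands = [g for g in gaps[chrom] if g[1] - g[0] >= length + 20]
            lo, hi = cands[int(rng.integers(len(cands)))]
            start = int(rng.integers(lo + 10, hi - length - 10 + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            mirnas.append(MirnaLocus(mid, GenomicInterval(chrom, start, start + length, strand)))
            truth_class[mid] = cls
            continue
        host = genes_by_id[host_ids[int(rng.integers(len(host_ids)))]]
        same = rng.random() < cfg.same_strand_prob
        strand = host.interval.strand if same else ("-" if host.interval.strand == "+" else "+")
        if cls == "intronic":
            introns = derive_introns(host)  # 5'->3' order
            fit = [(k + 1, iv) for k, iv in enumerate(introns) if len(iv) >= length + 4]
            w = np.array(
                [len(iv) * np.exp(-cfg.positional_bias_beta * (k - 1)) for k, iv in fit]
            )
            k, intron = fit[int(rng.choice(len(fit), p=w / w.sum()))]
            start = int(rng.integers(intron.start + 1, intron.end - length - 1 + 1))
            truth_ordinal[mid] = k
        else:  # exonic
            exon = host.exons[int(rng.integers(len(host.exons)))]
            start = exon.start
            if start + length > host.interval.end:
                start = host.interval.end - length
            truth_ordinal.pop(mid, None)
        iv = GenomicInterval(host.interval.chrom, start, start + length, strand)
        mirnas.append(MirnaLocus(mid, iv))
        truth_class[mid] = cls
        truth_host[mid] = host.gene_id
        truth_same[mid] = same
    return mirnas, truth_class, truth_host, truth_ordinal, truth_same


def _build_utr_sequences(cfg, rng, genes, host_pool):
    seqs: dict[tuple[str, str], str] = {}
    for g in genes:
        if not g.is_coding:
            continue
        from .annotation_io import derive_utr_lengths

        utr5_len, utr3_len = derive_utr_lengths(g)
        if utr5_len > 0:
            seqs[(g.gene_id, "utr5")] = _seq_str(
                _random_seq(rng, utr5_len, cfg.utr5_gc)
            )
        if utr3_len > 0:
            dens = cfg.host_are_per_kb if g.gene_id in host_pool else cfg.are_per_kb
            count = int(rng.poisson(dens * utr3_len / 1000.0))
            seqs[(g.gene_id, "utr3")] = _seq_str(_plant_ares(rng, utr3_len, count))
    return seqs


def _build_targets_and_pathways(cfg, rng, genes, host_pool, truth_class, truth_host):
    coding = sorted(g.gene_id for g in genes if g.is_coding)
    mirna_ids = sorted(truth_class)
    true_targets: dict[str, set[str]] = {}
    self_targets: set[str] = set()
    for mid in mirna_ids:
        n_t = max(5, int(rng.poisson(cfg.true_targets_per_mirna)))
        targets = set(rng.choice(coding, size=min(n_t, len(coding)), replace=False).tolist())
        host = truth_host.get(mid)
        if host is not None:
            targets.discard(host)
            if rng.random() < cfg.self_target_fraction:
                targets.add(host)
                self_targets.add(mid)
        true_targets[mid] = targets
    # pathways over the coding universe, seeded with hosts of intragenic miRNAs
    hosted = sorted({h for h in truth_host.values()})
    host_to_mirnas: dict[str, list[str]] = {}
    for mid, h in truth_host.items():
        host_to_mirnas.setdefault(h, []).append(mid)
    pathways: dict[str, set[str]] = {}
    for j in range(cfg.n_pathways):
        size = int(rng.integers(cfg.pathway_size_min, cfg.pathway_size_max + 1))
        members = set(rng.choice(coding, size=size, replace=False).tolist())
        if hosted and rng.random() < cfg.host_pathway_prob:
            k = int(rng.integers(1, 4))
            members.update(
                rng.choice(hosted, size=min(k, len(hosted)), replace=False).tolist()
            )
        pathways[f"PW{j:02d}"] = members
    eligible = [
        pid for pid, members in sorted(pathways.items())
        if any(g in host_to_mirnas for g in members)
    ]
    n_enriched = min(cfg.n_enriched_pathways, len(eligible))
    enriched = set(
        rng.choice(eligible, size=n_enriched, replace=False).tolist()
    ) if n_enriched and cfg.coverage_enrichment_gamma > 0 else set()
    for pid in sorted(enriched):
        members = sorted(pathways[pid])
        for h in sorted(set(pathways[pid]) & set(host_to_mirnas)):
            for mid in host_to_mirnas[h]:
                # never let the redirect plant an unintended self-target
                candidates = [m for m in members if m != truth_host[mid]]
                redirected = set()
                for t in sorted(true_targets[mid]):
                    if t != truth_host[mid] and rng.random() < cfg.coverage_enrichment_gamma:
                        redirected.add(candidates[int(rng.integers(len(candidates)))])
                    else:
                        redirected.add(t)
                true_targets[mid] = redirected
    return true_targets, self_targets, pathways, enriched


def _build_predictions(cfg, rng, true_targets, truth_host, self_targets, genes):
    coding = sorted(g.gene_id for g in genes if g.is_coding)
    mirna_ids = sorted(true_targets)
    tables: dict[str, pd.DataFrame] = {}
    sources: list[PredictionSource] = []
    for m, sens in enumerate(cfg.method_sensitivity, start=1):
        rows = []
        for mid in mirna_ids:
            for t in sorted(true_targets[mid]):
                if rng.random() < sens:
                    rows.append((mid, t))
            fp = rng.choice(coding, size=cfg.fp_per_mirna, replace=False)
            rows.extend((mid, g) for g in fp)
        name = f"method{m}"
        df = pd.DataFrame(sorted(set(rows)), columns=["mirna", "gene"])
        tables[name] = df
        sources.append(PredictionSource(name, frozenset(map(tuple, df.values))))
    # validation database: sampled true pairs, never miRNA-host pairs
    val_rows = []
    labels = np.array(["True", "Microarray", "Sequencing"])
    for mid in mirna_ids:
        for t in sorted(true_targets[mid]):
            if truth_host.get(mid) == t:
                continue
            if rng.random() < cfg.validation_fraction:
                support = labels[int(rng.choice(3, p=[0.6, 0.25, 0.15]))]
                val_rows.append((mid, t, support))
    validation = pd.DataFrame(val_rows, columns=["mirna", "gene", "support"])
    kept = validation[validation["support"].isin(DEFAULT_SUPPORT_FILTER)]
    sources.append(
        PredictionSource(
            "validated",
            frozenset(zip(kept["mirna"], kept["gene"])),
            is_validation_db=True,
        )
    )
    return tables, validation, sources


def _build_expression(cfg, rng, truth_class, truth_host, true_targets):
    hosts = sorted(
        {truth_host[m] for m, c in truth_class.items() if c == "intronic"}
    )
    samples = [f"N{i + 1}" for i in range(cfg.n_samples_per_group)] + [
        f"T{i + 1}" for i in range(cfg.n_samples_per_group)
    ]
    groups = {s: s[0] for s in samples}
    host_mirnas: dict[str, list[str]] = {}
    for m, h in truth_host.items():
        if truth_class[m] == "intronic":
            host_mirnas.setdefault(h, []).append(m)
    rows: dict[str, np.ndarray] = {}
    pairs: list[tuple[str, str]] = []
    n = cfg.n_samples_per_group
    for h in hosts:
        z = rng.normal(size=2 * n)
        rows[h] = z
        cand = sorted(
            set().union(*(true_targets[m] for m in host_mirnas[h])) - set(hosts)
        )
        if not cand:
            continue
        take = rng.choice(cand, size=min(cfg.expr_targets_per_host, len(cand)),
                          replace=False)
        for t in sorted(take):
            if t in rows:
                continue
            eps = rng.normal(size=2 * n)
            x = np.empty(2 * n)
            for sl, rho in ((slice(0, n), cfg.rho_normal),
                            (slice(n, 2 * n), cfg.rho_tumor)):
                x[sl] = rho * z[sl] + np.sqrt(1 - rho**2) * eps[sl]
            rows[t] = x
            pairs.append((h, t))
    expr = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    expr.index.name = "gene"
    return expr.sort_index(), groups, pairs


def _build_homology(cfg, rng, truth_class, truth_host, self_targets):
    rows = []
    for mid in sorted(truth_host):
        p = cfg.conserved_prob_self if mid in self_targets else cfg.conserved_prob_nonself
        rows.append((mid, truth_host[mid], int(rng.random() < p)))
    return pd.DataFrame(rows, columns=["mirna_id", "host_gene_id", "conserved"])


def _build_fold_changes(cfg, rng, true_targets, genes):
    coding = sorted(g.gene_id for g in genes if g.is_coding)
    rich = [m for m in sorted(true_targets) if len(true_targets[m]) >= 10]
    eval_mirnas = rng.choice(
        rich, size=min(cfg.n_eval_mirnas, len(rich)), replace=False
    ).tolist()
    fcs: dict[tuple[str, str], float] = {}
    for mid in sorted(eval_mirnas):
        targets = sorted(true_targets[mid])
        others = [g for g in coding if g not in true_targets[mid]]
        n_other = max(0, cfg.n_measured_per_mirna - len(targets))
        measured = targets + rng.choice(others, size=min(n_other, len(others)),
                                        replace=False).tolist()
        for g in measured:
            mu = -cfg.eval_effect if g in true_targets[mid] else 0.0
            fcs[(mid, g)] = float(rng.normal(mu, cfg.eval_noise_sd))
    return fcs, sorted(eval_mirnas)


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a complete, ground-truth-annotated input bundle."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, host_pool, gaps = _build_genes(config, rng)
    genes_by_id = {g.gene_id: g for g in genes}
    mirnas, t_class, t_host, t_ord, t_same = _place_mirnas(
        config, rng, genes_by_id, host_pool, gaps
    )
    utr_seqs = _build_utr_sequences(config, rng, genes, host_pool)
    true_targets, self_targets, pathways, enriched = _build_targets_and_pathways(
        config, rng, genes, host_pool, t_class, t_host
    )
    tables, validation, sources = _build_predictions(
        config, rng, true_targets, t_host, self_targets, genes
    )
    expr, groups, pairs = _build_expression(config, rng, t_class, t_host, true_targets)
    homology = _build_homology(config, rng, t_class, t_host, self_targets)
    fcs, eval_mirnas = _build_fold_changes(config, rng, true_targets, genes)
    annotation = GenomeAnnotation.from_lists(genes, mirnas)
    from .annotation_io import attach_utr_sequences

    attach_utr_sequences(annotation, utr_seqs)
    truth = SyntheticTruth(
        mirna_class=t_class,
        host=t_host,
        intron_ordinal=t_ord,
        same_strand=t_same,
        true_targets={m: sorted(s) for m, s in true_targets.items()},
        self_targets=sorted(self_targets),
        enriched_pathways=sorted(enriched),
        expression_pairs=pairs,
        eval_mirnas=eval_mirnas,
        planted={
            "host_length_ratio": config.host_length_ratio,
            "host_utr3_ratio": config.host_utr3_ratio,
            "are_ratio": config.host_are_per_kb / config.are_per_kb,
            "same_strand_prob": config.same_strand_prob,
            "self_target_fraction": config.self_target_fraction,
            "rho_normal": config.rho_normal,
            "rho_tumor": config.rho_tumor,
        },
    )
    return SyntheticBundle(
        config=config,
        annotation=annotation,
        utr_sequences=utr_seqs,
        prediction_tables=tables,
        validation_table=validation,
        sources=sources,
        pathways=pathways,
        expression=expr,
        groups=groups,
        homology=homology,
        fold_changes=fcs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict[str, str]:
    """Write every bundle component in its standard format.

    Returns a manifest mapping relative path → sha256, also written as
    ``manifest.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "predictions").mkdir(exist_ok=True)
    write_gene_models(bundle.annotation, directory / "genes.refflat.tsv", "refflat_tsv")
    write_mirna_gff(bundle.annotation.mirnas.values(), directory / "mirnas.gff")
    write_utr_fasta(bundle.utr_sequences, directory / "utrs.fasta")
    for name, df in sorted(bundle.prediction_tables.items()):
        df.to_csv(directory / "predictions" / f"{name}.tsv", sep="\t", index=False)
    bundle.validation_table.to_csv(
        directory / "predictions" / "validated.tsv", sep="\t", index=False
    )
    from .enrichment import write_gmt

    write_gmt(bundle.pathways, directory / "pathways.gmt")
    bundle.expression.to_csv(directory / "expression.tsv", sep="\t")
    pd.DataFrame(
        sorted(bundle.groups.items()), columns=["sample", "group"]
    ).to_csv(directory / "groups.tsv", sep="\t", index=False)
    bundle.homology.to_csv(directory / "homology.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(m, g, v) for (m, g), v in sorted(bundle.fold_changes.items())],
        columns=["mirna", "gene", "log_fc"],
    ).to_csv(directory / "foldchanges.tsv", sep="\t", index=False)
    (directory / "truth.json").write_text(bundle.truth.to_json())
    manifest: dict[str, str] = {}
    for path in sorted(directory.rglob("*")):
        if path.is_file() and path.name != "manifest.tsv":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest[str(path.relative_to(directory))] = digest
    with open(directory / "manifest.tsv", "w") as fh:
        fh.write("path\tsha256\n")
        for rel, digest in manifest.items():
            fh.write(f"{rel}\t{digest}\n")
    return manifest
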