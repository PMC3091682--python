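"""End-to-end orchestration: from input files to the report tables.

``run_all`` reads the annotation, classifies miRNAs, characterizes host
genes against matched controls, integrates target predictions, runs the
self-targeting and pathway target-coverage resampling statistics, the
conservation proportion test and the evaluation utilities, writing one
TSV report per stage. One seed governs every stochastic stage
(per-stage generators are derived deterministically), so a rerun with the
same config is byte-identical. Stages whose inputs are absent are skipped
with a logged notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    annotation_io,
    classification,
    enrichment,
    evaluation,
    gene_features,
    positional_stats,
    target_integration,
)

logger = logging.getLogger(__name__)

STAGES = (
    "classification",
    "positional",
    "features",
    "agreement",
    "selftarget",
    "coverage",
    "conservation",
    "evaluate",
)


@dataclass
class RunConfig:
    """Inputs, thresholds and seed for a full pipeline run."""

    gene_models: str
    gene_models_format: str
    mirna_gff: str
    predictions: list[dict] = field(default_factory=list)
    utr_fasta: str | None = None
    gmt: str | None = None
    expression: str | None = None
    groups: str | None = None
    homology: str | None = None
    foldchanges: str | None = None
    outdir: str = "intramir_out"
    seed: int = 0
    agreement_high_confidence: int = 6
    agreement_coverage: int = 2
    n_iter: int = 1000
    fdr_level: float = 0.10
    fdr_method: str = "storey"
    k_per_host: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(STAGES))
        return int(children[STAGES.index(stage)].generate_state(1)[0] % (2**31))


def _write(df: pd.DataFrame, outdir: Path, name: str, header: str) -> None:
    path = outdir / name
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


class PipelineError(RuntimeError):
    pass


def run_all(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage; returns (and writes) the report tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, pd.DataFrame] = {}

    def hdr(stage: str, seeded: bool = False) -> str:
        base = f"# intramir report: {stage}\n"
        if seeded:
            base += f"# seed={config.seed} stage_seed={config.stage_seed(stage)}\n"
        return base

    # --- annotation -------------------------------------------------------
    stage = "annotation"
    try:
        annotation = annotation_io.read_gene_models(
            config.gene_models, config.gene_models_format
        )
        annotation = annotation_io.collapse_to_canonical(annotation)
        for m in annotation_io.read_mirna_gff(config.mirna_gff):
            annotation.add_mirna(m)
        if config.utr_fasta:
            annotation_io.attach_utr_sequences(
                annotation, annotation_io.read_utr_fasta(config.utr_fasta)
            )
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # --- classification ---------------------------------------------------
    stage = "classification"
    try:
        placements = classification.classify_all(annotation)
        reports["classification"] = classification.placements_to_frame(
            placements, annotation
        )
        summary = classification.summarize_classification(placements, label="run")
        reports["classification_summary"] = pd.DataFrame(
            [
                {
                    "label": summary.label,
                    **{f"n_{c}": summary.counts[c] for c in classification.CLASSES},
                    **{f"pct_{c}": summary.percentages[c] for c in classification.CLASSES},
                    "n_same_strand": summary.same_strand,
                    "n_opposite_strand": summary.opposite_strand,
                    "pct_same_strand": summary.same_strand_pct,
                    "pct_opposite_strand": summary.opposite_strand_pct,
                }
            ]
        )
        _write(reports["classification"], outdir, "classification.tsv", hdr(stage))
        _write(
            reports["classification_summary"], outdir,
            "classification_summary.tsv", hdr(stage),
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    intragenic = [p for p in placements if p.host_gene_id is not None]
    intronic = [p for p in placements if p.mirna_class == "intronic"]
    host_ids = sorted({p.host_gene_id for p in intragenic})
    hosts = [annotation.genes[h] for h in host_ids]

    # --- positional stats -------------------------------------------------
    stage = "positional"
    try:
        reports["intron_position"] = positional_stats.position_report(
            placements, annotation.genes
        )
        n_same = sum(1 for p in intragenic if p.same_strand)
        chi2, p_strand = positional_stats.strand_bias_test(
            n_same, len(intragenic) - n_same
        )
        ff = positional_stats.first_five_metrics(placements, annotation.genes)
        reports["positional_stats"] = pd.DataFrame(
            [
                ("strand_bias_chi2", chi2),
                ("strand_bias_p", p_strand),
                ("fraction_hosts_first5", ff.fraction_hosts_first5),
                ("fraction_mirnas_first5", ff.fraction_mirnas_first5),
                ("first5_chi2", ff.chi2),
                ("first5_p", ff.p_value),
            ],
            columns=["statistic", "value"],
        )
        _write(reports["intron_position"], outdir, "intron_position.tsv", hdr(stage))
        _write(reports["positional_stats"], outdir, "positional_stats.tsv", hdr(stage))
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # --- host gene features ----------------------------------------------
    stage = "features"
    try:
        universe = [g for g in annotation.genes.values() if g.gene_id not in host_ids]
        controls = gene_features.sample_matched_controls(
            hosts, universe, k_per_host=config.k_per_host,
            seed=config.stage_seed(stage),
        )
        host_records = [gene_features.compute_features(g) for g in hosts]
        control_records = [gene_features.compute_features(g) for g in controls]
        reports["features"] = gene_features.features_frame(hosts)
        reports["feature_comparison"] = gene_features.comparison_table(
            host_records, control_records
        )
        _write(reports["features"], outdir, "features.tsv", hdr(stage, True))
        _write(
            reports["feature_comparison"], outdir,
            "feature_comparison.tsv", hdr(stage, True),
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # --- prediction agreement --------------------------------------------
    stage = "agreement"
    matrix = None
    try:
        sources = []
        known = set(annotation.mirnas)
        for spec in config.predictions:
            src = target_integration.read_prediction_table(
                spec["path"], spec["name"],
                is_validation_db=spec.get("is_validation_db", False),
            )
            sources.append(target_integration.harmonize_source(src, known))
        if sources:
            matrix = target_integration.build_agreement(sources)
            reports["agreement"] = target_integration.agreement_frame(matrix)
            _write(reports["agreement"], outdir, "agreement.tsv", hdr(stage))
        else:
            logger.info("no prediction sources configured; agreement skipped")
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # --- self-targeting ---------------------------------------------------
    stage = "selftarget"
    if matrix is not None:
        try:
            st_mirnas, st_hosts = enrichment.self_target_set(
                intragenic, matrix, k=config.agreement_coverage
            )
            st = enrichment.self_target_pvalue(
                len(st_mirnas), intragenic, matrix,
                universe_mode="predicted_targets",
                n_iter=config.n_iter, seed=config.stage_seed(stage),
                k=config.agreement_coverage,
            )
            reports["self_targeting"] = pd.DataFrame(
                [
                    {
                        "n_self_targeting_mirnas": len(st_mirnas),
                        "n_distinct_hosts": len(st_hosts),
                        "fraction_of_intragenic": len(st_mirnas) / len(intragenic)
                        if intragenic else float("nan"),
                        "null_mean": float(st.null_counts.mean()),
                        "p": st.p,
                        "n_iter": st.n_iter,
                    }
                ]
            )
            _write(
                reports["self_targeting"], outdir,
                "self_targeting.tsv", hdr(stage, True),
            )
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

    # --- pathway target coverage -----------------------------------------
    stage = "coverage"
    if matrix is not None and config.gmt:
        try:
            pathways = enrichment.read_gmt(config.gmt)
            reports["coverage"] = enrichment.coverage_analysis(
                pathways, intragenic, matrix,
                universe=set(annotation.genes),
                agreement_k=config.agreement_coverage,
                n_iter=config.n_iter,
                seed=config.stage_seed(stage),
                fdr_method=config.fdr_method,
            )
            _write(reports["coverage"], outdir, "coverage.tsv", hdr(stage, True))
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
    elif config.gmt is None:
        logger.info("no GMT configured; coverage stage skipped")

    # --- conservation -----------------------------------------------------
    stage = "conservation"
    if config.homology and matrix is not None:
        try:
            hom = pd.read_csv(config.homology, sep="\t")
            st_mirnas, _ = enrichment.self_target_set(
                intragenic, matrix, k=config.agreement_coverage
            )
            is_self = hom["mirna_id"].isin(st_mirnas)
            comp = evaluation.prop_test_cc(
                int(hom.loc[is_self, "conserved"].sum()), int(is_self.sum()),
                int(hom.loc[~is_self, "conserved"].sum()), int((~is_self).sum()),
            )
            reports["conservation"] = pd.DataFrame(
                [
                    {
                        "conserved_self": comp.conserved_a,
                        "total_self": comp.total_a,
                        "conserved_other": comp.conserved_b,
                        "total_other": comp.total_b,
                        "chi2": comp.chi2,
                        "p": comp.p_value,
                    }
                ]
            )
            _write(reports["conservation"], outdir, "conservation.tsv", hdr(stage))
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
    else:
        logger.info("homology table absent; conservation stage skipped")

    # --- evaluation -------------------------------------------------------
    stage = "evaluate"
    if config.foldchanges and matrix is not None:
        try:
            fc = pd.read_csv(config.foldchanges, sep="\t")
            fcs = {(r.mirna, r.gene): r.log_fc for r in fc.itertuples()}
            rocs = evaluation.auc_by_agreement(
                fcs, matrix, {m for m, _ in fcs},
            )
            reports["roc"] = pd.DataFrame(
                [
                    {"stratum": r.stratum, "auc": r.auc,
                     "n_pos": r.n_pos, "n_neg": r.n_neg}
                    for r in rocs
                ]
            )
            _write(reports["roc"], outdir, "roc.tsv", hdr(stage))
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
    else:
        logger.info("fold-change table absent; ROC stage skipped")

    if config.expression and config.groups and matrix is not None:
        try:
            expr = pd.read_csv(config.expression, sep="\t", index_col=0)
            groups = dict(
                pd.read_csv(config.groups, sep="\t").itertuples(index=False)
            )
            host_mirnas: dict[str, set[str]] = {}
            for p in intronic:
                host_mirnas.setdefault(p.host_gene_id, set()).add(p.mirna_id)
            frames = []
            for h in sorted(host_mirnas):
                if h not in expr.index:
                    continue
                targets = sorted(
                    {
                        g
                        for (m, g), c in matrix.counts.items()
                        if c >= config.agreement_coverage
                        and m in host_mirnas[h]
                        and g in expr.index
                        and g != h
                    }
                )
                if not targets:
                    continue
                contrasts = evaluation.correlation_contrast(
                    expr, h, targets, groups
                )
                frames.append(evaluation.contrast_frame(contrasts, h))
            if frames:
                reports["correlation"] = pd.concat(frames, ignore_index=True)
                _write(reports["correlation"], outdir, "correlation.tsv", hdr(stage))
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
    else:
        logger.info("expression inputs absent; correlation stage skipped")

    return reports


def bundle_run_config(directory: str | Path, outdir: str | Path, seed: int = 0,
                      **overrides) -> RunConfig:
    """RunConfig pointing at a written synthetic bundle directory."""
    d = Path(directory)
    predictions = [
        {"path": str(p), "name": p.stem}
        for p in sorted((d / "predictions").glob("method*.tsv"))
    ]
    val = d / "predictions" / "validated.tsv"
    if val.exists():
        predictions.append(
            {"path": str(val), "name": "validated", "is_validation_db": True}
        )
    cfg = RunConfig(
        gene_models=str(d / "genes.refflat.tsv"),
        gene_models_format="refflat_tsv",
        mirna_gff=str(d / "mirnas.gff"),
        utr_fasta=str(d / "utrs.fasta"),
        predictions=predictions,
        gmt=str(d / "pathways.gmt") if (d / "pathways.gmt").exists() else None,
        expression=str(d / "expression.tsv") if (d / "expression.tsv").exists() else None,
        groups=str(d / "groups.tsv") if (d / "groups.tsv").exists() else None,
        homology=str(d / "homology.tsv") if (d / "homology.tsv").exists() else None,
        foldchanges=str(d / "foldchanges.tsv") if (d / "foldchanges.tsv").exists() else None,
        outdir=str(outdir),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
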