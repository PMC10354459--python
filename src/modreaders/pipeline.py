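"""End-to-end orchestration: read -> normalize -> medians -> pseudocount
-> fold changes -> classify -> unique sets -> optional enrichment and
motif flags, with deterministic outputs and a run-metadata record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

import modreaders
from modreaders.design import MODIFICATIONS
from modreaders.enrichment import (
    DEFAULT_THRESHOLD_BEADS,
    DEFAULT_THRESHOLD_UNMOD,
    classify_candidates,
    compute_fold_changes,
    compute_pseudocount,
    median_by_condition,
    normalize_total_intensity,
    rank_candidates,
)
from modreaders.io import (
    QCPolicy,
    read_design,
    read_protein_groups,
    write_candidate_table,
)
from modreaders.motifs import (
    DEFAULT_PATTERNS,
    flag_rrm_candidates,
    read_fasta,
    read_pattern_file,
    write_rrm_flags,
)
from modreaders.phenotype import (
    AnnotationSets,
    enrich,
    normalize_query,
    read_background,
    read_gmt,
    write_enrichment,
)
from modreaders.sets import unique_binders, write_unique_binders, write_venn_counts

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run configuration is invalid."""


def call_candidates(
    records,
    design,
    threshold_beads: float = DEFAULT_THRESHOLD_BEADS,
    threshold_unmod: float = DEFAULT_THRESHOLD_UNMOD,
    strict: bool = False,
    pseudocount_mode: str = "derived",
    pseudocount_value: float | None = None,
):
    """In-memory quantitative chain on already-parsed records.

    Runs normalize -> medians -> pseudocount -> fold changes ->
    classify -> unique sets and returns
    ``(medians, pseudocount, fold_changes, calls, unique_sets)``.
    """
    norm = normalize_total_intensity(records, design)
    medians = median_by_condition(norm)
    eps = compute_pseudocount(medians, mode=pseudocount_mode, value=pseudocount_value)
    fct = compute_fold_changes(medians, eps)
    calls = classify_candidates(fct, threshold_beads, threshold_unmod, strict)
    return medians, eps, fct, calls, unique_binders(calls)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Required: the proteinGroups table, the design file and an output
    directory. Annotation/background (phenotype enrichment) and FASTA
    (motif flags) are optional stages. Thresholds, boundary mode,
    pseudocount mode and QC switches mirror the library defaults.
    """

    protein_groups: Path
    design: Path
    out_dir: Path
    annotation: Path | None = None
    background: Path | None = None
    fasta: Path | None = None
    patterns: Path | None = None
    ibaq_prefix: str = "iBAQ "
    threshold_beads: float = DEFAULT_THRESHOLD_BEADS
    threshold_unmod: float = DEFAULT_THRESHOLD_UNMOD
    strict: bool = False
    pseudocount_mode: str = "derived"
    pseudocount_value: float | None = None
    drop_reverse: bool = True
    drop_contaminant: bool = True
    drop_only_by_site: bool = False
    enrichment_q_cutoff: float = 0.05

    def __post_init__(self) -> None:
        for name in ("protein_groups", "design", "annotation", "background",
                     "fasta", "patterns"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        for name in ("protein_groups", "design"):
            if not Path(getattr(self, name)).is_file():
                raise ConfigError(f"{name} file not found: {getattr(self, name)}")
        for name in ("annotation", "background", "fasta", "patterns"):
            value = getattr(self, name)
            if value is not None and not value.is_file():
                raise ConfigError(f"{name} file not found: {value}")
        if (self.annotation is None) != (self.background is None):
            raise ConfigError("annotation and background must be given together")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run(config: RunConfig) -> dict:
    """Execute the pipeline; write the output bundle; return metadata.

    Outputs in ``config.out_dir``: ``candidates.tsv``,
    ``unique_binders.tsv``, ``venn_counts.tsv``, optionally
    ``enrichment_<mod>.tsv`` and ``rrm_flags.tsv``, plus
    ``run_metadata.json`` recording all parameters and the pseudocount
    actually used. Fixed inputs and config give byte-identical outputs.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    design = read_design(config.design)
    policy = QCPolicy(
        drop_reverse=config.drop_reverse,
        drop_contaminant=config.drop_contaminant,
        drop_only_by_site=config.drop_only_by_site,
    )
    records = read_protein_groups(
        config.protein_groups, design, policy, config.ibaq_prefix
    )
    logger.info("stage read: %d retained protein groups", len(records))

    norm = normalize_total_intensity(records, design)
    medians = median_by_condition(norm)
    eps = compute_pseudocount(
        medians, mode=config.pseudocount_mode, value=config.pseudocount_value
    )
    logger.info("stage pseudocount: epsilon=%g (%s)", eps.epsilon, eps.mode)
    fct = compute_fold_changes(medians, eps)
    calls = classify_candidates(
        fct, config.threshold_beads, config.threshold_unmod, config.strict
    )
    logger.info(
        "stage classify: candidates per bait %s",
        {m: int(calls[m].sum()) for m in MODIFICATIONS},
    )
    usets = unique_binders(calls)
    ranked = {m: rank_candidates(fct, calls, medians, m) for m in MODIFICATIONS}
    gene_names = {r.group_id: r.gene_name for r in records}

    write_candidate_table(
        records, medians.values, fct, calls, usets, out / "candidates.tsv"
    )
    write_venn_counts(usets, out / "venn_counts.tsv")
    write_unique_binders(usets, ranked, gene_names, out / "unique_binders.tsv")

    enrichment_files: dict[str, str] = {}
    if config.annotation is not None:
        terms = read_gmt(config.annotation)
        background = read_background(config.background)
        annotation = AnnotationSets(terms=terms, background=background)
        for mod in MODIFICATIONS:
            query = normalize_query(
                gene_names[g] for g in usets.unique[mod] if gene_names[g]
            )
            path = out / f"enrichment_{mod}.tsv"
            if not query & annotation.background:
                logger.info("stage enrich[%s]: empty effective query", mod)
                write_enrichment([], path)
            else:
                write_enrichment(enrich(query, annotation), path)
            enrichment_files[mod] = path.name

    if config.fasta is not None:
        patterns = (
            read_pattern_file(config.patterns)
            if config.patterns is not None
            else DEFAULT_PATTERNS
        )
        sequences = read_fasta(config.fasta)
        rows, unmatched = flag_rrm_candidates(usets, sequences, gene_names, patterns)
        write_rrm_flags(rows, unmatched, out / "rrm_flags.tsv", patterns)
        logger.info(
            "stage motifs: %d flagged, %d unmatched", len(rows), len(unmatched)
        )

    metadata = {
        "version": modreaders.__version__,
        "n_retained_proteins": len(records),
        "epsilon": eps.epsilon,
        "pseudocount_mode": eps.mode,
        "threshold_beads": config.threshold_beads,
        "threshold_unmod": config.threshold_unmod,
        "boundary": "strict (>)" if config.strict else "inclusive (>=)",
        "qc_policy": {
            "drop_reverse": config.drop_reverse,
            "drop_contaminant": config.drop_contaminant,
            "drop_only_by_site": config.drop_only_by_site,
        },
        "candidates_per_modification": {
            m: int(calls[m].sum()) for m in MODIFICATIONS
        },
        "unique_binders_per_modification": {
            m: len(usets.unique[m]) for m in MODIFICATIONS
        },
        "enrichment_files": enrichment_files,
    }
    with (out / "run_metadata.json").open("w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return metadata
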