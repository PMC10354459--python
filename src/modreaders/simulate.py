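"""Synthetic pulldown datasets with known ground truth.

The generator emulates the screen's design — six conditions (beads-only,
unmodified C, and the four modified baits) with replicate pulldowns —
and the gross statistical features of iBAQ tables: heavy-tailed
(log-normal) protein abundances, multiplicative replicate noise,
bead-sticky contaminants elevated in every sample, planted unique and
shared readers boosted in their cognate bait condition(s), and missing
values recorded as zero.

Every protein carries a ground-truth role so that candidate calls and
unique-binder sets can be scored for precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from modreaders.design import CONDITIONS, MODIFICATIONS, SampleDesign
from modreaders.io import ProteinRecord, write_design

#: Ground-truth role labels.
ROLE_BACKGROUND = "background"
ROLE_BEAD_STICKY = "bead_sticky"
ROLE_SHARED = "shared_reader"


def role_unique(mod: str) -> str:
    return f"unique_{mod}"


@dataclass(frozen=True)
class SyntheticParams:
    """Generator parameters.

    Defaults describe a realistic whole-lysate pulldown screen: ~2000
    background proteins with log-normal abundance spanning several
    orders of magnitude, a sleeve of bead-sticky contaminants, a
    handful of planted readers per bait, 3 biological replicates per
    condition, moderate multiplicative noise (sd 0.25 on the natural
    log) and 5% random missingness.

    ``effect_size`` multiplies a planted reader's abundance in its
    cognate bait condition(s) and must exceed 1. ``dropout_mode``
    ``"uniform"`` zeroes values independently of abundance;
    ``"intensity"`` concentrates missingness in low-abundance values
    (logistic in log-intensity), the regime real LFQ data shows.
    """

    n_background: int = 2000
    n_bead_sticky: int = 50
    n_unique_per_mod: int = 25
    n_shared: int = 30
    effect_size: float = 6.0
    log_sigma: float = 0.25
    dropout: float = 0.05
    dropout_mode: Literal["uniform", "intensity"] = "uniform"
    replicates: int = 3
    bead_sticky_boost: float = 8.0
    base_log_mean: float = 16.0
    base_log_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background", "n_bead_sticky", "n_unique_per_mod", "n_shared"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.effect_size > 1:
            raise ValueError("effect_size must exceed 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.log_sigma < 0:
            raise ValueError("log_sigma must be >= 0")


def default_design(replicates: int = 3) -> SampleDesign:
    """Canonical design: 6 conditions x ``replicates``, ids ``cond_rep``."""
    samples = tuple(
        (f"{cond}_{rep}", cond, rep)
        for cond in CONDITIONS
        for rep in range(1, replicates + 1)
    )
    return SampleDesign(samples)


def _roles(params: SyntheticParams) -> list[str]:
    roles = [ROLE_BACKGROUND] * params.n_background
    roles += [ROLE_BEAD_STICKY] * params.n_bead_sticky
    for mod in MODIFICATIONS:
        roles += [role_unique(mod)] * params.n_unique_per_mod
    roles += [ROLE_SHARED] * params.n_shared
    return roles


def generate_records(
    params: SyntheticParams,
) -> tuple[list[ProteinRecord], SampleDesign, dict[str, str]]:
    """In-memory dataset: records, design and truth (group_id -> role).

    Each sample value is ``base * condition_multiplier * exp(noise)``
    with ``noise ~ N(0, log_sigma)``, then dropout zeroes a value with
    the configured probability. Identical parameters (including seed)
    give identical output.
    """
    rng = np.random.default_rng(params.seed)
    design = default_design(params.replicates)
    roles = _roles(params)
    n = len(roles)
    if n == 0:
        raise ValueError("no proteins to generate")
    width = len(str(n))
    ids = [f"SYN{i:0{width}d}" for i in range(1, n + 1)]
    genes = [f"sgn-{i}" for i in range(1, n + 1)]

    base = np.exp(rng.normal(params.base_log_mean, params.base_log_sigma, size=n))
    sample_ids = design.sample_ids
    conditions = [design.condition_of(s) for s in sample_ids]

    mult = np.ones((n, len(sample_ids)))
    for i, role in enumerate(roles):
        for j, cond in enumerate(conditions):
            if role == ROLE_BEAD_STICKY:
                mult[i, j] = params.bead_sticky_boost
            elif role == ROLE_SHARED and cond in MODIFICATIONS:
                mult[i, j] = params.effect_size
            elif role.startswith("unique_") and cond == role.removeprefix("unique_"):
                mult[i, j] = params.effect_size

    noise = rng.normal(0.0, params.log_sigma, size=(n, len(sample_ids)))
    values = base[:, None] * mult * np.exp(noise)

    if params.dropout > 0:
        if params.dropout_mode == "uniform":
            drop = rng.random((n, len(sample_ids))) < params.dropout
        else:
            # missingness decays logistically with log-intensity around
            # the 10th percentile; peak rate 2*dropout at the low end
            logv = np.log(values)
            pivot = np.quantile(logv, 0.10)
            p = 2.0 * params.dropout / (1.0 + np.exp(logv - pivot))
            drop = rng.random((n, len(sample_ids))) < p
        values = np.where(drop, 0.0, values)

    records = [
        ProteinRecord(
            group_id=ids[i],
            gene_name=genes[i],
            majority_ids=[ids[i]],
            is_contaminant=False,
            is_reverse=False,
            is_only_by_site=False,
            intensities={s: float(values[i, j]) for j, s in enumerate(sample_ids)},
        )
        for i in range(n)
    ]
    truth = dict(zip(ids, roles))
    return records, design, truth


def generate(
    params: SyntheticParams, out_dir: str | Path
) -> tuple[Path, Path, dict[str, str]]:
    """Write proteinGroups.tsv, design.tsv and truth.tsv to ``out_dir``.

    Returns the proteinGroups path, design path and the truth mapping.
    The files round-trip through :mod:`modreaders.io`, and a fixed seed
    yields bit-identical files.
    """
    records, design, truth = generate_records(params)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pg_path = out_dir / "proteinGroups.tsv"
    design_path = out_dir / "design.tsv"
    truth_path = out_dir / "truth.tsv"

    sample_ids = design.sample_ids
    with pg_path.open("w", encoding="utf-8") as fh:
        header = [
            "Protein IDs",
            "Majority protein IDs",
            "Gene names",
            "Reverse",
            "Potential contaminant",
            "Only identified by site",
        ] + [f"iBAQ {s}" for s in sample_ids]
        fh.write("\t".join(header) + "\n")
        for rec in records:
            row = [rec.group_id, ";".join(rec.majority_ids), rec.gene_name, "", "", ""]
            row += [repr(rec.intensities[s]) for s in sample_ids]
            fh.write("\t".join(row) + "\n")

    write_design(design, design_path)

    with truth_path.open("w", encoding="utf-8") as fh:
        fh.write("group_id\trole\n")
        for rec in records:
            fh.write(f"{rec.group_id}\t{truth[rec.group_id]}\n")

    return pg_path, design_path, truth


def read_truth(path: str | Path) -> dict[str, str]:
    truth: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            gid, role = line.rstrip("\n").split("\t")
            truth[gid] = role
    return truth


@dataclass(frozen=True)
class RecoveryMetrics:
    """Per-modification confusion counts and precision/recall.

    ``precision_zero_denominator`` marks baits with no predicted
    positives, for which precision is reported as 1 by convention.
    """

    per_mod: dict[str, dict[str, float]]

    @property
    def mean_precision(self) -> float:
        return float(np.mean([m["precision"] for m in self.per_mod.values()]))

    @property
    def mean_recall(self) -> float:
        return float(np.mean([m["recall"] for m in self.per_mod.values()]))


def score_recovery(
    unique_sets: "object", truth: dict[str, str]
) -> RecoveryMetrics:
    """Score unique-binder sets against planted unique-reader truth.

    Positives for a modification are the proteins planted as its unique
    readers. ``precision = TP/(TP+FP)`` over the predicted unique set,
    ``recall = TP/(TP+FN)`` over the planted set; an empty predicted
    set gives precision 1 with the zero-denominator flag raised, and an
    empty planted set likewise gives recall 1.
    """
    per_mod: dict[str, dict[str, float]] = {}
    for mod in MODIFICATIONS:
        planted = {g for g, role in truth.items() if role == role_unique(mod)}
        predicted = set(unique_sets.unique[mod])
        tp = len(planted & predicted)
        fp = len(predicted - planted)
        fn = len(planted - predicted)
        per_mod[mod] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": tp / (tp + fp) if (tp + fp) else 1.0,
            "recall": tp / (tp + fn) if (tp + fn) else 1.0,
            "precision_zero_denominator": float((tp + fp) == 0),
            "recall_zero_denominator": float((tp + fn) == 0),
        }
    return RecoveryMetrics(per_mod=per_mod)
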