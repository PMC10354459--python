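"""Core quantitative chain: normalization, medians, pseudocount, fold
changes and candidate calls.

The procedure mirrors standard ranked-iBAQ pulldown analysis:

1. each sample's iBAQ values are divided by that sample's total
   intensity, giving column-stochastic unitless fractions;
2. the median over biological replicates is taken per condition;
3. a small pseudocount ``epsilon`` — by default 100-fold below the
   smallest positive median in the table — is added to every median;
4. per modified bait ``M``, fold changes are formed against both
   controls, ``(median_M + eps) / (median_beads + eps)`` and
   ``(median_M + eps) / (median_C + eps)``;
5. a protein is called a candidate reader of ``M`` when it clears both
   thresholds (default 2.0 vs beads and 1.5 vs unmodified C).

Because every step is a ratio of within-sample fractions, the whole
chain is invariant to rescaling any sample's raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from modreaders.design import CONDITIONS, MODIFICATIONS, SampleDesign
from modreaders.io import ProteinRecord, records_to_frame

#: Default fold-change cutoffs (vs beads-only, vs unmodified C).
DEFAULT_THRESHOLD_BEADS = 2.0
DEFAULT_THRESHOLD_UNMOD = 1.5


@dataclass(frozen=True)
class NormalizedMatrix:
    """Protein x sample fractions; each sample column sums to 1."""

    values: pd.DataFrame
    design: SampleDesign


@dataclass(frozen=True)
class ConditionMedians:
    """Protein x condition medians of normalized replicate values."""

    values: pd.DataFrame


@dataclass(frozen=True)
class Pseudocount:
    """Ratio-stabilizing constant added to all medians."""

    epsilon: float
    mode: str = "fixed"

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon!r}")


@dataclass(frozen=True)
class FoldChangeTable:
    """Per protein x modification fold changes against both controls."""

    fc_beads: pd.DataFrame
    fc_unmod: pd.DataFrame


def normalize_total_intensity(
    records: Sequence[ProteinRecord], design: SampleDesign
) -> NormalizedMatrix:
    """Divide each sample column by its total intensity.

    Zero entries stay zero; an all-zero sample column is an error (it
    cannot be normalized) and the error names the sample.
    """
    raw = records_to_frame(records, design)
    totals = raw.sum(axis=0)
    dead = totals[totals <= 0]
    if len(dead):
        raise ValueError(
            f"cannot normalize: sample(s) with zero total intensity: "
            f"{', '.join(dead.index)}"
        )
    return NormalizedMatrix(values=raw / totals, design=design)


def median_by_condition(norm: NormalizedMatrix) -> ConditionMedians:
    """Per-protein median over each condition's replicates.

    Zeros are ordinary values; for even replicate counts the midpoint
    of the two central values is used (numpy median semantics).
    """
    cols = {
        c: norm.values[norm.design.samples_of(c)].median(axis=1)
        for c in CONDITIONS
    }
    return ConditionMedians(values=pd.DataFrame(cols))


def compute_pseudocount(
    medians: ConditionMedians,
    mode: Literal["derived", "fixed"] = "derived",
    value: float | None = None,
) -> Pseudocount:
    """Pseudocount for fold-change stabilization.

    ``derived`` takes the smallest *positive* median in the table and
    divides it by 100 (zeros are excluded: a zero-derived pseudocount
    would defeat its purpose). ``fixed`` returns the supplied value.
    """
    if mode == "fixed":
        if value is None:
            raise ValueError("fixed mode requires a value")
        return Pseudocount(epsilon=float(value), mode="fixed")
    if mode != "derived":
        raise ValueError(f"unknown pseudocount mode {mode!r}")
    arr = medians.values.to_numpy()
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("cannot derive pseudocount: all medians are zero")
    return Pseudocount(epsilon=float(positive.min()) / 100.0, mode="derived")


def compute_fold_changes(
    medians: ConditionMedians, epsilon: Pseudocount | float
) -> FoldChangeTable:
    """Fold change of each modified bait vs both controls.

    ``epsilon`` is added to numerator and denominator medians alike, so
    a protein absent from bait and control lands exactly at fold change
    1 and every ratio is finite and positive.
    """
    eps = epsilon.epsilon if isinstance(epsilon, Pseudocount) else float(epsilon)
    if not eps > 0:
        raise ValueError(f"epsilon must be positive, got {eps!r}")
    m = medians.values
    beads = m["beads"] + eps
    unmod = m["C"] + eps
    fc_beads = pd.DataFrame(
        {mod: (m[mod] + eps) / beads for mod in MODIFICATIONS}
    )
    fc_unmod = pd.DataFrame(
        {mod: (m[mod] + eps) / unmod for mod in MODIFICATIONS}
    )
    return FoldChangeTable(fc_beads=fc_beads, fc_unmod=fc_unmod)


def classify_candidates(
    fct: FoldChangeTable,
    t_beads: float = DEFAULT_THRESHOLD_BEADS,
    t_unmod: float = DEFAULT_THRESHOLD_UNMOD,
    strict: bool = False,
) -> pd.DataFrame:
    """Boolean protein x modification candidate calls.

    A protein is a candidate reader of a modification when its fold
    change clears ``t_beads`` against the beads-only control AND
    ``t_unmod`` against the unmodified-C control. ``strict`` switches
    the comparison from >= (default) to >.
    """
    if not (t_beads > 0 and t_unmod > 0):
        raise ValueError("thresholds must be positive")
    if strict:
        return (fct.fc_beads > t_beads) & (fct.fc_unmod > t_unmod)
    return (fct.fc_beads >= t_beads) & (fct.fc_unmod >= t_unmod)


def rank_candidates(
    fct: FoldChangeTable,
    calls: pd.DataFrame,
    medians: ConditionMedians,
    modification: str,
) -> list[str]:
    """Candidates for one modification, strongest first.

    Ordered by descending median normalized iBAQ in the bait condition,
    ties broken by descending fold change vs unmodified C, then by
    ``group_id`` for determinism.
    """
    if modification not in MODIFICATIONS:
        raise ValueError(f"unknown modification {modification!r}")
    ids = calls.index[calls[modification]]
    return sorted(
        ids,
        key=lambda g: (
            -medians.values.at[g, modification],
            -fct.fc_unmod.at[g, modification],
            g,
        ),
    )
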