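"""Unique-binder classification and four-set overlap structure.

A *unique binder* is a protein called candidate for exactly one of the
four modified baits. The full overlap structure over the four candidate
sets has 15 regions (one per nonempty subset of baits), matching a
four-set Venn diagram.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from modreaders.design import MODIFICATIONS


@dataclass(frozen=True)
class UniqueBinderSets:
    """Per-modification unique-binder sets and 15-region overlap counts.

    ``unique`` maps each modification to the proteins called for it and
    nothing else; the four sets are pairwise disjoint. ``overlap_counts``
    maps each nonempty subset of modifications (as a sorted tuple in
    canonical bait order) to the number of proteins called in exactly
    that subset; the 15 region counts sum to the number of proteins
    called for at least one bait.
    """

    unique: dict[str, set[str]]
    overlap_counts: dict[tuple[str, ...], int]


def _regions() -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    for r in range(1, len(MODIFICATIONS) + 1):
        out.extend(combinations(MODIFICATIONS, r))
    return out


def unique_binders(calls: pd.DataFrame) -> UniqueBinderSets:
    """Derive unique sets and exact-subset region counts from calls.

    ``calls`` is a boolean protein x modification frame covering all
    four modifications. Proteins called for no modification belong to
    no region and no unique set.
    """
    missing = [m for m in MODIFICATIONS if m not in calls.columns]
    if missing:
        raise ValueError(f"calls missing modification column(s): {missing}")
    unique: dict[str, set[str]] = {m: set() for m in MODIFICATIONS}
    overlap_counts: dict[tuple[str, ...], int] = {r: 0 for r in _regions()}
    for gid, row in calls[list(MODIFICATIONS)].iterrows():
        subset = tuple(m for m in MODIFICATIONS if bool(row[m]))
        if not subset:
            continue
        overlap_counts[subset] += 1
        if len(subset) == 1:
            unique[subset[0]].add(gid)
    return UniqueBinderSets(unique=unique, overlap_counts=overlap_counts)


def write_venn_counts(sets: UniqueBinderSets, path: str | Path) -> None:
    """Region label (sorted modification list, '+'-joined) and count."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("region\tcount\n")
        for region in _regions():
            fh.write(f"{'+'.join(region)}\t{sets.overlap_counts[region]}\n")


def write_unique_binders(
    sets: UniqueBinderSets,
    ranked: dict[str, list[str]],
    gene_names: dict[str, str],
    path: str | Path,
) -> None:
    """One row per unique binder with its within-bait rank (1-based)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("modification\tgroup_id\tgene_name\trank\n")
        for mod in MODIFICATIONS:
            rank = 0
            for gid in ranked[mod]:
                if gid not in sets.unique[mod]:
                    continue
                rank += 1
                fh.write(f"{mod}\t{gid}\t{gene_names.get(gid, '')}\t{rank}\n")
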