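"""Reading and writing MaxQuant-style tables and pipeline outputs.

The parser targets the ``proteinGroups.txt`` dialect: tab-delimited,
UTF-8, one header row, one row per protein group, QC flag columns
(``Reverse``, ``Potential contaminant``, ``Only identified by site``)
containing ``+`` when set, and one iBAQ intensity column per sample
named ``<prefix><sample_id>`` (default prefix ``"iBAQ "``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from modreaders.design import CONDITIONS, MODIFICATIONS, DesignError, SampleDesign

DEFAULT_IBAQ_PREFIX = "iBAQ "

#: Canonical MaxQuant column names for the QC flags.
FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
}


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class QCPolicy:
    """Which QC-flagged rows to drop.

    MaxQuant flags decoy matches (``Reverse``), common contaminants
    (``Potential contaminant``) and groups identified only by a
    modification site. Standard practice drops the first two and keeps
    the third; all three switches are configurable.
    """

    drop_reverse: bool = True
    drop_contaminant: bool = True
    drop_only_by_site: bool = False


@dataclass
class ProteinRecord:
    """One protein group with identifiers, QC flags and per-sample iBAQ.

    Intensities are arbitrary units; ``0`` encodes "not detected" and is
    treated downstream as a measured zero.
    """

    group_id: str
    gene_name: str
    majority_ids: list[str]
    is_contaminant: bool
    is_reverse: bool
    is_only_by_site: bool
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, value in self.intensities.items():
            if value < 0:
                raise ValueError(
                    f"negative intensity {value!r} for protein "
                    f"{self.group_id!r}, sample {sample!r}"
                )


def _flag(value: object) -> bool:
    return str(value).strip() == "+"


def read_protein_groups(
    path: str | Path,
    design: SampleDesign,
    qc_policy: QCPolicy = QCPolicy(),
    ibaq_prefix: str = DEFAULT_IBAQ_PREFIX,
) -> list[ProteinRecord]:
    """Parse a proteinGroups table into one record per retained row.

    Parameters
    ----------
    path
        Tab-delimited proteinGroups file with a header row.
    design
        Sample design; every ``sample_id`` must have a matching
        ``<ibaq_prefix><sample_id>`` column.
    qc_policy
        Which flagged rows to drop.
    ibaq_prefix
        Prefix of per-sample intensity columns.

    Raises
    ------
    FormatError
        Missing header, missing iBAQ column for a designed sample, or a
        non-numeric intensity cell (the error names row and column).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, missing header row") from None
        col_index = {name: i for i, name in enumerate(header)}
        if "Protein IDs" not in col_index:
            raise FormatError(
                f"{path}: header lacks 'Protein IDs'; not a proteinGroups table"
            )
        sample_cols: dict[str, int] = {}
        for sample_id in design.sample_ids:
            col = f"{ibaq_prefix}{sample_id}"
            if col not in col_index:
                raise FormatError(
                    f"{path}: design mismatch, no column {col!r} for "
                    f"sample {sample_id!r}"
                )
            sample_cols[sample_id] = col_index[col]

        def cell(row: list[str], name: str) -> str:
            i = col_index.get(name)
            return row[i] if i is not None and i < len(row) else ""

        records: list[ProteinRecord] = []
        seen_ids: set[str] = set()
        for row_num, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            is_reverse = _flag(cell(row, FLAG_COLUMNS["reverse"]))
            is_contaminant = _flag(cell(row, FLAG_COLUMNS["contaminant"]))
            is_only_by_site = _flag(cell(row, FLAG_COLUMNS["only_by_site"]))
            if (
                (qc_policy.drop_reverse and is_reverse)
                or (qc_policy.drop_contaminant and is_contaminant)
                or (qc_policy.drop_only_by_site and is_only_by_site)
            ):
                continue
            group_id = cell(row, "Protein IDs")
            if group_id in seen_ids:
                raise FormatError(f"{path}: duplicate group id {group_id!r}")
            seen_ids.add(group_id)
            intensities: dict[str, float] = {}
            for sample_id, i in sample_cols.items():
                raw = row[i].strip() if i < len(row) else ""
                if raw == "":
                    value = 0.0
                else:
                    try:
                        value = float(raw)
                    except ValueError:
                        raise FormatError(
                            f"{path}: non-numeric intensity {raw!r} at row "
                            f"{row_num}, column {ibaq_prefix}{sample_id!r}"
                        ) from None
                    if value != value:  # NaN
                        raise FormatError(
                            f"{path}: non-numeric intensity {raw!r} at row "
                            f"{row_num}, column {ibaq_prefix}{sample_id!r}"
                        )
                intensities[sample_id] = value
            records.append(
                ProteinRecord(
                    group_id=group_id,
                    gene_name=cell(row, "Gene names"),
                    majority_ids=[
                        a
                        for a in cell(row, "Majority protein IDs").split(";")
                        if a
                    ],
                    is_contaminant=is_contaminant,
                    is_reverse=is_reverse,
                    is_only_by_site=is_only_by_site,
                    intensities=intensities,
                )
            )
    return records


def read_design(path: str | Path) -> SampleDesign:
    """Read a tab-delimited design file (sample_id, condition, replicate)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: design file missing column(s) {', '.join(sorted(missing))}"
        )
    samples = []
    for _, row in df.iterrows():
        try:
            replicate = int(row["replicate"])
        except (TypeError, ValueError):
            raise DesignError(
                f"{path}: non-integer replicate {row['replicate']!r} for "
                f"sample {row['sample_id']!r}"
            ) from None
        samples.append((str(row["sample_id"]), str(row["condition"]), replicate))
    return SampleDesign(tuple(samples))


def write_design(design: SampleDesign, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tcondition\treplicate\n")
        for sample_id, condition, replicate in design.samples:
            fh.write(f"{sample_id}\t{condition}\t{replicate}\n")


def records_to_frame(
    records: Sequence[ProteinRecord], design: SampleDesign
) -> pd.DataFrame:
    """Protein x sample intensity matrix (rows ordered as given)."""
    ids = [r.group_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate group_id among records")
    data = {
        sid: [r.intensities.get(sid, 0.0) for r in records]
        for sid in design.sample_ids
    }
    return pd.DataFrame(data, index=pd.Index(ids, name="group_id"), dtype=float)


def _fmt(x: float) -> str:
    return repr(float(x))


def write_candidate_table(
    records: Sequence[ProteinRecord],
    medians: "pd.DataFrame",
    fold_changes: "object",
    calls: pd.DataFrame,
    unique_sets: "object",
    path: str | Path,
) -> None:
    """Write the ranked per-protein candidate table.

    One row per protein: identifiers, per-condition medians, fold
    changes vs both controls, per-modification candidate flags and the
    unique-binder label. Rows are ordered by descending ranking score
    (the protein's largest bait-condition median), ties broken by
    ``group_id``; the order is deterministic for fixed inputs.
    """
    keys = [r.group_id for r in records]
    key_set = set(keys)
    for frame, label in (
        (medians, "medians"),
        (fold_changes.fc_beads, "fold changes"),
        (calls, "calls"),
    ):
        if set(frame.index) != key_set:
            raise ValueError(f"protein keys of {label} do not match records")

    unique_label = {}
    for mod, members in unique_sets.unique.items():
        for gid in members:
            unique_label[gid] = mod

    gene_of = {r.group_id: r.gene_name for r in records}
    score = medians[list(MODIFICATIONS)].max(axis=1)
    order = sorted(keys, key=lambda g: (-score[g], g))

    with Path(path).open("w", encoding="utf-8") as fh:
        cols = (
            ["group_id", "gene_name"]
            + [f"median_{c}" for c in CONDITIONS]
            + [f"fc_beads_{m}" for m in MODIFICATIONS]
            + [f"fc_unmod_{m}" for m in MODIFICATIONS]
            + [f"candidate_{m}" for m in MODIFICATIONS]
            + ["unique_binder"]
        )
        fh.write("\t".join(cols) + "\n")
        for gid in order:
            row = [gid, gene_of[gid]]
            row += [_fmt(medians.at[gid, c]) for c in CONDITIONS]
            row += [_fmt(fold_changes.fc_beads.at[gid, m]) for m in MODIFICATIONS]
            row += [_fmt(fold_changes.fc_unmod.at[gid, m]) for m in MODIFICATIONS]
            row += ["+" if calls.at[gid, m] else "" for m in MODIFICATIONS]
            row.append(unique_label.get(gid, ""))
            fh.write("\t".join(row) + "\n")


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    """Re-parse a table written by :func:`write_candidate_table`.

    Candidate flag columns come back as booleans; numeric columns as
    floats. Used for round-trip checks and downstream consumption.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"group_id": str, "gene_name": str}, keep_default_na=False
    )
    for m in MODIFICATIONS:
        df[f"candidate_{m}"] = df[f"candidate_{m}"].astype(str) == "+"
    for c in df.columns:
        if c.startswith(("median_", "fc_")):
            df[c] = df[c].astype(float)
    return df.set_index("group_id")
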