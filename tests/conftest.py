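from __future__ import annotations

import pytest

from modreaders.design import CONDITIONS, SampleDesign
from modreaders.io import ProteinRecord
from modreaders.simulate import default_design


@pytest.fixture(scope="session")
def design18() -> SampleDesign:
    """Canonical 6-condition x 3-replicate design (18 samples)."""
    return default_design(replicates=3)


def make_records(rows: dict[str, list[float]], design: SampleDesign,
                 genes: dict[str, str] | None = None) -> list[ProteinRecord]:
    """Build records from {group_id: [values in design sample order]}."""
    genes = genes or {}
    records = []
    for gid, values in rows.items():
        assert len(values) == len(design.sample_ids)
        records.append(
            ProteinRecord(
                group_id=gid,
                gene_name=genes.get(gid, gid.lower()),
                majority_ids=[gid],
                is_contaminant=False,
                is_reverse=False,
                is_only_by_site=False,
                intensities=dict(zip(design.sample_ids, map(float, values))),
            )
        )
    return records


@pytest.fixture
def toy_protein_groups(tmp_path, design18):
    """A 5-row proteinGroups file: 3 clean rows, 1 reverse, 1 contaminant."""
    sample_ids = design18.sample_ids
    header = (
        ["Protein IDs", "Majority protein IDs", "Gene names", "Reverse",
         "Potential contaminant", "Only identified by site"]
        + [f"iBAQ {s}" for s in sample_ids]
    )
    rows = [
        ["P1", "P1", "alpha-1", "", "", ""] + ["100"] * 18,
        ["P2", "P2;P2b", "beta-2", "", "", ""] + ["250"] * 18,
        ["REV__P3", "REV__P3", "", "+", "", ""] + ["50"] * 18,
        ["CON__P4", "CON__P4", "", "", "+", ""] + ["900"] * 18,
        ["P5", "P5", "gamma-3", "", "", "+"] + ["10"] * 18,
    ]
    path = tmp_path / "proteinGroups.txt"
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path
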