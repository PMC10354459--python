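"""RRM RNP1/RNP2 consensus-motif scanning on protein sequences.

The RNA recognition motif (RRM) carries two short ribonucleoprotein
consensus sequences on its beta-sheet surface. The default degenerate
patterns follow the standard literature consensus:

* RNP1 (8 residues): ``[RK]-G-[FY]-[GA]-[FY]-[ILVM]-x-[FY]``
* RNP2 (6 residues): ``[ILVM]-[FY]-[ILVM]-x-N-L``

``x`` matches any residue. ``X`` (unknown residue) is tolerated in
sequences but never matches a constrained position. Patterns are fully
overridable via a plain-text pattern file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_CHARS = set(AMINO_ACIDS) | {"X"}

#: Default degenerate patterns (bracketed character classes, x = any).
DEFAULT_PATTERNS: dict[str, str] = {
    "RNP1": "[RK]G[FY][GA][FY][ILVM]x[FY]",
    "RNP2": "[ILVM][FY][ILVM]xNL",
}


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``start`` is 0-based, interval half-open."""

    sequence_id: str
    motif: str
    start: int
    matched: str


def parse_pattern(pattern: str) -> list[frozenset[str] | None]:
    """Compile a degenerate pattern into per-position allowed sets.

    ``None`` marks an unconstrained (``x``) position, which matches any
    sequence character including ``X``.
    """
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed character class in pattern {pattern!r}")
            cls = pattern[i + 1 : j]
            if not cls or any(c not in AMINO_ACIDS for c in cls):
                raise ValueError(f"invalid character class {cls!r} in {pattern!r}")
            positions.append(frozenset(cls))
            i = j + 1
        elif ch == "x":
            positions.append(None)
            i += 1
        elif ch in AMINO_ACIDS:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise ValueError(f"illegal pattern character {ch!r} in {pattern!r}")
    if not positions:
        raise ValueError("empty pattern")
    return positions


def scan_rnp_motifs(
    sequence: str,
    patterns: Mapping[str, str] = DEFAULT_PATTERNS,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All (possibly overlapping) motif matches, left to right.

    The sequence must be over the 20-letter amino-acid alphabet plus
    ``X``; an illegal character raises with its position. ``X`` never
    satisfies a constrained pattern position.
    """
    seq = sequence.upper()
    for pos, ch in enumerate(seq):
        if ch not in _VALID_CHARS:
            raise ValueError(
                f"illegal amino-acid character {ch!r} at position {pos}"
                + (f" in sequence {sequence_id!r}" if sequence_id else "")
            )
    compiled = {name: parse_pattern(p) for name, p in patterns.items()}
    hits: list[MotifHit] = []
    for start in range(len(seq)):
        for name, positions in compiled.items():
            end = start + len(positions)
            if end > len(seq):
                continue
            window = seq[start:end]
            if all(
                allowed is None or window[i] in allowed
                for i, allowed in enumerate(positions)
            ):
                hits.append(MotifHit(sequence_id, name, start, window))
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA id -> amino-acid sequence."""
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def read_pattern_file(path: str | Path) -> dict[str, str]:
    """Pattern file: ``motif_name TAB degenerate_pattern`` per line."""
    patterns: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected name TAB pattern")
            parse_pattern(parts[1])  # validate eagerly
            patterns[parts[0]] = parts[1]
    if not patterns:
        raise ValueError(f"{path}: no patterns found")
    return patterns


def flag_rrm_candidates(
    unique_sets: "object",
    sequences: Mapping[str, str],
    gene_names: Mapping[str, str],
    patterns: Mapping[str, str] = DEFAULT_PATTERNS,
) -> tuple[list[dict], list[str]]:
    """Flag unique binders whose sequences carry RNP1/RNP2 motifs.

    Sequences are joined to candidates by gene name (case-insensitive
    exact match against FASTA record ids). Returns one row per matched
    candidate — ``group_id, modification, has_RNP1, has_RNP2`` plus a
    hit count per motif — and the list of unmatched candidate ids.
    """
    seq_by_key = {sid.lower(): (sid, s) for sid, s in sequences.items()}
    rows: list[dict] = []
    unmatched: list[str] = []
    for mod, members in unique_sets.unique.items():
        for gid in sorted(members):
            key = gene_names.get(gid, "").lower()
            if not key or key not in seq_by_key:
                unmatched.append(gid)
                continue
            sid, seq = seq_by_key[key]
            hits = scan_rnp_motifs(seq, patterns, sequence_id=sid)
            by_motif = {name: 0 for name in patterns}
            for h in hits:
                by_motif[h.motif] += 1
            row = {"group_id": gid, "modification": mod, "sequence_id": sid}
            for name in patterns:
                row[f"has_{name}"] = by_motif[name] > 0
                row[f"n_{name}"] = by_motif[name]
            rows.append(row)
    return rows, sorted(set(unmatched))


def write_rrm_flags(
    rows: list[dict],
    unmatched: list[str],
    path: str | Path,
    patterns: Mapping[str, str] = DEFAULT_PATTERNS,
) -> None:
    names = list(patterns)
    with Path(path).open("w", encoding="utf-8") as fh:
        cols = ["group_id", "modification", "sequence_id"]
        for n in names:
            cols += [f"has_{n}", f"n_{n}"]
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            out = [row["group_id"], row["modification"], row["sequence_id"]]
            for n in names:
                out += ["+" if row[f"has_{n}"] else "", str(row[f"n_{n}"])]
            fh.write("\t".join(out) + "\n")
        for gid in unmatched:
            fh.write(f"{gid}\tunmatched\t\t" + "\t".join([""] * 2 * len(names)) + "\n")
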