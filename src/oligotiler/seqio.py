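"""Sequence and design I/O.

FASTA reading/writing is delegated to Biopython; designs are exported as a
flat CSV order sheet (one row per oligomer, sequences written 5'->3' on the
oligomer's own strand) that round-trips back into an
:class:`~oligotiler.designer.AssemblyDesign`.

Internal coordinates are 0-based, half-open, on the top strand; the CSV
export uses 1-based inclusive coordinates as is conventional in oligo order
sheets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .designer import AssemblyDesign, DesignParams

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Column order of the design CSV export.
CSV_COLUMNS = [
    "index",
    "name",
    "strand",
    "ref_start",
    "ref_end",
    "length",
    "sequence",
    "overlap_with_next",
    "overlap_tm",
    "overlap_gc",
    "tm_dev",
    "three_prime_t",
    "gc_clamp",
    "r_within",
    "r_between",
    "total",
    "cluster",
]


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the A/C/G/T alphabet."""


def validate_dna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase *seq* and reject anything outside {A, C, G, T}.

    Ambiguity codes (N, R, Y, ...) are rejected rather than resolved: the
    nearest-neighbor thermodynamics downstream are defined only for the four
    unambiguous bases.  The error names the 1-based offending position.
    """
    seq = seq.upper()
    for pos, base in enumerate(seq, start=1):
        if base not in DNA_ALPHABET:
            raise SequenceValidationError(
                f"invalid base {base!r} at position {pos} in {context}"
            )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A validated DNA sequence with an identifier."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", validate_dna(self.residues, context=f"record {self.id!r}")
        )
        if len(self.residues) < 1:
            raise SequenceValidationError(f"record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement of *seq*, reversed (an involution)."""
    seq = validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read all records from a FASTA file, uppercased and validated."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to *path* in FASTA format."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def write_design_csv(design: "AssemblyDesign", path: str | Path) -> None:
    """Export a complete design as a CSV order sheet.

    One row per oligomer; sequences are the oligomer's own strand 5'->3'
    (bottom-strand rows carry the reverse complement of their reference
    slice).  Melting temperatures and GC percentages are rounded to two
    decimals; coordinates are 1-based inclusive.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for oligo, score in zip(design.oligomers, design.scores):
            ov = design.overlap_after(oligo.index)
            writer.writerow(
                [
                    oligo.index,
                    oligo.name,
                    oligo.strand,
                    oligo.ref_start + 1,
                    oligo.ref_end,
                    len(oligo.sequence),
                    oligo.sequence,
                    ov.sequence if ov is not None else "",
                    f"{ov.tm:.2f}" if ov is not None else "",
                    f"{ov.gc:.2f}" if ov is not None else "",
                    f"{score.tm_dev:.2f}",
                    score.three_prime_t,
                    score.gc_clamp,
                    score.r_within,
                    score.r_between,
                    f"{score.total:.2f}",
                    design.clusters.cluster_of(oligo.index),
                ]
            )


def read_design_csv(
    path: str | Path, params: "DesignParams | None" = None
) -> "AssemblyDesign":
    """Rebuild an :class:`AssemblyDesign` from a CSV written by
    :func:`write_design_csv`.

    The reference sequence is reconstructed by stitching the oligomer rows
    back together; Tm/GC/score fields are restored at the 2-decimal precision
    of the export.  *params* supplies the design parameters to attach (the
    CSV does not carry them); defaults are used when omitted.
    """
    from .designer import (
        AssemblyDesign,
        DesignParams,
        Oligomer,
        Overlap,
        ScoreBreakdown,
    )
    from .repeatscan import ClusterPartition, RepeatReport
    from . import verify as _verify

    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(CSV_COLUMNS) - set(reader.fieldnames):
            raise ValueError(f"{path} is not a design CSV (missing columns)")
        for row in reader:
            rows.append(row)
    if not rows:
        raise ValueError(f"{path} contains no oligomer rows")

    oligomers: list[Oligomer] = []
    overlaps: list[Overlap] = []
    scores: list[ScoreBreakdown] = []
    cluster_ids: list[int] = []
    for row in rows:
        idx = int(row["index"])
        start = int(row["ref_start"]) - 1
        end = int(row["ref_end"])
        oligomers.append(
            Oligomer(
                index=idx,
                strand=row["strand"],
                ref_start=start,
                ref_end=end,
                sequence=validate_dna(row["sequence"], context=f"oligomer {idx}"),
                name=row["name"],
            )
        )
        scores.append(
            ScoreBreakdown(
                tm_dev=float(row["tm_dev"]),
                three_prime_t=int(row["three_prime_t"]),
                gc_clamp=int(row["gc_clamp"]),
                r_within=int(row["r_within"]),
                r_between=int(row["r_between"]),
            )
        )
        cluster_ids.append(int(row["cluster"]))
        if row["overlap_with_next"]:
            overlaps.append(
                Overlap(
                    left_index=idx,
                    right_index=idx + 1,
                    ref_start=end - len(row["overlap_with_next"]),
                    ref_end=end,
                    sequence=validate_dna(
                        row["overlap_with_next"], context=f"overlap {idx}"
                    ),
                    tm=float(row["overlap_tm"]),
                    gc=float(row["overlap_gc"]),
                )
            )

    groups: list[tuple[int, int]] = []
    for idx, cid in zip(range(1, len(cluster_ids) + 1), cluster_ids):
        if groups and cid == len(groups):
            groups[-1] = (groups[-1][0], idx)
        else:
            groups.append((idx, idx))
    clusters = ClusterPartition(groups=groups)

    params = params if params is not None else DesignParams()
    design = AssemblyDesign(
        reference=SequenceRecord(id=path.stem, residues="A"),  # placeholder
        params=params,
        oligomers=oligomers,
        overlaps=overlaps,
        scores=scores,
        clusters=clusters,
        repeat_report=RepeatReport(
            r_within=[s.r_within for s in scores],
            r_between=[s.r_between for s in scores],
            conflict_pairs=[],
        ),
    )
    reference = _verify.reconstruct(design, check_reference=False)
    design.reference = SequenceRecord(id=path.stem, residues=reference)
    return design
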