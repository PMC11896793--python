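"""In-silico validation of a finished design.

``reconstruct`` stitches the oligomer set back into the double-stranded
target (the inverse of the tiling), and ``crosscheck`` screens every
non-adjacent pair of junction overlaps for shared canonical k-mers that
could drive mis-annealing during assembly.  Verification is advisory:
conflicts are reported, not fatal — sub-pool segregation, not rejection,
is how repeat-sharing junctions are handled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import repeatscan
from .designer import AssemblyDesign


class StructureError(RuntimeError):
    """The oligomer set is internally inconsistent (bad extents/overlaps)."""


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of reconstructing and screening a design.

    ``conflicts`` holds (junction pair, shared k-mer, severity) entries
    where the pair is (left oligomer ordinal of junction A, left oligomer
    ordinal of junction B) and severity is the shared base-pair coverage;
    sorted by severity descending, then pair index.
    """

    reconstructed: str
    matches_reference: bool
    unique_junctions: bool
    conflicts: list[tuple[tuple[int, int], str, int]] = field(default_factory=list)
    first_mismatch: int | None = None  # 0-based position, when not matching


def reconstruct(design: AssemblyDesign, *, check_reference: bool = True) -> str:
    """Rebuild the top-strand target from the oligomer set.

    Adjacent oligomers must intersect in exactly the recorded overlap and
    agree letter-for-letter on it; overlapping bases are counted once.
    Raises :class:`StructureError` naming the junction on any inconsistency.
    Pure function: the design is not modified.
    """
    oligos = design.oligomers
    if not oligos:
        raise StructureError("design contains no oligomers")
    if oligos[0].ref_start != 0:
        raise StructureError("first oligomer does not start at reference position 0")
    result = oligos[0].top_strand_sequence()
    prev_end = oligos[0].ref_end
    for left, right in zip(oligos, oligos[1:]):
        junction = left.index
        ov = design.overlap_after(junction)
        if ov is None:
            raise StructureError(f"missing overlap record at junction {junction}")
        if (ov.ref_start, ov.ref_end) != (right.ref_start, left.ref_end):
            raise StructureError(
                f"junction {junction}: recorded overlap "
                f"[{ov.ref_start}, {ov.ref_end}) is not the intersection of "
                f"oligomers {left.index} and {right.index}"
            )
        ov_len = left.ref_end - right.ref_start
        if ov_len <= 0:
            raise StructureError(
                f"junction {junction}: oligomers {left.index} and "
                f"{right.index} do not overlap"
            )
        top = right.top_strand_sequence()
        if top[:ov_len] != result[right.ref_start :]:
            raise StructureError(
                f"junction {junction}: overlap sequences disagree between "
                f"oligomers {left.index} and {right.index}"
            )
        result += top[ov_len:]
        prev_end = right.ref_end
    if len(result) != prev_end:
        raise StructureError("reconstructed length disagrees with final extent")
    if check_reference and result != design.reference.residues:
        raise StructureError(
            "reconstructed sequence disagrees with the design's reference"
        )
    return result


def crosscheck(design: AssemblyDesign, k: int | None = None) -> VerificationReport:
    """Reconstruct the design and screen overlaps for shared k-mers.

    Every non-adjacent junction pair (index distance >= 2) is screened with
    reverse-complement-aware k-mer keys; adjacent junctions are excluded by
    definition (their sharing is the designed overlap).  *k* defaults to the
    design's repeat_len_between.
    """
    if k is None:
        k = design.params.repeat_len_between
    if k < 2:
        raise ValueError("k must be >= 2")
    reconstructed = reconstruct(design, check_reference=False)
    reference = design.reference.residues
    matches = reconstructed == reference
    first_mismatch = None
    if not matches:
        limit = min(len(reconstructed), len(reference))
        first_mismatch = next(
            (i for i in range(limit) if reconstructed[i] != reference[i]), limit
        )

    conflicts: list[tuple[tuple[int, int], str, int]] = []
    overlaps = design.overlaps
    for a in range(len(overlaps)):
        for b in range(a + 2, len(overlaps)):
            shared = repeatscan.shared_kmers(
                overlaps[a].sequence, overlaps[b].sequence, k
            )
            if not shared:
                continue
            severity = repeatscan.shared_repeat_bp(
                overlaps[a].sequence, overlaps[b].sequence, k
            )
            for kmer in sorted(shared):
                conflicts.append(
                    (
                        (overlaps[a].left_index, overlaps[b].left_index),
                        kmer,
                        severity,
                    )
                )
    conflicts.sort(key=lambda c: (-c[2], c[0], c[1]))
    return VerificationReport(
        reconstructed=reconstructed,
        matches_reference=matches,
        unique_junctions=not conflicts,
        conflicts=conflicts,
        first_mismatch=first_mismatch,
    )
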