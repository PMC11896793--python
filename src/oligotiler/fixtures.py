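"""Deterministic synthetic-sequence generation for tests and examples.

Sequences are drawn with an exact base composition (the number of G+C bases
is fixed to the target percentage up to rounding, split evenly between G
and C, likewise A/T) and then shuffled with a seeded generator, so the
realized GC content is within 1/length of the target and every sequence is
reproducible across platforms for a fixed seed.  Known motifs can be
planted at fixed positions to create controlled repeat structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord, validate_dna


class FixtureSpecError(ValueError):
    """The fixture specification is inconsistent (e.g. overlapping plants)."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic sequence.

    planted_repeats is a list of (motif, positions) entries; each motif is
    written verbatim at every listed 0-based position, and planted regions
    must not overlap each other or run past the sequence end.
    """

    length: int
    seed: int
    gc_target: float = 50.0
    planted_repeats: list[tuple[str, list[int]]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise FixtureSpecError("length must be >= 1")
        if not 0 < self.gc_target < 100:
            raise FixtureSpecError("gc_target must be in (0, 100)")
        occupied: list[tuple[int, int]] = []
        for motif, positions in self.planted_repeats:
            validate_dna(motif, context=f"planted motif {motif!r}")
            for pos in positions:
                if pos < 0 or pos + len(motif) > self.length:
                    raise FixtureSpecError(
                        f"plant of {motif!r} at {pos} runs outside the sequence"
                    )
                span = (pos, pos + len(motif))
                for s, e in occupied:
                    if span[0] < e and s < span[1]:
                        raise FixtureSpecError(
                            f"planted regions overlap at positions {span[0]}..{span[1]}"
                        )
                occupied.append(span)


def random_sequence(spec: FixtureSpec) -> SequenceRecord:
    """Generate the sequence described by *spec* (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    n_gc = round(n * spec.gc_target / 100.0)
    n_g = n_gc // 2
    n_c = n_gc - n_g
    n_at = n - n_gc
    n_a = n_at // 2
    n_t = n_at - n_a
    pool = np.array(list("G" * n_g + "C" * n_c + "A" * n_a + "T" * n_t))
    seq = list(rng.permutation(pool))
    for motif, positions in spec.planted_repeats:
        for pos in positions:
            seq[pos : pos + len(motif)] = list(motif)
    name = spec.name or f"synthetic_s{spec.seed}_l{n}"
    return SequenceRecord(id=name, residues="".join(seq))


def gc_balanced(length: int, seed: int, name: str = "") -> SequenceRecord:
    """Convenience: a 50% GC random sequence."""
    return random_sequence(FixtureSpec(length=length, seed=seed, name=name))
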