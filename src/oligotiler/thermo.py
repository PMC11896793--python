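"""Nearest-neighbor duplex thermodynamics and simple sequence statistics.

Duplex stability is modeled as a sum over adjacent base-pair stacks, each
contributing tabulated enthalpy/entropy, plus terminal initiation terms
(the unified SantaLucia parameter set, shipped as a plain-text TSV so it is
inspectable and swappable).  The melting temperature follows the two-state
model with the classic 16.6*log10[Na+] monovalent-salt correction:

    Tm(degC) = 1000*dH / (dS + R*ln(C_T/4)) - 273.15 + 16.6*log10([Na+])

with R = 1.987 cal/(mol*K), dH in kcal/mol and dS in cal/(mol*K).  For a
self-complementary duplex the concentration factor is C_T/1 and the
symmetry entropy correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .seqio import reverse_complement, validate_dna

GAS_CONSTANT = 1.987  # cal / (mol K)

#: Terminal window inspected for GC-clamp excess, and the allowance within it.
GC_CLAMP_WINDOW = 5
GC_CLAMP_ALLOWANCE = 3


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor dimer parameters plus initiation/symmetry terms.

    ``dimer_params`` maps each of the 10 unique stacks to (dH kcal/mol,
    dS cal/(mol*K)); reverse-complement dimers share parameters and are
    resolved at lookup time.
    """

    dimer_params: dict[str, tuple[float, float]]
    init_gc: tuple[float, float]
    init_at: tuple[float, float]
    symmetry: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.dimer_params) != 10:
            raise ValueError(
                f"expected 10 unique nearest-neighbor dimers, got {len(self.dimer_params)}"
            )
        for dimer, (dh, _) in self.dimer_params.items():
            if dh >= 0:
                raise ValueError(f"stacking enthalpy for {dimer} must be negative")

    def lookup(self, dimer: str) -> tuple[float, float]:
        """Parameters for *dimer*, falling back to its reverse complement."""
        try:
            return self.dimer_params[dimer]
        except KeyError:
            return self.dimer_params[reverse_complement(dimer)]


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions for Tm evaluation.

    oligo_conc is the total strand concentration C_T in mol/L;
    monovalent_salt is the Na+ (equivalent) concentration in mol/L.
    Defaults are 250 nM total strand and 100 mM Na+ equivalent; the salt
    default places a typical 20-mer 50%-GC annealing overlap at ~56 degC,
    consistent with pairing 20 bp overlaps with a 56 degC target.  Both are
    configurable to match any vendor calculator.
    """

    oligo_conc: float = 2.5e-7
    monovalent_salt: float = 0.1

    def __post_init__(self) -> None:
        if self.oligo_conc <= 0 or self.monovalent_salt <= 0:
            raise ValueError("oligo_conc and monovalent_salt must be positive")


def load_nn_table(path: str | Path | None = None) -> NNParameterTable:
    """Load the nearest-neighbor table from a TSV (dimer, dH, dS).

    Without *path* the packaged unified table is used.
    """
    if path is None:
        text = (
            resources.files("oligotiler.data").joinpath("nn_unified_v1.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    dimers: dict[str, tuple[float, float]] = {}
    init_gc = init_at = symmetry = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, dh, ds = line.split("\t")
        value = (float(dh), float(ds))
        if key == "init_GC":
            init_gc = value
        elif key == "init_AT":
            init_at = value
        elif key == "symmetry":
            symmetry = value
        else:
            dimers[key] = value
    if init_gc is None or init_at is None or symmetry is None:
        raise ValueError("nearest-neighbor table is missing initiation/symmetry terms")
    return NNParameterTable(
        dimer_params=dimers, init_gc=init_gc, init_at=init_at, symmetry=symmetry
    )


DEFAULT_NN_TABLE = load_nn_table()


def duplex_enthalpy_entropy(
    seq: str, table: NNParameterTable = DEFAULT_NN_TABLE
) -> tuple[float, float]:
    """Total (dH kcal/mol, dS cal/(mol*K)) for the duplex of *seq*.

    Sum of the two terminal initiation terms and every consecutive dimer
    stack.  Invariant under reverse complementation (the duplex is the same
    molecule read from the other strand).
    """
    seq = validate_dna(seq)
    if len(seq) < 2:
        raise ValueError("duplex thermodynamics require at least one stacked pair")
    dh = ds = 0.0
    for terminal in (seq[0], seq[-1]):
        ih, is_ = table.init_gc if terminal in "GC" else table.init_at
        dh += ih
        ds += is_
    for i in range(len(seq) - 1):
        sh, ss = table.lookup(seq[i : i + 2])
        dh += sh
        ds += ss
    return dh, ds


def is_self_complementary(seq: str) -> bool:
    return seq == reverse_complement(seq)


def melting_temperature(
    seq: str,
    cond: ThermoConditions = ThermoConditions(),
    table: NNParameterTable = DEFAULT_NN_TABLE,
) -> float:
    """Two-state nearest-neighbor melting temperature in degrees Celsius."""
    dh, ds = duplex_enthalpy_entropy(seq, table)
    if is_self_complementary(seq):
        ds += table.symmetry[1]
        dh += table.symmetry[0]
        conc = cond.oligo_conc
    else:
        conc = cond.oligo_conc / 4.0
    tm_kelvin = 1000.0 * dh / (ds + GAS_CONSTANT * math.log(conc))
    return tm_kelvin - 273.15 + 16.6 * math.log10(cond.monovalent_salt)


def gc_content(seq: str) -> float:
    """G+C percentage of *seq* (0-100)."""
    seq = validate_dna(seq)
    if not seq:
        raise ValueError("gc_content of an empty sequence is undefined")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def gc_clamp_excess(overlap_seq: str) -> int:
    """G/C count above the allowance in the terminal 5 bases of an overlap.

    A few G/C near the annealing 3' terminus stabilize it; more than 3 in
    the last 5 bases promotes mispriming, so the penalty is the excess over
    that allowance (0 for any compliant terminus).
    """
    overlap_seq = validate_dna(overlap_seq)
    if len(overlap_seq) < GC_CLAMP_WINDOW:
        raise ValueError(
            f"overlap shorter than {GC_CLAMP_WINDOW} nt has no defined clamp window"
        )
    tail = overlap_seq[-GC_CLAMP_WINDOW:]
    return max(0, tail.count("G") + tail.count("C") - GC_CLAMP_ALLOWANCE)


def three_prime_thymine(oligo_seq: str) -> int:
    """1 if the 3'-terminal base of the (5'->3') oligomer is thymine, else 0."""
    oligo_seq = validate_dna(oligo_seq)
    if not oligo_seq:
        raise ValueError("empty oligomer has no 3' terminus")
    return 1 if oligo_seq[-1] == "T" else 0
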