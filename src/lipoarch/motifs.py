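"""Degenerate amino-acid consensus motifs and the LplA-N validation scan.

Archaeal LplA-N proteins are validated by two conserved motifs.  Motif 1,
``RRXTGGG(G/A/S/T)(A/I/V)(I/F/Y)HD`` (12 positions), sits at the LplA-N
/LplA-C functional interface and includes the lipoate-binding loop; its
second R and the first two Gs (positions 2, 5 and 6) form an invariant
core.  Motif 2, ``G(R/K)K(I/L/V)SGX(A/G)Q`` (9 positions), forms part of
strand β9 adjacent to the lipoate-binding loop; the first G, the S and
the Q (positions 1, 5 and 9) tolerate occasional substitution.

Pattern grammar: literal residues, ``X`` wildcard (any residue), and
parenthesized slash-separated alternatives like ``(G/A/S/T)``.
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import MotifParseError, ParameterError

AA_ALPHABET: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate consensus: one allowed-residue set per position."""

    positions: tuple[frozenset[str], ...]
    core_positions: frozenset[int]
    substitutable_positions: frozenset[int]
    name: str = ""
    pattern: str = ""

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    matched: str
    n_mismatches: int


@dataclass(frozen=True)
class LplANVerdict:
    sequence_id: str
    has_motif1: bool
    has_motif2: bool
    valid: bool
    motif1_hits: tuple[MotifHit, ...]
    motif2_hits: tuple[MotifHit, ...]


def parse_motif(
    pattern_string: str,
    core_positions: Iterable[int] = (),
    substitutable_positions: Iterable[int] = (),
    name: str = "",
) -> MotifPattern:
    """Parse a consensus pattern string into a :class:`MotifPattern`.

    ``core_positions`` (never relaxable) and ``substitutable_positions``
    (where mismatches may be tolerated) are 1-based indices within the
    motif and must be disjoint.
    """
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(pattern_string):
        ch = pattern_string[i]
        if ch == "(":
            j = pattern_string.find(")", i)
            if j < 0:
                raise MotifParseError(f"unbalanced parenthesis in {pattern_string!r}")
            alts = pattern_string[i + 1 : j].split("/")
            if not alts or any(len(a) != 1 or a not in AA_ALPHABET for a in alts):
                raise MotifParseError(f"bad alternative group {pattern_string[i:j+1]!r}")
            positions.append(frozenset(alts))
            i = j + 1
        elif ch == "X":
            positions.append(AA_ALPHABET)
            i += 1
        elif ch in AA_ALPHABET:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise MotifParseError(f"unexpected character {ch!r} in {pattern_string!r}")
    if not positions:
        raise MotifParseError("empty motif pattern")
    core = frozenset(core_positions)
    subst = frozenset(substitutable_positions)
    n = len(positions)
    for idx in core | subst:
        if not 1 <= idx <= n:
            raise MotifParseError(f"position {idx} outside motif of length {n}")
    if core & subst:
        raise MotifParseError("core and substitutable positions overlap")
    return MotifPattern(
        positions=tuple(positions),
        core_positions=core,
        substitutable_positions=subst,
        name=name,
        pattern=pattern_string,
    )


#: lipoate-binding-loop motif at the LplA-N:LplA-C interface (exact by default)
LPLA_N_MOTIF_1 = parse_motif(
    "RRXTGGG(G/A/S/T)(A/I/V)(I/F/Y)HD",
    core_positions=(2, 5, 6),
    name="lplA-N_interface",
)

#: β9 motif (residues 143–151 in T. acidophilum LplA-N); G1/S5/Q9 substitutable
LPLA_N_MOTIF_2 = parse_motif(
    "G(R/K)K(I/L/V)SGX(A/G)Q",
    substitutable_positions=(1, 5, 9),
    name="lplA-N_beta9",
)


def _matches_at(residue: str, pos_set: frozenset[str]) -> bool:
    # an unknown residue (X) only matches wildcard positions, never a
    # constrained set — in particular never a core position
    if residue == "X":
        return pos_set == AA_ALPHABET
    return residue in pos_set


def scan_motif(
    sequence: str, motif: MotifPattern, max_mismatch: int = 0,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """All windows matching the motif with ≤ ``max_mismatch`` mismatches.

    Mismatches are only tolerated at the motif's substitutable positions;
    core and other non-substitutable positions must match exactly.
    Overlapping hits are all reported, sorted by start.
    """
    if max_mismatch < 0:
        raise ParameterError("max_mismatch must be nonnegative")
    seq = sequence.upper()
    m = len(motif)
    hits: list[MotifHit] = []
    for start0 in range(len(seq) - m + 1):
        window = seq[start0 : start0 + m]
        n_mm = 0
        ok = True
        for offset, (residue, pos_set) in enumerate(zip(window, motif.positions)):
            if _matches_at(residue, pos_set):
                continue
            if (offset + 1) in motif.substitutable_positions:
                n_mm += 1
                if n_mm > max_mismatch:
                    ok = False
                    break
            else:
                ok = False
                break
        if ok:
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=start0 + 1,
                    end=start0 + m,
                    matched=window,
                    n_mismatches=n_mm,
                )
            )
    return hits


def validate_lpla_n(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    motif1: MotifPattern = LPLA_N_MOTIF_1,
    motif2: MotifPattern = LPLA_N_MOTIF_2,
    motif1_max_mismatch: int = 0,
    motif2_max_mismatch: int = 1,
) -> dict[str, LplANVerdict]:
    """Per-sequence verdict: valid LplA-N ⟺ ≥ 1 hit of each motif."""
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    verdicts: dict[str, LplANVerdict] = {}
    for seq_id, seq in items:
        h1 = scan_motif(seq, motif1, motif1_max_mismatch, sequence_id=seq_id)
        h2 = scan_motif(seq, motif2, motif2_max_mismatch, sequence_id=seq_id)
        verdicts[seq_id] = LplANVerdict(
            sequence_id=seq_id,
            has_motif1=bool(h1),
            has_motif2=bool(h2),
            valid=bool(h1) and bool(h2),
            motif1_hits=tuple(h1),
            motif2_hits=tuple(h2),
        )
    return verdicts
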