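"""Peptide chemistry model: tryptic digestion, monoisotopic masses,
singly-charged b/y fragment ions, matched-ion counting and coverage.

All masses are monoisotopic, in daltons.  Fragment m/z values are for
singly protonated ions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from regioprot.errors import ValidationError
from regioprot.io_formats import STANDARD_RESIDUES, VALID_MODIFICATIONS

# Monoisotopic residue masses (Da), standard peptide mass tables.
RESIDUE_MASSES: Mapping[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MASS = 18.010565
PROTON_MASS = 1.007276

MOD_DELTAS: Mapping[str, float] = {
    "Oxidation": 15.994915,
    "Carbamidomethyl": 57.021464,
    "Propionamide": 71.037114,
}

# search tolerances carried as metadata for the synthetic generator
PARENT_TOLERANCE_DA = 0.4
FRAGMENT_TOLERANCE_DA = 0.2


@dataclass(frozen=True)
class TrypticPeptide:
    """A digestion product with 1-based inclusive parent coordinates."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValidationError(
                f"coordinates {self.start}..{self.end} do not match "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class FragmentSeries:
    """Singly-charged b and y ion m/z ladders for one peptide."""

    b_mz: tuple[float, ...]
    y_mz: tuple[float, ...]
    charge: int = 1


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValidationError("empty sequence")
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise ValidationError(f"invalid residue(s) {sorted(bad)}")


def _check_modifications(
    sequence: str, modifications: Sequence[tuple[int, str]]
) -> None:
    for pos, name in modifications:
        if name not in VALID_MODIFICATIONS:
            raise ValidationError(f"unknown modification {name!r}")
        if not (1 <= pos <= len(sequence)):
            raise ValidationError(f"modification position {pos} out of range")
        if sequence[pos - 1] != VALID_MODIFICATIONS[name]:
            raise ValidationError(
                f"{name} not allowed on residue "
                f"{sequence[pos - 1]!r} at {pos}"
            )


def digest(sequence: str, max_missed: int = 1) -> list[TrypticPeptide]:
    """In-silico tryptic digestion with the Keil rule.

    Cleaves C-terminal to K or R unless the next residue is P.  Returns
    all peptides with 0..``max_missed`` missed cleavages (``max_missed``
    in {0, 1}), ordered by start position then length.
    """
    _check_sequence(sequence)
    if max_missed not in (0, 1):
        raise ValidationError("max_missed must be 0 or 1")
    n = len(sequence)
    # boundaries: index i means a cut between residue i and i+1 (0-based)
    cuts = [0]
    for i, residue in enumerate(sequence):
        if residue in "KR" and (i + 1 == n or sequence[i + 1] != "P"):
            if i + 1 < n:
                cuts.append(i + 1)
    cuts.append(n)

    base: list[TrypticPeptide] = []
    for lo, hi in zip(cuts, cuts[1:]):
        base.append(
            TrypticPeptide(
                sequence=sequence[lo:hi],
                start=lo + 1,
                end=hi,
                missed_cleavages=0,
            )
        )
    peptides = list(base)
    if max_missed == 1:
        for left, right in zip(base, base[1:]):
            peptides.append(
                TrypticPeptide(
                    sequence=left.sequence + right.sequence,
                    start=left.start,
                    end=right.end,
                    missed_cleavages=1,
                )
            )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def peptide_mass(
    sequence: str, modifications: Sequence[tuple[int, str]] = ()
) -> float:
    """Neutral monoisotopic peptide mass: residues + water + mod deltas."""
    _check_sequence(sequence)
    _check_modifications(sequence, modifications)
    mass = sum(RESIDUE_MASSES[res] for res in sequence) + WATER_MASS
    mass += sum(MOD_DELTAS[name] for _, name in modifications)
    return mass


def precursor_mz(
    sequence: str,
    modifications: Sequence[tuple[int, str]] = (),
    charge: int = 2,
) -> float:
    """m/z of the protonated precursor at the given charge."""
    if charge < 1:
        raise ValidationError("charge must be positive")
    mass = peptide_mass(sequence, modifications)
    return (mass + charge * PROTON_MASS) / charge


def fragment_ions(
    sequence: str,
    modifications: Sequence[tuple[int, str]] = (),
    charge: int = 1,
) -> FragmentSeries:
    """Singly-charged b and y ion ladders (b1..b(n-1), y1..y(n-1)).

    b_i = sum of the first i residue(+mod) masses + proton;
    y_i = sum of the last i residue(+mod) masses + water + proton.
    """
    _check_sequence(sequence)
    _check_modifications(sequence, modifications)
    if charge != 1:
        raise ValidationError("only singly-charged fragments are modeled")
    n = len(sequence)
    if n < 2:
        raise ValidationError("peptide must have at least 2 residues")
    per_residue = [RESIDUE_MASSES[res] for res in sequence]
    for pos, name in modifications:
        per_residue[pos - 1] += MOD_DELTAS[name]

    b_mz = []
    running = 0.0
    for i in range(n - 1):
        running += per_residue[i]
        b_mz.append(running + PROTON_MASS)
    y_mz = []
    running = 0.0
    for i in range(n - 1):
        running += per_residue[n - 1 - i]
        y_mz.append(running + WATER_MASS + PROTON_MASS)
    return FragmentSeries(b_mz=tuple(b_mz), y_mz=tuple(y_mz), charge=1)


def count_matched_ions(
    series: FragmentSeries,
    peaks: Iterable[float],
    tol: float = FRAGMENT_TOLERANCE_DA,
) -> tuple[int, int]:
    """Count theoretical b/y ions with >=1 observed peak within +/-tol.

    Each theoretical ion is judged independently and counts at most once;
    a single observed peak may satisfy several theoretical ions.
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    peak_list = sorted(peaks)

    def matched(mz: float) -> bool:
        import bisect

        i = bisect.bisect_left(peak_list, mz - tol)
        return i < len(peak_list) and peak_list[i] <= mz + tol

    n_b = sum(1 for mz in series.b_mz if matched(mz))
    n_y = sum(1 for mz in series.y_mz if matched(mz))
    return n_b, n_y


def coverage(
    intervals: Iterable[TrypticPeptide | tuple[int, int]],
    protein_length: int,
) -> float:
    """Percent of residues covered by the union of intervals, 1 decimal.

    Accepts :class:`TrypticPeptide` objects or (start, end) 1-based
    inclusive tuples; overlaps and duplicates are merged.
    """
    if protein_length < 1:
        raise ValidationError("protein_length must be positive")
    spans: list[tuple[int, int]] = []
    for item in intervals:
        if isinstance(item, TrypticPeptide):
            start, end = item.start, item.end
        else:
            start, end = item
        if start < 1 or end > protein_length or start > end:
            raise ValidationError(
                f"interval {start}..{end} outside 1..{protein_length}"
            )
        spans.append((start, end))
    if not spans:
        return 0.0
    spans.sort()
    covered = 0
    cur_start, cur_end = spans[0]
    for start, end in spans[1:]:
        if start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    covered += cur_end - cur_start + 1
    return round(covered / protein_length * 100, 1)
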