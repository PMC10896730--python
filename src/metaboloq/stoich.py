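"""Spectral-count estimation of protein-complex molar stoichiometry.

The estimator rests on the observation that a protein's peptide-spectrum
match count (PSM) in a shotgun run is approximately proportional to the
product of its molar abundance and the number of its tryptic peptides
detectable by MS (NOP), optionally corrected by a per-protein response
factor ("effective NOP").  Within one complex all subunits share the same
molar abundance, so a zero-intercept regression of PSM on effective NOP
across the complex's subunits estimates that abundance up to a common
instrument constant — and the ratio of two complexes' slopes is their
molar stoichiometry, instrument constant cancelled.

Pipeline: in-silico tryptic digestion -> effective NOP -> per-complex
zero-intercept slope -> slope ratio with a protein-level bootstrap
confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from pyteomics import parser as _pyt_parser

__all__ = [
    "AMINO_ACIDS",
    "ProteinEntry",
    "DigestionRules",
    "PSMTable",
    "SlopeFit",
    "StoichResult",
    "SequenceError",
    "EstimationError",
    "tryptic_peptides",
    "effective_nop",
    "complex_slope",
    "stoichiometry_ratio",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """A sequence contains a character outside the 20-letter alphabet."""


class EstimationError(ValueError):
    """A slope or ratio cannot be estimated from the given inputs."""


@dataclass(frozen=True)
class ProteinEntry:
    """A protein with its complex membership and optional MS response factor."""

    id: str
    sequence: str
    complex_label: str
    response_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.response_factor <= 0:
            raise ValueError(
                f"protein {self.id!r}: response_factor must be > 0, "
                f"got {self.response_factor}"
            )
        _check_sequence(self.sequence)


def _check_sequence(sequence: str) -> None:
    for pos, ch in enumerate(sequence):
        if ch not in AMINO_ACIDS:
            raise SequenceError(
                f"invalid amino-acid character {ch!r} at position {pos}"
            )


@dataclass(frozen=True)
class DigestionRules:
    """Trypsin digestion and detectability window.

    Cleavage is C-terminal to K or R; with ``suppress_proline`` a following
    proline blocks the cut.  Peptides with up to ``missed_cleavages``
    internal sites are enumerated, and only those whose length falls in
    [min_length, max_length] count as detectable.  The 7-35 residue window
    with no missed cleavages is a standard bottom-up heuristic.
    """

    suppress_proline: bool = True
    missed_cleavages: int = 0
    min_length: int = 7
    max_length: int = 35

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("need 0 < min_length <= max_length")

    @property
    def cleavage_rule(self) -> str:
        return r"[KR](?=[^P])" if self.suppress_proline else r"[KR]"


DEFAULT_RULES = DigestionRules()


@dataclass
class PSMTable:
    """Spectral counts keyed by protein id (unique ids, non-negative ints)."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for pid, c in self.counts.items():
            if int(c) != c or c < 0:
                raise ValueError(
                    f"PSM count for {pid!r} must be a non-negative integer, got {c}"
                )
        self.counts = {pid: int(c) for pid, c in self.counts.items()}

    @classmethod
    def from_rows(cls, rows) -> "PSMTable":
        counts: dict[str, int] = {}
        for pid, c in rows:
            if pid in counts:
                raise ValueError(f"duplicate protein id {pid!r} in PSM table")
            counts[pid] = c
        return cls(counts)


def tryptic_peptides(sequence: str, rules: DigestionRules | None = None) -> list[str]:
    """Detectable tryptic peptides of a sequence, N- to C-terminal order.

    NOP is the length of the returned list; identical peptides occurring at
    different positions are counted separately.
    """
    rules = rules or DEFAULT_RULES
    _check_sequence(sequence)
    if not sequence:
        return []
    pieces = list(
        _pyt_parser.icleave(
            sequence, rules.cleavage_rule, missed_cleavages=rules.missed_cleavages
        )
    )
    pieces.sort(key=lambda p: (p[0], len(p[1])))
    return [
        pep for _, pep in pieces if rules.min_length <= len(pep) <= rules.max_length
    ]


def effective_nop(protein: ProteinEntry, rules: DigestionRules | None = None) -> float:
    """NOP scaled by the protein's MS response factor (identity by default)."""
    return len(tryptic_peptides(protein.sequence, rules)) * protein.response_factor


@dataclass(frozen=True)
class SlopeFit:
    """Zero-intercept PSM-vs-effective-NOP slope for one complex."""

    complex_label: str
    slope: float
    n_proteins: int
    protein_ids: tuple[str, ...]
    eff_nop: tuple[float, ...]
    psm: tuple[int, ...]
    residuals: dict[str, float]


def _zero_intercept_slope(nop: np.ndarray, psm: np.ndarray) -> float:
    # argmin_b sum (psm - b*nop)^2  ==>  b = sum(psm*nop) / sum(nop^2)
    return float(np.dot(psm, nop) / np.dot(nop, nop))


def _complex_points(
    psm: PSMTable,
    proteins: list[ProteinEntry],
    complex_label: str,
    rules: DigestionRules | None,
):
    by_id = {p.id: p for p in proteins}
    for pid in psm.counts:
        if pid not in by_id:
            warnings.warn(
                f"PSM row {pid!r} has no protein entry; skipped", UserWarning
            )
    members = [p for p in proteins if p.complex_label == complex_label]
    pts = []
    for p in members:
        if p.id not in psm.counts:
            warnings.warn(
                f"protein {p.id!r} of complex {complex_label!r} missing from the "
                f"PSM table; skipped", UserWarning,
            )
            continue
        nop = effective_nop(p, rules)
        if nop > 0:
            pts.append((p.id, nop, psm.counts[p.id]))
    return pts


def complex_slope(
    psm: PSMTable,
    proteins: list[ProteinEntry],
    complex_label: str,
    rules: DigestionRules | None = None,
) -> SlopeFit:
    """Zero-intercept least-squares slope of PSM against effective NOP.

    Uses the complex's proteins present in both inputs with positive
    effective NOP; raises :class:`EstimationError` when none qualify.
    """
    pts = _complex_points(psm, proteins, complex_label, rules)
    if not pts:
        raise EstimationError(
            f"no usable proteins for complex {complex_label!r} "
            "(need membership, a PSM row and effective NOP > 0)"
        )
    ids, nop, counts = zip(*pts)
    nop_a = np.array(nop, dtype=float)
    psm_a = np.array(counts, dtype=float)
    slope = _zero_intercept_slope(nop_a, psm_a)
    residuals = {
        pid: float(c - slope * n) for pid, n, c in zip(ids, nop_a, psm_a)
    }
    return SlopeFit(
        complex_label=complex_label,
        slope=slope,
        n_proteins=len(pts),
        protein_ids=tuple(ids),
        eff_nop=tuple(float(n) for n in nop_a),
        psm=tuple(int(c) for c in counts),
        residuals=residuals,
    )


@dataclass
class StoichResult:
    """Slope-ratio molar stoichiometry of complex A to complex B."""

    fit_a: SlopeFit
    fit_b: SlopeFit
    ratio: float | None           # slope_a / slope_b; None when slope_b == 0
    ci_low: float | None
    ci_high: float | None
    n_boot: int
    n_boot_defined: int           # bootstrap resamples with a finite ratio
    seed: int

    @property
    def undefined(self) -> bool:
        return self.ratio is None


def stoichiometry_ratio(
    psm: PSMTable,
    proteins: list[ProteinEntry],
    complex_a: str,
    complex_b: str,
    rules: DigestionRules | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> StoichResult:
    """Molar stoichiometry A:B as the ratio of zero-intercept slopes.

    The 95% interval is a percentile bootstrap resampling proteins (the
    unit of replication) within each complex independently.  A zero B slope
    flags the ratio undefined instead of raising.
    """
    fit_a = complex_slope(psm, proteins, complex_a, rules)
    fit_b = complex_slope(psm, proteins, complex_b, rules)
    ratio = fit_a.slope / fit_b.slope if fit_b.slope != 0 else None

    rng = np.random.default_rng(seed)
    a_nop = np.array(fit_a.eff_nop)
    a_psm = np.array(fit_a.psm, dtype=float)
    b_nop = np.array(fit_b.eff_nop)
    b_psm = np.array(fit_b.psm, dtype=float)
    samples = []
    for _ in range(n_boot):
        ia = rng.integers(0, a_nop.size, size=a_nop.size)
        ib = rng.integers(0, b_nop.size, size=b_nop.size)
        sb = _zero_intercept_slope(b_nop[ib], b_psm[ib])
        if sb == 0:
            continue
        samples.append(_zero_intercept_slope(a_nop[ia], a_psm[ia]) / sb)
    if samples:
        lo, hi = np.percentile(samples, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        ci = (None, None)
    return StoichResult(
        fit_a=fit_a, fit_b=fit_b, ratio=ratio,
        ci_low=ci[0], ci_high=ci[1],
        n_boot=n_boot, n_boot_defined=len(samples), seed=seed,
    )
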