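"""Seeded generators for every input the pipeline consumes.

Two families of synthetic data:

* absorbance traces — the ODE model's reduced-cytochrome-c trajectory
  scaled by a gain, offset by a baseline and corrupted with i.i.d.
  Gaussian noise, emulating a spectrophotometer record of cytochrome c
  reduction in isolated mitochondria;
* proteomics fixtures — protein sequences constructed to digest into an
  exact number of detectable tryptic peptides, and PSM tables drawn from
  a Poisson model whose mean is proportional to complex molar abundance
  times effective NOP (the exact regime under which the slope-ratio
  stoichiometry estimator is consistent).

Every generator is deterministic given its seed and returns its ground
truth alongside the data, so recovery tests consume only the data and
compare against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import ObservedTrace
from .network import ReactionNetwork
from .qcycle import QCycleScenario, apply_scenario, build_canonical_network
from .simulate import SolverSettings, integrate
from .stoich import DigestionRules, PSMTable, ProteinEntry, effective_nop

__all__ = [
    "TraceNoiseModel",
    "SyntheticProteome",
    "synth_absorbance_trace",
    "synth_protein",
    "synth_psm_table",
    "make_synthetic_proteome",
]

# residues used for filler positions: no K/R (cleavage sites), no P
# (would suppress an adjacent site)
_FILLER_ALPHABET = "ACDEFGHILMNQSTVWY"


@dataclass(frozen=True)
class TraceNoiseModel:
    """Observation model for a synthetic absorbance trace."""

    sigma: float = 0.0          # Gaussian s.d., absorbance a.u.
    gain: float = 1.0           # absorbance a.u. per a.u. of reduced cyt c
    baseline: float = 0.0       # absorbance a.u.
    sample_times: np.ndarray | None = None  # default: 101 points on [0, t_end]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def synth_absorbance_trace(
    scenario: QCycleScenario,
    noise: TraceNoiseModel,
    network: ReactionNetwork | None = None,
    settings: SolverSettings | None = None,
) -> tuple[ObservedTrace, dict]:
    """Noisy absorbance trace from a scenario: baseline + gain*x5(t) + N(0, sigma^2).

    Returns the trace and a ground-truth record (scenario label, ETFDH
    level, gain, baseline, sigma, seed, noiseless signal).  Sample times
    beyond the integration horizon are a domain error.
    """
    network = network or build_canonical_network()
    settings = settings or SolverSettings()
    if noise.sample_times is None:
        times = np.linspace(0.0, settings.t_end, 101)
    else:
        times = np.asarray(noise.sample_times, dtype=float)
    if times.size == 0:
        raise ValueError("sample_times must be non-empty")
    if times.min() < 0 or times.max() > settings.t_end:
        raise ValueError(
            f"sample times must lie within [0, {settings.t_end}], got "
            f"[{times.min()}, {times.max()}]"
        )
    traj = integrate(
        apply_scenario(network, scenario), settings, t_eval=times,
        scenario_label=scenario.label,
    )
    clean = noise.baseline + noise.gain * traj.series("x5")
    rng = np.random.default_rng(noise.seed)
    signal = clean + rng.normal(0.0, noise.sigma, size=clean.size)
    trace = ObservedTrace(times=times, signal=signal)
    truth = {
        "scenario": scenario.label,
        "etfdh_level": scenario.etfdh_level,
        "overrides": dict(scenario.overrides),
        "gain": noise.gain,
        "baseline": noise.baseline,
        "sigma": noise.sigma,
        "seed": noise.seed,
        "noiseless_signal": clean,
    }
    return trace, truth


def synth_protein(
    n_detectable: int,
    protein_id: str = "SYN",
    seed: int = 0,
    complex_label: str = "NA",
    rules: DigestionRules | None = None,
) -> ProteinEntry:
    """Protein whose digestion yields exactly ``n_detectable`` peptides.

    Construction: ``n_detectable`` blocks of eight filler residues (drawn
    from a fixed K/R/P-free alphabet, seeded) each terminated by K — nine
    residues, inside the default 7-35 detectability window — followed by a
    short K/R-free tail that digests to an undetectable fragment.
    """
    if n_detectable < 0:
        raise ValueError("n_detectable must be >= 0")
    rules = rules or DigestionRules()
    block_len = max(rules.min_length, 9) - 1
    if block_len + 1 > rules.max_length:
        raise ValueError("detectability window too narrow for block construction")
    rng = np.random.default_rng(seed)
    letters = np.array(list(_FILLER_ALPHABET))
    blocks = [
        "".join(rng.choice(letters, size=block_len)) + "K"
        for _ in range(n_detectable)
    ]
    tail = "A" * min(4, rules.min_length - 1)
    return ProteinEntry(
        id=protein_id,
        sequence="".join(blocks) + tail,
        complex_label=complex_label,
    )


@dataclass
class SyntheticProteome:
    """Proteins with complex labels, complex molar abundances, and a target depth."""

    proteins: list[ProteinEntry]
    complex_abundances: dict[str, float]
    depth: float = 1e4   # expected total PSM count across all proteins
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"depth must be > 0, got {self.depth}")
        for label, a in self.complex_abundances.items():
            if a < 0:
                raise ValueError(f"abundance of {label!r} must be >= 0, got {a}")
        for p in self.proteins:
            if p.complex_label not in self.complex_abundances:
                raise ValueError(
                    f"protein {p.id!r} belongs to {p.complex_label!r}, which has "
                    "no abundance entry"
                )


def synth_psm_table(
    proteome: SyntheticProteome,
    rules: DigestionRules | None = None,
) -> tuple[PSMTable, dict]:
    """Poisson spectral counts under the proportionality assumption.

    PSM_p ~ Poisson(depth * abundance(complex of p) * effNOP_p / Z) with Z
    the total abundance-weighted effective NOP, so expected counts sum to
    ``depth`` and each complex's expected share is proportional to its
    molar abundance.  Returns the table and the ground truth (abundances,
    per-protein means, seed).
    """
    weights = {}
    for p in proteome.proteins:
        weights[p.id] = proteome.complex_abundances[p.complex_label] * effective_nop(
            p, rules
        )
    total = sum(weights.values())
    if total <= 0:
        raise ValueError(
            "degenerate proteome: all abundance-weighted effective NOPs are zero"
        )
    rng = np.random.default_rng(proteome.seed)
    lam = {pid: proteome.depth * w / total for pid, w in weights.items()}
    counts = {pid: int(rng.poisson(l)) for pid, l in lam.items()}
    truth = {
        "complex_abundances": dict(proteome.complex_abundances),
        "expected_counts": lam,
        "depth": proteome.depth,
        "seed": proteome.seed,
    }
    return PSMTable(counts), truth


def make_synthetic_proteome(
    complex_abundances: dict[str, float],
    proteins_per_complex: int = 4,
    nop_low: int = 5,
    nop_high: int = 40,
    depth: float = 1e4,
    seed: int = 0,
) -> SyntheticProteome:
    """Convenience proteome: per complex, proteins with NOPs spread over a range.

    Protein sizes (detectable-peptide counts) are drawn uniformly from
    [nop_low, nop_high] with a seeded generator; sequences come from
    :func:`synth_protein`.
    """
    if proteins_per_complex < 1:
        raise ValueError("proteins_per_complex must be >= 1")
    rng = np.random.default_rng(seed)
    proteins = []
    for label in sorted(complex_abundances):
        for i in range(proteins_per_complex):
            n = int(rng.integers(nop_low, nop_high + 1))
            proteins.append(
                synth_protein(
                    n,
                    protein_id=f"{label}_{i + 1}",
                    seed=int(rng.integers(0, 2**31 - 1)),
                    complex_label=label,
                )
            )
    return SyntheticProteome(
        proteins=proteins,
        complex_abundances=dict(complex_abundances),
        depth=depth,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
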