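"""Least-squares fitting of the Q-cycle model to reduced-cytochrome-c traces.

An observed trace is modelled as ``baseline + gain * x5(t; theta)`` where
x5 is the reduced cytochrome c state of the ODE model and theta collects
the free model quantities (rate constants and/or initial amounts).  Gain
and baseline absorb the arbitrary units of a spectrophotometer record and
are fitted as nuisance parameters by default.

Fitting is bounded multistart local least squares: starting points are
drawn uniformly within the bounds from a seeded generator, each start is
polished with scipy's trust-region reflective solver, and the best result
wins.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .network import ReactionNetwork, UnknownIdError
from .qcycle import build_canonical_network
from .simulate import IntegrationError, SolverSettings, integrate

__all__ = [
    "ObservedTrace",
    "FitResult",
    "PENALTY_LOSS",
    "model_loss",
    "fit_parameters",
    "recover_etfdh_level",
    "classify_genotype",
    "DEFAULT_ETFDH_BOUNDS",
]

#: RSS returned when the ODE solver fails at a proposed parameter point.
PENALTY_LOSS = 1e12

#: Default bounds for the ETFDH-level recovery problem.
DEFAULT_ETFDH_BOUNDS: dict[str, tuple[float, float]] = {
    "x9": (0.0, 2.0),
    "gain": (0.2, 5.0),
    "baseline": (-0.5, 0.5),
}


@dataclass
class ObservedTrace:
    """A reduced-cytochrome-c proxy signal sampled at distinct times.

    Points are sorted by time on construction, so the loss is invariant to
    the order in which they arrive; duplicate times are rejected.
    """

    times: np.ndarray
    signal: np.ndarray
    gain: float | None = None      # known gain, if any; else fitted/assumed 1
    baseline: float | None = None  # known baseline, if any; else fitted/assumed 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.signal)) or not np.all(np.isfinite(self.times)):
            raise ValueError("trace contains non-finite values")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.signal = self.signal[order]
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be distinct")


@dataclass
class FitResult:
    """Best multistart fit: estimates, residual sum of squares, diagnostics."""

    estimates: dict[str, float]
    loss: float
    n_evaluations: int
    converged: bool
    seed: int
    n_starts: int
    start_losses: list[float] = field(default_factory=list)


def _split_free(free_names, free_values):
    """Partition free quantities into species initials, parameters, gain, baseline."""
    species, params = {}, {}
    gain = baseline = None
    for name, value in zip(free_names, free_values):
        if name == "gain":
            gain = float(value)
        elif name == "baseline":
            baseline = float(value)
        elif name.startswith("k"):
            params[name] = float(value)
        elif name.startswith("x"):
            species[name] = float(value)
        else:
            raise UnknownIdError(f"free quantity {name!r} is not recognised")
    return species, params, gain, baseline


def _predict(
    free_values,
    free_names,
    trace: ObservedTrace,
    network: ReactionNetwork,
    settings: SolverSettings,
) -> np.ndarray | None:
    """Model signal at the trace's times, or None on integration failure."""
    species, params, gain, baseline = _split_free(free_names, free_values)
    if gain is None:
        gain = trace.gain if trace.gain is not None else 1.0
    if baseline is None:
        baseline = trace.baseline if trace.baseline is not None else 0.0
    net = network.with_updates(species, params)
    if trace.times[-1] > settings.t_end:
        settings = replace(settings, t_end=float(trace.times[-1]))
    try:
        traj = integrate(net, settings, t_eval=trace.times)
    except IntegrationError as err:
        warnings.warn(f"integration failed during fitting: {err}", RuntimeWarning)
        return None
    return baseline + gain * traj.series("x5")


def model_loss(
    free_values,
    free_names,
    trace: ObservedTrace,
    network: ReactionNetwork | None = None,
    settings: SolverSettings | None = None,
) -> float:
    """Residual sum of squares of the trace against the model signal.

    Integration failures return a large penalty (with a warning) instead of
    raising, so optimizers can route around bad regions.
    """
    network = network or build_canonical_network()
    settings = settings or SolverSettings()
    pred = _predict(free_values, free_names, trace, network, settings)
    if pred is None:
        return PENALTY_LOSS
    return float(np.sum((trace.signal - pred) ** 2))


def fit_parameters(
    trace: ObservedTrace,
    free_names: list[str],
    bounds: dict[str, tuple[float, float]],
    n_starts: int = 8,
    seed: int = 0,
    network: ReactionNetwork | None = None,
    settings: SolverSettings | None = None,
) -> FitResult:
    """Bounded multistart local least squares; deterministic given the seed.

    ``bounds`` must supply a finite (lower, upper) pair, lower < upper, for
    every free quantity.  The fit with the lowest RSS across starts wins.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    network = network or build_canonical_network()
    settings = settings or SolverSettings()
    lo = np.array([bounds[n][0] for n in free_names], dtype=float)
    hi = np.array([bounds[n][1] for n in free_names], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(lo < hi)):
        raise ValueError("bounds must be finite with lower < upper")

    n_eval = 0

    def residuals(theta):
        nonlocal n_eval
        n_eval += 1
        pred = _predict(theta, free_names, trace, network, settings)
        if pred is None:
            return np.full(trace.signal.size, np.sqrt(PENALTY_LOSS / trace.signal.size))
        return pred - trace.signal

    rng = np.random.default_rng(seed)
    starts = lo + rng.uniform(size=(n_starts, lo.size)) * (hi - lo)
    best = None
    start_losses: list[float] = []
    any_ok = False
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception as err:  # keep the multistart alive
            warnings.warn(f"a fitting start failed: {err}", RuntimeWarning)
            start_losses.append(float("inf"))
            continue
        rss = float(2.0 * res.cost)
        start_losses.append(rss)
        any_ok = any_ok or bool(res.success)
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        return FitResult({n: float("nan") for n in free_names}, float("inf"),
                         n_eval, False, seed, n_starts, start_losses)
    rss, res = best
    estimates = {n: float(v) for n, v in zip(free_names, res.x)}
    return FitResult(estimates, rss, n_eval, any_ok and bool(res.success),
                     seed, n_starts, start_losses)


def recover_etfdh_level(
    trace: ObservedTrace,
    seed: int = 0,
    network: ReactionNetwork | None = None,
    settings: SolverSettings | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 4,
) -> tuple[float, FitResult]:
    """Estimate the initial ETFDH level x9(0) from an absorbance trace.

    Convenience wrapper over :func:`fit_parameters` with free set
    {x9, gain, baseline}.  The estimate is clipped to the x9 bounds.  The
    3-parameter problem is well conditioned, so fewer starts than the
    generic default suffice.
    """
    if trace.times.size < 10:
        raise ValueError(
            f"ETFDH-level recovery needs >= 10 time points, got {trace.times.size}"
        )
    bounds = dict(DEFAULT_ETFDH_BOUNDS if bounds is None else bounds)
    result = fit_parameters(
        trace, ["x9", "gain", "baseline"], bounds,
        n_starts=n_starts, seed=seed, network=network, settings=settings,
    )
    lo, hi = bounds["x9"]
    estimate = float(np.clip(result.estimates.get("x9", lo), lo, hi))
    return estimate, result


def classify_genotype(
    etfdh_estimate: float, levels: tuple[float, ...] = (0.0, 0.5, 1.0)
) -> float:
    """Nearest canonical ETFDH level (ko=0, het=0.5, wt=1) to an estimate."""
    return float(min(levels, key=lambda g: abs(g - etfdh_estimate)))
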