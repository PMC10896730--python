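"""Numerical integration, derived observables and scenario comparison.

The integrator is scipy's adaptive LSODA (stiff-capable) driven by a
compiled form of the generalized mass-action right-hand side.  Observables
summarize a trajectory the way the model's predictions are phrased: how
much cytochrome c ends up reduced (final value and area under the curve),
and how long semiquinone radicals dwell on complex III.

Three semiquinone areas are reported.  ``semiquinone_auc_standby``
integrates the Qo-site radical x4 — the species that, without ETFDH,
is left stranded on the enzyme when the N-side proton pool runs out, and
hence the model's carrier of the "radical waiting on CIII" notion.  The
Qi-site area (x12 + x13) and the total including the ETFDH-bound radical
are reported alongside; note that these *grow* with ETFDH level simply
because ETFDH multiplies Q-cycle throughput.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import (
    NEGATIVE_STATE_TOL,
    NetworkError,
    ReactionNetwork,
    StateDomainError,
    stoichiometry_matrix,
)
from .qcycle import QCycleScenario, apply_scenario, build_canonical_network

__all__ = [
    "SolverSettings",
    "Trajectory",
    "Observables",
    "FluxSummary",
    "ScenarioComparison",
    "IntegrationError",
    "compile_rhs",
    "integrate",
    "steady_state_reached",
    "compute_observables",
    "integrated_fluxes",
    "compare_scenarios",
]


class IntegrationError(NetworkError):
    """The ODE solver failed or produced non-finite state."""


@dataclass(frozen=True)
class SolverSettings:
    """Integration horizon, output grid and tolerances.

    Defaults (t_end=10, rtol=1e-8, atol=1e-10) bring all three canonical
    ETFDH scenarios close to quiescence while conserving the linear pools
    to well below 1e-6.
    """

    t_end: float = 10.0
    n_out: int = 1001
    rtol: float = 1e-8
    atol: float = 1e-10
    steady_tol: float = 1e-8
    stop_at_steady: bool = False
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if self.n_out < 2:
            raise ValueError(f"n_out must be >= 2, got {self.n_out}")
        if min(self.rtol, self.atol, self.steady_tol) <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class Trajectory:
    """Dense time course of all state variables plus solver diagnostics."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    species_ids: list[str]
    scenario: str = "custom"
    settings: SolverSettings | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(self.species_ids)):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{self.times.size} times x {len(self.species_ids)} species"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.size and self.states.min() < NEGATIVE_STATE_TOL:
            raise ValueError(
                f"trajectory states dip below {NEGATIVE_STATE_TOL}: "
                f"min = {self.states.min()}"
            )

    def series(self, species_id: str) -> np.ndarray:
        try:
            return self.states[:, self.species_ids.index(species_id)]
        except ValueError:
            raise KeyError(
                f"species {species_id!r} not in trajectory (has {self.species_ids})"
            ) from None


def compile_rhs(network: ReactionNetwork):
    """Return fast callables ``f(x) -> dx/dt`` and ``rates(x) -> flux vector``.

    States in [-1e-9, 0) are clamped to zero before evaluation; the adaptive
    solver may transiently probe slightly negative values.
    """
    k = np.array([network.parameter_value(r.rate_constant) for r in network.reactions])
    factor_idx = [
        np.array([network.species_index(sp) for sp, _ in r.rate_factors])
        for r in network.reactions
    ]
    factor_exp = [
        np.array([e for _, e in r.rate_factors], dtype=float) for r in network.reactions
    ]
    all_unit = [bool(np.all(e == 1.0)) for e in factor_exp]
    S = stoichiometry_matrix(network).astype(float)
    n_r = network.n_reactions

    def rates(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, 0.0, None)
        r = np.empty(n_r)
        for j in range(n_r):
            xs = x[factor_idx[j]]
            r[j] = k[j] * (xs.prod() if all_unit[j] else np.prod(xs ** factor_exp[j]))
        return r

    def f(x: np.ndarray) -> np.ndarray:
        return S @ rates(x)

    return f, rates


def integrate(
    network: ReactionNetwork,
    settings: SolverSettings | None = None,
    t_eval: np.ndarray | None = None,
    scenario_label: str = "custom",
) -> Trajectory:
    """Adaptive integration of the network from its initial state.

    ``t_eval`` overrides the equally spaced output grid (it must start at 0
    or the first output row is still the state at its first time).  With
    ``settings.stop_at_steady`` the run terminates early once
    max|dx/dt| < steady_tol.

    Raises :class:`IntegrationError` on solver failure or non-finite output.
    """
    settings = settings or SolverSettings()
    x0 = network.initial_state()
    if x0.min() < 0:
        raise StateDomainError("initial state has negative entries")
    f, _ = compile_rhs(network)
    if t_eval is None:
        t_eval = np.linspace(0.0, settings.t_end, settings.n_out)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        if t_eval.size < 1 or np.any(np.diff(t_eval) <= 0):
            raise ValueError("t_eval must be non-empty and strictly increasing")
        if t_eval[-1] > settings.t_end or t_eval[0] < 0:
            raise ValueError("t_eval must lie within [0, t_end]")

    events = None
    if settings.stop_at_steady:
        def _steady(t, x):
            return float(np.max(np.abs(f(x)))) - settings.steady_tol
        _steady.terminal = True
        _steady.direction = -1
        events = _steady

    sol = solve_ivp(
        lambda t, x: f(x),
        (0.0, settings.t_end),
        x0,
        method=settings.method,
        t_eval=t_eval,
        rtol=settings.rtol,
        atol=settings.atol,
        events=events,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message} (nfev={sol.nfev})")
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        raise IntegrationError("non-finite state encountered during integration")
    if sol.t.size and sol.t[0] == 0.0:
        states[0] = x0  # the t=0 row is the initial condition, bit-exact
    # round-off guard: snap tiny negatives produced by the solver
    states = np.where((states < 0) & (states >= NEGATIVE_STATE_TOL), 0.0, states)
    if states.min() < NEGATIVE_STATE_TOL:
        raise IntegrationError(
            f"state fell below tolerance {NEGATIVE_STATE_TOL}: min = {states.min()}"
        )
    return Trajectory(
        times=sol.t,
        states=states,
        species_ids=list(network.species_ids),
        scenario=scenario_label,
        settings=settings,
        diagnostics={"nfev": int(sol.nfev), "status": int(sol.status),
                     "success": bool(sol.success), "message": str(sol.message)},
    )


def steady_state_reached(
    trajectory: Trajectory,
    network: ReactionNetwork,
    steady_tol: float | None = None,
) -> tuple[bool, float | None]:
    """Earliest output time with max|dx/dt| below tolerance, if any."""
    tol = steady_tol if steady_tol is not None else (
        trajectory.settings.steady_tol if trajectory.settings else 1e-8
    )
    f, _ = compile_rhs(network)
    for t, x in zip(trajectory.times, trajectory.states):
        if np.max(np.abs(f(x))) < tol:
            return True, float(t)
    return False, None


@dataclass(frozen=True)
class Observables:
    """Scalar summaries of a canonical-network trajectory (all in a.u.)."""

    cytc_red_final: float
    cytc_red_auc: float
    q_final: float
    semiquinone_auc_standby: float  # integral of x4 (Qo-site radical)
    semiquinone_auc_ciii: float     # integral of x12 + x13 (Qi-site radicals)
    semiquinone_auc_total: float    # integral of x12 + x13 + x14
    hplusP_final: float
    t_half_cytc: float | None

    def as_dict(self) -> dict:
        return {
            "cytc_red_final": self.cytc_red_final,
            "cytc_red_auc": self.cytc_red_auc,
            "q_final": self.q_final,
            "semiquinone_auc_standby": self.semiquinone_auc_standby,
            "semiquinone_auc_ciii": self.semiquinone_auc_ciii,
            "semiquinone_auc_total": self.semiquinone_auc_total,
            "hplusP_final": self.hplusP_final,
            "t_half_cytc": self.t_half_cytc,
        }


def _t_half(times: np.ndarray, x5: np.ndarray) -> float | None:
    """First time the signal reaches half its final value (linear interpolation)."""
    final = x5[-1]
    if final <= 0:
        return None
    half = 0.5 * final
    above = np.nonzero(x5 >= half)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0 or x5[i] == half:
        return float(times[i])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = x5[i - 1], x5[i]
    return float(t0 + (half - y0) / (y1 - y0) * (t1 - t0))


def compute_observables(trajectory: Trajectory) -> Observables:
    """Trapezoid-rule observables on the trajectory's own output grid."""
    t = trajectory.times
    x4 = trajectory.series("x4")
    x5 = trajectory.series("x5")
    x12 = trajectory.series("x12")
    x13 = trajectory.series("x13")
    x14 = trajectory.series("x14")
    return Observables(
        cytc_red_final=float(x5[-1]),
        cytc_red_auc=float(np.trapezoid(x5, t)),
        q_final=float(trajectory.series("x7")[-1]),
        semiquinone_auc_standby=float(np.trapezoid(x4, t)),
        semiquinone_auc_ciii=float(np.trapezoid(x12 + x13, t)),
        semiquinone_auc_total=float(np.trapezoid(x12 + x13 + x14, t)),
        hplusP_final=float(trajectory.series("x6")[-1]),
        t_half_cytc=_t_half(t, x5),
    )


@dataclass(frozen=True)
class FluxSummary:
    """Per-reaction integrated fluxes and the proton-per-cytochrome ratio."""

    integrated_flux: dict[str, float]
    delta_hplusP: float
    delta_cytc_red: float
    hplusP_per_cytc_red: float | None  # None when delta_cytc_red == 0


def integrated_fluxes(trajectory: Trajectory, network: ReactionNetwork) -> FluxSummary:
    """Trapezoid-integrated reaction fluxes over the run, plus delta x6 / delta x5."""
    _, rates = compile_rhs(network)
    R = np.array([rates(x) for x in trajectory.states])
    integrals = np.trapezoid(R, trajectory.times, axis=0)
    d6 = float(trajectory.series("x6")[-1] - trajectory.series("x6")[0])
    d5 = float(trajectory.series("x5")[-1] - trajectory.series("x5")[0])
    ratio = d6 / d5 if d5 != 0 else None
    return FluxSummary(
        integrated_flux={
            rid: float(v) for rid, v in zip(network.reaction_ids, integrals)
        },
        delta_hplusP=d6,
        delta_cytc_red=d5,
        hplusP_per_cytc_red=ratio,
    )


@dataclass
class ScenarioComparison:
    """Observables per ETFDH level, ratios against wild type, ordering report.

    ``ordering`` records, as booleans, whether the reduced-cytochrome-c AUC
    is strictly increasing in ETFDH level, whether the standby (Qo-site)
    semiquinone AUC is strictly decreasing, and whether the Qi-site AUC is
    strictly decreasing (the latter is false under canonical constants —
    throughput growth dominates; it is reported, not asserted).
    """

    levels: list[float]
    labels: list[str]
    observables: dict[str, Observables]
    ratios_vs_wt: dict[str, dict[str, float | None]]
    ordering: dict[str, bool]
    wt_label: str

    def to_rows(self) -> list[dict]:
        rows = []
        for lvl, lbl in zip(self.levels, self.labels):
            row = {"label": lbl, "etfdh_level": lvl}
            row.update(self.observables[lbl].as_dict())
            rows.append(row)
        return rows


def _strictly(vals: list[float], direction: int) -> bool:
    return all(
        (b - a) * direction > 0 for a, b in zip(vals, vals[1:])
    )


def compare_scenarios(
    levels: list[float],
    settings: SolverSettings | None = None,
    network: ReactionNetwork | None = None,
) -> ScenarioComparison:
    """Run one simulation per ETFDH level and compare observables.

    Levels are sorted ascending; the highest level is used as the ratio
    denominator ("wild type").  Ordering violations are reported in the
    ``ordering`` field, never raised.
    """
    if not levels:
        raise ValueError("levels must be non-empty")
    if any(l < 0 for l in levels):
        raise ValueError("levels must be non-negative")
    settings = settings or SolverSettings()
    network = network or build_canonical_network()
    levels = sorted(set(float(l) for l in levels))
    labels, obs = [], {}
    for lvl in levels:
        scn = QCycleScenario.from_level(lvl)
        label = scn.label if scn.label != "custom" else f"etfdh={lvl:g}"
        try:
            traj = integrate(apply_scenario(network, scn), settings,
                             scenario_label=label)
        except IntegrationError as err:
            raise IntegrationError(f"scenario {label!r}: {err}") from err
        labels.append(label)
        obs[label] = compute_observables(traj)
    wt_label = labels[-1]
    wt = obs[wt_label]
    ratios = {}
    for lbl in labels:
        o = obs[lbl]
        ratios[lbl] = {
            key: (val / ref if (val is not None and ref) else None)
            for (key, val), ref in zip(o.as_dict().items(), wt.as_dict().values())
        }
    cytc = [obs[l].cytc_red_auc for l in labels]
    standby = [obs[l].semiquinone_auc_standby for l in labels]
    qi = [obs[l].semiquinone_auc_ciii for l in labels]
    ordering = {
        "cytc_red_auc_strictly_increasing": _strictly(cytc, +1),
        "semiquinone_standby_strictly_decreasing": _strictly(standby, -1),
        "semiquinone_qi_auc_strictly_decreasing": _strictly(qi, -1),
    }
    return ScenarioComparison(
        levels=levels, labels=labels, observables=obs,
        ratios_vs_wt=ratios, ordering=ordering, wt_label=wt_label,
    )
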