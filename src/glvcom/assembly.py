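"""Sub-community equilibria, stability and co-culture prediction.

Interior equilibria of the clamped gLV model satisfy, whenever no clamp is
active, the linear system

    X_i = 1 + sum_{j != i} b_ij X_j        i.e.  (I - B_sub) X = 1,

so fixed-point locations depend only on the final-density interactions B
(growth rates and A set transient speed and the Jacobian, not the fixed
point, as long as the growth factor is clamped positive). If the linear
solution would activate a capacity clamp, the equilibrium is instead found
by long-horizon integration from a uniform inoculum and marked
``method="simulated"``.

Stability combines two checks: all Jacobian eigenvalues at the equilibrium
with real part below ``-1e-9``, and return to within 1% after a 1%
per-species perturbation by the simulation horizon. The double check guards
against clamp-boundary equilibria where the smooth-branch Jacobian is
misleading.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Iterator, Sequence

import numpy as np

from .config import ModelConfig
from .interactions import InteractionSet
from .model import glv_rhs, integrate, to_absolute

__all__ = [
    "CommunityState",
    "EnumerationResult",
    "SensitivityEnvelope",
    "interior_equilibrium",
    "assess_stability",
    "enumerate_stable_communities",
    "predict_coculture",
    "sensitivity_envelope",
]

logger = logging.getLogger(__name__)

_FEASIBILITY_TOL = 1e-9
_EIG_TOL = -1e-9
_PERTURBATION = 0.01


@dataclass
class CommunityState:
    """A species subset with its equilibrium and feasibility/stability flags."""

    members: tuple[str, ...]
    equilibrium: np.ndarray
    feasible: bool
    stable: bool | None
    method: str  # "linear" | "simulated"
    jacobian_stable: bool | None = None
    perturbation_stable: bool | None = None

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        self.equilibrium = np.asarray(self.equilibrium, dtype=float)
        if self.feasible and not np.all(self.equilibrium > 0):
            raise ValueError("feasible state must have all densities > 0")
        if self.stable and not self.feasible:
            raise ValueError("stable implies feasible")

    @property
    def richness(self) -> int:
        return len(self.members)


@dataclass
class EnumerationResult:
    """All sub-community states plus summary statistics."""

    states: list[CommunityState]
    stable_fraction: float
    max_stable_richness: int

    @property
    def stable_states(self) -> list[CommunityState]:
        return [s for s in self.states if s.stable]


@dataclass
class SensitivityEnvelope:
    """Monte-Carlo mean and SD of predicted fractions under measurement error."""

    members: tuple[str, ...]
    point: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_draws: int


def _member_system(members: Sequence[str], iset: InteractionSet
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    idx = [iset.index(m) for m in members]
    ix = np.ix_(idx, idx)
    return (iset.mono_rates[idx], iset.A[ix], iset.B[ix],
            iset.mono_capacities[idx])


def interior_equilibrium(members: Sequence[str], iset: InteractionSet,
                         config: ModelConfig | None = None) -> CommunityState:
    """Interior equilibrium of a species subset (stability not yet assessed).

    Solves ``(I - B_sub) X = 1``. Because the linear solution satisfies
    ``X_i = 1 + sum b_ij X_j`` exactly, a capacity clamp is active precisely
    when some ``X_i`` falls outside ``(capacity_floor, capacity_cap)``; in
    that case (and only when the community could still be viable) the state
    is recomputed by long-horizon integration from a uniform inoculum.
    Feasibility requires every density strictly positive (tolerance 1e-9).
    A singular linear system is flagged infeasible/unstable.
    """
    cfg = config or ModelConfig()
    members = tuple(members)
    g, A, B, _caps = _member_system(members, iset)
    if np.any(~np.isfinite(B)):
        raise ValueError("B contains missing entries; drop invalid species first")
    k = len(members)
    try:
        x = np.linalg.solve(np.eye(k) - B, np.ones(k))
    except np.linalg.LinAlgError:
        logger.info("singular (I - B) for %s; flagged not feasible", members)
        return CommunityState(members, np.full(k, np.nan), False, False, "linear")

    clamped = np.any(x >= cfg.capacity_cap) or np.any(x <= cfg.capacity_floor)
    if not clamped:
        feasible = bool(np.all(x > _FEASIBILITY_TOL))
        return CommunityState(members, x, feasible, None if feasible else False,
                              "linear")

    # clamp active: fall back to the dynamics from a uniform inoculum
    x0 = np.full(k, cfg.inoculum_od)
    traj = integrate(x0, g, A, B, cfg, species=list(members),
                     horizon_h=cfg.equilibration_h)
    xf = traj.final_state
    feasible = bool(np.all(xf > _FEASIBILITY_TOL))
    return CommunityState(members, xf, feasible, None if feasible else False,
                          "simulated")


def _numerical_jacobian(x: np.ndarray, g: np.ndarray, A: np.ndarray,
                        B: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    n = x.size
    J = np.zeros((n, n))
    for k in range(n):
        h = 1e-7 * max(1.0, abs(x[k]))
        xp = x.copy(); xp[k] += h
        xm = x.copy(); xm[k] = max(xm[k] - h, 0.0)
        fp = glv_rhs(xp, g, A, B, cfg)
        fm = glv_rhs(xm, g, A, B, cfg)
        J[:, k] = (fp - fm) / (xp[k] - xm[k])
    return J


def assess_stability(state: CommunityState, iset: InteractionSet,
                     config: ModelConfig | None = None) -> CommunityState:
    """Attach the stability verdict to a feasible equilibrium.

    Stable iff (a) all eigenvalues of the numerical Jacobian at the
    equilibrium have real part < -1e-9 and (b) integration from the
    equilibrium perturbed by +/-1% per species (alternating signs) returns
    to within 1% of it by the simulation horizon. Both sub-verdicts are
    recorded on the returned state.
    """
    if not state.feasible:
        return dc_replace(state, stable=False)
    cfg = config or ModelConfig()
    g, A, B, _caps = _member_system(state.members, iset)
    x = state.equilibrium
    J = _numerical_jacobian(x, g, A, B, cfg)
    eig_ok = bool(np.max(np.linalg.eigvals(J).real) < _EIG_TOL)
    signs = np.where(np.arange(x.size) % 2 == 0, 1.0, -1.0)
    x0 = x * (1.0 + _PERTURBATION * signs)
    traj = integrate(x0, g, A, B, cfg, species=list(state.members),
                     horizon_h=cfg.horizon_h)
    xf = traj.final_state
    returned = bool(np.all(np.abs(xf - x) <= _PERTURBATION * x + 1e-12))
    return dc_replace(state, stable=eig_ok and returned,
                      jacobian_stable=eig_ok, perturbation_stable=returned)


def _subsets(species: Sequence[str]) -> Iterator[tuple[str, ...]]:
    for k in range(1, len(species) + 1):
        yield from itertools.combinations(species, k)


def enumerate_stable_communities(iset: InteractionSet,
                                 config: ModelConfig | None = None,
                                 override_guard: bool = False
                                 ) -> EnumerationResult:
    """Classify every non-empty species subset as stable or not.

    Evaluates all ``2^n - 1`` subsets; refuses ``n > 20`` unless
    ``override_guard`` is set. Returns all states, the stable fraction and
    the maximum richness among stable communities. Deterministic.
    """
    if not iset.fully_valid:
        raise ValueError("interaction set has invalid entries; "
                         "apply drop_invalid_species first")
    n = iset.n_species
    if n > 20 and not override_guard:
        raise ValueError(f"{n} species means {2**n - 1} subsets; "
                         "pass override_guard=True to proceed")
    cfg = config or ModelConfig()
    states = []
    for members in _subsets(iset.species):
        state = interior_equilibrium(members, iset, cfg)
        if state.feasible:
            state = assess_stability(state, iset, cfg)
        states.append(state)
    n_stable = sum(bool(s.stable) for s in states)
    max_rich = max((s.richness for s in states if s.stable), default=0)
    return EnumerationResult(states=states,
                             stable_fraction=n_stable / len(states),
                             max_stable_richness=max_rich)


def predict_coculture(members: Sequence[str], iset: InteractionSet,
                      config: ModelConfig | None = None,
                      horizon_h: float | None = None) -> np.ndarray:
    """Predicted relative fractions of a co-culture experiment.

    Integrates from an equal-absolute-OD inoculum (total ``inoculum_od``
    split equally over members, mirroring equal-CFU mixing) over the
    experiment horizon (24 h default) and converts the final state to
    absolute-density fractions.
    """
    cfg = config or ModelConfig()
    members = tuple(members)
    g, A, B, caps = _member_system(members, iset)
    k = len(members)
    x0 = (cfg.inoculum_od / k) / caps
    horizon = horizon_h if horizon_h is not None else cfg.experiment_horizon_h
    traj = integrate(x0, g, A, B, cfg, species=list(members), horizon_h=horizon)
    comp = to_absolute(traj.final_state, caps)
    return comp.fractions


def sensitivity_envelope(members: Sequence[str], iset: InteractionSet,
                         config: ModelConfig | None = None,
                         n_draws: int = 100, seed: int = 0
                         ) -> SensitivityEnvelope:
    """Monte-Carlo error propagation of measurement SDs into predictions.

    Draws ``n_draws`` parameter sets entrywise-independently from normal
    distributions centered on the stored means with the stored SDs
    (growth rates and capacities redrawn while non-positive, at most 100
    tries), evaluates :func:`predict_coculture` for each, and returns the
    per-species mean and SD of the predicted fractions. Deterministic for
    a fixed seed.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    cfg = config or ModelConfig()
    members = tuple(members)
    sub = iset.subset(members)
    rng = np.random.default_rng(seed)

    def positive_draw(mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
        out = rng.normal(mean, sd)
        for _ in range(100):
            bad = out <= 0
            if not np.any(bad):
                return out
            out[bad] = rng.normal(mean[bad], sd[bad])
        raise RuntimeError("could not draw positive rates/capacities in 100 tries")

    draws = np.empty((n_draws, len(members)))
    for d in range(n_draws):
        pert = dc_replace(
            sub,
            mono_rates=positive_draw(sub.mono_rates, sub.mono_rate_sd),
            mono_capacities=positive_draw(sub.mono_capacities,
                                          sub.mono_capacity_sd),
            A=_offdiag_normal(rng, sub.A, sub.A_sd),
            B=_offdiag_normal(rng, sub.B, sub.B_sd),
        )
        draws[d] = predict_coculture(members, pert, cfg)
    point = predict_coculture(members, sub, cfg)
    sd = draws.std(axis=0, ddof=1)
    sd[np.ptp(draws, axis=0) == 0.0] = 0.0  # identical draws: exactly zero
    return SensitivityEnvelope(members=members, point=point,
                               mean=draws.mean(axis=0), sd=sd,
                               n_draws=n_draws)


def _offdiag_normal(rng: np.random.Generator, mean: np.ndarray,
                    sd: np.ndarray) -> np.ndarray:
    out = rng.normal(mean, sd)
    np.fill_diagonal(out, 0.0)
    return out
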