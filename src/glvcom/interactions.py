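"""Interaction matrices from conditioned-media growth parameters.

For acceptor ``i`` grown in medium conditioned by donor ``j``:

    a_ij = g_ij / g_i - 1        (growth-rate interaction)
    b_ij = N_ij / N_i - 1        (final-density interaction)
    eps  = ln(ratio)             (log-ratio form used for reporting)

where ``g_i, N_i`` are fresh-medium monoculture values. Natural log is used
for the eps matrices; the dynamical model consumes the raw ratios, which a
log-base change never touches. Measurement SDs are propagated by the delta
method for a ratio, ignoring covariance (conditions are measured
independently). Conditions in which the acceptor failed to grow are carried
as missing (NaN, ``valid=False``), never imputed as neutral.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .growth import GrowthParams

__all__ = [
    "InteractionSet",
    "build_interactions",
    "drop_invalid_species",
    "summarize_donor_acceptor_effects",
]

logger = logging.getLogger(__name__)

DropPolicy = Literal["drop-acceptors-with-any-missing", "drop-minimal-cover"]


@dataclass
class InteractionSet:
    """Square interaction matrices over an ordered species list.

    Row = acceptor ``i``, column = donor ``j``. Diagonals are exactly zero
    (self-interaction is not assessed; logistic self-limitation lives in the
    capacity term) and the diagonal of ``valid`` is True. Wherever ``valid``,
    ``exp(eps_density) == 1 + B`` and ``exp(eps_rate) == 1 + A``.
    """

    species: list[str]
    A: np.ndarray
    B: np.ndarray
    A_sd: np.ndarray
    B_sd: np.ndarray
    eps_density: np.ndarray
    eps_rate: np.ndarray
    valid: np.ndarray
    mono_rates: np.ndarray
    mono_capacities: np.ndarray
    mono_rate_sd: np.ndarray
    mono_capacity_sd: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.species)
        for name in ("A", "B", "A_sd", "B_sd", "eps_density", "eps_rate", "valid"):
            m = np.asarray(getattr(self, name))
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            setattr(self, name, m)
        for name in ("mono_rates", "mono_capacities", "mono_rate_sd",
                     "mono_capacity_sd"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, v)
        self.valid = self.valid.astype(bool)
        for m in (self.A, self.B, self.eps_density, self.eps_rate):
            if not np.allclose(np.diag(m), 0.0, atol=0.0):
                raise ValueError("interaction matrix diagonals must be zero")
        if not np.all(np.diag(self.valid)):
            raise ValueError("diagonal of valid must be True")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self.species.index(name)

    @property
    def fully_valid(self) -> bool:
        return bool(np.all(self.valid))

    def subset(self, members: Iterable[str]) -> "InteractionSet":
        """Restrict to a species subset (order follows ``members``)."""
        members = list(members)
        idx = [self.index(m) for m in members]
        ix = np.ix_(idx, idx)
        return InteractionSet(
            species=members,
            A=self.A[ix].copy(), B=self.B[ix].copy(),
            A_sd=self.A_sd[ix].copy(), B_sd=self.B_sd[ix].copy(),
            eps_density=self.eps_density[ix].copy(),
            eps_rate=self.eps_rate[ix].copy(),
            valid=self.valid[ix].copy(),
            mono_rates=self.mono_rates[idx].copy(),
            mono_capacities=self.mono_capacities[idx].copy(),
            mono_rate_sd=self.mono_rate_sd[idx].copy(),
            mono_capacity_sd=self.mono_capacity_sd[idx].copy(),
        )


def _ratio_sd(x: float, sx: float, y: float, sy: float) -> float:
    """Delta-method SD of R = x/y with independent errors."""
    r = x / y
    return abs(r) * float(np.hypot(sx / x, sy / y))


def build_interactions(params: Iterable[GrowthParams]) -> InteractionSet:
    """Assemble an :class:`InteractionSet` from fitted growth parameters.

    Every species must have a fresh-medium monoculture entry (``donor=None``)
    that grew; a species whose monoculture failed is a hard error (its
    interactions are undefined as both acceptor and donor). Conditioned
    entries with ``grew=False`` or absent altogether become invalid cells.
    """
    params = list(params)
    mono = {p.acceptor: p for p in params if p.donor is None}
    cond = {(p.acceptor, p.donor): p for p in params if p.donor is not None}
    species = sorted(mono)
    if not species:
        raise ValueError("no monoculture (donor=None) entries found")
    failed = [s for s in species if not mono[s].grew]
    if failed:
        raise ValueError(
            "monoculture failed to grow for species: " + ", ".join(failed))
    unknown = sorted(({a for a, _d in cond} | {d for _a, d in cond}) - set(species))
    if unknown:
        raise ValueError("conditioned entries reference unknown species: "
                         + ", ".join(unknown))

    n = len(species)
    A = np.zeros((n, n)); B = np.zeros((n, n))
    A_sd = np.zeros((n, n)); B_sd = np.zeros((n, n))
    eps_d = np.zeros((n, n)); eps_r = np.zeros((n, n))
    valid = np.eye(n, dtype=bool)

    for i, acc in enumerate(species):
        gi, ni = mono[acc].max_growth_rate, mono[acc].final_density
        gi_sd, ni_sd = mono[acc].rate_sd, mono[acc].density_sd
        for j, don in enumerate(species):
            if i == j:
                continue
            p = cond.get((acc, don))
            if p is None:
                logger.warning("missing conditioned-media pair: acceptor=%s donor=%s",
                               acc, don)
                A[i, j] = B[i, j] = eps_d[i, j] = eps_r[i, j] = np.nan
                A_sd[i, j] = B_sd[i, j] = np.nan
                continue
            if not p.grew:
                A[i, j] = B[i, j] = eps_d[i, j] = eps_r[i, j] = np.nan
                A_sd[i, j] = B_sd[i, j] = np.nan
                continue
            rate_ratio = p.max_growth_rate / gi
            dens_ratio = p.final_density / ni
            A[i, j] = rate_ratio - 1.0
            B[i, j] = dens_ratio - 1.0
            eps_r[i, j] = np.log(rate_ratio)
            eps_d[i, j] = np.log(dens_ratio)
            A_sd[i, j] = _ratio_sd(p.max_growth_rate, p.rate_sd, gi, gi_sd)
            B_sd[i, j] = _ratio_sd(p.final_density, p.density_sd, ni, ni_sd)
            valid[i, j] = True

    return InteractionSet(
        species=species, A=A, B=B, A_sd=A_sd, B_sd=B_sd,
        eps_density=eps_d, eps_rate=eps_r, valid=valid,
        mono_rates=np.array([mono[s].max_growth_rate for s in species]),
        mono_capacities=np.array([mono[s].final_density for s in species]),
        mono_rate_sd=np.array([mono[s].rate_sd for s in species]),
        mono_capacity_sd=np.array([mono[s].density_sd for s in species]),
    )


def _minimal_cover(species: list[str], invalid_cells: list[tuple[int, int]]) -> list[str]:
    """Smallest species set covering all invalid (acceptor, donor) cells.

    Exhaustive over subset sizes; ties broken by largest total involvement
    in invalid cells, then alphabetically.
    """
    involved = sorted({i for ij in invalid_cells for i in ij})
    counts = {k: sum(k in ij for ij in invalid_cells) for k in involved}
    for size in range(0, len(involved) + 1):
        candidates = [
            combo for combo in itertools.combinations(involved, size)
            if all(i in combo or j in combo for i, j in invalid_cells)
        ]
        if candidates:
            best = min(candidates,
                       key=lambda c: (-sum(counts[k] for k in c),
                                      tuple(species[k] for k in sorted(c))))
            return [species[k] for k in best]
    return [species[k] for k in involved]


def drop_invalid_species(iset: InteractionSet,
                         policy: DropPolicy = "drop-acceptors-with-any-missing"
                         ) -> InteractionSet:
    """Remove species until every off-diagonal cell is valid.

    ``drop-acceptors-with-any-missing`` removes every species with at least
    one invalid cell as acceptor (the study's rule: a species unable to grow
    in most conditioned media cannot be parameterized and is excluded).
    ``drop-minimal-cover`` removes a minimum-size species set covering all
    invalid cells, ties broken by involvement count then alphabetically.
    """
    if iset.fully_valid:
        return iset
    invalid_cells = [(i, j) for i in range(iset.n_species)
                     for j in range(iset.n_species)
                     if i != j and not iset.valid[i, j]]
    if policy == "drop-acceptors-with-any-missing":
        bad = {iset.species[i] for i, _j in invalid_cells}
    elif policy == "drop-minimal-cover":
        bad = set(_minimal_cover(iset.species, invalid_cells))
    else:
        raise ValueError(f"unknown policy: {policy!r}")
    keep = [s for s in iset.species if s not in bad]
    if not keep:
        logger.warning("drop_invalid_species removed every species")
    logger.info("dropped %d species (%s): %s", len(bad), policy,
                ", ".join(sorted(bad)))
    out = iset.subset(keep)
    assert out.fully_valid
    return out


def summarize_donor_acceptor_effects(iset: InteractionSet) -> pd.DataFrame:
    """Mean log density effect of each species as donor and as acceptor.

    Donor effect of ``j``: mean over acceptors ``i != j`` of
    ``eps_density[i, j]`` (how this species' spent medium affects others).
    Acceptor effect of ``i``: mean over donors ``j != i`` (how this species
    is affected by the others).
    """
    if not iset.fully_valid:
        raise ValueError("summarize requires a fully valid interaction set")
    n = iset.n_species
    eps = iset.eps_density
    off = ~np.eye(n, dtype=bool)
    donor = np.array([eps[off[:, j], j].mean() for j in range(n)])
    acceptor = np.array([eps[i, off[i, :]].mean() for i in range(n)])
    return pd.DataFrame({"species": iset.species,
                         "donor_effect": donor,
                         "acceptor_effect": acceptor}).set_index("species")
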