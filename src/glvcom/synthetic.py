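"""Ground-truth gLV worlds and simulated conditioned-media assay data.

The generator emulates the study design end to end: a species pool with
known growth rates, monoculture capacities and interaction matrices; a
conditioned-media assay in which every acceptor is grown in fresh medium and
in the spent medium of every other donor (``n`` monocultures plus
``n*(n-1)`` conditioned conditions); logistic growth curves over 24 h from
an OD-0.05 inoculum; multiplicative lognormal OD noise; and occasional
fully inhibited (no-growth) donor-acceptor pairs drawn by a separate
Bernoulli mechanism rather than as extreme interaction values.

Interaction signs come from a two-component mixture — a negative-dominated
truncated normal plus a half-normal positive tail — so the observed
"mostly inhibitory, occasionally facilitative" structure of gut-community
spent-media assays is reproducible while facilitation still occurs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import ModelConfig, derive_seed
from .growth import GrowthCurve
from .model import integrate, logistic_closed_form, to_absolute

__all__ = [
    "GroundTruthWorld",
    "NoiseModel",
    "sample_world",
    "simulate_growth_curve",
    "generate_assay_dataset",
    "simulate_coculture_fractions",
    "world_interactions",
]

#: most negative admissible density interaction; complete suppression is
#: modeled by the separate no-growth mechanism, not by b -> -1
_B_CLIP = -0.9
#: growth-rate effects are milder than density effects in spent-media assays
_A_CLIP = -0.3

DEFAULT_TIMES = np.arange(0.0, 24.0 + 1e-9, 0.25)


@dataclass
class GroundTruthWorld:
    """True parameters of a simulated species pool.

    ``A`` and ``B`` are the growth-rate and final-density interaction
    matrices (acceptor row, donor column, zero diagonal); ``growth_rates``
    (1/h) and ``capacities`` (OD 595 units) are the fresh-medium monoculture
    values the assay is meant to recover.
    """

    species: list[str]
    growth_rates: np.ndarray
    capacities: np.ndarray
    A: np.ndarray
    B: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        n = len(self.species)
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        self.capacities = np.asarray(self.capacities, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.growth_rates.shape != (n,) or self.capacities.shape != (n,):
            raise ValueError("rates/capacities must have one entry per species")
        if np.any(self.growth_rates <= 0) or np.any(self.capacities <= 0):
            raise ValueError("growth rates and capacities must be > 0")
        if self.A.shape != (n, n) or self.B.shape != (n, n):
            raise ValueError("A and B must be n x n")
        if np.any(np.diag(self.A) != 0) or np.any(np.diag(self.B) != 0):
            raise ValueError("A and B must have exactly zero diagonals")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def to_dict(self) -> dict:
        return {"species": self.species,
                "growth_rates": self.growth_rates.tolist(),
                "capacities": self.capacities.tolist(),
                "A": self.A.tolist(), "B": self.B.tolist(),
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthWorld":
        return cls(species=list(d["species"]),
                   growth_rates=np.array(d["growth_rates"]),
                   capacities=np.array(d["capacities"]),
                   A=np.array(d["A"]), B=np.array(d["B"]),
                   seed=int(d["seed"]))


@dataclass
class NoiseModel:
    """Measurement-noise and replication structure of the simulated assay."""

    od_cv: float = 0.05
    replicate_count: int = 9
    no_growth_prob: float = 0.0
    fraction_cv: float = 0.10
    fraction_replicates: int = 3

    def __post_init__(self) -> None:
        if self.od_cv < 0 or self.fraction_cv < 0:
            raise ValueError("CVs must be >= 0")
        if self.replicate_count < 1 or self.fraction_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if not 0.0 <= self.no_growth_prob <= 1.0:
            raise ValueError("no_growth_prob must be in [0, 1]")


def _mixture_matrix(rng: np.random.Generator, n: int, mean: float, sd: float,
                    positive_fraction: float | None, clip: float) -> np.ndarray:
    """Off-diagonal interaction draw: sign mixture or plain normal."""
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if positive_fraction is None:
                M[i, j] = max(rng.normal(mean, sd), clip)
                continue
            if rng.random() < positive_fraction:
                M[i, j] = abs(rng.normal(0.0, sd))
            else:
                if sd == 0:
                    if mean > 0:
                        raise ValueError(
                            "zero-variance negative component needs mean <= 0")
                    value = mean
                else:
                    value = rng.normal(mean, sd)
                    for _ in range(1000):
                        if value < 0:
                            break
                        value = rng.normal(mean, sd)
                    else:
                        raise ValueError("could not draw a negative interaction")
                M[i, j] = max(value, clip)
    return M


def sample_world(n_species: int, interaction_mean: float = -0.4,
                 interaction_sd: float = 0.3,
                 positive_fraction: float | None = 0.2,
                 seed: int = 0,
                 rate_range: tuple[float, float] = (0.5, 1.1),
                 capacity_range: tuple[float, float] = (0.6, 1.4)
                 ) -> GroundTruthWorld:
    """Draw a random ground-truth world.

    ``positive_fraction`` sets the Bernoulli sign mix of the density
    interactions ``B``; pass ``None`` for an untruncated normal draw
    (useful for sweeping the pooled interaction mean through positive
    values). The growth-rate matrix ``A`` is drawn with half the mean and
    SD and double the positive fraction, reflecting that spent-media
    effects on growth rate are milder and more often positive than on
    final density. Deterministic for a fixed seed.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if interaction_sd < 0:
        raise ValueError("interaction_sd must be >= 0")
    if positive_fraction is not None and not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1] or None")
    rng = np.random.default_rng(seed)
    species = [f"sp{i+1:02d}" for i in range(n_species)]
    rates = rng.uniform(*rate_range, size=n_species)
    caps = rng.uniform(*capacity_range, size=n_species)
    B = _mixture_matrix(rng, n_species, interaction_mean, interaction_sd,
                        positive_fraction, clip=_B_CLIP)
    pf_a = None if positive_fraction is None else min(1.0, 2.0 * positive_fraction)
    A = _mixture_matrix(rng, n_species, interaction_mean / 2.0,
                        interaction_sd / 2.0, pf_a, clip=_A_CLIP)
    return GroundTruthWorld(species=species, growth_rates=rates,
                            capacities=caps, A=A, B=B, seed=seed)


def simulate_growth_curve(world: GroundTruthWorld, acceptor: int,
                          donor: int | None, noise: NoiseModel,
                          times: Sequence[float] | None = None,
                          seed: int = 0, no_growth: bool = False,
                          inoculum_od: float = 0.05) -> GrowthCurve:
    """Simulate one noisy OD growth curve.

    The noiseless curve is the closed-form logistic with rate
    ``g_a (1 + a_ad)`` and capacity ``N_a (1 + b_ad)`` (monoculture values
    for ``donor=None``); multiplicative lognormal noise with coefficient of
    variation ``noise.od_cv`` is applied per OD reading. A no-growth pair
    stays at the inoculum (plus noise). A non-positive conditioned capacity
    is likewise treated as no growth.
    """
    if times is None:
        times = DEFAULT_TIMES
    times = np.asarray(times, dtype=float)
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")
    if donor is not None and donor == acceptor:
        raise ValueError("species are not assessed in their own conditioned media")
    if donor is None:
        r = world.growth_rates[acceptor]
        K = world.capacities[acceptor]
        donor_name = None
    else:
        r = world.growth_rates[acceptor] * (1.0 + world.A[acceptor, donor])
        K = world.capacities[acceptor] * (1.0 + world.B[acceptor, donor])
        donor_name = world.species[donor]
    if no_growth or K <= 0 or r <= 0:
        ods = np.full(times.size, inoculum_od)
    else:
        ods = logistic_closed_form(times, r, K, inoculum_od)
    if noise.od_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise.od_cv**2))
        ods = ods * rng.lognormal(-sigma**2 / 2.0, sigma, size=times.size)
    return GrowthCurve(acceptor=world.species[acceptor], donor=donor_name,
                       replicate="r1", times=times, ods=ods)


def generate_assay_dataset(world: GroundTruthWorld, noise: NoiseModel,
                           seed: int = 0,
                           times: Sequence[float] | None = None,
                           inoculum_od: float = 0.05,
                           no_growth_pairs: set[tuple[int, int]] | None = None
                           ) -> list[GrowthCurve]:
    """Simulate the full conditioned-media assay.

    Emits ``replicate_count`` curves for each of the ``n`` fresh-medium
    monocultures and the ``n*(n-1)`` conditioned-media conditions. No-growth
    pairs are drawn once per (acceptor, donor) pair with probability
    ``noise.no_growth_prob`` (consistent across replicates), or can be
    supplied explicitly via ``no_growth_pairs``.
    """
    n = world.n_species
    flag_rng = np.random.default_rng(derive_seed(seed, "no-growth-flags"))
    if no_growth_pairs is None:
        no_growth_pairs = {
            (a, d) for a in range(n) for d in range(n)
            if a != d and flag_rng.random() < noise.no_growth_prob}
    curves: list[GrowthCurve] = []
    for acceptor in range(n):
        for donor in [None, *[d for d in range(n) if d != acceptor]]:
            flagged = donor is not None and (acceptor, donor) in no_growth_pairs
            for rep in range(noise.replicate_count):
                rep_seed = derive_seed(
                    seed, f"curve:{acceptor}:{donor}:{rep}")
                curve = simulate_growth_curve(
                    world, acceptor, donor, noise, times=times,
                    seed=rep_seed, no_growth=flagged, inoculum_od=inoculum_od)
                curve.replicate = f"r{rep+1}"
                curves.append(curve)
    return curves


def world_interactions(world: GroundTruthWorld) -> "InteractionSet":
    """Exact :class:`~glvcom.interactions.InteractionSet` from ground truth.

    Zero SDs, all cells valid; the noise-free reference against which the
    assay-fitting pipeline is compared. Interactions at or below -1 (total
    suppression) have undefined log-ratios and are carried as -inf in the
    eps matrices.
    """
    from .interactions import InteractionSet

    n = world.n_species
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps_d = np.where(off, np.log1p(world.B), 0.0)
        eps_r = np.where(off, np.log1p(world.A), 0.0)
    z = np.zeros((n, n))
    return InteractionSet(
        species=list(world.species), A=world.A.copy(), B=world.B.copy(),
        A_sd=z.copy(), B_sd=z.copy(), eps_density=eps_d, eps_rate=eps_r,
        valid=np.ones((n, n), dtype=bool),
        mono_rates=world.growth_rates.copy(),
        mono_capacities=world.capacities.copy(),
        mono_rate_sd=np.zeros(n), mono_capacity_sd=np.zeros(n))


def simulate_coculture_fractions(world: GroundTruthWorld,
                                 members: Sequence[int],
                                 noise: NoiseModel, seed: int = 0,
                                 config: ModelConfig | None = None,
                                 horizon_h: float = 24.0,
                                 inoculum_od: float = 0.05) -> np.ndarray:
    """Noisy "measured" co-culture fractions from the true dynamics.

    Integrates the ground-truth gLV system from an equal-absolute-OD
    inoculum for ``horizon_h`` hours, converts to absolute-density
    fractions, applies multiplicative lognormal noise with CV
    ``noise.fraction_cv`` per species and replicate, renormalizes, and
    returns the replicate-mean fractions (shape ``(len(members),)``).
    """
    cfg = config or ModelConfig()
    members = list(members)
    k = len(members)
    g = world.growth_rates[members]
    caps = world.capacities[members]
    A = world.A[np.ix_(members, members)]
    B = world.B[np.ix_(members, members)]
    x0 = (inoculum_od / k) / caps
    traj = integrate(x0, g, A, B, cfg, horizon_h=horizon_h,
                     species=[world.species[m] for m in members])
    comp = to_absolute(traj.final_state, caps)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(noise.fraction_replicates):
        if noise.fraction_cv > 0:
            sigma = np.sqrt(np.log1p(noise.fraction_cv**2))
            noisy = comp.absolute * rng.lognormal(-sigma**2 / 2.0, sigma, size=k)
        else:
            noisy = comp.absolute.copy()
        total = noisy.sum()
        reps.append(noisy / total if total > 0 else np.zeros(k))
    return np.mean(reps, axis=0)
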