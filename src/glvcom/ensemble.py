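"""Synthetic-invader ensembles and invasion-predictor analysis.

Invaders with deliberately uncorrelated traits are built by resampling each
trait independently from the observed values: growth rate and capacity with
replacement from the per-species monoculture values, each interaction entry
with replacement from the pooled off-diagonal entries of the corresponding
matrix. Surveying the full cross product of invaders and stable communities
yields a trial table on which community and invader properties (diversity,
richness, total density, mean interactions) are scored for their ability to
predict invasion success, and on which the invasion-regime map (total
resident density vs mean resident-to-invader interaction) is drawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .assembly import CommunityState
from .config import ModelConfig, derive_seed
from .interactions import InteractionSet
from .invasion import InvaderParams, simulate_invasion
from .model import to_absolute

__all__ = [
    "SyntheticInvader",
    "CommunityProperties",
    "PROPERTY_COLUMNS",
    "sample_invaders",
    "compute_properties",
    "ensemble_survey",
    "score_property_predictiveness",
    "regime_boundaries",
]

PROPERTY_COLUMNS = [
    "shannon_diversity",
    "richness",
    "total_density",
    "mean_resident_resident_b",
    "mean_resident_to_invader_b",
    "mean_invader_to_resident_b",
]


@dataclass
class SyntheticInvader:
    """An artificial invader with independently resampled traits."""

    id: str
    growth_rate: float
    capacity: float
    pool_species: tuple[str, ...]
    incoming_a: np.ndarray
    outgoing_a: np.ndarray
    incoming_b: np.ndarray
    outgoing_b: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.pool_species = tuple(self.pool_species)
        if self.growth_rate <= 0 or self.capacity <= 0:
            raise ValueError("growth_rate and capacity must be > 0")
        k = len(self.pool_species)
        for name in ("incoming_a", "outgoing_a", "incoming_b", "outgoing_b"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (k,):
                raise ValueError(f"{name} must have length {k}")
            setattr(self, name, v)

    def as_params(self) -> InvaderParams:
        return InvaderParams(
            name=self.id, growth_rate=self.growth_rate, capacity=self.capacity,
            pool_species=self.pool_species,
            incoming_a=self.incoming_a, outgoing_a=self.outgoing_a,
            incoming_b=self.incoming_b, outgoing_b=self.outgoing_b)


@dataclass
class CommunityProperties:
    """Scalar descriptors of a resident community and its invader coupling."""

    shannon_diversity: float        # nats, on equilibrium absolute fractions
    richness: int
    total_density: float            # sum of normalized equilibrium densities
    mean_resident_resident_b: float
    mean_resident_to_invader_b: float
    mean_invader_to_resident_b: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PROPERTY_COLUMNS}


def sample_invaders(iset: InteractionSet, n: int, seed: int = 0
                    ) -> list[SyntheticInvader]:
    """Draw ``n`` synthetic invaders by independent trait resampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not iset.fully_valid:
        raise ValueError("interaction set must be fully valid")
    off = ~np.eye(iset.n_species, dtype=bool)
    pool_a = iset.A[off]
    pool_b = iset.B[off]
    rng = np.random.default_rng(seed)
    k = iset.n_species
    invaders = []
    for i in range(n):
        invaders.append(SyntheticInvader(
            id=f"synth{i:04d}",
            growth_rate=float(rng.choice(iset.mono_rates)),
            capacity=float(rng.choice(iset.mono_capacities)),
            pool_species=tuple(iset.species),
            incoming_a=rng.choice(pool_a, size=k),
            outgoing_a=rng.choice(pool_a, size=k),
            incoming_b=rng.choice(pool_b, size=k),
            outgoing_b=rng.choice(pool_b, size=k),
            seed=seed))
    return invaders


def compute_properties(residents: CommunityState,
                       invader: SyntheticInvader | InvaderParams,
                       iset: InteractionSet) -> CommunityProperties:
    """Community and coupling descriptors for one (community, invader) pair.

    Shannon diversity is computed in nats on the absolute-density fractions
    of the resident equilibrium; interaction means are over the stated index
    sets of the density matrix B.
    """
    if not residents.stable:
        raise ValueError("residents must be a stable community")
    idx = [iset.index(m) for m in residents.members]
    caps = iset.mono_capacities[idx]
    comp = to_absolute(residents.equilibrium, caps)
    f = comp.fractions[comp.fractions > 0]
    shannon = float(-(f * np.log(f)).sum())
    k = len(idx)
    if k > 1:
        sub = iset.B[np.ix_(idx, idx)]
        rr = float(sub[~np.eye(k, dtype=bool)].mean())
    else:
        rr = 0.0
    sel = np.array([invader.pool_species.index(m) for m in residents.members])
    return CommunityProperties(
        shannon_diversity=shannon,
        richness=residents.richness,
        total_density=float(residents.equilibrium.sum()),
        mean_resident_resident_b=rr,
        mean_resident_to_invader_b=float(np.asarray(invader.incoming_b)[sel].mean()),
        mean_invader_to_resident_b=float(np.asarray(invader.outgoing_b)[sel].mean()),
    )


def ensemble_survey(invaders: Sequence[SyntheticInvader],
                    communities: Sequence[CommunityState],
                    iset: InteractionSet,
                    config: ModelConfig | None = None) -> pd.DataFrame:
    """Simulate the full invaders-by-communities cross product.

    One row per trial: invader id, community id, all properties, the
    four-way outcome, persistence flag and the invader's final fraction.
    Reproducible: simulations are deterministic, so the table depends only
    on the inputs.
    """
    if not invaders or not communities:
        raise ValueError("invaders and communities must be non-empty")
    cfg = config or ModelConfig()
    rows = []
    for inv in invaders:
        for ci, comm in enumerate(communities):
            props = compute_properties(comm, inv, iset)
            result = simulate_invasion(comm, inv.as_params(), iset, cfg)
            rows.append({
                "invader": inv.id,
                "community": "+".join(comm.members),
                **props.as_dict(),
                "outcome": result.outcome,
                "invader_persists": result.invader_persists,
                "invader_final_fraction": result.invader_fraction_at(cfg.horizon_h),
                "success": result.outcome in ("augmentation", "displacement"),
            })
    return pd.DataFrame(rows)


def _threshold_classifier_score(x: np.ndarray, y: np.ndarray,
                                n_splits: int, seed: int) -> float:
    """Cross-validated balanced accuracy of the best univariate threshold."""
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = []
    for train, test in skf.split(x.reshape(-1, 1), y):
        xt, yt = x[train], y[train]
        order = np.argsort(xt)
        candidates = np.unique(xt[order])
        if candidates.size > 1:
            candidates = (candidates[:-1] + candidates[1:]) / 2.0
        best = (0.5, 1.0, candidates[0] if candidates.size else 0.0)
        for thr in candidates:
            for direction in (1.0, -1.0):
                pred = (direction * xt >= direction * thr)
                acc = balanced_accuracy_score(yt, pred)
                if acc > best[0]:
                    best = (acc, direction, thr)
        _, direction, thr = best
        pred_test = (direction * x[test] >= direction * thr)
        scores.append(balanced_accuracy_score(y[test], pred_test))
    return float(np.mean(scores))


def score_property_predictiveness(table: pd.DataFrame,
                                  properties: Sequence[str] | None = None,
                                  method: str = "threshold",
                                  n_splits: int = 5,
                                  seed: int = 0) -> pd.DataFrame:
    """Rank properties by their ability to predict invasion success.

    Default score: cross-validated balanced accuracy of a univariate
    threshold classifier for success (augmentation or displacement) versus
    failure; mutual information with the success label is reported as a
    secondary score. Ties are broken by property name. Requires at least
    two outcome classes in the table.
    """
    if method != "threshold":
        raise ValueError(f"unknown scoring method: {method!r}")
    props = list(properties) if properties is not None else PROPERTY_COLUMNS
    y = table["success"].to_numpy(dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("table contains a single outcome class; cannot score")
    records = []
    for p in props:
        x = table[p].to_numpy(dtype=float)
        score = _threshold_classifier_score(x, y, n_splits, seed)
        mi = float(mutual_info_classif(
            x.reshape(-1, 1), y, random_state=derive_seed(seed, f"mi:{p}"))[0])
        records.append({"property": p, "balanced_accuracy": score,
                        "mutual_information": mi})
    out = pd.DataFrame(records).sort_values(
        ["balanced_accuracy", "property"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def regime_boundaries(table: pd.DataFrame,
                      x: str = "total_density",
                      y: str = "mean_resident_to_invader_b",
                      n_bins: int = 8) -> pd.DataFrame:
    """Invasion-regime frontiers on the (x, y) plane.

    For each x-bin, the minimal y at which each success type occurred:
    the augmentation-possible and displacement-possible frontiers.
    Empty bins are reported as NaN, never interpolated. Columns with the
    ``_clean`` suffix carry isotonic-regression monotone cleanups (direction
    chosen automatically).
    """
    xs = table[x].to_numpy(dtype=float)
    edges = np.linspace(xs.min(), xs.max() + 1e-12, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    bin_idx = np.clip(np.digitize(xs, edges) - 1, 0, n_bins - 1)
    out = pd.DataFrame({"x_bin_center": centers})
    for outcome, col in (("augmentation", "augmentation_frontier"),
                         ("displacement", "displacement_frontier")):
        frontier = np.full(n_bins, np.nan)
        mask = table["outcome"].to_numpy() == outcome
        for b in range(n_bins):
            sel = mask & (bin_idx == b)
            if np.any(sel):
                frontier[b] = table.loc[sel, y].min()
        out[col] = frontier
        ok = np.isfinite(frontier)
        if ok.sum() >= 2:
            iso = IsotonicRegression(increasing="auto", out_of_bounds="clip")
            cleaned = frontier.copy()
            cleaned[ok] = iso.fit_transform(centers[ok], frontier[ok])
            out[col + "_clean"] = cleaned
        else:
            out[col + "_clean"] = frontier
    return out
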