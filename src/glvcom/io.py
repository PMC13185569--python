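"""File formats: growth-curve CSV, parameter CSV, interaction bundles,
community tables and trajectory exports.

Growth-curve dialect: columns ``acceptor, donor, replicate, time_h, od``
with a header row; an empty donor (or the literal ``none``) denotes a
fresh-medium monoculture. All readers validate and report offending rows by
line number; all writers round-trip losslessly through their readers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assembly import CommunityState, EnumerationResult
from .growth import GrowthCurve, GrowthParams
from .interactions import InteractionSet
from .model import CommunityTrajectory
from .synthetic import GroundTruthWorld

__all__ = [
    "ParseError",
    "read_growth_curves", "write_growth_curves",
    "read_growth_params", "write_growth_params",
    "read_interactions", "write_interactions",
    "write_community_table", "read_community_table",
    "write_trajectory",
    "read_world", "write_world",
    "read_fractions", "write_fractions",
]

GROWTH_CURVE_COLUMNS = ["acceptor", "donor", "replicate", "time_h", "od"]
PARAMS_COLUMNS = ["acceptor", "donor", "max_growth_rate", "rate_sd",
                  "final_density", "density_sd", "n_replicates", "grew"]


class ParseError(ValueError):
    """Malformed input file; message names the offending row/column."""


def _norm_donor(value) -> str | None:
    if pd.isna(value):
        return None
    s = str(value).strip()
    return None if s == "" or s.lower() == "none" else s


def read_growth_curves(path: str | Path) -> list[GrowthCurve]:
    """Parse a growth-curve CSV into validated curves, one per
    (acceptor, donor, replicate) condition. Row order is irrelevant;
    duplicated (condition, replicate, time) rows are an integrity error."""
    df = pd.read_csv(path, dtype={"acceptor": str, "replicate": str},
                     keep_default_na=True, float_precision="round_trip")
    missing = set(GROWTH_CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    df["donor"] = df["donor"].map(_norm_donor)
    df["_line"] = df.index + 2  # header is line 1
    for col in ("time_h", "od"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if not bad.empty:
            raise ParseError(
                f"{path}: non-numeric {col} at line {int(bad['_line'].iloc[0])}")
        df[col] = pd.to_numeric(df[col])
    neg = df[df["od"] < 0]
    if not neg.empty:
        raise ParseError(
            f"{path}: negative OD at line {int(neg['_line'].iloc[0])}")
    dup = df.duplicated(subset=["acceptor", "donor", "replicate", "time_h"])
    if dup.any():
        raise ParseError(
            f"{path}: duplicated (condition, replicate, time) row at line "
            f"{int(df.loc[dup, '_line'].iloc[0])}")
    curves = []
    grouped = df.sort_values("time_h").groupby(
        ["acceptor", "donor", "replicate"], dropna=False, sort=True)
    for (acceptor, donor, replicate), grp in grouped:
        times = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ParseError(
                f"{path}: non-increasing times for acceptor={acceptor} "
                f"donor={donor} replicate={replicate}")
        try:
            curves.append(GrowthCurve(
                acceptor=str(acceptor), donor=_norm_donor(donor),
                replicate=str(replicate), times=times,
                ods=grp["od"].to_numpy(dtype=float)))
        except ValueError as exc:
            raise ParseError(
                f"{path}: invalid curve for acceptor={acceptor} donor={donor} "
                f"replicate={replicate}: {exc}") from exc
    return curves


def write_growth_curves(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.ods):
            rows.append({"acceptor": c.acceptor, "donor": c.donor or "",
                         "replicate": c.replicate, "time_h": t, "od": od})
    pd.DataFrame(rows, columns=GROWTH_CURVE_COLUMNS).to_csv(path, index=False)


def write_growth_params(params: Iterable[GrowthParams], path: str | Path) -> None:
    rows = [{"acceptor": p.acceptor, "donor": p.donor or "",
             "max_growth_rate": p.max_growth_rate, "rate_sd": p.rate_sd,
             "final_density": p.final_density, "density_sd": p.density_sd,
             "n_replicates": p.n_replicates, "grew": p.grew}
            for p in params]
    pd.DataFrame(rows, columns=PARAMS_COLUMNS).to_csv(path, index=False)


def read_growth_params(path: str | Path) -> list[GrowthParams]:
    df = pd.read_csv(path, dtype={"acceptor": str},
                     float_precision="round_trip")
    missing = set(PARAMS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(GrowthParams(
            acceptor=str(row["acceptor"]), donor=_norm_donor(row["donor"]),
            max_growth_rate=float(row["max_growth_rate"]),
            final_density=float(row["final_density"]),
            rate_sd=float(row["rate_sd"]), density_sd=float(row["density_sd"]),
            n_replicates=int(row["n_replicates"]), grew=bool(row["grew"])))
    return out


_MATRIX_NAMES = ["A", "B", "A_sd", "B_sd", "eps_density", "eps_rate", "valid"]
_VECTOR_NAMES = ["mono_rates", "mono_capacities", "mono_rate_sd",
                 "mono_capacity_sd"]


def write_interactions(iset: InteractionSet, directory: str | Path) -> None:
    """Write one CSV per matrix (species-ordered header and index) plus a
    combined JSON bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _MATRIX_NAMES:
        pd.DataFrame(getattr(iset, name), index=iset.species,
                     columns=iset.species).to_csv(directory / f"{name}.csv")
    bundle = {"species": iset.species}
    for name in _MATRIX_NAMES + _VECTOR_NAMES:
        bundle[name] = np.asarray(getattr(iset, name)).tolist()
    with open(directory / "interactions.json", "w") as fh:
        json.dump(bundle, fh, indent=1)


def read_interactions(source: str | Path) -> InteractionSet:
    """Read an interaction bundle from its JSON file (or its directory)."""
    path = Path(source)
    if path.is_dir():
        path = path / "interactions.json"
    with open(path) as fh:
        bundle = json.load(fh)
    kwargs = {"species": list(bundle["species"])}
    for name in _MATRIX_NAMES + _VECTOR_NAMES:
        kwargs[name] = np.array(bundle[name])
    return InteractionSet(**kwargs)


def write_world(world: GroundTruthWorld, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(world.to_dict(), fh, indent=1)


def read_world(path: str | Path) -> GroundTruthWorld:
    with open(path) as fh:
        return GroundTruthWorld.from_dict(json.load(fh))


def write_community_table(result: EnumerationResult, species: Sequence[str],
                          path: str | Path) -> None:
    """Community table: bitmask, members, richness, flags and equilibrium."""
    rows = []
    for s in result.states:
        mask = sum(1 << species.index(m) for m in s.members)
        eq = {f"X_{m}": (s.equilibrium[i] if s.feasible else np.nan)
              for i, m in enumerate(s.members)}
        rows.append({"bitmask": mask, "members": "+".join(s.members),
                     "richness": s.richness, "feasible": s.feasible,
                     "stable": bool(s.stable), "method": s.method, **eq})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_community_table(path: str | Path) -> list[CommunityState]:
    df = pd.read_csv(path)
    states = []
    for _, row in df.iterrows():
        members = tuple(str(row["members"]).split("+"))
        eq = np.array([row.get(f"X_{m}", np.nan) for m in members], dtype=float)
        states.append(CommunityState(
            members=members, equilibrium=eq,
            feasible=bool(row["feasible"]), stable=bool(row["stable"]),
            method=str(row["method"])))
    return states


def write_trajectory(traj: CommunityTrajectory, path: str | Path,
                     capacities: Sequence[float] | None = None) -> None:
    """Time column plus one normalized-density column per species; absolute
    columns are added when capacities are given."""
    data = {"time_h": traj.times}
    for i, sp in enumerate(traj.species):
        data[f"X_{sp}"] = traj.densities[:, i]
    if capacities is not None:
        caps = np.asarray(capacities, dtype=float)
        for i, sp in enumerate(traj.species):
            data[f"od_{sp}"] = traj.densities[:, i] * caps[i]
    pd.DataFrame(data).to_csv(path, index=False)


def write_fractions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_fractions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"community": str, "species": str})
    missing = {"community", "species", "fraction"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return df
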