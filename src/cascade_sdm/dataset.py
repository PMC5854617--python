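"""Survey data model and preprocessing for presence/absence community studies.

A survey pairs a binary site-by-species community table with a site-by-variable
environmental table over the same, identically ordered sites.  Preprocessing
follows the conventions of presence/absence species distribution modelling:
rare species are dropped, stocked (non-environment-driven) species are dropped
by name, and environmental variables are min-max normalized to [0, 1] before
being fed to sigmoid networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DegenerateError,
    DomainError,
    SchemaError,
    StratificationError,
)

__all__ = [
    "SurveyDataset",
    "ExclusionReport",
    "read_survey",
    "write_survey",
    "filter_rare_species",
    "exclude_species",
    "normalize_environment",
    "velocity_to_score",
    "stratified_folds",
]


@dataclass
class SurveyDataset:
    """Aligned binary community matrix and environmental matrix.

    Parameters
    ----------
    occurrence : DataFrame of {0, 1}, sites x species, indexed by site id.
    environment : DataFrame of floats, sites x variables, same index.
    normalized : whether ``environment`` holds [0, 1] min-max normalized values.
    norm_params : per-variable ``(min, max)`` recorded at normalization time.
    """

    occurrence: pd.DataFrame
    environment: pd.DataFrame
    normalized: bool = False
    norm_params: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        occ, env = self.occurrence, self.environment
        if len(occ) != len(env) or not (occ.index == env.index).all():
            raise AlignmentError("occurrence and environment must share the same site ordering")
        bad = ~occ.isin([0, 1])
        if bad.to_numpy().any():
            row, col = next(zip(*np.nonzero(bad.to_numpy())))
            raise DomainError(
                f"non-binary occurrence value at site {occ.index[row]!r}, "
                f"species {occ.columns[col]!r}: {occ.iat[row, col]!r}"
            )
        self.occurrence = occ.astype(np.int8)
        self.environment = env.astype(float)
        if self.normalized:
            vals = self.environment.to_numpy()
            if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
                raise DomainError("normalized environment values must lie in [0, 1]")

    # -- convenience accessors -------------------------------------------------
    @property
    def site_ids(self) -> list:
        return list(self.occurrence.index)

    @property
    def species_names(self) -> list[str]:
        return list(self.occurrence.columns)

    @property
    def env_names(self) -> list[str]:
        return list(self.environment.columns)

    @property
    def n_sites(self) -> int:
        return len(self.occurrence)

    def species_vector(self, name: str) -> np.ndarray:
        if name not in self.occurrence.columns:
            raise SchemaError(f"unknown species {name!r}")
        return self.occurrence[name].to_numpy()

    def env_matrix(self) -> np.ndarray:
        return self.environment.to_numpy()

    def subset_sites(self, mask: np.ndarray) -> "SurveyDataset":
        """Row subset (boolean mask or positional indices), preserving order."""
        return SurveyDataset(
            self.occurrence.iloc[mask].copy(),
            self.environment.iloc[mask].copy(),
            normalized=self.normalized,
            norm_params=dict(self.norm_params) if self.norm_params else None,
        )

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(
            self.occurrence.copy(),
            self.environment.copy(),
            normalized=self.normalized,
            norm_params=dict(self.norm_params) if self.norm_params else None,
        )


@dataclass
class ExclusionReport:
    """Which species were dropped during preprocessing, and why."""

    removed_rare: list[tuple[str, int]] = field(default_factory=list)
    removed_listed: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "removed_rare": [[s, int(c)] for s, c in self.removed_rare],
                "removed_listed": list(self.removed_listed),
                "retained": list(self.retained),
            },
            indent=2,
        )


# -- I/O ----------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise DomainError(f"{path}: expected a site-id column plus data columns")
    return df.set_index(df.columns[0])


def read_survey(community_path, environment_path) -> SurveyDataset:
    """Read aligned community and environment CSVs (first column = site id)."""
    occ = _read_table(community_path)
    env = _read_table(environment_path)
    occ_sites, env_sites = set(occ.index), set(env.index)
    if occ_sites != env_sites:
        only_occ = sorted(occ_sites - env_sites)
        only_env = sorted(env_sites - occ_sites)
        raise AlignmentError(
            f"site sets differ: only in community {only_occ}, only in environment {only_env}"
        )
    env = env.loc[occ.index]
    return SurveyDataset(occ, env, normalized=False)


def write_survey(data: SurveyDataset, community_path, environment_path) -> None:
    """Write the two CSVs with full double precision (round-trips bit-exactly)."""
    data.occurrence.to_csv(community_path, index_label="site")
    data.environment.to_csv(environment_path, index_label="site", float_format="%.17g")


# -- species filtering --------------------------------------------------------

def filter_rare_species(
    data: SurveyDataset, min_presences: int = 10
) -> tuple[SurveyDataset, ExclusionReport]:
    """Drop species observed at fewer than ``min_presences`` sites (strict <).

    Rare species are removed because a network cannot learn a distribution
    pattern from a handful of presences; the threshold default matches the
    common "fewer than 10 records" exclusion rule.
    """
    counts = data.occurrence.sum(axis=0)
    rare = [(str(s), int(c)) for s, c in counts.items() if c < min_presences]
    keep = [s for s in data.species_names if counts[s] >= min_presences]
    report = ExclusionReport(removed_rare=rare, retained=keep)
    out = SurveyDataset(
        data.occurrence[keep].copy(),
        data.environment.copy(),
        normalized=data.normalized,
        norm_params=dict(data.norm_params) if data.norm_params else None,
    )
    return out, report


def exclude_species(
    data: SurveyDataset, names: list[str]
) -> tuple[SurveyDataset, ExclusionReport]:
    """Drop the listed species regardless of rarity (e.g. stocked species)."""
    unknown = [n for n in names if n not in data.occurrence.columns]
    if unknown:
        raise SchemaError(f"unknown species: {unknown}")
    keep = [s for s in data.species_names if s not in set(names)]
    report = ExclusionReport(removed_listed=list(names), retained=keep)
    out = SurveyDataset(
        data.occurrence[keep].copy(),
        data.environment.copy(),
        normalized=data.normalized,
        norm_params=dict(data.norm_params) if data.norm_params else None,
    )
    return out, report


# -- normalization ------------------------------------------------------------

def normalize_environment(
    data: SurveyDataset, params: dict[str, tuple[float, float]] | None = None
) -> SurveyDataset:
    """Min-max map each environmental variable to [0, 1].

    Without ``params`` the observed per-variable min/max are used ("global"
    mode, matching a once-over-the-whole-survey normalization).  With
    ``params`` (e.g. learned on training folds) values are mapped with the
    supplied ranges and clipped into [0, 1], so test data never leak into the
    scaling.
    """
    if data.normalized:
        raise DomainError("dataset is already normalized")
    env = data.environment.copy()
    stored: dict[str, tuple[float, float]] = {}
    for name in env.columns:
        col = env[name].to_numpy(dtype=float)
        if params is not None and name in params:
            lo, hi = map(float, params[name])
            if not hi > lo:
                raise DegenerateError(f"supplied range for {name!r} must have max > min")
        else:
            lo, hi = float(col.min()), float(col.max())
            if hi == lo:
                raise DegenerateError(
                    f"variable {name!r} is constant; supply an explicit (min, max)"
                )
        env[name] = np.clip((col - lo) / (hi - lo), 0.0, 1.0)
        stored[name] = (lo, hi)
    return SurveyDataset(data.occurrence.copy(), env, normalized=True, norm_params=stored)


# -- stream velocity score ----------------------------------------------------

#: upper bound (inclusive) of each semi-quantitative stream-velocity class, cm/s
_VELOCITY_UPPER = ((5.0, 0), (6.0, 1), (30.0, 2), (50.0, 3), (100.0, 4))


def velocity_to_score(velocity_cm_s: float) -> int:
    """Convert a stream velocity (cm/s) to the 0-5 semi-quantitative score.

    Classes: 0 still waters (< 5), 1 up to 6, 2 up to 30, 3 up to 50,
    4 up to 100, 5 above 100.  The class upper bounds are inclusive, making
    the mapping total over all nonnegative velocities.
    """
    v = float(velocity_cm_s)
    if v < 0:
        raise DomainError(f"velocity must be nonnegative, got {v}")
    if v < 5.0:
        return 0
    for upper, score in _VELOCITY_UPPER[1:]:
        if v <= upper:
            return score
    return 5


# -- cross-validation folds ---------------------------------------------------

def stratified_folds(
    data: SurveyDataset, target: str, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Assign each site to one of ``k`` folds, stratified on the target species.

    Sites are shuffled within each class with a seeded generator and dealt
    round-robin, so per-fold class counts differ from proportional allocation
    by at most one and the assignment is exactly reproducible.
    """
    if k < 2:
        raise StratificationError(f"need at least 2 folds, got {k}")
    y = data.species_vector(target)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise StratificationError(
                f"class {int(cls)} of {target!r} has {len(idx)} sites, fewer than k={k}"
            )
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment
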