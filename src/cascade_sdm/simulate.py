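"""Seeded virtual fish-community surveys for testing every cascade stage.

Sites carry a small number of latent habitat axes (standard normal).  The
observed environmental variables are noisy linear mixes of *some* of those
axes, rescaled to realistic field ranges; species occurrence probabilities
are logistic in the latents (plus optional biotic dependence on another
species and optional direct environmental terms), and occurrences are
independent Bernoulli draws given the probabilities.

Because the environment observes the latents only partially, the occurrence
of a well-predicted species carries information about a site that no measured
variable does — which is exactly the premise that makes co-predictor species
useful, and what the cascaded model is supposed to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataset import SurveyDataset
from .exceptions import ConfigError, DegenerateError, DomainError
from .tetrachoric import contingency_from_binary, tetrachoric_r

__all__ = [
    "EnvVarSim",
    "SpeciesSim",
    "CommunitySimConfig",
    "SimTruth",
    "simulate_community",
    "make_reference_scenario",
    "simulate_latent_binary_pair",
]


@dataclass(frozen=True)
class EnvVarSim:
    """One simulated environmental variable: latent mix + noise, rescaled."""

    name: str
    loadings: tuple[float, ...]
    noise_sd: float = 0.5
    low: float = 0.0
    high: float = 100.0


@dataclass(frozen=True)
class SpeciesSim:
    """One simulated species: logistic occurrence model on the latents.

    ``parent``/``parent_coef`` add a biotic dependence term on another
    species' realized occurrence; ``env_loadings`` (per environmental
    variable, applied to the pre-rescaling signal) add direct environmental
    effects beyond the latents.
    """

    name: str
    loadings: tuple[float, ...]
    intercept: float = 0.0
    parent: str | None = None
    parent_coef: float = 0.0
    env_loadings: tuple[float, ...] | None = None


@dataclass
class CommunitySimConfig:
    n_sites: int
    latent_dims: int
    env: list[EnvVarSim]
    species: list[SpeciesSim]
    target_name: str | None = None
    copredictor_names: tuple[str, ...] = ()
    seed: int = 0
    truth_correlations: bool = True
    n_aux: int = 20_000  # auxiliary sample size for realized tetrachoric r

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.latent_dims < 1:
            raise ConfigError("n_sites and latent_dims must be >= 1")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate species names")
        for s in self.species:
            if len(s.loadings) != self.latent_dims:
                raise ConfigError(f"{s.name}: loadings must have length {self.latent_dims}")
            if s.parent is not None and s.parent not in names:
                raise ConfigError(f"{s.name}: unknown parent {s.parent!r}")
            if s.env_loadings is not None and len(s.env_loadings) != len(self.env):
                raise ConfigError(f"{s.name}: env_loadings must have length {len(self.env)}")
        for e in self.env:
            if len(e.loadings) != self.latent_dims:
                raise ConfigError(f"{e.name}: loadings must have length {self.latent_dims}")
            if e.high <= e.low:
                raise ConfigError(f"{e.name}: high must exceed low")
        self._toposort()  # raises on cycles

    def _toposort(self) -> list[SpeciesSim]:
        by_name = {s.name: s for s in self.species}
        order: list[SpeciesSim] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(s: SpeciesSim) -> None:
            if state.get(s.name) == 1:
                return
            if state.get(s.name) == 0:
                raise ConfigError(f"cyclic biotic dependence involving {s.name!r}")
            state[s.name] = 0
            if s.parent is not None:
                visit(by_name[s.parent])
            state[s.name] = 1
            order.append(s)

        for s in self.species:
            visit(s)
        return order


@dataclass
class SimTruth:
    """What the generator knows: latents, true probabilities, realized r."""

    latents: np.ndarray
    probabilities: pd.DataFrame
    tetrachoric: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "latents": self.latents.tolist(),
            "probabilities": {
                c: self.probabilities[c].tolist() for c in self.probabilities.columns
            },
            "tetrachoric": self.tetrachoric,
        }


def _draw(config: CommunitySimConfig, n: int, rng: np.random.Generator):
    """Latents, raw env signals, probabilities and occurrences for n sites."""
    Z = rng.standard_normal((n, config.latent_dims))
    env_loadings = np.array([e.loadings for e in config.env])  # (n_env, d)
    noise = rng.standard_normal((n, len(config.env))) * np.array(
        [e.noise_sd for e in config.env]
    )
    env_raw = Z @ env_loadings.T + noise

    probs: dict[str, np.ndarray] = {}
    occ: dict[str, np.ndarray] = {}
    for s in config._toposort():
        logit = s.intercept + Z @ np.asarray(s.loadings)
        if s.env_loadings is not None:
            logit = logit + env_raw @ np.asarray(s.env_loadings)
        if s.parent is not None:
            logit = logit + s.parent_coef * occ[s.parent]
        p = expit(logit)
        probs[s.name] = p
        occ[s.name] = (rng.random(n) < p).astype(np.int8)
    return Z, env_raw, probs, occ


def simulate_community(config: CommunitySimConfig) -> tuple[SurveyDataset, SimTruth]:
    """Draw one virtual survey; same seed, same config -> identical output."""
    root = np.random.SeedSequence(config.seed)
    main_seed, aux_seed = root.generate_state(2)
    rng = np.random.default_rng(main_seed)
    Z, env_raw, probs, occ = _draw(config, config.n_sites, rng)

    site_ids = [f"S{i + 1:04d}" for i in range(config.n_sites)]
    env_df = pd.DataFrame(index=site_ids)
    for j, e in enumerate(config.env):
        col = env_raw[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            raise DegenerateError(f"simulated variable {e.name!r} is constant")
        env_df[e.name] = e.low + (col - lo) / (hi - lo) * (e.high - e.low)
    species_order = [s.name for s in config.species]
    occ_df = pd.DataFrame({s: occ[s] for s in species_order}, index=site_ids)
    prob_df = pd.DataFrame({s: probs[s] for s in species_order}, index=site_ids)

    truth = SimTruth(latents=Z, probabilities=prob_df)
    if config.truth_correlations and config.target_name is not None:
        aux_rng = np.random.default_rng(aux_seed)
        _, _, _, aux_occ = _draw(config, config.n_aux, aux_rng)
        y = aux_occ[config.target_name]
        for s in species_order:
            if s == config.target_name:
                continue
            try:
                truth.tetrachoric[s] = tetrachoric_r(
                    contingency_from_binary(aux_occ[s], y)
                ).r
            except DegenerateError:
                truth.tetrachoric[s] = float("nan")
    return SurveyDataset(occ_df, env_df, normalized=False), truth


def simulate_latent_binary_pair(
    rho: float, thresholds: tuple[float, float] = (0.0, 0.0), n: int = 10_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Dichotomized bivariate-normal draws (presence = latent above threshold).

    The standard recovery oracle for the tetrachoric estimator.
    """
    if not abs(rho) < 1:
        raise DomainError(f"|rho| must be < 1, got {rho}")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    h, k = thresholds
    return (z1 > h).astype(np.int8), (z2 > k).astype(np.int8)


# -- the canned study-shaped scenario -----------------------------------------

# Latent axes: 0 = main river gradient (lowland <-> upland), well observed by
# the environment; 1 = secondary habitat axis, observed; 2 = hidden habitat
# factor that no environmental variable measures (the reason co-predictor
# occurrences carry extra information).
_ENV_TABLE: list[tuple[str, tuple[float, float, float], float, float, float]] = [
    # each variable is a weak, noisy indicator: recovering the habitat axes
    # requires pooling many variables, as with real field descriptors
    ("elevation_m", (-0.9, 0.1, 0.0), 1.25, 13.0, 1785.0),
    ("mean_depth_m", (0.6, 0.2, 0.0), 1.75, 0.01, 1.46),
    ("runs_pct", (0.3, -0.5, 0.0), 2.0, 0.0, 100.0),
    ("pools_pct", (0.5, 0.4, 0.0), 2.0, 0.0, 90.0),
    ("riffles_pct", (-0.6, 0.2, 0.0), 2.0, 0.0, 100.0),
    ("mean_width_m", (0.5, -0.3, 0.0), 2.0, 1.0, 80.0),
    ("boulders_pct", (-0.7, 0.1, 0.0), 1.75, 0.0, 100.0),
    ("rocks_pebbles_pct", (-0.6, -0.2, 0.0), 2.0, 0.0, 100.0),
    ("gravel_pct", (-0.3, 0.5, 0.0), 2.25, 0.0, 96.0),
    ("sand_pct", (0.4, 0.4, 0.0), 2.25, 0.0, 80.0),
    ("silt_clay_pct", (0.8, 0.2, 0.0), 1.75, 0.0, 100.0),
    ("velocity_score", (-0.8, -0.3, 0.0), 1.5, 0.0, 5.0),
    ("vegetation_pct", (0.7, 0.3, 0.0), 2.0, 0.0, 100.0),
    ("shade_pct", (-0.4, 0.6, 0.0), 2.25, 0.0, 100.0),
    ("disturbance_score", (0.5, -0.4, 0.0), 2.25, 0.0, 4.0),
    ("ph", (0.3, 0.2, 0.0), 2.5, 5.63, 9.33),
    ("conductivity_uS_cm", (0.7, -0.2, 0.0), 1.75, 11.0, 1851.0),
    ("gradient_pct", (-0.8, 0.2, 0.0), 1.75, 0.02, 41.6),
    ("catchment_km2", (0.6, 0.1, 0.0), 2.0, 0.34, 3274.0),
    ("distance_source_km", (0.8, -0.1, 0.0), 1.5, 0.33, 119.27),
]

_TARGET = "Leucos aula"
_COPREDICTORS = ("Alburnus arborella", "Scardinius erythrophthalmus")
_NOISE_SPECIES = "Gasterosteus aculeatus"

_SPECIES_TABLE: list[SpeciesSim] = [
    # target: moderate lowland affinity plus a strong hidden-factor term,
    # intercept set for a prevalence near 0.35
    SpeciesSim(_TARGET, (1.8, 0.0, 2.2), intercept=-1.0),
    # co-predictors: same habitat plus the same hidden factor, but with much
    # sharper responses -> easier to model, strongly correlated with target
    SpeciesSim(_COPREDICTORS[0], (6.0, 0.0, 3.5), intercept=0.0),
    SpeciesSim(_COPREDICTORS[1], (5.5, 0.3, 3.2), intercept=-0.4),
    # strongly negatively correlated upland species
    SpeciesSim("Cottus gobio", (-2.8, 0.4, -1.2), intercept=-0.4),
    SpeciesSim("Salmo marmoratus", (-2.4, -0.3, -0.8), intercept=-0.8),
    # designated pure-noise species: no latent structure at all
    SpeciesSim(_NOISE_SPECIES, (0.0, 0.0, 0.0), intercept=-1.0),
    # the remaining community: varied affinities on the observed axes
    SpeciesSim("Squalius cephalus", (1.2, -0.6, 0.4), intercept=0.3),
    SpeciesSim("Padogobius bonelli", (0.8, -0.9, 0.0), intercept=0.1),
    SpeciesSim("Esox lucius", (1.4, 0.6, 0.5), intercept=-1.0),
    SpeciesSim("Tinca tinca", (1.6, 0.8, 0.6), intercept=-1.2),
    SpeciesSim("Cobitis taenia", (0.9, 0.7, 0.2), intercept=-0.6),
    SpeciesSim("Phoxinus phoxinus", (-1.5, 0.8, 0.0), intercept=-0.5),
    SpeciesSim("Anguilla anguilla", (1.0, -0.2, 0.3), intercept=-0.7),
    SpeciesSim("Knipowitschia punctatissima", (0.4, -1.2, 0.0), intercept=-1.1),
    SpeciesSim("Sabanejewia larvata", (1.1, 0.4, 0.3), intercept=-1.4),
    SpeciesSim("Ameiurus melas", (1.3, 0.9, 0.2), intercept=-1.5, parent=_TARGET, parent_coef=0.6),
    SpeciesSim("Lepomis gibbosus", (1.2, 0.5, 0.0), intercept=-1.3, parent=_COPREDICTORS[0], parent_coef=0.8),
    SpeciesSim("Barbus plebejus", (-0.6, -1.0, 0.0), intercept=-0.2),
    SpeciesSim("Protochondrostoma genei", (-0.3, -1.1, 0.4), intercept=-0.4),
    SpeciesSim("Carassius carassius", (1.5, 0.7, 0.4), intercept=-1.6),
    SpeciesSim("Gobio gobio", (0.5, -0.8, 0.1), intercept=-0.6),
    SpeciesSim("Telestes souffia", (-1.2, -0.7, 0.0), intercept=-0.6),
    SpeciesSim("Thymallus thymallus", (-2.0, -0.2, -0.4), intercept=-1.0),
]


def reference_scenario_config(seed: int = 0, n_sites: int = 264) -> CommunitySimConfig:
    """The canned study-shaped configuration (see :func:`make_reference_scenario`)."""
    return CommunitySimConfig(
        n_sites=n_sites,
        latent_dims=3,
        env=[EnvVarSim(n, lo_, sd, low, high) for n, lo_, sd, low, high in _ENV_TABLE],
        species=list(_SPECIES_TABLE),
        target_name=_TARGET,
        copredictor_names=_COPREDICTORS,
        seed=seed,
    )


def reference_train_configs():
    """The study-shaped analysis settings used with this scenario.

    Target-species networks are kept small and decayed (4 hidden units,
    weight decay 1e-3) because their 0/1 labels are noisy realizations of
    probabilities near one half; co-predictor sub-models get more capacity
    and less decay (6 hidden units, 3e-4) because their responses are sharp
    and their occurrences nearly deterministic given the habitat.  Iteration
    budgets are modest since L-BFGS converges quickly at these sizes.

    Returns ``(target TrainConfig, sub-model TrainConfig)``.
    """
    from .network import TrainConfig

    target_cfg = TrainConfig(
        n_hidden=4, weight_decay=1e-3, max_iterations=200, tolerance=1e-6, restarts=2
    )
    submodel_cfg = TrainConfig(
        n_hidden=6, weight_decay=3e-4, max_iterations=300, tolerance=1e-6, restarts=2
    )
    return target_cfg, submodel_cfg


def make_reference_scenario(seed: int = 0, n_sites: int = 264) -> tuple[SurveyDataset, SimTruth]:
    """A virtual survey shaped like the study data.

    264 sites, 20 environmental variables with field-realistic ranges, 23
    species including one target of intermediate prevalence, two strongly
    correlated co-predictors whose shared habitat factor is partly hidden
    from the observed environment, strongly negatively correlated species,
    and one pure-noise species.
    """
    return simulate_community(reference_scenario_config(seed=seed, n_sites=n_sites))
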