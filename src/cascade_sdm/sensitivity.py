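"""Variable importance for trained occurrence networks.

Three complementary views of a fitted model:

* **Profile** (Lek): sweep one input across [0, 1] while holding every other
  input at one of five reference levels, recording the response curve.
* **Perturbation**: add uniform white noise to one input at a time and measure
  the percent increase in output mean squared error.
* **Connection weights** (Olden): signed sum over hidden neurons of
  input-to-hidden times hidden-to-output weights, giving the direction of each
  variable's influence.

All three accept either a raw :class:`~cascade_sdm.network.NetworkWeights` /
``SigmoidNetClassifier`` together with an input matrix, or a ``ModelSpec`` /
``CascadeModel`` with a :class:`~cascade_sdm.dataset.SurveyDataset` — in the
cascade case the sub-model probability inputs are profiled and perturbed like
any other variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import CascadeModel, ModelSpec
from .dataset import SurveyDataset
from .exceptions import ConfigError, DomainError, NotFittedStateError
from .network import NetworkWeights, SigmoidNetClassifier, forward

__all__ = [
    "SensitivityConfig",
    "ImportanceTable",
    "lek_profile",
    "perturbation_importance",
    "olden_weights",
]


@dataclass
class SensitivityConfig:
    """Knobs of the three importance methods.

    ``profile_scale`` is the number of sweep points per curve; ``noise_range``
    the half-width of the symmetric uniform perturbation; ``noise_reps`` the
    number of seeded noise draws averaged per variable.
    """

    profile_scale: int = 50
    profile_levels: str = "quartiles"  # or "fixed_grid"
    noise_range: float = 0.3
    noise_reps: int = 100
    clip: bool = True
    error_reference: str = "observations"  # or "predictions"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile_scale < 2:
            raise ConfigError("profile_scale must be >= 2")
        if self.profile_levels not in ("quartiles", "fixed_grid"):
            raise ConfigError(f"unknown profile_levels {self.profile_levels!r}")
        if self.noise_range < 0:
            raise ConfigError("noise_range must be nonnegative")
        if self.error_reference not in ("observations", "predictions"):
            raise ConfigError(f"unknown error_reference {self.error_reference!r}")


@dataclass
class ImportanceTable:
    """Long-format importance records: one row per variable (per method)."""

    method: str
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()


# -- model dispatch ------------------------------------------------------------


def _resolve(model, data) -> tuple:
    """Return (predict function over a plain matrix, input matrix, names, y)."""
    if isinstance(model, CascadeModel):
        if not isinstance(data, SurveyDataset):
            raise DomainError("a SurveyDataset is required with a CascadeModel")
        spec = model.target_model
        X_env = data.environment[spec.input_env].to_numpy(dtype=float)
        cols = [X_env] + [
            forward(model.sub_models[sp].weights, X_env)[:, None]
            for sp in spec.input_species
        ]
        X = np.column_stack(cols)
        names = list(spec.input_env) + [f"P({sp})" for sp in spec.input_species]
        y = data.species_vector(spec.target) if spec.target in data.species_names else None
        return (lambda M: forward(spec.weights, M)), X, names, y
    if isinstance(model, ModelSpec):
        if not isinstance(data, SurveyDataset):
            raise DomainError("a SurveyDataset is required with a ModelSpec")
        X = model.input_matrix(data)
        names = list(model.input_env) + list(model.input_species)
        y = (
            data.species_vector(model.target)
            if model.target in data.species_names
            else None
        )
        return (lambda M: forward(model.weights, M)), X, names, y
    if isinstance(model, SigmoidNetClassifier):
        if not hasattr(model, "network_"):
            raise NotFittedStateError("classifier is not fitted")
        model = model.network_
    if isinstance(model, NetworkWeights):
        X = np.asarray(data, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
        return (lambda M, w=model: forward(w, M)), X, names, None
    raise DomainError(f"unsupported model type {type(model).__name__}")


# -- profile method ------------------------------------------------------------


def lek_profile(model, data, config: SensitivityConfig | None = None, y=None) -> pd.DataFrame:
    """Five response curves per input variable (long-format DataFrame).

    Each variable in turn sweeps ``profile_scale`` evenly spaced points over
    [0, 1] while all other variables sit at one of five levels: their own
    minimum, Q1, median, Q3 and maximum over the data (``"quartiles"``) or the
    fixed grid {0, 0.25, 0.5, 0.75, 1} (``"fixed_grid"``).

    Returns columns: variable, level (1..5), level_value, x, response.
    """
    config = config or SensitivityConfig()
    fn, X, names, _ = _resolve(model, data)
    grid = np.linspace(0.0, 1.0, config.profile_scale)
    rows = []
    for j, name in enumerate(names):
        if config.profile_levels == "quartiles":
            others = np.delete(X, j, axis=1)
            levels = np.percentile(others, [0, 25, 50, 75, 100], axis=0)
        else:
            levels = np.tile(
                np.array([0.0, 0.25, 0.5, 0.75, 1.0])[:, None], (1, X.shape[1] - 1)
            )
        for li, level_row in enumerate(levels):
            M = np.empty((config.profile_scale, X.shape[1]))
            M[:, j] = grid
            other_idx = [c for c in range(X.shape[1]) if c != j]
            M[:, other_idx] = level_row
            resp = fn(M)
            rows.extend(
                {
                    "variable": name,
                    "level": li + 1,
                    "level_value": float(np.mean(level_row)) if level_row.size else np.nan,
                    "x": float(g),
                    "response": float(r),
                }
                for g, r in zip(grid, resp)
            )
    return pd.DataFrame(rows, columns=["variable", "level", "level_value", "x", "response"])


# -- perturbation method -------------------------------------------------------


def perturbation_importance(
    model, data, config: SensitivityConfig | None = None, y=None
) -> ImportanceTable:
    """Percent MSE increase when white noise corrupts one input at a time.

    For each variable, uniform noise on [-noise_range, +noise_range] is added
    to that column (clipped back to [0, 1] by default), the outputs are
    recomputed and the mean squared error — against the observed occurrences
    by default, or against the unperturbed predictions — is compared with the
    unperturbed error.  Averaged over ``noise_reps`` seeded repetitions.
    """
    config = config or SensitivityConfig()
    if config.noise_reps < 1:
        raise ConfigError("noise_reps must be >= 1")
    fn, X, names, y_data = _resolve(model, data)
    if y is None:
        y = y_data
    base_pred = fn(X)
    if config.error_reference == "observations":
        if y is None:
            raise DomainError("observations are required with error_reference='observations'")
        ref = np.asarray(y, dtype=float)
    else:
        ref = base_pred
    base_mse = float(np.mean((base_pred - ref) ** 2))

    # one shared bank of noise vectors: every variable is perturbed with the
    # same draws, so importances are paired and permutation-equivariant
    rng = np.random.default_rng(config.seed)
    noise_bank = rng.uniform(
        -config.noise_range, config.noise_range, size=(config.noise_reps, X.shape[0])
    )
    rows = []
    for j, name in enumerate(names):
        mses = np.empty(config.noise_reps)
        for rep in range(config.noise_reps):
            M = X.copy()
            M[:, j] = M[:, j] + noise_bank[rep]
            if config.clip:
                M[:, j] = np.clip(M[:, j], 0.0, 1.0)
            mses[rep] = np.mean((fn(M) - ref) ** 2)
        mean_mse = float(mses.mean())
        if base_mse > 0:
            pct = 100.0 * (mean_mse - base_mse) / base_mse
        else:  # perfect baseline: report perturbed MSE itself, scaled
            pct = 100.0 * mean_mse
        rows.append({"variable": name, "pct_mse_increase": pct})
    df = pd.DataFrame(rows)
    df["rank"] = df["pct_mse_increase"].rank(ascending=False, method="min").astype(int)
    return ImportanceTable(method="perturbation", records=df)


# -- connection-weights method -------------------------------------------------


def olden_weights(weights, names: list[str] | None = None) -> ImportanceTable:
    """Signed connection-weight contribution of each input variable.

    ``contribution_i = sum_h w_ih * v_h`` over hidden neurons ``h``, bias
    weights excluded.  Positive values mean the variable pushes the predicted
    occurrence probability up.
    """
    if isinstance(weights, SigmoidNetClassifier):
        if not hasattr(weights, "network_"):
            raise NotFittedStateError("classifier is not fitted")
        weights = weights.network_
    if isinstance(weights, ModelSpec):
        names = names or (list(weights.input_env) + list(weights.input_species))
        weights = weights.weights
    if not isinstance(weights, NetworkWeights):
        raise DomainError(f"unsupported weights type {type(weights).__name__}")
    w = weights.input_to_hidden[:-1]  # drop hidden biases
    v = weights.hidden_to_output[:-1]  # drop output bias
    contrib = w @ v
    names = names or [f"x{i}" for i in range(weights.n_inputs)]
    df = pd.DataFrame({"variable": names, "contribution": contrib})
    df["rank"] = df["contribution"].abs().rank(ascending=False, method="min").astype(int)
    return ImportanceTable(method="connection_weights", records=df)
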