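"""The four-step cascaded model: baseline, screening, sub-models, assembly.

Step 1 trains an environment-only network for the target species and records
its cross-validated kappa with a confidence interval (the baseline).  Step 2
re-trains the target model with each candidate species' *observed* occurrence
as one extra input; candidates whose median CV kappa exceeds the baseline CI
upper limit are selected as co-predictors.  Step 3 trains an environment-only
sub-model for each selected co-predictor.  Step 4 wires the sub-model
predicted occurrence probabilities into the target network as extra inputs,
yielding a cascade that consumes environmental variables only: the biotic
information is needed to train the cascade, never to run it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .dataset import SurveyDataset
from .evaluation import (
    CvReport,
    KappaResult,
    binarize,
    cohen_kappa,
    cross_validate,
    roc_analysis,
)
from .exceptions import (
    CompositionError,
    ConfigError,
    DomainError,
    SchemaError,
)
from .network import NetworkWeights, SigmoidNetClassifier, TrainConfig, forward
from .tetrachoric import contingency_from_binary, tetrachoric_r
from .exceptions import DegenerateError

__all__ = [
    "ModelSpec",
    "CandidateScreen",
    "ScreeningResult",
    "CascadeModel",
    "CascadeClassifier",
    "environment_model_factory",
    "cascade_model_factory",
    "train_baseline",
    "screen_copredictors",
    "train_submodel",
    "assemble_cascade",
    "predict_cascade",
    "cascade_to_json",
    "cascade_from_json",
]


# -- persistence-friendly model descriptions ----------------------------------


@dataclass
class ModelSpec:
    """One trained network plus everything needed to apply it to new sites."""

    target: str
    input_env: list[str]
    input_species: list[str]
    input_mode: dict[str, str]  # species -> "observed" | "predicted_probability"
    weights: NetworkWeights
    cutoff: float
    cv: CvReport | None = None

    def __post_init__(self) -> None:
        if self.weights.n_inputs != len(self.input_env) + len(self.input_species):
            raise CompositionError(
                "network input count does not match declared input variables"
            )

    def input_matrix(self, data: SurveyDataset) -> np.ndarray:
        """Assemble this model's inputs (env + observed species columns)."""
        cols = [data.environment[name].to_numpy() for name in self.input_env]
        for sp in self.input_species:
            if self.input_mode.get(sp) != "observed":
                raise CompositionError(
                    f"{sp!r} requires predicted probabilities; use the cascade to predict"
                )
            cols.append(data.species_vector(sp).astype(float))
        return np.column_stack(cols) if cols else np.empty((data.n_sites, 0))

    def predict_scores(self, data: SurveyDataset) -> np.ndarray:
        return forward(self.weights, self.input_matrix(data))

    def to_json_dict(self) -> dict:
        return {
            "target": self.target,
            "input_env": list(self.input_env),
            "input_species": list(self.input_species),
            "input_mode": dict(self.input_mode),
            "weights": self.weights.to_json_dict(),
            "cutoff": self.cutoff,
            "cv": self.cv.to_json_dict() if self.cv is not None else None,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            target=d["target"],
            input_env=list(d["input_env"]),
            input_species=list(d["input_species"]),
            input_mode=dict(d["input_mode"]),
            weights=NetworkWeights.from_json_dict(d["weights"]),
            cutoff=float(d["cutoff"]),
            cv=None,
        )


@dataclass(frozen=True)
class CandidateScreen:
    species: str
    r: float
    median_kappa: float
    selected: bool


@dataclass
class ScreeningResult:
    """Step-2 outcome: baseline kappa with CI and the per-candidate verdicts."""

    baseline: KappaResult
    candidates: list[CandidateScreen] = field(default_factory=list)

    def selected_species(self) -> list[str]:
        return [c.species for c in self.candidates if c.selected]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": c.species,
                    "tetrachoric_r": c.r,
                    "median_kappa": c.median_kappa,
                    "selected": c.selected,
                }
                for c in self.candidates
            ]
        )


@dataclass
class CascadeModel:
    """A target network fed by environment-only co-predictor sub-models."""

    target_model: ModelSpec
    sub_models: dict[str, ModelSpec]
    norm_params: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.target_model.input_species if s not in self.sub_models]
        if missing:
            raise CompositionError(f"no sub-model for species inputs: {missing}")
        extra = [s for s in self.sub_models if s not in self.target_model.input_species]
        if extra:
            raise CompositionError(f"sub-models for species that are not inputs: {extra}")


# -- scikit-learn estimators ---------------------------------------------------


def _stratified_assignment(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded within-class shuffle + round-robin deal (array version)."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment


class CascadeClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn meta-estimator for the cascaded occurrence model.

    ``fit(X, y, copredictors=C)`` takes the environmental matrix ``X``, the
    target occurrence ``y`` and a sites-by-co-predictors binary matrix ``C``
    of observed co-predictor occurrences.  For each co-predictor an
    environment-only sub-network is fitted; the target network is then trained
    on ``X`` augmented with the sub-model occurrence probabilities.
    ``predict``/``predict_proba`` consume ``X`` alone.

    Parameters
    ----------
    composition : "retrain" trains the target network on sub-model predicted
        probabilities (out-of-fold by default); "reuse" trains it on the
        observed co-predictor occurrences (the step-2 network) and swaps in
        sub-model probabilities at prediction time.
    copredictor_inputs : "probability" passes sub-model outputs as continuous
        probabilities; "binary" binarizes them at each sub-model's ROC cutoff.
    oof : "out_of_fold" computes the training-time probabilities with
        ``oof_folds``-fold refits so the target network never sees in-sample
        sub-model outputs; "in_sample" uses the final sub-models directly.
    """

    def __init__(
        self,
        n_hidden: int = 5,
        loss: str = "cross_entropy",
        weight_decay: float = 0.0,
        max_iter: int = 2000,
        tol: float = 1e-8,
        init_range: float = 0.5,
        restarts: int = 5,
        composition: str = "retrain",
        copredictor_inputs: str = "probability",
        oof: str = "out_of_fold",
        oof_folds: int = 5,
        cutoff: float = 0.5,
        random_state: int = 0,
    ) -> None:
        self.n_hidden = n_hidden
        self.loss = loss
        self.weight_decay = weight_decay
        self.max_iter = max_iter
        self.tol = tol
        self.init_range = init_range
        self.restarts = restarts
        self.composition = composition
        self.copredictor_inputs = copredictor_inputs
        self.oof = oof
        self.oof_folds = oof_folds
        self.cutoff = cutoff
        self.random_state = random_state

    # -- internals ------------------------------------------------------------

    def _net(self, seed: int, n_hidden: int | None = None) -> SigmoidNetClassifier:
        return SigmoidNetClassifier(
            n_hidden=n_hidden if n_hidden is not None else self.n_hidden,
            loss=self.loss,
            weight_decay=self.weight_decay,
            max_iter=self.max_iter,
            tol=self.tol,
            init_range=self.init_range,
            restarts=self.restarts,
            random_state=seed,
        )

    @staticmethod
    def _scores(model, X: np.ndarray) -> np.ndarray:
        if callable(model) and not hasattr(model, "predict_proba"):
            return np.asarray(model(X), dtype=float)
        return np.asarray(model.predict_proba(X), dtype=float)[:, 1]

    def _oof_probs(self, X: np.ndarray, c: np.ndarray, seed: int) -> np.ndarray:
        counts = np.bincount(c.astype(int), minlength=2)
        k = min(self.oof_folds, int(counts[counts > 0].min()))
        if k < 2:  # too rare to refit per fold; fall back to in-sample outputs
            return self._scores(self._net(seed).fit(X, c), X)
        assignment = _stratified_assignment(c, k, seed)
        out = np.empty(len(c), dtype=float)
        fold_seeds = np.random.SeedSequence(seed).generate_state(k)
        for i in range(k):
            hold = assignment == i
            net = self._net(int(fold_seeds[i])).fit(X[~hold], c[~hold])
            out[hold] = self._scores(net, X[hold])
        return out

    # -- estimator API ---------------------------------------------------------

    def fit(self, X, y, copredictors=None, submodels=None):
        """Fit sub-models and target network.

        ``copredictors`` may be omitted (or have zero columns), in which case
        the cascade degenerates to an environment-only baseline model.
        ``submodels`` optionally supplies prefitted sub-models (objects with
        ``predict_proba`` or callables X -> probability) used at prediction
        time and, with ``oof="in_sample"``, for the training inputs too.
        """
        if self.composition not in ("retrain", "reuse"):
            raise ConfigError(f"unknown composition {self.composition!r}")
        if self.copredictor_inputs not in ("probability", "binary"):
            raise ConfigError(f"unknown copredictor_inputs {self.copredictor_inputs!r}")
        if self.oof not in ("out_of_fold", "in_sample"):
            raise ConfigError(f"unknown oof mode {self.oof!r}")
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        y01 = (y == self.classes_[-1]).astype(float)
        if copredictors is None:
            C = np.empty((len(y01), 0))
        else:
            C = check_array(copredictors, ensure_2d=True)
        if C.shape[0] != X.shape[0]:
            raise DomainError("copredictors must have one row per site")
        n_co = C.shape[1]
        seeds = np.random.SeedSequence(self.random_state).generate_state(2 * n_co + 1)

        if submodels is not None:
            if len(submodels) != n_co:
                raise CompositionError("one prefitted sub-model per co-predictor required")
            self.submodels_ = list(submodels)
        else:
            self.submodels_ = [
                self._net(int(seeds[j])).fit(X, C[:, j]) for j in range(n_co)
            ]
        self.submodel_cutoffs_ = [
            roc_analysis(self._scores(m, X), C[:, j]).best_cutoff if n_co else 0.5
            for j, m in enumerate(self.submodels_)
        ]

        if self.composition == "reuse":
            Z = np.column_stack([X, C]) if n_co else X
        else:
            probs = []
            for j in range(n_co):
                if self.oof == "out_of_fold":
                    p = self._oof_probs(X, C[:, j], int(seeds[n_co + j]))
                else:
                    p = self._scores(self.submodels_[j], X)
                if self.copredictor_inputs == "binary":
                    p = binarize(p, self.submodel_cutoffs_[j]).astype(float)
                probs.append(p)
            Z = np.column_stack([X] + probs) if probs else X

        self.target_net_ = self._net(int(seeds[-1])).fit(Z, y01)
        self.n_features_in_ = X.shape[1]
        self.n_copredictors_ = n_co
        return self

    def _augment(self, X: np.ndarray) -> np.ndarray:
        cols = [X]
        for j, m in enumerate(self.submodels_):
            p = self._scores(m, X)
            if self.copredictor_inputs == "binary":
                p = binarize(p, self.submodel_cutoffs_[j]).astype(float)
            cols.append(p[:, None])
        return np.column_stack(cols) if len(cols) > 1 else X

    def predict_proba(self, X):
        check_is_fitted(self, "target_net_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"expected {self.n_features_in_} environmental columns, got {X.shape[1]}"
            )
        p = self.target_net_.predict_proba(self._augment(X))[:, 1]
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= self.cutoff).astype(int)]


# -- cross-validation factories -----------------------------------------------


class _SpeciesInputModel:
    """Environment (+ optional observed species) network, CV-factory shaped."""

    def __init__(self, target: str, extra_species: tuple[str, ...], config: TrainConfig):
        self.target = target
        self.extra_species = tuple(extra_species)
        self.config = config
        self.net: SigmoidNetClassifier | None = None

    def _matrix(self, data: SurveyDataset) -> np.ndarray:
        cols = [data.env_matrix()]
        for sp in self.extra_species:
            cols.append(data.species_vector(sp).astype(float)[:, None])
        return np.column_stack(cols)

    def fit(self, data: SurveyDataset, seed: int) -> "_SpeciesInputModel":
        cfg = self.config
        net = SigmoidNetClassifier(
            n_hidden=cfg.n_hidden,
            loss=cfg.loss,
            weight_decay=cfg.weight_decay,
            max_iter=cfg.max_iterations,
            tol=cfg.tolerance,
            init_range=cfg.init_range,
            restarts=cfg.restarts,
            random_state=seed,
        )
        self.net = net.fit(self._matrix(data), data.species_vector(self.target))
        return self

    def predict_scores(self, data: SurveyDataset) -> np.ndarray:
        assert self.net is not None
        return self.net.predict_proba(self._matrix(data))[:, 1]


def environment_model_factory(
    target: str, config: TrainConfig | None = None, extra_species: tuple[str, ...] = ()
):
    """Factory for :func:`cascade_sdm.evaluation.cross_validate`."""
    config = config or TrainConfig()

    def factory(train_data: SurveyDataset, seed: int) -> _SpeciesInputModel:
        return _SpeciesInputModel(target, extra_species, config).fit(train_data, seed)

    return factory


class _CascadeCvModel:
    """Whole-cascade refit on a training fold, CV-factory shaped."""

    def __init__(self, clf: CascadeClassifier, target: str, copredictors: tuple[str, ...]):
        self.clf = clf
        self.target = target
        self.copredictors = copredictors

    def predict_scores(self, data: SurveyDataset) -> np.ndarray:
        return self.clf.predict_proba(data.env_matrix())[:, 1]


def cascade_model_factory(
    target: str,
    copredictors: tuple[str, ...],
    config: TrainConfig | None = None,
    composition: str = "retrain",
    copredictor_inputs: str = "probability",
    oof: str = "out_of_fold",
    oof_folds: int = 5,
):
    """Factory cross-validating the full cascade (sub-models refit per fold)."""
    config = config or TrainConfig()

    def factory(train_data: SurveyDataset, seed: int) -> _CascadeCvModel:
        clf = CascadeClassifier(
            n_hidden=config.n_hidden,
            loss=config.loss,
            weight_decay=config.weight_decay,
            max_iter=config.max_iterations,
            tol=config.tolerance,
            init_range=config.init_range,
            restarts=config.restarts,
            composition=composition,
            copredictor_inputs=copredictor_inputs,
            oof=oof,
            oof_folds=oof_folds,
            random_state=seed,
        )
        C = np.column_stack(
            [train_data.species_vector(sp) for sp in copredictors]
        ) if copredictors else None
        clf.fit(train_data.env_matrix(), train_data.species_vector(target), copredictors=C)
        return _CascadeCvModel(clf, target, copredictors)

    return factory


def compare_cascade_benefit(
    data: SurveyDataset,
    target: str,
    copredictors: tuple[str, ...],
    target_config: TrainConfig | None = None,
    submodel_config: TrainConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    cutoff_mode: str = "test",
    submodel_scope: str = "survey",
) -> dict[str, CvReport]:
    """Cross-validated kappa of the three competing target models.

    Evaluates, with identical folds, (a) the environment-only baseline,
    (b) the model with the co-predictors' *observed* occurrences as extra
    inputs, and (c) the cascaded model fed sub-model predicted probabilities.

    ``submodel_scope="survey"`` applies the four-step procedure literally:
    the step-3 sub-models are trained once on the whole survey (observed
    co-predictor occurrences are available at every training site) before the
    target model is cross-validated.  Sub-model predictions at held-out sites
    therefore come from networks that saw those sites' occurrences during
    training — part of what makes predicted co-predictor probabilities
    informative, and flagged accordingly in the docs.  ``"fold"`` refits the
    sub-models inside each training fold instead (fully leakage-free).

    Returns ``{"baseline": CvReport, "observed": CvReport, "cascade": CvReport}``.
    """
    _require_normalized(data)
    if submodel_scope not in ("survey", "fold"):
        raise ConfigError(f"unknown submodel_scope {submodel_scope!r}")
    target_config = target_config or TrainConfig()
    submodel_config = submodel_config or target_config

    out: dict[str, CvReport] = {}
    out["baseline"] = cross_validate(
        data, target, environment_model_factory(target, target_config),
        folds=folds, seed=seed, cutoff_mode=cutoff_mode,
    )
    out["observed"] = cross_validate(
        data, target, environment_model_factory(target, target_config, tuple(copredictors)),
        folds=folds, seed=seed, cutoff_mode=cutoff_mode,
    )

    if submodel_scope == "survey":
        sub_seeds = np.random.SeedSequence(seed).generate_state(len(copredictors) + 1)
        subnets = [
            _SpeciesInputModel(sp, (), submodel_config).fit(data, int(sub_seeds[j]))
            for j, sp in enumerate(copredictors)
        ]

        def factory(train_data: SurveyDataset, fold_seed: int):
            P = np.column_stack([s.predict_scores(train_data) for s in subnets])
            cfg = target_config
            clf = SigmoidNetClassifier(
                n_hidden=cfg.n_hidden, loss=cfg.loss, weight_decay=cfg.weight_decay,
                max_iter=cfg.max_iterations, tol=cfg.tolerance,
                init_range=cfg.init_range, restarts=cfg.restarts, random_state=fold_seed,
            )
            clf.fit(
                np.column_stack([train_data.env_matrix(), P]),
                train_data.species_vector(target),
            )

            class _Predictor:
                def predict_scores(self, d: SurveyDataset) -> np.ndarray:
                    Pd = np.column_stack([s.predict_scores(d) for s in subnets])
                    return clf.predict_proba(np.column_stack([d.env_matrix(), Pd]))[:, 1]

            return _Predictor()

        out["cascade"] = cross_validate(
            data, target, factory, folds=folds, seed=seed, cutoff_mode=cutoff_mode
        )
    else:
        out["cascade"] = cross_validate(
            data, target,
            cascade_model_factory(target, tuple(copredictors), target_config),
            folds=folds, seed=seed, cutoff_mode=cutoff_mode,
        )
    return out


# -- the four-step procedure ---------------------------------------------------


def _require_normalized(data: SurveyDataset) -> None:
    if not data.normalized:
        raise DomainError("environment must be normalized to [0, 1] before training")


def _fit_env_spec(
    data: SurveyDataset,
    target: str,
    config: TrainConfig,
    extra_species: tuple[str, ...],
    folds: int,
    seed: int,
    cutoff_mode: str,
) -> ModelSpec:
    cv = cross_validate(
        data,
        target,
        environment_model_factory(target, config, extra_species),
        folds=folds,
        seed=seed,
        cutoff_mode=cutoff_mode,
    )
    final = _SpeciesInputModel(target, extra_species, config).fit(data, seed)
    scores = final.predict_scores(data)
    cutoff = roc_analysis(scores, data.species_vector(target)).best_cutoff
    return ModelSpec(
        target=target,
        input_env=data.env_names,
        input_species=list(extra_species),
        input_mode={sp: "observed" for sp in extra_species},
        weights=final.net.network_,
        cutoff=cutoff,
        cv=cv,
    )


def train_baseline(
    data: SurveyDataset,
    target: str,
    config: TrainConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    cutoff_mode: str = "test",
) -> ModelSpec:
    """Step 1: environment-only target model with its baseline CV kappa."""
    _require_normalized(data)
    if target not in data.species_names:
        raise SchemaError(f"unknown target species {target!r}")
    return _fit_env_spec(data, target, config or TrainConfig(), (), folds, seed, cutoff_mode)


def screen_copredictors(
    data: SurveyDataset,
    target: str,
    baseline: ModelSpec,
    candidates: list[str],
    config: TrainConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    cutoff_mode: str = "test",
) -> ScreeningResult:
    """Step 2: score each candidate co-predictor by the CV kappa it yields.

    A candidate is selected when the median CV kappa of the model using its
    observed occurrence as an extra input strictly exceeds the upper limit of
    the baseline kappa confidence interval.
    """
    _require_normalized(data)
    if target in candidates:
        raise DomainError("the target species cannot be its own co-predictor")
    if baseline.cv is None:
        raise CompositionError("baseline model carries no cross-validation report")
    base_kappa = cohen_kappa(baseline.cv.median_fold_matrix)
    result = ScreeningResult(baseline=base_kappa)
    config = config or TrainConfig()
    y = data.species_vector(target)
    cand_seeds = np.random.SeedSequence(seed).generate_state(max(len(candidates), 1))
    for j, sp in enumerate(candidates):
        try:
            r = tetrachoric_r(
                contingency_from_binary(data.species_vector(sp), y)
            ).r
        except DegenerateError:
            r = float("nan")
        cv = cross_validate(
            data,
            target,
            environment_model_factory(target, config, (sp,)),
            folds=folds,
            seed=int(cand_seeds[j]),
            cutoff_mode=cutoff_mode,
        )
        result.candidates.append(
            CandidateScreen(
                species=sp,
                r=r,
                median_kappa=cv.median_k,
                selected=cv.median_k > base_kappa.ci_high,
            )
        )
    return result


def train_submodel(
    data: SurveyDataset,
    copredictor: str,
    config: TrainConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    cutoff_mode: str = "test",
) -> ModelSpec:
    """Step 3: environment-only model for a co-predictor species."""
    _require_normalized(data)
    if copredictor not in data.species_names:
        raise SchemaError(f"unknown species {copredictor!r}")
    return _fit_env_spec(data, copredictor, config or TrainConfig(), (), folds, seed, cutoff_mode)


def assemble_cascade(
    data: SurveyDataset,
    target: str,
    selected: list[str],
    sub_models: dict[str, ModelSpec],
    config: TrainConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    composition: str = "retrain",
    oof: str = "out_of_fold",
    cutoff_mode: str = "test",
) -> CascadeModel:
    """Step 4: combine the target network with its co-predictor sub-models.

    With ``composition="retrain"`` (default) a new target network is trained
    on the environment plus sub-model occurrence probabilities (computed
    out-of-fold unless ``oof="in_sample"``); with ``"reuse"`` the step-2
    network trained on observed occurrences is kept and fed sub-model
    probabilities at run time.
    """
    _require_normalized(data)
    missing = [s for s in selected if s not in sub_models]
    if missing:
        raise CompositionError(f"missing sub-models for: {missing}")
    extra = [s for s in sub_models if s not in selected]
    if extra:
        raise CompositionError(f"sub-models supplied for unselected species: {extra}")

    config = config or TrainConfig()
    prefit = [
        (lambda X, w=sub_models[sp].weights: forward(w, X)) for sp in selected
    ]
    clf = CascadeClassifier(
        n_hidden=config.n_hidden,
        loss=config.loss,
        weight_decay=config.weight_decay,
        max_iter=config.max_iterations,
        tol=config.tolerance,
        init_range=config.init_range,
        restarts=config.restarts,
        composition=composition,
        oof=oof,
        random_state=seed,
    )
    C = (
        np.column_stack([data.species_vector(sp) for sp in selected])
        if selected
        else None
    )
    # training-time probabilities come from seeded out-of-fold refits (unless
    # oof="in_sample"); the runtime sub-models are the step-3 networks passed in
    clf.fit(
        data.env_matrix(),
        data.species_vector(target),
        copredictors=C,
        submodels=prefit,
    )
    clf.submodel_cutoffs_ = [sub_models[sp].cutoff for sp in selected]

    cv = cross_validate(
        data,
        target,
        cascade_model_factory(target, tuple(selected), config, composition=composition, oof=oof),
        folds=folds,
        seed=seed,
        cutoff_mode=cutoff_mode,
    )
    scores = clf.predict_proba(data.env_matrix())[:, 1]
    cutoff = roc_analysis(scores, data.species_vector(target)).best_cutoff
    target_spec = ModelSpec(
        target=target,
        input_env=data.env_names,
        input_species=list(selected),
        input_mode={sp: "predicted_probability" for sp in selected},
        weights=clf.target_net_.network_,
        cutoff=cutoff,
        cv=cv,
    )
    return CascadeModel(
        target_model=target_spec,
        sub_models={sp: sub_models[sp] for sp in selected},
        norm_params=dict(data.norm_params) if data.norm_params else None,
    )


def predict_cascade(model: CascadeModel, environment) -> tuple[np.ndarray, np.ndarray]:
    """Apply a cascade to environmental data only.

    ``environment`` is a DataFrame (or SurveyDataset) whose columns include
    the model's environmental inputs, matched by name; any other columns —
    including species columns — are ignored, so predictions are identical
    whether or not biotic data are present.
    """
    if isinstance(environment, SurveyDataset):
        environment = environment.environment
    spec = model.target_model
    missing = [c for c in spec.input_env if c not in environment.columns]
    if missing:
        raise SchemaError(f"missing environmental columns: {missing}")
    X = environment[spec.input_env].to_numpy(dtype=float)
    cols = [X]
    for sp in spec.input_species:
        cols.append(forward(model.sub_models[sp].weights, X)[:, None])
    probs = forward(spec.weights, np.column_stack(cols))
    return probs, binarize(probs, spec.cutoff)


# -- persistence ---------------------------------------------------------------


def cascade_to_json(model: CascadeModel, config_echo: dict | None = None) -> str:
    return json.dumps(
        {
            "format": "cascade-sdm/1",
            "target_model": model.target_model.to_json_dict(),
            "sub_models": {sp: m.to_json_dict() for sp, m in model.sub_models.items()},
            "norm_params": model.norm_params,
            "config": config_echo or {},
        },
        indent=2,
    )


def cascade_from_json(text: str) -> CascadeModel:
    d = json.loads(text)
    if d.get("format") != "cascade-sdm/1":
        raise ConfigError("not a cascade model bundle")
    norm = d.get("norm_params")
    return CascadeModel(
        target_model=ModelSpec.from_json_dict(d["target_model"]),
        sub_models={sp: ModelSpec.from_json_dict(m) for sp, m in d["sub_models"].items()},
        norm_params={k: (float(v[0]), float(v[1])) for k, v in norm.items()} if norm else None,
    )
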