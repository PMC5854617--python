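"""Tetrachoric correlation between binary species occurrence vectors.

The tetrachoric coefficient is the correlation of a latent bivariate normal
inferred from a 2x2 table of two dichotomized variables.  It is the natural
analogue of Pearson's r for presence/absence data and is used here to rank
candidate co-predictor species against a target species.

The estimator is the conventional two-step maximum-likelihood one: the latent
thresholds are fixed from the margins via the inverse normal CDF, then the
table likelihood is maximized over the latent correlation rho, with the
bivariate-normal rectangle probabilities evaluated through Owen's T function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri, owens_t

from .dataset import SurveyDataset
from .exceptions import DegenerateError, DomainError, SchemaError

__all__ = [
    "ContingencyTable2x2",
    "CorrelationResult",
    "contingency_from_binary",
    "bivariate_normal_cdf",
    "tetrachoric_r",
    "correlation_ranking",
    "ranking_to_frame",
]

RHO_BOUND = 0.9999  # keep the optimizer away from the +/-1 singularities


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Joint counts for two binary variables.

    ``n11`` both present, ``n10`` x only, ``n01`` y only, ``n00`` both absent.
    """

    n11: float
    n10: float
    n01: float
    n00: float

    def __post_init__(self) -> None:
        for cell in (self.n11, self.n10, self.n01, self.n00):
            if cell < 0:
                raise DomainError("contingency cells must be nonnegative")

    @property
    def n(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    def corrected(self) -> "ContingencyTable2x2":
        """Continuity correction: add 0.5 to every cell if any cell is zero."""
        cells = (self.n11, self.n10, self.n01, self.n00)
        if min(cells) > 0:
            return self
        return ContingencyTable2x2(*(c + 0.5 for c in cells))


@dataclass(frozen=True)
class CorrelationResult:
    """Tetrachoric estimate with its latent thresholds and estimator flags."""

    r: float
    thresholds: tuple[float, float]
    corrected: bool
    converged: bool


def contingency_from_binary(x, y) -> ContingencyTable2x2:
    """Tally the 2x2 table of two equal-length binary vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError(f"expected equal-length 1-D vectors, got {x.shape} and {y.shape}")
    if x.size < 1:
        raise DomainError("vectors must be non-empty")
    for name, v in (("x", x), ("y", y)):
        if not np.isin(v, (0, 1)).all():
            raise DomainError(f"{name} contains non-binary entries")
    x = x.astype(int)
    y = y.astype(int)
    return ContingencyTable2x2(
        n11=int(((x == 1) & (y == 1)).sum()),
        n10=int(((x == 1) & (y == 0)).sum()),
        n01=int(((x == 0) & (y == 1)).sum()),
        n00=int(((x == 0) & (y == 0)).sum()),
    )


def bivariate_normal_cdf(h: float, k: float, rho) -> np.ndarray | float:
    """P(X <= h, Y <= k) for standard bivariate normal, vectorized over rho.

    Uses Owen's (1956) T-function identity
    ``Phi2(h,k;rho) = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - beta`` with
    ``beta = 1/2`` when h and k fall on opposite sides of zero.
    """
    rho = np.asarray(rho, dtype=float)
    # nudge thresholds off zero so the T-function slopes are finite
    h = float(h) if abs(h) > 1e-10 else 1e-10
    k = float(k) if abs(k) > 1e-10 else 1e-10
    denom = np.sqrt(np.clip(1.0 - rho**2, 1e-14, None))
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    beta = 0.5 if h * k < 0 else 0.0
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _cell_probabilities(h: float, k: float, rho):
    """Latent rectangle probabilities (p11, p10, p01, p00) at thresholds h, k.

    A variable is "present" when its latent exceeds the threshold.
    """
    p00 = bivariate_normal_cdf(h, k, rho)
    p01 = ndtr(h) - p00  # x below threshold (absent), y above (present)
    p10 = ndtr(k) - p00
    p11 = 1.0 - ndtr(h) - ndtr(k) + p00
    return p11, p10, p01, p00


def _log_likelihood(table: ContingencyTable2x2, h: float, k: float, rho):
    probs = _cell_probabilities(h, k, rho)
    counts = (table.n11, table.n10, table.n01, table.n00)
    ll = 0.0
    for c, p in zip(counts, probs):
        ll = ll + c * np.log(np.clip(p, 1e-300, None))
    return ll


def tetrachoric_r(table: ContingencyTable2x2) -> CorrelationResult:
    """Two-step maximum-likelihood tetrachoric correlation of a 2x2 table.

    Raises
    ------
    DegenerateError
        if either margin is zero (a variable always or never "present").
    """
    if table.n < 1:
        raise DegenerateError("empty table")
    if table.n11 + table.n10 == 0 or table.n01 + table.n00 == 0:
        raise DegenerateError("x margin is degenerate (always or never present)")
    if table.n11 + table.n01 == 0 or table.n10 + table.n00 == 0:
        raise DegenerateError("y margin is degenerate (always or never present)")

    work = table.corrected()
    corrected = work is not table
    n = work.n
    # thresholds from margins: P(latent <= h) = P(absent)
    h = float(ndtri((work.n01 + work.n00) / n))
    k = float(ndtri((work.n10 + work.n00) / n))

    res = minimize_scalar(
        lambda rho: -_log_likelihood(work, h, k, rho),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return CorrelationResult(
        r=float(res.x),
        thresholds=(h, k),
        corrected=corrected,
        converged=bool(res.success),
    )


def correlation_ranking(
    data: SurveyDataset, target: str
) -> list[tuple[str, CorrelationResult | None]]:
    """Tetrachoric r of every non-target species against the target.

    Species with a degenerate occurrence column get a ``None`` result rather
    than being silently dropped.  Sorted by descending \\|r\\| (None last).
    """
    if target not in data.species_names:
        raise SchemaError(f"unknown target species {target!r}")
    if len(data.species_names) < 2:
        raise DomainError("need at least two species to rank")
    y = data.species_vector(target)
    results: list[tuple[str, CorrelationResult | None]] = []
    for sp in data.species_names:
        if sp == target:
            continue
        x = data.species_vector(sp)
        try:
            results.append((sp, tetrachoric_r(contingency_from_binary(x, y))))
        except DegenerateError:
            results.append((sp, None))
    results.sort(key=lambda t: -abs(t[1].r) if t[1] is not None else np.inf)
    return results


def ranking_to_frame(ranking) -> "pd.DataFrame":
    """Tabulate a ranking as species / r / corrected / converged columns."""
    import pandas as pd

    rows = []
    for sp, res in ranking:
        if res is None:
            rows.append({"species": sp, "r": np.nan, "corrected": False, "converged": False})
        else:
            rows.append(
                {"species": sp, "r": res.r, "corrected": res.corrected, "converged": res.converged}
            )
    return pd.DataFrame(rows, columns=["species", "r", "corrected", "converged"])
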