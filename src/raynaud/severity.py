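"""Poisson model of daily Raynaud attack counts versus temperature.

Attack diaries from pooled n-of-1 trials record, per patient-day, the
number of vasospastic attacks and the daily temperature at the nearest
weather station.  Counts are modelled as Poisson with a log link,

    attacks_day ~ Poisson(exp(b0 + b_T * temperature + ...)),

fitted by iteratively reweighted least squares (IRLS) implemented here,
with the coefficient covariance taken from the inverse Fisher information
at the optimum.  Predictions are summarised as weekly attack frequencies
(7x the daily rate) and, mirroring the empirical observation that attacks
cease above about 13 degC, a hard zero threshold is applied above a
configurable temperature.

A previously published fit (e.g. a coefficient file distributed alongside
the original diary data) can be imported with
:meth:`PoissonSeverityFit.from_coefficients` instead of refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDesignError, DegenerateFitError, ValidationError

#: Temperature (degC) at and above which predicted attack frequency is zero.
DEFAULT_ATTACK_THRESHOLD = 13.0

#: Default temperature range (degC) over which weekly effects are summarised.
DEFAULT_EFFECT_RANGE = (0.0, 13.0)

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


@dataclass
class AttackDiary:
    """One patient-day: attack count, temperature, optional extra covariates."""

    patient_id: str
    day: pd.Timestamp
    attack_count: int
    temperature: float
    extra_covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.attack_count < 0 or int(self.attack_count) != self.attack_count:
            raise ValidationError(
                f"patient {self.patient_id!r} day {self.day}: attack_count "
                f"{self.attack_count} must be a non-negative integer"
            )


def diaries_to_frame(diaries) -> pd.DataFrame:
    """Normalise a diary list or DataFrame to a validated DataFrame."""
    if isinstance(diaries, pd.DataFrame):
        df = diaries.copy()
    else:
        rows = []
        for d in diaries:
            row = {
                "patient_id": d.patient_id,
                "day": d.day,
                "attack_count": d.attack_count,
                "temperature": d.temperature,
            }
            row.update(d.extra_covariates)
            rows.append(row)
        df = pd.DataFrame(rows)
    required = {"patient_id", "day", "attack_count", "temperature"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"diary missing columns: {sorted(missing)}")
    counts = df["attack_count"].to_numpy()
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValidationError("attack_count must be non-negative integers")
    if df.duplicated(subset=["patient_id", "day"]).any():
        raise ValidationError("duplicate (patient_id, day) rows in diary")
    return df


def read_diaries(path) -> pd.DataFrame:
    """Read a diary CSV (``patient_id,day,attack_count,temperature[,...]``)."""
    df = pd.read_csv(path, parse_dates=["day"])
    return diaries_to_frame(df)


@dataclass
class PoissonSeverityFit:
    """Log-link Poisson fit of daily attack counts.

    ``coefficients`` maps coefficient names (``"intercept"``,
    ``"temperature"``, extras) to values on the log-rate scale;
    ``covariance`` is ordered the same way.
    """

    coefficients: dict[str, float]
    covariance: np.ndarray
    log_likelihood: float
    n_obs: int
    converged: bool
    iterations: int
    attack_threshold_temp: float = DEFAULT_ATTACK_THRESHOLD
    ll_path: list[float] = field(default_factory=list, repr=False)

    @property
    def names(self) -> list[str]:
        return list(self.coefficients)

    @property
    def beta(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()), dtype=float)

    def standard_errors(self) -> dict[str, float]:
        se = np.sqrt(np.diag(self.covariance))
        return dict(zip(self.names, se))

    @classmethod
    def from_coefficients(
        cls,
        coefficients: Mapping[str, float],
        attack_threshold_temp: float = DEFAULT_ATTACK_THRESHOLD,
    ) -> "PoissonSeverityFit":
        """Wrap externally estimated coefficients (no refit, no covariance)."""
        coefs = {str(k): float(v) for k, v in coefficients.items()}
        k = len(coefs)
        return cls(
            coefficients=coefs,
            covariance=np.full((k, k), np.nan),
            log_likelihood=np.nan,
            n_obs=0,
            converged=True,
            iterations=0,
            attack_threshold_temp=attack_threshold_temp,
        )

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "coefficients": self.coefficients,
                "covariance": np.asarray(self.covariance, dtype=float).tolist(),
                "log_likelihood": self.log_likelihood,
                "n_obs": self.n_obs,
                "converged": self.converged,
                "iterations": self.iterations,
                "attack_threshold_temp": self.attack_threshold_temp,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "PoissonSeverityFit":
        if hasattr(source, "read"):
            data = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        if "covariance" not in data:  # bare coefficient file
            return cls.from_coefficients(
                data.get("coefficients", data),
                data.get("attack_threshold_temp", DEFAULT_ATTACK_THRESHOLD),
            )
        data["covariance"] = np.array(data["covariance"], dtype=float)
        return cls(**data)


def _design_matrix(df: pd.DataFrame, covariate_names: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for name in covariate_names:
        if name not in df.columns:
            raise ValidationError(f"diary has no covariate column {name!r}")
        cols.append(df[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def poisson_log_likelihood(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Poisson log-likelihood (including the log y! normalising term)."""
    eta = X @ beta
    from scipy.special import gammaln

    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def fit_poisson(
    diaries,
    covariate_names: Sequence[str] = ("temperature",),
    attack_threshold_temp: float = DEFAULT_ATTACK_THRESHOLD,
    patient_effects: bool = False,
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
) -> PoissonSeverityFit:
    """Maximum-likelihood log-link Poisson fit via IRLS.

    The design is an intercept plus the named diary columns; with
    ``patient_effects=True``, patient indicator columns (first patient as
    reference) are appended as fixed effects.  Iteration stops when the
    relative log-likelihood change drops below ``tol`` (default 1e-8) or
    after ``max_iter`` iterations, in which case the fit is returned with
    ``converged=False``.  Exposure is one day per row.

    Raises
    ------
    DegenerateFitError
        if every count is zero (the MLE intercept is -inf).
    DegenerateDesignError
        if the design matrix is rank deficient.
    """
    df = diaries_to_frame(diaries)
    if len(df) < 10:
        raise ValidationError(f"need >= 10 diary rows, got {len(df)}")
    y = df["attack_count"].to_numpy(dtype=float)
    if not np.any(y > 0):
        raise DegenerateFitError("all attack counts are zero; log mean is -inf")

    X = _design_matrix(df, covariate_names)
    names = ["intercept", *covariate_names]
    if patient_effects:
        patients = sorted(df["patient_id"].unique())
        for pid in patients[1:]:
            X = np.column_stack([X, (df["patient_id"] == pid).to_numpy(float)])
            names.append(f"patient[{pid}]")

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError(
            "design matrix is rank deficient (collinear covariates)"
        )

    # Deterministic start: log mean count for the intercept, zero elsewhere.
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean() + 1e-6)
    ll = poisson_log_likelihood(beta, X, y)
    ll_path = [ll]

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.exp(eta)
        # Working response and weights of the log-link Poisson IRLS step.
        z = eta + (y - mu) / mu
        WX = X * mu[:, None]
        beta_full = np.linalg.solve(X.T @ WX, WX.T @ z)
        # Step halving keeps the likelihood path monotone even when a full
        # Newton step overshoots (possible far from the optimum).
        step = beta_full - beta
        beta_new = beta_full
        ll_new = poisson_log_likelihood(beta_new, X, y)
        halvings = 0
        while (not np.isfinite(ll_new) or ll_new < ll) and halvings < 30:
            step /= 2.0
            beta_new = beta + step
            ll_new = poisson_log_likelihood(beta_new, X, y)
            halvings += 1
        beta = beta_new
        ll_path.append(ll_new)
        if abs(ll_new - ll) <= tol * (abs(ll) + 1e-12):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    mu = np.exp(X @ beta)
    fisher = X.T @ (X * mu[:, None])
    covariance = np.linalg.inv(fisher)
    covariance = (covariance + covariance.T) / 2.0

    return PoissonSeverityFit(
        coefficients={n: float(b) for n, b in zip(names, beta)},
        covariance=covariance,
        log_likelihood=ll,
        n_obs=len(df),
        converged=converged,
        iterations=iterations,
        attack_threshold_temp=attack_threshold_temp,
        ll_path=ll_path,
    )


def _linear_predictor(
    fit: PoissonSeverityFit, temperature, extra_covariates: Mapping[str, float] | None
) -> np.ndarray:
    t = np.asarray(temperature, dtype=float)
    eta = np.zeros_like(t, dtype=float)
    extras = dict(extra_covariates or {})
    for name, value in fit.coefficients.items():
        if name == "intercept":
            eta = eta + value
        elif name == "temperature":
            eta = eta + value * t
        else:
            if name not in extras:
                raise ValidationError(f"missing required covariate value {name!r}")
            eta = eta + value * float(extras[name])
    return eta


def predict_weekly_attacks(
    fit: PoissonSeverityFit,
    temperature,
    extra_covariates: Mapping[str, float] | None = None,
    apply_threshold: bool = True,
) -> np.ndarray | float:
    """Expected attacks per week (7x the daily Poisson rate).

    At or above the fit's attack threshold temperature the prediction is
    forced to zero (when ``apply_threshold``); NaN temperatures propagate.
    """
    t = np.asarray(temperature, dtype=float)
    weekly = 7.0 * np.exp(_linear_predictor(fit, t, extra_covariates))
    if apply_threshold:
        weekly = np.where(t >= fit.attack_threshold_temp, 0.0, weekly)
    weekly = np.where(np.isnan(t), np.nan, weekly)
    return float(weekly) if np.isscalar(temperature) else weekly


@dataclass(frozen=True)
class WeeklyTemperatureEffect:
    """Secant-line summary of how weekly attacks change with temperature."""

    mean_slope: float  # attacks/week per degC
    degrees_per_one_fewer_attack: float  # degC; NaN when not defined
    t_low: float
    t_high: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.degrees_per_one_fewer_attack)


def weekly_temperature_effect(
    fit: PoissonSeverityFit,
    t_low: float = DEFAULT_EFFECT_RANGE[0],
    t_high: float = DEFAULT_EFFECT_RANGE[1],
    extra_covariates: Mapping[str, float] | None = None,
    apply_threshold: bool = True,
) -> WeeklyTemperatureEffect:
    """Average slope of weekly attacks over [t_low, t_high].

    ``degrees_per_one_fewer_attack`` is ``1/|mean_slope|`` when the slope is
    negative, i.e. how many degrees of warming remove one weekly attack on
    average over the range; it is NaN (with ``defined == False``) for a flat
    or increasing profile.
    """
    if not t_low < t_high:
        raise ValueError(f"require t_low < t_high, got ({t_low}, {t_high})")
    lo = predict_weekly_attacks(fit, t_low, extra_covariates, apply_threshold)
    hi = predict_weekly_attacks(fit, t_high, extra_covariates, apply_threshold)
    mean_slope = (hi - lo) / (t_high - t_low)
    degrees = 1.0 / abs(mean_slope) if mean_slope < 0 else float("nan")
    return WeeklyTemperatureEffect(
        mean_slope=float(mean_slope),
        degrees_per_one_fewer_attack=float(degrees),
        t_low=float(t_low),
        t_high=float(t_high),
    )
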