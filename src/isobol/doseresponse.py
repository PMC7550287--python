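"""Log-probit dose-response fitting for quantal (all-or-none) bioassay data.

A quantal assay records, for each dose group, how many of ``n_tested``
animals respond (e.g. are protected from electroshock-induced seizures).
The classical analysis regresses the probit of the response proportion on
log10(dose): the dose at probit 0 (50% response) is the median effective
dose ED50, and the line's slope measures how steeply response rises with
dose.

The primary fitting engine here is maximum-likelihood probit regression
(a binomial GLM with probit link on log10 dose), which generalises the
graphical log-probit method to a reproducible estimator with well-defined
standard errors.  The standard error of the ED50 is obtained by the delta
method on log10(ED50) = -intercept/slope and transformed back to the dose
scale.  A Berkson-style minimum chi-square variant on empirical probits is
available for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DoseGroup",
    "FitConfig",
    "ProbitFit",
    "ParallelismResult",
    "fit_log_probit",
    "predict_response",
    "test_parallelism",
    "Ed50NotIdentifiableError",
]

LN10 = math.log(10.0)


class Ed50NotIdentifiableError(ValueError):
    """Raised when the observed responses cannot bracket a 50% dose."""


@dataclass(frozen=True)
class DoseGroup:
    """One dose level's quantal outcome.

    Parameters
    ----------
    drug_id : str
        Identifier of the drug (or mixture) administered.
    dose : float
        Administered dose in mg/kg; for a mixture this is the total dose.
    n_tested : int
        Number of animals in the group.
    n_protected : int
        Number of animals showing the all-or-none response.
    pretreatment_min : float, optional
        Minutes between administration and test.  Metadata only; it never
        enters the fit.
    """

    drug_id: str
    dose: float
    n_tested: int
    n_protected: int
    pretreatment_min: float | None = None

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        if self.n_tested < 1:
            raise ValueError(f"n_tested must be >= 1, got {self.n_tested}")
        if not 0 <= self.n_protected <= self.n_tested:
            raise ValueError(
                f"n_protected must lie in [0, n_tested], got "
                f"{self.n_protected}/{self.n_tested}"
            )

    @property
    def fraction(self) -> float:
        return self.n_protected / self.n_tested


@dataclass(frozen=True)
class FitConfig:
    """Options controlling :func:`fit_log_probit`.

    engine
        ``"mle"`` (default): maximum-likelihood probit regression.
        ``"minchi2"``: Berkson-style minimum chi-square on empirical
        probits; 0%/100% groups are excluded since their probit is
        undefined.
    drop_extreme_groups
        When true, groups with 0% or 100% response are excluded before an
        MLE fit as well (the classical log-probit working rule).  Off by
        default: extreme groups are informative in the likelihood.
    df
        Override for the stored residual degrees of freedom; defaults to
        (number of dose groups - 2).
    """

    engine: Literal["mle", "minchi2"] = "mle"
    drop_extreme_groups: bool = False
    df: int | None = None


@dataclass(frozen=True)
class ProbitFit:
    """A fitted log-probit dose-response line.

    The model is ``P(response at dose d) = Phi(intercept + slope * log10 d)``
    with Phi the standard normal CDF, so ``log_ed50 = -intercept / slope``
    and ``ed50 = 10 ** log_ed50``.  Probits are centred at zero (probit 0 =
    50% response); the classical "+5" display offset belongs to plotting,
    not to the parameterisation.
    """

    drug_id: str
    slope: float  # probits per log10(mg/kg)
    intercept: float  # probits at log10(dose) = 0
    ed50: float  # mg/kg
    sem_ed50: float  # mg/kg, delta method
    log_ed50: float  # log10(mg/kg)
    sem_log_ed50: float
    param_covariance: np.ndarray  # 2x2, order (slope, intercept)
    n_total: int  # animals
    df: int
    converged: bool
    loglik: float
    engine: str = "mle"

    def __post_init__(self) -> None:
        cov = np.asarray(self.param_covariance, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("param_covariance must be 2x2")
        object.__setattr__(self, "param_covariance", cov)

    @property
    def se_slope(self) -> float:
        return float(np.sqrt(self.param_covariance[0, 0]))


@dataclass(frozen=True)
class ParallelismResult:
    """Outcome of a two-sided test of slope equality between two fits."""

    statistic: float
    df_description: str
    p_value: float
    parallel: bool
    alpha: float
    slope_a: float
    slope_b: float

    @property
    def slope_ratio(self) -> float:
        return self.slope_a / self.slope_b


def _binomial_loglik(
    log_doses: np.ndarray,
    n: np.ndarray,
    k: np.ndarray,
    slope: float,
    intercept: float,
) -> float:
    """Binomial log-likelihood of a probit line (combinatorial term omitted
    consistently, matching statsmodels' GLM convention up to a constant)."""
    eta = intercept + slope * log_doses
    # log Phi and log(1-Phi) evaluated stably
    logp = stats.norm.logcdf(eta)
    logq = stats.norm.logcdf(-eta)
    return float(np.sum(k * logp + (n - k) * logq))


def _validate_groups(groups: Sequence[DoseGroup]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(groups) == 0:
        raise ValueError("no dose groups supplied")
    doses = np.array([g.dose for g in groups], dtype=float)
    n = np.array([g.n_tested for g in groups], dtype=float)
    k = np.array([g.n_protected for g in groups], dtype=float)
    if len(np.unique(doses)) < 2:
        raise ValueError("at least 2 distinct doses are required")
    if np.all(k == 0) or np.all(k == n):
        raise Ed50NotIdentifiableError(
            "ED50 not identifiable: every dose group responded at 0% "
            "or every group at 100%"
        )
    return doses, n, k


def fit_log_probit(groups: Sequence[DoseGroup], config: FitConfig | None = None) -> ProbitFit:
    """Fit a probit line in log10(dose) to quantal dose-group data.

    Parameters
    ----------
    groups
        Dose groups for one drug (or one fixed-ratio mixture, using total
        dose).  At least two distinct doses are required, and the observed
        responses must not all sit at 0% or all at 100%.
    config
        Fitting options; see :class:`FitConfig`.

    Returns
    -------
    ProbitFit
        Fitted line with ED50 +/- SEM.  ``converged`` is honest: a fit that
        failed to converge (e.g. complete separation of the responses) is
        returned flagged, never silently.

    Raises
    ------
    Ed50NotIdentifiableError
        If every group responded at 0% or every group at 100%.
    ValueError
        Fewer than two distinct doses, or no usable groups after the
        configured extreme-group handling.
    """
    config = config or FitConfig()
    doses, n, k = _validate_groups(groups)
    drug_id = groups[0].drug_id

    if config.drop_extreme_groups or config.engine == "minchi2":
        keep = (k > 0) & (k < n)
        if config.engine == "mle" and config.drop_extreme_groups:
            # keep the MLE identifiable: need >= 2 distinct doses left
            if keep.sum() >= 2 and len(np.unique(doses[keep])) >= 2:
                doses, n, k = doses[keep], n[keep], k[keep]
        elif config.engine == "minchi2":
            doses, n, k = doses[keep], n[keep], k[keep]
            if len(doses) < 2 or len(np.unique(doses)) < 2:
                raise ValueError(
                    "minchi2 engine needs >= 2 distinct doses with "
                    "intermediate (0 < p < 1) response"
                )

    log_doses = np.log10(doses)
    n_groups = len(doses)
    df = config.df if config.df is not None else max(n_groups - 2, 0)

    if config.engine == "minchi2":
        slope, intercept, cov, converged = _fit_minchi2(log_doses, n, k)
    else:
        slope, intercept, cov, converged = _fit_mle(log_doses, n, k)
        if _completely_separated(log_doses, n, k):
            # the likelihood has no finite maximum: the slope estimate is
            # an artifact of where the optimiser stopped
            converged = False

    loglik = _binomial_loglik(log_doses, n, k, slope, intercept)

    if slope == 0 or not np.isfinite(slope):
        converged = False
        log_ed50 = math.nan
        sem_log = math.nan
        ed50 = math.nan
        sem_ed50 = math.nan
    else:
        log_ed50 = -intercept / slope
        # delta method: grad of -b0/b1 wrt (slope b1, intercept b0)
        grad = np.array([intercept / slope**2, -1.0 / slope])
        var_log = float(grad @ cov @ grad)
        sem_log = math.sqrt(var_log) if var_log >= 0 else math.nan
        ed50 = 10.0**log_ed50
        sem_ed50 = sem_log * ed50 * LN10
    if not (np.isfinite(cov).all() and np.isfinite(sem_ed50)):
        converged = False

    return ProbitFit(
        drug_id=drug_id,
        slope=float(slope),
        intercept=float(intercept),
        ed50=float(ed50),
        sem_ed50=float(sem_ed50),
        log_ed50=float(log_ed50),
        sem_log_ed50=float(sem_log),
        param_covariance=cov,
        n_total=int(n.sum()),
        df=int(df),
        converged=bool(converged),
        loglik=loglik,
        engine=config.engine,
    )


def _completely_separated(log_doses: np.ndarray, n: np.ndarray, k: np.ndarray) -> bool:
    """True when every group responded at 0% or 100% and all 0% groups sit
    at lower doses than all 100% groups: the probit likelihood then
    increases without bound as the slope diverges."""
    frac = k / n
    if np.any((frac > 0) & (frac < 1)):
        return False
    order = np.argsort(log_doses)
    f = frac[order]
    return bool(np.all(np.diff(f) >= 0))


def _fit_mle(
    log_doses: np.ndarray, n: np.ndarray, k: np.ndarray
) -> tuple[float, float, np.ndarray, bool]:
    """ML probit regression via a binomial GLM; returns (slope, intercept,
    cov in (slope, intercept) order, converged)."""
    endog = np.column_stack([k, n - k])
    exog = sm.add_constant(log_doses)  # columns: const, log10 dose
    model = sm.GLM(endog, exog, family=sm.families.Binomial(sm.families.links.Probit()))
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200, tol=1e-10)
        except Exception:
            # complete separation or other IRLS failure
            return math.nan, math.nan, np.full((2, 2), np.nan), False
    converged = bool(getattr(res, "converged", True))
    intercept, slope = res.params
    cov_ci = np.asarray(res.cov_params())  # order (const, slope)
    cov = cov_ci[::-1, ::-1]  # reorder to (slope, intercept)
    # a numerically divergent fit shows up as an absurd slope
    if not np.isfinite([slope, intercept]).all() or abs(slope) > 1e3:
        converged = False
    return float(slope), float(intercept), cov, converged


def _fit_minchi2(
    log_doses: np.ndarray, n: np.ndarray, k: np.ndarray
) -> tuple[float, float, np.ndarray, bool]:
    """Berkson-style minimum chi-square: weighted least squares of the
    empirical probits on log10 dose, weights n * phi(y)^2 / (p (1-p))."""
    p = k / n
    y = stats.norm.ppf(p)
    w = n * stats.norm.pdf(y) ** 2 / (p * (1 - p))
    X = np.column_stack([np.ones_like(log_doses), log_doses])
    W = np.diag(w)
    XtWX = X.T @ W @ X
    try:
        cov_ci = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        return math.nan, math.nan, np.full((2, 2), np.nan), False
    beta = cov_ci @ (X.T @ W @ y)
    intercept, slope = beta
    cov = cov_ci[::-1, ::-1]
    return float(slope), float(intercept), cov, True


def predict_response(fit: ProbitFit, dose: float) -> float:
    """Probability of response at ``dose`` under a fitted probit line.

    Strictly increasing in dose whenever the slope is positive; equals 0.5
    exactly at the ED50.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    if not dose > 0:
        raise ValueError(f"dose must be positive, got {dose}")
    return float(stats.norm.cdf(fit.slope * (math.log10(dose) - fit.log_ed50)))


def test_parallelism(
    fit_a: ProbitFit, fit_b: ProbitFit, alpha: float = 0.05
) -> ParallelismResult:
    """Two-sided z-test of slope equality between two fitted probit lines.

    Parallelism of the log-probit lines is the precondition for reading a
    fixed-ratio isobologram as a single additivity line; non-parallel
    components restrict the analysis to the equi-effective (1:1...) ratio.

    The statistic is (slope_a - slope_b) / sqrt(se_a^2 + se_b^2) referred
    to the standard normal; ``parallel`` is True when p >= alpha.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("parallelism test requires converged fits")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    se = math.sqrt(fit_a.se_slope**2 + fit_b.se_slope**2)
    diff = fit_a.slope - fit_b.slope
    if se == 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ParallelismResult(
        statistic=float(z),
        df_description="standard normal (pooled-SE z-test)",
        p_value=p,
        parallel=p >= alpha,
        alpha=alpha,
        slope_a=fit_a.slope,
        slope_b=fit_b.slope,
    )
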