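"""Bioassay statistics: probit dose-response with natural-response correction,
Abbott adjustment, and the two-group endpoint tests.

The dose-response model is the toxicological standard

    P(dead | dose) = c + (1 - c) * Phi(a + b * log10(dose)),

where Phi is the standard normal CDF, b is the probit slope per tenfold
concentration, and c in [0, 1) is the natural (control) mortality rate —
the correction SAS PROC PROBIT applies with its OPTC option. The LC50 is
the concentration at which Abbott-adjusted mortality reaches 50%,
lc50 = 10^(-a/b). Parameters are estimated by binomial maximum likelihood;
the 95% interval for the LC50 is a delta-method interval on log10(lc50),
back-transformed.

Binary endpoints from single-concentration assays are compared with
Fisher's exact test; continuous endpoints (weights, development times) with
a pooled-variance t test, with Levene's test available for the homogeneity
check that precedes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError, ValidationError
from .seq_io import BioassayRow

#: Optional slot for an external normality test (e.g. Shapiro-Wilk), called
#: as hook(values) -> (statistic, pvalue). The pipeline never requires it.
normality_hook: Callable[[Sequence[float]], tuple[float, float]] | None = None

_PMIN = 1e-12


@dataclass(frozen=True)
class DoseResponseData:
    """Mortality counts along a dose series, plus an optional dose-0 control."""

    doses: tuple[float, ...]
    n_exposed: tuple[int, ...]
    n_dead: tuple[int, ...]
    control_n: int = 0
    control_dead: int = 0

    def __post_init__(self):
        if not (len(self.doses) == len(self.n_exposed) == len(self.n_dead)):
            raise ValidationError("dose series fields differ in length")
        if any(d <= 0 for d in self.doses):
            raise ValidationError("doses must be positive (controls go in control_n)")
        for n, r in zip(self.n_exposed, self.n_dead):
            if not 0 <= r <= n:
                raise ValidationError(f"n_dead={r} outside [0, {n}]")
        if not 0 <= self.control_dead <= self.control_n:
            raise ValidationError("invalid control counts")

    @classmethod
    def from_rows(cls, rows: Sequence[BioassayRow]) -> "DoseResponseData":
        pos = [r for r in rows if r.dose > 0 and r.treatment != "positive_control"]
        ctrl = [r for r in rows if r.dose == 0 and r.treatment == "control"]
        pos.sort(key=lambda r: r.dose)
        return cls(
            doses=tuple(r.dose for r in pos),
            n_exposed=tuple(r.n_exposed for r in pos),
            n_dead=tuple(r.n_dead for r in pos),
            control_n=sum(r.n_exposed for r in ctrl),
            control_dead=sum(r.n_dead for r in ctrl),
        )

    @property
    def control_mortality(self) -> float:
        return self.control_dead / self.control_n if self.control_n else 0.0


@dataclass(frozen=True)
class ProbitFit:
    """ML estimates for the natural-response probit model."""

    a: float
    b: float
    c: float
    lc50: float
    ci_low: float
    ci_high: float
    loglik: float
    converged: bool
    se_log10_lc50: float = float("nan")
    message: str = ""


def abbott_correct(p_obs: float, p_control: float) -> float:
    """Abbott's natural-mortality adjustment, floored at 0."""
    if not 0 <= p_control < 1:
        raise ValidationError("p_control must lie in [0, 1)")
    if not 0 <= p_obs <= 1:
        raise ValidationError("p_obs must lie in [0, 1]")
    return max(0.0, (p_obs - p_control) / (1.0 - p_control))


def _nll(theta: np.ndarray, x, n, r, cn, cr, estimate_c: bool, c_fixed: float) -> float:
    a, b = theta[0], theta[1]
    c = theta[2] if estimate_c else c_fixed
    p = c + (1.0 - c) * stats.norm.cdf(a + b * x)
    p = np.clip(p, _PMIN, 1.0 - _PMIN)
    ll = float(np.sum(r * np.log(p) + (n - r) * np.log1p(-p)))
    if cn:
        pc = min(max(c, _PMIN), 1.0 - _PMIN)
        ll += cr * np.log(pc) + (cn - cr) * np.log1p(-pc)
    return -ll


def _start_values(data: DoseResponseData, c0: float) -> tuple[float, float]:
    """Least squares on empirical probits of Abbott-corrected proportions."""
    x = np.log10(np.array(data.doses, dtype=float))
    n = np.array(data.n_exposed, dtype=float)
    r = np.array(data.n_dead, dtype=float)
    # shrink 0/1 proportions away from the boundary before the probit
    p = (r + 0.5) / (n + 1.0)
    p_adj = np.clip((p - c0) / (1.0 - c0), 1e-4, 1.0 - 1e-4)
    z = stats.norm.ppf(p_adj)
    A = np.vstack([np.ones_like(x), x]).T
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    a0, b0 = float(coef[0]), float(coef[1])
    if not np.isfinite(a0) or not np.isfinite(b0):
        a0, b0 = 0.0, 1.0
    return a0, b0


def _numeric_hessian(f, theta: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = theta.size
    H = np.zeros((k, k))
    steps = h * np.maximum(1.0, np.abs(theta))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def fit_probit(
    data: DoseResponseData,
    estimate_c: bool = True,
    c_fixed: float | None = None,
) -> ProbitFit:
    """Maximum-likelihood probit fit with natural-response correction.

    When ``estimate_c`` is true, c is a free parameter in [0, 0.99]
    initialized at the observed control mortality (0 without a control
    group); otherwise c is fixed at ``c_fixed`` (default: the observed
    control mortality, or 0). Degenerate series — all-dead or all-alive at
    every positive dose — are reported as non-converged with NaN estimates
    rather than fabricated numbers.
    """
    if len(set(data.doses)) < 3:
        raise ValidationError("probit fit requires >= 3 distinct positive doses")
    x = np.log10(np.array(data.doses, dtype=float))
    n = np.array(data.n_exposed, dtype=float)
    r = np.array(data.n_dead, dtype=float)

    c0 = data.control_mortality if c_fixed is None else c_fixed
    c0 = min(max(c0, 0.0), 0.99)

    if np.all(r == 0) or np.all(r == n):
        return ProbitFit(
            a=float("nan"), b=float("nan"), c=c0, lc50=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), loglik=float("nan"),
            converged=False,
            message="degenerate response: no information about the slope",
        )

    a0, b0 = _start_values(data, c0)
    if estimate_c:
        theta0 = np.array([a0, b0, c0])
        bounds = [(None, None), (None, None), (0.0, 0.99)]
    else:
        theta0 = np.array([a0, b0])
        bounds = [(None, None), (None, None)]

    args = (x, n, r, data.control_n, data.control_dead, estimate_c, c0)
    f = lambda th: _nll(np.asarray(th, dtype=float), *args)
    res = optimize.minimize(
        f, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    a_hat, b_hat = float(res.x[0]), float(res.x[1])
    c_hat = float(res.x[2]) if estimate_c else c0
    converged = bool(res.success) and np.isfinite(res.fun)
    loglik = -float(res.fun)

    if not converged or b_hat == 0:
        return ProbitFit(
            a=a_hat, b=b_hat, c=c_hat, lc50=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), loglik=loglik,
            converged=False, message=str(res.message),
        )

    g = -a_hat / b_hat  # log10(lc50)
    lc50 = 10.0 ** g

    # delta-method variance of log10(lc50); c rows dropped when the estimate
    # sits on its bound (the curvature there is one-sided)
    H = _numeric_hessian(f, res.x)
    free = list(range(len(res.x)))
    if estimate_c and (c_hat <= 1e-6 or c_hat >= 0.99 - 1e-6):
        free = [0, 1]
    Hf = H[np.ix_(free, free)]
    grad_g = {0: -1.0 / b_hat, 1: a_hat / b_hat**2, 2: 0.0}
    gvec = np.array([grad_g[i] for i in free])
    try:
        cov = np.linalg.pinv(Hf)
        var_g = float(gvec @ cov @ gvec)
    except np.linalg.LinAlgError:  # pragma: no cover
        var_g = float("nan")
    se_g = np.sqrt(var_g) if var_g >= 0 else float("nan")
    zcrit = stats.norm.ppf(0.975)
    ci_low = 10.0 ** (g - zcrit * se_g) if np.isfinite(se_g) else float("nan")
    ci_high = 10.0 ** (g + zcrit * se_g) if np.isfinite(se_g) else float("nan")

    return ProbitFit(
        a=a_hat, b=b_hat, c=c_hat, lc50=lc50,
        ci_low=ci_low, ci_high=ci_high, loglik=loglik,
        converged=True, se_log10_lc50=se_g, message=str(res.message),
    )


def lc_p(fit: ProbitFit, p: float) -> float:
    """Concentration at which Abbott-adjusted mortality reaches p."""
    if not fit.converged:
        raise ConvergenceError("lc_p requires a converged fit")
    if not 0 < p < 1:
        raise ValidationError("p must lie strictly in (0, 1)")
    return 10.0 ** ((stats.norm.ppf(p) - fit.a) / fit.b)


# --- two-group endpoint tests ---------------------------------------------


@dataclass(frozen=True)
class TwoGroupCounts:
    """Binary endpoint counts for two groups (e.g. control vs treatment)."""

    labels: tuple[str, str]
    n_total: tuple[int, int]
    n_event: tuple[int, int]

    def __post_init__(self):
        for n, e in zip(self.n_total, self.n_event):
            if not 0 <= e <= n:
                raise ValidationError(f"n_event={e} outside [0, {n}]")


def fisher_exact(table: TwoGroupCounts) -> float:
    """Two-sided Fisher's exact p-value.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one. A zero margin carries
    no information: p = 1 with a warning.
    """
    (n1, n2), (e1, e2) = table.n_total, table.n_event
    mat = [[e1, n1 - e1], [e2, n2 - e2]]
    if min(e1 + e2, (n1 - e1) + (n2 - e2), n1, n2) == 0:
        warnings.warn("empty margin in 2x2 table; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(mat, alternative="two-sided")[1])


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pooled-variance Student's t with n_x + n_y - 2 df; returns (t, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float("inf") if np.mean(x) > np.mean(y) else float("-inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def levene_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Classical Levene W on absolute deviations from group means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        return 0.0, 1.0
    w, p = stats.levene(x, y, center="mean")
    if not np.isfinite(w):
        return 0.0, 1.0
    return float(w), float(p)
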