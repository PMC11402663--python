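"""Time-to-onset (TTO) analysis with the Weibull shape-parameter test.

TTO is the interval in days between the start of therapy (START_DT) and the
occurrence of the adverse event (EVENT_DT).  Pairs where the event precedes
the start, where either date is missing or only partially precise (month or
year resolution), or where an 8-digit date is not a real calendar date, are
excluded — the exclusions are values carried in the sample's accounting, not
exceptions.

The retained onsets are summarised by median and quartiles and fitted with a
two-parameter Weibull distribution by maximum likelihood.  The shape
parameter beta classifies the hazard over time: beta with 95% CI entirely
below 1 means a decreasing hazard ("early failure" — most onsets shortly
after starting the drug), a CI containing 1 is consistent with a constant
hazard ("random failure"), and a CI entirely above 1 an increasing hazard
("wear-out failure").
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import EventDataset, RawDate, normalize_drug_name, parse_raw_date

EXCLUSION_REASONS = (
    "event_before_start",
    "missing_date",
    "partial_precision",
    "invalid_date",
)


def compute_tto(event_dt: RawDate, start_dt: RawDate) -> tuple[float | None, str | None]:
    """Days from therapy start to event, or (None, exclusion reason).

    Both dates must be valid day-precision dates.  A negative interval is
    excluded as ``event_before_start``; identical dates yield 0.5 days (the
    same-day adjustment, so that onsets stay positive for the log-scale
    Weibull likelihood).
    """
    for d in (event_dt, start_dt):
        if d.precision == "missing":
            return None, "missing_date"
        if d.precision == "invalid":
            return None, "invalid_date"
        if d.precision in ("month", "year"):
            return None, "partial_precision"
    days = (event_dt.date - start_dt.date).days
    if days < 0:
        return None, "event_before_start"
    if days == 0:
        return 0.5, None
    return float(days), None


@dataclass
class TTOSample:
    """Retained onset days for one drug plus exclusion accounting.

    ``values`` carries the fitting values (same-day onsets as 0.5);
    ``descriptive_values`` maps those back to 0 for medians/quartiles.
    Invariant: len(values) + sum of exclusions == candidate pairs.
    """

    drug: str
    values: np.ndarray
    n_excluded_by_reason: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def n_candidates(self) -> int:
        return self.n + sum(self.n_excluded_by_reason.values())

    @property
    def descriptive_values(self) -> np.ndarray:
        v = np.asarray(self.values, dtype=float)
        return np.where(v == 0.5, 0.0, v)


def tto_summary(sample: TTOSample) -> tuple[float, float, float]:
    """(median, q1, q3) in days, linear interpolation between order statistics."""
    if sample.n < 1:
        raise ValueError(f"{sample.drug}: empty TTO sample")
    v = sample.descriptive_values
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# Weibull maximum likelihood
# ---------------------------------------------------------------------------

class WeibullFitError(RuntimeError):
    """The Weibull likelihood could not be maximised; message carries diagnostics."""


@dataclass(frozen=True)
class WeibullFit:
    """MLE of the two-parameter Weibull: scale alpha (days), shape beta."""

    alpha: float
    alpha_lo: float
    alpha_hi: float
    beta: float
    beta_lo: float
    beta_hi: float
    n: int
    loglik: float
    n_iter: int
    ci_method: str = "wald"


def _weibull_grad_hess(theta: np.ndarray, logt: np.ndarray):
    """Log-likelihood, gradient and Hessian in theta = (log alpha, log beta).

    With x_i = ln t_i - ln alpha and z_i = exp(beta * x_i) = (t_i/alpha)^beta:
      ll       = sum[ ln beta + (beta-1) ln t_i - beta ln alpha - z_i ]
      d ll/d t1 = beta * sum(z_i - 1)
      d ll/d t2 = n + beta * sum(x_i (1 - z_i))
    and the analytic second derivatives below.
    """
    n = logt.size
    t1, t2 = theta
    beta = math.exp(t2)
    x = logt - t1
    bx = np.clip(beta * x, -700.0, 700.0)
    z = np.exp(bx)
    ll = n * t2 + (beta - 1.0) * float(logt.sum()) - beta * t1 * n - float(z.sum())
    g1 = beta * float((z - 1.0).sum())
    g2 = n + beta * float((x * (1.0 - z)).sum())
    h11 = -beta * beta * float(z.sum())
    h12 = beta * (float((z - 1.0).sum()) + beta * float((x * z).sum()))
    h22 = beta * (float(x.sum()) - float((x * z).sum()) - beta * float((x * x * z).sum()))
    return ll, np.array([g1, g2]), np.array([[h11, h12], [h12, h22]])


def weibull_fit(
    values: np.ndarray | TTOSample,
    conf: float = 0.95,
    ci_method: str = "wald",
    n_boot: int = 1000,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> WeibullFit:
    """Fit Weibull(alpha, beta) by maximum likelihood (no censoring).

    Newton iterations on (log alpha, log beta) with analytic gradient and
    Hessian, step-halving damping, convergence when the step's max-norm falls
    below ``tol``.  95% CIs are Wald intervals on the log parameters from the
    observed information matrix, back-transformed; ``ci_method="bootstrap"``
    replaces them with seeded percentile-bootstrap intervals (for small n).

    Requires n >= 3 strictly positive values; identical values (shape
    unbounded) or non-convergence raise :class:`WeibullFitError`.
    """
    if isinstance(values, TTOSample):
        values = values.values
    t = np.asarray(values, dtype=float)
    if t.size < 3:
        raise WeibullFitError(f"need n >= 3 onsets, got {t.size}")
    if np.any(t <= 0):
        raise WeibullFitError("onset values must be strictly positive")
    logt = np.log(t)
    sd = float(logt.std(ddof=1))
    if sd == 0.0:
        raise WeibullFitError("all onset values identical; shape parameter unbounded")

    # method-of-moments start: Var(ln T) = pi^2 / (6 beta^2); E ln T = ln alpha - gamma/beta
    beta0 = (math.pi / math.sqrt(6.0)) / sd
    theta = np.array([float(logt.mean()) + 0.5772156649015329 / beta0, math.log(beta0)])

    ll, g, h = _weibull_grad_hess(theta, logt)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(h, -g)
        except np.linalg.LinAlgError:
            raise WeibullFitError(f"singular Hessian at iteration {n_iter}")
        # damped Newton: halve until the log-likelihood does not decrease
        lam, ok = 1.0, False
        for _ in range(60):
            cand = theta + lam * step
            ll_new, g_new, h_new = _weibull_grad_hess(cand, logt)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                ok = True
                break
            lam *= 0.5
        if not ok:
            raise WeibullFitError(f"line search failed at iteration {n_iter} (ll={ll:.6g})")
        theta, ll, g, h = cand, ll_new, g_new, h_new
        if float(np.max(np.abs(lam * step))) < tol:
            break
    else:
        raise WeibullFitError(
            f"no convergence in {max_iter} iterations (|grad|={np.abs(g).max():.3g})"
        )

    alpha, beta = math.exp(theta[0]), math.exp(theta[1])
    z = _norm_ppf(0.5 + conf / 2.0)
    if ci_method == "wald":
        cov = np.linalg.inv(-h)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        a_lo, a_hi = math.exp(theta[0] - z * se[0]), math.exp(theta[0] + z * se[0])
        b_lo, b_hi = math.exp(theta[1] - z * se[1]), math.exp(theta[1] + z * se[1])
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        alphas, betas = [], []
        for _ in range(n_boot):
            res = t[rng.integers(0, t.size, size=t.size)]
            try:
                fit = weibull_fit(res, conf=conf, ci_method="wald", tol=1e-8)
            except WeibullFitError:
                continue
            alphas.append(fit.alpha)
            betas.append(fit.beta)
        if len(alphas) < max(10, n_boot // 2):
            raise WeibullFitError("bootstrap failed on too many resamples")
        lo_p, hi_p = 100 * (0.5 - conf / 2.0), 100 * (0.5 + conf / 2.0)
        a_lo, a_hi = np.percentile(alphas, [lo_p, hi_p])
        b_lo, b_hi = np.percentile(betas, [lo_p, hi_p])
    else:
        raise ValueError("ci_method must be 'wald' or 'bootstrap'")

    return WeibullFit(
        alpha=alpha, alpha_lo=float(a_lo), alpha_hi=float(a_hi),
        beta=beta, beta_lo=float(b_lo), beta_hi=float(b_hi),
        n=int(t.size), loglik=float(ll), n_iter=n_iter, ci_method=ci_method,
    )


def _norm_ppf(p: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(p))


def classify_failure(beta: float, beta_lo: float, beta_hi: float) -> str:
    """Hazard-shape classification from the shape parameter's 95% CI.

    early: CI entirely below 1 (decreasing hazard); wear-out: entirely above
    1 (increasing hazard); random: CI contains 1; indeterminate: any bound
    non-finite.
    """
    if not (np.isfinite(beta) and np.isfinite(beta_lo) and np.isfinite(beta_hi)):
        return "indeterminate"
    if beta_hi < 1.0:
        return "early"
    if beta_lo > 1.0:
        return "wear-out"
    return "random"


# ---------------------------------------------------------------------------
# dataset plumbing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTOResult:
    """Summary and Weibull fit of the onset distribution for one drug."""

    drug: str
    n: int
    median: float
    q1: float
    q3: float
    fit: WeibullFit | None
    failure_type: str
    n_excluded_by_reason: dict


def collect_tto_sample(dataset: EventDataset, drug: str, pt: str) -> TTOSample:
    """Extract onset days for every case naming `drug` as primary suspect
    with the target event.

    The event date is the case's EVENT_DT; the start date is the earliest
    day-precision START_DT among therapy rows matching any of the case's
    primary-suspect sequences for the drug.  If therapy rows exist for the
    drug but none has day precision, the pair is excluded as
    ``partial_precision``; with no therapy row at all, ``missing_date``.
    """
    name = normalize_drug_name(drug)
    caseids = sorted(dataset.drug_caseids(name) & dataset.event_caseids(pt))
    mentions = dataset.drugs[dataset.drugs["drugname"] == name]
    seqs_by_case: dict[str, set[str]] = {}
    for cid, seq in zip(mentions["caseid"], mentions["drug_seq"]):
        seqs_by_case.setdefault(cid, set()).add(seq)
    ther = dataset.therapy
    values: list[float] = []
    excluded = {r: 0 for r in EXCLUSION_REASONS}
    for cid in caseids:
        event_dt = parse_raw_date(dataset.cases.at[cid, "event_dt"])
        rows = ther[(ther["caseid"] == cid) &
                    (ther["dsg_drug_seq"].isin(seqs_by_case.get(cid, set())))]
        starts = [parse_raw_date(s) for s in rows["start_dt"]]
        day_starts = sorted((s for s in starts if s.is_day),
                            key=lambda s: s.date)
        if day_starts:
            start_dt = day_starts[0]
        elif any(s.precision in ("month", "year") for s in starts):
            excluded["partial_precision"] += 1
            continue
        elif any(s.precision == "invalid" for s in starts):
            excluded["invalid_date"] += 1
            continue
        else:
            excluded["missing_date"] += 1
            continue
        days, reason = compute_tto(event_dt, start_dt)
        if reason is not None:
            excluded[reason] += 1
        else:
            values.append(days)
    return TTOSample(drug=name, values=np.asarray(values, dtype=float),
                     n_excluded_by_reason=excluded)


def tto_result(
    sample: TTOSample, min_n_fit: int = 3, ci_method: str = "wald", seed: int = 0
) -> TTOResult:
    """Median/IQR plus Weibull fit and failure classification for one sample.

    The fit is skipped (failure type ``indeterminate``) when fewer than
    ``min_n_fit`` onsets remain or the likelihood is degenerate.
    """
    median, q1, q3 = tto_summary(sample)
    fit: WeibullFit | None = None
    failure = "indeterminate"
    if sample.n >= min_n_fit:
        try:
            fit = weibull_fit(sample.values, ci_method=ci_method, seed=seed)
            failure = classify_failure(fit.beta, fit.beta_lo, fit.beta_hi)
        except WeibullFitError:
            fit = None
    return TTOResult(
        drug=sample.drug, n=sample.n, median=median, q1=q1, q3=q3,
        fit=fit, failure_type=failure,
        n_excluded_by_reason=dict(sample.n_excluded_by_reason),
    )
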