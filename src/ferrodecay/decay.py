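"""Broken-line decay modelling, half-life estimation and slope comparisons.

Transcript trajectories after transcription inhibition (or iron resupply)
decline on the natural-log scale and then plateau.  A segmented ("broken
line") regression captures this:

    y = alpha + B * min(t - t0, 0) + Bp * max(t - t0, 0) + e,  e ~ N(0, s2)

with changepoint t0, pre-changepoint slope B (per minute) and post-
changepoint slope Bp.  The decay rate is k = -B and the half-life
t1/2 = ln(2) / k.  The changepoint is profiled out by minimizing the
residual sum of squares over candidate t0 values (observed interior times
refined by golden-section search inside each inter-observation interval).

Decay rates between two treatments are compared by a likelihood-ratio test
on a joint model with per-treatment intercepts and slopes at fixed
changepoints, tying the pre-changepoint slopes under the null.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountMatrix, DataError

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)
_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

def log_transform(matrix: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Natural-log transform of a fully normalized matrix.

    Returns a probes x samples DataFrame of ln(count + pseudocount); the
    pseudocount is recorded in ``DataFrame.attrs['pseudocount']``.
    """
    if matrix.stage != "fully_normalized":
        raise DataError(
            f"log_transform expects a fully_normalized matrix, got "
            f"{matrix.stage!r}"
        )
    if pseudocount < 0:
        raise DataError("pseudocount must be >= 0")
    arr = matrix.values.to_numpy()
    if (arr < 0).any():
        raise DataError("negative counts cannot be log-transformed")
    out = np.log(matrix.values + pseudocount)
    out.attrs["pseudocount"] = pseudocount
    return out


# ---------------------------------------------------------------------------
# single-treatment broken-line fit
# ---------------------------------------------------------------------------

@dataclass
class BrokenLineFit:
    """Segmented-regression fit for one gene in one treatment.

    ``alpha`` is the fitted log count at the changepoint; ``B`` and ``Bp``
    are the slopes (per minute, natural-log scale) before and after ``t0``.
    """

    alpha: float
    B: float
    Bp: float
    t0: float
    sigma2: float
    rss: float
    loglik: float
    n: int
    times: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)


def _design(times: np.ndarray, t0: float) -> np.ndarray:
    return np.column_stack([
        np.ones_like(times),
        np.minimum(times - t0, 0.0),
        np.maximum(times - t0, 0.0),
    ])


def _ols_rss(times: np.ndarray, y: np.ndarray, t0: float):
    """Least-squares fit of the broken-line basis at fixed t0.

    Returns (coef, rss, rank)."""
    X = _design(times, t0)
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    rss = float(np.sum((y - fitted) ** 2))
    return coef, rss, rank


def _golden_min(f, lo: float, hi: float, tol: float = 1e-6, max_iter: int = 100):
    """Golden-section minimization of f on [lo, hi]; returns (x, f(x))."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    x = c if fc < fd else d
    return x, min(fc, fd)


def gaussian_loglik(rss: float, n: int) -> float:
    """Profile Gaussian log-likelihood at the MLE sigma2 = rss/n."""
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def fit_broken_line(
    times, y, t0_candidates="auto",
) -> BrokenLineFit:
    """Fit the broken-line model, profiling the changepoint over candidates.

    With ``t0_candidates='auto'`` the candidates are all distinct observed
    times strictly between the first and last, refined by golden-section
    search inside every interval between consecutive distinct times.  Ties
    in RSS break toward the earliest changepoint.  Requires >= 4
    observations at >= 3 distinct times.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if times.shape != y.shape or times.ndim != 1:
        raise DataError("times and y must be 1-D arrays of equal length")
    n = len(y)
    if n < 4:
        raise DataError(f"broken-line fit needs >= 4 observations, got {n}")
    distinct = np.unique(times)
    if len(distinct) < 3:
        raise DataError(
            f"broken-line fit needs >= 3 distinct times, got {len(distinct)}"
        )

    best_t0, best_rss, best_coef = None, np.inf, None

    def consider(t0: float) -> float:
        nonlocal best_t0, best_rss, best_coef
        coef, rss, rank = _ols_rss(times, y, t0)
        if rank < 3:
            return np.inf
        # strict improvement, or tie resolved toward the earliest t0
        if rss < best_rss - 1e-12 or (
            abs(rss - best_rss) <= 1e-12 and (best_t0 is None or t0 < best_t0)
        ):
            best_t0, best_rss, best_coef = t0, rss, coef
        return rss

    if isinstance(t0_candidates, str) and t0_candidates == "auto":
        for t0 in distinct[1:-1]:
            consider(float(t0))
        # continuous refinement inside every inter-observation interval
        for lo, hi in zip(distinct[:-1], distinct[1:]):
            span = hi - lo
            if span <= 1e-9:
                continue
            eps = min(1e-6, span * 1e-3)
            x, _ = _golden_min(
                lambda t0: _ols_rss(times, y, t0)[1], lo + eps, hi - eps
            )
            consider(float(x))
    else:
        for t0 in np.asarray(t0_candidates, dtype=float):
            consider(float(t0))

    if best_coef is None:
        raise DataError("all changepoint candidates give a collinear design")

    alpha, B, Bp = (float(c) for c in best_coef)
    sigma2 = best_rss / n
    return BrokenLineFit(
        alpha=alpha, B=B, Bp=Bp, t0=float(best_t0), sigma2=sigma2,
        rss=best_rss, loglik=gaussian_loglik(best_rss, n), n=n,
        times=times, y=y,
    )


# ---------------------------------------------------------------------------
# joint multi-treatment model
# ---------------------------------------------------------------------------

@dataclass
class TreatmentDecayModel:
    """Joint broken-line model with per-treatment coefficients.

    Basis per treatment (changepoints fixed): indicator, indicator *
    min(t, t0_tr) and indicator * max(t - t0_tr, 0); beta1 is the pre-
    changepoint slope (so beta0 is the intercept at time 0).  When two
    treatments are tied, they share a single beta1 coefficient.
    """

    treatments: list[str]
    beta0: dict[str, float]
    beta1: dict[str, float]
    beta2: dict[str, float]
    t0: dict[str, float]
    sigma2: float
    rss: float
    loglik: float
    n_total: int
    tied: tuple[str, str] | None = None


def fit_multi_treatment(
    y, times, treatments, t0_fixed: dict[str, float],
    tie_beta1: tuple[str, str] | None = None,
) -> TreatmentDecayModel:
    """Single OLS across treatments with fixed per-treatment changepoints.

    ``tie_beta1=(A, B)`` constrains treatments A and B to share one
    pre-changepoint slope (the null model of the decay-rate LRT).
    """
    y = np.asarray(y, dtype=float)
    times = np.asarray(times, dtype=float)
    treatments = np.asarray(treatments, dtype=object)
    if not (len(y) == len(times) == len(treatments)):
        raise DataError("y, times and treatments must have equal length")
    levels = sorted(set(treatments))
    for tr in levels:
        if tr not in t0_fixed:
            raise DataError(f"no fixed changepoint supplied for {tr!r}")
        if int(np.sum(treatments == tr)) < 4:
            raise DataError(f"treatment {tr!r} has fewer than 4 observations")
    if tie_beta1 is not None:
        a, b = tie_beta1
        if a not in levels or b not in levels:
            raise DataError(f"tie_beta1 pair {tie_beta1} not present in data")

    cols, names = [], []
    for tr in levels:
        ind = (treatments == tr).astype(float)
        t0 = t0_fixed[tr]
        cols.append(ind)
        names.append(("beta0", tr))
        cols.append(ind * np.maximum(times - t0, 0.0))
        names.append(("beta2", tr))
    if tie_beta1 is None:
        for tr in levels:
            ind = (treatments == tr).astype(float)
            cols.append(ind * np.minimum(times, t0_fixed[tr]))
            names.append(("beta1", tr))
    else:
        a, b = tie_beta1
        shared = np.zeros_like(times)
        for tr in (a, b):
            ind = (treatments == tr).astype(float)
            shared = shared + ind * np.minimum(times, t0_fixed[tr])
        cols.append(shared)
        names.append(("beta1", f"{a}+{b}"))
        for tr in levels:
            if tr in (a, b):
                continue
            ind = (treatments == tr).astype(float)
            cols.append(ind * np.minimum(times, t0_fixed[tr]))
            names.append(("beta1", tr))

    X = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise DataError(
            f"rank-deficient design for treatments {levels}; check that each "
            "treatment spans its changepoint"
        )
    rss = float(np.sum((y - X @ coef) ** 2))
    n = len(y)

    beta0, beta1, beta2 = {}, {}, {}
    for (kind, key), c in zip(names, coef):
        if kind == "beta0":
            beta0[key] = float(c)
        elif kind == "beta2":
            beta2[key] = float(c)
        elif "+" in key:
            for tr in key.split("+"):
                beta1[tr] = float(c)
        else:
            beta1[key] = float(c)

    return TreatmentDecayModel(
        treatments=levels, beta0=beta0, beta1=beta1, beta2=beta2,
        t0={tr: float(t0_fixed[tr]) for tr in levels},
        sigma2=rss / n, rss=rss, loglik=gaussian_loglik(rss, n),
        n_total=n, tied=tie_beta1,
    )


@dataclass
class LrtResult:
    """Likelihood-ratio test of equal pre-changepoint decay rates."""

    statistic: float
    df: int
    p_value: float
    null_hypothesis: str
    method: str = "chi2"


def lrt_equal_decay(
    model_free: TreatmentDecayModel,
    model_tied: TreatmentDecayModel,
    method: str = "chi2",
) -> LrtResult:
    """Test H0: the tied treatments share one decay rate.

    The Gaussian profile-likelihood statistic is n * ln(RSS_tied /
    RSS_free), referred to chi-square(1).  ``method='f'`` uses the exact
    finite-sample F(1, n - p) reference instead.
    """
    if model_tied.tied is None:
        raise DataError("model_tied must carry a beta1 equality constraint")
    n = model_free.n_total
    if n != model_tied.n_total:
        raise DataError("free and tied models must be fit on the same data")
    if model_tied.rss < model_free.rss * (1.0 - 1e-9):
        raise DataError(
            "RSS of the constrained model is below the free model: the "
            "models are not nested on the same data"
        )
    rss0 = max(model_tied.rss, model_free.rss)
    a, b = model_tied.tied
    null = f"beta1 equal between treatments {a} and {b}"
    if method == "chi2":
        stat = n * math.log(rss0 / model_free.rss) if model_free.rss > 0 else (
            0.0 if rss0 == model_free.rss else math.inf
        )
        p = float(stats.chi2.sf(stat, df=1))
        return LrtResult(statistic=float(stat), df=1, p_value=p,
                         null_hypothesis=null, method="chi2")
    if method == "f":
        p_free = 3 * len(model_free.treatments)
        dfe = n - p_free
        if model_free.rss <= 0:
            f_stat = math.inf if rss0 > model_free.rss else 0.0
        else:
            f_stat = (rss0 - model_free.rss) / (model_free.rss / dfe)
        p = float(stats.f.sf(f_stat, 1, dfe))
        return LrtResult(statistic=float(f_stat), df=1, p_value=p,
                         null_hypothesis=null, method="f")
    raise DataError(f"unknown LRT method {method!r}")


# ---------------------------------------------------------------------------
# half-lives
# ---------------------------------------------------------------------------

@dataclass
class DecayEstimate:
    """Per-gene decay summary for one treatment."""

    gene: str
    treatment: str
    k: float
    half_life_min: float | None
    t0_min: float
    reliable: bool
    slope_change_p: float | None = None


def half_life(beta1: float) -> tuple[float, float | None]:
    """Decay rate and half-life from the pre-changepoint slope.

    k = -beta1 (per minute, natural-log scale); t1/2 = ln(2)/k for k > 0,
    undefined (None) otherwise.
    """
    k = -float(beta1)
    return k, (LN2 / k if k > 0 else None)


def slope_change_test(fit: BrokenLineFit) -> float:
    """Two-sided t-test of equal slopes before and after the changepoint.

    The changepoint is treated as fixed at its estimate; the contrast
    Bp - B is tested with n - 4 residual degrees of freedom (one spent on
    the profiled changepoint).
    """
    if fit.n <= 4:
        raise DataError("slope-change test needs n > 4 observations")
    if fit.times is None or fit.y is None:
        raise DataError("fit does not carry its data")
    X = _design(fit.times, fit.t0)
    xtx_inv = np.linalg.pinv(X.T @ X)
    c = np.array([0.0, -1.0, 1.0])
    dof = fit.n - 4
    s2 = fit.rss / dof
    var = s2 * float(c @ xtx_inv @ c)
    diff = fit.Bp - fit.B
    if var <= 0:
        return 0.0 if diff != 0 else 1.0
    t = diff / math.sqrt(var)
    return float(2.0 * stats.t.sf(abs(t), dof))


def estimate_decay(
    gene: str, treatment: str, fit: BrokenLineFit,
    with_slope_test: bool = True,
) -> DecayEstimate:
    """Build the per-gene decay summary, flagging unreliable estimates.

    An estimate is unreliable when the pre-changepoint slope is
    non-negative or the implied half-life exceeds the observed time span.
    """
    k, hl = half_life(fit.B)
    span = float(fit.times.max() - fit.times.min())
    reliable = hl is not None and hl <= span
    p = None
    if with_slope_test and fit.n > 4:
        p = slope_change_test(fit)
    return DecayEstimate(
        gene=gene, treatment=treatment, k=k, half_life_min=hl,
        t0_min=fit.t0, reliable=reliable, slope_change_p=p,
    )


def summarize_half_lives(
    estimates: list[DecayEstimate],
    exclude: set[str] | str = "auto",
) -> tuple[pd.DataFrame, float]:
    """Per-gene half-life table and the average over included genes.

    ``exclude='auto'`` removes only unreliable estimates; a set of gene
    names removes those genes in addition.  The returned table marks
    excluded genes with an asterisk column.
    """
    if not estimates:
        raise DataError("no decay estimates to summarize")
    explicit = set() if exclude == "auto" else set(exclude)
    rows, included = [], []
    for e in estimates:
        excluded = (not e.reliable) or (e.gene in explicit)
        rows.append({
            "gene": e.gene,
            "treatment": e.treatment,
            "changepoint_min": e.t0_min,
            "k_per_min": e.k,
            "half_life_min": e.half_life_min,
            "reliable": e.reliable,
            "slope_change_p": e.slope_change_p,
            "excluded_from_average": excluded,
        })
        if not excluded and e.half_life_min is not None:
            included.append(e.half_life_min)
    if not included:
        raise DataError("exclusions leave no genes to average")
    table = pd.DataFrame(rows)
    return table, float(np.mean(included))


# ---------------------------------------------------------------------------
# matrix-level drivers
# ---------------------------------------------------------------------------

def fit_gene_treatment(
    log_counts: pd.DataFrame, matrix: CountMatrix, gene_probe: str,
    treatment: str, experiment: str | None = "ST",
    t0_candidates="auto",
) -> BrokenLineFit:
    """Broken-line fit for one probe in one treatment's time course."""
    samples = [
        s for s in matrix.biological_samples()
        if s.treatment == treatment
        and (experiment is None or s.experiment == experiment)
    ]
    if not samples:
        raise DataError(
            f"no samples for treatment {treatment!r} (experiment {experiment!r})"
        )
    times = np.array([s.time_min for s in samples])
    y = log_counts.loc[gene_probe, [s.sample_id for s in samples]].to_numpy()
    return fit_broken_line(times, y, t0_candidates=t0_candidates)


def compare_decay_rates(
    log_counts: pd.DataFrame, matrix: CountMatrix, gene_probe: str,
    treatment_a: str, treatment_b: str, experiment: str | None = "ST",
    method: str = "chi2",
) -> tuple[LrtResult, TreatmentDecayModel, TreatmentDecayModel]:
    """Per-gene decay-rate comparison between two treatments.

    Changepoints are first estimated per treatment by the single-treatment
    broken-line fit and then held fixed in the joint model; the tied and
    free joint fits feed the likelihood-ratio test.
    """
    t0_fixed, times_all, y_all, tr_all = {}, [], [], []
    for tr in (treatment_a, treatment_b):
        fit = fit_gene_treatment(log_counts, matrix, gene_probe, tr, experiment)
        t0_fixed[tr] = fit.t0
        times_all.append(fit.times)
        y_all.append(fit.y)
        tr_all.extend([tr] * fit.n)
    times = np.concatenate(times_all)
    y = np.concatenate(y_all)
    free = fit_multi_treatment(y, times, tr_all, t0_fixed)
    tied = fit_multi_treatment(
        y, times, tr_all, t0_fixed, tie_beta1=(treatment_a, treatment_b)
    )
    return lrt_equal_decay(free, tied, method=method), free, tied
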