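"""Single-hit Poisson limiting-dilution analysis.

In a limiting-dilution transplant assay, graded doses of cells are
injected and each recipient is scored as responding (tumour take) or not.
Under the single-hit Poisson model a dose of ``d`` cells contains a
Poisson number of active (tumour-initiating) cells with mean ``f·d``, so

    P(response | dose d) = 1 − exp(−f·d),

where ``f`` is the active-cell frequency, conventionally reported as
"1 in N" with N = 1/f. The binomial log-likelihood is maximized in
``log f`` (equivalently a complementary log-log GLM with offset
``log d``); the likelihood is unimodal in ``log f``, so a bracketed 1-D
search is robust to link-function edge cases. 95% confidence limits come
from the profile likelihood, with a Wald interval as fallback.

Assays where no animal, or every animal, responded carry no interior
maximum; these boundary cases are flagged and given one-sided 95% bounds
from the likelihood root instead of being hidden.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import BoundaryEstimateError

__all__ = [
    "DilutionExperiment",
    "FrequencyEstimate",
    "fit_single_hit",
    "compare_frequencies",
    "simulate_dilution",
    "read_dilution_table",
]

_CHI2_95_HALF = stats.chi2.ppf(0.95, 1) / 2.0  # 1.9207... profile-CI drop
_ONE_SIDED_DROP = -np.log(0.05)  # 2.9957... one-sided 95% likelihood root


@dataclass(frozen=True)
class DilutionExperiment:
    """Dose–response table: cells per transplant, animals tested, responders."""

    dose: np.ndarray
    tested: np.ndarray
    responded: np.ndarray
    group_label: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.dose, dtype=float)
        n = np.asarray(self.tested, dtype=int)
        x = np.asarray(self.responded, dtype=int)
        if d.size == 0 or d.shape != n.shape or d.shape != x.shape:
            raise ValueError("dose, tested, responded must be equal-length, non-empty")
        if np.any(d <= 0):
            raise ValueError("doses must be positive")
        if np.any(n <= 0):
            raise ValueError("tested must be positive")
        if np.any(x < 0) or np.any(x > n):
            raise ValueError("responded must satisfy 0 <= responded <= tested")
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "tested", n)
        object.__setattr__(self, "responded", x)


@dataclass(frozen=True)
class FrequencyEstimate:
    frequency: float
    ci95_low: float
    ci95_high: float
    log_likelihood: float
    boundary_flag: str = "none"  # none | all_negative | all_positive

    @property
    def one_in(self) -> float:
        """Display value: active-cell frequency as '1 in N' (rounded)."""
        if self.frequency <= 0:
            return float("inf")
        return float(round(1.0 / self.frequency))


def _loglik(f: float, exp: DilutionExperiment) -> float:
    """Binomial log-likelihood of frequency f (dropping binomial constants)."""
    fd = f * exp.dose
    # log(1 - exp(-fd)) computed stably; -expm1(-fd) = 1 - exp(-fd)
    with np.errstate(divide="ignore"):
        logp = np.log(-np.expm1(-fd))
    ll = 0.0
    pos = exp.responded > 0
    ll += float(np.sum(exp.responded[pos] * logp[pos]))
    ll += float(np.sum(-(exp.tested - exp.responded) * fd))
    return ll


def fit_single_hit(exp: DilutionExperiment) -> FrequencyEstimate:
    """Maximum-likelihood active-cell frequency with 95% profile CI.

    For a single dose the estimate has the closed form
    ``f = −ln(1 − x/n)/d``; the numeric fit agrees with it to high
    precision and generalizes to multiple doses.
    """
    x, n, d = exp.responded, exp.tested, exp.dose
    if np.all(x == 0):
        # likelihood maximized as f -> 0; one-sided upper bound solves
        # sum(n_d * f * d) = -ln(0.05)
        upper = _ONE_SIDED_DROP / float(np.sum(n * d))
        return FrequencyEstimate(0.0, 0.0, upper, 0.0, "all_negative")
    if np.all(x == n):
        # likelihood sup (0) approached as f -> inf; one-sided lower bound
        sup = 0.0
        g = lambda u: _loglik(np.exp(u), exp) - (sup - _ONE_SIDED_DROP)
        # start deep in saturation (g > 0 there) and walk down to the root
        lo = _expand_root(g, np.log(50.0 / d.min()), direction=-1)
        return FrequencyEstimate(float("inf"), np.exp(lo), float("inf"),
                                 sup, "all_positive")

    # crude starting value from the pooled response fraction
    p_bar = min(max(float(x.sum()) / float(n.sum()), 1e-6), 1 - 1e-6)
    f0 = -np.log1p(-p_bar) / float(np.average(d, weights=n))
    u0 = np.log(f0)
    res = optimize.minimize_scalar(
        lambda u: -_loglik(np.exp(u), exp),
        bounds=(u0 - 25.0, u0 + 25.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    u_hat = float(res.x)
    f_hat = float(np.exp(u_hat))
    ll_hat = _loglik(f_hat, exp)

    g = lambda u: _loglik(np.exp(u), exp) - (ll_hat - _CHI2_95_HALF)
    try:
        lo = _expand_root(g, u_hat, direction=-1)
        hi = _expand_root(g, u_hat, direction=+1)
        ci = (float(np.exp(lo)), float(np.exp(hi)))
    except (RuntimeError, ValueError):
        # Wald fallback on log f via numerical curvature
        h = 1e-4
        d2 = (_loglik(np.exp(u_hat + h), exp) - 2 * ll_hat + _loglik(np.exp(u_hat - h), exp)) / h**2
        se = np.sqrt(-1.0 / d2) if d2 < 0 else np.inf
        ci = (float(np.exp(u_hat - 1.959964 * se)), float(np.exp(u_hat + 1.959964 * se)))
    return FrequencyEstimate(f_hat, ci[0], ci[1], ll_hat, "none")


def _expand_root(g, u_start: float, direction: int, step: float = 0.5, max_span: float = 60.0):
    """Bracket and solve g(u)=0 moving from u_start in one direction."""
    u0 = u_start
    span = step
    while span <= max_span:
        u1 = u_start + direction * span
        if g(u1) < 0:
            lo, hi = (u1, u0) if direction < 0 else (u0, u1)
            return optimize.brentq(g, lo, hi, xtol=1e-10)
        u0 = u1
        span += step
    raise RuntimeError("failed to bracket likelihood root")


def compare_frequencies(a: DilutionExperiment, b: DilutionExperiment):
    """Likelihood-ratio test of a shared frequency versus group-specific ones.

    Returns ``(chi2_statistic, p)`` on 1 degree of freedom. Both groups at
    a boundary (no information about a ratio) is an error.
    """
    fa, fb = fit_single_hit(a), fit_single_hit(b)
    if fa.boundary_flag != "none" and fb.boundary_flag != "none":
        raise BoundaryEstimateError(
            "both groups are boundary-degenerate (all-negative/all-positive); "
            "the frequency ratio is not identified — collect interior doses"
        )
    pooled = DilutionExperiment(
        np.concatenate([a.dose, b.dose]),
        np.concatenate([a.tested, b.tested]),
        np.concatenate([a.responded, b.responded]),
        group_label="pooled",
    )
    fp = fit_single_hit(pooled)
    ll_sep = _boundary_ll(fa) + _boundary_ll(fb)
    stat = max(0.0, 2.0 * (ll_sep - _boundary_ll(fp)))
    return stat, float(stats.chi2.sf(stat, 1))


def _boundary_ll(est: FrequencyEstimate) -> float:
    return est.log_likelihood


def simulate_dilution(
    f_true: float, doses, n_per_dose: int, seed: int, group_label: str = "sim"
) -> DilutionExperiment:
    """Draw responders ~ Binomial(n, 1 − exp(−f·d)) at each dose (seeded)."""
    if not f_true > 0:
        raise ValueError("f_true must be positive")
    d = np.asarray(doses, dtype=float)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed % 2**32)))
    p = -np.expm1(-f_true * d)
    x = rng.binomial(n_per_dose, p)
    return DilutionExperiment(d, np.full(d.shape, n_per_dose), x, group_label)


def read_dilution_table(path_or_buffer) -> dict[str, DilutionExperiment]:
    """Read a delimited table with header ``dose,tested,responded[,group]``.

    Returns one experiment per group ("all" when no group column).
    """
    df = pd.read_csv(path_or_buffer, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"dose", "tested", "responded"}
    if not required <= set(df.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if "group" not in df.columns:
        df["group"] = "all"
    out = {}
    for grp, sub in df.groupby("group", sort=True):
        out[str(grp)] = DilutionExperiment(
            sub["dose"].to_numpy(float),
            sub["tested"].to_numpy(int),
            sub["responded"].to_numpy(int),
            group_label=str(grp),
        )
    return out
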