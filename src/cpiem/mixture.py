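"""The CPI-EM mixture model over peak-intensity pairs.

The joint density of an overlapping intensity pair (x, y) is modelled as a
two-component mixture

    p(x, y) = w * f_c(x) g_c(y) + (1 - w) * f_n(x) g_n(y),

where the cooperative component (subscript c) and the non-cooperative
component (subscript n) each factorize over the target (x) and partner (y)
axes — intensities of the two TFs are assumed statistically independent
given the binding class.  Each marginal is a two-parameter Log-normal
(default), Gamma or Gaussian density, giving eight marginal parameters; the
mixture weight w is the ninth.  The nine parameters are fitted by
expectation maximization, and Bayes' formula then converts the fitted model
into a per-pair probability of cooperative binding.

The cooperative component is identified *after* fitting as the one with the
lower target-axis mean, reflecting the empirical observation that a
cooperatively bound target TF is, on average, more weakly bound than a
non-cooperatively bound one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import digamma, logsumexp, polygamma
from scipy.stats import norm

FAMILIES = ("lognormal", "gamma", "gaussian")

_SIGMA_FLOOR = 1e-6
_RESP_CLAMP = 1e-12
_WEIGHT_CLAMP = 1e-6


class DegenerateDataError(ValueError):
    """Input collapses onto a single point; no two-component fit exists."""


@dataclass
class MarginalParams:
    """One marginal density.

    ``location`` is the log-mean mu for lognormal, the mean for gaussian and
    the shape k for gamma; ``scale`` is the log-sd sigma, the sd, and the
    scale theta respectively.
    """

    family: str
    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.family == "gamma" and self.location <= 0:
            raise ValueError("gamma shape must be positive")

    @property
    def axis_mean(self) -> float:
        """The quantity compared to decide which component is cooperative."""
        if self.family == "gamma":
            return self.location * self.scale
        return self.location


@dataclass
class MixtureModel:
    """Fitted nine-parameter two-component product-marginal mixture."""

    family: str
    coop_target: MarginalParams
    coop_partner: MarginalParams
    noncoop_target: MarginalParams
    noncoop_partner: MarginalParams
    weight: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    ll_trace: tuple[float, ...] = ()


def _marginal_logpdf(params: MarginalParams, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if params.family in ("lognormal", "gamma") and np.any(x <= 0):
        raise ValueError(
            f"{params.family} density requires strictly positive intensities"
        )
    if params.family == "lognormal":
        lx = np.log(x)
        return norm.logpdf(lx, params.location, params.scale) - lx
    if params.family == "gaussian":
        return norm.logpdf(x, params.location, params.scale)
    from scipy.stats import gamma as gamma_dist

    return gamma_dist.logpdf(x, a=params.location, scale=params.scale)


def marginal_density(params: MarginalParams, x) -> np.ndarray | float:
    """Density of the marginal at x (x > 0 required for lognormal/gamma)."""
    out = np.exp(_marginal_logpdf(params, x))
    return float(out) if np.isscalar(x) else out


def _as_xy(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, tuple) and len(pairs) == 2:
        return np.asarray(pairs[0], float), np.asarray(pairs[1], float)
    arr = np.asarray(
        [(p.x, p.y) for p in pairs], dtype=float
    )
    if arr.size == 0:
        return np.empty(0), np.empty(0)
    return arr[:, 0], arr[:, 1]


def _moment_init(family: str, v: np.ndarray) -> tuple[float, float]:
    if family == "lognormal":
        lv = np.log(v)
        return float(lv.mean()), max(float(lv.std()), 1e-3)
    if family == "gaussian":
        return float(v.mean()), max(float(v.std()), 1e-3)
    m, var = float(v.mean()), max(float(v.var()), 1e-9)
    k = max(m * m / var, 1e-3)
    return k, m / k


def _weighted_fit(
    family: str, v: np.ndarray, lv: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Weighted maximum-likelihood M-step for one marginal."""
    sw = w.sum()
    if family in ("lognormal", "gaussian"):
        t = lv if family == "lognormal" else v
        m = float((w * t).sum() / sw)
        var = float((w * (t - m) ** 2).sum() / sw)
        return m, max(math.sqrt(var), _SIGMA_FLOOR)
    # gamma: Newton on the digamma equation, method-of-moments fallback
    m = float((w * v).sum() / sw)
    s = math.log(m) - float((w * lv).sum() / sw)
    k = None
    if s > 1e-12:
        k = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
        for _ in range(100):
            step = (math.log(k) - digamma(k) - s) / (1.0 / k - polygamma(1, k))
            k_new = k - step
            if not np.isfinite(k_new) or k_new <= 0:
                k = None
                break
            if abs(k_new - k) < 1e-12 * k_new:
                k = k_new
                break
            k = k_new
    if k is None or not np.isfinite(k):
        var = max(float((w * (v - m) ** 2).sum() / sw), 1e-12)
        k = max(m * m / var, 1e-6)
    return float(k), max(m / k, _SIGMA_FLOOR)


def _component_logpdf(
    family: str, loc: float, scale: float, v: np.ndarray, lv: np.ndarray
) -> np.ndarray:
    if family == "lognormal":
        return norm.logpdf(lv, loc, scale) - lv
    if family == "gaussian":
        return norm.logpdf(v, loc, scale)
    from scipy.stats import gamma as gamma_dist

    return gamma_dist.logpdf(v, a=loc, scale=scale)


def _run_em(
    x: np.ndarray,
    y: np.ndarray,
    family: str,
    init: dict,
    tol: float,
    max_iter: int,
) -> dict:
    if family == "gaussian":
        lx, ly = np.zeros_like(x), np.zeros_like(y)  # unused by this family
    else:
        lx, ly = np.log(x), np.log(y)
    params = {k: list(v) for k, v in init["marginals"].items()}
    w = init["weight"]
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        la = (
            math.log(w)
            + _component_logpdf(family, *params["ct"], x, lx)
            + _component_logpdf(family, *params["cp"], y, ly)
        )
        lb = (
            math.log1p(-w)
            + _component_logpdf(family, *params["nt"], x, lx)
            + _component_logpdf(family, *params["np"], y, ly)
        )
        ll_vec = np.logaddexp(la, lb)
        ll = float(ll_vec.sum())
        if trace and ll < trace[-1] - 1e-8 * (1.0 + abs(trace[-1])):
            raise AssertionError(
                f"EM log-likelihood decreased: {trace[-1]} -> {ll}"
            )
        if trace and abs(ll - trace[-1]) < tol * abs(trace[-1]):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        r = np.exp(la - ll_vec)
        r = np.clip(r, _RESP_CLAMP, 1.0 - _RESP_CLAMP)
        w = float(np.clip(r.mean(), _WEIGHT_CLAMP, 1.0 - _WEIGHT_CLAMP))
        params["ct"] = list(_weighted_fit(family, x, lx, r))
        params["cp"] = list(_weighted_fit(family, y, ly, r))
        params["nt"] = list(_weighted_fit(family, x, lx, 1.0 - r))
        params["np"] = list(_weighted_fit(family, y, ly, 1.0 - r))
    return {
        "params": params,
        "weight": w,
        "ll": trace[-1],
        "trace": trace,
        "iters": it,
        "converged": converged,
    }


def fit_mixture_em(
    pairs,
    family: str = "lognormal",
    n_restarts: int = 1,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> MixtureModel:
    """Fit the nine-parameter mixture by expectation maximization.

    Parameters
    ----------
    pairs
        A sequence of :class:`~cpiem.pairing.PeakPair`, or an ``(x, y)``
        tuple of intensity arrays.
    family
        Marginal family: ``lognormal`` (default), ``gamma`` or ``gaussian``.
    n_restarts
        Number of EM runs.  The first uses a deterministic initialization
        (median split on the target axis, low half seeding the cooperative
        component, weight 0.5); further restarts perturb it with ``seed``.
        The run with the highest final log-likelihood is returned.
    tol, max_iter
        Convergence is declared when the relative change of the total
        log-likelihood drops below ``tol`` (before ``max_iter`` sweeps).

    Notes
    -----
    Within every EM run the log-likelihood is non-decreasing across
    iterations (checked at each sweep).  After fitting, the component with
    the lower target-axis mean is labelled cooperative.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    x, y = _as_xy(pairs)
    if x.size < 20:
        raise ValueError(f"need at least 20 pairs, got {x.size}")
    if family != "gaussian" and (np.any(x <= 0) or np.any(y <= 0)):
        raise ValueError(f"{family} family requires strictly positive intensities")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise DegenerateDataError(
            "all intensity pairs identical; mixture fit is degenerate"
        )

    med = np.median(x)
    lo = x <= med
    if lo.all() or not lo.any():
        lo = np.arange(x.size) < x.size // 2
    base = {
        "weight": 0.5,
        "marginals": {
            "ct": _moment_init(family, x[lo]),
            "cp": _moment_init(family, y[lo]),
            "nt": _moment_init(family, x[~lo]),
            "np": _moment_init(family, y[~lo]),
        },
    }
    rng = np.random.default_rng(seed)
    best: dict | None = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            init = base
        else:
            marg = {}
            for key, (loc, scale) in base["marginals"].items():
                loc_p = loc + rng.normal(0.0, 0.25 * (abs(loc) + 0.1))
                scale_p = scale * math.exp(rng.normal(0.0, 0.25))
                if family == "gamma":
                    loc_p = max(loc_p, 1e-3)
                marg[key] = (loc_p, max(scale_p, _SIGMA_FLOOR))
            init = {"weight": float(rng.uniform(0.2, 0.8)), "marginals": marg}
        fit = _run_em(x, y, family, init, tol, max_iter)
        if best is None or fit["ll"] > best["ll"]:
            best = fit

    assert best is not None
    p = best["params"]
    ct = MarginalParams(family, *p["ct"])
    cp = MarginalParams(family, *p["cp"])
    nt = MarginalParams(family, *p["nt"])
    npart = MarginalParams(family, *p["np"])
    w = best["weight"]
    swap = ct.axis_mean > nt.axis_mean or (
        ct.axis_mean == nt.axis_mean and cp.axis_mean > npart.axis_mean
    )
    if swap:
        ct, nt = nt, ct
        cp, npart = npart, cp
        w = 1.0 - w
    return MixtureModel(
        family=family,
        coop_target=ct,
        coop_partner=cp,
        noncoop_target=nt,
        noncoop_partner=npart,
        weight=w,
        log_likelihood=best["ll"],
        n_iterations=best["iters"],
        converged=best["converged"],
        ll_trace=tuple(best["trace"]),
    )


def log_likelihood(model: MixtureModel, pairs) -> float:
    """Total data log-likelihood of a pair collection under the model."""
    x, y = _as_xy(pairs)
    la = (
        math.log(model.weight)
        + _marginal_logpdf(model.coop_target, x)
        + _marginal_logpdf(model.coop_partner, y)
    )
    lb = (
        math.log1p(-model.weight)
        + _marginal_logpdf(model.noncoop_target, x)
        + _marginal_logpdf(model.noncoop_partner, y)
    )
    return float(np.logaddexp(la, lb).sum())


def posterior_coop(model: MixtureModel, pairs) -> np.ndarray | float:
    """Bayes posterior probability of cooperative binding for each pair.

    Computed in log space:
    ``w f_c(x) g_c(y) / [w f_c(x) g_c(y) + (1-w) f_n(x) g_n(y)]``.
    Accepts a single :class:`~cpiem.pairing.PeakPair`, a sequence of pairs,
    or an ``(x, y)`` tuple; returns a float for a single pair.
    """
    single = hasattr(pairs, "x") and hasattr(pairs, "y")
    if single:
        pairs = [pairs]
    x, y = _as_xy(pairs)
    la = (
        math.log(model.weight)
        + _marginal_logpdf(model.coop_target, x)
        + _marginal_logpdf(model.coop_partner, y)
    )
    lb = (
        math.log1p(-model.weight)
        + _marginal_logpdf(model.noncoop_target, x)
        + _marginal_logpdf(model.noncoop_partner, y)
    )
    post = np.exp(la - np.logaddexp(la, lb))
    return float(post[0]) if single else post


def classify_pairs(posteriors, alpha: float) -> np.ndarray:
    """Cooperative call (True) iff posterior > alpha (strict)."""
    return np.asarray(posteriors, dtype=float) > alpha


def write_model(model: MixtureModel, path: str | Path) -> None:
    """Serialize the fitted parameters as a plain-text key-value file."""
    lines = [
        f"family\t{model.family}",
        f"weight\t{model.weight!r}",
        f"coop_target_location\t{model.coop_target.location!r}",
        f"coop_target_scale\t{model.coop_target.scale!r}",
        f"coop_partner_location\t{model.coop_partner.location!r}",
        f"coop_partner_scale\t{model.coop_partner.scale!r}",
        f"noncoop_target_location\t{model.noncoop_target.location!r}",
        f"noncoop_target_scale\t{model.noncoop_target.scale!r}",
        f"noncoop_partner_location\t{model.noncoop_partner.location!r}",
        f"noncoop_partner_scale\t{model.noncoop_partner.scale!r}",
        f"log_likelihood\t{model.log_likelihood!r}",
        f"n_iterations\t{model.n_iterations}",
        f"converged\t{model.converged}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> MixtureModel:
    kv = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            k, v = line.split("\t")
            kv[k] = v
    fam = kv["family"]
    mk = lambda pre: MarginalParams(
        fam, float(kv[f"{pre}_location"]), float(kv[f"{pre}_scale"])
    )
    return MixtureModel(
        family=fam,
        coop_target=mk("coop_target"),
        coop_partner=mk("coop_partner"),
        noncoop_target=mk("noncoop_target"),
        noncoop_partner=mk("noncoop_partner"),
        weight=float(kv["weight"]),
        log_likelihood=float(kv["log_likelihood"]),
        n_iterations=int(kv["n_iterations"]),
        converged=kv["converged"] == "True",
    )
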