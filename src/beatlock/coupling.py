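"""Ca2+ -> ATP transfer-function fits on paired event signal masses.

Four phenomenological transfer shapes cover the observed coupling
regimes: a two-component mixture of linear regressions (high-/low-gain
event populations), a Hill curve per cell (cooperative mitochondrial
Ca2+ control), a continuous two-segment changepoint line (load threshold
for Mode 2 dips), and an exponential (mitochondrial volume vs Ca signal
mass). All fits are invariant to input ordering; the mixture reduces to
ordinary least squares when BIC prefers one component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


@dataclass
class CouplingFit:
    """Result of one transfer-function fit."""

    kind: str                      # two_line | hill | changepoint | exponential
    params: dict
    r2: float
    resid_sd: float
    n_events: int
    assignments: np.ndarray | None = None
    ci: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.kind == "hill":
            xn = np.power(x, p["n"])
            return p["plateau"] * xn / (p["k"] ** p["n"] + xn)
        if self.kind == "changepoint":
            tau = p["threshold"]
            return np.where(
                x <= tau,
                p["intercept"] + p["slope_low_ca"] * x,
                p["intercept"] + p["slope_low_ca"] * tau
                + p["slope_high_ca"] * (x - tau),
            )
        if self.kind == "exponential":
            return p["scale"] * np.exp(p["rate"] * x)
        raise ValueError(f"predict not defined for kind {self.kind!r}")


def _r2(y, yhat):
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _as_xy(pairs_or_x, y=None):
    if y is None:
        df = pairs_or_x
        return (np.asarray(df["ca_mass"], dtype=float),
                np.asarray(df["atp_mass"], dtype=float))
    return (np.asarray(pairs_or_x, dtype=float), np.asarray(y, dtype=float))


# ------------------------------------------------- two-line regression mixture
def _wls(x, y, w):
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    if sxx <= 0:
        return 0.0, my
    b = (w * (x - mx) * (y - my)).sum() / sxx
    return b, my - b * mx


def _em_two_lines(x, y, resp, max_iter=300, tol=1e-10, var_floor=1e-12):
    """EM for a 2-component mixture of linear regressions.

    resp is the initial responsibility of component 1 per point. Returns
    (loglik, slopes, intercepts, sigmas, weights, responsibilities).
    """
    n = x.size
    r = np.clip(resp, 1e-6, 1 - 1e-6)
    ll_old = -np.inf
    for _ in range(max_iter):
        w = np.column_stack([1 - r, r])
        slopes, icpts, sig2 = np.zeros(2), np.zeros(2), np.zeros(2)
        pi = w.mean(axis=0)
        for k in range(2):
            slopes[k], icpts[k] = _wls(x, y, w[:, k])
            res = y - (slopes[k] * x + icpts[k])
            sig2[k] = max((w[:, k] * res ** 2).sum() / w[:, k].sum(), var_floor)
        # E-step
        log_pdf = np.empty((n, 2))
        for k in range(2):
            res = y - (slopes[k] * x + icpts[k])
            log_pdf[:, k] = (np.log(pi[k] + 1e-300)
                             - 0.5 * np.log(2 * np.pi * sig2[k])
                             - 0.5 * res ** 2 / sig2[k])
        m = log_pdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        ll = float(lse.sum())
        r = np.exp(log_pdf[:, 1] - lse)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return ll, slopes, icpts, np.sqrt(sig2), pi, r


def fit_two_line(pairs, y=None, seed: int = 0, n_starts: int = 5) -> CouplingFit:
    """Two-component mixture of linear regressions with BIC model choice.

    Fits K = 1 (ordinary least squares) and K = 2 (EM over slope,
    intercept and residual SD per component, multistart) and keeps the
    BIC-preferred model. For K = 2 the slopes are reported ordered
    (``slope_high`` >= ``slope_low`` by absolute value) and each pair is
    assigned to the component with the larger responsibility.
    """
    x, yv = _as_xy(pairs, y)
    n = x.size
    if n < 8:
        raise ValueError("two-line fit requires at least 8 pairs")
    rng = np.random.default_rng(seed)

    # K = 1: OLS
    b1, a1 = _wls(x, yv, np.ones(n))
    res1 = yv - (b1 * x + a1)
    s1 = max(float(np.sqrt(np.mean(res1 ** 2))), 1e-12)
    ll1 = float(np.sum(-0.5 * np.log(2 * np.pi * s1 ** 2)
                       - 0.5 * res1 ** 2 / s1 ** 2))
    bic1 = -2 * ll1 + 3 * np.log(n)

    # K = 2: multistart EM; one informed start splits by y/x ratio
    best = None
    ratio = yv / np.where(np.abs(x) > 1e-12, x, 1e-12)
    starts = [(ratio > np.median(ratio)).astype(float)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.random(n))
    for r0 in starts:
        out = _em_two_lines(x, yv, r0)
        if best is None or out[0] > best[0]:
            best = out
    ll2, slopes, icpts, sigmas, pi, resp = best
    bic2 = -2 * ll2 + 7 * np.log(n)

    if bic1 <= bic2:
        fit = CouplingFit(
            kind="two_line",
            params={"k": 1, "slope_high": b1, "slope_low": b1,
                    "intercept_high": a1, "intercept_low": a1,
                    "weight_high": 1.0, "bic": {1: bic1, 2: bic2}},
            r2=_r2(yv, b1 * x + a1),
            resid_sd=s1,
            n_events=n,
            assignments=np.zeros(n, dtype=int),
        )
        return fit

    order = np.argsort(np.abs(slopes))[::-1]  # high-gain first
    hi, lo = order
    assign = (resp if hi == 1 else 1 - resp) > 0.5
    yhat = np.where(assign, slopes[hi] * x + icpts[hi],
                    slopes[lo] * x + icpts[lo])
    return CouplingFit(
        kind="two_line",
        params={"k": 2,
                "slope_high": float(slopes[hi]), "slope_low": float(slopes[lo]),
                "intercept_high": float(icpts[hi]),
                "intercept_low": float(icpts[lo]),
                "weight_high": float(pi[hi]),
                "sigma_high": float(sigmas[hi]), "sigma_low": float(sigmas[lo]),
                "bic": {1: bic1, 2: bic2}},
        r2=_r2(yv, yhat),
        resid_sd=float(np.sqrt(np.mean((yv - yhat) ** 2))),
        n_events=n,
        assignments=assign.astype(int),
    )


def cell_gain_labels(pairs_by_cell, seed: int = 0) -> dict:
    """High-/low-gain cell labels by majority vote of pooled-event assignments.

    ``pairs_by_cell`` maps cell id -> DataFrame of event pairs; events are
    pooled, fit with :func:`fit_two_line`, and each cell is labelled by the
    component claiming the majority of its events.
    """
    import pandas as pd

    ids, frames = zip(*pairs_by_cell.items())
    pooled = pd.concat(frames, keys=ids, names=["cell"]).reset_index(level=0)
    fit = fit_two_line(pooled, seed=seed)
    pooled = pooled.assign(high_gain=fit.assignments == 1)
    votes = pooled.groupby("cell")["high_gain"].mean()
    return {cid: ("high" if v >= 0.5 else "low") for cid, v in votes.items()}


# --------------------------------------------------------------- Hill fit
def _hill(x, n, k, plateau):
    xn = np.power(x, n)
    return plateau * xn / (k ** n + xn)


def fit_hill(pairs, y=None, seed: int = 0, n_starts: int = 5,
             n_boot: int = 200) -> CouplingFit:
    """Least-squares Hill fit atp = plateau * ca^n / (K^n + ca^n).

    Bounds: n in [0.1, 10], K within the observed Ca range x [0.2, 5],
    plateau >= 0.8 max(y). Multistart over a grid of Hill coefficients
    avoids local minima; bootstrap percentile intervals for the three
    parameters when ``n_boot`` > 0. Data that do not span the
    half-saturation point produce a documented ill-conditioning warning.
    """
    x, yv = _as_xy(pairs, y)
    if x.size < 5:
        raise ValueError("Hill fit requires at least 5 points")
    if np.any(x <= 0):
        raise ValueError("Ca masses must be positive for a Hill fit")
    rng = np.random.default_rng(seed)
    lob = np.array([0.1, 0.2 * x.min(), 0.8 * np.max(yv)])
    hib = np.array([10.0, 5.0 * x.max(), 10.0 * max(np.max(yv), 1e-9)])

    def fit_once(xx, yy, warn=False):
        best = None
        n_grid = np.geomspace(0.3, 8.0, n_starts)
        for n0 in n_grid:
            p0 = np.clip([n0, np.median(xx), np.max(yy)], lob, hib)
            try:
                res = optimize.least_squares(
                    lambda p: _hill(xx, *p) - yy, p0,
                    bounds=(lob, hib), method="trf")
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("Hill fit failed from every start")
        return best.x

    n_hat, k_hat, plat_hat = fit_once(x, yv)
    warns = []
    half = plat_hat / 2.0
    if not (np.min(yv) < half < np.max(yv)):
        warns.append("data do not span half-saturation; "
                     "Hill parameters are ill-conditioned")
        warnings.warn(warns[-1], stacklevel=2)

    ci = {}
    if n_boot > 0:
        boots = np.empty((n_boot, 3))
        idx_all = np.arange(x.size)
        for b in range(n_boot):
            idx = rng.choice(idx_all, size=x.size, replace=True)
            try:
                boots[b] = fit_once(x[idx], yv[idx])
            except RuntimeError:
                boots[b] = (n_hat, k_hat, plat_hat)
        lo_q, hi_q = np.percentile(boots, [2.5, 97.5], axis=0)
        ci = {"n": (lo_q[0], hi_q[0]), "k": (lo_q[1], hi_q[1]),
              "plateau": (lo_q[2], hi_q[2])}

    yhat = _hill(x, n_hat, k_hat, plat_hat)
    return CouplingFit(
        kind="hill",
        params={"n": float(n_hat), "k": float(k_hat),
                "plateau": float(plat_hat)},
        r2=_r2(yv, yhat),
        resid_sd=float(np.sqrt(np.mean((yv - yhat) ** 2))),
        n_events=x.size,
        ci=ci,
        warnings=warns,
    )


# --------------------------------------------------------- changepoint fit
def fit_changepoint(pairs, y=None, n_grid: int = 41,
                    quantile_span: tuple = (5.0, 95.0)) -> CouplingFit:
    """Continuous two-segment linear fit with a grid-searched kink.

    Candidate thresholds are ``n_grid`` evenly spaced quantiles of the Ca
    masses between the 5th and 95th percentiles; for each, the hinge model
    y = a + b_low x + (b_high - b_low) relu(x - tau) is solved by least
    squares and the SSE-minimizing threshold is kept. A best threshold at
    the grid boundary yields a no-kink warning.
    """
    x, yv = _as_xy(pairs, y)
    if x.size < 10:
        raise ValueError("changepoint fit requires at least 10 pairs")
    taus = np.quantile(x, np.linspace(quantile_span[0] / 100.0,
                                      quantile_span[1] / 100.0, n_grid))
    best = None
    for tau in taus:
        design = np.column_stack([np.ones_like(x), x, np.maximum(x - tau, 0.0)])
        coef, *_ = np.linalg.lstsq(design, yv, rcond=None)
        sse = float(np.sum((design @ coef - yv) ** 2))
        if best is None or sse < best[0]:
            best = (sse, tau, coef)
    sse, tau, coef = best
    warns = []
    line = np.column_stack([np.ones_like(x), x])
    lcoef, *_ = np.linalg.lstsq(line, yv, rcond=None)
    sse_line = float(np.sum((line @ lcoef - yv) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if (tau in (taus[0], taus[-1])
            or sse >= sse_line * (1.0 - 1e-3)
            or sse_line <= 1e-12 * ss_tot):    # a single line is already exact
        warns.append("hinge barely improves on a single line "
                     "or sits at the search boundary: no clear kink")
        warnings.warn(warns[-1], stacklevel=2)
    a, b_low, delta = coef
    yhat = a + b_low * x + delta * np.maximum(x - tau, 0.0)
    return CouplingFit(
        kind="changepoint",
        params={"threshold": float(tau),
                "slope_low_ca": float(b_low),
                "slope_high_ca": float(b_low + delta),
                "intercept": float(a)},
        r2=_r2(yv, yhat),
        resid_sd=float(np.sqrt(sse / x.size)),
        n_events=x.size,
        warnings=warns,
    )


# --------------------------------------------------------- exponential fit
def fit_exponential(x, y) -> CouplingFit:
    """Least-squares fit of y = a exp(b x), e.g. volume vs Ca signal mass.

    Initialized from the log-linear regression when all y are positive,
    falling back to a direct nonlinear fit otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("exponential fit requires at least 5 points")
    if np.all(y > 0):
        b0, loga = np.polyfit(x, np.log(y), 1)
        p0 = (np.exp(loga), b0)
    else:
        p0 = (float(np.mean(y)), 0.0)
    popt, _ = optimize.curve_fit(
        lambda xx, a, b: a * np.exp(b * xx), x, y, p0=p0, maxfev=20000)
    a_hat, b_hat = popt
    yhat = a_hat * np.exp(b_hat * x)
    return CouplingFit(
        kind="exponential",
        params={"scale": float(a_hat), "rate": float(b_hat)},
        r2=_r2(y, yhat),
        resid_sd=float(np.sqrt(np.mean((y - yhat) ** 2))),
        n_events=x.size,
    )
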