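"""State-space point-process model of the branching rate.

A latent AR(1) log-rate drives Bernoulli-thinned bifurcation observations on a
discretized pathlength axis.  The forward pass is a point-process analogue of
the Kalman filter (Gaussian approximation with a per-bin scalar fixed point),
followed by a fixed-interval smoother; parameters are estimated by EM with
closed-form linear-Gaussian state updates and a closed-form baseline update.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize

from .trees import MorphTree, PointProcessSet, encode_population

log = logging.getLogger(__name__)


@dataclass
class StateSpaceParams:
    """Parameters of the AR(1) latent log-branching-rate model.

    x_k = rho * x_{k-1} + eps_k,   eps_k ~ N(0, sigma_eps2)
    lambda_k = exp(mu + beta * x_k)
    """

    rho: float
    mu: float
    beta: float = 1.0
    sigma_eps2: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_eps2 <= 0:
            raise ValueError("sigma_eps2 must be > 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")

    def stationary_variance(self) -> float:
        if abs(self.rho) < 1:
            return self.sigma_eps2 / (1.0 - self.rho**2)
        return self.sigma_eps2

    def to_dict(self) -> dict:
        return {"rho": self.rho, "mu": self.mu, "beta": self.beta,
                "sigma_eps2": self.sigma_eps2}

    @classmethod
    def from_dict(cls, d: dict) -> "StateSpaceParams":
        return cls(d["rho"], d["mu"], d.get("beta", 1.0), d["sigma_eps2"])


@dataclass
class FilterState:
    x_pred: np.ndarray   # x_{k|k-1}
    s_pred: np.ndarray   # sigma^2_{k|k-1}
    x_filt: np.ndarray   # x_{k|k}
    s_filt: np.ndarray   # sigma^2_{k|k}
    x0: float
    s0: float


@dataclass
class RateEstimate:
    """Smoothed latent state and the per-bin branching intensity."""

    x_smooth: np.ndarray       # x_{k|K}
    s_smooth: np.ndarray       # sigma^2_{k|K}
    gains: np.ndarray          # A_k, k = 0..K-2 (A_k links bins k and k+1)
    lam: np.ndarray            # exp(mu + beta x_{k|K}); events per unit axis
    delta: float
    params: StateSpaceParams | None = None
    x0_smooth: float = 0.0
    s0_smooth: float = 0.0
    gain0: float = 0.0

    @property
    def K(self) -> int:
        return len(self.lam)

    def event_probability(self) -> np.ndarray:
        """Expected events per bin, lambda_k * delta."""
        return self.lam * self.delta

    def to_table(self) -> "np.ndarray":
        k = np.arange(self.K)
        return np.column_stack(
            [k, (k + 1) * self.delta, self.x_smooth, self.s_smooth, self.lam]
        )

    def save(self, table_path, params_path=None) -> None:
        header = "bin\tpathlength\tx_smooth\tvar_smooth\tlambda"
        np.savetxt(table_path, self.to_table(), delimiter="\t", header=header)
        if params_path is not None and self.params is not None:
            with open(params_path, "w") as fh:
                json.dump(self.params.to_dict(), fh, indent=2)


class FilterConvergenceError(RuntimeError):
    pass


def _solve_update(x_pred: float, s_pred: float, beta: float, n_k: float,
                  r_k: float, mu: float, delta: float,
                  max_iter: int = 100, tol: float = 1e-10) -> float:
    """Solve x = x_pred + s_pred * beta * (n_k - r_k * exp(mu + beta x) * delta).

    Damped fixed-point iteration (damping equal to the local Newton scale,
    which makes each step a Newton step on the posterior score), with a
    bracketed root find as fallback.
    """
    if beta == 0.0:
        return x_pred

    def _rate(x: float) -> float:
        arg = mu + beta * x
        if arg > 700.0:
            return math.inf
        return r_k * math.exp(arg) * delta

    def g(x: float) -> float:
        rate = _rate(x)
        if math.isinf(rate):
            return math.inf if s_pred * beta > 0 else -math.inf
        return x - x_pred - s_pred * beta * (n_k - rate)

    # g is strictly monotone in x; damped (Newton-scaled) iteration with the
    # step clamped to avoid overshooting into the exp overflow region
    x = x_pred
    for _ in range(max_iter):
        rate = _rate(x)
        if math.isinf(rate):
            break
        gval = x - x_pred - s_pred * beta * (n_k - rate)
        gp = 1.0 + s_pred * beta * beta * rate
        step = gval / gp
        step = max(-10.0, min(10.0, step))
        x_new = x - step
        if abs(x_new - x) < tol:
            return x_new
        x = x_new
    # fallback: expand a bracket around x_pred and solve by bisection
    lo, hi = x_pred - 1.0, x_pred + 1.0
    for _ in range(200):
        glo, ghi = g(lo), g(hi)
        if glo == 0.0:
            return lo
        if glo < 0 < ghi:
            return brentq(g, lo, hi, xtol=tol)
        lo -= 2.0
        hi += 2.0
    raise FilterConvergenceError("filter update failed to converge")


def filter_forward(pp: PointProcessSet, params: StateSpaceParams,
                   x0: float = 0.0, s0: float | None = None) -> FilterState:
    """Forward pass: one-step prediction plus recursive nonlinear update.

    Bins beyond a sequence's observed length contribute nothing; ``r_k`` is
    the number of sequences still observed at bin k.
    """
    if s0 is None:
        s0 = params.stationary_variance()
    K = pp.K
    n = pp.event_counts().astype(float)
    r = pp.active_counts().astype(float)
    rho, mu, beta, se2 = params.rho, params.mu, params.beta, params.sigma_eps2
    delta = pp.delta

    x_pred = np.empty(K)
    s_pred = np.empty(K)
    x_filt = np.empty(K)
    s_filt = np.empty(K)
    xf, sf = x0, s0
    for k in range(K):
        xp = rho * xf
        sp = rho * rho * sf + se2
        try:
            xf = _solve_update(xp, sp, beta, n[k], r[k], mu, delta)
        except FilterConvergenceError as exc:
            raise FilterConvergenceError(f"bin {k}: {exc}") from exc
        sf = 1.0 / (1.0 / sp + r[k] * beta * beta * math.exp(mu + beta * xf) * delta)
        x_pred[k], s_pred[k], x_filt[k], s_filt[k] = xp, sp, xf, sf
    return FilterState(x_pred, s_pred, x_filt, s_filt, x0, s0)


def smooth(fs: FilterState, params: StateSpaceParams,
           delta: float = 1.0) -> RateEstimate:
    """Fixed-interval smoother: backward recursion over the filtered pass."""
    K = len(fs.x_filt)
    rho, mu, beta = params.rho, params.mu, params.beta
    x_s = np.empty(K)
    s_s = np.empty(K)
    gains = np.empty(max(K - 1, 0))
    x_s[K - 1] = fs.x_filt[K - 1]
    s_s[K - 1] = fs.s_filt[K - 1]
    for k in range(K - 2, -1, -1):
        A = rho * fs.s_filt[k] / fs.s_pred[k + 1]
        gains[k] = A
        x_s[k] = fs.x_filt[k] + A * (x_s[k + 1] - fs.x_pred[k + 1])
        s_s[k] = fs.s_filt[k] + A * A * (s_s[k + 1] - fs.s_pred[k + 1])
    A0 = rho * fs.s0 / fs.s_pred[0]
    x0_s = fs.x0 + A0 * (x_s[0] - fs.x_pred[0])
    s0_s = fs.s0 + A0 * A0 * (s_s[0] - fs.s_pred[0])
    lam = np.exp(mu + beta * x_s)
    return RateEstimate(x_s, s_s, gains, lam, delta, params, x0_s, s0_s, A0)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(40)


def _approx_loglik(pp: PointProcessSet, fs: FilterState,
                   params: StateSpaceParams) -> float:
    """Observed-data log-likelihood via Gauss-Hermite quadrature over each
    one-step predictive density (multinomial constants dropped)."""
    n = pp.event_counts().astype(float)
    r = pp.active_counts().astype(float)
    mu, beta, delta = params.mu, params.beta, pp.delta
    total = 0.0
    for k in range(pp.K):
        x = fs.x_pred[k] + math.sqrt(fs.s_pred[k]) * _GH_NODES
        logrates = mu + beta * x + math.log(delta)
        ll = n[k] * logrates - r[k] * np.exp(logrates)
        m = ll.max()
        total += m + math.log(float(np.dot(_GH_WEIGHTS, np.exp(ll - m)))) \
            - 0.5 * math.log(2.0 * math.pi)
    return total


@dataclass
class EMResult:
    params: StateSpaceParams
    rate: RateEstimate
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def em_fit(pp: PointProcessSet, init: StateSpaceParams | None = None,
           tol: float = 1e-5, max_iter: int = 500,
           fit_beta: bool = False) -> EMResult:
    """Estimate (rho, mu, sigma_eps2) — and beta when requested — by EM.

    The E-step runs the approximate filter and smoother; the M-step uses the
    standard linear-Gaussian sufficient statistics for rho and sigma_eps2 and
    a closed-form update for mu (joint numerical update of (mu, beta) when
    beta is free).  x_{0|0} is held at 0 with the stationary prior variance.
    """
    if pp.N_total < 1:
        raise ValueError("no events to fit")
    if init is None:
        rk = pp.active_counts().sum()
        init = StateSpaceParams(
            rho=0.9,
            mu=math.log(max(pp.N_total, 1) / (rk * pp.delta)),
            beta=1.0,
            sigma_eps2=0.1,
        )
    params = StateSpaceParams(**init.to_dict())
    delta = pp.delta
    n = pp.event_counts().astype(float)
    r = pp.active_counts().astype(float)
    K = pp.K

    trace: list[float] = []
    rate = None
    converged = False
    prev: tuple[StateSpaceParams, RateEstimate] | None = None
    it = 0
    for it in range(1, max_iter + 1):
        # x0 is treated as the known constant 0 (s0 = 0) so the closed-form
        # M-step maximizes exactly the Q implied by this E-step
        fs = filter_forward(pp, params, x0=0.0, s0=0.0)
        rate = smooth(fs, params, delta)
        ll = _approx_loglik(pp, fs, params)
        if not math.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood in EM")
        if trace and ll < trace[-1] - 1e-9:
            # the approximate E-step can wander once the likelihood plateaus;
            # revert to the previous (better) iterate and stop
            params, rate = prev  # type: ignore[misc]
            converged = True
            it -= 1
            break
        trace.append(ll)
        prev = (params, rate)

        # E-step second moments (x0 fixed at 0, smoothed via gain0)
        xs = np.concatenate([[rate.x0_smooth], rate.x_smooth])
        ss = np.concatenate([[rate.s0_smooth], rate.s_smooth])
        gains = np.concatenate([[rate.gain0], rate.gains])  # A_{k-1} for k=1..K
        S_kk = xs**2 + ss                                   # E[x_k^2], k=0..K
        cross = gains * rate.s_smooth + xs[1:] * xs[:-1]    # E[x_k x_{k-1}]

        num = float(cross.sum())
        den = float(S_kk[:-1].sum())
        rho_new = max(-0.999, min(0.999, num / den)) if den > 0 else 0.0
        se2_new = float(
            (S_kk[1:].sum() - 2.0 * rho_new * num + rho_new**2 * den) / K
        )
        se2_new = max(se2_new, 1e-12)

        beta_new = params.beta
        if fit_beta:
            xbar, var = rate.x_smooth, rate.s_smooth

            def neg_q(theta):
                mu_t, beta_t = theta
                lograte = mu_t + beta_t * xbar + 0.5 * beta_t**2 * var
                return -(np.sum(n * (mu_t + beta_t * xbar))
                         - np.sum(r * delta * np.exp(lograte)))

            res = minimize(neg_q, np.array([params.mu, params.beta]),
                           method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            mu_new, beta_new = float(res.x[0]), float(res.x[1])
        else:
            expect = np.exp(params.beta * rate.x_smooth
                            + 0.5 * params.beta**2 * rate.s_smooth)
            mu_new = math.log(n.sum() / float((r * delta * expect).sum()))

        change = max(
            abs(rho_new - params.rho), abs(mu_new - params.mu),
            abs(beta_new - params.beta), abs(se2_new - params.sigma_eps2),
        )
        params = StateSpaceParams(rho_new, mu_new, beta_new, se2_new)
        if change < tol:
            converged = True
            break

    if not converged:
        log.warning("EM reached max_iter=%d without converging", max_iter)
    assert rate is not None
    return EMResult(params, rate, trace, it, converged)


def estimate_branching_rate(trees: list[MorphTree], delta: float | None = None,
                            normalize: bool = True, n_bins: int = 100,
                            tip_events: bool = True, **em_kwargs) -> EMResult:
    """Pool all trees' terminal-path point processes and fit the rate model.

    ``tip_events=False`` estimates the bifurcation rate alone, with tips
    marking sequence extent only — the right input for regeneration, where
    termination is imposed by the anatomical boundary rather than the rate.
    """
    if not trees:
        raise ValueError("need at least one tree")
    pp = encode_population(trees, delta=delta, normalize=normalize,
                           n_bins=n_bins, tip_events=tip_events)
    return em_fit(pp, **em_kwargs)
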