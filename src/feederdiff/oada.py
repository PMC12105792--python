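"""Order-of-acquisition diffusion analysis (OADA).

OADA asks whether the order in which individuals first perform a behaviour
(here: revisiting a refilled feeder) follows the social network more closely
than expected under purely asocial discovery.  Under the additive rate model
the acquisition rate of a naive individual *i* is

    R_i = exp(beta * x_i) + s * sum_j a_ij * z_j

where ``a_ij`` is the dyadic association strength, ``z_j = 1`` once *j* is
informed, ``x_i`` is an individual-level variable (ILV) moderating only the
asocial rate, and ``s`` is the social-transmission strength relative to the
baseline asocial rate of an average individual.  Because OADA conditions on
the order alone, the shared baseline rate cancels from the likelihood and is
never parameterized.

The module provides the likelihood, maximum-likelihood fitting with
multistart and convergence diagnostics, AICc model comparison with the
convention that a winning social model with convergence problems is replaced
by the asocial model, profile-likelihood confidence intervals for ``s``, the
per-event attribution estimator of the proportion of social transmission
(pST), and a 2xK Fisher exact test for best-model frequency tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .association import AssociationNetwork
from .visits import DiffusionRecord

BETA_BOUND = 20.0
PST_UPPER_UNBOUNDED = 0.99999


# ---------------------------------------------------------------------------
# Likelihood machinery


class DiffusionDesign:
    """Precomputed arrays for one diffusion's OADA likelihood.

    Parameters
    ----------
    network : (N, N) symmetric association matrix over the risk set.
    order : indices (into the risk set) of acquirers, in acquisition order.
    ilv : optional (N,) covariate vector; zeros when absent.
    """

    def __init__(self, network, order, ilv=None):
        A = np.asarray(network, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("network must be a square matrix")
        if np.isnan(A).any():
            raise ValueError("network contains NaN")
        if not np.allclose(A, A.T):
            raise ValueError("network must be symmetric")
        self.A = A
        self.N = A.shape[0]
        self.order = np.asarray(order, dtype=int)
        if self.order.size and (
            self.order.min() < 0 or self.order.max() >= self.N
        ):
            raise ValueError("order indices out of range")
        if len(set(self.order.tolist())) != self.order.size:
            raise ValueError("order contains duplicates")
        self.m = self.order.size
        self.x = (
            np.zeros(self.N)
            if ilv is None
            else np.asarray(ilv, dtype=float)
        )
        if self.x.shape != (self.N,):
            raise ValueError("ilv must align with the risk set")
        # exposure[k, i]: network connection of i to the k first acquirers
        cum = np.cumsum(self.A[self.order, :], axis=0) if self.m else np.zeros((0, self.N))
        self.exposure = np.vstack([np.zeros((1, self.N)), cum[:-1]]) if self.m else cum
        # naive[k, i]: i not yet informed before event k
        self.naive = np.ones((self.m, self.N), dtype=bool)
        for k in range(1, self.m):
            self.naive[k] = self.naive[k - 1]
            self.naive[k, self.order[k - 1]] = False

    @classmethod
    def from_records(
        cls, diff: DiffusionRecord, network: AssociationNetwork
    ) -> "DiffusionDesign":
        missing = [i for i in diff.risk_set if i not in network.ids]
        if missing:
            raise ValueError(
                f"risk set members absent from the association network: {missing}"
            )
        pos = {ind: k for k, ind in enumerate(diff.risk_set)}
        order = [pos[i] for i in diff.acquisition_order]
        A = network.submatrix(diff.risk_set)
        np.fill_diagonal(A, 0.0)
        return cls(A, order, diff.ilv)

    def rates(self, s: float, beta: float) -> np.ndarray:
        """(m, N) matrix of acquisition rates before each event."""
        return np.exp(beta * self.x)[None, :] + s * self.exposure

    def loglik(self, s: float, beta: float) -> float:
        if self.m == 0:
            return 0.0
        R = self.rates(s, beta)
        num = R[np.arange(self.m), self.order]
        den = np.where(self.naive, R, 0.0).sum(axis=1)
        with np.errstate(divide="ignore"):
            ll = np.log(num) - np.log(den)
        if not np.all(np.isfinite(ll)):
            warnings.warn("zero event probability encountered (underflow)")
            return -np.inf
        return float(ll.sum())

    def event_attribution(self, s: float, beta: float) -> np.ndarray:
        """Per-event social share q_k = s*exposure / (asocial + s*exposure)."""
        if self.m == 0:
            return np.zeros(0)
        social = s * self.exposure[np.arange(self.m), self.order]
        asocial = np.exp(beta * self.x[self.order])
        return social / (asocial + social)


def _as_designs(diffs, networks=None) -> list[DiffusionDesign]:
    if isinstance(diffs, DiffusionDesign):
        return [diffs]
    if isinstance(diffs, DiffusionRecord):
        return [DiffusionDesign.from_records(diffs, networks)]
    diffs = list(diffs)
    if all(isinstance(d, DiffusionDesign) for d in diffs):
        return diffs
    nets = list(networks)
    return [DiffusionDesign.from_records(d, n) for d, n in zip(diffs, nets, strict=True)]


def event_rates(risk_set, informed_set, network, s, beta, ilv=None):
    """Acquisition rates for every member of the risk set given the informed set.

    Informed individuals transmit; the returned vector covers the whole risk
    set (informed members included — their entries are their would-be rates,
    only naive entries enter the OADA likelihood).
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    risk = list(risk_set)
    if not set(informed_set) <= set(risk):
        raise ValueError("informed_set must be a subset of the risk set")
    A = np.asarray(network, dtype=float)
    x = np.zeros(len(risk)) if ilv is None else np.asarray(ilv, dtype=float)
    z = np.array([1.0 if i in set(informed_set) else 0.0 for i in risk])
    return np.exp(beta * x) + s * (A @ z)


def oada_loglik(diffs, networks=None, s: float = 0.0, beta: float = 0.0) -> float:
    """Pooled OADA log-likelihood over one or more diffusions.

    Censored individuals never acquire but remain in every denominator.
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    return sum(d.loglik(s, beta) for d in _as_designs(diffs, networks))


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class OadaModelSpec:
    """Settings for one OADA model fit."""

    model_type: str = "social"  # "social" or "asocial"
    s_max: float = 1e6
    n_starts: int = 5
    seed: int = 0
    grad_tol: float = 1e-2

    def __post_init__(self) -> None:
        if self.model_type not in ("social", "asocial"):
            raise ValueError("model_type must be 'social' or 'asocial'")
        if self.s_max <= 0:
            raise ValueError("s_max must be positive")


@dataclass
class OadaFit:
    model_type: str
    s_hat: float | None
    beta_hat: float
    loglik: float
    k: int
    n_events: int
    aicc: float
    converged: bool
    grad_norm: float = np.nan
    hessian_cond: float = np.nan


@dataclass
class ModelSelection:
    winner: str  # "social" or "asocial"
    fit: OadaFit
    delta_aicc: float
    replaced: bool = False


def aicc(loglik: float, k: int, n_events: int) -> float:
    """Small-sample corrected AIC with n = number of acquisition events."""
    if n_events <= k + 1:
        raise ValueError(
            f"AICc undefined for n_events={n_events} <= k+1={k + 1}; pool"
            " diffusions to gain events"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_events - k - 1)


def _numeric_grad(f, theta, h=1e-5):
    theta = np.asarray(theta, dtype=float)
    g = np.zeros_like(theta)
    for i in range(theta.size):
        e = np.zeros_like(theta)
        e[i] = h * max(1.0, abs(theta[i]))
        g[i] = (f(theta + e) - f(theta - e)) / (2 * e[i])
    return g

def _numeric_hess(f, theta, h=1e-4):
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    H = np.zeros((n, n))
    steps = [h * max(1.0, abs(t)) for t in theta]
    f0 = f(theta)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / steps[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej)
                - f(theta + ei - ej)
                - f(theta - ei + ej)
                + f(theta - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H


def fit_oada(diffs, networks=None, spec: OadaModelSpec | None = None) -> OadaFit:
    """Maximum-likelihood OADA fit (social: s, beta; asocial: beta only).

    Multistart bounded optimization guards against the flat likelihood ridge
    that arises when a diffusion follows the network almost perfectly; a fit
    is flagged non-converged when the optimizer fails, the (projected)
    gradient is large, the Hessian at an interior optimum is not positive
    definite, or ``s`` ends up pinned at the ``s_max`` cap.
    """
    spec = spec or OadaModelSpec()
    designs = _as_designs(diffs, networks)
    n_events = sum(d.m for d in designs)
    if n_events < 1:
        raise ValueError("at least one acquisition event is required")

    def negll(theta):
        if spec.model_type == "social":
            s, beta = theta
        else:
            s, beta = 0.0, theta[0]
        return -sum(d.loglik(s, beta) for d in designs)

    rng = np.random.default_rng(spec.seed)
    if spec.model_type == "social":
        k = 2
        base_starts = np.array([0.01, 1.0, 5.0, 25.0, 200.0])
        s_starts = base_starts[: max(1, spec.n_starts)] * np.exp(
            0.1 * rng.standard_normal(min(spec.n_starts, base_starts.size))
        )
        bounds = [(0.0, spec.s_max), (-BETA_BOUND, BETA_BOUND)]
        starts = [np.array([s0, 0.0]) for s0 in s_starts]
    else:
        k = 1
        bounds = [(-BETA_BOUND, BETA_BOUND)]
        starts = [np.array([b0]) for b0 in (0.0, 1.0, -1.0)[: max(1, spec.n_starts)]]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    ll = -float(best.fun)

    # convergence diagnostics: projected gradient, interior Hessian, cap hit
    grad = _numeric_grad(negll, theta)
    interior = []
    proj = grad.copy()
    for i, (lo, hi) in enumerate(bounds):
        at_lo = theta[i] <= lo + 1e-10 * max(1.0, abs(lo))
        at_hi = theta[i] >= hi - 1e-8 * max(1.0, abs(hi))
        if at_lo and grad[i] > 0:
            proj[i] = 0.0
        elif at_hi and grad[i] < 0:
            proj[i] = 0.0
        if not (at_lo or at_hi):
            interior.append(i)
    grad_norm = float(np.linalg.norm(proj))
    converged = bool(best.success) and grad_norm <= spec.grad_tol * max(1.0, abs(ll))
    hess_cond = np.nan
    if interior:
        H = _numeric_hess(negll, theta)[np.ix_(interior, interior)]
        eig = np.linalg.eigvalsh(H)
        hess_cond = float(eig.max() / eig.min()) if eig.min() > 0 else np.inf
        # A meaningfully negative eigenvalue means a saddle, not a maximum.
        # A singular (ridge) Hessian is expected when the diffusion follows
        # the network closely and s runs toward its asymptote; those fits
        # are legitimate and surface downstream as unbounded profile CIs.
        if eig.min() < -1e-6 * max(1.0, abs(eig).max()):
            converged = False
        if not np.all(np.isfinite(H)):
            converged = False

    if spec.model_type == "social":
        s_hat, beta_hat = float(theta[0]), float(theta[1])
    else:
        s_hat, beta_hat = None, float(theta[0])
    return OadaFit(
        model_type=spec.model_type,
        s_hat=s_hat,
        beta_hat=beta_hat,
        loglik=ll,
        k=k,
        n_events=n_events,
        aicc=aicc(ll, k, n_events),
        converged=converged,
        grad_norm=grad_norm,
        hessian_cond=hess_cond,
    )


def compare_models(social: OadaFit, asocial: OadaFit) -> ModelSelection:
    """AICc winner with the convergence-replacement convention.

    Lower AICc wins; an exact tie goes to the asocial model (parsimony).  A
    social winner flagged non-converged is replaced by the asocial model and
    the replacement is recorded.
    """
    if social.n_events != asocial.n_events:
        raise ValueError("models were fitted on different numbers of events")
    delta = social.aicc - asocial.aicc
    if delta < 0:
        if not social.converged:
            return ModelSelection("asocial", asocial, delta, replaced=True)
        return ModelSelection("social", social, delta)
    return ModelSelection("asocial", asocial, delta)


# ---------------------------------------------------------------------------
# Profile likelihood and pST


@dataclass
class ProfileCi:
    """Profile-likelihood confidence interval for s."""

    s_lower: float
    s_upper: float  # np.inf when unbounded below the cap
    unbounded_upper: bool
    level: float
    beta_at_lower: float
    beta_at_upper: float
    pst_lower: float | None = None
    pst_upper: float | None = None


def _profile_beta(designs, s):
    def neg(beta):
        return -sum(d.loglik(s, beta) for d in designs)

    res = optimize.minimize_scalar(
        neg, bounds=(-BETA_BOUND, BETA_BOUND), method="bounded",
        options={"xatol": 1e-8},
    )
    return -float(res.fun), float(res.x)


def profile_ci_s(
    diffs,
    networks=None,
    fit: OadaFit | None = None,
    level: float = 0.95,
    s_cap: float = 1e6,
    rel_tol: float = 1e-4,
) -> ProfileCi:
    """Profile-likelihood CI for s, profiling beta out at every s.

    Bounds solve ``2*(loglik_max - profile(s)) = chi2_{1,level}`` by
    bisection.  When the profile never drops below the threshold up to
    ``s_cap`` the upper limit is flagged unbounded (the diffusion follows the
    network closely enough that arbitrarily strong transmission fits).
    """
    if fit is None or fit.model_type != "social":
        raise ValueError("profile_ci_s requires a fitted social model")
    designs = _as_designs(diffs, networks)
    crit = stats.chi2.ppf(level, df=1) / 2.0
    s_hat = fit.s_hat
    llmax, _ = _profile_beta(designs, s_hat)
    target = llmax - crit

    def deficit(s):
        ll, beta = _profile_beta(designs, s)
        return ll - target, beta

    def bisect(lo, hi, lo_above):
        # profile(lo) above target iff lo_above; find the crossing
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            d, _ = deficit(mid)
            if (d >= 0) == lo_above:
                lo = mid
            else:
                hi = mid
            if hi - lo <= rel_tol * max(1.0, hi):
                break
        return 0.5 * (lo + hi)

    d0, beta0 = deficit(0.0)
    if d0 >= 0:
        s_lower, beta_lower = 0.0, beta0
    else:
        s_lower = bisect(0.0, s_hat, lo_above=False)
        _, beta_lower = deficit(s_lower)

    dcap, betacap = deficit(s_cap)
    if dcap >= 0:
        return ProfileCi(
            s_lower=s_lower,
            s_upper=np.inf,
            unbounded_upper=True,
            level=level,
            beta_at_lower=beta_lower,
            beta_at_upper=betacap,
        )
    s_upper = bisect(s_hat, s_cap, lo_above=True)
    _, beta_upper = deficit(s_upper)
    return ProfileCi(
        s_lower=s_lower,
        s_upper=s_upper,
        unbounded_upper=False,
        level=level,
        beta_at_lower=beta_lower,
        beta_at_upper=beta_upper,
    )


def compute_pst(diffs, networks=None, s: float = 0.0, beta: float = 0.0) -> float:
    """Proportion of acquisition events attributable to social transmission.

    Deterministic per-event attribution: for acquirer i at event k,
    ``q_k = s*exposure / (exp(beta*x_i) + s*exposure)``; pST is the mean of
    q_k over all acquisition events (the first acquirer has no informed
    associates, so q_1 = 0).
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    designs = _as_designs(diffs, networks)
    qs = np.concatenate([d.event_attribution(s, beta) for d in designs])
    if qs.size == 0:
        return 0.0
    return float(qs.mean())


def simulate_pst(
    diffs, networks=None, s: float = 0.0, beta: float = 0.0,
    n_rep: int = 1000, seed: int = 0,
) -> float:
    """Simulation-based pST cross-check.

    Replays each diffusion's sequential sampling under (s, beta) and scores
    each simulated event as social with its attribution probability; agrees
    with :func:`compute_pst` in expectation over the fitted order but may
    differ slightly because it averages over resimulated orders.
    """
    rng = np.random.default_rng(seed)
    designs = _as_designs(diffs, networks)
    total_social = 0.0
    total_events = 0
    for _ in range(n_rep):
        for d in designs:
            naive = list(range(d.N))
            informed: list[int] = []
            z = np.zeros(d.N)
            for _k in range(d.m):
                R = np.exp(beta * d.x[naive]) + s * (d.A[naive] @ z)
                p = R / R.sum()
                pick = naive[rng.choice(len(naive), p=p)]
                expo = s * float(d.A[pick] @ z)
                total_social += expo / (np.exp(beta * d.x[pick]) + expo)
                total_events += 1
                naive.remove(pick)
                informed.append(pick)
                z[pick] = 1.0
    return total_social / total_events if total_events else 0.0


@dataclass
class PstEstimate:
    """pST for one feeder x DP, ready for the temperature meta-regression."""

    feeder_id: str
    dp_index: int
    pst: float
    source: str  # "social_fit" or "fixed_zero"
    pst_lower: float | None = None
    pst_upper: float | None = None
    s_hat: float | None = None
    unbounded_upper: bool = False
    temperature: float | None = None
    logit_pst: float | None = None
    logit_se: float | None = None
    weight: float | None = None


def pst_with_ci(
    fit: OadaFit, ci: ProfileCi, diffs, networks=None,
    feeder_id: str = "", dp_index: int = 0,
) -> PstEstimate:
    """pST at the MLE with CI endpoints mapped through the profile bounds.

    An unbounded upper s limit maps to the conventional pST upper limit of
    0.99999.
    """
    designs = _as_designs(diffs, networks)
    pst = compute_pst(designs, s=fit.s_hat, beta=fit.beta_hat)
    lower = compute_pst(designs, s=ci.s_lower, beta=ci.beta_at_lower)
    if ci.unbounded_upper:
        upper = PST_UPPER_UNBOUNDED
    else:
        upper = compute_pst(designs, s=ci.s_upper, beta=ci.beta_at_upper)
    # pST is monotone in s at fixed beta, but the profiled beta moves with s
    # and can push an endpoint past the point estimate; keep the CI bracketing
    lower = min(lower, pst)
    upper = max(upper, pst)
    ci.pst_lower, ci.pst_upper = lower, upper
    return PstEstimate(
        feeder_id=feeder_id,
        dp_index=dp_index,
        pst=pst,
        source="social_fit",
        pst_lower=lower,
        pst_upper=upper,
        s_hat=fit.s_hat,
        unbounded_upper=ci.unbounded_upper,
    )


def fixed_zero_pst(feeder_id: str = "", dp_index: int = 0) -> PstEstimate:
    """pST fixed to 0 when the asocial model wins; SE imputed downstream."""
    return PstEstimate(
        feeder_id=feeder_id, dp_index=dp_index, pst=0.0, source="fixed_zero"
    )


# ---------------------------------------------------------------------------
# Fisher exact test for 2 x K best-model frequency tables


def _log_table_prob(row1, colsums, n, r1):
    lp = -(_log_binom(n, r1))
    for a, c in zip(row1, colsums):
        lp += _log_binom(c, a)
    return lp


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2xk(
    table, max_exact_total: int = 200, n_mc: int = 100_000, seed: int = 0
) -> float:
    """Two-sided Fisher exact test for a 2 x K contingency table.

    Exact enumeration of all tables with the observed margins (multivariate
    hypergeometric null) when the grand total is at most ``max_exact_total``;
    the p-value sums the probabilities of tables no more probable than the
    observed one (with a small slack for float ties).  Larger tables fall
    back to seeded Monte-Carlo sampling.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("table must be 2 x K with K >= 2")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    rowsums = t.sum(axis=1)
    colsums = t.sum(axis=0)
    n = int(t.sum())
    if rowsums.min() == 0 or colsums.min() == 0:
        warnings.warn("degenerate margin: Fisher exact p-value is 1")
        return 1.0
    r1 = int(rowsums[0])
    lp_obs = _log_table_prob(t[0], colsums, n, r1)
    slack = 1e-12

    if n <= max_exact_total:
        p = 0.0

        def recurse(k, remaining, lp):
            nonlocal p
            if k == len(colsums) - 1:
                a = remaining
                if 0 <= a <= colsums[k]:
                    lpt = lp + _log_binom(colsums[k], a)
                    if math.exp(lpt) <= math.exp(lp_obs) + slack:
                        p += math.exp(lpt)
                return
            lo = max(0, remaining - int(colsums[k + 1 :].sum()))
            hi = min(int(colsums[k]), remaining)
            for a in range(lo, hi + 1):
                recurse(k + 1, remaining - a, lp + _log_binom(colsums[k], a))

        recurse(0, r1, -_log_binom(n, r1))
        return min(1.0, p)

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(colsums, r1, size=n_mc)
    base = -_log_binom(n, r1)
    lps = base + sum(
        _log_binom(c, draws[:, j]) for j, c in enumerate(colsums)
    )
    hits = np.count_nonzero(np.exp(lps) <= math.exp(lp_obs) + slack)
    return (1 + hits) / (1 + n_mc)
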