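"""Tumor-fraction deconvolution of plasma methylation counts (timMRD).

Model
-----
For plasma sample *i* and panel block *j*, the methylated count is
binomial, ``M_ij | N_ij, beta_ij ~ Binomial(N_ij, beta_ij)``, where the
latent methylation probability is a three-way mixture

    beta_ij = alpha * beta_t_j + gamma * beta_n_j + (1 - alpha - gamma) * b0_j

with ``alpha`` the ctDNA fraction (malignancy density ratio), ``gamma``
the tumor-adjacent-normal cfDNA fraction, ``beta_t``/``beta_n`` the
patient's tumor / adjacent-normal tissue levels, and the background level
``b0_j ~ Beta(p_j, q_j)`` drawn from the healthy-plasma prior. The block
marginal likelihood integrates the binomial pmf over ``b0``, and the
sample log-likelihood sums the block marginals over the patient panel.

``(alpha, gamma)`` are estimated by constrained maximum likelihood on the
simplex ``alpha >= 0, gamma >= 0, alpha + gamma < 1``; the *timMRD score*
is the Wald statistic for the null hypothesis ``alpha = 0``, compared
against a chi-square(1 df) quantile — 5.412 at the default 98th
percentile. Scores strictly above the threshold call the sample MRD-high.

Numerics
--------
The background integral is evaluated with Gauss-Jacobi quadrature whose
weight function *is* the Beta(p, q) density: after mapping to (0, 1) the
remaining integrand is the binomial pmf, a polynomial of degree N in
``b0``, so the rule of order K is exact for N <= 2K - 1 and remains
accurate for deeper blocks. This also handles shape parameters below 1
(integrable endpoint singularities) without special treatment.
Accumulation is in log-space throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.linalg import eigh_tridiagonal
from scipy.special import betaln, gammaln, logsumexp, xlog1py, xlogy

from .background_prior import BackgroundPrior
from .dmb_selection import PatientPanel
from .errors import ConstraintError, FitError, ValidationError
from .panel_io import BlockCounts

DEFAULT_STARTS: tuple[tuple[float, float], ...] = tuple(
    (a, g) for a in (0.0, 1e-3, 1e-2) for g in (0.0, 0.05, 0.2)
)


@dataclass(frozen=True)
class ScoringOptions:
    """Numerical options for likelihood evaluation and fitting."""

    quad_order: int = 128
    starts: tuple[tuple[float, float], ...] = DEFAULT_STARTS
    tol: float = 1e-9
    percentile: float = 0.98
    eps_simplex: float = 1e-6
    hessian_step: float = 1e-4
    boundary_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.quad_order < 16:
            raise ValidationError("quad_order must be >= 16")
        if not 0.0 < self.percentile < 1.0:
            raise ValidationError("percentile must be in (0, 1)")


@dataclass
class TimmrdFit:
    """Result of deconvolving one plasma sample against a patient panel."""

    alpha_hat: float
    gamma_hat: float
    loglik_full: float
    loglik_null: float
    score: float
    call: str  # high | low
    n_blocks_used: int
    converged: bool
    alpha_se: float | None = None
    sample_id: str | None = None
    patient_id: str | None = None


def mixture_mean(
    alpha: float, gamma: float, beta_t: float, beta_n: float, beta0: float
) -> float:
    """Expected methylation level of the plasma mixture (convex combination)."""
    for name, v in (("alpha", alpha), ("gamma", gamma), ("beta_t", beta_t),
                    ("beta_n", beta_n), ("beta0", beta0)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name}={v} outside [0, 1]")
    if alpha + gamma >= 1.0:
        raise ConstraintError(f"alpha + gamma = {alpha + gamma} must be < 1")
    return alpha * beta_t + gamma * beta_n + (1.0 - alpha - gamma) * beta0


@lru_cache(maxsize=4096)
def _beta_quad_nodes(p: float, q: float, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes on (0,1) and log-weights of the Beta(p, q)-weighted Gauss rule.

    Returns ``(b0_nodes, log_weights)`` such that
    ``E_{b0~Beta(p,q)}[f(b0)] = sum_k exp(log_w_k) * f(b0_k)`` exactly for
    polynomial f of degree <= 2*order - 1.

    Built by Golub-Welsch on the Jacobi-polynomial recurrence for the
    weight (1-x)^(q-1) (1+x)^(p-1) on [-1, 1]. Working directly with the
    normalized measure (weights are squared first eigenvector components,
    summing to 1) keeps the rule overflow-free at arbitrarily large
    concentrations p + q, where textbook Jacobi weight formulas blow up.
    """
    a = q - 1.0  # exponent of (1 - x)
    b = p - 1.0  # exponent of (1 + x)
    n = np.arange(order, dtype=float)
    s = 2.0 * n + a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        diag = (b * b - a * a) / (s * (s + 2.0))
    diag = np.where(np.isfinite(diag), diag, 0.0)  # 0/0 when p = q = 1 at n = 0
    k = np.arange(1, order, dtype=float)
    sk = 2.0 * k + a + b
    off_sq = np.empty(order - 1)
    off_sq[0] = 4.0 * (1.0 + a) * (1.0 + b) / ((2.0 + a + b) ** 2 * (3.0 + a + b))
    if order > 2:
        kk, skk = k[1:], sk[1:]
        off_sq[1:] = (
            4.0 * kk * (kk + a) * (kk + b) * (kk + a + b)
            / (skk**2 * (skk + 1.0) * (skk - 1.0))
        )
    x, vec = eigh_tridiagonal(diag, np.sqrt(off_sq))
    nodes = 0.5 * (x + 1.0)
    # far-tail weights can underflow to exactly 0; they contribute -inf terms
    # that logsumexp ignores, flooring log-pmf accuracy at ~ -70 log-units
    with np.errstate(divide="ignore"):
        logw = 2.0 * np.log(np.abs(vec[0, :]))
    return nodes, logw


def beta_binomial_logpmf(m: int, n: int, p: float, q: float) -> float:
    """Closed-form beta-binomial log-pmf (the alpha = gamma = 0 limit)."""
    return float(
        gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
        + betaln(m + p, n - m + q) - betaln(p, q)
    )


def block_marginal_loglik(
    alpha: float,
    gamma: float,
    n_total: int,
    n_meth: int,
    beta_t: float,
    beta_n: float,
    p: float,
    q: float,
    quad_order: int = 128,
) -> float:
    """Log marginal probability of one block's counts given (alpha, gamma).

    Integrates the binomial pmf over the latent background level
    ``b0 ~ Beta(p, q)`` mapped through the mixture mean. A block with
    N = 0 carries no information and contributes 0.
    """
    if not 0 <= n_meth <= n_total:
        raise ValidationError(f"need 0 <= M <= N, got M={n_meth}, N={n_total}")
    if p <= 0 or q <= 0:
        raise ValidationError("beta shapes must be positive")
    if alpha < 0 or gamma < 0 or alpha + gamma >= 1.0:
        raise ConstraintError(f"infeasible (alpha, gamma) = ({alpha}, {gamma})")
    if n_total == 0:
        return 0.0
    nodes, logw = _beta_quad_nodes(float(p), float(q), int(quad_order))
    beta = alpha * beta_t + gamma * beta_n + (1.0 - alpha - gamma) * nodes
    logc = gammaln(n_total + 1) - gammaln(n_meth + 1) - gammaln(n_total - n_meth + 1)
    logpmf = logc + xlogy(n_meth, beta) + xlog1py(n_total - n_meth, -beta)
    return float(logsumexp(logw + logpmf))


class PanelLikelihood:
    """Pre-assembled likelihood machinery for one patient panel.

    Caches quadrature nodes per block so repeated evaluations (optimizer
    iterations, many samples from the same patient) stay cheap. Arrays are
    laid out blocks x quadrature-nodes.
    """

    def __init__(
        self,
        panel: PatientPanel,
        prior: BackgroundPrior,
        opts: ScoringOptions | None = None,
    ) -> None:
        self.opts = opts or ScoringOptions()
        self.panel = panel
        if panel.m < 1:
            raise ValidationError(f"patient {panel.patient_id}: empty panel")
        missing = [b.block_id for b in panel.blocks if b.block_id not in prior]
        if missing:
            raise ValidationError(
                f"patient {panel.patient_id}: no background prior for blocks "
                + ", ".join(missing[:10])
            )
        order = self.opts.quad_order
        self.block_ids = [b.block_id for b in panel.blocks]
        self.beta_t = np.array([b.beta_t for b in panel.blocks])
        self.beta_n = np.array([b.beta_n for b in panel.blocks])
        nodes_rows, logw_rows = [], []
        for b in panel.blocks:
            e = prior[b.block_id]
            nodes, logw = _beta_quad_nodes(float(e.p), float(e.q), order)
            nodes_rows.append(nodes)
            logw_rows.append(logw)
        self.nodes = np.vstack(nodes_rows)  # (m, K)
        self.logw = np.vstack(logw_rows)  # (m, K)

    # -- per-sample state -------------------------------------------------

    def sample_arrays(self, counts: BlockCounts) -> tuple[np.ndarray, np.ndarray]:
        n = np.array([counts.get(bid)[0] for bid in self.block_ids], dtype=float)
        m = np.array([counts.get(bid)[1] for bid in self.block_ids], dtype=float)
        if np.any(m > n):
            raise ValidationError(f"sample {counts.sample_id}: M > N in counts")
        return n, m

    def loglik_grad(
        self, alpha: float, gamma: float, n: np.ndarray, m: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Sample log-likelihood and its gradient wrt (alpha, gamma)."""
        use = n > 0
        if not np.any(use):
            return 0.0, np.zeros(2)
        t = self.nodes[use]
        logw = self.logw[use]
        bt = self.beta_t[use, None]
        bn = self.beta_n[use, None]
        nn = n[use, None]
        mm = m[use, None]
        beta = alpha * bt + gamma * bn + (1.0 - alpha - gamma) * t
        a = logw + xlogy(mm, beta) + xlog1py(nn - mm, -beta)
        block_ll = logsumexp(a, axis=1)
        soft = np.exp(a - block_ll[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            dlog = mm / beta - (nn - mm) / (1.0 - beta)
        dlog = np.nan_to_num(dlog, nan=0.0, posinf=0.0, neginf=0.0)
        grad_a = float(np.sum(soft * dlog * (bt - t)))
        grad_g = float(np.sum(soft * dlog * (bn - t)))
        logc = gammaln(n[use] + 1) - gammaln(m[use] + 1) - gammaln(n[use] - m[use] + 1)
        return float(np.sum(block_ll + logc)), np.array([grad_a, grad_g])

    def loglik(self, alpha: float, gamma: float, n: np.ndarray, m: np.ndarray) -> float:
        return self.loglik_grad(alpha, gamma, n, m)[0]

    def loglik_grid(
        self, alphas: np.ndarray, gammas: np.ndarray, n: np.ndarray, m: np.ndarray
    ) -> np.ndarray:
        """Vectorized log-likelihood at many (alpha, gamma) points at once."""
        alphas = np.asarray(alphas, dtype=float)
        gammas = np.asarray(gammas, dtype=float)
        total = np.zeros(alphas.shape)
        s = 1.0 - alphas - gammas
        for j in range(len(self.block_ids)):
            if n[j] <= 0:
                continue
            beta = (
                alphas[:, None] * self.beta_t[j]
                + gammas[:, None] * self.beta_n[j]
                + s[:, None] * self.nodes[j][None, :]
            )
            a = self.logw[j][None, :] + xlogy(m[j], beta) + xlog1py(n[j] - m[j], -beta)
            total += logsumexp(a, axis=1)
            total += gammaln(n[j] + 1) - gammaln(m[j] + 1) - gammaln(n[j] - m[j] + 1)
        return total


def total_loglik(
    alpha: float,
    gamma: float,
    panel: PatientPanel,
    counts: BlockCounts,
    prior: BackgroundPrior,
    opts: ScoringOptions | None = None,
) -> float:
    """Sum of block marginal log-likelihoods over the patient panel."""
    if alpha < 0 or gamma < 0 or alpha + gamma >= 1.0:
        raise ConstraintError(f"infeasible (alpha, gamma) = ({alpha}, {gamma})")
    pl = PanelLikelihood(panel, prior, opts)
    n, m = pl.sample_arrays(counts)
    return pl.loglik(alpha, gamma, n, m)


def classification_threshold(percentile: float = 0.98) -> float:
    """Chi-square(1 df) quantile used as the MRD-high score threshold."""
    if not 0.0 < percentile < 1.0:
        raise ValidationError(f"percentile {percentile} must be in (0, 1)")
    return float(stats.chi2.ppf(percentile, df=1))


def classify(score: float, threshold: float) -> str:
    """MRD call: 'high' iff the score strictly exceeds the threshold."""
    if score < 0:
        raise ValidationError(f"score must be non-negative, got {score}")
    return "high" if score > threshold else "low"


def wald_score(
    loglik_fn: Callable[[float, float], float],
    grad_fn: Callable[[float, float], np.ndarray],
    alpha_hat: float,
    gamma_hat: float,
    *,
    step: float = 1e-4,
    boundary_eps: float = 1e-8,
    eps_simplex: float = 1e-6,
) -> tuple[float, float | None]:
    """Wald statistic for H0: alpha = 0 at the MLE.

    Uses the (alpha, alpha) entry of the inverse observed information,
    with the Hessian from central differences of the analytic gradient
    (steps shrunk to stay inside the feasible simplex). Falls back to the
    profile-likelihood curvature in alpha when the information matrix is
    not positive definite. An MLE at the alpha = 0 boundary scores 0 by
    convention. Returns ``(score, alpha_se)``.
    """
    if alpha_hat <= boundary_eps:
        return 0.0, None

    slack = 1.0 - eps_simplex - alpha_hat - gamma_hat
    h_a = min(step, alpha_hat / 2.0, max(slack / 2.0, boundary_eps))
    h_g = min(step, max(gamma_hat / 2.0, step / 10.0), max(slack / 2.0, boundary_eps))

    def central_hess() -> np.ndarray:
        ga_p = grad_fn(alpha_hat + h_a, gamma_hat)
        ga_m = grad_fn(alpha_hat - h_a, gamma_hat)
        gg_p = grad_fn(alpha_hat, gamma_hat + h_g)
        gg_m = grad_fn(alpha_hat, gamma_hat - h_g)
        col_a = (ga_p - ga_m) / (2.0 * h_a)
        col_g = (gg_p - gg_m) / (2.0 * h_g)
        hess = np.array([[col_a[0], col_g[0]], [col_a[1], col_g[1]]])
        return 0.5 * (hess + hess.T)

    hess = central_hess()
    if not np.all(np.isfinite(hess)):
        raise FitError(f"non-finite curvature at MLE ({alpha_hat}, {gamma_hat})")
    info = -hess
    var: float | None = None
    eigs = np.linalg.eigvalsh(info)
    if np.all(eigs > 0):
        v = float(np.linalg.inv(info)[0, 0])
        if np.isfinite(v) and v > 0:
            var = v
    if var is None:
        # profile-likelihood curvature in alpha
        hp = min(1e-3, alpha_hat / 2.0)

        def profile(a: float) -> float:
            res = optimize.minimize_scalar(
                lambda g: -loglik_fn(a, g),
                bounds=(0.0, 1.0 - eps_simplex - a),
                method="bounded",
                options={"xatol": 1e-10},
            )
            return -float(res.fun)

        d2 = (profile(alpha_hat + hp) - 2.0 * profile(alpha_hat)
              + profile(alpha_hat - hp)) / hp**2
        if not np.isfinite(d2) or d2 >= 0:
            raise FitError(
                f"could not estimate Wald variance at ({alpha_hat}, {gamma_hat})"
            )
        var = -1.0 / d2
    return alpha_hat**2 / var, float(np.sqrt(var))


def fit_timmrd(
    panel: PatientPanel,
    counts: BlockCounts,
    prior: BackgroundPrior,
    opts: ScoringOptions | None = None,
) -> TimmrdFit:
    """Constrained MLE of (alpha, gamma) plus Wald score and MRD call.

    Multi-start SLSQP with analytic gradients on the simplex
    ``{alpha >= 0, gamma >= 0, alpha + gamma <= 1 - eps}``; the null
    log-likelihood profiles gamma at alpha = 0. Deterministic for fixed
    inputs and options.
    """
    opts = opts or ScoringOptions()
    pl = PanelLikelihood(panel, prior, opts)
    n, m = pl.sample_arrays(counts)
    n_used = int(np.sum(n > 0))
    if n_used == 0:
        raise ValidationError(
            f"sample {counts.sample_id}: no panel block with coverage"
        )
    eps = opts.eps_simplex

    def neg(x: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = pl.loglik_grad(float(x[0]), float(x[1]), n, m)
        return -ll, -g

    constraint = {
        "type": "ineq",
        "fun": lambda x: 1.0 - eps - x[0] - x[1],
        "jac": lambda x: np.array([-1.0, -1.0]),
    }
    bounds = [(0.0, 1.0 - eps), (0.0, 1.0 - eps)]
    best: optimize.OptimizeResult | None = None
    any_success = False
    for a0, g0 in opts.starts:
        x0 = np.array([min(a0, 1.0 - 2 * eps), min(g0, 1.0 - 2 * eps)])
        if x0.sum() > 1.0 - eps:
            x0 *= (1.0 - 2 * eps) / x0.sum()
        res = optimize.minimize(
            neg, x0, jac=True, method="SLSQP", bounds=bounds,
            constraints=[constraint], options={"maxiter": 200, "ftol": opts.tol},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError(f"sample {counts.sample_id}: optimization failed at all starts")

    alpha_hat = float(np.clip(best.x[0], 0.0, 1.0 - eps))
    gamma_hat = float(np.clip(best.x[1], 0.0, 1.0 - eps))
    if alpha_hat + gamma_hat > 1.0 - eps:
        scale = (1.0 - eps) / (alpha_hat + gamma_hat)
        alpha_hat *= scale
        gamma_hat *= scale
    loglik_full = pl.loglik(alpha_hat, gamma_hat, n, m)

    null_res = optimize.minimize_scalar(
        lambda g: -pl.loglik(0.0, float(g), n, m),
        bounds=(0.0, 1.0 - eps),
        method="bounded",
        options={"xatol": 1e-10},
    )
    loglik_null = -float(null_res.fun)
    if loglik_null > loglik_full:
        # the boundary profile dominates: the MLE is at alpha = 0
        alpha_hat, gamma_hat = 0.0, float(null_res.x)
        loglik_full = loglik_null

    score, alpha_se = wald_score(
        lambda a, g: pl.loglik(a, g, n, m),
        lambda a, g: pl.loglik_grad(a, g, n, m)[1],
        alpha_hat,
        gamma_hat,
        step=opts.hessian_step,
        boundary_eps=opts.boundary_eps,
        eps_simplex=eps,
    )
    threshold = classification_threshold(opts.percentile)
    return TimmrdFit(
        alpha_hat=alpha_hat,
        gamma_hat=gamma_hat,
        loglik_full=loglik_full,
        loglik_null=loglik_null,
        score=score,
        call=classify(score, threshold),
        n_blocks_used=n_used,
        converged=any_success,
        alpha_se=alpha_se,
        sample_id=counts.sample_id,
        patient_id=panel.patient_id,
    )


def grid_oracle_fit(
    panel: PatientPanel,
    counts: BlockCounts,
    prior: BackgroundPrior,
    grid_step: float = 0.005,
    alpha_max: float = 1.0,
    gamma_max: float = 1.0,
    opts: ScoringOptions | None = None,
) -> TimmrdFit:
    """Exhaustive grid maximization of the likelihood (test oracle).

    Evaluates the log-likelihood on the feasible (alpha, gamma) lattice at
    resolution ``grid_step`` and returns the argmax. Intended for small
    panels only; validates :func:`fit_timmrd` in tests.
    """
    opts = opts or ScoringOptions()
    pl = PanelLikelihood(panel, prior, opts)
    n, m = pl.sample_arrays(counts)
    a_vals = np.arange(0.0, min(alpha_max, 1.0) + grid_step / 2, grid_step)
    g_vals = np.arange(0.0, min(gamma_max, 1.0) + grid_step / 2, grid_step)
    aa, gg = np.meshgrid(a_vals, g_vals, indexing="ij")
    feasible = aa + gg <= 1.0 - opts.eps_simplex
    af, gf = aa[feasible], gg[feasible]
    ll = pl.loglik_grid(af, gf, n, m)
    k = int(np.argmax(ll))
    alpha_hat, gamma_hat = float(af[k]), float(gf[k])
    loglik_full = float(ll[k])
    null_mask = af == 0.0
    loglik_null = float(np.max(ll[null_mask]))
    threshold = classification_threshold(opts.percentile)
    score, alpha_se = wald_score(
        lambda a, g: pl.loglik(a, g, n, m),
        lambda a, g: pl.loglik_grad(a, g, n, m)[1],
        alpha_hat,
        gamma_hat,
        step=opts.hessian_step,
        boundary_eps=opts.boundary_eps,
        eps_simplex=opts.eps_simplex,
    )
    return TimmrdFit(
        alpha_hat=alpha_hat,
        gamma_hat=gamma_hat,
        loglik_full=loglik_full,
        loglik_null=loglik_null,
        score=score,
        call=classify(score, threshold),
        n_blocks_used=int(np.sum(n > 0)),
        converged=True,
        alpha_se=alpha_se,
        sample_id=counts.sample_id,
        patient_id=panel.patient_id,
    )


def write_score_table(fits: Sequence[TimmrdFit], path, extra: dict | None = None) -> None:
    """Write fitted sample scores as a TSV, one row per sample."""
    with open(path, "w", encoding="utf-8") as handle:
        if extra:
            for k, v in extra.items():
                handle.write(f"# {k}: {v}\n")
        handle.write(
            "#sample_id\tpatient_id\talpha_hat\tgamma_hat\tscore\tcall\t"
            "n_blocks_used\tconverged\n"
        )
        for f in fits:
            handle.write(
                f"{f.sample_id or ''}\t{f.patient_id or ''}\t{f.alpha_hat:.8g}\t"
                f"{f.gamma_hat:.8g}\t{f.score:.8g}\t{f.call}\t{f.n_blocks_used}\t"
                f"{f.converged}\n"
            )
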