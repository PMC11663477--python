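"""Relevance vector regression: sparse Bayesian linear-kernel regression.

The model places an independent zero-mean Gaussian prior with precision
``alpha_i`` on each basis weight and a Gaussian likelihood with noise
precision ``beta`` on the targets. Hyperparameters are estimated by
maximising the marginal likelihood (evidence) with the classic fixed-point
updates

    Sigma = (diag(alpha) + beta * Phi' Phi)^-1
    mu    = beta * Sigma * Phi' t
    gamma_i = 1 - alpha_i * Sigma_ii
    alpha_i <- gamma_i / mu_i^2
    beta    <- (n - sum_i gamma_i) / ||t - Phi mu||^2

together with the per-basis analytic machinery of the fast
marginal-likelihood method: a constructive start from the best-aligned
basis, add moves for bases whose quality factor warrants (re-)introduction,
deletion of bases whose evidence optimum sits at infinite precision, and
damped, backtracked steps so the recorded evidence path never decreases.
Bases whose precision diverges past ``prune_threshold`` are also removed;
the surviving training samples are the relevance vectors. Targets are
centred before fitting and the mean is restored at prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateModelError, NumericalError, ShapeError

log = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class KernelSpec:
    """Linear-kernel configuration. ``scale=None`` defaults to n_features."""

    kind: str = "linear"
    include_bias: bool = True
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.kind != "linear":
            raise ValueError(f"only the linear kernel is supported, got {self.kind!r}")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("kernel scale must be positive")


@dataclass
class FitSettings:
    """Evidence-maximisation controls.

    ``beta_init=None`` initialises the noise precision at ``1/var(t)``.
    """

    alpha_init: float = 1e-6
    beta_init: float | None = None
    prune_threshold: float = 1e9
    tol: float = 1e-6
    alpha_tol: float = 1e-3
    max_iter: int = 500
    jitter: float = 1e-10
    start_full: bool = False

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class RVRModel:
    """A fitted sparse Bayesian regressor.

    ``active`` indexes the retained columns of the training design matrix
    (column 0 is the bias when present, columns 1..n the kernel bases).
    Feature-space fields (``relevance_vectors``, ``training_feature_means``)
    are populated when the model is trained through
    :func:`anbrainage.brainage.train_brain_age_model`; a bare ``fit_rvr``
    leaves them ``None``.
    """

    weights: np.ndarray
    alphas: np.ndarray
    noise_precision: float
    active: np.ndarray
    posterior_cov: np.ndarray
    target_mean: float
    n_basis_total: int
    converged: bool
    n_iterations: int
    log_evidence_path: np.ndarray
    kernel: KernelSpec | None = None
    relevance_vectors: np.ndarray | None = None
    relevance_indices: np.ndarray | None = None
    training_feature_means: np.ndarray | None = None
    tissue: str | None = None
    has_bias: bool = field(init=False)

    def __post_init__(self) -> None:
        self.has_bias = bool(np.any(self.active == 0)) if self.n_basis_total else False

    @property
    def log_evidence(self) -> float:
        return float(self.log_evidence_path[-1])


def linear_kernel(A: np.ndarray, B: np.ndarray, spec: KernelSpec | None = None) -> np.ndarray:
    """``K[i, j] = (A_i . B_j) / scale``; symmetric when ``A is B``."""
    spec = spec or KernelSpec()
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ShapeError(f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}")
    scale = spec.scale if spec.scale is not None else A.shape[1]
    return A @ B.T / scale


def design_matrix(K: np.ndarray, include_bias: bool = True) -> np.ndarray:
    """Prepend the constant bias column to a kernel matrix."""
    K = np.atleast_2d(K)
    if not include_bias:
        return K
    return np.hstack([np.ones((K.shape[0], 1)), K])


def posterior_stats(Phi: np.ndarray, t: np.ndarray, alphas: np.ndarray, beta: float,
                    jitter: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance of the weights at fixed hyperparameters.

    ``t`` is used as given (no centring); callers centre if they wish.
    """
    Phi = np.atleast_2d(Phi)
    alphas = np.broadcast_to(np.asarray(alphas, dtype=float), (Phi.shape[1],))
    H = np.diag(alphas) + beta * Phi.T @ Phi
    if jitter:
        H = H + jitter * np.eye(H.shape[0])
    try:
        L = np.linalg.cholesky(H)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"posterior precision not positive definite: {exc}") from exc
    Linv = np.linalg.solve(L, np.eye(L.shape[0]))
    Sigma = Linv.T @ Linv
    mu = beta * Sigma @ (Phi.T @ t)
    return mu, Sigma


def log_marginal_likelihood(Phi: np.ndarray, t: np.ndarray, alphas: np.ndarray,
                            beta: float) -> float:
    """Gaussian evidence log p(t | alpha, beta) = -1/2 [n log 2pi + log|C| + t' C^-1 t].

    Evaluated through the weight-space precision ``H = diag(alpha) + beta Phi'Phi``
    using the matrix determinant and inversion lemmas, which keeps the cost at
    O(m^3) in the number of bases.
    """
    Phi = np.atleast_2d(Phi)
    n, m = Phi.shape
    alphas = np.broadcast_to(np.asarray(alphas, dtype=float), (m,))
    H = np.diag(alphas) + beta * Phi.T @ Phi
    try:
        L = np.linalg.cholesky(H)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"evidence evaluation failed: {exc}") from exc
    logdet_H = 2.0 * np.sum(np.log(np.diag(L)))
    logdet_C = logdet_H - np.sum(np.log(alphas)) - n * np.log(beta)
    mu = beta * np.linalg.solve(H, Phi.T @ t)
    quad = beta * (t @ t - t @ (Phi @ mu))
    return float(-0.5 * (n * LOG2PI + logdet_C + quad))


def fit_rvr(Phi: np.ndarray, t: np.ndarray, settings: FitSettings | None = None) -> RVRModel:
    """Fit the sparse Bayesian regression by evidence maximisation.

    ``Phi`` is the full training design matrix (kernel columns plus optional
    bias column that the caller already prepended). Raises
    :class:`DegenerateModelError` if every basis is pruned and
    :class:`NumericalError` on non-finite evidence.
    """
    settings = settings or FitSettings()
    Phi = np.atleast_2d(np.asarray(Phi, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    n, m = Phi.shape
    if n < 2:
        raise ValueError("need at least two training samples")
    if t.shape[0] != n:
        raise ShapeError(f"{n} rows in Phi but {t.shape[0]} targets")
    if not np.all(np.isfinite(t)):
        raise ValueError("targets must be finite")

    target_mean = float(t.mean())
    tc = t - target_mean
    var_t = float(tc @ tc / n)
    if var_t < 1e-24:
        # constant targets: every centred basis weight is zero, so the model
        # reduces to the bias (target mean) alone
        beta = settings.beta_init if settings.beta_init is not None else 1e12
        logL = -0.5 * n * (LOG2PI - np.log(beta))
        return RVRModel(
            weights=np.empty(0), alphas=np.empty(0), noise_precision=float(beta),
            active=np.empty(0, dtype=int), posterior_cov=np.empty((0, 0)),
            target_mean=target_mean, n_basis_total=m, converged=True,
            n_iterations=0, log_evidence_path=np.asarray([logL]),
        )
    beta = settings.beta_init if settings.beta_init is not None else 1.0 / var_t

    if settings.start_full:
        # flat start: every basis in the model at alpha_init
        active = np.arange(m)
        alphas = np.full(m, settings.alpha_init, dtype=float)
    else:
        # constructive start: the single best-aligned basis at its per-basis
        # evidence optimum; further bases enter through the add move. The
        # full start tends to settle in a dense local optimum of the
        # evidence, the constructive start in the sparse one.
        norms = np.einsum("ij,ij->j", Phi, Phi)
        with np.errstate(divide="ignore", invalid="ignore"):
            align = (Phi.T @ tc) ** 2 / np.maximum(norms, 1e-300)
        j0 = int(np.argmax(align))
        S0 = beta * norms[j0]
        Q0 = beta * float(Phi[:, j0] @ tc)
        theta0 = Q0 ** 2 - S0
        a0 = S0 ** 2 / theta0 if theta0 > 0 else max(settings.alpha_init, 1.0)
        active = np.asarray([j0])
        alphas = np.asarray([min(a0, settings.prune_threshold / 10)])
    mu, Sigma = posterior_stats(Phi[:, active], tc, alphas, beta,
                                jitter=settings.jitter)
    logL = log_marginal_likelihood(Phi[:, active], tc, alphas, beta)
    if not np.isfinite(logL):
        raise NumericalError("non-finite evidence at initialisation")
    evidence_path: list[float] = [logL]
    converged = False

    def relevance_factors(active, alphas, beta, mu, Sigma):
        """Per-basis sparsity/quality factors (s_i, q_i) of the evidence.

        With basis i's own contribution removed from the posterior, the
        evidence as a function of alpha_i alone is maximised at
        ``s_i^2 / (q_i^2 - s_i)`` when ``q_i^2 > s_i`` and at infinity
        (basis irrelevant) otherwise. The factors are only well determined
        once alpha_i has moved clearly off the flat initialisation
        (``alpha_i - S_i`` away from zero); other bases are flagged
        undecided.
        """
        Phi_a = Phi[:, active]
        proj = Phi_a @ (Sigma @ (Phi_a.T @ Phi_a))  # n x k
        col_sq = np.einsum("ij,ij->j", Phi_a, Phi_a)
        S = beta * col_sq - beta ** 2 * np.einsum("ij,ij->j", Phi_a, proj)
        Q = beta * (Phi_a.T @ tc) - beta ** 2 * (proj.T @ tc)
        denom = alphas - S
        decisive = denom > 0.1 * alphas
        s = np.where(decisive, alphas * S / np.where(decisive, denom, 1.0), 0.0)
        q = np.where(decisive, alphas * Q / np.where(decisive, denom, 1.0), 1.0)
        return s, q, decisive

    def relevance_prune(active, alphas, beta, mu, Sigma, logL):
        """Delete bases whose per-basis evidence optimum is at alpha = inf."""
        s, q, decisive = relevance_factors(active, alphas, beta, mu, Sigma)
        keep = ~(decisive & ((q ** 2 - s) <= 0))
        if keep.all() or not keep.any():
            return active, alphas, mu, Sigma, logL
        new_active = active[keep]
        new_alphas = alphas[keep]
        n_mu, n_Sigma = posterior_stats(Phi[:, new_active], tc, new_alphas, beta,
                                        jitter=settings.jitter)
        n_logL = log_marginal_likelihood(Phi[:, new_active], tc, new_alphas, beta)
        if not np.isfinite(n_logL) or n_logL < logL - 1e-12 * max(abs(logL), 1.0):
            return active, alphas, mu, Sigma, logL  # numerics disagree: keep
        return new_active, new_alphas, n_mu, n_Sigma, n_logL

    def evaluate(t_active, t_alphas, t_beta, iteration):
        t_mu, t_Sigma = posterior_stats(Phi[:, t_active], tc, t_alphas, t_beta,
                                        jitter=settings.jitter)
        t_logL = log_marginal_likelihood(Phi[:, t_active], tc, t_alphas, t_beta)
        if not np.isfinite(t_logL):
            raise NumericalError(
                f"non-finite evidence at iteration {iteration}; "
                f"path so far: {evidence_path[-5:]}"
            )
        return t_mu, t_Sigma, t_logL

    alpha_settled = False  # alpha criterion met on the previous iteration
    for iteration in range(1, settings.max_iter + 1):
        active, alphas, mu, Sigma, logL = relevance_prune(
            active, alphas, beta, mu, Sigma, logL)
        slack = 1e-12 * max(abs(logL), 1.0)

        # alpha proposals: the analytic per-basis evidence optimum
        # s^2/(q^2 - s) where the relevance factors are decisive, and the
        # gamma/mu^2 fixed point otherwise; beta from its fixed point
        gamma = np.clip(1.0 - alphas * np.diag(Sigma), 1e-12, None)
        mu_sq = mu ** 2
        prop_alphas = np.where(mu_sq > 1e-300, gamma / np.maximum(mu_sq, 1e-300), np.inf)
        s, q, decisive = relevance_factors(active, alphas, beta, mu, Sigma)
        theta = q ** 2 - s
        analytic = decisive & (theta > 0) & (s > 0)
        prop_alphas = np.where(analytic,
                               s ** 2 / np.where(analytic, theta, 1.0),
                               prop_alphas)
        resid = tc - Phi[:, active] @ mu
        prop_beta = float((n - gamma.sum()) / max(float(resid @ resid), 1e-300))
        prop_beta = min(max(prop_beta, 1e-12), 1e12)

        # phase 1: alpha step, backtracked in log space so every recorded
        # evidence value corresponds to an accepted (non-decreasing) move
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            log_ratio = np.log(prop_alphas) - np.log(alphas)
        alpha_step = 0.0
        delta_log_alpha = 0.0
        step = 1.0
        for _ in range(8):
            trial_alphas = alphas * np.exp(step * log_ratio)
            keep = trial_alphas < settings.prune_threshold
            if not keep.any():
                raise DegenerateModelError("all bases pruned during evidence maximisation")
            t_mu, t_Sigma, t_logL = evaluate(active[keep], trial_alphas[keep],
                                             beta, iteration)
            if t_logL >= logL - slack:
                delta_log_alpha = float(np.max(np.abs(
                    np.clip(step * log_ratio[keep], -50, 50))))
                active, alphas = active[keep], trial_alphas[keep]
                mu, Sigma, logL = t_mu, t_Sigma, t_logL
                alpha_step = step
                break
            step *= 0.5
        if alpha_step == 0.0 and not decisive.all():
            # sharpening move: the flat-prior plateau leaves most relevance
            # factors undecided and the joint fixed-point direction can point
            # downhill; raising undecided precisions a decade costs nothing
            # along these flat directions and makes the factors decisive
            trial_alphas = np.where(decisive, alphas, alphas * 10.0)
            t_mu, t_Sigma, t_logL = evaluate(active, trial_alphas, beta, iteration)
            if t_logL >= logL - slack:
                alphas = trial_alphas
                mu, Sigma, logL = t_mu, t_Sigma, t_logL
                alpha_step = 1.0
                delta_log_alpha = np.log(10.0)

        # re-introduction move: a previously pruned basis whose quality
        # factor q^2 now exceeds its sparsity factor S would increase the
        # evidence if added back at its per-basis optimum alpha = S^2/(q^2-S)
        added = False
        inactive = np.setdiff1d(np.arange(m), active, assume_unique=False)
        if len(inactive):
            Phi_a = Phi[:, active]
            Phi_i = Phi[:, inactive]
            proj = Phi_a @ (Sigma @ (Phi_a.T @ Phi_i))  # n x n_inactive
            S_out = beta * np.einsum("ij,ij->j", Phi_i, Phi_i) \
                - beta ** 2 * np.einsum("ij,ij->j", Phi_i, proj)
            Q_out = beta * (Phi_i.T @ tc) - beta ** 2 * (proj.T @ tc)
            theta_out = Q_out ** 2 - S_out
            ok = (theta_out > 0) & (S_out > 1e-12)
            if ok.any():
                with np.errstate(divide="ignore", invalid="ignore"):
                    gain = np.where(
                        ok,
                        0.5 * ((Q_out ** 2 - S_out) / S_out
                               + np.log(S_out / Q_out ** 2)),
                        -np.inf,
                    )
                j = int(np.argmax(gain))
                if gain[j] > settings.tol * max(abs(logL), 1.0):
                    cand = int(inactive[j])
                    new_active = np.append(active, cand)
                    new_alphas = np.append(alphas, S_out[j] ** 2 / theta_out[j])
                    t_mu, t_Sigma, t_logL = evaluate(new_active, new_alphas,
                                                     beta, iteration)
                    if t_logL > logL + slack:  # adds must strictly improve
                        order = np.argsort(new_active)
                        active = new_active[order]
                        alphas = new_alphas[order]
                        mu, Sigma, logL = (t_mu[order],
                                           t_Sigma[np.ix_(order, order)], t_logL)
                        added = True

        # phase 2: beta step, backtracked independently. Updating beta every
        # iteration lets the noise precision run away to the non-sparse
        # interpolation optimum before pruning can act, so it moves on a
        # slower clock than the alphas (standard sparse-Bayes practice) and
        # is forced whenever the alphas look settled
        beta_due = (iteration % 4 == 0) or alpha_step == 0.0 or alpha_settled
        beta_step = 0.0
        beta_change = 0.0
        if beta_due:
            step = 1.0
            for _ in range(8):
                trial_beta = beta * (prop_beta / beta) ** step
                t_mu, t_Sigma, t_logL = evaluate(active, alphas, trial_beta, iteration)
                if t_logL >= logL - slack:
                    beta_change = abs(np.log(trial_beta) - np.log(beta))
                    beta = trial_beta
                    mu, Sigma, logL = t_mu, t_Sigma, t_logL
                    beta_step = step
                    break
                step *= 0.5

        prev = evidence_path[-1]
        evidence_path.append(logL)
        if alpha_step == 0.0 and not added and beta_due and beta_step == 0.0:
            converged = True  # no ascent direction left at this resolution
            break
        rel = abs(logL - prev) / max(abs(prev), 1.0)
        alpha_settled = (rel < settings.tol
                         and delta_log_alpha < settings.alpha_tol
                         and not added)
        if alpha_settled and beta_due and beta_change < settings.alpha_tol:
            converged = True
            break

    model = RVRModel(
        weights=mu,
        alphas=alphas,
        noise_precision=float(beta),
        active=active,
        posterior_cov=Sigma,
        target_mean=target_mean,
        n_basis_total=m,
        converged=converged,
        n_iterations=len(evidence_path),
        log_evidence_path=np.asarray(evidence_path),
    )
    if not converged:
        log.info("fit_rvr stopped at max_iter=%d without meeting tol", settings.max_iter)
    return model


def predict_rvr(model: RVRModel, Phi_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance for rows of ``Phi_test``.

    ``Phi_test`` may carry either the full training basis set (columns are
    subset to the retained bases) or exactly the retained columns in model
    order.
    """
    Phi_test = np.atleast_2d(np.asarray(Phi_test, dtype=float))
    k = len(model.active)
    if Phi_test.shape[1] == model.n_basis_total and model.n_basis_total != k:
        Phi_a = Phi_test[:, model.active]
    elif Phi_test.shape[1] == k:
        Phi_a = Phi_test
    else:
        raise ShapeError(
            f"Phi_test has {Phi_test.shape[1]} columns; expected {model.n_basis_total} (full) "
            f"or {k} (retained)"
        )
    mean = Phi_a @ model.weights + model.target_mean
    var = 1.0 / model.noise_precision + np.einsum(
        "ij,jk,ik->i", Phi_a, model.posterior_cov, Phi_a
    )
    return mean, var
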