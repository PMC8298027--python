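"""Average-information REML for univariate and bivariate animal models.

Model (univariate):  y = X b + g + e,  g ~ N(0, K sa2),  e ~ N(0, I se2),
with K any relationship matrix (genomic G or pedigree A).  The restricted
likelihood is maximized by Newton-type updates using the average-information
(AI) matrix, with EM steps as warm-up and as a fallback whenever an AI
update would leave the parameter space.  Variances are floored at a small
fraction of the phenotypic variance; boundary hits are flagged.

The bivariate model stacks the two trait records; the genetic covariance
acts through the relationship matrix between the two (possibly unequal)
sample sets, while the residual covariance applies only to records taken on
the same animal (missing-at-random treatment of partially observed pairs).

Standard errors come from the inverse AI matrix at the optimum, with the
delta method for heritability h2 = sa2 / (sa2 + se2) and the genetic
correlation r_g = cov_a / sqrt(sa2_1 * sa2_2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .kinship import RelationshipMatrix
from .traits import DesignMatrix

logger = logging.getLogger(__name__)


@dataclass
class REMLOptions:
    max_iter: int = 100
    tol_loglik: float = 1e-6     # |change in restricted logL|
    tol_param: float = 1e-5      # max relative parameter change
    floor_frac: float = 1e-6     # variance floor as a fraction of var(y)
    n_em_warmup: int = 2         # EM iterations before switching to AI
    algorithm: str = "ai"        # "ai" (EM warmup + AI) or "em" (pure EM)


@dataclass
class VarianceComponents:
    """Estimated (co)variance components of a one- or two-trait animal model.

    ``sigma2_a``/``sigma2_e`` hold one entry per trait; ``cov_a``/``cov_e``
    are set only for bivariate fits.  ``param_cov`` is the inverse AI matrix
    in the parameter order sigma2_a + [cov_a] + sigma2_e + [cov_e] for the
    bivariate case and (sigma2_a, sigma2_e) for the univariate case.
    """

    traits: list
    kinship_kind: str
    sigma2_a: np.ndarray
    sigma2_e: np.ndarray
    cov_a: float | None = None
    cov_e: float | None = None
    param_cov: np.ndarray | None = None
    loglik: float = np.nan
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    identifiable: bool = True
    boundary: bool = False
    n_iter: int = 0

    @property
    def sigma2_p(self) -> np.ndarray:
        return self.sigma2_a + self.sigma2_e

    @property
    def h2(self) -> np.ndarray:
        return self.sigma2_a / self.sigma2_p

    @property
    def r_g(self) -> float:
        if self.cov_a is None:
            raise ValueError("r_g is defined only for bivariate fits")
        return float(self.cov_a / np.sqrt(self.sigma2_a[0] * self.sigma2_a[1]))

    @property
    def lambda_(self) -> float:
        """Shrinkage ratio se2/sa2 (univariate) for the mixed-model equations."""
        if len(self.sigma2_a) != 1:
            raise ValueError("lambda_ is defined for univariate fits")
        return float(self.sigma2_e[0] / self.sigma2_a[0])


def heritability(vc: VarianceComponents, trait: int = 0) -> tuple:
    """(h2, SE) for one trait, SE by the delta method from the AI inverse."""
    a, e = vc.sigma2_a[trait], vc.sigma2_e[trait]
    sp = a + e
    if sp <= 0:
        raise ValueError("phenotypic variance is zero")
    h2 = a / sp
    se = np.nan
    if vc.param_cov is not None:
        T = len(vc.sigma2_a)
        if T == 1:
            ia, ie = 0, 1
        else:  # parameter order: a11, a12, a22, e11, e12, e22
            ia = 0 if trait == 0 else 2
            ie = 3 if trait == 0 else 5
        grad = np.zeros(vc.param_cov.shape[0])
        grad[ia] = e / sp ** 2
        grad[ie] = -a / sp ** 2
        var = float(grad @ vc.param_cov @ grad)
        se = float(np.sqrt(max(var, 0.0)))
    return float(h2), se


def genetic_correlation(vc: VarianceComponents) -> tuple:
    """(r_g, SE) from a bivariate fit, SE by the delta method."""
    r = vc.r_g
    a1, a2, c = vc.sigma2_a[0], vc.sigma2_a[1], vc.cov_a
    se = np.nan
    if vc.param_cov is not None:
        grad = np.zeros(vc.param_cov.shape[0])
        grad[0] = -r / (2 * a1)      # d r / d a11
        grad[1] = 1.0 / np.sqrt(a1 * a2)  # d r / d a12
        grad[2] = -r / (2 * a2)      # d r / d a22
        var = float(grad @ vc.param_cov @ grad)
        se = float(np.sqrt(max(var, 0.0)))
    return float(r), se


# ---------------------------------------------------------------------------
# generic AI-REML driver
# ---------------------------------------------------------------------------

class _Structure:
    """Variance structure: builds V(theta) and the derivative actions.

    Subclasses supply ``build_V``, ``trace_P_Vi`` (computed from P blocks by
    elementwise products, never forming P Vi), ``Vi_dot`` and the parameter
    constraint ``project``.
    """

    theta0: np.ndarray
    n: int

    def build_V(self, theta): ...
    def trace_P_Vi(self, P, i): ...
    def Vi_dot(self, theta_index, w): ...
    def valid(self, theta) -> bool: ...
    def project(self, theta) -> np.ndarray: ...


def _ai_reml(y, X, struct, opts: REMLOptions):
    n, p = X.shape
    theta = struct.theta0.copy()
    n_par = len(theta)
    loglik_trace = []
    prev_ll = -np.inf
    converged = False
    identifiable = True
    AI = np.eye(n_par)
    it = 0

    for it in range(1, opts.max_iter + 1):
        V = struct.build_V(theta)
        try:
            cf = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            V = V + 1e-8 * np.trace(V) / n * np.eye(n)
            cf = cho_factor(V, lower=True)
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vinv = cho_solve(cf, np.eye(n))
        W = Vinv @ X
        XtVX = X.T @ W
        logdetX = np.linalg.slogdet(XtVX)[1]
        P = Vinv - W @ np.linalg.solve(XtVX, W.T)
        P = 0.5 * (P + P.T)
        w = P @ y
        ll = -0.5 * (logdetV + logdetX + float(y @ w))
        loglik_trace.append(ll)

        u = [struct.Vi_dot(i, w) for i in range(n_par)]
        grad = np.array([-0.5 * struct.trace_P_Vi(P, i) + 0.5 * float(w @ u[i])
                         for i in range(n_par)])
        Pu = [P @ ui for ui in u]
        AI = 0.5 * np.array([[float(u[i] @ Pu[j]) for j in range(n_par)]
                             for i in range(n_par)])
        AI = 0.5 * (AI + AI.T)

        d_ll = ll - prev_ll
        if it > 1 and abs(d_ll) < opts.tol_loglik:
            converged = True
            break
        prev_ll = ll

        use_em = opts.algorithm == "em" or it <= opts.n_em_warmup
        if use_em:
            theta_new = struct.project(theta + theta ** 2 * 2.0 * grad / n)
        else:
            cond = np.linalg.cond(AI)
            if not np.isfinite(cond) or cond > 1e10:
                identifiable = False
                delta = np.linalg.pinv(AI) @ grad
            else:
                delta = np.linalg.solve(AI, grad)
            step = 1.0
            theta_new = None
            for _ in range(30):
                cand = theta + step * delta
                if struct.valid(cand):
                    theta_new = cand
                    break
                step *= 0.5
            if theta_new is None:
                # AI direction unusable from this point: fall back to EM
                theta_new = struct.project(theta + theta ** 2 * 2.0 * grad / n)
        theta_new = struct.project(theta_new)
        param_change = np.max(np.abs(theta_new - theta) / (np.abs(theta) + 1e-12))
        theta = theta_new
        if param_change < opts.tol_param and it > opts.n_em_warmup:
            converged = True
            # one more pass will recompute ll/AI at the final point
    else:
        logger.warning("AI-REML did not converge in %d iterations", opts.max_iter)

    param_cov = np.linalg.pinv(AI)
    if np.linalg.cond(AI) > 1e10:
        identifiable = False
    return theta, loglik_trace, converged, identifiable, param_cov, it


# ---------------------------------------------------------------------------
# univariate
# ---------------------------------------------------------------------------

class _UnivariateStructure(_Structure):
    def __init__(self, K, n, var_y, floor_frac):
        self.K = K
        self.n = n
        self.floor = floor_frac * var_y
        self.theta0 = np.array([var_y / 2.0, var_y / 2.0])

    def build_V(self, th):
        return th[0] * self.K + th[1] * np.eye(self.n)

    def trace_P_Vi(self, P, i):
        return float(np.sum(P * self.K)) if i == 0 else float(np.trace(P))

    def Vi_dot(self, i, w):
        return self.K @ w if i == 0 else w

    def valid(self, th):
        return th[0] >= self.floor and th[1] >= self.floor

    def project(self, th):
        return np.maximum(th, self.floor)


def reml_univariate(dm: DesignMatrix, K: RelationshipMatrix,
                    options: REMLOptions | None = None) -> VarianceComponents:
    """AI-REML fit of the single-trait animal model.

    The relationship matrix is subset internally to the phenotyped samples
    of ``dm``.  Non-convergence returns the last iterate flagged
    ``converged=False``; an unidentifiable variance split (e.g. K = I, where
    genetic and residual effects are indistinguishable) is flagged
    ``identifiable=False``.
    """
    opts = options or REMLOptions()
    y, X = dm.y, dm.X
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"too few records (n={n}) for {p} fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is singular; rebuild with build_design")
    Ksub = K.subset(dm.sample_ids).values

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    var_y = float(resid @ resid / max(n - p, 1))
    struct = _UnivariateStructure(Ksub, n, var_y, opts.floor_frac)

    theta, trace, converged, ident, pcov, n_iter = _ai_reml(y, X, struct, opts)
    boundary = bool(np.any(theta <= struct.floor * (1 + 1e-9)))
    if boundary:
        logger.info("variance component at the floor: theta=%s", theta)
    return VarianceComponents(
        traits=[dm.trait], kinship_kind=K.kind,
        sigma2_a=np.array([theta[0]]), sigma2_e=np.array([theta[1]]),
        param_cov=pcov, loglik=trace[-1], loglik_trace=trace,
        converged=converged, identifiable=ident, boundary=boundary,
        n_iter=n_iter)


# ---------------------------------------------------------------------------
# bivariate
# ---------------------------------------------------------------------------

class _BivariateStructure(_Structure):
    """Stacked two-trait structure with overlap-aware residual covariance.

    Parameter order: (a11, a12, a22, e11, e12, e22).
    """

    def __init__(self, K11, K12, K22, S12, theta0, floors):
        self.K11, self.K12, self.K22, self.S12 = K11, K12, K22, S12
        self.n1, self.n2 = K11.shape[0], K22.shape[0]
        self.n = self.n1 + self.n2
        self.theta0 = theta0
        self.var_floor = floors  # (floor1, floor2)

    def build_V(self, th):
        a11, a12, a22, e11, e12, e22 = th
        V = np.empty((self.n, self.n))
        V[:self.n1, :self.n1] = a11 * self.K11 + e11 * np.eye(self.n1)
        V[self.n1:, self.n1:] = a22 * self.K22 + e22 * np.eye(self.n2)
        V12 = a12 * self.K12 + e12 * self.S12
        V[:self.n1, self.n1:] = V12
        V[self.n1:, :self.n1] = V12.T
        return V

    def _blocks(self, P):
        return (P[:self.n1, :self.n1], P[:self.n1, self.n1:],
                P[self.n1:, self.n1:])

    def trace_P_Vi(self, P, i):
        P11, P12, P22 = self._blocks(P)
        if i == 0:
            return float(np.sum(P11 * self.K11))
        if i == 1:
            return 2.0 * float(np.sum(P12 * self.K12))
        if i == 2:
            return float(np.sum(P22 * self.K22))
        if i == 3:
            return float(np.trace(P11))
        if i == 4:
            return 2.0 * float(np.sum(P12 * self.S12))
        return float(np.trace(P22))

    def Vi_dot(self, i, w):
        w1, w2 = w[:self.n1], w[self.n1:]
        out = np.zeros_like(w)
        if i == 0:
            out[:self.n1] = self.K11 @ w1
        elif i == 1:
            out[:self.n1] = self.K12 @ w2
            out[self.n1:] = self.K12.T @ w1
        elif i == 2:
            out[self.n1:] = self.K22 @ w2
        elif i == 3:
            out[:self.n1] = w1
        elif i == 4:
            out[:self.n1] = self.S12 @ w2
            out[self.n1:] = self.S12.T @ w1
        else:
            out[self.n1:] = w2
        return out

    def valid(self, th):
        a11, a12, a22, e11, e12, e22 = th
        f1, f2 = self.var_floor
        if a11 < f1 or a22 < f2 or e11 < f1 or e22 < f2:
            return False
        bound = 1.0 - 1e-6
        return (a12 ** 2 <= bound * a11 * a22
                and e12 ** 2 <= bound * e11 * e22)

    def project(self, th):
        a11, a12, a22, e11, e12, e22 = th
        f1, f2 = self.var_floor
        a11, e11 = max(a11, f1), max(e11, f1)
        a22, e22 = max(a22, f2), max(e22, f2)
        bound = 1.0 - 1e-6
        lim_a = np.sqrt(bound * a11 * a22)
        lim_e = np.sqrt(bound * e11 * e22)
        if abs(a12) > lim_a:
            logger.info("genetic covariance projected onto the PD boundary")
            a12 = np.sign(a12) * lim_a
        e12 = np.clip(e12, -lim_e, lim_e)
        return np.array([a11, a12, a22, e11, e12, e22])


def reml_bivariate(dm1: DesignMatrix, dm2: DesignMatrix, K: RelationshipMatrix,
                   options: REMLOptions | None = None) -> VarianceComponents:
    """AI-REML fit of the two-trait animal model.

    The two traits may be observed on overlapping but unequal sample sets;
    the residual covariance contributes only where the same animal carries
    both records.  Returns per-trait components plus the genetic and
    residual covariances (r_g via :func:`genetic_correlation`).
    """
    opts = options or REMLOptions()
    idx1 = K.align(dm1.sample_ids)
    idx2 = K.align(dm2.sample_ids)
    Kv = K.values
    K11 = Kv[np.ix_(idx1, idx1)]
    K12 = Kv[np.ix_(idx1, idx2)]
    K22 = Kv[np.ix_(idx2, idx2)]
    S12 = (idx1[:, None] == idx2[None, :]).astype(float)

    y = np.concatenate([dm1.y, dm2.y])
    n1, p1 = dm1.X.shape
    n2, p2 = dm2.X.shape
    X = np.zeros((n1 + n2, p1 + p2))
    X[:n1, :p1] = dm1.X
    X[n1:, p1:] = dm2.X

    floors, starts = [], []
    for dm in (dm1, dm2):
        resid = dm.y - dm.X @ np.linalg.lstsq(dm.X, dm.y, rcond=None)[0]
        v = float(resid @ resid / max(dm.n - dm.X.shape[1], 1))
        floors.append(opts.floor_frac * v)
        starts.append(v / 2.0)
    theta0 = np.array([starts[0], 0.0, starts[1], starts[0], 0.0, starts[1]])
    struct = _BivariateStructure(K11, K12, K22, S12, theta0, tuple(floors))

    theta, trace, converged, ident, pcov, n_iter = _ai_reml(y, X, struct, opts)
    a11, a12, a22, e11, e12, e22 = theta
    boundary = bool(a12 ** 2 >= (1 - 1e-5) * a11 * a22
                    or a11 <= floors[0] * (1 + 1e-9)
                    or a22 <= floors[1] * (1 + 1e-9))
    return VarianceComponents(
        traits=[dm1.trait, dm2.trait], kinship_kind=K.kind,
        sigma2_a=np.array([a11, a22]), sigma2_e=np.array([e11, e22]),
        cov_a=float(a12), cov_e=float(e12),
        param_cov=pcov, loglik=trace[-1], loglik_trace=trace,
        converged=converged, identifiable=ident, boundary=boundary,
        n_iter=n_iter)
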