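"""Maximum-likelihood detection of heritable variation in PC scores.

For one principal component with scores y, centroid sizes s and relatedness
matrix K, the model is

    y ~ MVN(beta * s + mu0,  sigma2 * (h2 * K + (1 - h2) * I))

i.e. a single-variance-component animal model on the PC axis, with a linear
allometric mean. The null hypothesis h2 = 0 is tested against h2 > 0 with a
likelihood-ratio statistic lambda = 2 (L_A - L_0). Because h2 = 0 lies on
the boundary of the parameter space, lambda is referred to the 50:50 mixture
of a point mass at zero and chi-squared with 1 df.

The likelihood is evaluated in the eigenbasis of K, computed once, so each
(h2, nuisance) evaluation is O(n); for fixed h2 the nuisance parameters
(beta, mu0, sigma2) have closed-form GLS/ML solutions, leaving a 1-D profile
likelihood in h2 maximized deterministically on [0, 1 - 1e-6].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinship import KinshipMatrix

__all__ = [
    "HeritabilityModel",
    "HeritabilityResults",
    "mixture_pvalue",
    "neg_log_likelihood",
    "fit_heritability",
    "test_top_pcs",
]

H2_MAX = 1.0 - 1e-6
_LAMBDA_CLIP = 1e-6
_LOG2PI = float(np.log(2.0 * np.pi))


def mixture_pvalue(lam: float) -> float:
    """P-value of the boundary LRT statistic under the 1/2 chi2_0 + 1/2 chi2_1
    mixture: p = 1 when lambda = 0, else p = 0.5 * P(chi2_1 >= lambda)."""
    if lam < -_LAMBDA_CLIP:
        raise ValueError(f"negative LRT statistic {lam}")
    lam = max(float(lam), 0.0)
    if lam == 0.0:
        return 1.0
    return float(0.5 * stats.chi2.sf(lam, df=1))


@dataclass
class HeritabilityResults:
    """ML fit of the heritability model on one PC, with its boundary LRT."""

    pc_index: int
    h2: float
    h2_se: float
    beta: float
    mu0: float
    sigma2: float
    loglik_null: float
    loglik_alt: float
    lrt: float
    pvalue: float
    alpha_per_test: float
    significant: bool
    nobs: int

    # kept for diagnostics
    beta_null: float = np.nan
    mu0_null: float = np.nan
    sigma2_null: float = np.nan

    def summary(self) -> str:
        lines = [
            f"Heritability LRT — PC{self.pc_index} (n = {self.nobs})",
            "-" * 48,
            f"  h2        {self.h2:10.4f}   (SE {self.h2_se:.4f})",
            f"  beta      {self.beta:10.4g}",
            f"  mu0       {self.mu0:10.4g}",
            f"  sigma2    {self.sigma2:10.4g}",
            f"  logL(h2=0) {self.loglik_null:9.3f}",
            f"  logL(alt)  {self.loglik_alt:9.3f}",
            f"  lambda    {self.lrt:10.4f}",
            f"  p (chi2_0:chi2_1 mixture) {self.pvalue:.4g}",
            f"  significant at alpha = {self.alpha_per_test:g}: "
            f"{'yes' if self.significant else 'no'}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "pc": self.pc_index, "h2": self.h2, "h2_se": self.h2_se,
            "beta": self.beta, "mu0": self.mu0, "sigma2": self.sigma2,
            "loglik_null": self.loglik_null, "loglik_alt": self.loglik_alt,
            "lambda": self.lrt, "pvalue": self.pvalue,
            "alpha_per_test": self.alpha_per_test,
            "significant": self.significant,
        }


class HeritabilityModel:
    """Animal-model likelihood for one PC's scores.

    Parameters
    ----------
    scores : (n,) PC scores.
    sizes : (n,) centroid sizes entering the allometric mean.
    kinship : KinshipMatrix or (n, n) array, ordered like the scores.
    pc_index : 1-based label used in reports.
    """

    def __init__(self, scores, sizes, kinship, pc_index: int = 1,
                 _eig: Optional[Tuple[np.ndarray, np.ndarray]] = None):
        self.y = np.asarray(scores, dtype=float).ravel()
        self.sizes = np.asarray(sizes, dtype=float).ravel()
        self.n = self.y.size
        if self.sizes.size != self.n:
            raise ValueError("scores and sizes differ in length")
        K = kinship.K if isinstance(kinship, KinshipMatrix) else np.asarray(kinship, float)
        if K.shape != (self.n, self.n):
            raise ValueError("kinship matrix does not match the number of scores")
        if self.n < 2:
            raise ValueError("need at least 2 observations")
        self.pc_index = int(pc_index)
        if _eig is None:
            evals, evecs = np.linalg.eigh(K)
            evals = np.clip(evals, 0.0, None)  # K is PSD up to round-off
        else:
            evals, evecs = _eig
        self._evals = evals
        self._evecs = evecs
        # one-time rotation into the eigenbasis of K
        self._yt = evecs.T @ self.y
        X = np.column_stack([self.sizes, np.ones(self.n)])
        self._Xt = evecs.T @ X

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, kinship,
                       score_col: str = "score", size_col: str = "size",
                       id_col: str = "specimen_id", **kwargs) -> "HeritabilityModel":
        """Build from a tidy frame; the kinship matrix is reordered to the
        frame's specimen order when it carries ids."""
        if isinstance(kinship, KinshipMatrix) and id_col in data.columns:
            kinship = kinship.reorder(data[id_col].astype(str))
        return cls(data[score_col].to_numpy(), data[size_col].to_numpy(),
                   kinship, **kwargs)

    # -- likelihood ---------------------------------------------------------

    def _weights(self, h2: float) -> np.ndarray:
        return h2 * self._evals + (1.0 - h2)

    def loglike(self, h2: float, beta: float, mu0: float, sigma2: float) -> float:
        """Exact log-likelihood at the given parameter point (O(n))."""
        if not (0.0 <= h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        if sigma2 <= 0.0:
            raise ValueError("sigma2 must be positive")
        w = self._weights(h2)
        if np.any(w <= 0.0):
            raise np.linalg.LinAlgError(
                "singular covariance: with h2 = 1 and a singular K the model "
                "degenerates; bound h2 below 1 - 1e-6"
            )
        r = self._yt - self._Xt @ np.array([beta, mu0])
        quad = float(np.sum(r**2 / w)) / sigma2
        logdet = float(np.sum(np.log(w))) + self.n * np.log(sigma2)
        return -0.5 * (self.n * _LOG2PI + logdet + quad)

    def profile(self, h2: float) -> Tuple[float, float, float, float]:
        """Profile log-likelihood at h2: GLS beta/mu0 and the ML sigma2.

        Returns (loglik, beta, mu0, sigma2).
        """
        w = self._weights(h2)
        Xw = self._Xt / w[:, None]
        xtx = self._Xt.T @ Xw
        xty = Xw.T @ self._yt
        theta = np.linalg.solve(xtx, xty)
        r = self._yt - self._Xt @ theta
        sigma2 = float(np.sum(r**2 / w)) / self.n
        if sigma2 <= 0.0:
            sigma2 = np.finfo(float).tiny
        ll = -0.5 * (self.n * _LOG2PI + float(np.sum(np.log(w)))
                     + self.n * np.log(sigma2) + self.n)
        return ll, float(theta[0]), float(theta[1]), sigma2

    # -- fitting ------------------------------------------------------------

    def fit(self, family_alpha: float = 0.05, n_tests: int = 1,
            grid_points: int = 41, xatol: float = 1e-10) -> HeritabilityResults:
        """ML fit of null (h2 = 0) and alternative (h2 in [0, 1-1e-6]).

        The alternative maximizes the 1-D profile likelihood by a coarse grid
        followed by bounded scalar refinement; the null solution is always a
        candidate, so loglik_alt >= loglik_null by construction.
        """
        if self.n < 4:
            raise ValueError("fitting needs n >= 4 (three nuisance parameters "
                             "plus at least 1 df)")
        ll0, b0, m0, s0 = self.profile(0.0)

        grid = np.linspace(0.0, H2_MAX, grid_points)
        vals = np.array([self.profile(h)[0] for h in grid])
        i = int(np.argmax(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid_points - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda h: -self.profile(h)[0], bounds=(lo, hi),
                method="bounded", options={"xatol": xatol},
            )
            candidates = [0.0, float(grid[i]), float(res.x), H2_MAX]
        else:
            candidates = [0.0, float(grid[i]), H2_MAX]
        best_h2, best = 0.0, -np.inf
        for h in candidates:
            ll = self.profile(h)[0]
            if ll > best:
                best_h2, best = h, ll
        llA, bA, mA, sA = self.profile(best_h2)

        lam = 2.0 * (llA - ll0)
        if lam < -_LAMBDA_CLIP:
            raise RuntimeError(
                f"likelihood nesting violated (lambda = {lam:.3g}); "
                f"null logL {ll0:.6f}, alt logL {llA:.6f}"
            )
        lam = max(lam, 0.0)
        p = mixture_pvalue(lam)
        alpha = family_alpha / n_tests
        se = self._h2_se(best_h2)
        return HeritabilityResults(
            pc_index=self.pc_index, h2=best_h2, h2_se=se,
            beta=bA, mu0=mA, sigma2=sA,
            loglik_null=ll0, loglik_alt=llA, lrt=lam, pvalue=p,
            alpha_per_test=alpha, significant=bool(p < alpha),
            nobs=self.n, beta_null=b0, mu0_null=m0, sigma2_null=s0,
        )

    def _h2_se(self, h2_hat: float, step: float = 1e-4) -> float:
        """SE from the curvature of the profile log-likelihood.

        At a boundary optimum the quadratic approximation is unusable and the
        SE is reported as 0 (the convention used for boundary estimates).
        """
        if h2_hat < step or h2_hat > H2_MAX - step:
            return 0.0
        ll = lambda h: self.profile(h)[0]
        d2 = (ll(h2_hat + step) - 2.0 * ll(h2_hat) + ll(h2_hat - step)) / step**2
        if d2 >= 0.0 or not np.isfinite(d2):
            return 0.0
        return float(1.0 / np.sqrt(-d2))


def neg_log_likelihood(scores, sizes, K, h2: float, beta: float,
                       mu0: float, sigma2: float) -> float:
    """Negative log-likelihood of the animal model at an explicit parameter
    point (functional form of :meth:`HeritabilityModel.loglike`)."""
    model = HeritabilityModel(scores, sizes, K)
    return -model.loglike(h2, beta, mu0, sigma2)


def fit_heritability(scores, sizes, K, pc_index: int = 1,
                     family_alpha: float = 0.05, n_tests: int = 1,
                     ) -> HeritabilityResults:
    """Convenience wrapper: build the model and fit it."""
    return HeritabilityModel(scores, sizes, K, pc_index=pc_index).fit(
        family_alpha=family_alpha, n_tests=n_tests)


def test_top_pcs(pca, sizes, kinship, n_pcs: int = 4,
                 family_alpha: float = 0.05) -> List[HeritabilityResults]:
    """Boundary LRT on the top ``n_pcs`` PC scores with Bonferroni control.

    ``pca`` is a ShapePCA (or an (n, m) score matrix). Each PC is tested at
    family_alpha / n_pcs; with the defaults (0.05, 4 PCs) that is 0.0125.
    The kinship eigendecomposition is shared across the tested PCs. Testing
    many low-variance PCs dilutes the correction, so keep n_pcs to the few
    leading axes suggested by the eigenvalue spectrum.
    """
    scores = pca.scores if hasattr(pca, "scores") else np.asarray(pca, float)
    if not (0.0 < family_alpha < 1.0):
        raise ValueError("family_alpha must be in (0, 1)")
    if n_pcs < 1 or n_pcs > scores.shape[1]:
        raise ValueError(
            f"n_pcs = {n_pcs} exceeds the {scores.shape[1]} available PCs")
    K = kinship.K if isinstance(kinship, KinshipMatrix) else np.asarray(kinship, float)
    evals, evecs = np.linalg.eigh(K)
    evals = np.clip(evals, 0.0, None)
    out = []
    for j in range(n_pcs):
        model = HeritabilityModel(scores[:, j], sizes, K, pc_index=j + 1,
                                  _eig=(evals, evecs))
        out.append(model.fit(family_alpha=family_alpha, n_tests=n_pcs))
    return out
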