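"""Polygenic variance-component model and kinship estimation.

The model for a phenotype vector y is

    y = X b + g + e,   g ~ N(0, sg^2 * 2K),   e ~ N(0, se^2 * I)

with K the kinship matrix on the coefficient-of-kinship scale (diagonal 0.5,
full sibs 0.25), so 2K is the genomic relationship matrix.  The model is fit
by maximum likelihood (not REML) via the one-dimensional profile likelihood
over the heritability h^2 = sg^2 / (sg^2 + se^2): after rotating into the
eigenbasis of 2K, the covariance is sigma^2 * diag(h*d + (1-h)) and both the
fixed effects and sigma^2 have closed forms given h.

This is the engine behind every association scan (score tests reuse the
fitted inverse covariance; likelihood-ratio tests refit the alternative) and
behind the heritability decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .cohort import GenotypeMatrix

_LOG2PI = np.log(2.0 * np.pi)
_H_MAX = 1.0 - 1e-6


@dataclass
class KinshipMatrix:
    """Symmetric relationship coefficients (coefficient-of-kinship scale)."""

    values: np.ndarray
    sample_ids: list[str]
    source: str = "genomic"

    def __post_init__(self):
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    def subset(self, mask: np.ndarray) -> "KinshipMatrix":
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return KinshipMatrix(self.values[np.ix_(mask, mask)], ids, self.source)


class EigenKinship:
    """Cached eigendecomposition of 2K with the documented bending step.

    Eigenvalues of K below 1e-8 are floored at 1e-8 ("bending") before any
    inversion, making the covariance operator positive definite.
    """

    def __init__(self, kinship: KinshipMatrix, floor: float = 1e-8):
        vals, vecs = np.linalg.eigh(kinship.values)
        bent = np.maximum(vals, floor)
        self.d = 2.0 * bent  # eigenvalues of the relationship matrix 2K
        self.U = vecs
        self.sample_ids = list(kinship.sample_ids)
        self.n = len(self.sample_ids)
        # likelihood is flat in h when 2K is (a multiple of) the identity
        self.degenerate = float(np.ptp(self.d)) < 1e-10

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.U.T @ a

    def rotate32(self, a: np.ndarray) -> np.ndarray:
        """Single-precision rotation for memory-bound genome-wide scans."""
        if not hasattr(self, "_U32"):
            self._U32 = self.U.astype(np.float32)
        return self._U32.T @ np.asarray(a, dtype=np.float32)


@dataclass
class PolygenicFit:
    """ML fit of the polygenic model."""

    beta: np.ndarray
    beta_names: list[str]
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    residuals: np.ndarray
    eig: EigenKinship
    h2_degenerate: bool = False
    converged: bool = True
    n: int = 0

    @property
    def sigma2(self) -> float:
        return self.sigma_g2 + self.sigma_e2

    def vinv(self, a: np.ndarray) -> np.ndarray:
        """Apply the inverse phenotypic covariance V^-1 to a vector/matrix."""
        w = self.h2 * self.eig.d + (1.0 - self.h2)
        at = self.eig.rotate(a)
        return self.eig.U @ (at / (self.sigma2 * (w if a.ndim == 1 else w[:, None])))


@dataclass
class LRTResult:
    """Likelihood-ratio test: chi2 statistic, degrees of freedom, P-value."""

    chi2: float
    df: int
    p: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.p is None:
            self.p = float(stats.chi2.sf(self.chi2, self.df))


def genomic_kinship(
    g: GenotypeMatrix, maf_min: float = 0.05, floor: float = 1e-8
) -> KinshipMatrix:
    """Allele-frequency-weighted genomic kinship (IBS-style estimator).

    K_ij = 1/2 * mean over SNPs of (x_i - 2p)(x_j - 2p) / (2p(1-p)), using
    SNPs with MAF > ``maf_min``.  Negative eigenvalues are bent to ``floor``
    by consumers before inversion (see :class:`EigenKinship`).
    """
    use = g.maf > maf_min
    if int(use.sum()) < 2:
        raise ValueError("need polymorphic SNPs above the MAF cut-off")
    x = g.dosages[:, use]
    p = x.mean(axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    x = x[:, ok]
    p = p[ok]
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    K = 0.5 * (z @ z.T) / z.shape[1]
    K = 0.5 * (K + K.T)
    return KinshipMatrix(values=K, sample_ids=list(g.sample_ids), source="genomic")


def _profile_loglik(h: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profile log-likelihood over (beta, sigma^2) at heritability h."""
    w = h * d + (1.0 - h)
    sw = np.sqrt(w)
    Xw = Xt / sw[:, None]
    yw = yt / sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n = yt.size
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    ll = -0.5 * n * (_LOG2PI + 1.0 + np.log(sigma2)) - 0.5 * float(np.log(w).sum())
    return ll, beta, sigma2


def fit_polygenic(
    y: np.ndarray,
    X: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
    beta_names: list[str] | None = None,
    xatol: float = 1e-8,
) -> PolygenicFit:
    """Maximum-likelihood fit of the polygenic model.

    ``X`` is the fixed-effects design (must include an intercept column if
    one is wanted).  Profile likelihood over h^2 in [0, 1) is maximized with
    bounded Brent iteration at tolerance ``xatol``; the h = 0 (pure OLS)
    endpoint is always evaluated so the optimum never falls below the OLS
    likelihood.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("design and phenotype lengths differ")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    eig = kinship if isinstance(kinship, EigenKinship) else EigenKinship(kinship)
    if eig.n != y.size:
        raise ValueError("kinship not aligned with phenotype")
    # aliased design columns make the likelihood ill-defined for inference
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (aliased covariates)")

    yt = eig.rotate(y)
    Xt = eig.rotate(X)

    if eig.degenerate:
        ll, beta, sigma2 = _profile_loglik(0.0, eig.d, yt, Xt)
        if sigma2 <= 1e-12 * float(np.var(y)):
            raise ValueError(
                "design explains the phenotype exactly (aliased response)"
            )
        resid = y - X @ beta
        return PolygenicFit(
            beta=beta, beta_names=beta_names or [], sigma_g2=0.0,
            sigma_e2=sigma2, h2=0.0, loglik=ll, residuals=resid, eig=eig,
            h2_degenerate=True, n=y.size,
        )

    neg = lambda h: -_profile_loglik(h, eig.d, yt, Xt)[0]
    res = optimize.minimize_scalar(
        neg, bounds=(0.0, _H_MAX), method="bounded",
        options={"xatol": xatol, "maxiter": 500},
    )
    candidates = [0.0, float(res.x)]
    best_h = max(candidates, key=lambda h: _profile_loglik(h, eig.d, yt, Xt)[0])
    ll, beta, sigma2 = _profile_loglik(best_h, eig.d, yt, Xt)
    if sigma2 <= 1e-12 * float(np.var(y)):
        raise ValueError("design explains the phenotype exactly (aliased response)")
    resid = y - X @ beta
    return PolygenicFit(
        beta=beta,
        beta_names=beta_names or [],
        sigma_g2=best_h * sigma2,
        sigma_e2=(1.0 - best_h) * sigma2,
        h2=best_h,
        loglik=ll,
        residuals=resid,
        eig=eig,
        h2_degenerate=False,
        converged=bool(res.success),
        n=y.size,
    )


def lrt_nested(alt: PolygenicFit, null: PolygenicFit, df: int) -> LRTResult:
    """Likelihood-ratio test of nested polygenic fits (chi2 clipped at 0)."""
    if alt.n != null.n:
        raise ValueError("alternative and null fits use different samples")
    if df < 1:
        raise ValueError("df must be positive")
    chi2 = max(0.0, 2.0 * (alt.loglik - null.loglik))
    return LRTResult(chi2=chi2, df=df)


def estimate_heritability(
    y: np.ndarray,
    X: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
) -> tuple[float, LRTResult, PolygenicFit]:
    """Heritability estimate with the 1-df LRT against sg^2 = 0.

    The null fixes heritability at zero (ordinary least squares); the test
    uses a plain 1-df chi-squared reference, which is conservative at the
    boundary (documented, not corrected).
    """
    eig = kinship if isinstance(kinship, EigenKinship) else EigenKinship(kinship)
    alt = fit_polygenic(y, X, eig)
    yt = eig.rotate(np.asarray(y, dtype=float))
    Xt = eig.rotate(np.atleast_2d(np.asarray(X, dtype=float)))
    ll0, *_ = _profile_loglik(0.0, eig.d, yt, Xt)
    chi2 = max(0.0, 2.0 * (alt.loglik - ll0))
    return alt.h2, LRTResult(chi2=chi2, df=1), alt


def heritability_reduction_test(
    y: np.ndarray,
    X: np.ndarray,
    extra: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
    extra_names: list[str] | None = None,
) -> tuple[LRTResult, float, float]:
    """Test whether extra covariates (SNP dosages / CpG levels) absorb signal.

    Compares the polygenic model (h^2 optimized) without and with the extra
    covariates; df equals the number of non-aliased added columns.  Returns
    the LRT plus the heritability before and after adjustment.
    """
    eig = kinship if isinstance(kinship, EigenKinship) else EigenKinship(kinship)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    extra = np.atleast_2d(np.asarray(extra, dtype=float))
    if extra.shape[0] != X.shape[0]:
        extra = extra.T
    full = np.column_stack([X, extra])
    names = [f"x{i}" for i in range(X.shape[1])] + (
        extra_names or [f"extra{i}" for i in range(extra.shape[1])]
    )
    from .qc import drop_aliased

    full, kept = drop_aliased(full, names)
    df = full.shape[1] - X.shape[1]
    null = fit_polygenic(y, X, eig)
    if df == 0:
        return LRTResult(chi2=0.0, df=1, p=1.0), null.h2, null.h2
    alt = fit_polygenic(y, full, eig)
    return lrt_nested(alt, null, df), null.h2, alt.h2
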