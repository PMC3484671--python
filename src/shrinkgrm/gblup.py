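"""GBLUP: mixed-model breeding-value prediction with a genomic relationship matrix.

Model
-----
    y = mu 1 + a + e,    a ~ N(0, A sigma^2),    e ~ N(0, I sigma_e^2)

with A an estimated realized relationship matrix.  Variance components are
estimated by REML using a spectral (eigendecomposition) algorithm: the
restricted likelihood of the error contrasts (an orthonormal basis of the
complement of span(1)) is profiled over the variance ratio
lambda = sigma_e^2 / sigma^2 after a single eigendecomposition of the
projected training kinship, then maximized by a coarse grid plus
golden-section refinement.  A may be singular (the plain estimator always has
a zero eigenvalue from centering); the contrast representation handles this
without forming V^-1 explicitly.

The fixed effect and breeding values use the standard BLUE/BLUP formulas
    mu_hat = (1' V^-1 1)^-1 1' V^-1 y,
    a_hat  = sigma^2 A V^-1 (y - mu_hat 1),
evaluated in the eigenbasis of the training kinship.  Heritability is
reported both as the regression form h^2 = a_hat'(y - mu_hat 1)/||y - mu_hat 1||^2
and as the variance-component form h^2 = sigma^2 (1+f) / (sigma^2 (1+f) + sigma_e^2).

Usage
-----
>>> model = GBLUP(y, kinship)          # y: pandas Series indexed by line ID
>>> res = model.fit()
>>> res.summary()
>>> res.predict(other_ids)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import minimize_scalar

from .kinship import KinshipMatrix

__all__ = [
    "GBLUP",
    "GBLUPResults",
    "fit_gblup",
    "predict_gebv",
    "heritability_regression",
    "heritability_components",
    "accuracy",
]

_LOGLAM_LO = -18.4  # lambda in [1e-8, 1e8]
_LOGLAM_HI = 18.4
_N_GRID = 64


@lru_cache(maxsize=8)
def _ones_complement_basis(n: int) -> np.ndarray:
    """Orthonormal basis (n x n-1) of the space of contrasts orthogonal to 1."""
    return null_space(np.ones((1, n)))


def _as_kinship(A) -> KinshipMatrix:
    if isinstance(A, KinshipMatrix):
        return A
    A = np.asarray(A, dtype=float)
    return KinshipMatrix(A, [str(i) for i in range(A.shape[0])], method="plain")


class GBLUP:
    """GBLUP mixed model for one trait.

    Parameters
    ----------
    y : pandas.Series or array-like
        Phenotypes.  A Series is aligned to the kinship by its index (the
        index defines the training lines); a bare array must either match
        ``train_ids`` or cover every line of the kinship in order.
    kinship : KinshipMatrix or (n, n) array
        Relationship matrix over all lines (phenotyped or not).
    train_ids : sequence of str, optional
        Training lines; defaults to the Series index, or to all lines.
    """

    def __init__(self, y, kinship, train_ids=None):
        self.kinship = _as_kinship(kinship)
        if isinstance(y, pd.Series):
            if train_ids is None:
                train_ids = [str(i) for i in y.index]
            y = y.loc[[i for i in train_ids]].to_numpy(dtype=float)
        else:
            y = np.asarray(y, dtype=float)
            if train_ids is None:
                if len(y) != self.kinship.n_lines:
                    raise ValueError(
                        "bare-array phenotypes without train_ids must cover "
                        "every line of the kinship"
                    )
                train_ids = list(self.kinship.line_ids)
        self.train_ids = [str(i) for i in train_ids]
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != len(self.train_ids):
            raise ValueError("phenotype / train_ids length mismatch")
        if len(self.y) < 3:
            raise ValueError("need at least 3 training lines")
        if not np.isfinite(self.y).all():
            raise ValueError("phenotypes must be finite")
        if np.var(self.y) <= 0:
            raise ValueError("phenotypic variance is zero")
        self.train_idx = self.kinship.index_of(self.train_ids)
        self._is_full = (len(self.train_idx) == self.kinship.n_lines
                         and np.array_equal(self.train_idx,
                                            np.arange(self.kinship.n_lines)))

    # -- spectral pieces -------------------------------------------------

    def _contrast_eigh(self, A_tt: np.ndarray):
        if self._is_full and "contrast_eigh" in self.kinship._cache:
            return self.kinship._cache["contrast_eigh"]
        n = A_tt.shape[0]
        C = _ones_complement_basis(n)
        lam_c, V = np.linalg.eigh(C.T @ A_tt @ C)
        lam_c = np.clip(lam_c, 0.0, None)
        out = (C, lam_c, V)
        if self._is_full:
            self.kinship._cache["contrast_eigh"] = out
        return out

    def _train_eigh(self, A_tt: np.ndarray):
        if self._is_full:
            d, E = self.kinship.spectral()
            return np.clip(d, 0.0, None), E
        d, E = np.linalg.eigh(A_tt)
        return np.clip(d, 0.0, None), E

    # -- fitting ---------------------------------------------------------

    def loglike_restricted(self, log_lambda: float, u2=None, lam_c=None) -> float:
        """Profiled restricted log-likelihood at variance ratio exp(log_lambda).

        sigma^2 is profiled out analytically; the value is the log-likelihood
        of the orthonormal error contrasts at (sigma^2_hat(lambda), lambda).
        """
        if u2 is None or lam_c is None:
            A_tt = self.kinship.A[np.ix_(self.train_idx, self.train_idx)]
            C, lam_c, V = self._contrast_eigh(A_tt)
            u2 = (V.T @ (C.T @ self.y)) ** 2
        lam = np.exp(log_lambda)
        dv = lam_c + lam
        k = len(u2)
        s2 = float(np.sum(u2 / dv)) / k
        return -0.5 * (k * (np.log(2.0 * np.pi * s2) + 1.0)
                       + float(np.sum(np.log(dv))))

    def fit(self) -> "GBLUPResults":
        A_tt = self.kinship.A[np.ix_(self.train_idx, self.train_idx)]
        C, lam_c, V = self._contrast_eigh(A_tt)
        u2 = (V.T @ (C.T @ self.y)) ** 2
        k = len(u2)

        grid = np.linspace(_LOGLAM_LO, _LOGLAM_HI, _N_GRID)
        vals = np.array([self.loglike_restricted(g, u2, lam_c) for g in grid])
        best = int(np.argmax(vals))
        boundary = best in (0, _N_GRID - 1)
        if np.ptp(vals) < 1e-9 * max(1.0, abs(vals[best])):
            boundary = True  # flat ridge: variance split unidentified (A ~ I)
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, _N_GRID - 1)]
        res = minimize_scalar(lambda g: -self.loglike_restricted(g, u2, lam_c),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        log_lam = float(res.x)
        if vals[best] > -res.fun:  # flat profile: keep the grid argmax
            log_lam = float(grid[best])
        lam = float(np.exp(log_lam))
        dv = lam_c + lam
        sigma2 = float(np.sum(u2 / dv)) / k
        sigma_e2 = lam * sigma2
        logreml = self.loglike_restricted(log_lam, u2, lam_c)
        if log_lam <= _LOGLAM_LO + 1e-6 or log_lam >= _LOGLAM_HI - 1e-6:
            boundary = True

        # BLUE / BLUP in the eigenbasis of the training kinship
        d, E = self._train_eigh(A_tt)
        dv2 = d + lam
        t1 = E.T @ np.ones(len(self.y))
        ty = E.T @ self.y
        mu = float(np.sum(t1 * ty / dv2) / np.sum(t1 * t1 / dv2))
        r = self.y - mu
        w = E @ ((E.T @ r) / dv2)  # (A_tt + lam I)^-1 r  ==  sigma^2 V^-1 r
        gebv = A_tt @ w

        ssr = float(r @ r)
        h2_reg = float(gebv @ r) / ssr
        h2_comp = heritability_components(sigma2, sigma_e2, self.kinship.f)
        return GBLUPResults(
            model=self, mu_hat=mu, sigma2=sigma2, sigma_e2=sigma_e2,
            lam=lam, gebv=gebv, logREML=float(logreml), boundary=boundary,
            h2_regression=h2_reg, h2_components=h2_comp,
            train_ids=list(self.train_ids), _w=w,
        )


@dataclass
class GBLUPResults:
    """Fitted GBLUP: variance components, BLUE/BLUP solutions, diagnostics.

    ``boundary`` flags an optimum at the edge of the variance-ratio search
    range (e.g. A close to I, where only sigma^2 + sigma_e^2 is identified,
    or a noiseless trait driving sigma_e^2 to zero).
    """

    model: GBLUP
    mu_hat: float
    sigma2: float
    sigma_e2: float
    lam: float
    gebv: np.ndarray
    logREML: float
    boundary: bool
    h2_regression: float
    h2_components: float
    train_ids: list[str]
    _w: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def gebv_series(self) -> pd.Series:
        return pd.Series(self.gebv, index=self.train_ids, name="gebv")

    def predict(self, target_ids) -> pd.Series:
        """GEBVs for any lines of the kinship, phenotyped or not.

        a_hat[target] = sigma^2 A[target, train] V^-1 (y - mu 1); for
        target = train this reproduces ``gebv`` exactly.
        """
        K = self.model.kinship
        tgt = K.index_of(target_ids)
        vals = K.A[np.ix_(tgt, self.model.train_idx)] @ self._w
        return pd.Series(vals, index=[str(i) for i in target_ids], name="gebv")

    def summary(self) -> str:
        n = len(self.train_ids)
        lines = [
            "GBLUP mixed-model fit (REML, spectral algorithm)",
            "=" * 48,
            f"training lines            {n}",
            f"mu_hat                    {self.mu_hat: .6g}",
            f"sigma2 (genetic)          {self.sigma2: .6g}",
            f"sigma_e2 (residual)       {self.sigma_e2: .6g}",
            f"lambda = sigma_e2/sigma2  {self.lam: .6g}",
            f"log restricted likelihood {self.logREML: .6g}",
            f"f (from kinship)          {self.model.kinship.f: .6g}",
            f"h2 (regression form)      {self.h2_regression: .6g}",
            f"h2 (variance components)  {self.h2_components: .6g}",
        ]
        if self.boundary:
            lines.append("WARNING: optimum at search boundary "
                         "(variance ratio weakly identified)")
        return "\n".join(lines)


def fit_gblup(y, A, train_ids=None) -> GBLUPResults:
    """Fit the GBLUP model; see :class:`GBLUP`."""
    return GBLUP(y, A, train_ids=train_ids).fit()


def predict_gebv(fit: GBLUPResults, A, target_ids) -> pd.Series:
    """GEBVs for ``target_ids`` from a fitted model (same kinship)."""
    K = _as_kinship(A)
    if K is not fit.model.kinship and list(K.line_ids) != list(fit.model.kinship.line_ids):
        raise ValueError("kinship does not match the fitted model")
    return fit.predict(target_ids)


def heritability_regression(fit: GBLUPResults, y) -> float:
    """Parent-offspring-regression heritability a_hat'(y - mu 1)/||y - mu 1||^2."""
    y = np.asarray(y, dtype=float)
    if len(y) != len(fit.gebv):
        raise ValueError("phenotypes not aligned with the fit")
    r = y - fit.mu_hat
    ssr = float(r @ r)
    if ssr <= 0:
        raise ValueError("phenotypic variance is zero")
    return float(fit.gebv @ r) / ssr


def heritability_components(sigma2: float, sigma_e2: float, f: float) -> float:
    """Large-population heritability sigma^2 (1+f) / (sigma^2 (1+f) + sigma_e^2)."""
    if sigma2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    if sigma2 == 0 and sigma_e2 == 0:
        raise ValueError("both variance components are zero")
    if not -1.0 - 1e-8 <= f <= 1.0 + 1e-8:
        raise ValueError("inbreeding coefficient must lie in [-1, 1]")
    f = min(1.0, max(-1.0, f))
    num = sigma2 * (1.0 + f)
    return num / (num + sigma_e2)


def accuracy(x, y) -> float:
    """Pearson correlation between two vectors (e.g. GEBV vs true values)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.var(x) <= 0 or np.var(y) <= 0:
        raise ValueError("zero variance in input")
    return float(np.corrcoef(x, y)[0, 1])
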