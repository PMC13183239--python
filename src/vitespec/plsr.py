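"""Partial least squares regression (PLS1) via orthogonal-scores NIPALS.

Implemented from first principles for a single response. Predictors are
mean-centred (optionally unit-variance scaled); the response is centred.
For a univariate response the NIPALS weight step converges in one pass and
response-side deflation is a no-op, so it is omitted — the algorithm is then
equivalent to SIMPLS for the fitted values.

Per component ``a`` the model stores the unit-norm weight vector ``w_a``,
the predictor loading ``p_a``, the response loading ``q_a`` and the score
sum of squares ``t_a' t_a``. Regression coefficient vectors are precomputed
for every component count 1..A, so cross-validation can evaluate all
truncations from a single fit. The response variance explained by component
``a`` is ``SSY_a = q_a^2 * (t_a' t_a)``, the quantity entering the VIP
weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSRModel", "fit_plsr"]

_EPS = 1e-12


@dataclass
class PLSRModel:
    """Fitted PLS1 model; build with :func:`fit_plsr`."""

    x_mean: np.ndarray
    x_scale: np.ndarray          # ones when scale=False
    y_mean: float
    weights: np.ndarray          # p x A, unit-norm columns
    x_loadings: np.ndarray       # p x A
    y_loadings: np.ndarray       # A
    score_ss: np.ndarray         # A, t_a' t_a
    coefs: np.ndarray            # p x A; column a-1 = coefficients for a components
    ncomp: int
    scaled: bool = False
    zero_variance_y: bool = False
    n_samples: int = 0

    # -- prediction ----------------------------------------------------

    def coefficients(self, ncomp: int | None = None) -> np.ndarray:
        """Regression coefficients (centred/scaled space) for ``ncomp`` components."""
        a = self._resolve_ncomp(ncomp)
        if a == 0:
            return np.zeros(self.x_mean.size)
        return self.coefs[:, a - 1]

    def _resolve_ncomp(self, ncomp: int | None) -> int:
        if ncomp is None:
            return self.ncomp
        if ncomp < 0:
            raise ValueError("ncomp must be >= 0")
        # a request beyond the components actually extracted (rank-deficient
        # X) falls back to the deepest available truncation
        return min(ncomp, self.ncomp)

    def predict(self, X: np.ndarray, ncomp: int | None = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"X has {X.shape[1]} bands, model expects {self.x_mean.size}"
            )
        b = self.coefficients(ncomp)
        return self.y_mean + ((X - self.x_mean) / self.x_scale) @ b

    # -- interpretation ------------------------------------------------

    def explained_y_ss(self) -> np.ndarray:
        """Response sum of squares captured per component, SSY_a = q_a^2 t_a't_a."""
        return self.y_loadings**2 * self.score_ss

    def vip(self, ncomp: int | None = None) -> np.ndarray:
        """Variable importance in projection over the first ``ncomp`` components.

        VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ) with unit-norm
        weights; mean(VIP^2) = 1 by construction.
        """
        a = self._resolve_ncomp(ncomp)
        if a < 1:
            raise ValueError("VIP requires at least one fitted component")
        ssy = self.explained_y_ss()[:a]
        total = ssy.sum()
        if total <= 0:
            raise ValueError("no response variance explained; VIP undefined")
        p = self.x_mean.size
        w2 = self.weights[:, :a] ** 2
        return np.sqrt(p * (w2 @ ssy) / total)

    # -- persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "score_ss": self.score_ss.tolist(),
            "coefs": self.coefs.tolist(),
            "ncomp": self.ncomp,
            "scaled": self.scaled,
            "zero_variance_y": self.zero_variance_y,
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSRModel":
        arr = lambda k: np.asarray(d[k], dtype=float)
        return cls(
            x_mean=arr("x_mean"),
            x_scale=arr("x_scale"),
            y_mean=float(d["y_mean"]),
            weights=arr("weights"),
            x_loadings=arr("x_loadings"),
            y_loadings=arr("y_loadings"),
            score_ss=arr("score_ss"),
            coefs=arr("coefs"),
            ncomp=int(d["ncomp"]),
            scaled=bool(d["scaled"]),
            zero_variance_y=bool(d["zero_variance_y"]),
            n_samples=int(d["n_samples"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PLSRModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_plsr(X: np.ndarray, y: np.ndarray, ncomp: int, scale: bool = False) -> PLSRModel:
    """Fit a PLS1 model with up to ``ncomp`` latent components.

    Parameters
    ----------
    X : (n, p) predictor matrix (no missing values)
    y : (n,) response
    ncomp : maximum number of components; must satisfy
        ``1 <= ncomp <= min(n - 1, p)``
    scale : divide each predictor by its standard deviation after centring

    A zero-variance response yields a valid model with all-zero coefficients
    and ``zero_variance_y=True`` rather than an error. If the predictor
    residual degenerates before ``ncomp`` components, the model truncates at
    the rank actually available.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("PLSR inputs must be finite (impute or drop missing first)")
    if ncomp < 1 or ncomp > min(n - 1, p):
        raise ValueError(f"ncomp must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")

    x_mean = X.mean(axis=0)
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale < _EPS] = 1.0
    else:
        x_scale = np.ones(p)
    y_mean = float(y.mean())

    Xa = (X - x_mean) / x_scale
    yc = y - y_mean

    y_ss = float(yc @ yc)
    if y_ss < _EPS:
        zeros = np.zeros((p, 1))
        return PLSRModel(
            x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
            weights=zeros, x_loadings=zeros, y_loadings=np.zeros(1),
            score_ss=np.zeros(1), coefs=zeros, ncomp=1, scaled=scale,
            zero_variance_y=True, n_samples=n,
        )

    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    tss = np.zeros(ncomp)
    x_norm0 = np.linalg.norm(Xa) + _EPS

    a = 0
    for a in range(ncomp):
        w = Xa.T @ yc
        wn = np.linalg.norm(w)
        if wn <= _EPS * np.sqrt(y_ss) * x_norm0:
            break
        w /= wn
        t = Xa @ w
        tt = float(t @ t)
        if tt <= (_EPS * x_norm0) ** 2:
            break
        pl = Xa.T @ t / tt
        W[:, a], P[:, a] = w, pl
        q[a] = float(yc @ t) / tt
        tss[a] = tt
        Xa -= np.outer(t, pl)
        a += 1

    if a == 0:
        # no covariance direction at all; behave like the zero-variance case
        zeros = np.zeros((p, 1))
        return PLSRModel(
            x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
            weights=zeros, x_loadings=zeros, y_loadings=np.zeros(1),
            score_ss=np.zeros(1), coefs=zeros, ncomp=1, scaled=scale,
            zero_variance_y=True, n_samples=n,
        )

    W, P, q, tss = W[:, :a], P[:, :a], q[:a], tss[:a]
    # rotation from raw (centred) X to scores: R = W (P'W)^{-1}; P'W is unit
    # upper-triangular in exact arithmetic, so the solve is well conditioned
    R = np.linalg.solve((P.T @ W).T, W.T).T
    coefs = np.cumsum(R * q, axis=1)

    return PLSRModel(
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q, score_ss=tss,
        coefs=coefs, ncomp=a, scaled=scale, n_samples=n,
    )
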