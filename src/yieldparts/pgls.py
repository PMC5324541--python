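"""Phylogenetic generalized least squares with Pagel's λ.

Species means are not independent: close relatives resemble each other. GLS
handles this by giving the residuals the covariance σ²·V(λ), where the base
matrix C holds shared root-to-ancestor branch lengths (C_ij = depth of the
most recent common ancestor of taxa i and j on an ultrametric tree) and
Pagel's λ ∈ [0, 1] rescales the off-diagonal entries,

    V(λ) = λ·C + (1 − λ)·diag(C).

λ = 1 is Brownian-motion covariance; λ = 0 is a star phylogeny, reducing
GLS to OLS. λ is estimated by maximising the Gaussian log-likelihood
profiled over the GLS coefficients and the ML residual scale
σ̂² = eᵀV⁻¹e/n.

The headline model regresses a species-mean trait on domestication status
(crop vs wild progenitor) with an intercept. With n taxa the F test has
(1, n−2) degrees of freedom: (1, 15) for the full 17-taxon set, (1, 8) for
the 10 cereals. For log-transformed traits the status effect back-transforms
to a crop:progenitor ratio exp(β̂) with Wald CI exp(β̂ ± t₀.₉₇₅,ₙ₋₂·se);
for traits analysed untransformed (fractions, rates, durations), the effect
is an absolute difference, also expressible as a percentage of the fitted
progenitor mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .io import TRAIT_TRANSFORMS


class PglsError(ValueError):
    pass


def phylo_covariance(tree: dendropy.Tree, taxa: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Shared branch-length matrix C from a rooted tree with branch lengths.

    C_ij = depth_i for i = j and, for i ≠ j,
    C_ij = (depth_i + depth_j − patristic distance)/2, i.e. the root
    distance of the MRCA. ``taxa`` selects and orders the rows; the tree is
    pruned to them first so internal paths are unaffected.
    """
    if taxa is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        if set(taxa) != tips:
            tree = tree.clone(depth=1)
            tree.retain_taxa_with_labels(list(taxa))
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    order = list(taxa) if taxa is not None else sorted(leaves)
    missing = [t for t in order if t not in leaves]
    if missing:
        raise PglsError(f"taxa absent from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(order)
    C = np.zeros((n, n))
    for i, a in enumerate(order):
        C[i, i] = leaves[a].root_distance
        for j in range(i + 1, n):
            b = order[j]
            d = pdm.patristic_distance(leaves[a].taxon, leaves[b].taxon)
            C[i, j] = C[j, i] = 0.5 * (leaves[a].root_distance + leaves[b].root_distance - d)
    return C, order


def pagel_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """V(λ): multiply off-diagonal entries of C by λ; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise PglsError(f"Pagel's lambda must lie in [0, 1], got {lam}")
    V = lam * np.asarray(C, dtype=float)
    np.fill_diagonal(V, np.diag(C))
    return V


@dataclass(slots=True)
class GLSFit:
    beta: np.ndarray
    se: np.ndarray            # from the unbiased scale e'V^-1 e/(n-p)
    sigma2_ml: float          # e'V^-1 e / n
    sigma2_unbiased: float
    loglik: float             # Gaussian log-likelihood at the ML scale
    resid: np.ndarray
    xtvix_inv: np.ndarray


def gls_fit(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> GLSFit:
    """Generalized least squares via Cholesky whitening (no explicit
    inverse): β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, σ̂²_ML = eᵀV⁻¹e/n."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise PglsError("design matrix is singular (e.g. all taxa share one status)")
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise PglsError(f"covariance matrix not positive definite: {e}") from e
    L = np.tril(c)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    ew = yw - Xw @ beta
    q = float(ew @ ew)
    sigma2_ml = q / n
    sigma2_unb = q / (n - p) if n > p else np.nan
    xtx = Xw.T @ Xw
    xtx_inv = np.linalg.inv(xtx)
    se = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * sigma2_unb)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2_ml > 0:
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdetV + n)
    else:
        loglik = np.inf  # perfect fit; degenerate likelihood
    return GLSFit(beta=beta, se=se, sigma2_ml=sigma2_ml, sigma2_unbiased=sigma2_unb,
                  loglik=loglik, resid=y - X @ beta, xtvix_inv=xtx_inv)


@dataclass(slots=True)
class PglsResult:
    """Status contrast on the analysis scale, with back-transformed ratio
    for log traits (``ratio`` is None for untransformed traits)."""

    beta: float
    se: float
    ci95: tuple[float, float]
    intercept: float
    lambda_hat: float
    sigma2: float
    F: float
    df: tuple[int, int]
    p: float
    loglik: float
    lambda_flat: bool
    ratio: float | None = None
    ratio_ci: tuple[float, float] | None = None
    percent_of_progenitor: float | None = None


class PGLS(BaseEstimator):
    """Phylogenetic GLS regression with Pagel's λ.

    Parameters
    ----------
    lambda_method : "ml" or a float in [0, 1]
        Maximise the profile likelihood over λ (bounded Brent, tolerance
        1e-6, both endpoints evaluated) or fix λ.
    fit_intercept : bool, default True

    Attributes (after :meth:`fit`): ``coef_``, ``intercept_``, ``se_``,
    ``lambda_``, ``lambda_flat_``, ``sigma2_``, ``loglik_``, ``fstat_``,
    ``df_``, ``pvalue_``, ``ci95_``.
    """

    _LAMBDA_TOL = 1e-6

    def __init__(self, lambda_method: str | float = "ml", fit_intercept: bool = True):
        self.lambda_method = lambda_method
        self.fit_intercept = fit_intercept

    def fit(self, X, y, C: np.ndarray) -> "PGLS":
        """Fit with feature matrix X (n × k), response y (n,) and base
        phylogenetic covariance C (n × n) aligned to the rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
            X = X.T
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        C = np.asarray(C, dtype=float)
        if C.shape != (n, n):
            raise PglsError(f"covariance shape {C.shape} does not match n={n}")
        design = np.column_stack([np.ones(n), X]) if self.fit_intercept else X

        def negll(lam: float) -> float:
            return -gls_fit(y, design, pagel_transform(C, lam)).loglik

        if self.lambda_method == "ml":
            res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                                  options={"xatol": self._LAMBDA_TOL})
            cands = [(negll(0.0), 0.0), (negll(1.0), 1.0), (res.fun, float(res.x))]
            cands = [c for c in cands if np.isfinite(c[0])]
            if not cands:
                raise PglsError("likelihood not finite anywhere in lambda in [0, 1]")
            best_nll, lam_hat = min(cands, key=lambda c: c[0])
            spread = max(c[0] for c in cands) - best_nll
            lam_flat = spread < 1e-6
        else:
            lam_hat = float(self.lambda_method)
            lam_flat = False
        fitres = gls_fit(y, design, pagel_transform(C, lam_hat))
        self.n_ = n
        self.lambda_ = lam_hat
        self.lambda_flat_ = lam_flat
        self.intercept_ = fitres.beta[0] if self.fit_intercept else 0.0
        self.coef_ = fitres.beta[1:] if self.fit_intercept else fitres.beta
        self.se_ = fitres.se[1:] if self.fit_intercept else fitres.se
        self.sigma2_ = fitres.sigma2_ml
        self.loglik_ = fitres.loglik
        k = design.shape[1]
        self.df_ = (1, n - k)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = fitres.beta / fitres.se
        t1 = tvals[1] if self.fit_intercept else tvals[0]
        self.fstat_ = float(t1 ** 2)
        self.pvalue_ = float(stats.f.sf(self.fstat_, 1, n - k))
        tq = stats.t.ppf(0.975, n - k)
        b1 = self.coef_[0]
        s1 = self.se_[0]
        self.ci95_ = (b1 - tq * s1, b1 + tq * s1)
        self._fitres = fitres
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept_ + X @ self.coef_


def pgls_ml(y, X, C, transform: str = "identity") -> PglsResult:
    """One-predictor PGLS with ML Pagel's λ, packaged for the status
    contrast (X is the crop indicator, 1 = crop, 0 = progenitor)."""
    est = PGLS(lambda_method="ml").fit(np.asarray(X, dtype=float).reshape(-1, 1), y, C)
    beta = float(est.coef_[0])
    se = float(est.se_[0])
    lo, hi = est.ci95_
    ratio = ratio_ci = pct = None
    if transform == "log":
        ratio = float(np.exp(beta))
        ratio_ci = (float(np.exp(lo)), float(np.exp(hi)))
    else:
        if est.intercept_ != 0:
            pct = float(-100.0 * beta / est.intercept_)
    return PglsResult(
        beta=beta, se=se, ci95=(float(lo), float(hi)), intercept=float(est.intercept_),
        lambda_hat=float(est.lambda_), sigma2=float(est.sigma2_), F=float(est.fstat_),
        df=est.df_, p=float(est.pvalue_), loglik=float(est.loglik_),
        lambda_flat=bool(est.lambda_flat_), ratio=ratio, ratio_ci=ratio_ci,
        percent_of_progenitor=pct,
    )


def crop_progenitor_contrast(summary: pd.DataFrame, trait: str, tree: dendropy.Tree,
                             transforms: dict[str, str] | None = None) -> PglsResult:
    """PGLS status contrast for one trait from an analysis-scale species
    summary (one row per taxon, indexed by species_id, with a ``status``
    column). Taxa with a missing trait mean are dropped (with their tips)."""
    transforms = TRAIT_TRANSFORMS if transforms is None else transforms
    sub = summary.loc[summary[trait].notna(), ["status", trait]]
    taxa = list(sub.index)
    if len(taxa) < 3:
        raise PglsError(f"trait {trait!r}: only {len(taxa)} taxa with data")
    C, order = phylo_covariance(tree, taxa)
    sub = sub.loc[order]
    y = sub[trait].to_numpy(dtype=float)
    x = (sub["status"] == "crop").to_numpy(dtype=float)
    return pgls_ml(y, x, C, transform=transforms.get(trait, "identity"))


def pgls_correlation(summary: pd.DataFrame, trait_x: str, trait_y: str,
                     tree: dendropy.Tree) -> dict:
    """Between-species trait correlation under PGLS: slope of trait_y on
    trait_x with ML λ, and R² as the squared correlation of the
    V⁻¹-whitened (centred) variables."""
    sub = summary.loc[summary[[trait_x, trait_y]].notna().all(axis=1)]
    C, order = phylo_covariance(tree, list(sub.index))
    sub = sub.loc[order]
    x = sub[trait_x].to_numpy(dtype=float)
    y = sub[trait_y].to_numpy(dtype=float)
    est = PGLS(lambda_method="ml").fit(x.reshape(-1, 1), y, C)
    V = pagel_transform(C, est.lambda_)
    c, low = cho_factor(V, lower=True)
    L = np.tril(c)
    ones = np.ones_like(y)
    xw = solve_triangular(L, x, lower=True)
    yw = solve_triangular(L, y, lower=True)
    ow = solve_triangular(L, ones, lower=True)
    # GLS-centre: project out the whitened intercept
    proj = lambda v: v - ow * (ow @ v) / (ow @ ow)
    xc, yc = proj(xw), proj(yw)
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return {"slope": float(est.coef_[0]), "intercept": float(est.intercept_),
            "lambda_hat": float(est.lambda_), "r2": r * r, "p": float(est.pvalue_),
            "F": float(est.fstat_), "df": est.df_, "n": int(y.size)}
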