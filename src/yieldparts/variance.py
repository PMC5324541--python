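"""First-order (delta-method) decomposition of the variance in yield.

For a trait vector θ with yield Y(θ), the first-order approximation is

    Var(Y) ≈ Σ_i Σ_j Cov(θ_i, θ_j) · (∂Y/∂θ_i) · (∂Y/∂θ_j)

with the gradient evaluated at the sample mean θ̄. The terms define a square
trait × trait contribution matrix; each trait's contribution to the variance
is its row sum divided by the grand total, so shares include covariance
terms and can be negative (a trait that negatively covaries with the other
determinants of yield can have a negative net contribution).

Two trait sets are supported:

* decomposition 1 (growth/allocation): θ = (Ms, λ̃, d, Ar, c),
  Y = Ms·exp(λ̃d)·Ar·(1−c)
* decomposition 2 (packaging): θ = (Ms, Ns, Ni) with Y = Ms·Ns·Ni, or
  θ = (Ms, N_total) with Y = Ms·N_total for taxa without per-infructescence
  counts.

The analysis unit defaults to species means on the natural (measurement)
scale, since Y is differentiated in natural units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

TRAITS_1 = ("Ms", "lambda_bar", "d", "Ar", "c")
TRAITS_2_CEREAL = ("Ms", "Ns", "Ni")
TRAITS_2_POOLED = ("Ms", "N_total")


def yield_function(theta: np.ndarray, decomposition: int) -> np.ndarray:
    """Evaluate Y(θ) row-wise for the given decomposition's trait order."""
    theta = np.asarray(theta, dtype=float)
    one = theta.ndim == 1
    th = np.atleast_2d(theta)
    if decomposition == 1:
        Ms, lam, d, Ar, c = th.T
        y = Ms * np.exp(lam * d) * Ar * (1.0 - c)
    elif decomposition == 2:
        y = np.prod(th, axis=1)  # Ms·Ns·Ni or Ms·N_total
    else:
        raise ValueError(f"decomposition must be 1 or 2, got {decomposition}")
    return y[0] if one else y


def gradient_yield(theta_mean: np.ndarray, decomposition: int) -> np.ndarray:
    """Analytic gradient ∂Y/∂θ at θ̄ (verified against central differences
    in the test suite).

    Decomposition 1: with Y = Ms·exp(λ̃d)·Ar·(1−c),
    ∂Y/∂Ms = Y/Ms, ∂Y/∂λ̃ = Y·d, ∂Y/∂d = Y·λ̃, ∂Y/∂Ar = Y/Ar,
    ∂Y/∂c = −Y/(1−c).
    Decomposition 2: ∂Y/∂Ms = Ns·Ni, ∂Y/∂Ns = Ms·Ni, ∂Y/∂Ni = Ms·Ns
    (or (N_total, Ms) for the two-trait variant).
    """
    th = np.asarray(theta_mean, dtype=float)
    if decomposition == 1:
        Ms, lam, d, Ar, c = th
        if Ms <= 0:
            raise ValueError("Ms must be > 0")
        if not 0 < Ar <= 1:
            raise ValueError(f"Ar={Ar} must be in (0, 1]")
        if not 0 <= c < 1:
            raise ValueError(f"c={c} must be in [0, 1)")
        Y = Ms * np.exp(lam * d) * Ar * (1.0 - c)
        return np.array([Y / Ms, Y * d, Y * lam, Y / Ar, -Y / (1.0 - c)])
    if decomposition == 2:
        if th.size == 3:
            Ms, Ns, Ni = th
            return np.array([Ns * Ni, Ms * Ni, Ms * Ns])
        if th.size == 2:
            Ms, Nt = th
            return np.array([Nt, Ms])
        raise ValueError("decomposition 2 takes 2 or 3 traits")
    raise ValueError(f"decomposition must be 1 or 2, got {decomposition}")


@dataclass(slots=True)
class ContributionTable:
    """Contribution matrix C (trait × trait), per-trait shares (row sums over
    the grand total) and the delta-method total-variance approximation."""

    traits: tuple[str, ...]
    matrix: pd.DataFrame
    shares: pd.Series
    total_variance: float
    covariance: pd.DataFrame
    gradient: pd.Series


class DeltaVarianceDecomposition(BaseEstimator):
    """Delta-method variance decomposition of yield over analysis units.

    Parameters
    ----------
    decomposition : {1, 2}
        Trait set and yield function (see module docstring).
    ddof : int, default 1
        Delta degrees of freedom for the sample covariance (n − ddof).

    Attributes (after :meth:`fit`)
    ------------------------------
    traits_ : tuple of str
        Trait columns used, in gradient order.
    mean_, gradient_ : pd.Series
        Sample mean θ̄ and ∂Y/∂θ evaluated there.
    covariance_, contributions_ : pd.DataFrame
        Sample covariance of θ and the contribution matrix
        C_ij = Cov(θ_i, θ_j)·g_i·g_j.
    shares_ : pd.Series
        Row sums of C over the grand total; sum to 1 by construction.
    total_variance_ : float
        Sum of all entries of C (the delta approximation to Var Y).
    """

    def __init__(self, decomposition: int = 1, ddof: int = 1):
        self.decomposition = decomposition
        self.ddof = ddof

    def _trait_set(self, columns) -> tuple[str, ...]:
        if self.decomposition == 1:
            want = TRAITS_1
        elif self.decomposition == 2:
            if all(t in columns for t in TRAITS_2_CEREAL):
                want = TRAITS_2_CEREAL
            else:
                want = TRAITS_2_POOLED
        else:
            raise ValueError(f"decomposition must be 1 or 2, got {self.decomposition}")
        missing = [t for t in want if t not in columns]
        if missing:
            raise ValueError(f"theta sample lacks trait column(s): {missing}")
        return want

    def fit(self, theta: pd.DataFrame, y=None) -> "DeltaVarianceDecomposition":
        """Fit on a theta sample (one row per analysis unit)."""
        if isinstance(theta, np.ndarray):
            names = TRAITS_1 if self.decomposition == 1 else (
                TRAITS_2_CEREAL if theta.shape[1] == 3 else TRAITS_2_POOLED)
            theta = pd.DataFrame(theta, columns=list(names))
        traits = self._trait_set(theta.columns)
        sample = theta.loc[:, list(traits)].astype(float)
        if sample.isna().any().any():
            raise ValueError("theta sample contains missing cells for the chosen trait set")
        n = len(sample)
        if n < 3:
            raise ValueError(f"need >= 3 analysis units, got {n}")
        mean = sample.mean(axis=0)
        grad = gradient_yield(mean.to_numpy(), self.decomposition)
        cov = np.cov(sample.to_numpy(), rowvar=False, ddof=self.ddof)
        C = cov * np.outer(grad, grad)
        total = float(C.sum())
        if total == 0:
            raise ValueError("total delta variance is zero (constant theta sample)")
        idx = pd.Index(traits, name="trait")
        self.traits_ = traits
        self.n_units_ = n
        self.mean_ = pd.Series(mean.to_numpy(), index=idx)
        self.gradient_ = pd.Series(grad, index=idx)
        self.covariance_ = pd.DataFrame(cov, index=idx, columns=idx)
        self.contributions_ = pd.DataFrame(C, index=idx, columns=idx)
        self.shares_ = pd.Series(C.sum(axis=1) / total, index=idx, name="share")
        self.total_variance_ = total
        return self

    def table_(self) -> ContributionTable:
        return ContributionTable(
            traits=self.traits_,
            matrix=self.contributions_,
            shares=self.shares_,
            total_variance=self.total_variance_,
            covariance=self.covariance_,
            gradient=self.gradient_,
        )

    def check_accuracy(self, theta: pd.DataFrame) -> dict:
        """Compare the delta total with the empirical variance of Y(θ)
        computed directly per unit.

        Returns a dict with both variances, their ratio (None when both are
        zero) and a flag raised when the ratio departs from 1 by more than
        25% — expected when trait coefficients of variation are large, since
        the approximation is first-order.
        """
        traits = self._trait_set(theta.columns)
        sample = theta.loc[:, list(traits)].astype(float).to_numpy()
        yvals = yield_function(sample, self.decomposition)
        emp = float(np.var(yvals, ddof=self.ddof))
        delta = getattr(self, "total_variance_", None)
        if delta is None:
            try:
                delta = float(self.fit(theta).total_variance_)
            except ValueError:  # constant theta: zero delta variance
                delta = 0.0
        eps = 1e-12 * (1.0 + float(np.mean(yvals)) ** 2)
        if emp == 0 and delta <= eps:  # numerically constant sample
            return {"delta_total": 0.0, "empirical": 0.0, "ratio": None, "flagged": False}
        ratio = delta / emp if emp > 0 else float("inf")
        return {
            "delta_total": delta,
            "empirical": emp,
            "ratio": ratio,
            "flagged": not (0.75 <= ratio <= 1.25),
        }


def contribution_matrix(theta: pd.DataFrame, decomposition: int = 1,
                        ddof: int = 1) -> ContributionTable:
    """Functional wrapper over :class:`DeltaVarianceDecomposition`."""
    est = DeltaVarianceDecomposition(decomposition=decomposition, ddof=ddof).fit(theta)
    return est.table_()


def check_delta_accuracy(theta: pd.DataFrame, decomposition: int = 1) -> dict:
    return DeltaVarianceDecomposition(decomposition=decomposition).fit(theta).check_accuracy(theta)


def theta_from_species_means(natural_means: pd.DataFrame, decomposition: int,
                             group: str = "all") -> pd.DataFrame:
    """Build a theta sample from natural-scale species means.

    ``group`` is ``"all"``, ``"cereals"`` or ``"pulses"``. Decomposition 1
    uses sown seed mass; decomposition 2 uses harvested seed mass, with
    (Ms, Ns, Ni) for cereals and (Ms, N_total) otherwise (per-infructescence
    counts are not measured for pulses).
    """
    df = natural_means
    if group == "cereals":
        df = df[df["family"] == "grass"]
    elif group == "pulses":
        df = df[df["family"] == "legume"]
    elif group != "all":
        raise ValueError(f"unknown group {group!r}")
    if decomposition == 1:
        out = pd.DataFrame({
            "Ms": df["Ms_sown"], "lambda_bar": df["lambda_bar"], "d": df["d"],
            "Ar": df["Ar"], "c": df["c"],
        })
    elif decomposition == 2:
        if group == "cereals":
            out = pd.DataFrame({"Ms": df["Ms_harvest"], "Ns": df["Ns"], "Ni": df["Ni"]})
        else:
            out = pd.DataFrame({"Ms": df["Ms_harvest"], "N_total": df["N_total"]})
    else:
        raise ValueError(f"decomposition must be 1 or 2, got {decomposition}")
    return out.dropna()
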