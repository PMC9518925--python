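"""Partial Pearson correlation networks with BH-controlled edge calls.

The partial correlation of a species pair, conditioned on all remaining
species, comes from the inverse of the correlation matrix (the precision
matrix P): rho_ij = -P_ij / sqrt(P_ii P_jj). Significance uses the exact
t-transform under Gaussian residuals with conditioning-set-corrected degrees
of freedom, and the Benjamini-Hochberg step-up procedure controls the false
discovery rate over the s(s-1)/2 lower-triangle pairs of one dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PartialCorrelationResult",
    "partial_correlation_matrix",
    "partial_correlation_pvalues",
    "bh_adjust",
    "infer_network",
    "edge_table",
]

# condition-number ceiling beyond which we refuse to invert (collinearity);
# reported, never silently regularized
_MAX_COND = 1e12


@dataclass(frozen=True)
class PartialCorrelationResult:
    """rho matrix plus per-pair raw/adjusted p-values and significance.

    ``pairs`` lists the lower-triangle (i, j) index pairs (i > j) in the
    order used by ``p_raw``/``p_adjusted``/``significant``.
    """

    rho: np.ndarray  # (s, s), symmetric, unit diagonal
    pairs: np.ndarray  # (n_pairs, 2) ints, i > j
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray  # bool
    n_hosts: int
    level: float = 0.05

    @property
    def n_species(self) -> int:
        return self.rho.shape[0]

    def significant_matrix(self) -> np.ndarray:
        """Symmetric boolean matrix of significant pairs."""
        s = self.n_species
        m = np.zeros((s, s), bool)
        i, j = self.pairs.T
        m[i, j] = m[j, i] = self.significant
        return m


def partial_correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Partial correlations of every column pair given all other columns.

    Parameters
    ----------
    X : ndarray, shape (n_hosts, n_species)
        Cross-sectional abundance matrix. Requires n_hosts > n_species + 2
        and non-constant columns.
    """
    X = np.asarray(X, float)
    n, s = X.shape
    if n <= s + 2:
        raise ValueError(f"need more than {s + 2} observations for {s} variables")
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("constant column: correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("non-finite correlation matrix")
    if np.linalg.cond(R) > _MAX_COND:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular (collinear columns); "
            "partial correlations are not identifiable"
        )
    P = np.linalg.inv(R)
    d = np.sqrt(np.diag(P))
    rho = -P / np.outer(d, d)
    rho = (rho + rho.T) / 2.0  # symmetrize away rounding asymmetry
    np.fill_diagonal(rho, 1.0)
    return rho


def partial_correlation_pvalues(
    rho: np.ndarray, n_hosts: int, n_conditioned: int | None = None
) -> np.ndarray:
    """Two-sided p-values for the lower-triangle partial correlations.

    Uses t = rho * sqrt(df / (1 - rho^2)) with df = n - 2 - g, where g is the
    size of the conditioning set (all remaining species, g = s - 2, unless
    overridden). Returns p-values in lower-triangle (row-major, i > j) order.
    """
    rho = np.asarray(rho, float)
    s = rho.shape[0]
    g = s - 2 if n_conditioned is None else n_conditioned
    df = n_hosts - 2 - g
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    i, j = np.tril_indices(s, k=-1)
    r = np.clip(rho[i, j], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) == 1.0] = 0.0
    return p


def bh_adjust(p_raw: np.ndarray, level: float = 0.05):
    """Benjamini-Hochberg step-up adjustment over one dataset's tests.

    Returns (p_adjusted, significant) with significance defined as adjusted
    p < level. Adjusted values are the usual monotone step-up quantities
    capped at 1.
    """
    p_raw = np.asarray(p_raw, float)
    if p_raw.size == 0:
        return p_raw.copy(), np.zeros(0, bool)
    if np.any((p_raw < 0) | (p_raw > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    return p_adj, p_adj < level


def infer_network(
    X: np.ndarray, level: float = 0.05, n_conditioned: int | None = None
) -> PartialCorrelationResult:
    """Full inference pass on one hosts x species abundance matrix."""
    X = np.asarray(X, float)
    n = X.shape[0]
    rho = partial_correlation_matrix(X)
    p_raw = partial_correlation_pvalues(rho, n, n_conditioned)
    p_adj, sig = bh_adjust(p_raw, level)
    i, j = np.tril_indices(rho.shape[0], k=-1)
    return PartialCorrelationResult(
        rho=rho,
        pairs=np.column_stack([i, j]),
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=sig,
        n_hosts=n,
        level=level,
    )


def edge_table(result: PartialCorrelationResult):
    """Tidy per-pair edge table (i, j, rho, p_raw, p_adj, significant)."""
    import pandas as pd

    i, j = result.pairs.T
    return pd.DataFrame(
        {
            "i": i,
            "j": j,
            "rho": result.rho[i, j],
            "p_raw": result.p_raw,
            "p_adj": result.p_adjusted,
            "significant": result.significant,
        }
    )
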