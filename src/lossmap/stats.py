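"""Cross-layer association statistics.

Ordinary least squares with R-squared, Spearman partial rank correlation
(rank-then-Pearson-partial with a t-based p-value at n-3 degrees of
freedom), upper-tail hypergeometric over-representation, and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_se: float
    slope_se: float

    @property
    def slope_magnitude(self) -> float:
        return abs(self.slope)

    def to_payload(self) -> dict:
        return {
            "slope": self.slope,
            "slope_magnitude": self.slope_magnitude,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "residual_se": self.residual_se,
            "slope_se": self.slope_se,
        }


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares line y = a + b*x with R^2 = 1 - SS_res / SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be equal-length 1-D series")
    n = x.size
    if n < 3:
        raise StatsError("ols_fit requires n >= 3")
    if np.ptp(x) == 0:
        raise StatsError("x is constant")
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(model.rsquared),
        n=int(n),
        residual_se=float(np.sqrt(model.scale)),
        slope_se=float(model.bse[1]),
    )


@dataclass(frozen=True)
class PartialCorrResult:
    coefficient: float
    p_value: float
    n: int
    covariate: str
    method: str  # "partial-spearman" or "spearman" fallback

    def to_payload(self) -> dict:
        return {
            "coefficient": self.coefficient,
            "p_value": self.p_value,
            "n": self.n,
            "covariate": self.covariate,
            "method": self.method,
        }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def spearman_partial(
    x: Sequence[float],
    y: Sequence[float],
    covariate: Sequence[float],
    covariate_label: str = "covariate",
) -> PartialCorrResult:
    """First-order partial rank correlation of x and y controlling covariate.

    All three series are rank-transformed (average ranks for ties), then
    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the
    two-sided p-value comes from a t statistic with n - 3 df.  A covariate
    that is constant after ranking triggers a fallback to plain Spearman
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise StatsError("x, y and covariate must be equal-length 1-D series")
    n = x.size
    if n < 4:
        raise StatsError("spearman_partial requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("constant x or y")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rz = sps.rankdata(z)
    if np.ptp(rz) == 0:
        warnings.warn(
            "covariate constant after ranking; falling back to plain Spearman",
            stacklevel=2,
        )
        rho, p = sps.spearmanr(x, y)
        return PartialCorrResult(
            coefficient=float(rho),
            p_value=float(p),
            n=n,
            covariate=covariate_label,
            method="spearman",
        )
    r_xy = _pearson(rx, ry)
    r_xz = _pearson(rx, rz)
    r_yz = _pearson(ry, rz)
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0:
        raise StatsError("covariate perfectly correlated with x or y after ranking")
    r = (r_xy - r_xz * r_yz) / denom
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrResult(
        coefficient=r,
        p_value=p,
        n=n,
        covariate=covariate_label,
        method="partial-spearman",
    )


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap: int       # k
    term_size: int     # K
    set_size: int      # n
    universe_size: int  # N
    p_value: float
    q_value: float

    def to_payload(self) -> dict:
        return {
            "term": self.term,
            "overlap": self.overlap,
            "term_size": self.term_size,
            "set_size": self.set_size,
            "universe_size": self.universe_size,
            "p_value": self.p_value,
            "q_value": self.q_value,
        }


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise StatsError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = ranked
    return q.tolist()


def hypergeom_enrich(
    gene_set: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation per term, sorted by p.

    For each term with K annotated genes in a universe of N, and a query
    set of n genes overlapping the term in k, p = P(X >= k).
    """
    universe_set = set(universe)
    if not universe_set:
        raise StatsError("empty universe")
    query = set(gene_set)
    stray = query - universe_set
    if stray:
        raise StatsError(f"gene set not contained in universe: {sorted(stray)[:5]}")
    N = len(universe_set)
    n = len(query)
    terms: list[tuple[str, int, int, float]] = []
    for term, genes in annotations.items():
        term_genes = set(genes)
        stray = term_genes - universe_set
        if stray:
            raise StatsError(
                f"term {term!r} annotates genes outside the universe: "
                f"{sorted(stray)[:5]}"
            )
        K = len(term_genes)
        k = len(term_genes & query)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        terms.append((term, k, K, p))
    terms.sort(key=lambda t: (t[3], t[0]))
    qvals = bh_adjust([t[3] for t in terms])
    return [
        EnrichmentResult(
            term=term,
            overlap=k,
            term_size=K,
            set_size=n,
            universe_size=N,
            p_value=p,
            q_value=q,
        )
        for (term, k, K, p), q in zip(terms, qvals)
    ]
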