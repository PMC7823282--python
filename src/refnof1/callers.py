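"""Built-in differential-expression callers and the external-table adapter.

Replicated RNA-seq comparisons are normally analysed with dedicated tools
(edgeR, DESeq2, NOISeq, ...); their output enters this package through
:func:`adapt_external`. The built-in callers below are deliberately simple,
transparent statistics spanning the same distributional families — an exact
conditional (hypergeometric) test on pooled counts, a negative-binomial Wald
test, an exact rank-sum test, and a delta-method test on the log2 ratio of
scaled means — so that the concordance/consensus machinery can be exercised
end-to-end without external dependencies. Method identity is a plain string,
so external tools slot in transparently alongside the built-ins.

Multiple-testing correction is Benjamini–Hochberg, computed over exactly the
p-values of the expression-filtered universe handed to :func:`call_degs`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Callable, FrozenSet, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import CapabilityError, ConfigurationError, ValidationError
from .io import CountMatrix, ExternalDEGTable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
#: uniform significance levels used in practice; both are exposed as presets
ALPHA_PRESETS = (0.05, 0.001)

_DISP_MIN, _DISP_MAX = 1e-8, 10.0


@dataclass(frozen=True)
class DEGSet:
    """One method's significant genes within one grid region."""

    method_id: str
    region_id: str
    genes: FrozenSet[str]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Exact conditional test on pooled counts (hypergeometric)

#: gene totals up to this size take the exact integer-arithmetic path
_EXACT_SUPPORT_MAX = 64
#: log-space tolerance for probability ties in the float path
_LOG_TIE_TOL = 1e-9


def hypergeom_two_sided_p(k_obs: int, t: int, lib_a: int, lib_b: int) -> float:
    """Two-sided p of the exact conditional test on a pooled 2x2 table.

    Conditioning on the gene's pooled total ``t`` and the two library sizes,
    the count in condition A is hypergeometric under the null of equal
    proportions; the two-sided p-value sums the probabilities of all tables
    no more probable than the observed one.

    Small tables (``t`` <= 64) are evaluated in exact integer arithmetic so
    probability ties are resolved exactly; larger tables use log-space
    summation with a 1e-9 relative tie tolerance.
    """
    if t == 0:
        return 1.0
    k_min = max(0, t - lib_b)
    k_max = min(t, lib_a)
    if not (k_min <= k_obs <= k_max):
        raise ValidationError("observed count incompatible with margins")
    if t <= _EXACT_SUPPORT_MAX:
        nums = [comb(lib_a, k) * comb(lib_b, t - k)
                for k in range(k_min, k_max + 1)]
        obs = nums[k_obs - k_min]
        total = comb(lib_a + lib_b, t)
        p = Fraction(sum(n for n in nums if n <= obs), total)
        return float(min(p, Fraction(1)))
    k = np.arange(k_min, k_max + 1)
    logpmf = (
        gammaln(lib_a + 1) - gammaln(k + 1) - gammaln(lib_a - k + 1)
        + gammaln(lib_b + 1) - gammaln(t - k + 1) - gammaln(lib_b - t + k + 1)
        - (gammaln(lib_a + lib_b + 1) - gammaln(t + 1)
           - gammaln(lib_a + lib_b - t + 1))
    )
    log_obs = logpmf[k_obs - k_min]
    include = logpmf <= log_obs + _LOG_TIE_TOL
    return float(min(1.0, np.exp(logsumexp(logpmf[include]))))


def pooled_exact(counts: CountMatrix) -> pd.DataFrame:
    """Exact conditional test per gene on condition-pooled counts.

    Pools counts within each condition, then tests each gene's 2x2 table
    (gene count vs remainder of the pooled library, condition A vs B).
    Valid down to one sample per condition.
    """
    a, b = counts.condition_labels
    pooled_a = counts.counts[counts.samples_in(a)].sum(axis=1)
    pooled_b = counts.counts[counts.samples_in(b)].sum(axis=1)
    lib_a = int(pooled_a.sum())
    lib_b = int(pooled_b.sum())
    p = np.ones(len(pooled_a))
    if lib_a > 0 and lib_b > 0:
        ka = pooled_a.to_numpy()
        kb = pooled_b.to_numpy()
        for i, (xa, xb) in enumerate(zip(ka, kb)):
            p[i] = hypergeom_two_sided_p(int(xa), int(xa + xb), lib_a, lib_b)
        with np.errstate(divide="ignore"):
            log2fc = np.log2(((ka + 0.5) / max(lib_a, 1))
                             / ((kb + 0.5) / max(lib_b, 1)))
    else:
        log2fc = np.zeros(len(pooled_a))
    return pd.DataFrame({"log2fc": log2fc, "pvalue": p},
                        index=counts.gene_ids)


# ---------------------------------------------------------------------------
# Shared helpers for the mean-based tests


def _size_factors(counts: CountMatrix) -> np.ndarray:
    lib = counts.library_sizes.to_numpy(dtype=float)
    mean = lib.mean()
    if mean <= 0:
        return np.ones_like(lib)
    sf = lib / mean
    sf[sf == 0] = 1.0
    return sf


def _condition_split(counts: CountMatrix):
    a, b = counts.condition_labels
    ia = [counts.sample_ids.get_loc(s) for s in counts.samples_in(a)]
    ib = [counts.sample_ids.get_loc(s) for s in counts.samples_in(b)]
    return np.array(ia), np.array(ib)


def _mom_dispersion(y: np.ndarray, sf: np.ndarray, ia: np.ndarray,
                    ib: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments dispersion from within-condition variance.

    For scaled counts y = x/s with x ~ NB(mu*s, phi): Var(y) = mu/s + phi*mu^2,
    so phi = (pooled within-condition variance - mu * mean(1/s)) / mu^2.
    """
    na, nb = len(ia), len(ib)
    ssa = ((y[:, ia] - y[:, ia].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((y[:, ib] - y[:, ib].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = (ssa + ssb) / max(na + nb - 2, 1)
    mu = y.mean(axis=1)
    inv_s = float(np.mean(1.0 / sf))
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (pooled_var - mu * inv_s) / np.where(mu > 0, mu ** 2, np.nan)
    return np.clip(np.nan_to_num(phi, nan=_DISP_MIN), _DISP_MIN, _DISP_MAX)


def _trend_shrink(phi: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Shrink per-gene dispersions toward a fitted a + b/mu mean trend."""
    ok = mu > 0
    if ok.sum() < 10:
        return phi
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(x, phi[ok], rcond=None)
    a, b = max(coef[0], 0.0), max(coef[1], 0.0)
    trend = np.clip(a + np.divide(b, mu, out=np.full_like(mu, _DISP_MAX),
                                  where=mu > 0), _DISP_MIN, _DISP_MAX)
    # 1:2 weighting of gene-wise vs trended estimate (few replicates make the
    # gene-wise estimate noisy; the trend carries most of the information)
    return np.clip((phi + 2.0 * trend) / 3.0, _DISP_MIN, _DISP_MAX)


def _log_ratio_test(counts: CountMatrix, phi: np.ndarray) -> pd.DataFrame:
    """Wald-type test on ln(qA/qB) with delta-method NB variance.

    qA, qB are scaled condition means; Var(ln qA) is approximated as
    (1/nA^2) * (sum_j 1/(qA*s_j) + nA*phi) and the statistic is referenced
    against the standard normal. The plug-in variance makes the test mildly
    anticonservative at very small replicate numbers.
    """
    sf = _size_factors(counts)
    ia, ib = _condition_split(counts)
    y = counts.counts.to_numpy(dtype=float) / sf
    na, nb = len(ia), len(ib)
    qa = y[:, ia].mean(axis=1)
    qb = y[:, ib].mean(axis=1)
    any_zero = (qa == 0) | (qb == 0)
    qa_ = np.where(any_zero, qa + 0.5, qa)
    qb_ = np.where(any_zero, qb + 0.5, qb)
    beta = np.log(qa_) - np.log(qb_)
    inv_sa = float(np.sum(1.0 / sf[ia]))
    inv_sb = float(np.sum(1.0 / sf[ib]))
    var_a = (inv_sa / qa_ + na * phi) / na ** 2
    var_b = (inv_sb / qb_ + nb * phi) / nb ** 2
    se = np.sqrt(var_a + var_b)
    z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"log2fc": beta / np.log(2.0),
                         "pvalue": np.minimum(p, 1.0)},
                        index=counts.gene_ids)


def nb_wald(counts: CountMatrix, dispersion: float | None = None
            ) -> pd.DataFrame:
    """Negative-binomial Wald test on the log fold change.

    Per-gene method-of-moments dispersions are shrunk toward the fitted
    mean–variance trend; with one sample per condition a fixed external
    ``dispersion`` must be supplied (TWCR mode). Library sizes enter as
    total-count offsets.
    """
    ia, ib = _condition_split(counts)
    na, nb = len(ia), len(ib)
    if dispersion is None:
        if min(na, nb) < 2:
            raise CapabilityError(
                "nb_wald needs >= 2 replicates per condition to estimate "
                "dispersion; supply a fixed dispersion for 1-vs-1 designs"
            )
        sf = _size_factors(counts)
        y = counts.counts.to_numpy(dtype=float) / sf
        phi = _trend_shrink(_mom_dispersion(y, sf, ia, ib), y.mean(axis=1))
    else:
        if dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        phi = np.full(len(counts.gene_ids), max(dispersion, _DISP_MIN))
    return _log_ratio_test(counts, phi)


def zlogfc(counts: CountMatrix, dispersion: float | None = None
           ) -> pd.DataFrame:
    """Test on the log2 ratio of scaled condition means.

    The per-gene variance comes from a Poisson-plus-dispersion delta-method
    approximation with a single common dispersion (median of the per-gene
    method-of-moments estimates, or a fixed external value for 1-vs-1).
    """
    ia, ib = _condition_split(counts)
    na, nb = len(ia), len(ib)
    if dispersion is None:
        if min(na, nb) < 2:
            raise CapabilityError(
                "zlogfc needs >= 2 replicates per condition to estimate a "
                "common dispersion; supply a fixed dispersion for 1-vs-1"
            )
        sf = _size_factors(counts)
        y = counts.counts.to_numpy(dtype=float) / sf
        per_gene = _mom_dispersion(y, sf, ia, ib)
        expressed = y.mean(axis=1) > 0
        common = float(np.median(per_gene[expressed])) if expressed.any() \
            else _DISP_MIN
        phi = np.full(len(counts.gene_ids), max(common, _DISP_MIN))
    else:
        if dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        phi = np.full(len(counts.gene_ids), max(dispersion, _DISP_MIN))
    return _log_ratio_test(counts, phi)


# ---------------------------------------------------------------------------
# Exact rank-sum test


@lru_cache(maxsize=64)
def _mwu_pmf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of the Mann–Whitney U statistic (no ties), by counting."""
    u_max = n1 * n2
    c = np.zeros((n1 + 1, u_max + 1))
    c[:, 0] = 1.0
    for n in range(1, n2 + 1):
        new = c.copy()
        for m in range(1, n1 + 1):
            new[m, n:] += new[m - 1, :-n]
        c = new
    return c[n1] / comb(n1 + n2, n1)


def rank_sum(counts: CountMatrix) -> pd.DataFrame:
    """Exact two-sided rank-sum (Mann–Whitney) test on scaled counts.

    Requires >= 3 replicates per condition. Genes with tied scaled counts
    fall back to the tie-corrected normal approximation with continuity
    correction.
    """
    ia, ib = _condition_split(counts)
    na, nb = len(ia), len(ib)
    if min(na, nb) < 3:
        raise CapabilityError("rank_sum needs >= 3 replicates per condition")
    sf = _size_factors(counts)
    y = counts.counts.to_numpy(dtype=float) / sf
    data = np.concatenate([y[:, ia], y[:, ib]], axis=1)
    ranks = stats.rankdata(data, axis=1)
    r_a = ranks[:, :na].sum(axis=1)
    u = r_a - na * (na + 1) / 2.0
    m = na * nb
    has_ties = np.array([len(np.unique(row)) < row.size for row in data])

    p = np.ones(len(u))
    pmf = _mwu_pmf(na, nb)
    cdf = np.cumsum(pmf)
    exact = ~has_ties
    if exact.any():
        u_int = np.rint(u[exact]).astype(int)
        lo = np.minimum(u_int, m - u_int)
        hi = m - lo
        # p = P(U <= lo) + P(U >= hi); when lo == hi the tails coincide
        p_ex = np.where(lo == hi, 1.0, cdf[lo] + 1.0 - cdf[np.maximum(hi, 1) - 1])
        p[exact] = np.minimum(p_ex, 1.0)
    if has_ties.any():
        n_tot = na + nb
        mu_u = m / 2.0
        tie_term = np.zeros(int(has_ties.sum()))
        for j, row in enumerate(data[has_ties]):
            _, cnt = np.unique(row, return_counts=True)
            tie_term[j] = np.sum(cnt ** 3 - cnt)
        var_u = (m / 12.0) * (n_tot + 1 - tie_term / (n_tot * (n_tot - 1)))
        var_u = np.maximum(var_u, 1e-12)
        z = (np.abs(u[has_ties] - mu_u) - 0.5) / np.sqrt(var_u)
        p[has_ties] = np.minimum(2.0 * stats.norm.sf(np.maximum(z, 0.0)), 1.0)

    qa = y[:, ia].mean(axis=1)
    qb = y[:, ib].mean(axis=1)
    any_zero = (qa == 0) | (qb == 0)
    log2fc = np.log2(np.where(any_zero, qa + 0.5, qa)
                     / np.where(any_zero, qb + 0.5, qb))
    return pd.DataFrame({"log2fc": log2fc, "pvalue": p},
                        index=counts.gene_ids)


# ---------------------------------------------------------------------------
# Registry and driver


@dataclass(frozen=True)
class MethodSpec:
    func: Callable[..., pd.DataFrame]
    min_replicates: int
    #: usable on a 1-vs-1 pair (possibly requiring a fixed dispersion)
    twcr_capable: bool
    needs_dispersion_for_twcr: bool = False


METHODS: dict[str, MethodSpec] = {
    "pooled_exact": MethodSpec(pooled_exact, 1, True),
    "nb_wald": MethodSpec(nb_wald, 2, True, needs_dispersion_for_twcr=True),
    "rank_sum": MethodSpec(rank_sum, 3, False),
    "zlogfc": MethodSpec(zlogfc, 2, True, needs_dispersion_for_twcr=True),
}


def call_degs(method: str, counts: CountMatrix,
              alpha: float = DEFAULT_ALPHA, **params) -> pd.DataFrame:
    """Run one registered caller on a (filtered) count matrix.

    Returns one row per gene in the matrix with columns ``log2fc``,
    ``pvalue``, ``padj`` (Benjamini–Hochberg over exactly this universe)
    and ``significant`` (padj < alpha).
    """
    if method not in METHODS:
        raise ConfigurationError(
            f"unknown method {method!r}; registered: {sorted(METHODS)}"
        )
    spec = METHODS[method]
    a, b = counts.condition_labels
    n_min = min(len(counts.samples_in(a)), len(counts.samples_in(b)))
    needs = spec.min_replicates
    if "dispersion" in params and params["dispersion"] is not None \
            and spec.needs_dispersion_for_twcr:
        needs = 1
    if n_min < needs:
        raise CapabilityError(
            f"method {method!r} requires >= {needs} replicates per "
            f"condition, got {n_min}"
        )
    result = spec.func(counts, **params)
    result = result.copy()
    result["padj"] = bh_adjust(result["pvalue"].to_numpy())
    result["significant"] = result["padj"] < alpha
    return result


def significant_genes(result: pd.DataFrame) -> frozenset[str]:
    return frozenset(result.index[result["significant"]])


def adapt_external(table: ExternalDEGTable, universe: Sequence[str],
                   alpha: float = DEFAULT_ALPHA,
                   region_id: str = "") -> DEGSet:
    """Threshold an external tool's table within a gene universe.

    The external tool's own multiple-testing correction is authoritative:
    its ``padj`` is compared to ``alpha`` with no re-adjustment. Universe
    genes absent from the table are treated as untested (logged).
    """
    universe_set = set(universe)
    present = universe_set & set(table.table.index)
    missing = len(universe_set) - len(present)
    if missing:
        logger.info("adapt_external(%s): %d universe genes absent from table",
                    table.method_id, missing)
    padj = table.table.loc[sorted(present), "padj"]
    genes = frozenset(padj.index[padj < alpha])
    return DEGSet(method_id=table.method_id, region_id=region_id, genes=genes)
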