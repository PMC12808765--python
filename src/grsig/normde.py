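"""Count normalization and differential expression.

TMM (trimmed mean of M-values) between-sample normalization, logCPM
transformation, low-expression filtering, and a per-contrast Welch t test
on logCPM with Benjamini-Hochberg correction. The TMM routine follows the
published algorithm: reference chosen by the 75th-percentile CPM rule,
gene-wise log-ratios doubly trimmed by M (30%) and A (5%), and the factor
taken as the inverse-variance-weighted mean of the surviving M values,
with factors rescaled to geometric mean one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError


def _libsizes(counts: pd.DataFrame) -> np.ndarray:
    y = counts.to_numpy()
    if (y < 0).any():
        raise DataError("count matrix contains negative entries")
    lib = y.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise DataError(f"all-zero sample(s): {list(counts.columns[zero])}")
    return lib.astype(float)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """log2 TMM factor of one sample against the reference."""
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        raise DataError("sample shares no nonzero gene with the reference")
    o = obs[mask] / n_obs
    r = ref[mask] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic binomial (delta-method) variance of M
    v = (n_obs - obs[mask]) / (n_obs * obs[mask]) + (n_ref - ref[mask]) / (n_ref * ref[mask])
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile CPM is closest
    to the mean 75th percentile across samples.
    """
    if counts.shape[1] < 2:
        raise DataError("TMM requires at least two samples")
    lib = _libsizes(counts)
    y = counts.to_numpy(dtype=float)
    f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    logf = np.array(
        [
            0.0 if j == ref else _tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref],
                                           trim_m, trim_a)
            for j in range(y.shape[1])
        ]
    )
    factors = np.exp2(logf)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def logcpm(counts: pd.DataFrame, norm_factors: pd.Series | None = None,
           prior: float = 0.5) -> pd.DataFrame:
    """log2 counts per million against TMM-effective library sizes.

    logCPM_gs = log2( (y_gs + prior) / (libsize_s * f_s + 2 * prior) * 1e6 ).
    """
    if prior <= 0:
        raise DataError("prior count must be > 0")
    lib = _libsizes(counts)
    if norm_factors is not None:
        lib = lib * norm_factors.reindex(counts.columns).to_numpy()
    if (lib <= 0).any():
        raise DataError("nonpositive effective library size")
    y = counts.to_numpy(dtype=float)
    vals = np.log2((y + prior) / (lib + 2 * prior)[None, :] * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def filter_low_expressed(counts: pd.DataFrame, samples: pd.DataFrame | None = None,
                         min_cpm: float = 1.0,
                         min_samples: int | None = None) -> pd.Series:
    """Boolean keep-mask: CPM >= min_cpm in at least ``min_samples`` samples.

    ``min_samples`` defaults to the smallest experimental group size
    (model x treatment x timepoint) from the sample sheet, or 3 if no
    sheet is given.
    """
    if min_samples is None:
        if samples is not None:
            grp_cols = [c for c in ("model", "treatment", "timepoint")
                        if c in samples.columns]
            min_samples = int(samples.groupby(grp_cols).size().min()) if grp_cols else 3
        else:
            min_samples = min(3, counts.shape[1])
    lib = _libsizes(counts)
    cpm = counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return pd.Series(keep, index=counts.index, name="keep")


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances toward a common prior.

    Method-of-moments fit of a scaled inverse-chi-square prior on the
    log sample variances (the squeezeVar approach): returns the posterior
    variances (d0*s0^2 + df*s2) / (d0 + df) and the prior df d0. If the
    observed spread of log variances is no larger than expected from
    chi-square sampling alone, d0 is infinite and all variances collapse
    to the common value.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0
    z = np.log(s2[ok])
    e_z = z.mean()
    var_z = z.var(ddof=1)
    excess = var_z - float(special.polygamma(1, df / 2))
    if excess <= 0:
        s0_2 = np.exp(e_z - special.digamma(df / 2) + np.log(df / 2))
        return np.full_like(s2, s0_2), np.inf
    # invert the trigamma function by Newton's method
    y = excess
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        delta = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0_2 = np.exp(e_z - special.digamma(df / 2) + special.digamma(d0 / 2)
                  - np.log(d0 / df))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def de_test(log_expr: pd.DataFrame, group_a: list[str], group_b: list[str],
            moderated: bool = True) -> pd.DataFrame:
    """Per-gene two-sample t test of group A vs group B on logCPM.

    By default the pooled per-gene variances are moderated by
    empirical-Bayes shrinkage toward a common prior (borrowing strength
    across genes, as small-replicate designs require); ``moderated=False``
    gives a plain Welch t. Returns logFC (mean A - mean B, log2 units),
    p_value and BH-adjusted fdr. Genes with zero (posterior) variance and
    equal means get p = 1 by convention.
    """
    if len(set(group_a) & set(group_b)):
        raise DataError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataError("each group needs at least 2 samples")
    xa = log_expr[list(group_a)].to_numpy()
    xb = log_expr[list(group_b)].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    lfc = ma - mb
    if moderated:
        d_res = na + nb - 2
        s2 = ((na - 1) * va + (nb - 1) * vb) / d_res
        post, d0 = _squeeze_var(s2, d_res)
        se2 = post * (1.0 / na + 1.0 / nb)
        df = np.full_like(se2, min(d_res + d0, 1e6))
    else:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2 ** 2 / (va ** 2 / (na ** 2 * (na - 1)) + vb ** 2 / (nb ** 2 * (nb - 1)))
    p = np.ones_like(lfc)
    ok = se2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(se2)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    return pd.DataFrame(
        {"logFC": lfc, "p_value": p, "fdr": bh_adjust(p)}, index=log_expr.index
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise DataError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def threshold_de(de: pd.DataFrame, lfc: float = 1.0, fdr: float = 0.01,
                 direction: str = "both") -> pd.Index:
    """Genes with fdr < threshold and |logFC| > threshold (strict).

    ``direction`` restricts the sign: 'up' keeps logFC > lfc, 'down' keeps
    logFC < -lfc, 'both' keeps |logFC| > lfc.
    """
    if lfc <= 0:
        raise DataError("lfc threshold must be > 0")
    sig = de["fdr"] < fdr
    if direction == "up":
        sig &= de["logFC"] > lfc
    elif direction == "down":
        sig &= de["logFC"] < -lfc
    elif direction == "both":
        sig &= de["logFC"].abs() > lfc
    else:
        raise DataError(f"unknown direction {direction!r}")
    return de.index[sig]
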