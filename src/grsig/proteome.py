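"""TMT reporter-ion quantification.

Channel equalization (each channel scaled so every total matches the mean
channel total), PSM-to-protein rollup by summation, differential
abundance on log2(x + 1) intensities with a two-sample t test (optional
variance moderation) and BH correction, and RNA-protein fold-change
concordance by Pearson correlation on the gene-joined tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .normde import bh_adjust

META_COLS = ("psm_id", "protein", "gene")


def channel_columns(m: pd.DataFrame) -> list[str]:
    return [c for c in m.columns if c not in META_COLS]


def normalize_channels(m: pd.DataFrame,
                       channel_cols: list[str] | None = None) -> pd.DataFrame:
    """Equalize total reporter ion intensity across channels.

    Each channel is scaled by (mean channel total / its own total), so all
    post-normalization totals equal the mean of the input totals.
    Within-channel intensity ratios are preserved exactly.
    """
    cols = channel_cols or channel_columns(m)
    totals = m[cols].sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise DataError(f"zero-total channel(s): {bad}")
    out = m.copy()
    out[cols] = m[cols] * (totals.mean() / totals)
    return out


def rollup_proteins(m: pd.DataFrame,
                    channel_cols: list[str] | None = None,
                    protein_col: str = "protein") -> pd.DataFrame:
    """Sum PSM intensities per protein and channel.

    PSMs without a protein mapping are excluded; their count is recorded
    in ``result.attrs['n_unmapped']``. A ``psm_count`` column records the
    number of PSMs contributing to each protein.
    """
    cols = channel_cols or channel_columns(m)
    mapped = m[m[protein_col].notna()]
    n_unmapped = len(m) - len(mapped)
    grouped = mapped.groupby(protein_col)[cols].sum()
    grouped["psm_count"] = mapped.groupby(protein_col).size()
    grouped.attrs["n_unmapped"] = int(n_unmapped)
    return grouped


def protein_de(ab: pd.DataFrame, group_a: list[str], group_b: list[str],
               lfc: float = 0.5, fdr: float = 0.05,
               moderated: bool = False, prior_df: float = 4.0) -> pd.DataFrame:
    """Differential abundance of group A vs group B on log2(x + 1) intensities.

    logFC is the group-mean difference; p from a Welch two-sample t, or,
    with ``moderated=True``, a pooled-variance t with per-protein variances
    shrunk toward the mean variance with ``prior_df`` prior degrees of
    freedom. ``significant`` applies the strict |logFC| > lfc and
    fdr < threshold rule.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataError("each group needs at least 2 channels")
    xa = np.log2(ab[list(group_a)].to_numpy() + 1.0)
    xb = np.log2(ab[list(group_b)].to_numpy() + 1.0)
    na, nb = xa.shape[1], xb.shape[1]
    lfc_hat = xa.mean(axis=1) - xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    if moderated:
        d = na + nb - 2
        s2 = ((na - 1) * va + (nb - 1) * vb) / d
        s2_shrunk = (prior_df * s2.mean() + d * s2) / (prior_df + d)
        se2 = s2_shrunk * (1.0 / na + 1.0 / nb)
        dof = np.full_like(se2, d + prior_df)
    else:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            dof = se2 ** 2 / (va ** 2 / (na ** 2 * (na - 1)) + vb ** 2 / (nb ** 2 * (nb - 1)))
    p = np.ones_like(lfc_hat)
    ok = se2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, lfc_hat / np.sqrt(se2), 0.0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), dof[ok])
    out = pd.DataFrame(
        {"logFC": lfc_hat, "p_value": p, "fdr": bh_adjust(p)}, index=ab.index
    )
    out["significant"] = (out["fdr"] < fdr) & (out["logFC"].abs() > lfc)
    return out


def correlate_rna_protein(rna_de: pd.DataFrame, prot_de: pd.DataFrame
                          ) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of RNA and protein logFC over shared gene symbols."""
    joined = rna_de[["logFC"]].join(prot_de[["logFC"]], how="inner",
                                    lsuffix="_rna", rsuffix="_protein")
    if len(joined) < 3:
        raise DataError("fewer than 3 shared gene symbols")
    r = float(stats.pearsonr(joined["logFC_rna"], joined["logFC_protein"]).statistic)
    return r, joined
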