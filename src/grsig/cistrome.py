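"""ChIP-seq peak filtering and GREAT-style peak-to-gene assignment.

All coordinates follow the BED convention: 0-based, half-open [start,
end). Peaks are filtered by excluded chromosomes / blacklist overlap and
by per-sample log-enrichment; ER/GR co-binding is classified on merged
regions; each gene gets a basal-plus-extension regulatory domain (basal:
5 kb upstream, 1 kb downstream of the TSS, strand-oriented; extension:
outward up to a distal limit, with the gap between neighboring basal
domains split at its midpoint so extensions never overlap); a peak is
assigned to every gene whose domain contains the peak midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

BED_COLS = ["chrom", "start", "end"]
DEFAULT_EXCLUDED_CHROMS = frozenset({"chrM", "chrX", "chrY"})


@dataclass
class RegulatoryDomainParams:
    """Basal-plus-extension settings (defaults: 5 kb up, 1 kb down, 1 kb distal)."""

    basal_up: int = 5000
    basal_down: int = 1000
    distal_limit: int = 1000

    def __post_init__(self):
        if min(self.basal_up, self.basal_down, self.distal_limit) < 0:
            raise DataError("regulatory domain parameters must be >= 0")


def _check_intervals(peaks: pd.DataFrame) -> None:
    for col in BED_COLS:
        if col not in peaks.columns:
            raise DataError(f"peak table lacks column {col!r}")
    bad = peaks.index[peaks["start"] >= peaks["end"]]
    if len(bad):
        raise DataError(f"malformed interval at row(s) {list(bad[:5])}: start >= end")


def _sorted(peaks: pd.DataFrame) -> pd.DataFrame:
    return peaks.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def _overlaps_any(peaks: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """Per peak: does it overlap any interval in ``other`` by >= 1 bp."""
    out = np.zeros(len(peaks), dtype=bool)
    if other.empty or peaks.empty:
        return out
    for chrom, sub in other.groupby("chrom"):
        sel = np.flatnonzero((peaks["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        o = sub.sort_values("start")
        starts = o["start"].to_numpy()
        ends_cummax = np.maximum.accumulate(o["end"].to_numpy())
        p_start = peaks["start"].to_numpy()[sel]
        p_end = peaks["end"].to_numpy()[sel]
        # candidates: intervals starting before the peak end
        k = np.searchsorted(starts, p_end, side="left")
        hit = (k > 0) & (np.where(k > 0, ends_cummax[np.maximum(k - 1, 0)], 0) > p_start)
        out[sel] = hit
    return out


def exclude_regions(peaks: pd.DataFrame,
                    excluded_chroms=DEFAULT_EXCLUDED_CHROMS,
                    blacklist: pd.DataFrame | None = None) -> pd.DataFrame:
    """Drop peaks on excluded chromosomes or overlapping a blacklist interval."""
    _check_intervals(peaks)
    keep = ~peaks["chrom"].isin(set(excluded_chroms)).to_numpy()
    if blacklist is not None and len(blacklist):
        _check_intervals(blacklist)
        keep &= ~_overlaps_any(peaks, blacklist)
    return _sorted(peaks.loc[keep])


def filter_by_enrichment(peaks: pd.DataFrame, threshold: float = 2.0,
                         min_samples: int = 1,
                         enrichment_cols: list[str] | None = None) -> pd.DataFrame:
    """Keep peaks with log-enrichment > threshold (strict) in >= min_samples samples."""
    _check_intervals(peaks)
    if enrichment_cols is None:
        enrichment_cols = [c for c in peaks.columns if c not in BED_COLS
                           and pd.api.types.is_numeric_dtype(peaks[c])]
    if not enrichment_cols:
        raise DataError("no enrichment columns found")
    missing = [c for c in enrichment_cols if c not in peaks.columns]
    if missing:
        raise DataError(f"missing enrichment column(s): {missing}")
    enr = peaks[enrichment_cols].to_numpy()
    keep = (enr > threshold).sum(axis=1) >= min_samples
    return _sorted(peaks.loc[keep])


def merge_intervals(peaks: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping intervals per chromosome (touching intervals stay separate)."""
    _check_intervals(peaks)
    rows = []
    for chrom, sub in _sorted(peaks).groupby("chrom"):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # >= 1 bp overlap
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=BED_COLS)


def classify_overlap(er: pd.DataFrame, gr: pd.DataFrame) -> pd.DataFrame:
    """Label merged regions as ER_only, GR_only or shared (>= 1 bp overlap).

    Within-factor overlapping peaks are merged first; ER and GR regions
    that overlap each other are merged into single ``shared`` regions.
    """
    m_er = merge_intervals(er) if len(er) else pd.DataFrame(columns=BED_COLS)
    m_gr = merge_intervals(gr) if len(gr) else pd.DataFrame(columns=BED_COLS)
    er_shared = _overlaps_any(m_er, m_gr)
    gr_shared = _overlaps_any(m_gr, m_er)
    shared_src = pd.concat([m_er.loc[er_shared], m_gr.loc[gr_shared]], ignore_index=True)
    shared = merge_intervals(shared_src) if len(shared_src) else shared_src
    out = pd.concat(
        [
            m_er.loc[~er_shared].assign(label="ER_only"),
            m_gr.loc[~gr_shared].assign(label="GR_only"),
            shared.assign(label="shared") if len(shared) else
            pd.DataFrame(columns=BED_COLS + ["label"]),
        ],
        ignore_index=True,
    )
    return _sorted(out)


def build_regulatory_domains(genes: pd.DataFrame,
                             params: RegulatoryDomainParams | None = None,
                             chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-gene basal-plus-extension regulatory domain.

    Basal: [tss - basal_up, tss + basal_down) on the + strand, mirrored on
    the - strand. Each basal edge extends outward by at most
    ``distal_limit`` bp, but never past the midpoint of the gap to the
    nearest neighboring basal domain (so extensions of adjacent genes do
    not overlap); domains are clipped to chromosome bounds.
    """
    params = params or RegulatoryDomainParams()
    req = {"gene_id", "chrom", "strand", "tss"}
    if not req <= set(genes.columns):
        raise DataError(f"gene annotation needs columns {sorted(req)}")
    if chrom_lengths:
        for _, g in genes.iterrows():
            if not 0 <= g["tss"] < chrom_lengths.get(g["chrom"], np.inf):
                raise DataError(f"TSS of {g['gene_id']} outside chromosome bounds")

    plus = genes["strand"] == "+"
    basal_start = np.where(plus, genes["tss"] - params.basal_up,
                           genes["tss"] - params.basal_down).astype(np.int64)
    basal_end = np.where(plus, genes["tss"] + params.basal_down,
                         genes["tss"] + params.basal_up).astype(np.int64)
    df = genes.copy()
    df["basal_start"], df["basal_end"] = basal_start, basal_end

    out = []
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("tss", kind="stable")
        bs = sub["basal_start"].to_numpy()
        be = sub["basal_end"].to_numpy()
        n = len(sub)
        # nearest basal edge to the left/right among the other genes
        left_edge = np.empty(n)
        right_edge = np.empty(n)
        run_max = -np.inf
        for i in range(n):
            left_edge[i] = run_max
            run_max = max(run_max, be[i])
        run_min = np.inf
        for i in range(n - 1, -1, -1):
            right_edge[i] = run_min
            run_min = min(run_min, bs[i])

        left_fin = np.isfinite(left_edge)
        right_fin = np.isfinite(right_edge)
        mid_left = (np.where(left_fin, left_edge, 0) + bs) // 2
        mid_right = (np.where(right_fin, right_edge, 0) + be) // 2
        ext_start = np.maximum(bs - params.distal_limit,
                               np.where(left_fin, np.minimum(bs, mid_left),
                                        bs - params.distal_limit))
        # both neighbors use the same floor midpoint, so extensions abut at most
        ext_end = np.minimum(be + params.distal_limit,
                             np.where(right_fin, np.maximum(be, mid_right),
                                      be + params.distal_limit))
        ext_start = np.minimum(ext_start, bs)  # never shrink the basal domain
        ext_end = np.maximum(ext_end, be)
        lim = chrom_lengths.get(chrom) if chrom_lengths else None
        ext_start = np.maximum(ext_start, 0)
        if lim is not None:
            ext_end = np.minimum(ext_end, lim)
        res = sub[["gene_id", "chrom", "strand", "tss"]].copy()
        res["basal_start"], res["basal_end"] = np.maximum(bs, 0), be
        if lim is not None:
            res["basal_end"] = np.minimum(be, lim)
        res["start"] = ext_start.astype(np.int64)
        res["end"] = ext_end.astype(np.int64)
        out.append(res)
    return pd.concat(out, ignore_index=True).sort_values(
        ["chrom", "start"], kind="stable").reset_index(drop=True)


def assign_peaks(peaks: pd.DataFrame, domains: pd.DataFrame) -> pd.DataFrame:
    """Assign each peak to every gene whose domain contains its midpoint.

    Midpoint = floor((start + end) / 2); containment uses the half-open
    convention (start <= mid < end). Returns a (gene_id, peak_index)
    table, peak_index referring to the input peak row.
    """
    _check_intervals(peaks)
    rows = []
    mids = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    for chrom, dsub in domains.groupby("chrom"):
        sel = np.flatnonzero((peaks["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        m = mids[sel]
        ds = dsub["start"].to_numpy()[:, None]
        de = dsub["end"].to_numpy()[:, None]
        inside = (ds <= m[None, :]) & (m[None, :] < de)
        gi, pj = np.nonzero(inside)
        for g, p in zip(dsub["gene_id"].to_numpy()[gi], peaks.index.to_numpy()[sel][pj]):
            rows.append((g, p))
    return pd.DataFrame(rows, columns=["gene_id", "peak_index"])


def gene_set_peak_fraction(gene_set, assignment: pd.DataFrame) -> float:
    """Fraction of the gene set with at least one assigned peak."""
    gene_set = list(gene_set)
    if not gene_set:
        raise DataError("gene set is empty")
    with_peak = set(assignment["gene_id"])
    return sum(g in with_peak for g in gene_set) / len(gene_set)
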