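"""Independent from-the-definition reference implementations.

Deliberately written as plain loops, separate from the package code, so
the fast implementations can be checked against the definitions.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _avg_ranks(x):
    """Average ranks (ties share the mean rank), 1-based."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    xs = np.asarray(x)[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and xs[j + 1] == xs[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def tmm_reference(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05):
    """Trimmed-mean-of-M-values factors, straight from the published recipe."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    lib = counts.sum(axis=0)
    f75 = []
    for j in range(n_samples):
        f75.append(np.quantile(counts[:, j] / lib[j], 0.75))
    f75 = np.array(f75)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = []
    for j in range(n_samples):
        if j == ref:
            log_factors.append(0.0)
            continue
        ms, as_, vs = [], [], []
        for g in range(n_genes):
            yo, yr = counts[g, j], counts[g, ref]
            if yo > 0 and yr > 0:
                po, pr = yo / lib[j], yr / lib[ref]
                ms.append(np.log2(po / pr))
                as_.append(0.5 * np.log2(po * pr))
                vs.append((lib[j] - yo) / (lib[j] * yo) + (lib[ref] - yr) / (lib[ref] * yr))
        ms, as_, vs = map(np.array, (ms, as_, vs))
        if ms.size == 0 or np.max(np.abs(ms)) < 1e-6:
            log_factors.append(0.0)
            continue
        n = ms.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm, ra = _avg_ranks(ms), _avg_ranks(as_)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += ms[i] / vs[i]
                den += 1.0 / vs[i]
        log_factors.append(num / den if den > 0 else 0.0)
    f = np.exp2(log_factors)
    return f / np.exp(np.mean(np.log(f)))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_reference(p):
    """Step-up definition: q_(i) = min_{j >= i} p_(j) * n / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running = np.inf
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_reference(time, event):
    """Product-limit estimator as a dict time -> S(t), events only."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    out = {}
    for t in np.unique(time):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        if d > 0:
            s *= 1.0 - d / at_risk
        out[float(t)] = s
    return out


# ---------------------------------------------------------------------------
# GSEA running sum
# ---------------------------------------------------------------------------

def es_reference(values, in_set, weight=1.0):
    """Brute-force walk: increment |r|^p / N_R at hits, else -1/(N - k)."""
    values = np.asarray(values, float)
    in_set = np.asarray(in_set, bool)
    n = len(values)
    k = int(in_set.sum())
    nr = float(np.sum(np.abs(values[in_set]) ** weight))
    miss = 1.0 / (n - k) if n > k else 0.0
    run = 0.0
    hi = lo = 0.0
    for i in range(n):
        if in_set[i]:
            run += abs(values[i]) ** weight / nr
        else:
            run -= miss
        hi = max(hi, run)
        lo = min(lo, run)
    # same tie rule as the implementation: positive wins near-equal magnitudes
    return hi if hi >= -lo - 1e-9 else lo


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

def overlaps(a_chrom, a_start, a_end, b_chrom, b_start, b_end):
    return a_chrom == b_chrom and a_start < b_end and b_start < a_end


def exclude_reference(peaks, excluded_chroms, blacklist):
    """Row indices of peaks surviving chromosome/blacklist exclusion."""
    keep = []
    for i, p in peaks.iterrows():
        if p["chrom"] in excluded_chroms:
            continue
        hit = False
        if blacklist is not None:
            for _, b in blacklist.iterrows():
                if overlaps(p["chrom"], p["start"], p["end"],
                            b["chrom"], b["start"], b["end"]):
                    hit = True
                    break
        if not hit:
            keep.append(i)
    return keep


def merge_reference(peaks):
    """All-pairs interval merging (union of overlapping intervals)."""
    items = [(p["chrom"], int(p["start"]), int(p["end"]))
             for _, p in peaks.iterrows()]
    merged = []
    for it in sorted(items):
        for i, m in enumerate(merged):
            if overlaps(it[0], it[1], it[2], *m):
                merged[i] = (m[0], min(m[1], it[1]), max(m[2], it[2]))
                break
        else:
            merged.append(it)
    # repeat until stable (chained overlaps)
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                if overlaps(*merged[i], *merged[j]):
                    a, b = merged[i], merged[j]
                    merged[i] = (a[0], min(a[1], b[1]), max(a[2], b[2]))
                    del merged[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(merged)


def classify_reference(er, gr):
    """Label counts {ER_only, GR_only, shared} via all-pairs overlap."""
    m_er, m_gr = merge_reference(er), merge_reference(gr)
    er_shared = [any(overlaps(*a, *b) for b in m_gr) for a in m_er]
    gr_shared = [any(overlaps(*a, *b) for b in m_er) for a in m_gr]
    shared_src = [a for a, s in zip(m_er, er_shared) if s] + \
                 [b for b, s in zip(m_gr, gr_shared) if s]
    import pandas as pd
    shared = merge_reference(pd.DataFrame(shared_src, columns=["chrom", "start", "end"])) \
        if shared_src else []
    return {
        "ER_only": sorted(a for a, s in zip(m_er, er_shared) if not s),
        "GR_only": sorted(b for b, s in zip(m_gr, gr_shared) if not s),
        "shared": shared,
    }


def domains_reference(genes, basal_up, basal_down, distal, chrom_lengths):
    """Per-gene basal-plus-extension domains by all-pairs neighbor search."""
    out = {}
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            bs, be = g["tss"] - basal_up, g["tss"] + basal_down
        else:
            bs, be = g["tss"] - basal_down, g["tss"] + basal_up
        left = [
            (o["tss"] - basal_up if o["strand"] == "+" else o["tss"] - basal_down,
             o["tss"] + basal_down if o["strand"] == "+" else o["tss"] + basal_up)
            for _, o in genes.iterrows()
            if o["chrom"] == g["chrom"] and o["tss"] < g["tss"]
        ]
        right = [
            (o["tss"] - basal_up if o["strand"] == "+" else o["tss"] - basal_down,
             o["tss"] + basal_down if o["strand"] == "+" else o["tss"] + basal_up)
            for _, o in genes.iterrows()
            if o["chrom"] == g["chrom"] and o["tss"] > g["tss"]
        ]
        if left:
            le = max(e for _, e in left)
            ext_s = max(bs - distal, min(bs, (le + bs) // 2))
        else:
            ext_s = bs - distal
        if right:
            re_ = min(s for s, _ in right)
            ext_e = min(be + distal, max(be, (re_ + be) // 2))
        else:
            ext_e = be + distal
        ext_s = max(ext_s, 0)
        ext_e = min(ext_e, chrom_lengths[g["chrom"]])
        out[g["gene_id"]] = (g["chrom"], int(ext_s), int(ext_e))
    return out


def assign_reference(peaks, domains):
    """All-pairs midpoint containment: set of (gene_id, peak_row_index)."""
    pairs = set()
    for i, p in peaks.iterrows():
        mid = (int(p["start"]) + int(p["end"])) // 2
        for gid, (chrom, s, e) in domains.items():
            if p["chrom"] == chrom and s <= mid < e:
                pairs.add((gid, i))
    return pairs
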