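"""GR activity signature derivation and scoring.

The signature is derived from the Dex time course in three steps:

1. *Shared-effect filter*: genes passing |logFC| > 2 and FDR < 0.01 at 24 h
   in both cell-line models, with concordant fold-change sign.
2. *k-means* (k = 4) on the mean-centered logCPM profiles of those genes
   across all samples.
3. *Onset selection*: the cluster with the strongest positive expression
   onset — mean logCPM in Dex 8 h samples minus mean logCPM in vehicle
   samples — becomes the signature (genes upregulated already at 8 h).

Samples or patients are scored by the total log-expression of the
signature genes. Early/late response timing is classified from the 8 h
and 24 h contrasts of both models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import normde
from .errors import DataError


@dataclass
class SignatureParams:
    """Derivation parameters (defaults follow the published procedure)."""

    lfc_thresh: float = 2.0
    fdr_thresh: float = 0.01
    k: int = 4
    n_restarts: int = 50
    max_iter: int = 300
    seed: int = 0
    require_sign_concordance: bool = True
    control_scope: str = "all_vehicle"  # or "vehicle_8h"
    onset_stat: str = "mean"  # or "median"
    exclude_genes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.k < 2:
            raise DataError("k must be >= 2")
        if self.lfc_thresh <= 0 or self.fdr_thresh <= 0:
            raise DataError("thresholds must be > 0")
        if self.control_scope not in ("all_vehicle", "vehicle_8h"):
            raise DataError(f"unknown control_scope {self.control_scope!r}")


@dataclass
class Signature:
    """An ordered gene list plus the derivation metadata that produced it."""

    gene_ids: tuple[str, ...]
    cluster_label: int
    onset_scores: dict[int, float]
    inertia: float
    params: SignatureParams | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.gene_ids) == 0:
            raise DataError("signature gene list is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("signature gene ids are not unique")

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": list(self.gene_ids),
            "cluster_label": int(self.cluster_label),
            "onset_scores": {str(k): v for k, v in self.onset_scores.items()},
            "inertia": self.inertia,
            "params": asdict(self.params) if self.params else None,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Signature":
        with open(path) as fh:
            d = json.load(fh)
        params = d.get("params")
        if params is not None:
            params["exclude_genes"] = tuple(params.get("exclude_genes", ()))
            params = SignatureParams(**params)
        return cls(
            gene_ids=tuple(d["gene_ids"]),
            cluster_label=int(d["cluster_label"]),
            onset_scores={int(k): v for k, v in d["onset_scores"].items()},
            inertia=d["inertia"],
            params=params,
            provenance=d.get("provenance", {}),
        )


def shared_effect_genes(de_a: pd.DataFrame, de_b: pd.DataFrame,
                        params: SignatureParams | None = None) -> pd.Index:
    """Genes significant in both models with concordant fold-change sign."""
    params = params or SignatureParams()
    if not de_a.index.equals(de_b.index):
        common = de_a.index.intersection(de_b.index)
        if len(common) == 0:
            raise DataError("DE tables share no genes")
        de_a, de_b = de_a.loc[common], de_b.loc[common]
    hit_a = (de_a["fdr"] < params.fdr_thresh) & (de_a["logFC"].abs() > params.lfc_thresh)
    hit_b = (de_b["fdr"] < params.fdr_thresh) & (de_b["logFC"].abs() > params.lfc_thresh)
    keep = hit_a & hit_b
    if params.require_sign_concordance:
        keep &= np.sign(de_a["logFC"]) == np.sign(de_b["logFC"])
    idx = de_a.index[keep]
    if params.exclude_genes:
        idx = idx.difference(pd.Index(params.exclude_genes), sort=False)
    return idx


def mean_center(log_expr: pd.DataFrame, genes) -> pd.DataFrame:
    """Rows for ``genes``, each centered by its mean over all samples."""
    missing = pd.Index(genes).difference(log_expr.index)
    if len(missing):
        raise DataError(f"unknown genes: {list(missing[:5])}")
    sub = log_expr.loc[list(genes)]
    return sub.sub(sub.mean(axis=1), axis=0)


def kmeans_cluster(centered: pd.DataFrame,
                   params: SignatureParams | None = None) -> tuple[pd.Series, float]:
    """k-means (k-means++, multiple restarts, seeded) on gene profiles."""
    params = params or SignatureParams()
    if centered.shape[0] < params.k:
        raise DataError(f"need at least k={params.k} genes to cluster")
    km = KMeans(
        n_clusters=params.k,
        init="k-means++",
        n_init=params.n_restarts,
        max_iter=params.max_iter,
        random_state=params.seed,
    ).fit(centered.to_numpy())
    labels = pd.Series(km.labels_, index=centered.index, name="cluster")
    return labels, float(km.inertia_)


def _control_samples(samples: pd.DataFrame, scope: str) -> pd.Series:
    veh = samples["treatment"] == "vehicle"
    if scope == "vehicle_8h":
        veh &= samples["timepoint"] == "8h"
    return veh


def onset_score(genes, log_expr: pd.DataFrame, samples: pd.DataFrame,
                control_scope: str = "all_vehicle", stat: str = "mean") -> float:
    """Expression onset: Dex 8 h mean minus vehicle mean, averaged over genes."""
    genes = list(genes)
    if not genes:
        raise DataError("cluster is empty")
    dex8 = samples.loc[
        (samples["treatment"] == "dex") & (samples["timepoint"] == "8h"), "sample_id"
    ]
    ctrl = samples.loc[_control_samples(samples, control_scope), "sample_id"]
    if dex8.empty or ctrl.empty:
        raise DataError("need both Dex 8 h and vehicle samples for the onset score")
    diff = (
        log_expr.loc[genes, list(dex8)].mean(axis=1)
        - log_expr.loc[genes, list(ctrl)].mean(axis=1)
    )
    return float(diff.median() if stat == "median" else diff.mean())


def select_signature(labels: pd.Series, log_expr: pd.DataFrame,
                     samples: pd.DataFrame, params: SignatureParams | None = None,
                     inertia: float = float("nan")) -> Signature:
    """Pick the cluster with the strongest positive onset as the signature.

    Ties in onset are broken by the larger Dex 24 h minus vehicle
    difference, then by the smaller cluster label.
    """
    params = params or SignatureParams()
    dex24 = samples.loc[
        (samples["treatment"] == "dex") & (samples["timepoint"] == "24h"), "sample_id"
    ]
    ctrl = samples.loc[_control_samples(samples, params.control_scope), "sample_id"]
    records = []
    onsets = {}
    for lab in sorted(labels.unique()):
        genes = labels.index[labels == lab]
        ons = onset_score(genes, log_expr, samples, params.control_scope,
                          params.onset_stat)
        late = float(
            (log_expr.loc[genes, list(dex24)].mean(axis=1)
             - log_expr.loc[genes, list(ctrl)].mean(axis=1)).mean()
        ) if len(dex24) else 0.0
        onsets[int(lab)] = ons
        records.append((ons, late, int(lab)))
    records.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best_onset, _, best_lab = records[0]
    if best_onset <= 0:
        raise DataError(
            "no cluster has a positive expression onset; review thresholds or k"
        )
    genes = tuple(labels.index[labels == best_lab])
    return Signature(
        gene_ids=genes,
        cluster_label=best_lab,
        onset_scores=onsets,
        inertia=inertia,
        params=params,
    )


def classify_response_timing(de_8h_a, de_8h_b, de_24h_a, de_24h_b,
                             lfc: float = 1.0, fdr: float = 0.01) -> pd.Series:
    """Classify genes as early/late up/down or unchanged.

    Early = passes the threshold in both models at 8 h (regardless of 24 h);
    late = passes at 24 h in both models but not at 8 h.
    """
    idx = de_8h_a.index
    for de in (de_8h_b, de_24h_a, de_24h_b):
        if not de.index.equals(idx):
            raise DataError("DE tables must share one gene universe")

    def both(de_x, de_y, direction):
        a = normde.threshold_de(de_x, lfc=lfc, fdr=fdr, direction=direction)
        b = normde.threshold_de(de_y, lfc=lfc, fdr=fdr, direction=direction)
        return idx.isin(a) & idx.isin(b)

    up8 = both(de_8h_a, de_8h_b, "up")
    dn8 = both(de_8h_a, de_8h_b, "down")
    up24 = both(de_24h_a, de_24h_b, "up")
    dn24 = both(de_24h_a, de_24h_b, "down")

    out = np.array(["unchanged"] * len(idx), dtype=object)
    out[up24 & ~up8] = "late_up"
    out[dn24 & ~dn8] = "late_down"
    out[up8] = "early_up"
    out[dn8] = "early_down"
    return pd.Series(out, index=idx, name="timing")


def score_samples(expr: pd.DataFrame, sig: Signature,
                  min_present: float = 0.5) -> pd.Series:
    """Per-sample signature score: total log-expression of signature genes.

    ``expr`` is gene x sample. Up to half the signature may be absent
    (cross-platform application); missing genes trigger a warning, more
    than half an error.
    """
    present = [g for g in sig.gene_ids if g in expr.index]
    missing = [g for g in sig.gene_ids if g not in expr.index]
    if len(present) < min_present * len(sig.gene_ids) or not present:
        raise DataError(f"too few signature genes present; missing: {missing}")
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from the matrix; "
                      "scoring over the remainder", stacklevel=2)
    return expr.loc[present].sum(axis=0).rename("signature_score")


def score_cohort(cohort: pd.DataFrame, sig: Signature,
                 min_present: float = 0.5) -> pd.Series:
    """Score a patient-per-row cohort table (gene columns)."""
    gene_cols = [c for c in cohort.columns if c not in ("time", "event")]
    return score_samples(cohort[gene_cols].T, sig, min_present=min_present)


def derive_signature(counts: pd.DataFrame, samples: pd.DataFrame,
                     params: SignatureParams | None = None) -> Signature:
    """End-to-end derivation from raw counts to a Signature.

    filter_low_expressed -> TMM -> logCPM -> Welch DE per (model,
    timepoint) -> shared-effect filter at 24 h -> mean-center -> k-means ->
    onset-based cluster selection. The returned Signature carries a
    provenance dict with the gene count at each stage.
    """
    params = params or SignatureParams()
    keep = normde.filter_low_expressed(counts, samples)
    filtered = counts.loc[keep]
    nf = normde.tmm_factors(filtered)
    lcpm = normde.logcpm(filtered, nf)

    models = sorted(samples["model"].unique())
    if len(models) < 2:
        raise DataError("derivation requires two cell-line models")
    de = {}
    for m in models[:2]:
        for tp in ("8h", "24h"):
            sel = (samples["model"] == m) & (samples["timepoint"] == tp)
            ga = samples.loc[sel & (samples["treatment"] == "dex"), "sample_id"]
            gb = samples.loc[sel & (samples["treatment"] == "vehicle"), "sample_id"]
            de[(m, tp)] = normde.de_test(lcpm, list(ga), list(gb))

    shared = shared_effect_genes(de[(models[0], "24h")], de[(models[1], "24h")], params)
    if len(shared) < params.k:
        raise DataError(
            f"only {len(shared)} shared-effect genes; cannot cluster with k={params.k}"
        )
    centered = mean_center(lcpm, shared)
    labels, inertia = kmeans_cluster(centered, params)
    sig = select_signature(labels, lcpm, samples, params, inertia=inertia)
    sig.provenance = {
        "n_genes_input": int(counts.shape[0]),
        "n_after_filter": int(keep.sum()),
        "n_shared_effect": int(len(shared)),
        "cluster_sizes": {int(l): int((labels == l).sum()) for l in sorted(labels.unique())},
        "n_signature": len(sig.gene_ids),
        "de_contrasts": [f"{m}_{tp}" for (m, tp) in de],
    }
    return sig
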