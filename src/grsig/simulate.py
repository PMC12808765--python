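"""Synthetic-data generators for every pipeline input.

Each generator plants a known ground truth (differential genes, hazard
effects, peak-to-gene links, abundance changes, synergy depth) so that the
downstream stages — normalization/DE, signature derivation, survival
analysis, cistrome assignment, proteomics and synergy testing — can be
validated by recovery rather than against external accessions.

All randomness flows from a single integer seed through named substreams,
so partial runs (e.g. only the cohort) are reproducible independently of
the other generators.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError

MODELS = ("A", "B")
TREATMENTS = ("vehicle", "dex")
TIMEPOINTS = ("8h", "24h")
PLANTED_CLASSES = ("early_up", "late_up", "early_down", "late_down")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG: deterministic in (seed, name), independent across names."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass
class SimCountConfig:
    """Design of the two-cell-line Dex time-course count experiment.

    The default design is 2 models x {vehicle, dex} x {8 h, 24 h} x 3
    replicates = 24 samples, with four planted response classes: early
    classes respond at both timepoints, late classes only at 24 h.
    ``effect`` is the log2 fold change magnitude; counts are negative
    binomial with Var = mu + dispersion * mu^2.
    """

    n_genes: int = 5000
    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: {c: 60 for c in PLANTED_CLASSES}
    )
    effect: float = 3.0
    dispersion: float = 0.1
    baseline_logmean_mu: float = 5.0   # log2 scale of relative abundance
    baseline_logmean_sd: float = 2.0
    libsize_range: tuple[float, float] = (5e6, 1.5e7)
    n_models: int = 2
    n_reps: int = 3
    model_jitter_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.class_sizes) - set(PLANTED_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown planted classes: {sorted(unknown)}")
        if sum(self.class_sizes.values()) > self.n_genes:
            raise ConfigurationError(
                "sum of class_sizes exceeds n_genes "
                f"({sum(self.class_sizes.values())} > {self.n_genes})"
            )
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if not self.libsize_range[0] <= self.libsize_range[1]:
            raise ConfigurationError("libsize_range min must be <= max")
        if self.n_models < 1 or self.n_reps < 1:
            raise ConfigurationError("n_models and n_reps must be >= 1")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mu)
    n = 1.0 / phi
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_counts(
    cfg: SimCountConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the count matrix, its sample sheet and the planted truth.

    Returns
    -------
    counts : DataFrame, genes x samples, non-negative integers.
    samples : DataFrame with sample_id, model, treatment, timepoint, replicate.
    truth : DataFrame per gene with planted_class, planted_log2fc_8h/_24h and
        the per-model jittered fold changes actually applied
        (log2fc_{8h,24h}_{model}).
    """
    cfg.validate()
    rng = substream(cfg.seed, "counts")

    gene_ids = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    models = [MODELS[i] if i < len(MODELS) else f"M{i + 1}" for i in range(cfg.n_models)]

    # baseline relative abundances
    log2_base = rng.normal(cfg.baseline_logmean_mu, cfg.baseline_logmean_sd, cfg.n_genes)
    base = np.exp2(log2_base)
    base /= base.sum()

    # assign planted classes to random gene indices
    perm = rng.permutation(cfg.n_genes)
    classes = np.array(["null"] * cfg.n_genes, dtype=object)
    pos = 0
    for cls in PLANTED_CLASSES:
        k = int(cfg.class_sizes.get(cls, 0))
        classes[perm[pos:pos + k]] = cls
        pos += k

    sign = np.zeros(cfg.n_genes)
    sign[classes == "early_up"] = 1.0
    sign[classes == "late_up"] = 1.0
    sign[classes == "early_down"] = -1.0
    sign[classes == "late_down"] = -1.0
    early = np.isin(classes, ["early_up", "early_down"])

    lfc8 = np.where(early, sign * cfg.effect, 0.0)
    lfc24 = sign * cfg.effect  # late classes respond at 24 h only; early at both

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted_class": classes,
            "planted_log2fc_8h": lfc8,
            "planted_log2fc_24h": lfc24,
        }
    ).set_index("gene_id")

    # per-model jitter keeps the shared-effect intersection nontrivial
    model_lfc8, model_lfc24 = {}, {}
    for m in models:
        jit = rng.normal(0.0, cfg.model_jitter_sd, cfg.n_genes)
        model_lfc8[m] = np.where(lfc8 != 0, lfc8 + jit, 0.0)
        model_lfc24[m] = np.where(lfc24 != 0, lfc24 + jit, 0.0)
        truth[f"log2fc_8h_{m}"] = model_lfc8[m]
        truth[f"log2fc_24h_{m}"] = model_lfc24[m]

    rows = []
    for m in models:
        for trt in TREATMENTS:
            for tp in TIMEPOINTS:
                for r in range(1, cfg.n_reps + 1):
                    rows.append(
                        {
                            "sample_id": f"{m}_{trt}_{tp}_r{r}",
                            "model": m,
                            "treatment": trt,
                            "timepoint": tp,
                            "replicate": r,
                        }
                    )
    samples = pd.DataFrame(rows)

    libsizes = rng.uniform(*cfg.libsize_range, size=len(samples))
    samples["target_libsize"] = libsizes
    counts = np.empty((cfg.n_genes, len(samples)), dtype=np.int64)
    for j, row in samples.iterrows():
        lfc = np.zeros(cfg.n_genes)
        if row["treatment"] == "dex":
            lfc = model_lfc8[row["model"]] if row["timepoint"] == "8h" else model_lfc24[row["model"]]
        mu = base * np.exp2(lfc)
        mu = mu / mu.sum() * libsizes[j]  # compositional renormalization to target depth
        counts[:, j] = _nb_draw(rng, mu, cfg.dispersion)

    counts = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples["sample_id"].tolist())
    return counts, samples, truth


# ---------------------------------------------------------------------------
# Patient cohort with planted survival effect
# ---------------------------------------------------------------------------

@dataclass
class SimCohortConfig:
    """Cohort whose hazard depends on a planted signature score.

    Event times are exponential with hazard h0 * exp(beta * z), where z is
    the standardized total log-expression over ``signature_genes``;
    administrative censoring at ``censor_admin_time``. The baseline hazard
    h0 is solved so that the expected event fraction equals
    ``event_fraction``. An ESR1 column is appended with planted
    anti-correlation strength ``gamma_esr1`` to the score.
    """

    n_patients: int = 800
    n_genes: int = 200
    signature_genes: Sequence[str] | None = None  # default: first 20 genes
    beta: float = -0.8
    censor_admin_time: float = 120.0  # months
    gamma_esr1: float = 0.6
    noise_sd: float = 1.0
    event_fraction: float = 0.6
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"cg{i + 1:04d}" for i in range(self.n_genes)]

    def resolved_signature(self) -> list[str]:
        if self.signature_genes is None:
            return self.gene_ids()[:20]
        return list(self.signature_genes)

    def validate(self) -> None:
        if self.n_patients < 8:
            raise ConfigurationError("n_patients must be >= 8")
        sig = self.resolved_signature()
        if len(sig) == 0:
            raise ConfigurationError("signature_genes must be nonempty")
        if not set(sig) <= set(self.gene_ids()):
            raise ConfigurationError("signature_genes must be a subset of simulated genes")
        if not 0 < self.event_fraction < 1:
            raise ConfigurationError("event_fraction must be in (0, 1)")


def expected_event_fraction(h0: float, beta: float, t_c: float) -> float:
    """E_z[1 - exp(-h0 e^{beta z} t_c)] for z ~ N(0,1), by Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    p = 1.0 - np.exp(-h0 * np.exp(beta * nodes) * t_c)
    return float(np.sum(weights * p) / np.sqrt(2 * np.pi))


def solve_baseline_hazard(beta: float, t_c: float, target: float) -> float:
    """Baseline hazard giving the target expected event fraction before t_c."""
    f = lambda log_h0: expected_event_fraction(np.exp(log_h0), beta, t_c) - target
    lo, hi = np.log(1e-8), np.log(1e3)
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-12)))


def simulate_cohort(cfg: SimCohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a patient cohort (expression + survival) and its truth table.

    Returns
    -------
    cohort : DataFrame indexed by patient_id with ``time`` (months),
        ``event`` (1/0), one column per gene and an ``ESR1`` column.
    truth : DataFrame with the raw planted score, its standardized value z,
        the uncensored event time and the attrs ``h0`` /
        ``expected_event_fraction``.
    """
    cfg.validate()
    rng = substream(cfg.seed, "cohort")
    genes = cfg.gene_ids()
    sig = cfg.resolved_signature()

    mu = substream(cfg.seed, "cohort-genes").normal(8.0, 1.0, cfg.n_genes)
    expr = mu + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_patients, cfg.n_genes))
    cohort = pd.DataFrame(expr, columns=genes)
    cohort.index = pd.Index([f"p{i + 1:04d}" for i in range(cfg.n_patients)],
                            name="patient_id")

    score = cohort[sig].sum(axis=1).to_numpy()
    # analytic standardization: iid gene noise around fixed means
    z = (score - mu[[genes.index(g) for g in sig]].sum()) / (
        np.sqrt(len(sig)) * cfg.noise_sd
    )

    h0 = solve_baseline_hazard(cfg.beta, cfg.censor_admin_time, cfg.event_fraction)
    rate = h0 * np.exp(cfg.beta * z)
    t_event = rng.exponential(1.0 / rate)
    time = np.minimum(t_event, cfg.censor_admin_time)
    event = (t_event <= cfg.censor_admin_time).astype(int)

    esr1 = 10.0 - cfg.gamma_esr1 * z + rng.normal(0.0, cfg.noise_sd, cfg.n_patients)
    cohort.insert(0, "event", event)
    cohort.insert(0, "time", time)
    cohort["ESR1"] = esr1

    truth = pd.DataFrame(
        {"score": score, "z": z, "event_time": t_event},
        index=cohort.index,
    )
    truth.attrs["h0"] = h0
    truth.attrs["expected_event_fraction"] = expected_event_fraction(
        h0, cfg.beta, cfg.censor_admin_time
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Toy genome, gene annotation and factor peak sets
# ---------------------------------------------------------------------------

@dataclass
class SimPeakConfig:
    """Toy genome with GR/ER peak sets and planted gene-proximal GR peaks.

    A ``target_fraction`` of genes receives a GR peak whose midpoint lies
    inside the gene's basal regulatory domain (5 kb upstream / 1 kb
    downstream of the TSS, strand-oriented). The ER 1 h set loses peaks at
    24 h (``er_24h_retention``), echoing the genome-wide loss of ER binding
    after prolonged Dex.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_500_000}
    )
    n_genes: int = 100
    target_fraction: float = 0.6
    n_background_peaks: int = 150
    enrichment_mean: float = 4.0
    enrichment_sd: float = 1.0
    bg_enrichment_mean: float = 1.0
    bg_enrichment_sd: float = 0.7
    n_enrichment_samples: int = 2
    er_24h_retention: float = 0.4
    peak_width: int = 400
    min_gene_spacing: int = 10_000
    max_retries: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.target_fraction <= 1:
            raise ConfigurationError("target_fraction must be in [0, 1]")
        if not 0 <= self.er_24h_retention <= 1:
            raise ConfigurationError("er_24h_retention must be in [0, 1]")
        if any(l <= 2 * self.min_gene_spacing for l in self.chrom_lengths.values()):
            raise ConfigurationError("chromosomes too short for the gene spacing")


def _place_genes(cfg: SimPeakConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    placed: dict[str, list[int]] = {c: [] for c in chroms}
    rows = []
    for i in range(cfg.n_genes):
        for _ in range(cfg.max_retries):
            c = chroms[rng.choice(len(chroms), p=probs)]
            lo, hi = cfg.min_gene_spacing, cfg.chrom_lengths[c] - cfg.min_gene_spacing
            tss = int(rng.integers(lo, hi))
            if all(abs(tss - t) >= cfg.min_gene_spacing for t in placed[c]):
                placed[c].append(tss)
                rows.append(
                    {
                        "gene_id": f"tg{i + 1:04d}",
                        "chrom": c,
                        "strand": "+" if rng.random() < 0.5 else "-",
                        "tss": tss,
                        "biotype": "protein_coding",
                    }
                )
                break
        else:
            raise ConfigurationError(
                f"could not place gene {i + 1} without TSS collision after "
                f"{cfg.max_retries} retries"
            )
    return pd.DataFrame(rows)


def _enrich_cols(rng, n, mean, sd, n_samples):
    return {
        f"enr_s{s + 1}": rng.normal(mean, sd, n) for s in range(n_samples)
    }


def simulate_genome_and_peaks(
    cfg: SimPeakConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate gene annotation, GR/ER peak sets and the gene-level truth.

    Returns
    -------
    genes : annotation DataFrame (gene_id, chrom, strand, tss, biotype).
    peaks : dict with keys ``GR_1h``, ``ER_1h``, ``ER_24h``; each a BED-like
        DataFrame (chrom, start, end, per-sample log-enrichment columns).
    truth : DataFrame per gene with ``has_gr_peak``.
    """
    cfg.validate()
    rng = substream(cfg.seed, "peaks")
    genes = _place_genes(cfg, rng)

    n_target = int(round(cfg.target_fraction * cfg.n_genes))
    target_idx = rng.choice(cfg.n_genes, size=n_target, replace=False)
    has_peak = np.zeros(cfg.n_genes, dtype=bool)
    has_peak[target_idx] = True

    half = cfg.peak_width // 2
    gr_rows = []
    for i in target_idx:
        g = genes.iloc[i]
        # strand-oriented offset keeps the midpoint inside the basal domain
        off = int(rng.integers(-4500, 800))
        mid = g["tss"] + (off if g["strand"] == "+" else -off)
        start = max(0, mid - half)
        end = min(cfg.chrom_lengths[g["chrom"]], mid + half)
        gr_rows.append({"chrom": g["chrom"], "start": start, "end": end})
    gr = pd.DataFrame(gr_rows)
    n_planted_gr = len(gr)
    gr = pd.concat([gr, _random_peaks(cfg, rng, cfg.n_background_peaks)], ignore_index=True)
    enr_rng = substream(cfg.seed, "gr-enr")
    for s in range(cfg.n_enrichment_samples):
        gr[f"enr_s{s + 1}"] = np.concatenate(
            [
                enr_rng.normal(cfg.enrichment_mean, cfg.enrichment_sd, n_planted_gr),
                enr_rng.normal(cfg.bg_enrichment_mean, cfg.bg_enrichment_sd,
                               len(gr) - n_planted_gr),
            ]
        )

    er = _random_peaks(cfg, rng, max(cfg.n_background_peaks, 50))
    er = er.assign(**_enrich_cols(substream(cfg.seed, "er-enr"), len(er),
                                  cfg.enrichment_mean, cfg.enrichment_sd,
                                  cfg.n_enrichment_samples))
    n_keep = int(round(cfg.er_24h_retention * len(er)))
    keep_idx = np.sort(rng.choice(len(er), size=n_keep, replace=False))
    er24 = er.iloc[keep_idx].reset_index(drop=True)

    peaks = {
        "GR_1h": _sort_peaks(gr),
        "ER_1h": _sort_peaks(er),
        "ER_24h": _sort_peaks(er24),
    }
    truth = pd.DataFrame({"gene_id": genes["gene_id"], "has_gr_peak": has_peak})
    return genes, peaks, truth


def _random_peaks(cfg: SimPeakConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    half = cfg.peak_width // 2
    rows = []
    for _ in range(n):
        c = chroms[rng.choice(len(chroms), p=probs)]
        mid = int(rng.integers(half, cfg.chrom_lengths[c] - half))
        rows.append({"chrom": c, "start": mid - half, "end": mid + half})
    return pd.DataFrame(rows)


def _sort_peaks(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# TMT reporter matrix
# ---------------------------------------------------------------------------

@dataclass
class SimTmtConfig:
    """PSM-level TMT reporter intensities with channel loading biases.

    Channels split half/half into vehicle and dex groups; a ``de_fraction``
    of proteins change in dex by ±``effect`` log2 units (half up, half
    down). Reporter intensity = protein signal x PSM share x channel load
    factor x multiplicative log-normal noise.
    """

    n_psms: int = 2000
    n_proteins: int = 400
    n_channels: int = 8
    channel_load_factors: Sequence[float] | None = None
    de_fraction: float = 0.1
    effect: float = 2.0
    noise_cv: float = 0.1
    seed: int = 0

    def resolved_load_factors(self) -> np.ndarray:
        if self.channel_load_factors is None:
            return np.linspace(0.7, 1.4, self.n_channels)
        return np.asarray(self.channel_load_factors, dtype=float)

    def validate(self) -> None:
        lf = self.resolved_load_factors()
        if len(lf) != self.n_channels:
            raise ConfigurationError("channel_load_factors length must equal n_channels")
        if np.any(lf <= 0):
            raise ConfigurationError("channel_load_factors must be > 0")
        if self.n_channels < 4 or self.n_channels % 2:
            raise ConfigurationError("n_channels must be even and >= 4")
        if self.n_psms < self.n_proteins:
            raise ConfigurationError("need at least one PSM per protein")


def simulate_reporter(
    cfg: SimTmtConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a PSM-level reporter matrix, the channel design and protein truth.

    Returns
    -------
    psms : DataFrame with psm_id, protein, gene and one intensity column per
        channel (``ch1``..``chN``).
    channels : DataFrame mapping channel -> group ({vehicle, dex}).
    truth : per-protein planted log2 fold change (dex - vehicle).
    """
    cfg.validate()
    rng = substream(cfg.seed, "tmt")
    proteins = [f"P{i + 1:04d}" for i in range(cfg.n_proteins)]
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_proteins)]

    n_de = int(round(cfg.de_fraction * cfg.n_proteins))
    de_idx = rng.choice(cfg.n_proteins, size=n_de, replace=False)
    lfc = np.zeros(cfg.n_proteins)
    lfc[de_idx[: n_de // 2]] = cfg.effect
    lfc[de_idx[n_de // 2:]] = -cfg.effect

    base = np.exp2(rng.normal(16.0, 1.5, cfg.n_proteins))
    # every protein gets >=1 PSM; the rest are assigned at random
    assign = np.concatenate(
        [np.arange(cfg.n_proteins), rng.integers(0, cfg.n_proteins, cfg.n_psms - cfg.n_proteins)]
    )
    share = np.exp2(rng.normal(-1.0, 0.8, cfg.n_psms))

    half = cfg.n_channels // 2
    groups = ["vehicle"] * half + ["dex"] * half
    load = cfg.resolved_load_factors()
    sigma = np.sqrt(np.log1p(cfg.noise_cv ** 2))
    noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=(cfg.n_psms, cfg.n_channels)))

    cond = np.ones((cfg.n_psms, cfg.n_channels))
    cond[:, half:] = np.exp2(lfc[assign])[:, None]
    intensities = (base[assign] * share)[:, None] * cond * load[None, :] * noise

    chan_cols = [f"ch{c + 1}" for c in range(cfg.n_channels)]
    psms = pd.DataFrame(intensities, columns=chan_cols)
    psms.insert(0, "gene", [genes[i] for i in assign])
    psms.insert(0, "protein", [proteins[i] for i in assign])
    psms.insert(0, "psm_id", [f"psm{i + 1:05d}" for i in range(cfg.n_psms)])

    channels = pd.DataFrame({"channel": chan_cols, "group": groups})
    truth = pd.DataFrame({"protein": proteins, "gene": genes, "planted_log2fc": lfc})
    return psms, channels, truth


# ---------------------------------------------------------------------------
# Viability plates
# ---------------------------------------------------------------------------

@dataclass
class SimViabilityConfig:
    """Four-arm viability plate (vehicle C, singles A/B, combination AB).

    Arm means follow C, aC, bC and abC(1 - sigma): sigma = 0 is Bliss
    independence, sigma > 0 plants synergy. Replicates carry multiplicative
    log-normal noise of coefficient of variation ``noise_cv``.
    """

    base: float = 1000.0
    a: float = 0.5
    b: float = 0.5
    synergy_depth: float = 0.3
    noise_cv: float = 0.05
    n_reps: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.a <= 1 and 0 < self.b <= 1):
            raise ConfigurationError("single-drug effects a, b must be in (0, 1]")
        if not 0 <= self.synergy_depth < 1:
            raise ConfigurationError("synergy_depth must be in [0, 1)")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")


def simulate_viability(cfg: SimViabilityConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a plate table (arm, replicate, value) and the synergy truth."""
    cfg.validate()
    rng = substream(cfg.seed, "viability")
    means = {
        "C": cfg.base,
        "A": cfg.a * cfg.base,
        "B": cfg.b * cfg.base,
        "AB": cfg.a * cfg.b * cfg.base * (1.0 - cfg.synergy_depth),
    }
    sigma = np.sqrt(np.log1p(cfg.noise_cv ** 2))
    rows = []
    for arm, mu in means.items():
        noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma, cfg.n_reps))
        for r in range(cfg.n_reps):
            rows.append({"arm": arm, "replicate": r + 1, "value": mu * noise[r]})
    plate = pd.DataFrame(rows)
    truth = {"expected_ci": 1.0 - cfg.synergy_depth,
             "synergistic": cfg.synergy_depth > 0}
    return plate, truth
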