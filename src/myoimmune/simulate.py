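"""Synthetic study generator with known ground truth.

Emulates the data structure of a multi-compartment checkpoint-myocarditis
cohort: donor-clustered multinomial cell-type composition with case
effects and per-donor-per-cluster Gaussian random intercepts (the exact
data-generating process of the mixed-logistic abundance model),
negative-binomial UMI counts with cluster-specific marker genes and
case-specific fold changes, truncated power-law TCR-beta repertoires per
tissue with configurable heart/tumor enriched sets and cross-tissue
overlap, blood cells carrying heart-expanded clonotypes concentrated in
a designated subset for fatal donors, log-normal serum analytes with
group shifts, and a log-linear troponin severity link.

Defaults mirror the emulated study's design: 12 case and 8 control
donors for the heart comparison, 4 fatal cases, 4 donors with
heart/tumor/control-tissue repertoires carrying 19 heart-enriched and 28
tumor-enriched clones of which 5 are shared, and a 71-analyte serum
panel with 16 truly shifted analytes.

Identical ``SimConfig`` (including seed) always yields bit-identical
output; each ``generate_*`` stage derives its own seed stream from the
config seed so stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "generate_cells_and_counts",
    "generate_cohort",
    "generate_repertoires",
    "generate_serum",
    "simulate_study",
]

_NT = np.array(list("ACGT"))


def _default_case_log_odds():
    return None


@dataclass
class SimConfig:
    """Ground-truth parameters for a synthetic cohort.

    Units: abundance effects are log-odds; expression fold changes are
    log2; serum parameters are on the natural-log scale.
    """

    seed: int = 0
    # cohort
    n_case_donors: int = 12
    n_control_donors: int = 8
    n_fatal: int = 4
    cells_per_donor: int | tuple = 1000
    # composition
    n_clusters: int = 8
    baseline_cluster_logits: np.ndarray | None = None
    case_log_odds: np.ndarray | None = None  # default: ln 4 on cluster 0
    donor_sd: float = 0.5
    # expression
    n_genes: int = 300
    markers_per_cluster: int = 10
    marker_log2fc: float = 3.0
    de_spec: list | None = None  # default: 20 genes at the top of the index, cluster 0, log2fc 1
    nb_dispersion: float = 0.5
    base_mean_log_mu: float = -0.5
    base_mean_log_sd: float = 1.0
    libsize_lognormal: tuple = (0.0, 0.3)
    mito_fail_fraction: float = 0.05
    lowgene_fail_fraction: float = 0.05
    # TCR repertoires
    n_tcr_donors: int = 4
    n_clones: int = 300
    powerlaw_exponent: float = 1.0
    total_reads: dict = field(
        default_factory=lambda: {"heart": 5000, "tumor": 5000, "control_tissue": 5000}
    )
    n_heart_enriched: int = 19
    n_tumor_enriched: int = 28
    heart_tumor_overlap_fraction: float = 5.0 / 19.0
    enriched_freq_range: tuple = (0.01, 0.03)
    # blood sharing
    n_blood_subsets: int = 6
    blood_cells_per_donor: int = 1000
    fatal_sharing_subset: int = 1
    fatal_sharing_rate: float = 0.15
    nonfatal_sharing_rate: float = 0.01
    # serum
    n_analytes: int = 71
    n_shifted_analytes: int = 16
    serum_log_mean: float = 2.0
    serum_log_shift: float = 1.0
    serum_log_sd: float = 0.5
    # troponin severity link: log(troponin) = a + b*log(abundance) + noise
    troponin_cluster: int = 0
    troponin_link: tuple = (1.0, 1.0, 0.5)

    def __post_init__(self):
        if min(self.n_case_donors, self.n_control_donors) < 1:
            raise ValueError("donor counts must be positive")
        if not 0 <= self.n_fatal <= self.n_case_donors:
            raise ValueError("n_fatal must be between 0 and n_case_donors")
        if self.donor_sd < 0:
            raise ValueError("donor_sd must be >= 0")
        if not 0.0 <= self.heart_tumor_overlap_fraction <= 1.0:
            raise ValueError("heart_tumor_overlap_fraction must lie in [0, 1]")
        for name in ("mito_fail_fraction", "lowgene_fail_fraction",
                     "fatal_sharing_rate", "nonfatal_sharing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.baseline_cluster_logits is None:
            self.baseline_cluster_logits = np.zeros(self.n_clusters)
        self.baseline_cluster_logits = np.asarray(self.baseline_cluster_logits, dtype=float)
        if self.case_log_odds is None:
            self.case_log_odds = np.zeros(self.n_clusters)
            self.case_log_odds[0] = np.log(4.0)
        self.case_log_odds = np.asarray(self.case_log_odds, dtype=float)
        for vec in (self.baseline_cluster_logits, self.case_log_odds):
            if len(vec) != self.n_clusters:
                raise ValueError("cluster-effect vectors must have length n_clusters")
        if self.n_tcr_donors > self.n_case_donors:
            raise ValueError("n_tcr_donors cannot exceed n_case_donors")
        if self.de_spec is None:
            lo = max(0, self.n_genes - 20)
            self.de_spec = [(0, tuple(range(lo, self.n_genes)), 1.0)]
        for cluster, gene_set, _ in self.de_spec:
            if not 0 <= cluster < self.n_clusters:
                raise ValueError("de_spec cluster out of range")
            if gene_set and max(gene_set) >= self.n_genes:
                raise ValueError("de_spec gene index out of range")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_cluster_logits"] = self.baseline_cluster_logits.tolist()
        d["case_log_odds"] = self.case_log_odds.tolist()
        return d


@dataclass
class SimulatedStudy:
    """Generated tables plus the ground truth that produced them."""

    sample_meta: pd.DataFrame
    cell_table: pd.DataFrame
    counts: sp.csr_matrix
    genes: pd.Index
    heart_bulk_clones: dict
    tumor_clones: dict
    control_tissue_clones: dict
    blood_cells: pd.DataFrame
    serum_table: pd.DataFrame
    truth: dict


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """One heart-sample row per donor with clinical annotations.

    Troponin follows log(troponin) = a + b * log(expected abundance of
    the designated cluster for that donor) + Normal(0, sd); the expected
    abundance (from the donor's own random intercepts) is stored so the
    zero-noise link is exactly affine.
    """
    rng = _rng(config, 1)
    donors = [f"case_{i + 1:02d}" for i in range(config.n_case_donors)] + [
        f"ctrl_{i + 1:02d}" for i in range(config.n_control_donors)
    ]
    is_case = np.array([d.startswith("case") for d in donors])
    fatal = np.zeros(len(donors), dtype=bool)
    fatal_idx = rng.choice(config.n_case_donors, size=config.n_fatal, replace=False)
    fatal[fatal_idx] = True

    # per-donor-per-cluster random intercepts (part of cohort truth)
    u = rng.normal(0.0, config.donor_sd, size=(len(donors), config.n_clusters))
    logits = (
        config.baseline_cluster_logits[None, :]
        + np.outer(is_case, config.case_log_odds)
        + u
    )
    probs = np.vstack([_softmax(row) for row in logits])

    a, b, sd = config.troponin_link
    abund = probs[:, config.troponin_cluster]
    log_trop = a + b * np.log(abund) + rng.normal(0.0, sd, size=len(donors))

    meta = pd.DataFrame(
        {
            "donor": donors,
            "sample": [f"{d}_heart" for d in donors],
            "compartment": "heart",
            "group": np.where(is_case, "case", "control"),
            "fatal": fatal,
            "steroid_timing": np.where(is_case, "pre-corticosteroid", ""),
            "troponin": np.exp(log_trop),
            "troponin_offset_days": 0,
            "troponin_truth_abundance": abund,
        }
    )
    meta.attrs["donor_intercepts"] = u
    meta.attrs["cluster_probs"] = probs
    return meta


# ---------------------------------------------------------------------------
# cells and counts


def _base_means(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """cluster x gene base means with per-cluster marker-gene blocks."""
    gene_mu = np.exp(
        rng.normal(config.base_mean_log_mu, config.base_mean_log_sd, size=config.n_genes)
    )
    means = np.tile(gene_mu, (config.n_clusters, 1))
    for k in range(config.n_clusters):
        lo = k * config.markers_per_cluster
        hi = min(lo + config.markers_per_cluster, config.n_genes)
        means[k, lo:hi] *= 2.0**config.marker_log2fc
    return means


def generate_cells_and_counts(config: SimConfig, meta: pd.DataFrame):
    """Draw per-cell cluster labels and NB UMI counts for heart samples.

    Returns ``(cell_table, counts, genes)``; counts is cells x genes CSR.
    A configured fraction of cells has its QC covariates overwritten to
    fail the mito / unique-gene filters (counts are left untouched).
    """
    rng = _rng(config, 2)
    u = meta.attrs.get("donor_intercepts")
    if u is None:
        raise ValueError("meta must come from generate_cohort")
    is_case = (meta["group"] == "case").to_numpy()
    base = _base_means(config, rng)
    case_fold = np.ones((config.n_clusters, config.n_genes))
    for cluster, gene_set, log2fc in config.de_spec:
        case_fold[cluster, list(gene_set)] *= 2.0**log2fc

    genes = pd.Index([f"G{i:04d}" for i in range(config.n_genes)], name="gene")
    records = []
    blocks = []
    for d in range(len(meta)):
        if isinstance(config.cells_per_donor, tuple):
            mean_n, disp = config.cells_per_donor
            r = 1.0 / disp
            n_cells = int(rng.negative_binomial(r, r / (r + mean_n))) or 1
        else:
            n_cells = int(config.cells_per_donor)
        logits = (
            config.baseline_cluster_logits
            + (config.case_log_odds if is_case[d] else 0.0)
            + u[d]
        )
        clusters = rng.choice(config.n_clusters, size=n_cells, p=_softmax(logits))
        lib = np.exp(rng.normal(*config.libsize_lognormal, size=n_cells))
        mu = base[clusters] * lib[:, None]
        if is_case[d]:
            mu = mu * case_fold[clusters]
        r_nb = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
        blocks.append(sp.csr_matrix(counts))
        donor = meta["donor"].iloc[d]
        for i in range(n_cells):
            records.append((f"{donor}-{i:05d}", donor, meta["sample"].iloc[d], clusters[i]))

    counts = sp.vstack(blocks).tocsr()
    counts.eliminate_zeros()
    cell_table = pd.DataFrame(records, columns=["barcode", "donor", "sample", "cluster"])
    cell_table["compartment"] = "heart"
    # QC covariates emulate full-transcriptome droplets (the simulated
    # count matrix is desk-scale, so unique-gene counts are simulated,
    # not derived from it)
    cell_table["n_genes"] = rng.integers(500, 4000, size=len(cell_table))
    cell_table["mito_frac"] = rng.uniform(0.0, 0.15, size=len(cell_table))

    # inject QC failures by overwriting covariates only
    n = len(cell_table)
    fail_mito = rng.random(n) < config.mito_fail_fraction
    fail_genes = (~fail_mito) & (rng.random(n) < config.lowgene_fail_fraction)
    cell_table.loc[fail_mito, "mito_frac"] = rng.uniform(0.20, 0.9, size=int(fail_mito.sum()))
    cell_table.loc[fail_genes, "n_genes"] = rng.integers(
        1, 300, size=int(fail_genes.sum())
    )
    return cell_table, counts, genes


# ---------------------------------------------------------------------------
# TCR repertoires


def _random_clone_keys(rng: np.random.Generator, n: int, prefix: str) -> list:
    keys = []
    for i in range(n):
        v = f"TRBV{rng.integers(1, 31)}"
        cdr3 = "".join(rng.choice(_NT, size=39))
        keys.append(f"{v}|{cdr3}")
    return keys


def _split_even(total: int, parts: int) -> list:
    base = total // parts
    out = [base + (1 if i < total % parts else 0) for i in range(parts)]
    return out


def generate_repertoires(config: SimConfig, meta: pd.DataFrame):
    """Per-donor clone tables for heart / tumor / control tissue plus
    blood cells carrying heart-expanded clonotypes.

    The first ``n_tcr_donors`` case donors get matched three-tissue
    repertoires: control tissue follows a truncated power law; heart and
    tumor boost their designated enriched clones to the configured
    frequency band.  Heart- and tumor-enriched truth sets overlap by
    ``round(overlap_fraction * n_heart_enriched)`` clones.  The
    remaining case donors get a heart-only power-law repertoire (no
    matched tumor / control tissue), mirroring a cohort where only the
    autopsy donors have three-tissue data.  Blood cells of every case
    donor carry that donor's heart-expanded keys at the fatal or
    non-fatal rate inside the designated subset and at the non-fatal
    background rate elsewhere.
    """
    rng = _rng(config, 3)
    case_meta = meta.loc[meta["group"] == "case"]
    tcr_donors = list(case_meta["donor"].iloc[: config.n_tcr_donors])
    n_shared_total = int(round(config.heart_tumor_overlap_fraction * config.n_heart_enriched))
    heart_per = _split_even(config.n_heart_enriched, len(tcr_donors))
    tumor_per = _split_even(config.n_tumor_enriched, len(tcr_donors))
    shared_per = _split_even(n_shared_total, len(tcr_donors))

    base_freq = (1.0 + np.arange(config.n_clones)) ** (-config.powerlaw_exponent)
    base_freq = base_freq / base_freq.sum()

    heart_tables, tumor_tables, control_tables = {}, {}, {}
    truth_heart, truth_tumor, truth_shared = {}, {}, {}
    for j, donor in enumerate(tcr_donors):
        keys = _random_clone_keys(rng, config.n_clones, donor)
        n_h, n_t, n_s = heart_per[j], tumor_per[j], min(shared_per[j], heart_per[j], tumor_per[j])
        # enriched clones live in the power-law tail so control freq is low
        tail = np.arange(config.n_clones // 2, config.n_clones)
        picks = rng.choice(tail, size=n_h + n_t - n_s, replace=False)
        heart_idx = picks[:n_h]
        tumor_idx = np.concatenate([picks[:n_s], picks[n_h:]])

        def boosted(idx):
            freq = base_freq.copy()
            target = rng.uniform(*config.enriched_freq_range, size=len(idx))
            freq[idx] = 0.0
            freq = freq / freq.sum() * (1.0 - target.sum())
            freq[idx] = target
            return freq

        tissues = {
            "control_tissue": base_freq,
            "heart": boosted(heart_idx),
            "tumor": boosted(tumor_idx),
        }
        for tissue, freq in tissues.items():
            reads = rng.multinomial(config.total_reads[tissue], freq)
            table = pd.DataFrame(
                {"clone_key": keys, "count": reads, "frequency": reads / reads.sum()}
            )
            table = table.loc[table["count"] > 0].reset_index(drop=True)
            if tissue == "heart":
                heart_tables[donor] = table
            elif tissue == "tumor":
                tumor_tables[donor] = table
            else:
                control_tables[donor] = table
        truth_heart[donor] = {keys[i] for i in heart_idx}
        truth_tumor[donor] = {keys[i] for i in tumor_idx}
        truth_shared[donor] = {keys[i] for i in picks[:n_s]}

    # heart-only repertoires for the remaining case donors (power-law head
    # clones are naturally expanded, supporting the sharing analysis)
    other_donors = [d for d in case_meta["donor"] if d not in tcr_donors]
    for donor in other_donors:
        keys = _random_clone_keys(rng, config.n_clones, donor)
        reads = rng.multinomial(config.total_reads["heart"], base_freq)
        table = pd.DataFrame(
            {"clone_key": keys, "count": reads, "frequency": reads / reads.sum()}
        )
        heart_tables[donor] = table.loc[table["count"] > 0].reset_index(drop=True)
        truth_heart[donor] = set()

    # blood cells for every case donor with a heart repertoire
    blood_rows = []
    for donor in list(tcr_donors) + other_donors:
        fatal = bool(meta.loc[meta["donor"] == donor, "fatal"].iloc[0])
        rate = config.fatal_sharing_rate if fatal else config.nonfatal_sharing_rate
        heart_tab = heart_tables[donor]
        total = heart_tab["count"].sum()
        expanded = sorted(
            heart_tab.loc[
                (heart_tab["count"] / total > 0.005) & (heart_tab["count"] >= 2),
                "clone_key",
            ]
        )
        bystander = _random_clone_keys(rng, 200, donor + "_blood")
        subsets = rng.integers(0, config.n_blood_subsets, size=config.blood_cells_per_donor)
        for i in range(config.blood_cells_per_donor):
            in_target = subsets[i] == config.fatal_sharing_subset
            p_shared = rate if in_target else config.nonfatal_sharing_rate / 2.0
            if expanded and rng.random() < p_shared:
                key = expanded[rng.integers(0, len(expanded))]
            else:
                key = bystander[rng.integers(0, len(bystander))]
            blood_rows.append((f"{donor}-b{i:05d}", donor, subsets[i], key))
    blood_cells = pd.DataFrame(
        blood_rows, columns=["barcode", "donor", "cluster", "clone_key"]
    )
    blood_cells["compartment"] = "blood"
    truth = {
        "heart_enriched": truth_heart,
        "tumor_enriched": truth_tumor,
        "heart_tumor_shared": truth_shared,
    }
    return heart_tables, tumor_tables, control_tables, blood_cells, truth


# ---------------------------------------------------------------------------
# serum


def generate_serum(config: SimConfig, meta: pd.DataFrame) -> pd.DataFrame:
    """Log-normal serum panel; the first n_shifted analytes are case-shifted."""
    rng = _rng(config, 4)
    analytes = [f"analyte_{i + 1:02d}" for i in range(config.n_analytes)]
    shifted = set(analytes[: config.n_shifted_analytes])
    rows = []
    for donor, group in zip(meta["donor"], meta["group"]):
        is_case = group == "case"
        for a in analytes:
            mu = config.serum_log_mean + (
                config.serum_log_shift if (is_case and a in shifted) else 0.0
            )
            rows.append((a, donor, float(np.exp(rng.normal(mu, config.serum_log_sd)))))
    table = pd.DataFrame(rows, columns=["analyte", "donor", "value"])
    table.attrs["shifted_analytes"] = sorted(shifted)
    return table


# ---------------------------------------------------------------------------
# full study


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate the complete synthetic study with ground truth attached."""
    meta = generate_cohort(config)
    cell_table, counts, genes = generate_cells_and_counts(config, meta)
    heart, tumor, control, blood_cells, tcr_truth = generate_repertoires(config, meta)
    serum_table = generate_serum(config, meta)
    truth = {
        "config": config.to_dict(),
        "donor_intercepts": meta.attrs["donor_intercepts"],
        "cluster_probs": meta.attrs["cluster_probs"],
        "case_log_odds": config.case_log_odds.copy(),
        "de_spec": list(config.de_spec),
        "shifted_analytes": serum_table.attrs["shifted_analytes"],
        **tcr_truth,
    }
    return SimulatedStudy(
        sample_meta=meta,
        cell_table=cell_table,
        counts=counts,
        genes=genes,
        heart_bulk_clones=heart,
        tumor_clones=tumor,
        control_tissue_clones=control,
        blood_cells=blood_cells,
        serum_table=serum_table,
        truth=truth,
    )
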