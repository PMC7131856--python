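"""Synthetic panel-count generator with planted, recoverable structure.

Emulates the data a targeted immune-oncology amplicon panel produces on a
brain-metastasis cohort: a gene x sample matrix of negative-binomial read
counts with log-normal library-size factors, ten stably expressed
housekeeping genes, a low-level no-template-control background, paired
tumor/adjacent samples sharing a patient-level random intercept, and
planted log2 expression effects (individual differentially expressed
genes and per-class signature shifts by primary cancer type).

The default cohort mirrors the study design the pipeline targets: 25
patients (12 lung, 6 breast, 7 colorectal primaries), of whom 10 lung and
3 breast patients contribute a paired adjacent noncancerous brain sample
(38 tissue samples in all), with the published ages, genders and
prior-treatment flags. Every planted effect is emitted in a first-class
truth record so downstream benchmarks never reach into generator
internals.

Model
-----
``log2 mu[g, s] = b_g + lib_s + u_patient(s)·[g not HK] + effects(g, s)
+ eps[g, s]`` with gene baselines ``b_g ~ N(8, 2)`` (log2-count scale),
library factors ``lib_s ~ N(0, library_sd)``, and per-gene patient
intercepts ``u[g, patient] ~ N(0, patient_sd)`` shared by both tissues of
a patient (target genes only, so the within-pair correlation survives
housekeeping normalization without shifting global amplitude), plus
residual biological noise. Counts are NB with dispersion ``alpha`` (Poisson at 0)
plus a Poisson background whose per-gene rate also generates the NTC
column. Housekeeping baseline RPMs are set to the expected HK counts of a
library-factor-1 sample, so a reference-like sample has all HK ratios ~ 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import (
    CountMatrix,
    PanelDefinition,
    SampleMetadata,
    SeqQCStats,
)
from .signatures import DEFAULT_SIGNATURES

# Cohort table mirrored from the target study design:
# (patient, cancer, age, gender, paired adjacent tissue, prior treatment)
STUDY_COHORT: list[tuple[str, str, int, str, bool, bool]] = [
    ("P01", "lung", 64, "male", True, False),
    ("P02", "lung", 61, "male", True, False),
    ("P03", "lung", 74, "male", True, False),
    ("P04", "lung", 80, "male", True, False),
    ("P05", "lung", 64, "male", False, True),
    ("P06", "lung", 62, "male", True, False),
    ("P07", "lung", 66, "female", True, True),
    ("P08", "lung", 57, "female", False, True),
    ("P09", "lung", 49, "male", True, False),
    ("P10", "lung", 53, "male", True, False),
    ("P11", "lung", 72, "male", True, False),
    ("P12", "lung", 49, "male", True, False),
    ("P13", "breast", 69, "female", True, False),
    ("P14", "breast", 53, "female", True, True),
    ("P15", "breast", 52, "female", True, True),
    ("P16", "breast", 64, "female", False, True),
    ("P17", "breast", 39, "female", False, True),
    ("P18", "breast", 54, "female", False, False),
    ("P19", "colorectal", 77, "female", False, False),
    ("P20", "colorectal", 29, "male", False, True),
    ("P21", "colorectal", 67, "male", False, False),
    ("P22", "colorectal", 68, "male", False, True),
    ("P23", "colorectal", 50, "male", False, True),
    ("P24", "colorectal", 60, "male", False, False),
    ("P25", "colorectal", 78, "female", False, False),
]

#: named non-housekeeping genes embedded in the synthetic panel so the
#: default signature definitions resolve
_NAMED_GENES: dict[str, str] = {
    **{g: cls for cls, genes in DEFAULT_SIGNATURES.items() for g in genes},
    "KIAA0101": "tumor marker",
    "TOP2A": "tumor marker",
    "CCL17": "other immune function",
    "CA4": "other immune function",
    "NCAM1": "other immune function",
    "EGR3": "other immune function",
    "KLF2": "other immune function",
    "CX3CR1": "other immune function",
    "CD226": "other immune function",
    "RORC": "other immune function",
}

_FILL_CATEGORIES = ("tumor antigen", "tumor marker", "other immune function")


@dataclass
class PlantedEffect:
    """A log2 mean shift applied to a gene set in a sample stratum.

    ``cancer`` / ``tissue`` restrict the stratum (None = no restriction),
    e.g. ``tissue="BM"`` plants a tumor-vs-adjacent effect in every
    cancer type, while ``cancer="lung", tissue="BM"`` plants a
    lung-specific overexpression.
    """

    genes: list[str]
    log2_effect: float
    cancer: str | None = None
    tissue: str | None = None


@dataclass
class SimulationConfig:
    """Conditions of a synthetic panel run; the seed is mandatory."""

    seed: int
    n_genes: int = 395
    n_hk: int = 10
    #: cancer type -> (n patients, n of them with a paired adjacent sample)
    cohort: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "lung": (12, 10), "breast": (6, 3), "colorectal": (7, 0),
        }
    )
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    hk_log2_mean: float = 9.5
    hk_log2_sd: float = 0.3
    dispersion: float = 0.05       # NB dispersion alpha (0 = Poisson)
    library_sd: float = 0.3        # log2 library-size factor sd
    patient_sd: float = 0.5        # paired random intercept sd (log2)
    residual_sd: float = 0.4       # per-sample biological noise sd (log2)
    hk_residual_sd: float = 0.05   # housekeeping genes are quasi-stable
    ntc_rate: float = 5.0          # mean background count per gene
    planted: list[PlantedEffect] = field(default_factory=list)
    #: gene class -> cancer type -> log2 shift in that cancer's tumors
    signature_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.n_hk > self.n_genes:
            raise ValueError("n_hk cannot exceed n_genes")
        if self.n_hk < 1:
            raise ValueError("the QC gate needs housekeeping genes (n_hk >= 1)")


def default_config(seed: int) -> SimulationConfig:
    """Study-shaped conditions with the planted structure the analysis
    is meant to recover: tumor-marker up / adhesion-gene down shifts in
    tumors versus adjacent tissue, and a +1.5 log2 shift of all four
    immune gene classes in lung-derived metastases."""
    cfg = SimulationConfig(seed=seed)
    cfg.planted = [
        PlantedEffect(
            genes=["KIAA0101", "TOP2A", "CCL17"], log2_effect=2.0, tissue="BM"
        ),
        PlantedEffect(
            genes=["CA4", "NCAM1", "EGR3", "KLF2", "CX3CR1", "CD226"],
            log2_effect=-2.0,
            tissue="BM",
        ),
    ]
    cfg.signature_effects = {
        cls: {"lung": 1.5} for cls in DEFAULT_SIGNATURES
    }
    return cfg


# ---------------------------------------------------------------------------
# panel synthesis


def _gene_names(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """(target genes, HK genes) of the synthetic panel, panel order."""
    n_targets = config.n_genes - config.n_hk
    named = list(_NAMED_GENES)[:n_targets]
    filler = [f"G{i:04d}" for i in range(n_targets - len(named))]
    hk = [f"HK{i + 1:02d}" for i in range(config.n_hk)]
    return named + filler, hk


def _gene_baselines(config: SimulationConfig) -> pd.Series:
    """Per-gene baseline log2 expected count at library factor 1."""
    targets, hk = _gene_names(config)
    rng = np.random.default_rng([config.seed, 1])
    b_t = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, len(targets))
    b_h = rng.normal(config.hk_log2_mean, config.hk_log2_sd, len(hk))
    return pd.Series(
        np.concatenate([b_t, b_h]), index=targets + hk, dtype=float
    )


def simulate_panel(config: SimulationConfig) -> PanelDefinition:
    """Synthesize a panel definition consistent with :func:`simulate_counts`.

    HK baseline RPMs equal the expected HK counts of a library-factor-1
    sample, so such a reference-like sample has all HK ratios ~ 1.
    """
    targets, hk = _gene_names(config)
    rng = np.random.default_rng([config.seed, 0])
    category = {}
    for g in targets:
        category[g] = _NAMED_GENES.get(
            g, _FILL_CATEGORIES[rng.integers(len(_FILL_CATEGORIES))]
        )
    for g in hk:
        category[g] = "housekeeping"
    baselines = _gene_baselines(config)
    hk_baseline_rpm = {g: float(2.0 ** baselines[g]) for g in hk}
    return PanelDefinition(
        genes=targets + hk,
        category=category,
        hk_genes=hk,
        hk_baseline_rpm=hk_baseline_rpm,
    )


# ---------------------------------------------------------------------------
# cohort metadata


def _cohort_metadata(
    config: SimulationConfig, rng: np.random.Generator
) -> list[SampleMetadata]:
    default = {"lung": (12, 10), "breast": (6, 3), "colorectal": (7, 0)}
    records = []
    if config.cohort == default:
        rows = STUDY_COHORT
    else:
        rows = []
        i = 0
        for cancer, (n_pat, n_paired) in config.cohort.items():
            for j in range(n_pat):
                i += 1
                gender = "female" if (
                    cancer == "breast" or rng.random() < 0.35
                ) else "male"
                rows.append(
                    (
                        f"P{i:02d}", cancer,
                        int(rng.integers(30, 81)), gender,
                        j < n_paired, bool(rng.random() < 0.4),
                    )
                )
    for pid, cancer, age, gender, paired, treated in rows:
        records.append(
            SampleMetadata(
                sample_id=f"{pid}_BM", patient_id=pid, primary_cancer=cancer,
                tissue="BM", age=age, gender=gender, prior_treatment=treated,
            )
        )
        if paired:
            records.append(
                SampleMetadata(
                    sample_id=f"{pid}_ADJ", patient_id=pid,
                    primary_cancer=cancer, tissue="adjacent", age=age,
                    gender=gender, prior_treatment=treated,
                )
            )
    return records


# ---------------------------------------------------------------------------
# count synthesis


def _effect_rows(
    config: SimulationConfig, panel: PanelDefinition
) -> list[tuple[list[str], float, str | None, str | None, str]]:
    rows = []
    panel_genes = set(panel.genes)
    for eff in config.planted:
        missing = set(eff.genes) - panel_genes
        if missing:
            raise ValueError(f"planted genes absent from panel: {sorted(missing)}")
        rows.append((list(eff.genes), eff.log2_effect, eff.cancer, eff.tissue, "planted"))
    for cls, shifts in config.signature_effects.items():
        genes = panel.genes_in_category(cls)
        if not genes:
            raise ValueError(f"no panel genes in class {cls!r}")
        for cancer, shift in shifts.items():
            rows.append((genes, shift, cancer, "BM", "signature"))
    return rows


def simulate_counts(
    config: SimulationConfig, panel: PanelDefinition | None = None
) -> tuple[CountMatrix, list[SampleMetadata], list[SeqQCStats], pd.DataFrame]:
    """Draw one synthetic cohort: counts, metadata, QC stats and truth.

    The truth record (one row per gene x planted effect, with the stratum
    it applies to) is the contract for benchmarking: planted tumor-vs-
    adjacent genes should be recovered by the paired contrast, class
    shifts by the between-cancer contrasts and signature association.
    """
    if panel is None:
        panel = simulate_panel(config)
    meta = _cohort_metadata(config, np.random.default_rng([config.seed, 2]))
    rng = np.random.default_rng([config.seed, 3])

    genes = panel.genes
    baselines = _gene_baselines(config).loc[genes]
    hk_mask = np.array([g in set(panel.hk_genes) for g in genes])
    sample_ids = [m.sample_id for m in meta]
    patients = sorted({m.patient_id for m in meta})
    # per-gene patient intercepts: within-pair correlation gene by gene,
    # without a global amplitude shift (HK genes stay patient-free)
    u_patient = {
        p: np.where(hk_mask, 0.0, rng.normal(0.0, config.patient_sd, len(genes)))
        for p in patients
    }
    lib = rng.normal(0.0, config.library_sd, len(meta))

    effects = _effect_rows(config, panel)
    gene_pos = {g: i for i, g in enumerate(genes)}

    log2mu = np.empty((len(genes), len(meta)))
    for j, m in enumerate(meta):
        col = baselines.to_numpy() + lib[j] + u_patient[m.patient_id]
        for eff_genes, shift, cancer, tissue, _ in effects:
            if cancer is not None and m.primary_cancer != cancer:
                continue
            if tissue is not None and m.tissue != tissue:
                continue
            idx = [gene_pos[g] for g in eff_genes]
            col[idx] += shift
        eps_sd = np.where(hk_mask, config.hk_residual_sd, config.residual_sd)
        col = col + rng.normal(0.0, 1.0, len(genes)) * eps_sd
        log2mu[:, j] = col

    mu = np.power(2.0, log2mu)
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        signal = rng.negative_binomial(r, r / (r + mu))
    else:
        signal = rng.poisson(mu)

    bg_rate = rng.gamma(2.0, config.ntc_rate / 2.0, len(genes))
    background = rng.poisson(bg_rate[:, None], size=(len(genes), len(meta)))
    counts = pd.DataFrame(
        signal + background, index=pd.Index(genes, name="gene"),
        columns=sample_ids,
    )
    ntc = pd.Series(rng.poisson(bg_rate), index=counts.index, name="NTC")

    on_target = rng.uniform(0.85, 0.95, len(meta))
    # gene-assigned counts are a fraction of mapped on-target reads
    # (duplicates, off-amplicon and unassigned reads are mapped but not
    # counted), so mapped reads exceed the count total accordingly
    assigned_frac = rng.uniform(0.55, 0.7, len(meta))
    qc = [
        SeqQCStats(
            sample_id=s,
            mapped_reads=int(
                round(counts[s].sum() / (on_target[j] * assigned_frac[j]))
            ),
            on_target_ratio=float(round(on_target[j], 4)),
            n_hk_detected=int((counts.loc[panel.hk_genes, s] > 0).sum()),
        )
        for j, s in enumerate(sample_ids)
    ]

    truth = pd.DataFrame(
        [
            {
                "gene": g,
                "log2_effect": shift,
                "cancer": cancer if cancer is not None else "*",
                "tissue": tissue if tissue is not None else "*",
                "source": source,
            }
            for eff_genes, shift, cancer, tissue, source in effects
            for g in eff_genes
        ],
        columns=["gene", "log2_effect", "cancer", "tissue", "source"],
    )
    return CountMatrix(counts=counts, ntc=ntc), meta, qc, truth


# ---------------------------------------------------------------------------
# QC corruption


QC_CORRUPTION_MODES = ("low_depth", "off_target", "hk_dropout")


def corrupt_qc(
    stats: list[SeqQCStats],
    mode: str,
    sample_ids: list[str] | None = None,
) -> list[SeqQCStats]:
    """Force the designated samples to fail exactly one QC criterion.

    ``low_depth`` drops mapped reads below 200k, ``off_target`` pushes
    the on-target ratio to 45%, ``hk_dropout`` sets detected HK genes to
    5. Other samples (and other criteria) are untouched.
    """
    if mode not in QC_CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}")
    targets = set(sample_ids) if sample_ids is not None else {
        s.sample_id for s in stats
    }
    out = []
    for s in stats:
        if s.sample_id not in targets:
            out.append(
                SeqQCStats(s.sample_id, s.mapped_reads, s.on_target_ratio, s.n_hk_detected)
            )
            continue
        mapped, ratio, nhk = s.mapped_reads, s.on_target_ratio, s.n_hk_detected
        if mode == "low_depth":
            mapped = 150_000
        elif mode == "off_target":
            ratio = 0.45
        elif mode == "hk_dropout":
            nhk = 5
        out.append(SeqQCStats(s.sample_id, mapped, ratio, nhk))
    return out
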