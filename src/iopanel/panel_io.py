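"""Panel definitions, count matrices, sample metadata and sequencing QC stats.

The targeted immune-oncology panel measures ~395 human genes (immune
checkpoints, lymphocyte-infiltration markers, TCR machinery, interferon
response genes, tumor antigens/markers) plus ten housekeeping genes whose
read counts calibrate each sample against a baseline reads-per-million
profile measured on replicate GM12878 runs. This module defines the
in-memory containers for the panel and its data files and the TSV/YAML
readers and writers, with validation of their mutual consistency.

File formats
------------
* panel definition: YAML with a ``genes`` list of ``{symbol, category}``
  records and an ``hk_baseline_rpm`` mapping (housekeeping gene -> baseline
  RPM);
* count matrix: TSV, gene rows x sample columns, first column ``gene``,
  one reserved column (default ``NTC``) holding the no-template control;
* sample metadata and sequencing QC stats: one-row-per-sample TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: functional categories a panel gene may belong to
CATEGORIES = frozenset(
    {
        "checkpoint pathway",
        "lymphocyte infiltration",
        "TCR coexpression",
        "type II interferon signaling",
        "tumor antigen",
        "tumor marker",
        "other immune function",
        "housekeeping",
    }
)

#: reserved sample identifier for the no-template control column
NTC_ID = "NTC"

CANCER_TYPES = ("lung", "breast", "colorectal")
TISSUES = ("BM", "adjacent")


class PanelValidationError(ValueError):
    """A panel definition or data file violates a structural invariant."""


@dataclass
class PanelDefinition:
    """Gene universe, functional category map and housekeeping calibration.

    Parameters
    ----------
    genes
        Ordered gene symbols of the panel.
    category
        Map gene symbol -> functional category (one of :data:`CATEGORIES`).
    hk_genes
        Housekeeping genes used as endogenous controls (subset of `genes`).
    hk_baseline_rpm
        Baseline reads-per-million per housekeeping gene, measured on the
        reference cell-line runs; strictly positive (it is a divisor).
    """

    genes: list[str]
    category: dict[str, str]
    hk_genes: list[str]
    hk_baseline_rpm: dict[str, float]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise PanelValidationError(f"duplicate gene in panel: {g!r}")
            seen.add(g)
        bad_cat = {g: c for g, c in self.category.items() if c not in CATEGORIES}
        if bad_cat:
            raise PanelValidationError(f"unknown categories: {bad_cat}")
        uncovered = seen - set(self.category)
        if uncovered or set(self.category) - seen:
            raise PanelValidationError(
                "category map must cover every panel gene exactly once; "
                f"uncovered={sorted(uncovered)} "
                f"extra={sorted(set(self.category) - seen)}"
            )
        if len(self.hk_genes) < 6:
            raise PanelValidationError(
                f"at least 6 housekeeping genes required, got {len(self.hk_genes)}"
            )
        missing_hk = set(self.hk_genes) - seen
        if missing_hk:
            raise PanelValidationError(
                f"housekeeping genes absent from gene list: {sorted(missing_hk)}"
            )
        for hk in self.hk_genes:
            if hk not in self.hk_baseline_rpm:
                raise PanelValidationError(
                    f"missing housekeeping baseline RPM for gene {hk!r}"
                )
            if not self.hk_baseline_rpm[hk] > 0:
                raise PanelValidationError(
                    f"housekeeping baseline RPM must be > 0, gene {hk!r} has "
                    f"{self.hk_baseline_rpm[hk]!r}"
                )

    @property
    def target_genes(self) -> list[str]:
        """Panel genes excluding the housekeeping controls."""
        hk = set(self.hk_genes)
        return [g for g in self.genes if g not in hk]

    def genes_in_category(self, category: str) -> list[str]:
        return [g for g in self.genes if self.category[g] == category]


@dataclass
class CountMatrix:
    """Absolute read counts, gene rows x sample columns, plus the NTC column.

    ``counts`` holds non-negative integers; ``ntc`` is the per-gene
    no-template-control count used for background subtraction.
    """

    counts: pd.DataFrame
    ntc: pd.Series

    def __post_init__(self) -> None:
        if not self.ntc.index.equals(self.counts.index):
            self.ntc = self.ntc.reindex(self.counts.index)
        if self.ntc.isna().any():
            raise PanelValidationError("NTC counts missing for some panel genes")
        arr = self.counts.to_numpy()
        if (arr < 0).any() or (self.ntc.to_numpy() < 0).any():
            raise PanelValidationError("read counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class SampleMetadata:
    """Clinical annotation of one profiled tissue sample."""

    sample_id: str
    patient_id: str
    primary_cancer: str
    tissue: str
    age: float
    gender: str
    prior_treatment: bool

    def __post_init__(self) -> None:
        if self.primary_cancer not in CANCER_TYPES:
            raise PanelValidationError(
                f"unknown cancer type {self.primary_cancer!r} for sample "
                f"{self.sample_id!r}; expected one of {CANCER_TYPES}"
            )
        if self.tissue not in TISSUES:
            raise PanelValidationError(
                f"unknown tissue {self.tissue!r} for sample {self.sample_id!r}"
            )
        if self.gender not in ("male", "female"):
            raise PanelValidationError(
                f"unknown gender {self.gender!r} for sample {self.sample_id!r}"
            )
        if not self.age > 0:
            raise PanelValidationError(
                f"age must be a positive number for sample {self.sample_id!r}"
            )


@dataclass
class SeqQCStats:
    """Per-sample sequencing quality statistics feeding the QC gate."""

    sample_id: str
    mapped_reads: int
    on_target_ratio: float
    n_hk_detected: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.on_target_ratio <= 1.0:
            raise PanelValidationError(
                f"on_target_ratio must lie in [0, 1], sample {self.sample_id!r} "
                f"has {self.on_target_ratio!r}"
            )
        if self.mapped_reads < 0 or self.n_hk_detected < 0:
            raise PanelValidationError("counts must be non-negative")


# ---------------------------------------------------------------------------
# panel definition I/O


def read_panel(path: str | Path) -> PanelDefinition:
    """Read and validate a YAML panel definition.

    The file holds a ``genes`` list of ``{symbol, category}`` records (so
    duplicate symbols are detectable, unlike a mapping) and an
    ``hk_baseline_rpm`` mapping for the housekeeping genes.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "genes" not in doc:
        raise PanelValidationError(f"panel file {path} lacks a 'genes' section")
    genes: list[str] = []
    category: dict[str, str] = {}
    for rec in doc["genes"]:
        sym, cat = rec["symbol"], rec["category"]
        if sym in category:
            raise PanelValidationError(f"duplicate gene in panel file: {sym!r}")
        genes.append(sym)
        category[sym] = cat
    baseline = {g: float(v) for g, v in (doc.get("hk_baseline_rpm") or {}).items()}
    hk_genes = [g for g in genes if category[g] == "housekeeping"]
    return PanelDefinition(
        genes=genes, category=category, hk_genes=hk_genes, hk_baseline_rpm=baseline
    )


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    doc = {
        "genes": [
            {"symbol": g, "category": panel.category[g]} for g in panel.genes
        ],
        "hk_baseline_rpm": {
            g: float(panel.hk_baseline_rpm[g]) for g in panel.hk_genes
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# count matrix I/O


def read_counts(
    path: str | Path, panel: PanelDefinition, ntc_id: str = NTC_ID
) -> CountMatrix:
    """Read a gene x sample TSV of absolute read counts.

    Genes are reordered to panel order. Genes present in the file but not in
    the panel are dropped with a warning (panel-version drift); panel genes
    missing from the file are a hard error, as are non-integral or negative
    cells and a missing or duplicated NTC column.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dups = sorted({c for c in header if header.count(c) > 1})
        raise PanelValidationError(f"duplicated sample columns: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise PanelValidationError(f"duplicated gene rows: {dups}")
    if ntc_id not in df.columns:
        raise PanelValidationError(
            f"no-template control column {ntc_id!r} required but absent"
        )
    extra = [g for g in df.index if g not in set(panel.genes)]
    if extra:
        logger.warning(
            "dropping %d genes absent from the panel definition: %s",
            len(extra), extra[:10],
        )
        df = df.drop(index=extra)
    missing = [g for g in panel.genes if g not in set(df.index)]
    if missing:
        raise PanelValidationError(f"panel genes missing from counts: {missing[:10]}")
    df = df.reindex(panel.genes)
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        raise PanelValidationError("non-numeric cells in count matrix")
    if ((num % 1) != 0).any().any():
        raise PanelValidationError("read counts must be integral")
    if (num < 0).any().any():
        raise PanelValidationError("read counts must be non-negative")
    num = num.astype(int)
    ntc = num[ntc_id]
    return CountMatrix(counts=num.drop(columns=[ntc_id]), ntc=ntc)


def write_counts(
    cm: CountMatrix, path: str | Path, ntc_id: str = NTC_ID
) -> None:
    out = cm.counts.copy()
    out[ntc_id] = cm.ntc
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample metadata I/O

_META_COLS = [
    "sample_id", "patient_id", "primary_cancer", "tissue",
    "age", "gender", "prior_treatment",
]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample clinical metadata from TSV.

    Adjacent-tissue samples whose patient has no matching tumor sample are
    kept but flagged with a warning: they cannot enter paired contrasts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in _META_COLS if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"metadata lacks columns: {missing_cols}")
    records = []
    for _, row in df.iterrows():
        if pd.isna(row["age"]) or str(row["age"]).strip() == "":
            raise PanelValidationError(
                f"age missing for sample {row['sample_id']!r}; age is a "
                "required adjustment covariate"
            )
        records.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                primary_cancer=row["primary_cancer"],
                tissue=row["tissue"],
                age=float(row["age"]),
                gender=row["gender"],
                prior_treatment=str(row["prior_treatment"]).lower()
                in ("1", "true", "yes"),
            )
        )
    bm_patients = {r.patient_id for r in records if r.tissue == "BM"}
    orphans = [
        r.sample_id for r in records
        if r.tissue == "adjacent" and r.patient_id not in bm_patients
    ]
    if orphans:
        logger.warning(
            "adjacent-tissue samples without a matching tumor sample "
            "(excluded from paired contrasts): %s", orphans,
        )
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    metadata_frame(records).to_csv(path, sep="\t", index=False)


def metadata_frame(records: Iterable[SampleMetadata]) -> pd.DataFrame:
    """Tabulate metadata records, one row per sample."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "primary_cancer": r.primary_cancer,
                "tissue": r.tissue,
                "age": r.age,
                "gender": r.gender,
                "prior_treatment": r.prior_treatment,
            }
            for r in records
        ]
    )


def paired_patients(records: Sequence[SampleMetadata]) -> dict[str, tuple[str, str]]:
    """Patients with both a tumor and an adjacent sample.

    Returns patient_id -> (BM sample_id, adjacent sample_id).
    """
    by_patient: dict[str, dict[str, str]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, {})[r.tissue] = r.sample_id
    return {
        p: (t["BM"], t["adjacent"])
        for p, t in by_patient.items()
        if "BM" in t and "adjacent" in t
    }


# ---------------------------------------------------------------------------
# sequencing QC stats I/O

_QC_COLS = ["sample_id", "mapped_reads", "on_target_ratio", "n_hk_detected"]


def read_qc_stats(path: str | Path) -> list[SeqQCStats]:
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in _QC_COLS if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"QC stats lack columns: {missing_cols}")
    return [
        SeqQCStats(
            sample_id=str(row.sample_id),
            mapped_reads=int(row.mapped_reads),
            on_target_ratio=float(row.on_target_ratio),
            n_hk_detected=int(row.n_hk_detected),
        )
        for row in df.itertuples()
    ]


def write_qc_stats(stats: Sequence[SeqQCStats], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "mapped_reads": s.mapped_reads,
                "on_target_ratio": s.on_target_ratio,
                "n_hk_detected": s.n_hk_detected,
            }
            for s in stats
        ]
    ).to_csv(path, sep="\t", index=False)
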