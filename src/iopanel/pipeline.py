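"""End-to-end orchestration: QC -> normalize -> DEG -> overlap -> signatures.

The run mirrors the analysis workflow of a targeted immune panel study of
brain metastases: admit samples through the sequencing QC gate, normalize
to nRPM, compare tumors with paired adjacent tissue per cancer type,
compare tumors between primary cancer types, intersect the resulting DEG
lists, score the immune gene-class signatures and test their
covariate-adjusted association with the primary site. The report is a
plain dict (serialized as JSON) plus TSV tables, deterministic for a
fixed configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import Contrast, deg_table, log_transform, overlap
from .normalization import NormalizedMatrix, normalize, qc_gate
from .panel_io import (
    CountMatrix,
    PanelDefinition,
    SampleMetadata,
    SeqQCStats,
    metadata_frame,
    paired_patients,
)
from .signatures import (
    SignatureDefinition,
    associate,
    association_frame,
    default_signatures,
    pca_embedding,
    score_signatures,
)
from .simulate import SimulationConfig, default_config, simulate_counts, simulate_panel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """What to run: either a simulation config or pre-loaded inputs."""

    sim: SimulationConfig | None = None
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    pseudocount: float = 1.0
    signatures: list[SignatureDefinition] = field(default_factory=default_signatures)
    #: contrast names to run; empty list = QC + normalization only
    contrasts: list[str] = field(
        default_factory=lambda: [
            "lung_BM_vs_adjacent",
            "breast_BM_vs_adjacent",
            "lung_vs_breast",
            "lung_vs_colorectal",
        ]
    )
    outcome: tuple[str, str] = ("lung", "breast")  # coded 1 vs 0
    outdir: Path | None = None
    make_figures: bool = False


def hk_ratio_median_near_one(
    cm: CountMatrix, panel: PanelDefinition, tol: float = 0.15
) -> bool:
    """Heuristic: does a matrix look already normalized?

    When per-sample medians of HK ratios all sit near 1, the matrix is
    already on the nRPM scale and normalization should be skipped.
    """
    from .normalization import _hk_ratio_frame

    med = _hk_ratio_frame(cm.counts, panel).median(axis=0)
    return bool(((med - 1.0).abs() <= tol).all())


def build_contrasts(
    meta: list[SampleMetadata], names: list[str]
) -> list[Contrast]:
    """Materialize named contrasts from cohort metadata.

    ``<cancer>_BM_vs_adjacent`` is paired within patients of that cancer
    type; ``<cancer>_vs_<cancer>`` compares tumor samples unpaired.
    """
    by_cancer_bm: dict[str, list[str]] = {}
    for m in meta:
        if m.tissue == "BM":
            by_cancer_bm.setdefault(m.primary_cancer, []).append(m.sample_id)
    pairs = paired_patients(meta)
    cancer_of = {m.patient_id: m.primary_cancer for m in meta}
    contrasts = []
    for name in names:
        if name.endswith("_BM_vs_adjacent"):
            cancer = name[: -len("_BM_vs_adjacent")]
            cpairs = {
                p: ab for p, ab in pairs.items() if cancer_of[p] == cancer
            }
            if len(cpairs) < 2:
                raise ValueError(
                    f"contrast {name!r}: fewer than 2 pairs available"
                )
            contrasts.append(
                Contrast(
                    name=name,
                    design="paired",
                    group_a=[ab[0] for ab in cpairs.values()],
                    group_b=[ab[1] for ab in cpairs.values()],
                    pairing=cpairs,
                )
            )
        elif "_vs_" in name:
            a, b = name.split("_vs_")
            contrasts.append(
                Contrast(
                    name=name,
                    design="unpaired",
                    group_a=by_cancer_bm.get(a, []),
                    group_b=by_cancer_bm.get(b, []),
                )
            )
        else:
            raise ValueError(f"cannot interpret contrast name {name!r}")
    return contrasts


def run_pipeline(
    config: RunConfig,
    cm: CountMatrix | None = None,
    panel: PanelDefinition | None = None,
    meta: list[SampleMetadata] | None = None,
    qc_stats: list[SeqQCStats] | None = None,
) -> dict:
    """Run the full analysis; returns the machine-readable report.

    Inputs can be supplied directly (ingest mode) or generated from
    ``config.sim`` (simulation mode). The report carries per-contrast DEG
    counts, overlap region sizes, the signature association table, QC
    exclusions and provenance; tables and figures are written under
    ``config.outdir`` when set.
    """
    truth = None
    if cm is None:
        sim = config.sim or default_config(seed=0)
        panel = simulate_panel(sim)
        cm, meta, qc_stats, truth = simulate_counts(sim, panel)
    if panel is None or meta is None:
        raise ValueError("ingest mode requires panel and metadata")

    # --- QC gate
    verdicts = (
        [qc_gate(s, panel) for s in qc_stats] if qc_stats is not None else None
    )
    excluded = (
        {v.sample_id: v.reasons for v in verdicts if not v.passed}
        if verdicts
        else {}
    )

    # --- normalization (skipped when the input is already on nRPM scale)
    already_normalized = hk_ratio_median_near_one(cm, panel) and (
        cm.ntc == 0
    ).all()
    if already_normalized:
        logger.info("input looks already normalized (HK ratio medians ~ 1)")
        keep = [
            s for s in cm.sample_ids
            if not verdicts or s not in excluded
        ]
        nm = NormalizedMatrix(
            nrpm=cm.counts[keep].astype(float),
            norm_ratio=pd.Series(1.0, index=keep),
            hk_ratios=pd.DataFrame(
                1.0, index=panel.hk_genes, columns=keep
            ),
        )
    else:
        nm = normalize(cm, panel, verdicts)
    logx = log_transform(nm.nrpm, config.pseudocount)
    meta_kept = [m for m in meta if m.sample_id in set(nm.sample_ids)]

    report: dict = {
        "provenance": {
            "iopanel_version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.sim.seed if config.sim else None,
        },
        "qc": {
            "n_samples_in": len(cm.sample_ids),
            "n_samples_passing": len(nm.sample_ids),
            "excluded": excluded,
        },
        "normalization": {
            "already_normalized_input": bool(already_normalized),
            "norm_ratio": {
                s: float(r) for s, r in nm.norm_ratio.items()
            },
        },
        "contrasts": {},
        "overlaps": {},
        "signatures": {},
    }

    # --- differential expression
    deg_tables: dict[str, pd.DataFrame] = {}
    if config.contrasts:
        contrasts = build_contrasts(meta_kept, config.contrasts)
        for c in contrasts:
            table = deg_table(
                logx, c, config.fc_threshold, config.p_threshold
            )
            deg_tables[c.name] = table
            report["contrasts"][c.name] = {
                "design": c.design,
                "n_a": len(c.group_a),
                "n_b": len(c.group_b),
                "n_deg": int(table["is_deg"].sum()),
                "n_up": int((table["direction"] == "up").sum()),
                "n_down": int((table["direction"] == "down").sum()),
            }

        # --- co-regulation overlaps mirroring the study's Venn analyses
        def deg_set(name: str, direction: str | None = None) -> set[str]:
            t = deg_tables.get(name)
            if t is None:
                return set()
            mask = t["is_deg"] if direction is None else t["direction"] == direction
            return set(t.index[mask])

        if {"lung_BM_vs_adjacent", "breast_BM_vs_adjacent"} <= set(deg_tables):
            for direction in ("up", "down"):
                ov = overlap(
                    {
                        "lung": deg_set("lung_BM_vs_adjacent", direction),
                        "breast": deg_set("breast_BM_vs_adjacent", direction),
                    }
                )
                report["overlaps"][f"BM_vs_adjacent_{direction}"] = ov.sizes()
        if {"lung_vs_breast", "lung_vs_colorectal"} <= set(deg_tables):
            ov = overlap(
                {
                    "vs_breast": deg_set("lung_vs_breast"),
                    "vs_colorectal": deg_set("lung_vs_colorectal"),
                }
            )
            report["overlaps"]["lung_vs_other_types"] = ov.sizes()
            report["overlaps"]["lung_shared_deg_genes"] = ov.region(
                "vs_breast", "vs_colorectal"
            )

    # --- signatures and association
    resolvable = [
        s for s in config.signatures
        if any(g in logx.index for g in s.member_genes)
    ]
    if resolvable and config.contrasts:
        scores = score_signatures(logx, resolvable)
        lvl1, lvl0 = config.outcome
        outcome = {
            m.sample_id: 1.0 if m.primary_cancer == lvl1 else 0.0
            for m in meta_kept
            if m.tissue == "BM" and m.primary_cancer in (lvl1, lvl0)
        }
        assoc = associate(
            scores,
            metadata_frame(meta_kept),
            outcome,
            signature_sizes={
                s.name: len(s.member_genes) for s in resolvable
            },
        )
        report["signatures"] = {
            "outcome": f"{lvl1}=1_vs_{lvl0}=0",
            "associations": association_frame(assoc).to_dict("records"),
        }

    if truth is not None:
        report["truth_summary"] = {
            "n_planted_genes": int(truth["gene"].nunique()),
        }

    if config.outdir is not None:
        _write_outputs(
            Path(config.outdir), report, nm, logx, deg_tables, truth, config
        )
    return report


def _config_hash(config: RunConfig) -> str:
    blob = repr(
        (
            config.sim,
            config.fc_threshold,
            config.p_threshold,
            config.pseudocount,
            [(s.name, tuple(s.member_genes)) for s in config.signatures],
            config.contrasts,
            config.outcome,
        )
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_outputs(
    outdir: Path,
    report: dict,
    nm: NormalizedMatrix,
    logx: pd.DataFrame,
    deg_tables: dict[str, pd.DataFrame],
    truth: pd.DataFrame | None,
    config: RunConfig,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    nm.nrpm.to_csv(outdir / "nrpm.tsv", sep="\t")
    for name, table in deg_tables.items():
        table.to_csv(outdir / f"deg_{name}.tsv", sep="\t")
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    if config.make_figures and deg_tables:
        from . import plots

        plots.render_figures(outdir, report, logx, deg_tables)
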