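"""Sequencing QC gate and housekeeping-ratio nRPM normalization.

A panel run is admitted when it has >= 200k mapped reads, a strictly
greater than 50% on-target ratio, and at least 6 detected housekeeping
genes. Admitted samples are normalized in three steps:

1. background subtraction — the no-template-control (NTC) count of each
   gene is subtracted from the sample's absolute count, clamped at zero;
2. housekeeping ratios — each HK gene's *absolute* (pre-subtraction)
   count is divided by its baseline RPM from the reference cell-line
   profile, ``ratio = count / baseline_rpm``;
3. scaling — the sample's normalization ratio is the median of its HK
   ratios, and ``nRPM[g, s] = background_subtracted[g, s] / ratio(s)``.

The median over the ten HK ratios makes the scale factor robust to a
minority of unstable controls; a HK gene with zero counts contributes a
ratio of 0 (the QC gate's >=6-detected rule is the guard against too many
of those).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel_io import CountMatrix, PanelDefinition, SeqQCStats

logger = logging.getLogger(__name__)

MIN_MAPPED_READS = 200_000
MIN_ON_TARGET = 0.50  # strict: exactly 50% fails
MIN_HK_DETECTED = 6


@dataclass
class QCVerdict:
    """Pass/fail decision for one sample with the criteria it failed."""

    sample_id: str
    passed: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


@dataclass
class NormalizedMatrix:
    """nRPM values for QC-passing samples plus the per-sample calibration."""

    nrpm: pd.DataFrame          # gene x sample, non-negative reals
    norm_ratio: pd.Series       # sample -> median HK ratio (> 0)
    hk_ratios: pd.DataFrame     # HK gene x sample

    @property
    def sample_ids(self) -> list[str]:
        return list(self.nrpm.columns)


def qc_gate(stats: SeqQCStats, panel: PanelDefinition | None = None) -> QCVerdict:
    """Apply the three-criterion sequencing QC gate to one sample."""
    reasons = []
    if not stats.mapped_reads >= MIN_MAPPED_READS:
        reasons.append(
            f"mapped_reads {stats.mapped_reads} < {MIN_MAPPED_READS}"
        )
    if not stats.on_target_ratio > MIN_ON_TARGET:
        reasons.append(
            f"on_target_ratio {stats.on_target_ratio} <= {MIN_ON_TARGET}"
        )
    if not stats.n_hk_detected >= MIN_HK_DETECTED:
        reasons.append(
            f"n_hk_detected {stats.n_hk_detected} < {MIN_HK_DETECTED}"
        )
    return QCVerdict(
        sample_id=stats.sample_id, passed=not reasons, reasons=reasons
    )


def subtract_background(cm: CountMatrix) -> pd.DataFrame:
    """Per-gene NTC background subtraction, clamped at zero.

    The clamp keeps nRPM non-negative (required for the log transform);
    a background count exceeding the sample count carries no signal.
    """
    sub = cm.counts.sub(cm.ntc, axis=0)
    return sub.clip(lower=0)


def hk_ratio(
    cm: CountMatrix, panel: PanelDefinition, sample_id: str
) -> pd.Series:
    """Housekeeping ratios of one sample: absolute count / baseline RPM.

    Ratios deliberately use the raw (pre-subtraction) HK readout. A HK
    gene with zero counts yields ratio 0 and still enters the median.
    """
    baseline = pd.Series(panel.hk_baseline_rpm).loc[panel.hk_genes]
    counts = cm.counts.loc[panel.hk_genes, sample_id]
    zero = counts.index[counts == 0].tolist()
    if zero:
        logger.warning(
            "sample %s: housekeeping genes with zero counts (ratio 0): %s",
            sample_id, zero,
        )
    return counts / baseline


def _hk_ratio_frame(counts: pd.DataFrame, panel: PanelDefinition) -> pd.DataFrame:
    baseline = pd.Series(panel.hk_baseline_rpm).loc[panel.hk_genes]
    return counts.loc[panel.hk_genes].div(baseline, axis=0)


def normalize(
    cm: CountMatrix,
    panel: PanelDefinition,
    verdicts: list[QCVerdict] | None = None,
) -> NormalizedMatrix:
    """Background-subtract and scale to nRPM; QC-failing samples excluded.

    A passing sample whose median HK ratio is 0 cannot be scaled and is
    excluded with a warning.
    """
    if verdicts is not None:
        passing = [v.sample_id for v in verdicts if v.passed]
        excluded = [v.sample_id for v in verdicts if not v.passed]
        if excluded:
            logger.info("QC-excluded samples: %s", excluded)
        keep = [s for s in cm.sample_ids if s in set(passing)]
    else:
        keep = cm.sample_ids
    if not keep:
        raise ValueError("no QC-passing samples to normalize")

    counts = cm.counts[keep]
    hk = _hk_ratio_frame(counts, panel)
    ratio = hk.median(axis=0)
    bad = ratio.index[ratio <= 0].tolist()
    if bad:
        logger.warning(
            "samples with non-positive normalization ratio excluded: %s", bad
        )
        keep = [s for s in keep if s not in set(bad)]
        if not keep:
            raise ValueError("all samples have zero normalization ratio")
        counts, hk, ratio = counts[keep], hk[keep], ratio[keep]

    background_subtracted = subtract_background(
        CountMatrix(counts=counts, ntc=cm.ntc)
    )
    nrpm = background_subtracted.div(ratio, axis=1)
    return NormalizedMatrix(nrpm=nrpm, norm_ratio=ratio, hk_ratios=hk)


class NRPMNormalizer(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping absolute counts to nRPM values.

    Follows the scikit-learn sample-by-feature convention: `X` is a
    samples x genes DataFrame whose columns cover the panel. Each sample
    is calibrated only by its own housekeeping counts, so nothing is
    learned at fit time; ``fit`` validates and records the calibration of
    the fitted data for inspection.

    Parameters
    ----------
    panel
        Panel definition supplying the HK gene list and baseline RPMs.
    ntc
        Per-gene no-template-control counts (mapping or Series).
    """

    def __init__(self, panel: PanelDefinition, ntc: pd.Series | dict):
        self.panel = panel
        self.ntc = ntc

    def _to_count_matrix(self, X: pd.DataFrame) -> CountMatrix:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame")
        missing = [g for g in self.panel.genes if g not in X.columns]
        if missing:
            raise ValueError(f"X lacks panel genes: {missing[:10]}")
        counts = X[self.panel.genes].T
        ntc = pd.Series(self.ntc, dtype=float).reindex(self.panel.genes)
        return CountMatrix(counts=counts, ntc=ntc)

    def fit(self, X: pd.DataFrame, y=None) -> "NRPMNormalizer":
        cm = self._to_count_matrix(X)
        hk = _hk_ratio_frame(cm.counts, self.panel)
        self.hk_ratios_ = hk.T
        self.norm_ratio_ = hk.median(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cm = self._to_count_matrix(X)
        nm = normalize(cm, self.panel)
        return nm.nrpm.T

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.panel.genes, dtype=object)
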