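"""Immune gene-class signature scores and their clinical associations.

A signature score is the unweighted mean of log2 nRPM values over a gene
class (checkpoint pathway, lymphocyte infiltration, TCR coexpression,
type II interferon signaling) per sample — a deliberately simple summary
that is robust at panel scale and keeps units interpretable (log2 nRPM).
The association of each signature with the primary-cancer origin of a
brain metastasis is estimated by logistic regression of the binary origin
on the score, adjusted for age and gender, one model per signature, with
two-sided Wald p-values for the score coefficient.

With cohorts of ~25 samples, quasi-complete separation is a real risk;
the default is plain maximum likelihood with explicit non-convergence
flagging, and a Jeffreys-prior (Firth) penalized fit is available via
``method="firth"`` for users who want finite estimates under separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .panel_io import SampleMetadata, metadata_frame

#: gene classes reported for the lung-vs-breast metastasis signature panel
DEFAULT_SIGNATURES: dict[str, list[str]] = {
    "checkpoint pathway": ["CD274", "PDCD1LG2", "IDO1"],
    "lymphocyte infiltration": [
        "PTPN7", "IL10RA", "GZMK", "CD52", "CD2", "CCR5", "CCL5",
    ],
    "TCR coexpression": ["GPR18", "IL7R", "CD3G", "CD3D", "CD8B"],
    "type II interferon signaling": ["CXCL10", "CIITA", "IRF1", "PSMB9"],
}


@dataclass
class SignatureDefinition:
    """A named gene class whose mean log2 nRPM is the signature score."""

    name: str
    member_genes: list[str]

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError(f"signature {self.name!r} has no member genes")


def default_signatures() -> list[SignatureDefinition]:
    return [
        SignatureDefinition(name=k, member_genes=list(v))
        for k, v in DEFAULT_SIGNATURES.items()
    ]


def score_signatures(
    logx: pd.DataFrame, sigs: Sequence[SignatureDefinition]
) -> pd.DataFrame:
    """Signature x sample matrix of mean log2 nRPM over member genes.

    A signature none of whose members appear in the matrix is an error;
    members absent from the matrix are otherwise ignored with the score
    taken over the resolvable ones.
    """
    rows = {}
    for sig in sigs:
        present = [g for g in sig.member_genes if g in logx.index]
        if not present:
            raise ValueError(
                f"signature {sig.name!r}: no member genes found in matrix"
            )
        rows[sig.name] = logx.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


class SignatureScorer(TransformerMixin, BaseEstimator):
    """Transformer from samples x genes log2 expression to signature scores.

    ``transform`` returns a samples x signatures DataFrame; stateless
    beyond the signature definitions supplied at construction.
    """

    def __init__(self, signatures: Sequence[SignatureDefinition] | None = None):
        self.signatures = signatures

    def _sigs(self) -> list[SignatureDefinition]:
        return list(self.signatures) if self.signatures else default_signatures()

    def fit(self, X: pd.DataFrame, y=None) -> "SignatureScorer":
        for sig in self._sigs():
            if not any(g in X.columns for g in sig.member_genes):
                raise ValueError(
                    f"signature {sig.name!r}: no member genes found in matrix"
                )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return score_signatures(X.T, self._sigs()).T

    def get_feature_names_out(self, input_features=None):
        return np.asarray([s.name for s in self._sigs()], dtype=object)


# ---------------------------------------------------------------------------
# covariate-adjusted logistic association


@dataclass
class AssociationResult:
    """Logistic association of one signature score with a binary outcome."""

    signature: str
    n_genes: int
    n_samples: int
    coef: float
    se: float
    p_value: float
    converged: bool
    separation: str  # "", "positive" or "negative"

    @property
    def significant(self) -> bool:
        return self.converged and self.p_value < 0.05


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100):
    """Jeffreys-prior penalized logistic regression (Firth's correction).

    Newton iteration on the penalized score U*(b) = X'(y - p + h(1/2 - p))
    where h are hatvalues of the weighted design; gives finite estimates
    under complete separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    se = np.sqrt(np.diag(info_inv))
    return beta, se


def associate(
    scores: pd.DataFrame,
    meta: Sequence[SampleMetadata] | pd.DataFrame,
    outcome: pd.Series | dict,
    signature_sizes: dict[str, int] | None = None,
    method: str = "mle",
) -> list[AssociationResult]:
    """Per-signature logistic regression of outcome on score + age + gender.

    Parameters
    ----------
    scores
        signature x sample score matrix.
    meta
        Sample metadata (records or frame) supplying age and gender.
    outcome
        Binary (0/1) outcome per sample, e.g. 1 for lung-derived and 0
        for breast-derived metastases; samples missing from it are left
        out of the fit.
    method : {"mle", "firth"}
        Plain maximum likelihood (default; separation is flagged, not
        papered over) or Firth's penalized likelihood.
    """
    mdf = meta if isinstance(meta, pd.DataFrame) else metadata_frame(meta)
    mdf = mdf.set_index("sample_id")
    out = pd.Series(outcome).dropna()
    samples = [s for s in scores.columns if s in out.index]
    if len(samples) < 3:
        raise ValueError("need >= 3 samples with a defined outcome")
    y = out.loc[samples].astype(float).to_numpy()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    age = mdf.loc[samples, "age"].astype(float).to_numpy()
    gender = (mdf.loc[samples, "gender"] == "male").astype(float).to_numpy()

    results = []
    for sig in scores.index:
        s = scores.loc[sig, samples].to_numpy(dtype=float)
        X = sm.add_constant(
            np.column_stack([s, age, gender]), has_constant="add"
        )
        n_genes = (signature_sizes or {}).get(sig, 0)
        converged, separation, coef, se, p = False, "", np.nan, np.nan, np.nan
        if np.ptp(s) == 0:
            # constant score carries no information about the outcome
            results.append(
                AssociationResult(
                    signature=str(sig), n_genes=n_genes, n_samples=len(samples),
                    coef=0.0, se=np.inf, p_value=1.0, converged=True,
                    separation="",
                )
            )
            continue
        if method == "firth":
            beta, ses = _firth_logit(X, y)
            coef, se = float(beta[1]), float(ses[1])
            z = coef / se if se > 0 else np.nan
            p = float(2.0 * stats.norm.sf(abs(z)))
            converged = np.isfinite(p)
        else:
            try:
                # separation is detected and flagged below; silence the
                # library's own warning about it
                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                coef = float(fit.params[1])
                se = float(fit.bse[1])
                p = float(fit.pvalues[1])
                converged = bool(fit.mle_retvals.get("converged", False)) and (
                    np.isfinite(se) and se < 1e3
                )
            except Exception:
                converged = False
            if not converged:
                # report the direction of separation instead of a Wald p
                hi = s[y == 1].mean()
                lo = s[y == 0].mean()
                separation = "positive" if hi >= lo else "negative"
                p, se = np.nan, np.nan
        results.append(
            AssociationResult(
                signature=str(sig),
                n_genes=n_genes,
                n_samples=len(samples),
                coef=coef,
                se=se,
                p_value=p,
                converged=converged,
                separation=separation,
            )
        )
    return results


def association_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "signature": r.signature,
                "n_genes": r.n_genes,
                "n_samples": r.n_samples,
                "coef": r.coef,
                "se": r.se,
                "p": r.p_value,
                "converged": r.converged,
                "separation": r.separation,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# PCA sample embedding


class OrientedPCA(TransformerMixin, BaseEstimator):
    """PCA of centered (optionally standardized) log2 expression with a
    deterministic sign convention: each component is flipped so that its
    largest-magnitude gene loading is positive.

    ``X`` is samples x genes; features (genes) are mean-centered, as in
    ordinary PCA of expression profiles. Scaling genes to unit variance is
    off by default.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X: pd.DataFrame, y=None) -> "OrientedPCA":
        X = pd.DataFrame(X)
        if X.shape[0] < 3 or X.shape[1] < 2:
            raise ValueError("need >= 3 samples and >= 2 genes")
        arr = X.to_numpy(dtype=float)
        if np.allclose(arr, arr[0], atol=1e-12):
            raise ValueError("rank-deficient input: all sample profiles identical")
        if self.scale:
            sd = arr.std(axis=0, ddof=1)
            self._scale_sd = np.where(sd == 0, 1.0, sd)
            arr = arr / self._scale_sd  # centering handled inside PCA
        else:
            self._scale_sd = None
        self._pca = PCA(n_components=min(self.n_components, *arr.shape))
        self._pca.fit(arr)
        flips = np.ones(self._pca.components_.shape[0])
        for i, comp in enumerate(self._pca.components_):
            if comp[np.argmax(np.abs(comp))] < 0:
                flips[i] = -1.0
        self._flips = flips
        self.components_ = self._pca.components_ * flips[:, None]
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        arr = X.to_numpy(dtype=float)
        if self.scale:
            arr = arr / self._scale_sd
        coords = self._pca.transform(arr) * self._flips
        return pd.DataFrame(
            coords,
            index=X.index,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        )


def pca_embedding(
    logx: pd.DataFrame,
    genes: Sequence[str] | None = None,
    n_components: int = 2,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample embedding on the first principal components of a gene subset.

    ``logx`` is gene x sample; returns (sample x PC coordinates,
    variance-explained fractions).
    """
    sub = logx.loc[list(genes)] if genes is not None else logx
    est = OrientedPCA(n_components=n_components, scale=scale).fit(sub.T)
    return est.transform(sub.T), est.explained_variance_ratio_
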