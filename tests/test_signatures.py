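import numpy as np
import pandas as pd
import pytest

from iopanel.panel_io import SampleMetadata
from iopanel.signatures import (
    OrientedPCA,
    SignatureDefinition,
    SignatureScorer,
    associate,
    default_signatures,
    pca_embedding,
    score_signatures,
)


def _meta(n, rng, balance=0.5):
    return [
        SampleMetadata(
            sample_id=f"S{i}",
            patient_id=f"P{i}",
            primary_cancer="lung" if rng.random() < balance else "breast",
            tissue="BM",
            age=float(rng.integers(35, 80)),
            gender="male" if rng.random() < 0.5 else "female",
            prior_treatment=False,
        )
        for i in range(n)
    ]


class TestScoreSignatures:
    def test_single_gene_signature_is_identity(self, rng):
        logx = pd.DataFrame(
            rng.normal(5, 1, (4, 3)),
            index=["g1", "g2", "g3", "g4"],
            columns=["S1", "S2", "S3"],
        )
        sig = SignatureDefinition("solo", ["g2"])
        scores = score_signatures(logx, [sig])
        assert (scores.loc["solo"] == logx.loc["g2"]).all()

    def test_arithmetic_mean(self):
        logx = pd.DataFrame({"S1": [2.0, 4.0, 6.0]}, index=["a", "b", "c"])
        scores = score_signatures(logx, [SignatureDefinition("m", ["a", "b", "c"])])
        assert scores.loc["m", "S1"] == 4.0

    def test_matches_independent_per_sample_mean(self, rng):
        genes = [f"g{i}" for i in range(50)]
        logx = pd.DataFrame(
            rng.normal(6, 2, (50, 8)), index=genes,
            columns=[f"S{i}" for i in range(8)],
        )
        members = list(rng.choice(genes, 20, replace=False))
        scores = score_signatures(logx, [SignatureDefinition("r", members)])
        for s in logx.columns:
            expected = sum(logx.loc[g, s] for g in members) / 20
            assert np.isclose(scores.loc["r", s], expected, atol=1e-12)

    def test_affine_shift_equivariance(self, rng):
        logx = pd.DataFrame(
            rng.normal(6, 2, (10, 5)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"S{i}" for i in range(5)],
        )
        sig = SignatureDefinition("s", [f"g{i}" for i in range(4)])
        base = score_signatures(logx, [sig])
        shifted = logx.copy()
        shifted.loc[sig.member_genes] += 1.75
        assert np.allclose(
            score_signatures(shifted, [sig]) - base, 1.75, atol=1e-12
        )

    def test_unresolvable_signature_named_in_error(self):
        logx = pd.DataFrame({"S1": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="ghost"):
            score_signatures(logx, [SignatureDefinition("ghost", ["nope"])])

    def test_scorer_transformer_matches_function(self, rng):
        genes = [f"g{i}" for i in range(6)]
        logx = pd.DataFrame(
            rng.normal(5, 1, (6, 4)), index=genes,
            columns=[f"S{i}" for i in range(4)],
        )
        sigs = [SignatureDefinition("half", genes[:3])]
        out = SignatureScorer(sigs).fit(logx.T).transform(logx.T)
        pd.testing.assert_frame_equal(out.T, score_signatures(logx, sigs))


class TestAssociate:
    def _fit(self, scores_row, meta, outcome, **kw):
        scores = pd.DataFrame(
            [scores_row], index=["sig"], columns=[m.sample_id for m in meta]
        )
        return associate(scores, meta, outcome, **kw)[0]

    def test_informative_score_detected(self, rng):
        meta = _meta(120, rng)
        y = {m.sample_id: 1.0 if m.primary_cancer == "lung" else 0.0 for m in meta}
        score = np.array(
            [1.2 if y[m.sample_id] else 0.0 for m in meta]
        ) + rng.normal(0, 1.0, len(meta))
        r = self._fit(score, meta, y)
        assert r.converged
        assert r.coef > 0 and r.p_value < 0.05

    def test_constant_score_is_uninformative(self, rng):
        meta = _meta(60, rng)
        y = {m.sample_id: 1.0 if m.primary_cancer == "lung" else 0.0 for m in meta}
        r = self._fit(np.full(60, 3.3), meta, y)
        # no information in the score: coefficient ~ 0, p far from small
        assert r.converged
        assert r.p_value > 0.5

    def test_complete_separation_flagged_with_direction(self, rng):
        meta = _meta(40, rng)
        y = {m.sample_id: 1.0 if m.primary_cancer == "lung" else 0.0 for m in meta}
        score = np.array([5.0 if y[m.sample_id] else -5.0 for m in meta])
        r = self._fit(score, meta, y)
        assert not r.converged
        assert r.separation == "positive"
        assert np.isnan(r.p_value)

    def test_firth_gives_finite_fit_under_separation(self, rng):
        meta = _meta(40, rng)
        y = {m.sample_id: 1.0 if m.primary_cancer == "lung" else 0.0 for m in meta}
        score = np.array([5.0 if y[m.sample_id] else -5.0 for m in meta])
        r = self._fit(score, meta, y, method="firth")
        assert r.converged
        assert np.isfinite(r.coef) and np.isfinite(r.se)
        assert r.coef > 0

    def test_gender_relabel_leaves_score_inference_unchanged(self, rng):
        meta = _meta(100, rng)
        y = {m.sample_id: 1.0 if m.primary_cancer == "lung" else 0.0 for m in meta}
        score = rng.normal(0, 1, 100) + np.array(
            [0.8 if y[m.sample_id] else 0.0 for m in meta]
        )
        r1 = self._fit(score, meta, y)
        flipped = [
            SampleMetadata(
                m.sample_id, m.patient_id, m.primary_cancer, m.tissue, m.age,
                "female" if m.gender == "male" else "male", m.prior_treatment,
            )
            for m in meta
        ]
        r2 = self._fit(score, flipped, y)
        assert np.isclose(r1.coef, r2.coef, atol=1e-6)
        assert np.isclose(r1.p_value, r2.p_value, atol=1e-6)

    def test_age_rescaling_leaves_score_inference_unchanged(self, rng):
        meta = _meta(100, rng)
        y = {m.sample_id: 1.0 if m.primary_cancer == "lung" else 0.0 for m in meta}
        score = rng.normal(0, 1, 100) + np.array(
            [0.8 if y[m.sample_id] else 0.0 for m in meta]
        )
        r1 = self._fit(score, meta, y)
        rescaled = [
            SampleMetadata(
                m.sample_id, m.patient_id, m.primary_cancer, m.tissue,
                m.age / 10.0, m.gender, m.prior_treatment,
            )
            for m in meta
        ]
        r2 = self._fit(score, rescaled, y)
        assert np.isclose(r1.coef, r2.coef, atol=1e-5)
        assert np.isclose(r1.p_value, r2.p_value, atol=1e-5)

    def test_default_signatures_have_the_four_classes(self):
        names = {s.name for s in default_signatures()}
        assert names == {
            "checkpoint pathway", "lymphocyte infiltration",
            "TCR coexpression", "type II interferon signaling",
        }


class TestPCA:
    def test_matches_spectral_oracle(self, rng):
        logx = pd.DataFrame(
            rng.normal(5, 2, (32, 25)),
            index=[f"g{i}" for i in range(32)],
            columns=[f"S{i}" for i in range(25)],
        )
        coords, frac = pca_embedding(logx, n_components=2)
        # oracle: eigendecomposition of the sample covariance of centered data
        X = logx.T.to_numpy()
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for k in range(2):
            proj = Xc @ v[:, k]
            got = coords.iloc[:, k].to_numpy()
            agree = min(
                np.max(np.abs(got - proj)), np.max(np.abs(got + proj))
            )
            assert agree < 1e-8
            assert np.isclose(frac[k], w[k] / w.sum(), atol=1e-10)

    def test_two_cluster_separation_on_pc1(self, rng):
        a = rng.normal(0, 0.3, (10, 16))
        b = rng.normal(4, 0.3, (10, 16))
        logx = pd.DataFrame(
            np.vstack([a, b]).T, index=[f"g{i}" for i in range(16)],
            columns=[f"S{i}" for i in range(20)],
        )
        coords, frac = pca_embedding(logx)
        assert frac[0] > 0.5
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:10].max() < pc1[10:].min()) or (pc1[10:].max() < pc1[:10].min())

    def test_duplicated_sample_gets_identical_coordinates(self, rng):
        logx = pd.DataFrame(
            rng.normal(0, 1, (8, 6)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"S{i}" for i in range(6)],
        )
        logx["S_dup"] = logx["S0"]
        coords, _ = pca_embedding(logx)
        assert np.allclose(coords.loc["S0"], coords.loc["S_dup"], atol=1e-10)

    def test_gene_reordering_invariance_up_to_sign(self, rng):
        logx = pd.DataFrame(
            rng.normal(0, 1, (12, 9)),
            index=[f"g{i}" for i in range(12)],
            columns=[f"S{i}" for i in range(9)],
        )
        c1, _ = pca_embedding(logx)
        shuffled = logx.sample(frac=1, random_state=1)
        c2, _ = pca_embedding(shuffled)
        for k in ("PC1", "PC2"):
            d = min(
                np.max(np.abs(c1[k] - c2[k])), np.max(np.abs(c1[k] + c2[k]))
            )
            assert d < 1e-8

    def test_sign_convention_largest_loading_positive(self, rng):
        logx = pd.DataFrame(
            rng.normal(0, 1, (10, 8)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"S{i}" for i in range(8)],
        )
        est = OrientedPCA(n_components=2).fit(logx.T)
        for comp in est.components_:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_degenerate_input_rejected(self):
        logx = pd.DataFrame(
            np.ones((5, 4)), index=[f"g{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(4)],
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            pca_embedding(logx)
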