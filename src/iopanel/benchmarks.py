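"""Self-validation benchmarks: each routine recomputes a pipeline result
from scratch and measures it against an independent reference computation
or a generator truth record.

These are the package's always-runnable correctness surface: exact oracle
equivalence for the deterministic primitives (normalization arithmetic,
Venn partitions, signature means), calibration and recovery simulations
for the statistical machinery (moderated-t null behavior, planted-DEG
recovery, logistic coefficient recovery). The embedded reference
implementations are deliberately written in a different style (explicit
loops, statistics.median) so agreement is evidence of correctness rather
than shared code.

Every routine takes a seed and returns a flat dict of metrics.
"""

from __future__ import annotations

from statistics import median

import numpy as np
import pandas as pd

from .differential import Contrast, ModeratedTTest, deg_table, log_transform, overlap
from .normalization import normalize, qc_gate
from .panel_io import CountMatrix, PanelDefinition, SampleMetadata, SeqQCStats, paired_patients
from .signatures import SignatureDefinition, associate, score_signatures
from .simulate import PlantedEffect, SimulationConfig, simulate_counts, simulate_panel


def _random_panel(rng, n_genes: int = 395, n_hk: int = 10) -> PanelDefinition:
    targets = [f"T{i:03d}" for i in range(n_genes - n_hk)]
    hk = [f"HK{i:02d}" for i in range(n_hk)]
    category = {g: "other immune function" for g in targets}
    category.update({g: "housekeeping" for g in hk})
    return PanelDefinition(
        genes=targets + hk,
        category=category,
        hk_genes=hk,
        hk_baseline_rpm={g: float(rng.uniform(100, 2000)) for g in hk},
    )


def normalization_oracle_check(
    seed: int, n_matrices: int = 20, n_genes: int = 395, n_samples: int = 10
) -> dict:
    """Compare nRPM against a line-by-line recomputation of the three
    normalization formulas (background subtraction, HK ratios, median
    scaling) on random count matrices; expected elementwise exact."""
    rng = np.random.default_rng([seed, 101])
    max_diff = 0.0
    n_cells = 0
    for _ in range(n_matrices):
        panel = _random_panel(rng, n_genes)
        counts = pd.DataFrame(
            rng.poisson(rng.uniform(50, 2000), size=(n_genes, n_samples)),
            index=panel.genes,
            columns=[f"S{j}" for j in range(n_samples)],
        )
        ntc = pd.Series(rng.poisson(5.0, n_genes), index=panel.genes)
        nm = normalize(CountMatrix(counts=counts, ntc=ntc), panel)
        for s in counts.columns:
            ratios = [
                counts.loc[hk, s] / panel.hk_baseline_rpm[hk]
                for hk in panel.hk_genes
            ]
            norm_ratio = median(ratios)
            for g in panel.genes:
                bg = counts.loc[g, s] - ntc[g]
                if bg < 0:
                    bg = 0
                expected = bg / norm_ratio
                diff = abs(nm.nrpm.loc[g, s] - expected)
                if diff > max_diff:
                    max_diff = diff
                n_cells += 1
    return {"max_abs_diff": float(max_diff), "n_cells": n_cells}


def depth_equivariance_check(
    seed: int, factors: tuple = (0.5, 2.0, 10.0), n_genes: int = 395
) -> dict:
    """Scaling all counts of a sample by c (NTC fixed at 0) must leave its
    nRPM vector unchanged; reports the worst relative deviation."""
    rng = np.random.default_rng([seed, 102])
    panel = _random_panel(rng, n_genes)
    base = rng.poisson(400.0, n_genes) * 2  # even, so c=0.5 stays integral
    zero_ntc = pd.Series(0, index=panel.genes)
    ref = normalize(
        CountMatrix(
            counts=pd.DataFrame({"S1": base}, index=panel.genes), ntc=zero_ntc
        ),
        panel,
    ).nrpm["S1"]
    worst = 0.0
    for c in factors:
        scaled = normalize(
            CountMatrix(
                counts=pd.DataFrame({"S1": base * c}, index=panel.genes),
                ntc=zero_ntc,
            ),
            panel,
        ).nrpm["S1"]
        nonzero = ref != 0
        rel = np.abs(scaled[nonzero] - ref[nonzero]) / ref[nonzero]
        worst = max(worst, float(rel.max()))
        assert (scaled[~nonzero] == 0).all()
    return {"max_rel_diff": worst, "n_factors": len(factors)}


def qc_truth_table_check() -> dict:
    """All 8 pass/fail combinations of the three QC criteria, exercised at
    their boundary values (200k mapped passes, 50.0% on-target fails,
    6 detected HK genes pass)."""
    depth = {True: 200_000, False: 199_999}
    target = {True: 0.51, False: 0.50}
    hk = {True: 6, False: 5}
    n_correct = 0
    for d_ok in (True, False):
        for t_ok in (True, False):
            for h_ok in (True, False):
                v = qc_gate(
                    SeqQCStats("s", depth[d_ok], target[t_ok], hk[h_ok])
                )
                expected_pass = d_ok and t_ok and h_ok
                expected_n_reasons = (not d_ok) + (not t_ok) + (not h_ok)
                if (
                    v.passed == expected_pass
                    and len(v.reasons) == expected_n_reasons
                ):
                    n_correct += 1
    return {"n_correct": n_correct, "n_total": 8}


def moderated_t_limits_check(seed: int) -> dict:
    """The two analytic limits of the variance shrinkage: prior df 0
    reproduces the ordinary t-statistic; infinite prior df pools every
    gene's variance to the common prior."""
    from scipy import stats

    rng = np.random.default_rng([seed, 103])
    sd = rng.lognormal(-0.5, 0.6, 150)
    data = rng.normal(0, 1, (150, 10)) * sd[:, None]
    X = pd.DataFrame(data.T)
    y = np.array(["a"] * 5 + ["b"] * 5)
    fit0 = ModeratedTTest(design="unpaired", prior_df=0).fit(X, y)
    ref_t, _ = stats.ttest_ind(data[:, :5], data[:, 5:], axis=1, equal_var=True)
    d0_diff = float(np.max(np.abs(fit0.t_ - ref_t)))
    fit_inf = ModeratedTTest(design="unpaired", prior_df=np.inf).fit(X, y)
    pool_diff = float(np.max(np.abs(fit_inf.s2_post_ - fit_inf.s2_prior_)))
    return {"d0_zero_max_t_diff": d0_diff, "d0_inf_max_pool_diff": pool_diff}


def null_type1_check(
    seed: int, n_reps: int = 50, n_genes: int = 200, n_per_group: int = 5
) -> dict:
    """Empirical type-I error of the moderated t at p<.05 on null data
    (per-gene variances drawn from a log-normal, no effects)."""
    n_sig = 0
    n_tot = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 104, rep])
        sd = rng.lognormal(-0.5, 0.6, n_genes)
        X = pd.DataFrame(
            (rng.normal(0, 1, (n_genes, 2 * n_per_group)) * sd[:, None]).T
        )
        y = np.array(["a"] * n_per_group + ["b"] * n_per_group)
        fit = ModeratedTTest(design="unpaired").fit(X, y)
        n_sig += int((fit.p_value_ < 0.05).sum())
        n_tot += n_genes
    return {"type1_error": n_sig / n_tot, "n_tests": n_tot}


def planted_recovery_check(
    seed: int, n_planted: int = 20, n_pairs: int = 10
) -> dict:
    """Sensitivity and false-positive rate of the DEG-calling rule on a
    paired cohort with planted |log2 effect| = 2 genes and within-pair
    noise around 0.5 on the log2 scale."""
    cfg = SimulationConfig(
        seed=seed,
        cohort={"lung": (n_pairs, n_pairs)},
        residual_sd=0.3,   # within-pair difference sd ~ 0.5 incl count noise
        dispersion=0.02,
        patient_sd=0.5,
    )
    panel = simulate_panel(cfg)
    planted = [g for g in panel.target_genes if g.startswith("G")][:n_planted]
    half = n_planted // 2
    cfg.planted = [
        PlantedEffect(genes=planted[:half], log2_effect=2.0, tissue="BM"),
        PlantedEffect(genes=planted[half:], log2_effect=-2.0, tissue="BM"),
    ]
    cm, meta, _, truth = simulate_counts(cfg, panel)
    nm = normalize(cm, panel)
    logx = log_transform(nm.nrpm)
    pairs = paired_patients(meta)
    contrast = Contrast(
        "bm_vs_adjacent", "paired",
        [v[0] for v in pairs.values()],
        [v[1] for v in pairs.values()],
        pairing=pairs,
    )
    table = deg_table(logx, contrast)
    called = set(table.index[table["is_deg"]])
    truth_genes = set(truth["gene"])
    nulls = set(panel.genes) - truth_genes
    return {
        "sensitivity": len(called & truth_genes) / len(truth_genes),
        "fpr": len(called & nulls) / len(nulls),
        "n_planted": len(truth_genes),
        "n_null": len(nulls),
    }


def venn_oracle_check(seed: int, n_triples: int = 100) -> dict:
    """Venn partition versus brute-force membership enumeration."""
    rng = np.random.default_rng([seed, 105])
    genes = [f"G{i}" for i in range(150)]
    n_exact = 0
    for _ in range(n_triples):
        sets = {
            lab: set(rng.choice(genes, size=int(rng.integers(20, 70)), replace=False))
            for lab in ("s1", "s2", "s3")
        }
        ov = overlap(sets)
        # brute force: classify every union member by its membership key
        expected: dict[tuple, list] = {}
        for g in sorted(set().union(*sets.values())):
            key = tuple(g in sets[lab] for lab in ov.labels)
            expected.setdefault(key, []).append(g)
        got = {k: v for k, v in ov.regions.items() if v}
        conserved = sum(len(v) for v in ov.regions.values()) == len(
            set().union(*sets.values())
        )
        if got == expected and conserved:
            n_exact += 1
    return {"n_exact": n_exact, "n_triples": n_triples}


def signature_score_check(seed: int, n_genes: int = 80, n_samples: int = 12) -> dict:
    """Signature scores versus independent per-sample means, and the
    affine-shift equivariance of the score."""
    rng = np.random.default_rng([seed, 106])
    genes = [f"g{i}" for i in range(n_genes)]
    logx = pd.DataFrame(
        rng.normal(6, 2, (n_genes, n_samples)),
        index=genes,
        columns=[f"S{i}" for i in range(n_samples)],
    )
    members = sorted(rng.choice(genes, 20, replace=False))
    sig = SignatureDefinition("probe", members)
    scores = score_signatures(logx, [sig])
    max_diff = 0.0
    for s in logx.columns:
        expected = sum(logx.loc[g, s] for g in members) / len(members)
        max_diff = max(max_diff, abs(float(scores.loc["probe", s]) - expected))
    shift = 1.75
    shifted = logx.copy()
    shifted.loc[members] += shift
    dev = (score_signatures(shifted, [sig]) - scores - shift).abs().to_numpy().max()
    return {"max_abs_diff": float(max_diff), "max_affine_dev": float(dev)}


def logistic_recovery_check(
    seed: int, n_reps: int = 200, n: int = 500, true_coef: float = 1.0
) -> dict:
    """Coefficient recovery and 95% Wald CI coverage of the covariate-
    adjusted logistic association on synthetic cohorts where the score has
    a known log-odds effect and age/gender have none."""
    coefs = []
    covered = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 107, rep])
        score = rng.normal(0, 1, n)
        age = rng.uniform(30, 80, n)
        male = rng.random(n) < 0.5
        eta = -0.2 + true_coef * score
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        meta = [
            SampleMetadata(
                f"S{i}", f"P{i}", "lung", "BM", float(age[i]),
                "male" if male[i] else "female", False,
            )
            for i in range(n)
        ]
        scores = pd.DataFrame(
            [score], index=["sig"], columns=[m.sample_id for m in meta]
        )
        r = associate(
            scores, meta, {m.sample_id: y[i] for i, m in enumerate(meta)}
        )[0]
        coefs.append(r.coef)
        if r.converged and (
            r.coef - 1.96 * r.se <= true_coef <= r.coef + 1.96 * r.se
        ):
            covered += 1
    return {
        "mean_coef": float(np.mean(coefs)),
        "coverage": covered / n_reps,
        "n_reps": n_reps,
    }
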