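"""Independent reference implementations used only to check iopanel.

Deliberately written in a different style from the package (explicit
Python loops, scipy.optimize root finding) so that agreement is evidence
of correctness, not shared code.
"""

from statistics import median

import numpy as np
from scipy import optimize, special, stats


def nrpm_oracle(counts, ntc, hk_genes, hk_baseline, sample_ids, genes):
    """Line-by-line recomputation of the three normalization formulas.

    counts: dict (gene, sample) -> count; ntc: dict gene -> count.
    Returns dict (gene, sample) -> nRPM.
    """
    out = {}
    for s in sample_ids:
        ratios = []
        for hk in hk_genes:
            ratios.append(counts[(hk, s)] / hk_baseline[hk])
        norm_ratio = median(ratios)
        for g in genes:
            bg_sub = counts[(g, s)] - ntc[g]
            if bg_sub < 0:
                bg_sub = 0
            out[(g, s)] = bg_sub / norm_ratio
    return out


def moderated_t_oracle(xa, xb, paired=False):
    """Independent moderated-t: per-gene stats via loops, hyperparameters
    via brentq inversion of the trigamma moment equation.

    xa, xb: genes x samples arrays (columns aligned pairs when paired).
    Returns (t, p, d0, s02) arrays/scalars.
    """
    n_genes = xa.shape[0]
    coefs, s2s = [], []
    if paired:
        for g in range(n_genes):
            d = xa[g] - xb[g]
            coefs.append(float(np.mean(d)))
            s2s.append(float(np.var(d, ddof=1)))
        df = xa.shape[1] - 1
        v = 1.0 / xa.shape[1]
    else:
        na, nb = xa.shape[1], xb.shape[1]
        for g in range(n_genes):
            ma, mb = float(np.mean(xa[g])), float(np.mean(xb[g]))
            sa = float(np.var(xa[g], ddof=1))
            sb = float(np.var(xb[g], ddof=1))
            coefs.append(ma - mb)
            s2s.append(((na - 1) * sa + (nb - 1) * sb) / (na + nb - 2))
        df = na + nb - 2
        v = 1.0 / na + 1.0 / nb

    coefs = np.array(coefs)
    s2s = np.array(s2s)
    z = np.log(s2s)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if evar > 0:
        half_d0 = optimize.brentq(
            lambda y: special.polygamma(1, y) - evar, 1e-8, 1e8
        )
        d0 = 2 * half_d0
        s02 = np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0))
        s2_post = (d0 * s02 + df * s2s) / (d0 + df)
        df_total = df + d0
    else:
        d0 = np.inf
        s02 = np.exp(np.mean(e))
        s2_post = np.full_like(s2s, s02)
        df_total = 1e6 + df
    t = coefs / (np.sqrt(s2_post) * np.sqrt(v))
    p = 2 * stats.t.sf(np.abs(t), df_total)
    return t, p, d0, s02


def pooled_t_oracle(a, b):
    """Textbook pooled two-sample t computed with explicit arithmetic."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / (sp2 * (1 / na + 1 / nb)) ** 0.5
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def venn_regions_oracle(sets):
    """Brute-force membership enumeration over the union."""
    labels = list(sets)
    union = set()
    for v in sets.values():
        union |= set(v)
    regions = {}
    for g in sorted(union):
        key = tuple(g in sets[lab] for lab in labels)
        regions.setdefault(key, []).append(g)
    return labels, regions
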