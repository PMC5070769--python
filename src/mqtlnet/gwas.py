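"""Mixed-linear-model association mapping for metabolite traits.

Trait preprocessing (completeness filter + log transform), VanRaden
kinship, structure principal components, and a per-SNP scan under

    y = mu + Q*gamma + SNP*beta + u + e,   u ~ N(0, sg2*K),  e ~ N(0, se2*I)

with the variance ratio estimated once per trait under the null by REML
through a spectral decomposition of K and then held fixed for every SNP
(the P3D approximation), followed by a per-SNP Wald test on beta.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import GenotypeMatrix

__all__ = [
    "preprocess_traits",
    "compute_kinship",
    "compute_structure_pcs",
    "mlm_scan",
    "qq_points",
    "genomic_inflation",
]


def preprocess_traits(traits: pd.DataFrame, min_complete: float = 0.40):
    """Drop low-completeness traits and log-transform the survivors.

    A trait is kept when its fraction of non-missing accessions is at
    least ``min_complete`` (boundary inclusive); surviving intensities are
    natural-log transformed.  Returns ``(transformed traits, report)``
    where the report lists per-trait completeness and kept/dropped status.

    Raises ``ValueError`` naming the trait and accession on any
    non-positive observed intensity.
    """
    if not 0.0 <= min_complete <= 1.0:
        raise ValueError("min_complete must lie in [0, 1]")
    bad = (traits <= 0)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        acc = bad[col].idxmax()
        raise ValueError(
            f"non-positive intensity for trait {col!r} at accession {acc!r}"
        )
    completeness = traits.notna().mean(axis=0)
    keep = completeness >= min_complete
    report = pd.DataFrame({
        "trait": traits.columns,
        "completeness": completeness.values,
        "kept": keep.values,
    })
    return np.log(traits.loc[:, keep]), report


def compute_kinship(genotypes: GenotypeMatrix) -> np.ndarray:
    """VanRaden kinship from centered dosages.

    K = Z Z' / sum_j 2 p_j (1 - p_j) with Z the frequency-centered dosage
    matrix; monomorphic SNPs carry no information and are excluded.  A
    small diagonal shrinkage is applied if numerical noise makes the
    matrix indefinite.
    """
    X = genotypes.dosages.astype(float)
    p = X.mean(axis=0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; kinship undefined")
    Xp = X[:, poly]
    pp = p[poly]
    Z = Xp - pp
    denom = float(np.sum(2.0 * pp * (1.0 - pp)))
    K = (Z @ Z.T) / denom
    wmin = float(np.linalg.eigvalsh(K).min())
    if wmin < 0:
        K = K + (abs(wmin) + 1e-10) * np.eye(K.shape[0])
    return K


def compute_structure_pcs(genotypes: GenotypeMatrix, n_pcs: int = 3) -> np.ndarray:
    """First ``n_pcs`` principal-component scores of the centered dosages.

    Deterministic up to sign; the sign is fixed so the score of largest
    magnitude on each axis is positive.
    """
    X = genotypes.dosages.astype(float)
    n = X.shape[0]
    if n_pcs >= n:
        raise ValueError("n_pcs must be smaller than the number of accessions")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > (s[0] if s.size else 0.0) * 1e-10))
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank {rank}")
    scores = U[:, :n_pcs] * s[:n_pcs]
    for k in range(n_pcs):
        j = int(np.argmax(np.abs(scores[:, k])))
        if scores[j, k] < 0:
            scores[:, k] = -scores[:, k]
    return scores


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, ys: np.ndarray,
                     Cs: np.ndarray) -> float:
    """Negative restricted log-likelihood profile in delta = sg2/se2."""
    d = np.exp(log_delta) * lam + 1.0
    W = 1.0 / d
    A = Cs.T @ (W[:, None] * Cs)
    b = Cs.T @ (W * ys)
    try:
        alpha = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    r = ys - Cs @ alpha
    rss = float(np.sum(W * r * r))
    nc = len(ys) - Cs.shape[1]
    if rss <= 0 or nc <= 0:
        return np.inf
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (nc * np.log(2.0 * np.pi * rss / nc) + nc
                 + float(np.sum(np.log(d))) + logdetA)
    return -ll


def _estimate_delta(lam: np.ndarray, ys: np.ndarray, Cs: np.ndarray) -> float:
    """REML point estimate of delta by log-grid search plus refinement."""
    grid = np.linspace(np.log(1e-5), np.log(1e5), 61)
    vals = np.array([_reml_neg_loglik(g, lam, ys, Cs) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(lam, ys, Cs),
        method="bounded", options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def mlm_scan(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    K: np.ndarray,
    Q: np.ndarray | None = None,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Per-SNP mixed-model Wald scan with the P3D approximation.

    ``trait`` is indexed by accession id; accessions with missing trait
    values are dropped pairwise.  SNPs with MAF <= ``maf_min`` on the
    analysis subset are excluded.  SNPs collinear with the fixed effects
    are flagged and their p-value is recorded as missing.

    Returns a DataFrame (trait, snp, chrom, pos, maf, beta, se, p, lod,
    flag) sorted by (chrom, pos).
    """
    order = {a: i for i, a in enumerate(genotypes.accessions)}
    missing_acc = [a for a in trait.index if a not in order]
    if missing_acc:
        raise ValueError(f"trait accessions absent from genotypes: {missing_acc[:5]}")
    trait = trait.dropna()
    idx = np.array([order[a] for a in trait.index])
    if idx.size < 3:
        raise ValueError("fewer than 3 accessions with observed trait values")
    y = trait.to_numpy(dtype=float)
    X = genotypes.dosages[idx].astype(float)
    Ksub = K[np.ix_(idx, idx)]
    C = np.ones((idx.size, 1))
    if Q is not None:
        C = np.hstack([C, np.asarray(Q, dtype=float)[idx]])

    freq = X.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf > maf_min
    n = idx.size

    lam, U = np.linalg.eigh(Ksub)
    lam = np.clip(lam, 0.0, None)
    ys = U.T @ y
    Cs = U.T @ C
    # Degenerate K (identity-like spectrum): any delta gives the same fit.
    if np.allclose(lam, lam[0]):
        delta = 0.0
    else:
        delta = _estimate_delta(lam, ys, Cs)

    w = 1.0 / (delta * lam + 1.0)
    sw = np.sqrt(w)
    z = sw * ys
    Xc = sw[:, None] * Cs
    Qm, _ = np.linalg.qr(Xc)
    z_r = z - Qm @ (Qm.T @ z)
    rss0 = float(z_r @ z_r)

    Gs = sw[:, None] * (U.T @ X[:, keep])
    G_r = Gs - Qm @ (Qm.T @ Gs)
    denom = np.einsum("ij,ij->j", G_r, G_r)
    df = n - C.shape[1] - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")
    ok = denom > 1e-10
    beta = np.full(denom.shape, np.nan)
    se = np.full(denom.shape, np.nan)
    pval = np.full(denom.shape, np.nan)
    beta[ok] = (G_r[:, ok].T @ z_r) / denom[ok]
    sigma2 = np.clip(rss0 - beta[ok] ** 2 * denom[ok], 0.0, None) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se[ok] = np.sqrt(sigma2 / denom[ok])
        tstat = beta[ok] / se[ok]
    pok = 2.0 * stats.t.sf(np.abs(tstat), df)
    pval[ok] = np.clip(pok, np.finfo(float).tiny, 1.0)

    kept_idx = np.flatnonzero(keep)
    out = pd.DataFrame({
        "trait": trait.name if trait.name is not None else "trait",
        "snp": [genotypes.snp_ids[j] for j in kept_idx],
        "chrom": genotypes.chrom[kept_idx],
        "pos": genotypes.pos[kept_idx],
        "maf": maf[kept_idx],
        "beta": beta,
        "se": se,
        "p": pval,
        "lod": -np.log10(pval),
        "flag": np.where(ok, "", "collinear"),
    })
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def qq_points(pvalues) -> pd.DataFrame:
    """Observed vs expected -log10 p with a 95% beta order-statistic band.

    Returns a DataFrame (expected, observed, band_lo, band_hi) with points
    ordered from most to least significant.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values supplied")
    n = p.size
    p_sorted = np.sort(p)
    i = np.arange(1, n + 1)
    expected = -np.log10((i - 0.5) / n)
    observed = -np.log10(p_sorted)
    band_lo = -np.log10(stats.beta.ppf(0.975, i, n - i + 1))
    band_hi = -np.log10(stats.beta.ppf(0.025, i, n - i + 1))
    return pd.DataFrame({
        "expected": expected,
        "observed": observed,
        "band_lo": band_lo,
        "band_hi": band_hi,
    })


def genomic_inflation(pvalues) -> float:
    """Genomic-control lambda: median association chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values supplied")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
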