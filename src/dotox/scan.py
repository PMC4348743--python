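"""Kinship-adjusted founder-haplotype genome scan.

At each marker the log phenotype is regressed on the eight founder-dosage
columns (plus covariates) after whitening by the null mixed model
``y ~ N(Xb, sigma_g2 * K + sigma_e2 * I)``; variance components are estimated
once under the null and held fixed across markers, which is standard for this
model class and makes the per-marker statistic a generalized least-squares
likelihood ratio:

    LOD = (n / 2) * log10(RSS_0 / RSS_1).

Founder coefficients are reported as deviations from their mean because the
eight dosage columns sum to 2 and the intercept absorbs the overall level.
Genome-wide significance comes from permuting phenotype rows (the kinship
structure is deliberately ignored under permutation — simple phenotype
shuffling, as in standard practice for these scans), and the QTL support
interval from the Bayesian credible-interval method: 10**LOD normalized over
the peak chromosome and accumulated outward from the peak.

Association mapping within an interval imputes SNP allele dosages from the
haplotype reconstruction (dosage = sum_f haplotype_dosage_f * allele_f) and
runs the same whitened regression with 1 df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    FOUNDER_IDS,
    N_FOUNDERS,
    HaplotypeDosage,
    VarianceComponents,
)
from .quantgen import fit_variance_components

logger = logging.getLogger(__name__)


def kinship_from_dosages(dosages: HaplotypeDosage) -> np.ndarray:
    """Genome-wide kinship: K[i, j] = (1/m) sum_markers (d_i / 2) . (d_j / 2).

    Scaled so two identical fully homozygous genomes give 1 and mice with
    disjoint founder content give 0.  As a Gram matrix of dosage profiles it
    is symmetric positive semidefinite by construction (no shrinkage needed).
    """
    n, m, _ = dosages.dosages.shape
    if n < 2:
        raise ValueError("need at least two mice for a kinship matrix")
    p = (dosages.dosages / 2.0).reshape(n, -1)
    K = (p @ p.T) / m
    return 0.5 * (K + K.T)


@dataclass
class Whitener:
    """Decorrelation transform from the null mixed model: multiplies by
    ``diag(1/sqrt(sigma_g2 * S + sigma_e2)) @ U.T`` where K = U diag(S) U.T."""

    U: np.ndarray
    weights: np.ndarray  # 1 / sqrt(sigma_g2 * S + sigma_e2)

    def apply(self, M: np.ndarray) -> np.ndarray:
        M = np.asarray(M, float)
        if M.ndim == 1:
            return self.weights * (self.U.T @ M)
        return self.weights[:, None] * (self.U.T @ M)


def fit_null(
    y: np.ndarray,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    reml: bool = True,
) -> tuple[VarianceComponents, Whitener]:
    """Null mixed-model fit plus the whitening transform used by the scan."""
    y = np.asarray(y, float)
    n = len(y)
    X = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        X = np.column_stack([X, cov])
    vc = fit_variance_components(y, K, X=X, reml=reml)
    # component scale matches the unit-mean-diagonal kinship normalization
    # used by the variance-component fit
    Kn = np.asarray(K, float)
    Kn = Kn / np.mean(np.diag(Kn))
    S, U = np.linalg.eigh(Kn)
    S = np.clip(S, 0.0, None)
    if np.isnan(vc.h2):
        # unidentifiable (K ~ I): whitening reduces to identity scaling
        weights = np.ones(n) / np.sqrt(max(vc.sigma_e2, 1e-300))
    else:
        weights = 1.0 / np.sqrt(vc.sigma_g2 * S + vc.sigma_e2)
    return vc, Whitener(U=U, weights=weights)


@dataclass
class ScanResult:
    """Per-marker LOD and founder effects, with peak and support interval."""

    table: pd.DataFrame  # marker, chr, pos_Mb, lod, coef_A..coef_H
    peak: dict
    n_used: int
    variance_explained: float  # 1 - RSS1/RSS0 at the peak on the whitened scale
    variance_explained_raw: float = 0.0  # same ratio from the plain regression
    threshold: float | None = None
    alpha: float | None = None
    support_interval: tuple | None = None
    varcomp: VarianceComponents | None = None

    @property
    def max_lod(self) -> float:
        return float(self.peak["lod"])


def _design(y, covariates):
    y = np.asarray(y, float)
    n = len(y)
    X0 = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        X0 = np.column_stack([X0, cov])
    return y, X0


def _rss(yw: np.ndarray, Xw: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    return float(r @ r)


def _whiten_all(y, X0, dosage_arr, K, covariates, varcomp):
    """Returns whitened (yw, X0w, Dw) and the fitted null components."""
    n = len(y)
    if K is None:
        return y, X0, dosage_arr, None
    if varcomp is None:
        vc, wh = fit_null(y, K, covariates=covariates)
    else:
        vc = varcomp
        Kn = np.asarray(K, float)
        Kn = Kn / np.mean(np.diag(Kn))
        S, U = np.linalg.eigh(Kn)
        S = np.clip(S, 0.0, None)
        wh = Whitener(U=U, weights=1.0 / np.sqrt(vc.sigma_g2 * S + vc.sigma_e2))
    yw = wh.weights * (wh.U.T @ y)
    X0w = wh.weights[:, None] * (wh.U.T @ X0)
    m = dosage_arr.shape[1]
    Dw = wh.weights[:, None, None] * np.einsum(
        "ij,jmf->imf", wh.U.T, dosage_arr
    )
    return yw, X0w, Dw, vc


def linkage_scan(
    y: np.ndarray,
    dosages: HaplotypeDosage,
    K: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    varcomp: VarianceComponents | None = None,
    interval_prob: float = 0.95,
) -> ScanResult:
    """Haplotype-dosage linkage scan of a log-scale phenotype.

    With ``K=None`` the scan is ordinary least squares; otherwise the
    phenotype and designs are whitened by the null mixed model first.
    """
    y, X0 = _design(y, covariates)
    n = len(y)
    if dosages.dosages.shape[0] != n:
        raise ValueError("dosages and phenotype cover different numbers of mice")
    yw, X0w, Dw, vc = _whiten_all(y, X0, dosages.dosages, K, covariates, varcomp)

    rss0 = _rss(yw, X0w)
    mmap = dosages.marker_map
    m = len(mmap)
    lods = np.zeros(m)
    coefs = np.zeros((m, N_FOUNDERS))
    flat = rss0 <= 1e-12 * max(1.0, float(yw @ yw))
    if flat:
        warnings.warn("phenotype is constant under the null model; all LOD = 0")
    for j in range(m):
        if flat:
            break
        X1 = np.column_stack([X0w, Dw[:, j, :]])
        beta, *_ = np.linalg.lstsq(X1, yw, rcond=None)
        r = yw - X1 @ beta
        rss1 = float(r @ r)
        lods[j] = max(0.0, 0.5 * n * np.log10(rss0 / max(rss1, 1e-300)))
        fc = beta[X0w.shape[1]:]
        coefs[j] = fc - fc.mean()

    table = mmap[["marker", "chr", "pos_Mb"]].copy().reset_index(drop=True)
    table["lod"] = lods
    for k, f in enumerate(FOUNDER_IDS):
        table[f"coef_{f}"] = coefs[:, k]

    # tie-break max LOD by lowest (chromosome, position)
    order = np.lexsort((table["pos_Mb"], table["chr"], -table["lod"]))
    peak_row = table.iloc[order[0]]
    peak = {
        "marker": peak_row["marker"],
        "chr": peak_row["chr"],
        "pos_Mb": float(peak_row["pos_Mb"]),
        "lod": float(peak_row["lod"]),
    }
    j_peak = int(order[0])
    if flat:
        ve = ve_raw = 0.0
    else:
        X1 = np.column_stack([X0w, Dw[:, j_peak, :]])
        ve = 1.0 - _rss(yw, X1) / rss0
        # phenotypic-variance fraction from the unadjusted regression at the
        # peak (the ratio usually quoted for a mapped locus)
        X1r = np.column_stack([X0, dosages.dosages[:, j_peak, :]])
        ve_raw = 1.0 - _rss(y, X1r) / max(_rss(y, X0), 1e-300)

    result = ScanResult(
        table=table,
        peak=peak,
        n_used=n,
        variance_explained=float(ve),
        variance_explained_raw=float(ve_raw),
        varcomp=vc,
    )
    try:
        result.support_interval = credible_interval(
            result, peak["chr"], prob=interval_prob
        )
    except ValueError:
        result.support_interval = None
    return result


def permutation_threshold(
    y: np.ndarray,
    dosages: HaplotypeDosage,
    K: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    varcomp: VarianceComponents | None = None,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    Phenotype rows are shuffled jointly against genotypes, covariates and
    kinship; the threshold is the empirical (1 - alpha) quantile of the
    genome-wide maximum LOD.  Fully vectorized: per marker, an orthonormal
    basis of the whitened design projects all permuted phenotypes at once.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable quantile")
    y, X0 = _design(y, covariates)
    n = len(y)
    yw, X0w, Dw, vc = _whiten_all(y, X0, dosages.dosages, K, covariates, varcomp)

    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm), dtype=float)
    for p in range(n_perm):
        perms[:, p] = y[rng.permutation(n)]
    if K is not None:
        # whiten permuted phenotypes with the same (fixed) transform
        Kn = np.asarray(K, float)
        Kn = Kn / np.mean(np.diag(Kn))
        S, U = np.linalg.eigh(Kn)
        S = np.clip(S, 0.0, None)
        weights = 1.0 / np.sqrt(vc.sigma_g2 * S + vc.sigma_e2)
        Yw = weights[:, None] * (U.T @ perms)
    else:
        Yw = perms

    Q0, _ = np.linalg.qr(X0w)
    tot = np.sum(Yw**2, axis=0)
    rss0 = tot - np.sum((Q0.T @ Yw) ** 2, axis=0)
    m = Dw.shape[1]
    max_lod = np.zeros(n_perm)
    for j in range(m):
        Q, _ = np.linalg.qr(np.column_stack([X0w, Dw[:, j, :]]))
        rss1 = tot - np.sum((Q.T @ Yw) ** 2, axis=0)
        lod = 0.5 * n * np.log10(np.maximum(rss0, 1e-300) / np.maximum(rss1, 1e-300))
        np.maximum(max_lod, lod, out=max_lod)
    return float(np.quantile(max_lod, 1.0 - alpha))


def credible_interval(
    scan: ScanResult | pd.DataFrame, chromosome, prob: float = 0.95
) -> tuple[float, float]:
    """Bayesian credible interval for the QTL peak on one chromosome.

    10**LOD is normalized over the chromosome's markers and mass accumulated
    outward from the peak, always taking the heavier neighbor first, until at
    least ``prob`` is covered.  Endpoints are marker positions (Mb).
    """
    table = scan.table if isinstance(scan, ScanResult) else scan
    sub = table[table["chr"] == chromosome]
    if sub.empty:
        raise ValueError(f"chromosome {chromosome} not in scan")
    pos = sub["pos_Mb"].to_numpy(float)
    lod = sub["lod"].to_numpy(float)
    if np.ptp(lod) < 1e-12:
        warnings.warn(
            f"flat LOD profile on chr {chromosome}: interval spans the chromosome"
        )
        return float(pos[0]), float(pos[-1])
    w = 10.0 ** (lod - lod.max())
    w = w / w.sum()
    k = int(np.argmax(lod))
    lo = hi = k
    mass = w[k]
    while mass < prob and (lo > 0 or hi < len(w) - 1):
        left = w[lo - 1] if lo > 0 else -1.0
        right = w[hi + 1] if hi < len(w) - 1 else -1.0
        if left >= right:
            lo -= 1
            mass += w[lo]
        else:
            hi += 1
            mass += w[hi]
    return float(pos[lo]), float(pos[hi])


def impute_snp_dosages(
    dosages: HaplotypeDosage,
    founder_alleles: np.ndarray,
    marker_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Impute SNP allele dosages from haplotype dosages within an interval.

    ``founder_alleles`` is (n_snps, 8) of 0/1 founder alleles at the interval
    markers (rows aligned with ``marker_indices`` into the dosage marker map,
    default all markers).  Returns (snp_dosages (n_mice, n_kept), kept_idx);
    monomorphic SNPs (all founders share the allele) and SNPs with missing
    founder alleles are skipped with a log message.
    """
    if marker_indices is None:
        marker_indices = np.arange(founder_alleles.shape[0])
    marker_indices = np.asarray(marker_indices, dtype=int)
    if founder_alleles.shape != (len(marker_indices), N_FOUNDERS):
        raise ValueError("founder_alleles must be (n_snps, 8) aligned with indices")
    D = dosages.dosages[:, marker_indices, :]  # (n, s, 8)
    al = np.asarray(founder_alleles, dtype=float)
    valid = ~np.isnan(al).any(axis=1)
    poly = valid & (np.nanmax(al, axis=1) != np.nanmin(al, axis=1))
    skipped = int((~poly).sum())
    if skipped:
        logger.info("skipping %d monomorphic or incomplete SNPs", skipped)
    snp = np.einsum("nsf,sf->ns", D[:, poly, :], al[poly])
    return np.clip(snp, 0.0, 2.0), marker_indices[poly]


def snp_association_scan(
    y: np.ndarray,
    snp_dosages: np.ndarray,
    positions: np.ndarray | None = None,
    K: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    varcomp: VarianceComponents | None = None,
) -> pd.DataFrame:
    """Additive 1-df regression of y on each imputed SNP dosage; LOD per SNP."""
    y, X0 = _design(y, covariates)
    n = len(y)
    snp = np.asarray(snp_dosages, float)
    if snp.ndim != 2 or snp.shape[0] != n:
        raise ValueError("snp_dosages must be (n_mice, n_snps)")
    poly = snp.std(axis=0) > 1e-12
    if not poly.any():
        warnings.warn("all SNPs monomorphic in the sample; empty association result")
        return pd.DataFrame(columns=["snp", "pos_Mb", "lod"])
    D3 = snp[:, :, None]
    yw, X0w, Dw, _ = _whiten_all(y, X0, D3, K, covariates, varcomp)
    rss0 = _rss(yw, X0w)
    lods = np.zeros(snp.shape[1])
    for j in np.flatnonzero(poly):
        X1 = np.column_stack([X0w, Dw[:, j, :]])
        lods[j] = max(
            0.0, 0.5 * n * np.log10(rss0 / max(_rss(yw, X1), 1e-300))
        )
    out = pd.DataFrame({"snp": np.arange(snp.shape[1]), "lod": lods})
    out["polymorphic"] = poly
    if positions is not None:
        out["pos_Mb"] = np.asarray(positions, float)
    return out[out["polymorphic"]].drop(columns="polymorphic").reset_index(drop=True)
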