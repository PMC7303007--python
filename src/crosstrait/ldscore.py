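"""LD scores and LD score regression (heritability and genetic correlation).

Under a polygenic model the expected association chi-square of variant j
grows linearly in its LD score l_j = sum_k r2(j, k) over variants k within a
physical window:

    E[chi2_j]      = 1 + N * h2 * l_j / M            (one trait)
    E[z1_j * z2_j] = c + sqrt(N1*N2) * rho_g * l_j / M   (two traits)

so the slope of a weighted regression of chi2 (or z1*z2) on l estimates the
SNP heritability h2 (or the genetic covariance rho_g), while the free
intercept absorbs confounding and, in the bivariate case, the sample-overlap
term c = rho_pheno * Ns / sqrt(N1*N2).  The genetic correlation is
r_g = rho_g / sqrt(h2_1 * h2_2).  Standard errors come from a contiguous
block jackknife over the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_JACKKNIFE_BLOCKS = 200


# ---------------------------------------------------------------------------
# LD scores
# ---------------------------------------------------------------------------

def compute_ld_scores(
    genotypes,
    positions,
    snp_ids=None,
    window_bp: int = DEFAULT_WINDOW_BP,
    maf=None,
    min_maf: float = 0.01,
    min_samples: int = 25,
) -> pd.Series:
    """Per-variant LD scores from a reference genotype/dosage matrix.

    Parameters
    ----------
    genotypes
        (n_variants, n_samples) array of allele dosages for one chromosome
        (or any region in which positions are comparable).
    positions
        Base-pair positions, ascending.
    snp_ids
        Index of the returned series (defaults to the row number).
    window_bp
        Half-width of the physical window; pairs farther apart contribute 0.
    maf
        Optional per-variant allele frequencies used for the ``min_maf``
        filter.  When omitted and the matrix looks like 0..2 dosages, the
        frequency is estimated as ``mean/2``.
    min_maf
        Minor-allele-frequency floor applied to the reference; r2 estimates
        are unstable for rarer variants.

    Cross-variant terms use the small-sample-adjusted estimator
    ``r2_adj = r2 - (1 - r2)/(n - 2)``; the self term is counted as exactly 1.
    Monomorphic (zero-variance) variants are excluded with a warning.
    """
    G = np.asarray(genotypes, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if G.ndim != 2 or G.shape[0] != positions.shape[0]:
        raise ValueError("genotypes must be (n_variants, n_samples) matching positions")
    m, n = G.shape
    if n < min_samples:
        raise ValueError(f"need >= {min_samples} reference samples, got {n}")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted ascending")
    if snp_ids is None:
        snp_ids = np.arange(m)
    snp_ids = np.asarray(snp_ids)

    sd = G.std(axis=1)
    keep = sd > 0
    if not keep.all():
        log.warning("excluding %d monomorphic variants", int((~keep).sum()))
    if maf is None and G.min() >= 0 and G.max() <= 2:
        maf = np.minimum(G.mean(axis=1) / 2, 1 - G.mean(axis=1) / 2)
    if maf is not None:
        maf = np.asarray(maf, dtype=float)
        keep &= maf >= min_maf
    G, positions, snp_ids = G[keep], positions[keep], snp_ids[keep]
    m = G.shape[0]
    if m == 0:
        raise ValueError("no polymorphic variants left in the reference")

    X = G - G.mean(axis=1, keepdims=True)
    X /= np.linalg.norm(X, axis=1, keepdims=True)  # rows unit norm: X@X.T = r

    l = np.ones(m)
    for d in range(1, m):
        sep = positions[d:] - positions[:-d]
        if sep.min() > window_bp:
            break
        r2 = np.einsum("ij,ij->i", X[:-d], X[d:]) ** 2
        adj = r2 - (1.0 - r2) / (n - 2)
        adj[sep > window_bp] = 0.0
        l[: m - d] += adj
        l[d:] += adj
    return pd.Series(l, index=snp_ids, name="l")


def read_reference_vcf(path, min_samples: int = 25):
    """Load a VCF reference panel into per-chromosome dosage arrays.

    Returns a dict ``chrom -> (dosages, positions, snp_ids)`` suitable for
    :func:`compute_ld_scores`.  Requires :mod:`cyvcf2`.
    """
    from cyvcf2 import VCF  # optional dependency

    by_chrom: dict[str, list] = {}
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        dosage = np.array(var.gt_types, dtype=float)  # 0,1,3->2 coding
        dosage[dosage == 2] = np.nan  # UNKNOWN
        dosage[dosage == 3] = 2.0
        if np.isnan(dosage).any():
            mean = np.nanmean(dosage)
            dosage = np.where(np.isnan(dosage), mean, dosage)
        by_chrom.setdefault(var.CHROM, []).append(
            (var.POS, var.ID or f"{var.CHROM}:{var.POS}", dosage)
        )
    out = {}
    for chrom, rows in by_chrom.items():
        rows.sort(key=lambda r: r[0])
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        ids = np.array([r[1] for r in rows])
        G = np.vstack([r[2] for r in rows])
        if G.shape[1] < min_samples:
            raise ValueError(f"VCF has {G.shape[1]} samples; need >= {min_samples}")
        out[chrom] = (G, pos, ids)
    return out


def read_ld_scores(path) -> pd.Series:
    """Read precomputed LD scores from a two-column TSV (snp_id, l)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("LD score file must have two columns: snp_id, l")
    return pd.Series(df.iloc[:, 1].to_numpy(float),
                     index=df.iloc[:, 0].astype(str), name="l")


def write_ld_scores(ld: pd.Series, path) -> None:
    ld.rename_axis("snp_id").rename("l").reset_index().to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# weighted regression with block jackknife
# ---------------------------------------------------------------------------

def _n_blocks_for(n_snps: int, n_blocks: int) -> int:
    if n_snps < 200:
        n_blocks = max(n_snps // 10, 2)
    if n_snps < n_blocks:
        raise ValueError(f"{n_snps} SNPs is fewer than {n_blocks} jackknife blocks")
    return n_blocks


def _wls_jackknife(x, y, w, n_blocks):
    """Weighted least squares of y on x with delete-one-block estimates.

    Returns (slope, intercept, slope_del, intercept_del) where the ``_del``
    arrays hold the estimate with each contiguous block removed.  Uses
    per-block sufficient statistics so the jackknife costs O(blocks).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    edges = np.linspace(0, len(x), n_blocks + 1).astype(int)
    starts = edges[:-1]

    sw = np.add.reduceat(w, starts)
    swx = np.add.reduceat(w * x, starts)
    swy = np.add.reduceat(w * y, starts)
    swxx = np.add.reduceat(w * x * x, starts)
    swxy = np.add.reduceat(w * x * y, starts)

    def solve(a_w, a_x, a_y, a_xx, a_xy):
        denom = a_w * a_xx - a_x**2
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (a_w * a_xy - a_x * a_y) / denom
            intercept = (a_y - slope * a_x) / a_w
        return slope, intercept

    slope, intercept = solve(sw.sum(), swx.sum(), swy.sum(), swxx.sum(), swxy.sum())
    slope_del, intercept_del = solve(
        sw.sum() - sw, swx.sum() - swx, swy.sum() - swy,
        swxx.sum() - swxx, swxy.sum() - swxy,
    )
    return slope, intercept, slope_del, intercept_del


def jackknife_se(theta_del) -> float:
    """Delete-one block-jackknife standard error."""
    theta_del = np.asarray(theta_del, float)
    g = len(theta_del)
    return float(np.sqrt((g - 1) / g * np.sum((theta_del - theta_del.mean()) ** 2)))


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityFit:
    """Univariate LD score regression result."""

    h2: float
    se_h2: float
    intercept: float
    se_intercept: float
    m: int
    mean_chi2: float
    n_snps: int
    n_blocks: int
    h2_del: np.ndarray  # delete-one-block slopes (for downstream jackknives)

    def to_report(self) -> str:
        return "\n".join(
            f"{k}={v:.6g}"
            for k, v in [
                ("h2", self.h2), ("se_h2", self.se_h2),
                ("intercept", self.intercept), ("se_intercept", self.se_intercept),
                ("M", self.m), ("mean_chi2", self.mean_chi2),
                ("n_snps", self.n_snps), ("n_blocks", self.n_blocks),
            ]
        )


@dataclass
class GeneticCorrelationFit:
    """Bivariate LD score regression result."""

    gcov: float
    se_gcov: float
    rg: float
    se_rg: float
    p_rg: float
    cross_intercept: float
    se_cross_intercept: float
    fit1: HeritabilityFit
    fit2: HeritabilityFit
    defined: bool = True

    def to_report(self) -> str:
        return "\n".join(
            f"{k}={v:.6g}"
            for k, v in [
                ("gcov", self.gcov), ("se_gcov", self.se_gcov),
                ("rg", self.rg), ("se_rg", self.se_rg), ("p_rg", self.p_rg),
                ("cross_intercept", self.cross_intercept),
                ("se_cross_intercept", self.se_cross_intercept),
                ("h2_1", self.fit1.h2), ("h2_2", self.fit2.h2),
            ]
        )


def _regression_weights(l):
    # 1/max(l,1): downweights high-LD variants whose chi2 has higher variance
    return 1.0 / np.maximum(np.asarray(l, float), 1.0)


def fit_h2(z, n, ld, m_total: int | None = None,
           n_blocks: int = DEFAULT_JACKKNIFE_BLOCKS) -> HeritabilityFit:
    """Estimate SNP heritability by regressing chi2 on N*l/M.

    ``z``, ``n`` and ``ld`` are aligned per-SNP arrays in genomic order
    (contiguity matters for the block jackknife).  ``m_total`` defaults to
    the number of SNPs supplied.
    """
    z = np.asarray(z, float)
    n = np.asarray(n, float)
    l = np.asarray(ld, float)
    if not (len(z) == len(n) == len(l)):
        raise ValueError("z, n and ld must be aligned")
    n_snps = len(z)
    if n_snps < 200:
        raise ValueError("need >= 200 SNPs with LD scores for a stable fit")
    m = m_total or n_snps
    g = _n_blocks_for(n_snps, n_blocks)

    x = n * l / m
    y = z**2
    w = _regression_weights(l)
    slope, intercept, slope_del, intercept_del = _wls_jackknife(x, y, w, g)
    return HeritabilityFit(
        h2=float(slope), se_h2=jackknife_se(slope_del),
        intercept=float(intercept), se_intercept=jackknife_se(intercept_del),
        m=m, mean_chi2=float(y.mean()), n_snps=n_snps, n_blocks=g,
        h2_del=slope_del,
    )


def fit_rg(
    pairs: pd.DataFrame,
    ld,
    m_total: int | None = None,
    n_overlap: int | None = None,
    n_blocks: int = DEFAULT_JACKKNIFE_BLOCKS,
) -> GeneticCorrelationFit:
    """Bivariate LD score regression on a harmonized pair table.

    ``pairs`` must carry columns ``z1, z2, n1, n2`` (and ``snp_id`` when
    ``ld`` is a Series to align on).  Fits both univariate regressions plus
    the cross-product regression of z1*z2 on sqrt(N1*N2)*l/M with a free
    intercept absorbing the sample-overlap term (``n_overlap`` is accepted
    for bookkeeping only).  r_g and its jackknife SE are formed from
    delete-one-block estimates of all three slopes on a shared block grid.

    If either heritability estimate is non-positive, r_g is undefined and
    the result is returned with ``defined=False`` and NaN r_g.
    """
    if isinstance(ld, pd.Series):
        l = ld.reindex(pairs["snp_id"].astype(ld.index.dtype)).to_numpy(float)
        if np.isnan(l).any():
            raise ValueError("LD scores missing for some variants in pairs")
    else:
        l = np.asarray(ld, float)
    z1 = pairs["z1"].to_numpy(float)
    z2 = pairs["z2"].to_numpy(float)
    n1 = pairs["n1"].to_numpy(float)
    n2 = pairs["n2"].to_numpy(float)
    n_snps = len(z1)
    m = m_total or n_snps
    g = _n_blocks_for(n_snps, n_blocks)

    fit1 = fit_h2(z1, n1, l, m_total=m, n_blocks=g)
    fit2 = fit_h2(z2, n2, l, m_total=m, n_blocks=g)

    x = np.sqrt(n1 * n2) * l / m
    y = z1 * z2
    w = _regression_weights(l)
    gcov, icpt, gcov_del, icpt_del = _wls_jackknife(x, y, w, g)
    se_gcov = jackknife_se(gcov_del)
    se_icpt = jackknife_se(icpt_del)

    if fit1.h2 <= 0 or fit2.h2 <= 0:
        log.warning("non-positive heritability estimate; r_g undefined")
        return GeneticCorrelationFit(
            gcov=float(gcov), se_gcov=se_gcov, rg=float("nan"),
            se_rg=float("nan"), p_rg=float("nan"),
            cross_intercept=float(icpt), se_cross_intercept=se_icpt,
            fit1=fit1, fit2=fit2, defined=False,
        )

    rg = float(gcov / np.sqrt(fit1.h2 * fit2.h2))
    prod_del = fit1.h2_del * fit2.h2_del
    ok = prod_del > 0
    if not ok.all():
        log.warning("dropping %d jackknife blocks with non-positive h2 product",
                    int((~ok).sum()))
    rg_del = gcov_del[ok] / np.sqrt(prod_del[ok])
    se_rg = jackknife_se(rg_del)
    p_rg = float(2 * stats.norm.sf(abs(rg) / se_rg)) if se_rg > 0 else 0.0
    return GeneticCorrelationFit(
        gcov=float(gcov), se_gcov=se_gcov, rg=rg, se_rg=se_rg,
        p_rg=min(max(p_rg, np.nextafter(0, 1)), 1.0),
        cross_intercept=float(icpt), se_cross_intercept=se_icpt,
        fit1=fit1, fit2=fit2,
    )
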