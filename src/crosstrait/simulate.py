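"""Synthetic two-trait GWAS summary statistics with known truth.

The generator works directly on the Z-score scale — the sufficiency level
every analysis in this package consumes — under an infinitesimal model on
standardized genotypes.  The genome is a set of independent LD blocks with
AR(1) correlation ``R_ij = ar_rho^|i-j|`` inside each block, for which the
LD score has the closed form ``l_j = 1 + sum_{k!=j} ar_rho^(2|j-k|)``,
enabling analytic cross-checks.

Per block with correlation matrix R and true per-SNP effects b_t of trait t
(drawn bivariate normal with variances h2_t/M and covariance
rg*sqrt(h2_1*h2_2)/M):

    Z_t = sqrt(N_t) R b_t + eps_t,
    Var(eps_t) = R,   Cov(eps_1, eps_2) = c R,

where ``c = pheno_corr * n_overlap / sqrt(N1*N2)`` is the overlapping-sample
noise correlation.  This reproduces exactly the regression relations the LD
score fits exploit (E[chi2] = 1 + N h2 l / M; E[z1 z2] = c + sqrt(N1 N2)
rho_g l / M) and the null Z-Z correlation the bivariate tests must absorb.

A small Gaussian-dosage genotype simulator with the same block correlation
feeds the empirical LD score computation in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import STANDARD_COLUMNS, SumStatsTable

# effect allele is the alphabetically earlier base; palindromic pairs are
# avoided so harmonization keeps every simulated variant
_ALLELE_PAIRS = np.array([("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a two-trait summary-statistics simulation.

    Defaults describe a desk-scale polygenic psychiatric-trait pair:
    M = 20,000 SNPs in 200 independent AR(1) blocks of 100, SNP
    heritabilities of 0.3, genetic correlation 0.5 and two studies of
    20,000 samples with no overlap.

    ``ar_rho`` is either one AR(1) parameter shared by all blocks, or a
    ``(lo, hi)`` pair giving evenly spaced per-block values.  Real genomes
    have strongly heterogeneous LD, and that heterogeneity is what
    identifies the LD-score-regression slope, so the default spreads block
    LD over (0.1, 0.9).
    """

    n_blocks: int = 200
    block_size: int = 100
    ar_rho: float | tuple = (0.1, 0.9)
    h2_1: float = 0.3
    h2_2: float = 0.3
    rg: float = 0.5
    n1: int = 20_000
    n2: int = 20_000
    n_overlap: int = 0
    pheno_corr: float = 0.0
    maf_range: tuple = (0.05, 0.5)
    seed: int = 0

    @property
    def m(self) -> int:
        return self.n_blocks * self.block_size

    def __post_init__(self):
        rhos = self.block_rhos
        if np.any(rhos < 0) or np.any(rhos >= 1):
            raise ValueError("ar_rho must lie in [0, 1)")
        if not (0 <= self.h2_1 < 1 and 0 <= self.h2_2 < 1):
            raise ValueError("heritabilities must be in [0, 1)")
        if not -1 <= self.rg <= 1:
            raise ValueError("rg must be in [-1, 1]")
        if self.n_overlap > min(self.n1, self.n2):
            raise ValueError("n_overlap cannot exceed min(N1, N2)")
        if not -1 <= self.pheno_corr <= 1:
            raise ValueError("pheno_corr must be in [-1, 1]")

    @property
    def block_rhos(self) -> np.ndarray:
        """Per-block AR(1) parameter."""
        if isinstance(self.ar_rho, (tuple, list)):
            lo, hi = self.ar_rho
            return np.linspace(lo, hi, self.n_blocks)
        return np.full(self.n_blocks, float(self.ar_rho))

    @property
    def overlap_corr(self) -> float:
        """Null Z-Z correlation induced by overlapping samples."""
        return self.pheno_corr * self.n_overlap / np.sqrt(self.n1 * self.n2)


@dataclass
class SimTruth:
    """Ground truth underlying one simulated summary-statistics pair."""

    beta1: np.ndarray
    beta2: np.ndarray
    realized_rg: float
    ld_scores: np.ndarray
    overlap_corr: float
    config: SimConfig


# ---------------------------------------------------------------------------
# LD structure
# ---------------------------------------------------------------------------

_WITHIN_BLOCK_SPACING_BP = 1_000
_BLOCK_SPACING_BP = 3_000_000  # keeps distinct blocks outside the +-1 Mb window


def ar1_correlation(block_size: int, ar_rho: float) -> np.ndarray:
    """AR(1) correlation matrix R_ij = ar_rho^|i-j| (positive definite)."""
    idx = np.arange(block_size)
    return ar_rho ** np.abs(idx[:, None] - idx[None, :])


def build_ld_blocks(cfg: SimConfig):
    """Block correlation matrices and base-pair positions.

    Blocks are spaced so that variants of different blocks never share a
    +-1 Mb window while a block always fits inside one.  Returns
    ``(blocks, positions)`` with one AR(1) matrix per block.
    """
    blocks = [ar1_correlation(cfg.block_size, rho) for rho in cfg.block_rhos]
    within = np.arange(cfg.block_size) * _WITHIN_BLOCK_SPACING_BP
    offsets = np.arange(cfg.n_blocks) * _BLOCK_SPACING_BP
    positions = (offsets[:, None] + within[None, :] + 1).ravel()
    return blocks, positions


def analytic_ld_scores(cfg: SimConfig) -> np.ndarray:
    """Closed-form LD scores l_j = 1 + sum_{k != j} rho_b^(2|j-k|)."""
    idx = np.arange(cfg.block_size)
    dist = np.abs(idx[:, None] - idx[None, :])  # (B, B)
    rho2 = cfg.block_rhos[:, None, None] ** 2
    l = (rho2**dist).sum(axis=2)  # includes the self term exactly once
    return l.ravel()


_CHOL_CACHE: dict[tuple, tuple] = {}


def _block_matrices(cfg: SimConfig):
    """Stacked (n_blocks, B, B) correlation and Cholesky factors, cached."""
    key = (cfg.block_size, tuple(np.round(cfg.block_rhos, 12)))
    if key not in _CHOL_CACHE:
        idx = np.arange(cfg.block_size)
        dist = np.abs(idx[:, None] - idx[None, :])
        Rs = cfg.block_rhos[:, None, None] ** dist
        Ls = np.linalg.cholesky(Rs)
        if len(_CHOL_CACHE) > 8:  # bounded cache
            _CHOL_CACHE.clear()
        _CHOL_CACHE[key] = (Rs, Ls)
    return _CHOL_CACHE[key]


# ---------------------------------------------------------------------------
# effects and summary statistics
# ---------------------------------------------------------------------------

def draw_effects(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Draw per-SNP true effect pairs under the infinitesimal model.

    (beta1, beta2) are bivariate normal with variances h2_t/M and
    correlation rg (on the standardized-genotype scale); rg = +-1 yields an
    exact linear relation between the two effect vectors.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    x = rng.standard_normal(cfg.m)
    y = rng.standard_normal(cfg.m)
    beta1 = np.sqrt(cfg.h2_1 / cfg.m) * x
    shared = cfg.rg * x + np.sqrt(max(1.0 - cfg.rg**2, 0.0)) * y
    beta2 = np.sqrt(cfg.h2_2 / cfg.m) * shared
    if beta1.std() > 0 and beta2.std() > 0:
        realized = float(np.corrcoef(beta1, beta2)[0, 1])
    else:
        realized = float("nan")
    return SimTruth(
        beta1=beta1, beta2=beta2, realized_rg=realized,
        ld_scores=analytic_ld_scores(cfg), overlap_corr=cfg.overlap_corr,
        config=cfg,
    )


def simulate_sumstats(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SumStatsTable, SumStatsTable, SimTruth]:
    """Generate a harmonizable two-trait summary-statistics pair.

    Deterministic given ``cfg.seed`` (or an explicit generator).  Both
    tables carry the same variants, positions and allele assignments, so the
    pair round-trips through harmonization unchanged.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    truth = draw_effects(cfg, rng)
    Rs, Ls = _block_matrices(cfg)
    c = cfg.overlap_corr

    b1 = truth.beta1.reshape(cfg.n_blocks, cfg.block_size)
    b2 = truth.beta2.reshape(cfg.n_blocks, cfg.block_size)
    mean1 = np.sqrt(cfg.n1) * np.einsum("bij,bj->bi", Rs, b1)
    mean2 = np.sqrt(cfg.n2) * np.einsum("bij,bj->bi", Rs, b2)
    x1 = rng.standard_normal((cfg.n_blocks, cfg.block_size))
    x2 = rng.standard_normal((cfg.n_blocks, cfg.block_size))
    eps1 = np.einsum("bij,bj->bi", Ls, x1)
    eps2 = np.einsum("bij,bj->bi", Ls, c * x1 + np.sqrt(1.0 - c**2) * x2)
    z1 = (mean1 + eps1).ravel()
    z2 = (mean2 + eps2).ravel()

    _, positions = build_ld_blocks(cfg)
    alleles = _ALLELE_PAIRS[rng.integers(0, len(_ALLELE_PAIRS), cfg.m)]
    maf = rng.uniform(*cfg.maf_range, cfg.m)
    eaf = np.where(rng.random(cfg.m) < 0.5, maf, 1.0 - maf)

    def table(z, n, trait):
        df = pd.DataFrame(
            {
                "snp_id": [f"snp{i:06d}" for i in range(cfg.m)],
                "chrom": "1",
                "pos": positions,
                "a1": alleles[:, 0],
                "a2": alleles[:, 1],
                "eaf": eaf,
                "z": z,
                "n": float(n),
                "p": 2.0 * stats.norm.sf(np.abs(z)),
            }
        )
        return SumStatsTable(df[list(STANDARD_COLUMNS)], trait=trait,
                             m_total=cfg.m)

    return table(z1, cfg.n1, "trait1"), table(z2, cfg.n2, "trait2"), truth


def simulate_null_pair(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SumStatsTable, SumStatsTable]:
    """Two traits with no shared genetics and no shared samples.

    Per-trait polygenicity (h2 > 0) may remain; only the cross-trait
    structure is forced null (rg = 0, no overlap) — the negative-control
    condition for the false-positive audit.
    """
    null_cfg = replace(cfg, rg=0.0, n_overlap=0, pheno_corr=0.0)
    t1, t2, _ = simulate_sumstats(null_cfg, rng)
    return t1, t2


def simulate_genotypes(
    cfg: SimConfig, n_samples: int, rng: np.random.Generator | None = None
):
    """Standardized Gaussian dosages with the configured block LD.

    Returns ``(genotypes, positions, snp_ids)`` with genotypes of shape
    (M, n_samples); Gaussian dosages carry the target Pearson correlation
    exactly, which is what LD-score computation consumes.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    _, Ls = _block_matrices(cfg)
    X = np.einsum(
        "bij,bsj->bsi", Ls,
        rng.standard_normal((cfg.n_blocks, n_samples, cfg.block_size)),
    )
    G = X.transpose(0, 2, 1).reshape(cfg.m, n_samples)
    _, positions = build_ld_blocks(cfg)
    snp_ids = np.array([f"snp{i:06d}" for i in range(cfg.m)])
    return G, positions, snp_ids


def block_r2_lookup(cfg: SimConfig):
    """True pairwise r2 under the AR(1) block model, keyed by snp_id.

    Returns a callable ``(snp_a, snp_b) -> r2``: ``rho_b^(2|i-j|)`` within
    block b, 0 across blocks.
    """
    rhos = cfg.block_rhos

    def r2(a: str, b: str) -> float:
        ia, ib = int(a[3:]), int(b[3:])
        block = ia // cfg.block_size
        if block != ib // cfg.block_size:
            return 0.0
        return float(rhos[block] ** (2 * abs(ia - ib)))

    return r2


def write_truth_sidecar(truth: SimTruth, path) -> None:
    """JSON sidecar with the simulation's true parameters."""
    payload = {
        "config": asdict(truth.config),
        "realized_rg": truth.realized_rg,
        "overlap_corr": truth.overlap_corr,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
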