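"""Bivariate association tests for dependent Z statistics.

Two studies' Z-scores for the same variant are correlated under the null
whenever the studies share samples (or phenotypes are correlated within the
overlap).  With that null correlation ``s`` estimated genome-wide, two
combined statistics are available per variant:

* O'Brien (OB): the optimal equally-weighted linear combination,
  ``t = (1' S^-1 z) / sqrt(1' S^-1 1)`` with ``S = [[1, s], [s, 1]]``,
  which for two statistics reduces to ``(z1 + z2) / sqrt(2 (1 + s))``.
* dLC: a direct linear combination with externally chosen non-negative
  weights, ``t = (w1 z1 + w2 z2) / sqrt(w1^2 + w2^2 + 2 s w1 w2)``; by
  default the weights are sqrt(N), favouring the better-powered study.

Both are standard normal under the null.  The scan reports the smaller of
the two p-values as the bivariate p-value; this min-p rule is deliberately
not corrected for testing two statistics (its inflation is quantified by
the evaluation experiments instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ZCorrelation:
    """Null correlation between the two traits' Z statistics."""

    s: float
    n_snps_used: int
    estimation_method: str = "null_band"

    def __post_init__(self):
        if not abs(self.s) < 1:
            raise ValueError(f"|s| must be < 1, got {self.s}")
        if self.n_snps_used < 100:
            raise ValueError("s must be estimated from >= 100 SNPs")


def _box_truncated_corr(s: float, band: float, n_grid: int = 129) -> float:
    """Pearson correlation of a BVN(s) pair truncated to the |z|<=band box.

    Restricting a bivariate normal to a symmetric box attenuates its
    correlation; this evaluates the attenuated value by quadrature.
    """
    from numpy.polynomial.legendre import leggauss

    nodes, wts = leggauss(n_grid)
    z = nodes * band  # map [-1, 1] -> [-band, band]
    w = wts * band
    phi = stats.norm.pdf  # 1-D factors of the BVN density
    # density f(z1, z2) = phi(z1) * phi((z2 - s z1)/sig)/sig
    sig = np.sqrt(1.0 - s * s)
    f = (phi(z)[:, None] * w[:, None]) * (
        phi((z[None, :] - s * z[:, None]) / sig) / sig * w[None, :]
    )
    mass = f.sum()
    ez2 = (f * (z**2)[:, None]).sum() / mass  # symmetric in the two axes
    ez1z2 = (f * np.outer(z, z)).sum() / mass
    return float(ez1z2 / ez2)


def _invert_truncation(r_obs: float, band: float) -> float:
    """Solve _box_truncated_corr(s) = r_obs for s (monotone in s)."""
    from scipy.optimize import brentq

    hi = 1 - 1e-9
    r_obs = float(np.clip(r_obs, _box_truncated_corr(-hi, band) + 1e-12,
                          _box_truncated_corr(hi, band) - 1e-12))
    return float(
        brentq(lambda s: _box_truncated_corr(s, band) - r_obs, -hi, hi,
               xtol=1e-10)
    )


def estimate_z_correlation(
    pairs: pd.DataFrame,
    null_band: float = 2.0,
    min_snps: int = 100,
) -> ZCorrelation:
    """Estimate the null Z-Z correlation from the genome-wide scan.

    Restricts to the "null band" of variants with ``|z| <= null_band`` in
    both traits, which is robust to contamination by true polygenic signal,
    and corrects the band correlation for the attenuation induced by the
    box truncation (assuming standard-normal nulls), so the estimate is
    consistent for the untruncated null correlation.  Falls back to all
    variants, uncorrected, when the band holds fewer than ``min_snps``
    variants (with a warning).
    """
    z1 = pairs["z1"].to_numpy(float)
    z2 = pairs["z2"].to_numpy(float)
    mask = (np.abs(z1) <= null_band) & (np.abs(z2) <= null_band)
    method = "null_band"
    if mask.sum() < min_snps:
        log.warning(
            "only %d variants in the |z|<=%.3g null band; using all %d",
            int(mask.sum()), null_band, len(z1),
        )
        mask = np.ones_like(mask)
        method = "all_snps"
    if mask.sum() < min_snps:
        raise ValueError(f"need >= {min_snps} variants to estimate s")
    s = float(np.corrcoef(z1[mask], z2[mask])[0, 1])
    if not abs(s) < 1:
        raise ValueError("degenerate Z-Z correlation (|s| >= 1); are the "
                         "two inputs the same study?")
    if method == "null_band":
        s = _invert_truncation(s, null_band)
    return ZCorrelation(s=s, n_snps_used=int(mask.sum()),
                        estimation_method=method)


def _s_value(s) -> float:
    s = s.s if isinstance(s, ZCorrelation) else float(s)
    if not abs(s) < 1:
        raise ValueError(f"|s| must be < 1, got {s}")
    return s


def obrien_stat(z1, z2, s):
    """O'Brien combined statistic and two-sided p-value.

    Vectorized over ``z1``/``z2``; ``s`` is a scalar or :class:`ZCorrelation`.
    """
    s = _s_value(s)
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    t = (z1 + z2) / np.sqrt(2.0 * (1.0 + s))
    return t, 2.0 * stats.norm.sf(np.abs(t))


def dlc_stat(z1, z2, s, w1, w2):
    """Direct linear combination of dependent Z statistics.

    Weights must be non-negative with ``w1 + w2 > 0``; they may be scalars
    or per-variant arrays (the default scan uses sqrt of each study's N).
    """
    s = _s_value(s)
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    w1 = np.asarray(w1, float)
    w2 = np.asarray(w2, float)
    if np.any(w1 < 0) or np.any(w2 < 0) or np.any(w1 + w2 <= 0):
        raise ValueError("weights must be non-negative with w1 + w2 > 0")
    denom = np.sqrt(w1**2 + w2**2 + 2.0 * s * w1 * w2)
    t = (w1 * z1 + w2 * z2) / denom
    return t, 2.0 * stats.norm.sf(np.abs(t))


def bivariate_scan(
    pairs: pd.DataFrame,
    s,
    weights: tuple | None = None,
) -> pd.DataFrame:
    """Run OB and dLC over a harmonized pair table.

    Returns one row per variant in the input (genomic) order with columns
    ``snp_id, chrom, pos, z1, z2, t_ob, p_ob, t_dlc, p_dlc, p_biv, p1, p2,
    same_direction`` where ``p_biv = min(p_ob, p_dlc)``.  ``weights``
    overrides the default per-variant dLC weights ``(sqrt(n1), sqrt(n2))``.
    ``same_direction`` is True only for two nonzero Z of equal sign.
    """
    z1 = pairs["z1"].to_numpy(float)
    z2 = pairs["z2"].to_numpy(float)
    if weights is None:
        w1 = np.sqrt(pairs["n1"].to_numpy(float))
        w2 = np.sqrt(pairs["n2"].to_numpy(float))
    else:
        w1, w2 = weights
    t_ob, p_ob = obrien_stat(z1, z2, s)
    t_dlc, p_dlc = dlc_stat(z1, z2, s, w1, w2)
    out = pd.DataFrame(
        {
            "snp_id": pairs["snp_id"].to_numpy(),
            "chrom": pairs["chrom"].to_numpy() if "chrom" in pairs else "NA",
            "pos": pairs["pos"].to_numpy() if "pos" in pairs else -1,
            "z1": z1,
            "z2": z2,
            "t_ob": t_ob,
            "p_ob": p_ob,
            "t_dlc": t_dlc,
            "p_dlc": p_dlc,
            "p_biv": np.minimum(p_ob, p_dlc),
            "p1": pairs["p1"].to_numpy(float) if "p1" in pairs
            else 2.0 * stats.norm.sf(np.abs(z1)),
            "p2": pairs["p2"].to_numpy(float) if "p2" in pairs
            else 2.0 * stats.norm.sf(np.abs(z2)),
            "same_direction": (np.sign(z1) == np.sign(z2)) & (z1 != 0) & (z2 != 0),
        }
    )
    return out
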