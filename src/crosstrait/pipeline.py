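"""End-to-end orchestration and evaluation experiments.

``run_pipeline`` chains harmonization -> null Z-Z correlation ->
bivariate scan -> four-criterion discovery filter -> clumping -> optional
replication (one-sided test, dLC meta-analysis, three-criterion rule,
post-hoc BH-FDR), logging record counts at every stage.

The experiment functions quantify the statistical behaviour of the method
under the simulator: type-I error of the OB test and min-p inflation,
false-positive locus counts on negative-control (null cross-trait) pairs,
and bias/coverage of the genetic-correlation estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import bivariate, ldscore, loci as loci_mod, simulate, sumstats

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File-based configuration (the YAML surface of the CLI)."""

    sumstats1: str
    sumstats2: str
    replication: str | None = None
    ld_scores: str | None = None
    ld_pairs: str | None = None
    trait1: str = "trait1"
    trait2: str = "trait2"
    n_default1: float | None = None
    n_default2: float | None = None
    criteria: loci_mod.DiscoveryCriteria = field(
        default_factory=loci_mod.DiscoveryCriteria
    )
    clump_r2: float = loci_mod.DEFAULT_R2_THRESHOLD
    clump_window_bp: int = loci_mod.DEFAULT_CLUMP_WINDOW_BP
    drop_palindromic: bool = True
    seed: int = 0
    outdir: str | None = None


@dataclass
class PipelineResult:
    harmonized: pd.DataFrame
    z_correlation: bivariate.ZCorrelation
    scan: pd.DataFrame
    passing: pd.DataFrame
    loci: list
    replication: pd.DataFrame | None
    counts: dict
    rg_fit: ldscore.GeneticCorrelationFit | None = None


def run_pipeline(
    t1: sumstats.SumStatsTable,
    t2: sumstats.SumStatsTable,
    r2,
    rep_table: sumstats.SumStatsTable | None = None,
    ld=None,
    criteria: loci_mod.DiscoveryCriteria | None = None,
    clump_r2: float = loci_mod.DEFAULT_R2_THRESHOLD,
    clump_window_bp: int = loci_mod.DEFAULT_CLUMP_WINDOW_BP,
    drop_palindromic: bool = True,
    analysis: str = "bivariate",
) -> PipelineResult:
    """Run the full bivariate discovery (and optional replication) analysis.

    Parameters
    ----------
    t1, t2
        The two studies' summary statistics.
    r2
        Pairwise LD lookup ``(snp_a, snp_b) -> r2`` used for clumping.
    rep_table
        Independent replication summary statistics (harmonized internally
        onto study 1's effect alleles).
    ld
        Optional per-SNP LD scores (Series indexed by snp_id); when given,
        a bivariate LD score regression is fit and reported alongside.

    Deterministic given its inputs: no randomness is consumed.
    """
    criteria = criteria or loci_mod.DiscoveryCriteria()
    counts: dict[str, int] = {"input_1": len(t1), "input_2": len(t2)}

    pairs = sumstats.harmonize_pair(t1, t2, drop_palindromic=drop_palindromic)
    counts["harmonized"] = len(pairs)

    rg_fit = None
    if ld is not None:
        rg_fit = ldscore.fit_rg(pairs, ld, m_total=max(t1.m_total, t2.m_total))

    zc = bivariate.estimate_z_correlation(pairs)
    scan = bivariate.bivariate_scan(pairs, zc)
    counts["scanned"] = len(scan)

    passing = scan[loci_mod.discovery_mask(scan, criteria)].reset_index(drop=True)
    counts["discovery_pass"] = len(passing)

    found = loci_mod.clump(passing, r2, r2_thresh=clump_r2,
                           window_bp=clump_window_bp, analysis=analysis)
    counts["loci"] = len(found)

    replication = None
    if rep_table is not None and found:
        replication = _replicate(t1, pairs, scan, found, rep_table,
                                 drop_palindromic=drop_palindromic)
        counts["replicated"] = int(replication["replicated"].sum())

    log.info("pipeline counts: %s", counts)
    return PipelineResult(
        harmonized=pairs, z_correlation=zc, scan=scan, passing=passing,
        loci=found, replication=replication, counts=counts, rg_fit=rg_fit,
    )


def _replicate(t1, pairs, scan, found, rep_table,
               drop_palindromic=True) -> pd.DataFrame:
    """Replication stage: one-sided test + dLC meta-analysis + 3 criteria."""
    leads = {loc.lead for loc in found}
    sub = sumstats.SumStatsTable(
        t1.df[t1.df["snp_id"].isin(leads)].reset_index(drop=True),
        trait=t1.trait, m_total=t1.m_total,
    )
    rep_pairs = sumstats.harmonize_pair(sub, rep_table,
                                        drop_palindromic=drop_palindromic)
    rep_by_snp = rep_pairs.set_index("snp_id")
    scan_by_snp = scan.set_index("snp_id")
    # combined discovery sample size per variant (both discovery studies)
    disc_n = (pairs["n1"] + pairs["n2"]).groupby(pairs["snp_id"]).first()

    rows = []
    for loc in found:
        srow = scan_by_snp.loc[loc.lead]
        if loc.lead not in rep_by_snp.index:
            rows.append((loc.lead, loc.analysis, np.nan, np.nan, False,
                         np.nan, np.nan, srow["p_biv"], False, True))
            continue
        rrow = rep_by_snp.loc[loc.lead]
        z_rep = float(rrow["z2"])
        sign = 1 if srow["z1"] > 0 else -1
        p_rep = float(loci_mod.one_sided_p(z_rep, sign))
        consistent = (
            np.sign(srow["z1"]) == np.sign(srow["z2"]) == np.sign(z_rep)
            and z_rep != 0
        )
        t_comb, p_comb = loci_mod.combine_disc_rep(
            float(srow["t_dlc"]), z_rep,
            n_disc=float(disc_n[loc.lead]), n_rep=float(rrow["n2"]),
        )
        rec = loci_mod.ReplicationRecord(
            snp_id=loc.lead, p_rep_one_sided=p_rep,
            direction_consistent=bool(consistent),
            p_combined=float(p_comb), p_biv_discovery=float(srow["p_biv"]),
        )
        rows.append((loc.lead, loc.analysis, z_rep, p_rep, bool(consistent),
                     float(t_comb), float(p_comb), float(srow["p_biv"]),
                     rec.replicated, rec.untested))

    out = pd.DataFrame(
        rows,
        columns=["snp_id", "analysis", "z_rep", "p_rep_one_sided",
                 "direction_consistent", "t_comb", "p_comb",
                 "p_biv_discovery", "replicated", "untested"],
    )
    tested = out["p_rep_one_sided"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = loci_mod.bh_fdr(
            out.loc[tested, "p_rep_one_sided"].to_numpy(float)
        )
    return out


def write_loci(found, path) -> None:
    """Serialize clumped loci as TSV."""
    pd.DataFrame(
        [
            {
                "lead": loc.lead, "chrom": loc.chrom,
                "span_start": loc.span[0], "span_end": loc.span[1],
                "analysis": loc.analysis, "p_biv": loc.p_lead,
                "n_members": len(loc.members),
                "members": ",".join(sorted(loc.members)),
            }
            for loc in found
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# evaluation experiments
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Point estimates with Monte-Carlo standard errors for one experiment."""

    experiment: str
    n_reps: int
    estimates: dict
    ses: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment, "n_reps": self.n_reps,
            "estimates": self.estimates, "ses": self.ses, "seed": self.seed,
        }


def type1_error_experiment(
    cfg: simulate.SimConfig,
    alphas=(0.01, 0.05),
    n_reps: int = 1,
    seed: int = 0,
) -> EvaluationReport:
    """Empirical per-SNP type-I error of OB and min-p under the null.

    ``cfg`` should describe a null pair (rg = 0).  Reports, per alpha, the
    fraction of null SNPs with p_ob < alpha and with p_biv < alpha, plus the
    min-p inflation factor (min-p rate / OB rate at each alpha).
    """
    rng = np.random.default_rng(seed)
    null_cfg = dc_replace(cfg, rg=0.0)
    rates_ob = {a: [] for a in alphas}
    rates_minp = {a: [] for a in alphas}
    for _ in range(n_reps):
        t1, t2, _ = simulate.simulate_sumstats(null_cfg, rng)
        pairs = sumstats.harmonize_pair(t1, t2)
        zc = bivariate.estimate_z_correlation(pairs)
        scan = bivariate.bivariate_scan(pairs, zc)
        for a in alphas:
            rates_ob[a].append(float((scan["p_ob"] < a).mean()))
            rates_minp[a].append(float((scan["p_biv"] < a).mean()))
    estimates, ses = {}, {}
    for a in alphas:
        ob = np.array(rates_ob[a])
        mp = np.array(rates_minp[a])
        estimates[f"ob_rate@{a}"] = float(ob.mean())
        estimates[f"minp_rate@{a}"] = float(mp.mean())
        estimates[f"minp_inflation@{a}"] = float(mp.mean() / ob.mean())
        n_total = n_reps * null_cfg.m
        ses[f"ob_rate@{a}"] = float(np.sqrt(ob.mean() * (1 - ob.mean()) / n_total))
        ses[f"minp_rate@{a}"] = float(np.sqrt(mp.mean() * (1 - mp.mean()) / n_total))
    return EvaluationReport("type1_error", n_reps, estimates, ses, seed)


def negative_control_experiment(
    cfg: simulate.SimConfig,
    n_reps: int = 6,
    seed: int = 0,
) -> EvaluationReport:
    """False-positive locus audit on null cross-trait pairs.

    Each replicate simulates a pair with per-trait polygenicity but no
    shared genetics or samples, runs the full discovery pipeline, and counts
    loci passing (a) the full four-criterion filter and (b) the genome-wide
    p threshold alone — both are reported because published negative-control
    counts do not state which rule was applied to the controls.
    """
    rng = np.random.default_rng(seed)
    r2 = simulate.block_r2_lookup(cfg)
    full_counts, gw_counts = [], []
    for _ in range(n_reps):
        t1, t2 = simulate.simulate_null_pair(cfg, rng)
        res = run_pipeline(t1, t2, r2)
        full_counts.append(len(res.loci))
        gw_only = res.scan[res.scan["p_biv"] < loci_mod.DiscoveryCriteria().p_gw]
        gw_counts.append(
            len(loci_mod.clump(gw_only.reset_index(drop=True), r2))
        )
    full = np.array(full_counts, float)
    gw = np.array(gw_counts, float)
    estimates = {
        "mean_loci_full_filter": float(full.mean()),
        "mean_loci_gw_only": float(gw.mean()),
    }
    ses = {
        "mean_loci_full_filter": float(full.std(ddof=1) / np.sqrt(n_reps))
        if n_reps > 1 else float("nan"),
        "mean_loci_gw_only": float(gw.std(ddof=1) / np.sqrt(n_reps))
        if n_reps > 1 else float("nan"),
    }
    return EvaluationReport("negative_control", n_reps, estimates, ses, seed)


def rg_recovery_experiment(
    rg_grid=(0.0, 0.25, 0.5, 0.8),
    n_reps: int = 100,
    cfg: simulate.SimConfig | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Bias, RMSE and jackknife-CI coverage of the r_g estimator.

    For each true r_g on the grid, simulates ``n_reps`` independent pairs
    under ``cfg`` (analytic LD scores supplied to the fit) and summarizes
    the distribution of the estimate and of +-1.96 SE interval coverage.
    """
    cfg = cfg or simulate.SimConfig()
    rng = np.random.default_rng(seed)
    estimates, ses = {}, {}
    for rg_true in rg_grid:
        point_cfg = dc_replace(cfg, rg=rg_true)
        l = simulate.analytic_ld_scores(point_cfg)
        rg_hat, covered, h2_hat = [], [], []
        for _ in range(n_reps):
            t1, t2, _ = simulate.simulate_sumstats(point_cfg, rng)
            pairs = sumstats.harmonize_pair(t1, t2)
            fit = ldscore.fit_rg(pairs, l, m_total=point_cfg.m)
            if not fit.defined:
                continue
            rg_hat.append(fit.rg)
            h2_hat.append(fit.fit1.h2)
            covered.append(abs(fit.rg - rg_true) <= 1.96 * fit.se_rg)
        rg_hat = np.array(rg_hat)
        h2_hat = np.array(h2_hat)
        key = f"rg={rg_true}"
        estimates[f"bias@{key}"] = float(rg_hat.mean() - rg_true)
        estimates[f"rmse@{key}"] = float(
            np.sqrt(np.mean((rg_hat - rg_true) ** 2))
        )
        estimates[f"coverage@{key}"] = float(np.mean(covered))
        estimates[f"h2_bias@{key}"] = float(h2_hat.mean() - cfg.h2_1)
        ses[f"bias@{key}"] = float(rg_hat.std(ddof=1) / np.sqrt(len(rg_hat)))
        ses[f"coverage@{key}"] = float(
            np.sqrt(np.mean(covered) * (1 - np.mean(covered)) / len(covered))
        )
        ses[f"h2_bias@{key}"] = float(h2_hat.std(ddof=1) / np.sqrt(len(h2_hat)))
    return EvaluationReport("rg_recovery", n_reps, estimates, ses, seed)
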