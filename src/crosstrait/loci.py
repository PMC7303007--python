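"""Locus definition, discovery and replication filtering, and FDR audit.

A bivariate scan yields per-variant p-values; this module turns them into
independent loci and applies the discovery and replication rules:

Discovery (all four must hold):
  (i)   bivariate p < 5e-8 (genome-wide significance);
  (ii)  bivariate p at least one order of magnitude below BOTH univariate p;
  (iii) both univariate p < 1e-3;
  (iv)  the two studies' effects point the same way.

Locus definition: greedy clumping — the most significant unassigned variant
leads a locus and absorbs unassigned variants with r2 > 0.10 within +-1 Mb;
lead variants of distinct loci are therefore pairwise r2 <= 0.10.

Replication (all three must hold):
  (i)   one-sided replication p < 0.05 in the discovery direction;
  (ii)  all three effect signs (both discovery studies and replication)
        agree;
  (iii) the combined discovery+replication p is more significant (strictly
        smaller) than the discovery bivariate p.

A post-hoc Benjamini-Hochberg FDR over the replication p-values audits the
replication call set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bivariate import dlc_stat

log = logging.getLogger(__name__)

DEFAULT_R2_THRESHOLD = 0.10
DEFAULT_CLUMP_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class DiscoveryCriteria:
    """Thresholds of the four-part discovery filter."""

    p_gw: float = 5e-8
    magnitude_factor: float = 10.0
    p_uni_max: float = 1e-3
    require_same_direction: bool = True

    def __post_init__(self):
        if self.p_gw <= 0 or self.p_uni_max <= 0:
            raise ValueError("thresholds must be positive")
        if self.magnitude_factor < 1:
            raise ValueError("magnitude_factor must be >= 1")


def apply_discovery_filter(result, criteria: DiscoveryCriteria = DiscoveryCriteria()):
    """Evaluate the four discovery criteria on one scan row.

    ``result`` is any mapping (dict, Series, namedtuple-as-dict) with keys
    ``p_biv, p1, p2, same_direction``.  Returns ``(passed, failed)`` where
    ``failed`` lists the labels of violated criteria
    (``genome_wide, magnitude, uni_p1, uni_p2, direction``).
    """
    get = result.get if hasattr(result, "get") else lambda k: getattr(result, k)
    p_biv, p1, p2 = float(get("p_biv")), float(get("p1")), float(get("p2"))
    failed = []
    if not p_biv < criteria.p_gw:
        failed.append("genome_wide")
    # non-strict at the exact order-of-magnitude boundary
    if not (p_biv <= p1 / criteria.magnitude_factor
            and p_biv <= p2 / criteria.magnitude_factor):
        failed.append("magnitude")
    if not p1 < criteria.p_uni_max:
        failed.append("uni_p1")
    if not p2 < criteria.p_uni_max:
        failed.append("uni_p2")
    if criteria.require_same_direction and not bool(get("same_direction")):
        failed.append("direction")
    return (not failed), failed


def discovery_mask(scan: pd.DataFrame,
                   criteria: DiscoveryCriteria = DiscoveryCriteria()) -> np.ndarray:
    """Vectorized four-criterion filter over a scan table."""
    p_biv = scan["p_biv"].to_numpy(float)
    p1 = scan["p1"].to_numpy(float)
    p2 = scan["p2"].to_numpy(float)
    ok = (
        (p_biv < criteria.p_gw)
        & (p_biv <= p1 / criteria.magnitude_factor)
        & (p_biv <= p2 / criteria.magnitude_factor)
        & (p1 < criteria.p_uni_max)
        & (p2 < criteria.p_uni_max)
    )
    if criteria.require_same_direction:
        ok &= scan["same_direction"].to_numpy(bool)
    return ok


# ---------------------------------------------------------------------------
# LD lookup and clumping
# ---------------------------------------------------------------------------

class PairwiseR2:
    """Symmetric sparse r2 lookup; absent pairs count as r2 = 0."""

    def __init__(self, pairs=None):
        self._r2: dict[frozenset, float] = {}
        if pairs is not None:
            for a, b, r2 in pairs:
                self.set(a, b, r2)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "PairwiseR2":
        """Build from a DataFrame with columns (snp_a, snp_b, r2)."""
        return cls(df.iloc[:, :3].itertuples(index=False, name=None))

    def set(self, a, b, r2: float) -> None:
        self._r2[frozenset((a, b))] = float(r2)

    def get(self, a, b) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    __call__ = get


@dataclass(frozen=True)
class Locus:
    """A clumped locus led by its most significant variant."""

    lead: str
    members: frozenset
    analysis: str = ""
    chrom: str = ""
    span: tuple = (0, 0)
    p_lead: float = float("nan")
    gene: str | None = None

    def __post_init__(self):
        if self.lead not in self.members:
            raise ValueError("lead must be a member of its locus")


def clump(
    results: pd.DataFrame,
    r2,
    r2_thresh: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
    analysis: str = "",
) -> list[Locus]:
    """Greedy clumping of discovery-passing variants into independent loci.

    ``results`` needs columns ``snp_id, chrom, pos, p_biv``; ``r2`` is a
    callable ``(snp_a, snp_b) -> r2`` (e.g. :class:`PairwiseR2`).  Repeatedly
    the unassigned variant with the smallest ``p_biv`` becomes a lead and
    absorbs all unassigned variants on the same chromosome within
    ``window_bp`` that have ``r2 > r2_thresh`` with it.  Absorption is not
    chained: a variant linked only to an absorbed member can seed its own
    locus later.
    """
    df = results.reset_index(drop=True)
    order = np.argsort(df["p_biv"].to_numpy(float), kind="stable")
    assigned = np.zeros(len(df), dtype=bool)
    snp = df["snp_id"].to_numpy()
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(np.int64)
    p = df["p_biv"].to_numpy(float)

    loci = []
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        members = [i]
        near = (
            ~assigned
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        for j in np.flatnonzero(near):
            if r2(snp[i], snp[j]) > r2_thresh:
                assigned[j] = True
                members.append(j)
        loci.append(
            Locus(
                lead=snp[i],
                members=frozenset(snp[k] for k in members),
                analysis=analysis,
                chrom=chrom[i],
                span=(int(min(pos[k] for k in members)),
                      int(max(pos[k] for k in members))),
                p_lead=float(p[i]),
            )
        )
    return loci


def collapse_cross_analysis(
    loci,
    r2,
    r2_thresh: float = DEFAULT_R2_THRESHOLD,
) -> list[list[Locus]]:
    """Merge loci from several bivariate runs into independent components.

    Two loci are dependent when they share any member variant or when their
    lead variants have ``r2 > r2_thresh``.  Returns the connected components
    (union-find), each a list of the original loci.
    """
    loci = list(loci)
    parent = list(range(len(loci)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            if loci[i].members & loci[j].members:
                union(i, j)
            elif r2(loci[i].lead, loci[j].lead) > r2_thresh:
                union(i, j)

    groups: dict[int, list] = {}
    for i, loc in enumerate(loci):
        groups.setdefault(find(i), []).append(loc)
    return list(groups.values())


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def one_sided_p(z_rep, expected_sign) -> float:
    """One-sided replication p in the direction expected from discovery.

    ``expected_sign`` is +1/-1 (or '+'/'-').  Returns
    ``Phi(-z_rep * sign)``: the probability of a statistic at least as
    extreme in the expected direction.
    """
    if isinstance(expected_sign, str):
        expected_sign = {"+": 1, "-": -1}[expected_sign]
    if expected_sign not in (1, -1):
        raise ValueError("expected_sign must be +1 or -1")
    return stats.norm.sf(np.asarray(z_rep, float) * expected_sign)


def combine_disc_rep(t_disc, z_rep, n_disc, n_rep):
    """Meta-analyze the discovery bivariate statistic with replication.

    A dLC combination with sqrt-sample-size weights and zero cross-cohort
    correlation (discovery and replication samples are independent):
    ``t = (sqrt(n_disc) t_disc + sqrt(n_rep) z_rep) / sqrt(n_disc + n_rep)``.
    Returns ``(t_comb, two-sided p)``.
    """
    return dlc_stat(t_disc, z_rep, 0.0, np.sqrt(n_disc), np.sqrt(n_rep))


@dataclass
class ReplicationRecord:
    """Replication outcome for one discovery locus lead."""

    snp_id: str
    p_rep_one_sided: float | None
    direction_consistent: bool | None
    p_combined: float | None
    p_biv_discovery: float
    replicated: bool = field(init=False, default=False)
    untested: bool = field(init=False, default=False)

    def __post_init__(self):
        self.replicated = apply_replication_filter(self)
        self.untested = self.p_rep_one_sided is None or (
            isinstance(self.p_rep_one_sided, float)
            and np.isnan(self.p_rep_one_sided)
        )


def apply_replication_filter(rec) -> bool:
    """Conjunction of the three replication criteria.

    ``rec`` carries ``p_rep_one_sided``, ``direction_consistent``,
    ``p_combined`` and ``p_biv_discovery``.  A missing replication statistic
    means "untested", which is not replicated.
    """
    get = rec.get if hasattr(rec, "get") else lambda k: getattr(rec, k)
    p_rep = get("p_rep_one_sided")
    p_comb = get("p_combined")
    if p_rep is None or p_comb is None:
        return False
    p_rep, p_comb = float(p_rep), float(p_comb)
    if np.isnan(p_rep) or np.isnan(p_comb):
        return False
    return (
        p_rep < 0.05
        and bool(get("direction_consistent"))
        and p_comb < float(get("p_biv_discovery"))  # strictly more significant
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving on the input."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_novelty(loci: pd.DataFrame, known_loci) -> pd.Series:
    """Flag replicated loci absent from a prior-report list as novel.

    ``loci`` needs columns ``replicated`` and either ``gene`` or ``lead``;
    ``known_loci`` is a collection of gene names and/or variant ids.
    An empty known list makes every replicated locus novel.
    """
    known = set(known_loci)
    label = loci["gene"] if "gene" in loci else loci["lead"]
    return loci["replicated"].astype(bool) & ~label.isin(known)


# ---------------------------------------------------------------------------
# bookkeeping over a printed discovery/replication results table
# ---------------------------------------------------------------------------

@dataclass
class ReportedTableSummary:
    """Locus bookkeeping recomputed from a printed results table."""

    per_row: pd.DataFrame
    components: list
    n_loci: int
    n_replicated: int
    replicated_genes: list
    n_novel: int
    novel_genes: list
    q_replicated: pd.Series  # BH q-values, indexed by unique replicated snp_id


def evaluate_reported_table(
    table: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    known_genes,
    criteria: DiscoveryCriteria = DiscoveryCriteria(),
) -> ReportedTableSummary:
    """Re-run the discovery/replication/novelty bookkeeping on printed rows.

    ``table`` mirrors a published per-analysis results table: one row per
    lead variant and analysis with columns ``snp_id, chrom, pos, gene,
    analysis, p_broad, p_analysis, p_biv, p_rep_1sided, p_comb, ed`` where
    ``ed`` is the three-character effect-direction triplet (study 1,
    study 2, replication).  Printed combined p-values are taken as input to
    the replication rule.  ``ld_pairs`` supplies lead-lead r2 values for
    cross-analysis collapsing.
    """
    df = table.copy().reset_index(drop=True)
    ed = df["ed"].astype(str)
    df["same_direction"] = ed.str[0] == ed.str[1]
    df["direction_consistent"] = df["same_direction"] & (ed.str[1] == ed.str[2])

    disc = [
        apply_discovery_filter(
            {"p_biv": r.p_biv, "p1": r.p_broad, "p2": r.p_analysis,
             "same_direction": r.same_direction},
            criteria,
        )[0]
        for r in df.itertuples()
    ]
    df["discovery_pass"] = disc
    df["replication_pass"] = [
        apply_replication_filter(
            {"p_rep_one_sided": r.p_rep_1sided,
             "direction_consistent": r.direction_consistent,
             "p_combined": r.p_comb,
             "p_biv_discovery": r.p_biv}
        )
        for r in df.itertuples()
    ]

    r2 = PairwiseR2.from_table(ld_pairs)
    row_loci = [
        Locus(lead=r.snp_id, members=frozenset([r.snp_id]), analysis=r.analysis,
              chrom=str(r.chrom), span=(r.pos, r.pos), p_lead=r.p_biv,
              gene=r.gene)
        for r in df.itertuples()
    ]
    components = collapse_cross_analysis(row_loci, r2)

    rep_by_snp = df.groupby("snp_id")["replication_pass"].any()
    replicated_components = [
        comp for comp in components if any(rep_by_snp[loc.lead] for loc in comp)
    ]
    replicated_genes = sorted({loc.gene for comp in replicated_components
                               for loc in comp})
    known = set(known_genes)
    novel_components = [
        comp for comp in replicated_components
        if not any(loc.gene in known for loc in comp)
    ]
    novel_genes = sorted({loc.gene for comp in novel_components for loc in comp})

    rep_rows = df[df["replication_pass"]].drop_duplicates("snp_id")
    q = pd.Series(
        bh_fdr(rep_rows["p_rep_1sided"].to_numpy(float)),
        index=rep_rows["snp_id"].to_numpy(),
        name="q",
    )
    return ReportedTableSummary(
        per_row=df,
        components=components,
        n_loci=len(components),
        n_replicated=len(replicated_components),
        replicated_genes=replicated_genes,
        n_novel=len(novel_components),
        novel_genes=novel_genes,
        q_replicated=q,
    )
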