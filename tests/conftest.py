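"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from crosstrait import datasets
from crosstrait.sumstats import STANDARD_COLUMNS, SumStatsTable


@pytest.fixture(scope="session")
def reported_table():
    return datasets.load_discovery_table()


@pytest.fixture(scope="session")
def reported_ld():
    return datasets.load_reported_ld()


@pytest.fixture(scope="session")
def known_genes():
    return set(datasets.load_known_depression_loci()["gene"])


def make_table(rows, trait="trait", m_total=None):
    """Build a SumStatsTable from (snp_id, chrom, pos, a1, a2, eaf, z, n, p)
    tuples without going through file I/O."""
    df = pd.DataFrame(rows, columns=list(STANDARD_COLUMNS))
    df["chrom"] = df["chrom"].astype(str)
    return SumStatsTable(df, trait=trait, m_total=m_total or len(df))


def greedy_clump_oracle(df, r2, r2_thresh=0.10, window_bp=1_000_000):
    """Literal restatement of the clumping rule, kept independent of the
    implementation: repeatedly promote the unassigned variant with the
    smallest bivariate p to lead and absorb unassigned variants with
    r2 > threshold within the window on the same chromosome.

    Returns a list of (lead, frozenset(members)) in lead-promotion order.
    """
    remaining = {
        row.snp_id: (str(row.chrom), int(row.pos), float(row.p_biv))
        for row in df.itertuples()
    }
    out = []
    while remaining:
        lead = min(remaining, key=lambda s: (remaining[s][2], df.index[df["snp_id"] == s][0]))
        lc, lp, _ = remaining.pop(lead)
        members = {lead}
        for snp, (c, p, _) in list(remaining.items()):
            if c == lc and abs(p - lp) <= window_bp and r2(lead, snp) > r2_thresh:
                members.add(snp)
                del remaining[snp]
        out.append((lead, frozenset(members)))
    return out


def bh_oracle(pvalues):
    """Textbook Benjamini-Hochberg step-up q-values (independent oracle)."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        q[i] = running_min
    return q
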