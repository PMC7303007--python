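"""Packaged reference datasets.

The package ships the printed discovery/replication results of the bivariate
depression analyses as small TSV fixtures: the 23-row lead-variant table
(one row per lead SNP and bivariate analysis, with univariate, bivariate,
replication and combined p-values and effect-direction triplets), the
lead-lead LD values noted in its footnotes, and the prior-report list of
depression loci used for novelty annotation.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

_DATA = files("crosstrait") / "data"


def load_discovery_table() -> pd.DataFrame:
    """The printed per-analysis lead-variant results (23 rows).

    Columns include ``snp_id, a1, a2, eaf_ukb, chrom, pos, gene, analysis``
    (sMDD, rMDD, BPD or SCZ), the sample sizes, the univariate p-values
    (``p_broad``, ``p_analysis``), the bivariate discovery p (``p_biv``),
    the one-sided replication p (``p_rep_1sided``), the combined p
    (``p_comb``), the effect-direction triplet ``ed`` and the prior-report
    flag.  One lead (rs2535629) appears under both the bipolar and the
    schizophrenia analyses.
    """
    with (_DATA / "discovery_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_reported_ld() -> pd.DataFrame:
    """Lead-lead r2 values reported alongside the results table."""
    with (_DATA / "reported_ld.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_known_depression_loci() -> pd.DataFrame:
    """Previously reported depression loci (gene label + first report)."""
    with (_DATA / "known_depression_loci.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
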