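"""FDR adjustment and aggregation of repeat runs into the final result table.

Two Benjamini-Hochberg corrections are applied to the raw empirical
p-values of each embedding repeat: a *global* adjustment across all gene-GO
pairs jointly (cross-gene relevance calls) and a *gene* adjustment within
each gene's own annotation set (per-gene ranking). Point estimates and
uncertainties are then aggregated across the nreps_graph repeats.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene", "go_id", "go_name", "go_domain", "ncon_gene", "ncon_go",
    "mean_sim", "sem_sim",
    "gene_padj", "gene_padj_cilow", "gene_padj_ciupp",
    "global_padj", "global_padj_cilow", "global_padj_ciupp",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} min(1, m * p_(j) / j) for the i-th order statistic.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dual_adjust(records: pd.DataFrame) -> pd.DataFrame:
    """Add gene_padj and global_padj columns to one repeat's record table.

    ``records`` needs columns gene, go_id, p_value. global_padj is BH over
    all rows jointly; gene_padj is BH within each gene's rows independently.
    """
    out = records.copy()
    out["global_padj"] = bh_adjust(out["p_value"].to_numpy())
    out["gene_padj"] = (
        out.groupby("gene", sort=False)["p_value"]
        .transform(lambda s: bh_adjust(s.to_numpy()))
    )
    return out


def aggregate_repeats(per_repeat: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine nreps_graph per-repeat tables into one row per gene-GO pair.

    Per pair: mean similarity with s.e.m., and mean gene/global padj with a
    Student-t 95% CI (mean +/- t_{0.975, n-1} * s.e.m.), clipped to [0, 1].
    All repeats must cover the same pair set; pairs missing from some repeat
    are dropped with a warning.
    """
    if not per_repeat:
        raise ValueError("no repeat tables to aggregate")
    nreps = len(per_repeat)
    if nreps == 1:
        warnings.warn(
            "single repeat: confidence intervals collapse to the point estimate"
        )
    key = ["gene", "go_id"]
    common = set(map(tuple, per_repeat[0][key].itertuples(index=False)))
    for tab in per_repeat[1:]:
        common &= set(map(tuple, tab[key].itertuples(index=False)))
    stacked = pd.concat(per_repeat, ignore_index=True)
    n_all = stacked.drop_duplicates(key).shape[0]
    if n_all > len(common):
        warnings.warn(
            f"{n_all - len(common)} gene-GO pairs untested in some repeats; "
            "excluded from aggregation"
        )
        mask = [tuple(t) in common for t in stacked[key].itertuples(index=False)]
        stacked = stacked.loc[mask]

    tcrit = sps.t.ppf(0.975, nreps - 1) if nreps > 1 else 0.0

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(nreps) if nreps > 1 else 0.0

    g = stacked.groupby(key, sort=False)
    agg = g.agg(
        mean_sim=("similarity", "mean"),
        sem_sim=("similarity", _sem),
        gene_padj=("gene_padj", "mean"),
        sem_gene=("gene_padj", _sem),
        global_padj=("global_padj", "mean"),
        sem_global=("global_padj", _sem),
    ).reset_index()
    agg["gene_padj_cilow"] = np.clip(agg.gene_padj - tcrit * agg.sem_gene, 0, 1)
    agg["gene_padj_ciupp"] = np.clip(agg.gene_padj + tcrit * agg.sem_gene, 0, 1)
    agg["global_padj_cilow"] = np.clip(
        agg.global_padj - tcrit * agg.sem_global, 0, 1
    )
    agg["global_padj_ciupp"] = np.clip(
        agg.global_padj + tcrit * agg.sem_global, 0, 1
    )
    return agg.drop(columns=["sem_gene", "sem_global"])
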