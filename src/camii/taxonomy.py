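"""Isolate taxonomy assignment from ASV counts and community summaries.

Each picked isolate is sequenced at the 16S V4 locus and its reads are
tabulated against amplicon sequence variants (ASVs). The isolate is assigned
the taxonomy of its most abundant ASV; isolates with fewer than 5 total reads
or top-ASV purity below 0.5 are filtered as failed. Community summaries
include bulk relative abundance, biobank coverage (cumulated abundance of the
ASVs represented by isolates), Shannon diversity/equitability, and a greedy
ranking of growth conditions by the novel taxa they contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

logger = logging.getLogger(__name__)

MIN_READS = 5
MIN_PURITY = 0.5


@dataclass
class IsolateAssignment:
    isolate_id: str
    total_reads: int
    top_asv: str | None
    purity: float
    passed: bool
    genus: str | None = None
    family: str | None = None
    phylum: str | None = None


def assign_isolates(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    min_reads: int = MIN_READS,
    min_purity: float = MIN_PURITY,
) -> pd.DataFrame:
    """Assign each isolate the taxonomy of its highest-count ASV.

    ``table``: isolates x ASVs integer counts. Pass/fail follows
    total_reads >= ``min_reads`` and purity >= ``min_purity`` (both
    boundary-inclusive: the stated filter removes reads counts < 5 or purity
    < 0.5). Top-ASV ties break toward the lexicographically lowest ASV id and
    are logged. Zero-read isolates fail with purity 0.
    """
    if table.empty:
        raise ValueError("empty ASV count table")
    counts = table.to_numpy()
    if (counts < 0).any():
        raise ValueError("negative counts in ASV table")
    asv_order = np.argsort(table.columns.astype(str))
    sorted_cols = table.columns[asv_order]

    rows = []
    for isolate, row in table.iterrows():
        total = int(row.sum())
        if total == 0:
            rows.append((isolate, 0, None, 0.0, False))
            continue
        vals = row[sorted_cols]
        top_idx = int(np.argmax(vals.to_numpy()))  # first max = lowest ASV id
        top_asv = str(sorted_cols[top_idx])
        top_count = int(vals.iloc[top_idx])
        if (vals.to_numpy() == top_count).sum() > 1:
            logger.info(
                "isolate %s: top-ASV tie at %d reads, broken to %s",
                isolate,
                top_count,
                top_asv,
            )
        purity = top_count / total
        passed = total >= min_reads and purity >= min_purity
        rows.append((isolate, total, top_asv, purity, passed))
    out = pd.DataFrame(
        rows, columns=["isolate_id", "total_reads", "top_asv", "purity", "passed"]
    )
    if taxonomy is not None:
        tax = taxonomy.set_index("asv_id") if "asv_id" in taxonomy.columns else taxonomy
        for level in ("genus", "family", "phylum"):
            if level in tax.columns:
                out[level] = out["top_asv"].map(tax[level])
    return out


def bulk_relative_abundance(row: pd.Series) -> pd.Series:
    """Normalize one bulk sample's ASV counts to relative abundance."""
    row = row.astype(float)
    if (row < 0).any():
        raise ValueError("negative counts")
    total = row.sum()
    if total <= 0:
        raise ValueError("all-zero bulk sample; relative abundance undefined")
    return row / total


def biobank_coverage(abundance: pd.Series, cultured_asvs) -> float:
    """Cumulated bulk abundance of the ASVs represented in the biobank."""
    cultured = set(cultured_asvs)
    return float(abundance[abundance.index.isin(cultured)].sum())


def diversity_metrics(abundance, base: float = np.e) -> tuple[float, float]:
    """Shannon index H = -sum p log p and equitability H / log S.

    ``abundance`` must be normalized (sums to 1). S counts nonzero taxa; the
    single-taxon profile has equitability 0 by convention.
    """
    p = np.asarray(abundance, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("abundance vector must be normalized to sum to 1")
    if (p < 0).any():
        raise ValueError("negative abundances")
    nz = p[p > 0]
    if nz.size == 0:
        raise ValueError("need at least one taxon")
    h = float(-(nz * (np.log(nz) / np.log(base))).sum())
    s = nz.size
    eq = h / (np.log(s) / np.log(base)) if s > 1 else 0.0
    return h, float(eq)


def rank_conditions(
    profiles: pd.DataFrame,
    base_condition: str,
    detection_threshold: float = 0.001,
) -> pd.DataFrame:
    """Rank growth conditions by the unique taxa they add over the base.

    ``profiles``: conditions x families, each row a normalized family-level
    abundance profile. Each condition gets a uniqueness score (families above
    ``detection_threshold`` that the base condition lacks) and a Bray-Curtis
    dissimilarity to the base, then conditions are greedily ordered so each
    step maximizes the cumulative family union (ties to higher dissimilarity,
    then name).
    """
    if base_condition not in profiles.index:
        raise ValueError(f"base condition {base_condition!r} missing from profiles")
    if len(profiles) < 2:
        raise ValueError("need at least 2 conditions")
    present = profiles >= detection_threshold
    base_set = set(profiles.columns[present.loc[base_condition]])
    base_vec = profiles.loc[base_condition].to_numpy(dtype=float)

    info = {}
    for cond in profiles.index:
        if cond == base_condition:
            continue
        fams = set(profiles.columns[present.loc[cond]])
        info[cond] = {
            "families": fams,
            "uniqueness": len(fams - base_set),
            "bray_curtis": float(
                braycurtis(profiles.loc[cond].to_numpy(dtype=float), base_vec)
            ),
        }

    covered = set(base_set)
    order = []
    remaining = set(info)
    while remaining:
        best = max(
            remaining,
            key=lambda c: (
                len(info[c]["families"] - covered),
                info[c]["bray_curtis"],
                # final tie-break: stable, ascending name
            ),
        )
        ties = [
            c
            for c in remaining
            if len(info[c]["families"] - covered)
            == len(info[best]["families"] - covered)
            and info[c]["bray_curtis"] == info[best]["bray_curtis"]
        ]
        best = min(ties)
        covered |= info[best]["families"]
        order.append(
            {
                "condition": best,
                "uniqueness": info[best]["uniqueness"],
                "bray_curtis": info[best]["bray_curtis"],
                "cumulative_union": len(covered),
            }
        )
        remaining.remove(best)
    return pd.DataFrame(
        order, columns=["condition", "uniqueness", "bray_curtis", "cumulative_union"]
    )


def read_counts_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_taxonomy_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
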