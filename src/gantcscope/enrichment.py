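"""Differential-expression classification and gene-set enrichment.

Log-ratios are log2 throughout, so ">= 2-fold" means |log_ratio| >= 1.
Significance uses Benjamini-Hochberg adjusted p-values with a strict
cut-off (p_adj < alpha). Enrichment of a gene property within a gene set
is measured on the 2x2 table (in-set/has-property) with Fisher's exact
test, one-sided for over-representation by default, and a fold enrichment
defined as the in-set property frequency relative to the universe-wide
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DEClassification:
    """Significance / direction / strength gene sets derived from GeneStats."""

    stats: pd.DataFrame  # gene_id, log_ratio, p_raw, p_adj
    alpha: float
    strong_fold: float
    universe: set
    significant: set
    up: set
    down: set
    strong_up: set
    strong_down: set

    @property
    def strong(self) -> set:
        return self.strong_up | self.strong_down


def classify_de(stats_df: pd.DataFrame, alpha: float = 0.01, strong_fold: float = 2.0) -> DEClassification:
    """Bin genes into significant / up / down / strong sets.

    significant = {p_adj < alpha} (strict); up/down split the significant
    set by the sign of log_ratio; strong additionally requires
    |log_ratio| >= log2(strong_fold).
    """
    df = stats_df
    required = {"gene_id", "log_ratio", "p_adj"}
    if not required <= set(df.columns):
        raise ValueError(f"GeneStats table missing columns: {sorted(required - set(df.columns))}")
    cut = np.log2(strong_fold)
    sig = df["p_adj"] < alpha
    up = sig & (df["log_ratio"] > 0)
    down = sig & (df["log_ratio"] < 0)
    strong = np.abs(df["log_ratio"]) >= cut
    gid = df["gene_id"]
    return DEClassification(
        stats=df,
        alpha=alpha,
        strong_fold=strong_fold,
        universe=set(gid),
        significant=set(gid[sig]),
        up=set(gid[up]),
        down=set(gid[down]),
        strong_up=set(gid[up & strong]),
        strong_down=set(gid[down & strong]),
    )


def simple_de(matrix: pd.DataFrame, labels, mutant: str = "mut", wild_type: str = "wt") -> pd.DataFrame:
    """Two-sample Welch t test per gene on a log2 intensity matrix.

    A lightweight stand-in for a moderated microarray fit, intended for
    synthetic replicate matrices: log_ratio is the mean log2 difference
    mutant - wild type, p-values are two-sided Welch, adjusted with
    Benjamini-Hochberg. Degenerate zero-variance genes get p = 1.
    """
    labels = np.asarray(labels)
    a = matrix.loc[:, labels == mutant].to_numpy(float)
    b = matrix.loc[:, labels == wild_type].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least two replicates per condition")
    log_ratio = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene_id": matrix.index, "log_ratio": log_ratio, "p_raw": p, "p_adj": p_adj}
    ).reset_index(drop=True)


@dataclass
class EnrichmentResult:
    set_name: str
    property_name: str
    a: int  # in set, has property
    b: int  # in set, lacks property
    c: int  # out of set, has property
    d: int  # out of set, lacks property
    fold: float
    odds_ratio: float
    p_value: float
    direction: str  # over / under

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def fisher_from_counts(a: int, b: int, c: int, d: int, sided: str = "greater") -> tuple[float, float, float]:
    """(fold, odds_ratio, p) for a 2x2 in-set x has-property table."""
    n = a + b + c + d
    set_size = a + b
    prop_total = a + c
    if n == 0 or set_size == 0:
        raise ValueError("empty universe or empty gene set")
    fold = (
        (a / set_size) / (prop_total / n) if prop_total > 0 else float("nan")
    )
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=sided)
    return fold, float(odds), float(p)


def fisher_enrichment(
    gene_set: set,
    property_set: set,
    universe: set,
    sided: str = "greater",
    set_name: str = "set",
    property_name: str = "property",
) -> EnrichmentResult:
    """Fisher's exact test of a gene property within a gene set."""
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set) & universe
    property_set = set(property_set) & universe
    if not gene_set:
        raise ValueError(f"gene set {set_name!r} empty within the universe")
    a = len(gene_set & property_set)
    b = len(gene_set) - a
    c = len(property_set) - a
    d = len(universe) - a - b - c
    fold, odds, p = fisher_from_counts(a, b, c, d, sided)
    direction = "over" if (np.isnan(fold) or fold >= 1) else "under"
    return EnrichmentResult(set_name, property_name, a, b, c, d, fold, odds, p, direction)


def enrichment_battery(
    classification: DEClassification,
    catalog: dict[str, set] | None = None,
    promoter_flags: pd.Series | None = None,
    conservation: pd.Series | None = None,
    conservation_levels=(1, 2),
    sided: str = "greater",
    add_bh: bool = True,
) -> pd.DataFrame:
    """All (gene set x DE property) Fisher tests of the standard battery.

    Properties are the classification's significant/up/down/strong sets.
    Catalog sets are tested against each property; the promoter-motif flag
    and conservation >= level strata are additionally tested as properties
    of the DE sets (the figure-style question: are motif-bearing promoters
    over-represented among misregulated genes?). Raw p-values are reported
    (matching the published presentation); a BH column is appended for
    convenience when ``add_bh``.
    """
    universe = classification.universe
    de_sets = {
        "significant": classification.significant,
        "down": classification.down,
        "up": classification.up,
        "strong_down": classification.strong_down,
        "strong_up": classification.strong_up,
    }
    results = []
    if catalog:
        for name, members in catalog.items():
            for prop_name, prop in de_sets.items():
                if not prop:
                    continue
                results.append(
                    fisher_enrichment(set(members), prop, universe, sided, name, prop_name)
                )
    properties = {}
    if promoter_flags is not None:
        properties["promoter_motif"] = set(promoter_flags.index[promoter_flags.astype(bool)])
    if conservation is not None:
        for level in conservation_levels:
            properties[f"conserved_ge_{level}"] = set(
                conservation.index[conservation >= level]
            )
    for prop_name, prop in properties.items():
        for de_name, de_set in de_sets.items():
            if not de_set:
                continue
            results.append(
                fisher_enrichment(de_set, prop, universe, sided, de_name, prop_name)
            )
    df = pd.DataFrame([r.as_dict() for r in results])
    if add_bh and len(df):
        df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def excess_direct_targets(n_observed: int, fold_enrichment: float) -> int:
    """Excess count attributable to direct regulation.

    Of n observed motif-bearing misregulated genes at fold enrichment f,
    n/f would be expected by chance, leaving n * (1 - 1/f) in excess;
    rounded to the nearest integer, floored at zero when f <= 1.
    """
    if fold_enrichment <= 0:
        raise ValueError("fold_enrichment must be positive")
    excess = n_observed * (1.0 - 1.0 / fold_enrichment)
    return max(0, int(round(excess)))


def candidate_direct_targets(
    classification: DEClassification,
    promoter_flags: pd.Series,
    conservation: pd.Series,
    essential_set: set | None = None,
    min_conservation: int = 2,
) -> pd.DataFrame:
    """Significant genes with a (conserved) promoter motif.

    Keeps genes that are significantly misregulated AND carry a promoter
    motif AND whose conservation count is >= min_conservation; joins the
    essential-gene flag and splits repressed (down in the mutant) from
    activated, sorted by log_ratio.
    """
    stats_df = classification.stats.set_index("gene_id")
    flags = promoter_flags.astype(bool)
    keep = [
        g
        for g in classification.significant
        if flags.get(g, False) and conservation.get(g, 0) >= min_conservation
    ]
    if not keep:
        return pd.DataFrame(
            columns=["gene_id", "log_ratio", "p_adj", "conservation", "essential", "direction"]
        )
    out = pd.DataFrame(
        {
            "gene_id": keep,
            "log_ratio": [stats_df.at[g, "log_ratio"] for g in keep],
            "p_adj": [stats_df.at[g, "p_adj"] for g in keep],
            "conservation": [int(conservation.get(g, 0)) for g in keep],
        }
    )
    out["essential"] = out["gene_id"].isin(essential_set or set())
    out["direction"] = np.where(out["log_ratio"] < 0, "repressed", "activated")
    return out.sort_values("log_ratio").reset_index(drop=True)
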