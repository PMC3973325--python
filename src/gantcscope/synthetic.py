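"""Synthetic genomes, kinetics and expression data with known ground truth.

The generators emulate the statistical structure of a CcrM-style study:
a circular chromosome whose GANTC sites occur at controllable densities in
coding vs intergenic DNA; per-site per-strand methylated-population
fractions following a replication-timing gradient from origin to terminus,
plus planted bilaterally under-methylated and asymmetric sites;
coverage-averaged noisy IPD ratios; and replicate expression matrices with
planted differential expression optionally coupled to promoter motif
presence. Every generator emits a truth table so each downstream stage has
a recovery target, and a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import GenomeRecord, make_feature_table
from .methylome import motif_adenines
from .motifs import GANTC, scan_motif

# sub-stream indices so each generator draws from an independent stream of
# the plan seed
_STREAM_GENOME = 0
_STREAM_METHYLATION = 1
_STREAM_IPD = 2
_STREAM_EXPRESSION = 3
_STREAM_GENESETS = 4
_STREAM_ORTHOLOGS = 5
_STREAM_IPD_REFERENCE = 6


@dataclass
class SyntheticPlan:
    """All knobs of the synthetic study, with study-condition defaults.

    Defaults describe a 1-Mb circular chromosome carrying ~2000 GANTC
    sites (1.5/kb in coding DNA, 3/kb intergenic, mirroring intergenic
    over-representation), a hemi-methylation gradient from 80% of cells at
    the origin to 10% at the terminus, 24 bilaterally under-methylated and
    11 asymmetric planted sites, fully-methylated IPD ratio 7.68 with 30%
    per-molecule coefficient of variation at 50x mean coverage, and
    triplicate expression with 10% of genes differentially expressed at
    |log2 FC| = 2, replicate noise of 0.1 log2 units (typical
    post-normalization array replicate scatter) and a 4x
    motif/down-regulation odds coupling.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    circular: bool = True
    n_genes: int = 900
    gene_length_mean: int = 800
    rna_gene_fraction: float = 0.05
    gc_content: float = 0.5
    motif_density_coding: float = 1.5
    motif_density_intergenic: float = 3.0
    origin_position: int = 0
    gradient: tuple = (0.8, 0.1)
    n_under: int = 24
    n_asym: int = 11
    r_full_true: float = 7.68
    ipd_cv: float = 0.3
    coverage_mean: float = 50.0
    n_replicates: int = 3
    de_fraction: float = 0.1
    de_effect: float = 2.0
    motif_de_coupling: float = 4.0
    noise_sd: float = 0.1
    contig_id: str = "synthetic_chr"

    def validate(self) -> None:
        if min(self.genome_length, self.n_genes, self.gene_length_mean) <= 0:
            raise ValueError("genome_length, n_genes and gene_length_mean must be positive")
        for name in ("motif_density_coding", "motif_density_intergenic", "ipd_cv",
                     "coverage_mean", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_under < 0 or self.n_asym < 0:
            raise ValueError("planted site counts must be >= 0")
        if not all(0.0 <= g <= 1.0 for g in self.gradient):
            raise ValueError("gradient fractions must lie in [0, 1]")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.n_genes * self.gene_length_mean > 0.9 * self.genome_length:
            raise ValueError("genes do not fit: n_genes * gene_length_mean too large")
        if self.motif_de_coupling <= 0:
            raise ValueError("motif_de_coupling must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def as_dict(self) -> dict:
        return asdict(self)


def _scrub_pattern(chars: np.ndarray, circular: bool, rng: np.random.Generator,
                   planted: set[int], protected: set[int]) -> None:
    """Mutate the sequence in place until only planted GANTC sites remain."""
    alt = {"G": "ACT", "C": "AGT"}
    for _ in range(50):
        seq = "".join(chars)
        extra = [p for p in scan_motif(seq, GANTC, circular) if p not in planted]
        if not extra:
            return
        L = len(chars)
        for p in extra:
            # disrupt a determinate base of the occurrence that is not part
            # of a planted site (the central N cannot disrupt the motif)
            for off in (0, 4, 1, 3):
                q = (p + off) % L
                if q not in protected:
                    cur = chars[q]
                    choices = alt.get(cur, "ACGT".replace(cur, ""))
                    chars[q] = choices[rng.integers(len(choices))]
                    break
            else:  # fully inside planted sites: genuinely overlapping, impossible
                raise AssertionError("unexpected motif fully inside planted sites")
    raise RuntimeError("failed to scrub accidental motifs (pathological input)")


def _place_nonoverlapping(intervals, n: int, rng: np.random.Generator, taken: list[int],
                          min_gap: int = 5) -> list[int]:
    """Sample n motif start positions inside the intervals, >= min_gap apart."""
    usable = [(s, e) for s, e in intervals if e - s >= min_gap]
    if not usable:
        if n == 0:
            return []
        raise ValueError("requested motif density infeasible: no usable intervals")
    weights = np.array([e - s - (min_gap - 1) for s, e in usable], dtype=float)
    weights /= weights.sum()
    placed = []
    attempts = 0
    max_attempts = 200 * max(n, 1)
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"requested motif density infeasible: placed {len(placed)} of {n} sites"
            )
        i = rng.choice(len(usable), p=weights)
        s, e = usable[i]
        pos = int(s + rng.integers(0, e - s - (min_gap - 1)))
        j = bisect_left(taken, pos)
        if j > 0 and pos - taken[j - 1] < min_gap:
            continue
        if j < len(taken) and taken[j] - pos < min_gap:
            continue
        insort(taken, pos)
        placed.append(pos)
    return placed


def generate_genome(plan: SyntheticPlan):
    """Random circular genome with genes and planted GANTC sites.

    Returns ``(genome, features, sites)`` where ``sites`` is the truth
    table of planted motif start coordinates with their compartment.
    Accidental GANTC occurrences in the random background are scrubbed, so
    the genome's motif complement is exactly the planted set.
    """
    plan.validate()
    rng = plan.rng(_STREAM_GENOME)
    L = plan.genome_length
    gc = plan.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    chars = rng.choice(np.array(list("ACGT")), size=L, p=probs)

    # non-overlapping genes on an even grid with jitter
    spacing = L // plan.n_genes
    if spacing < 100:
        raise ValueError("fewer than 100 bp per gene slot; reduce n_genes")
    rows = []
    for i in range(plan.n_genes):
        glen = int(np.clip(rng.normal(plan.gene_length_mean, 0.15 * plan.gene_length_mean),
                           60, spacing - 30))
        margin = spacing - glen - 1
        start = i * spacing + int(rng.integers(0, max(margin, 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        kind = "rna" if rng.random() < plan.rna_gene_fraction else "protein_coding"
        rows.append(
            {
                "feature_id": f"GENE_{i:04d}",
                "contig": plan.contig_id,
                "start": start,
                "end": start + glen,
                "strand": strand,
                "kind": kind,
            }
        )
    features = make_feature_table(rows)

    gene_iv = list(zip(features["start"], features["end"]))
    coding_len = sum(e - s for s, e in gene_iv)
    inter_iv = []
    prev_end = 0
    for s, e in gene_iv:
        if s > prev_end:
            inter_iv.append((prev_end, s))
        prev_end = e
    if prev_end < L:
        inter_iv.append((prev_end, L))
    inter_len = L - coding_len

    n_cod = int(round(plan.motif_density_coding * coding_len / 1000.0))
    n_int = int(round(plan.motif_density_intergenic * inter_len / 1000.0))
    for n, length, label in ((n_cod, coding_len, "coding"), (n_int, inter_len, "intergenic")):
        if n * 10 > length:
            raise ValueError(
                f"requested motif density infeasible: {n} sites in {length} bp of {label} DNA"
            )

    taken: list[int] = []
    cod_sites = _place_nonoverlapping(gene_iv, n_cod, rng, taken)
    int_sites = _place_nonoverlapping(inter_iv, n_int, rng, taken)

    planted = sorted(cod_sites) + sorted(int_sites)
    compartments = ["coding"] * len(cod_sites) + ["intergenic"] * len(int_sites)
    order = np.argsort(planted, kind="stable")
    sites = pd.DataFrame(
        {
            "site": np.asarray(planted)[order],
            "compartment": np.asarray(compartments)[order],
        }
    )

    protected = set()
    for p in sites["site"]:
        word = f"GA{'ACGT'[rng.integers(4)]}TC"
        for off, base in enumerate(word):
            chars[(p + off) % L] = base
            protected.add((p + off) % L)
    _scrub_pattern(chars, plan.circular, rng, set(sites["site"]), protected)

    genome = GenomeRecord(plan.contig_id, "".join(chars), circular=plan.circular)
    return genome, features, sites


def generate_methylation_plan(plan: SyntheticPlan, sites) -> pd.DataFrame:
    """Per-site per-strand methylated-population fractions.

    Non-planted sites follow the replication-timing gradient: the
    hemi-methylated population fraction h interpolates linearly in
    circular distance from the origin between ``gradient[0]`` (origin) and
    ``gradient[1]`` (terminus); the fully methylated site fraction is
    1 - h, and each strand is methylated in a fraction f = 1 - h/2 of
    chromosomes (a hemi-methylated chromosome carries the methyl mark on
    one of the two strands, evenly split across the population).
    ``n_under`` planted sites get fraction 0 on both strands and
    ``n_asym`` sites fraction 0 on one uniformly chosen strand.
    """
    plan.validate()
    sites = np.asarray(sites, dtype=int)
    if sites.size == 0:
        raise ValueError("sites must be non-empty")
    if plan.n_under + plan.n_asym > sites.size:
        raise ValueError(
            f"n_under + n_asym = {plan.n_under + plan.n_asym} exceeds number of sites ({sites.size})"
        )
    rng = plan.rng(_STREAM_METHYLATION)
    L = plan.genome_length
    d = np.abs(sites - plan.origin_position) % L
    d = np.minimum(d, L - d)
    h_ori, h_ter = plan.gradient
    h = h_ori + (h_ter - h_ori) * d / (L / 2.0)

    f = 1.0 - h / 2.0
    out = pd.DataFrame(
        {
            "site": sites,
            "hemi_fraction": h,
            "full_fraction": 1.0 - h,
            "f_plus": f,
            "f_minus": f.copy(),
            "site_class": "gradient",
            "asym_strand": "",
        }
    )
    special = rng.choice(sites.size, size=plan.n_under + plan.n_asym, replace=False)
    under = special[: plan.n_under]
    asym = special[plan.n_under :]
    out.loc[under, ["f_plus", "f_minus"]] = 0.0
    out.loc[under, "site_class"] = "under"
    strands = rng.choice(["+", "-"], size=asym.size)
    for idx, strand in zip(asym, strands):
        out.loc[idx, "f_plus" if strand == "+" else "f_minus"] = 0.0
        out.loc[idx, "site_class"] = "asym"
        out.loc[idx, "asym_strand"] = strand
    return out


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_ipd_dataset(
    genome: GenomeRecord,
    methylation: pd.DataFrame,
    plan: SyntheticPlan,
    reference: bool = False,
) -> pd.DataFrame:
    """Coverage-averaged IPD ratios at every motif adenine, both strands.

    Each sequenced molecule contributes a lognormal IPD ratio with mean
    r_full_true if its strand is methylated on that molecule (probability
    f) and mean 1 otherwise, with coefficient of variation ``ipd_cv``; the
    observed value is the mean over Poisson(coverage_mean) molecules
    (floored at one). Hence E[observed] = f * r_full_true + (1 - f).
    With ``reference=True`` all fractions are forced to 1, emulating a
    constitutively methylating calibration strain.
    """
    plan.validate()
    rng = plan.rng(_STREAM_IPD_REFERENCE if reference else _STREAM_IPD)
    ad = motif_adenines(methylation["site"].to_numpy(), length=genome.length,
                        circular=genome.circular)
    mu_m, sg_m = _lognormal_params(plan.r_full_true, plan.ipd_cv)
    mu_u, sg_u = _lognormal_params(1.0, plan.ipd_cv)

    rows = []
    frac = methylation[["f_plus", "f_minus"]].itertuples(index=False, name=None)
    for (site, plus_pos, minus_pos), (f_plus, f_minus) in zip(
        ad.itertuples(index=False, name=None), frac
    ):
        for pos, strand, f in ((plus_pos, "+", f_plus), (minus_pos, "-", f_minus)):
            if reference:
                f = 1.0
            cov = max(1, int(rng.poisson(plan.coverage_mean)))
            m = int(rng.binomial(cov, f))
            if plan.ipd_cv == 0:
                obs = (m * plan.r_full_true + (cov - m) * 1.0) / cov
            else:
                meth = rng.lognormal(mu_m, sg_m, size=m) if m else np.empty(0)
                un = rng.lognormal(mu_u, sg_u, size=cov - m) if cov - m else np.empty(0)
                obs = float(np.concatenate([meth, un]).mean())
            rows.append((genome.contig_id, int(pos), strand, float(obs), cov))
    return pd.DataFrame(rows, columns=["contig", "position", "strand", "ipd_ratio", "coverage"])


def generate_expression_dataset(
    features: pd.DataFrame,
    promoter_flags: pd.Series,
    plan: SyntheticPlan,
):
    """Replicate log2 intensity matrix with planted differential expression.

    ``round(de_fraction * n)`` genes are planted, half down- and half
    up-regulated by +/- de_effect; the probability that a motif-bearing
    gene is picked for the down set is multiplied by ``motif_de_coupling``
    (weights renormalised). Returns ``(matrix, truth)``; matrix columns
    are wt_1..wt_k then mut_1..mut_k.
    """
    plan.validate()
    rng = plan.rng(_STREAM_EXPRESSION)
    genes = features["feature_id"].tolist()
    n = len(genes)
    flags = promoter_flags.reindex(genes).fillna(False).astype(bool).to_numpy()

    n_de = int(round(plan.de_fraction * n))
    n_down = n_de // 2
    n_up = n_de - n_down
    w = np.where(flags, plan.motif_de_coupling, 1.0)
    down_idx = rng.choice(n, size=n_down, replace=False, p=w / w.sum()) if n_down else np.empty(0, int)
    rest = np.setdiff1d(np.arange(n), down_idx)
    up_idx = rng.choice(rest, size=n_up, replace=False) if n_up else np.empty(0, int)

    effect = np.zeros(n)
    effect[down_idx] = -plan.de_effect
    effect[up_idx] = plan.de_effect

    baseline = rng.normal(10.0, 1.5, size=n)
    k = plan.n_replicates
    wt = baseline[:, None] + rng.normal(0.0, plan.noise_sd, size=(n, k))
    mut = (baseline + effect)[:, None] + rng.normal(0.0, plan.noise_sd, size=(n, k))
    cols = [f"wt_{i + 1}" for i in range(k)] + [f"mut_{i + 1}" for i in range(k)]
    matrix = pd.DataFrame(np.hstack([wt, mut]), index=pd.Index(genes, name="gene_id"), columns=cols)

    planted = np.full(n, "none", dtype=object)
    planted[down_idx] = "down"
    planted[up_idx] = "up"
    truth = pd.DataFrame(
        {"gene_id": genes, "planted": planted, "effect": effect, "has_motif": flags}
    )
    return matrix, truth


DEFAULT_SET_SPECS = {
    # name: (size, overlap fraction with planted down-regulated genes)
    "CtrA_regulon": (120, 0.30),
    "DnaA_regulon": (80, 0.30),
    "GcrA_regulon": (100, 0.50),
    "cell_cycle": (200, 0.30),
    "Fur_regulon": (60, 0.0),
    "SigT_regulon": (60, 0.0),
    "FixKL_regulon": (50, 0.0),
    "heavy_metal": (50, 0.0),
    "essential": (150, 0.25),
}

COG_LETTERS = "JKLDVTMNOCGEFHIPQRS"


def generate_gene_sets(features: pd.DataFrame, de_truth: pd.DataFrame, plan: SyntheticPlan,
                       set_specs: dict | None = None):
    """Named gene sets with configurable planted overlap, plus COG labels.

    Each set of size s with overlap fraction q draws round(q*s) members
    from the planted down-regulated genes (fewer if the truth table has
    fewer) and the rest uniformly from the remaining genes. Returns
    ``(catalog, cog)`` where catalog maps set name -> set of gene ids and
    cog is a per-gene single-letter functional label Series.
    """
    plan.validate()
    rng = plan.rng(_STREAM_GENESETS)
    specs = DEFAULT_SET_SPECS if set_specs is None else set_specs
    genes = np.asarray(features["feature_id"])
    down = np.asarray(de_truth.loc[de_truth["planted"] == "down", "gene_id"])
    catalog = {}
    for name, (size, overlap) in specs.items():
        size = min(size, len(genes))
        n_ov = min(int(round(overlap * size)), len(down))
        chosen = list(rng.choice(down, size=n_ov, replace=False)) if n_ov else []
        pool = np.setdiff1d(genes, np.asarray(chosen, dtype=object))
        chosen += list(rng.choice(pool, size=size - n_ov, replace=False))
        catalog[name] = set(chosen)
    cog = pd.Series(
        rng.choice(list(COG_LETTERS), size=len(genes)), index=pd.Index(genes, name="gene_id"),
        name="cog",
    )
    return catalog, cog


def generate_ortholog_panel(
    features: pd.DataFrame,
    plan: SyntheticPlan,
    n_species: int = 5,
    conservation_probs=0.6,
) -> pd.DataFrame:
    """Bernoulli promoter-motif presence matrix across related species.

    ``conservation_probs`` is a scalar or per-gene propensity; coupling
    conservation to the focal genome's promoter motifs is achieved by
    passing e.g. ``np.where(has_motif, 0.8, 0.1)``.
    """
    plan.validate()
    rng = plan.rng(_STREAM_ORTHOLOGS)
    genes = features["feature_id"].tolist()
    p = np.broadcast_to(np.asarray(conservation_probs, dtype=float), (len(genes),))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("conservation probabilities must lie in [0, 1]")
    mat = rng.random((len(genes), n_species)) < p[:, None]
    return pd.DataFrame(
        mat, index=pd.Index(genes, name="gene_id"),
        columns=[f"species_{i + 1}" for i in range(n_species)],
    )
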