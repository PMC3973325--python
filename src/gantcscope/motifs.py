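"""Degenerate pentanucleotide counting and observed/expected statistics.

The expected genome-wide count of a motif is the product, over its non-N
positions, of the genome-wide single-base frequencies, times the genome
length; an N position contributes a factor of 1 (it matches any base).
Expected counts inside a genome partition (coding / RNA / intergenic) are
allocated proportionally to partition length, and the intergenic observed
count is defined by subtraction:

    observed[intergenic] = observed[genome] - observed[coding] - observed[rna]

which reproduces how counts in whole-genome vs gene-sequence files relate,
at the price of possibly going negative when genes overlap (a warning is
emitted in that case).
"""

from __future__ import annotations

import itertools
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeRecord, feature_sequence, validate_features

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

GANTC = "GANTC"
PARTITIONS = ("genome", "coding", "rna", "intergenic")


def _check_pattern(pattern: str) -> str:
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC letters in pattern: {sorted(bad)!r}")
    return pattern


def scan_motif(seq: str, pattern: str, circular: bool = False) -> list[int]:
    """0-based start positions of all (overlapping) IUPAC matches.

    On circular sequences, matches spanning the end-start junction are
    reported once, at their start position. Windows containing N never
    match (IUPAC classes expand to concrete bases only).
    """
    pattern = _check_pattern(pattern)
    seq = seq.upper()
    k = len(pattern)
    if len(seq) < k:
        return []
    regex = "".join(f"[{IUPAC[c]}]" for c in pattern)
    ext = seq + seq[: k - 1] if circular else seq
    return [m.start() for m in re.finditer(f"(?={regex})", ext)]


def base_frequencies(genome: GenomeRecord | str) -> dict[str, float]:
    """Genome-wide A/C/G/T frequencies; N bases excluded entirely."""
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    counts = Counter(seq)
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    return {b: counts[b] / total for b in "ACGT"}


def expected_count_genome(pattern: str, freqs: dict[str, float], genome_length: int) -> float:
    """Expected motif count under the single-base composition null."""
    pattern = _check_pattern(pattern)
    prod = 1.0
    for letter in pattern:
        prod *= sum(freqs[b] for b in IUPAC[letter])
    return prod * genome_length


def expected_count_subsequence(sub_length: int, genome_length: int, total_observed: float) -> float:
    """Length-proportional allocation of the genome total to a partition."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return (sub_length / genome_length) * total_observed


@dataclass
class PartitionCounts:
    """Observed and expected counts of one pattern across genome partitions."""

    pattern: str
    observed: dict
    expected: dict
    base_freq: dict
    genome_length: int
    lengths: dict = field(default_factory=dict)

    @property
    def ratios(self) -> dict:
        return {
            k: (self.observed[k] / self.expected[k] if self.expected[k] > 0 else float("nan"))
            for k in self.observed
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pattern": self.pattern,
                "partition": part,
                "length": self.lengths.get(part, np.nan),
                "observed": self.observed[part],
                "expected": self.expected[part],
                "obs_exp_ratio": self.ratios[part],
            }
            for part in PARTITIONS
        ]
        return pd.DataFrame(rows)


def partition_counts(genome: GenomeRecord, features: pd.DataFrame, pattern: str = GANTC) -> PartitionCounts:
    """Count a pattern genome-wide and in coding/RNA partitions.

    Features are extracted 5'->3' on their own strand and counted
    individually (no artificial junctions between concatenated genes).
    """
    pattern = _check_pattern(pattern)
    validate_features(features, genome)
    L = genome.length

    obs_genome = len(scan_motif(genome.sequence, pattern, genome.circular))
    obs = {"genome": obs_genome, "coding": 0, "rna": 0}
    lengths = {"genome": L, "coding": 0, "rna": 0}
    class_to_part = {"protein_coding": "coding", "rna": "rna"}
    for row in features.itertuples(index=False):
        part = class_to_part.get(row.kind)
        if part is None:
            continue
        seq = feature_sequence(genome, row)
        obs[part] += len(scan_motif(seq, pattern, circular=False))
        lengths[part] += row.end - row.start

    obs["intergenic"] = obs["genome"] - obs["coding"] - obs["rna"]
    lengths["intergenic"] = L - lengths["coding"] - lengths["rna"]
    if obs["intergenic"] < 0:
        warnings.warn(
            f"negative intergenic count ({obs['intergenic']}) for {pattern}: "
            "overlapping genes double-count motifs",
            stacklevel=2,
        )

    freqs = base_frequencies(genome)
    expected = {"genome": expected_count_genome(pattern, freqs, L)}
    for part in ("coding", "rna", "intergenic"):
        expected[part] = expected_count_subsequence(lengths[part], L, obs_genome)

    return PartitionCounts(pattern, obs, expected, freqs, L, lengths)


def enumerate_gantc_like() -> list[str]:
    """The 24 pentanucleotides X1 X2 N X3 X4 with {X1..X4} a permutation of ACGT."""
    pats = {
        f"{a}{b}N{c}{d}" for a, b, c, d in itertools.permutations("ACGT")
    }
    return sorted(pats)


def species_panel_summary(panel, pattern: str = GANTC, groups=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Obs/exp ratios per genome plus group quartiles.

    Parameters
    ----------
    panel : list of (GenomeRecord, FeatureTable)
    groups : optional list of group labels, same length as ``panel``

    Returns
    -------
    (per_genome, summary) : per-genome ratio table and per-group
    Q1/median/Q3 of each partition's obs/exp ratio.
    """
    if groups is None:
        groups = ["all"] * len(panel)
    rows = []
    for (genome, features), group in zip(panel, groups):
        pc = partition_counts(genome, features, pattern)
        ratios = pc.ratios
        rows.append(
            {
                "contig": genome.contig_id,
                "group": group,
                "pattern": pc.pattern,
                "ratio_genome": ratios["genome"],
                "ratio_coding": ratios["coding"],
                "ratio_intergenic": ratios["intergenic"],
            }
        )
    per_genome = pd.DataFrame(rows)
    summaries = []
    for group, sub in per_genome.groupby("group", sort=False):
        for col in ("ratio_genome", "ratio_coding", "ratio_intergenic"):
            q1, med, q3 = np.quantile(sub[col].to_numpy(), [0.25, 0.5, 0.75])
            summaries.append(
                {"group": group, "statistic": col, "q1": q1, "median": med, "q3": q3}
            )
    return per_genome, pd.DataFrame(summaries)
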