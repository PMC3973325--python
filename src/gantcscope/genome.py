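"""Genome sequences and gene feature tables.

Coordinates are 0-based half-open everywhere inside the package; the GFF3
boundary (1-based inclusive) is converted in :mod:`gantcscope.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: feature classes the pipeline distinguishes
FEATURE_CLASSES = ("protein_coding", "rna", "other")

FEATURE_COLUMNS = ["feature_id", "contig", "start", "end", "strand", "kind"]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """A single contig, optionally circular.

    Parameters
    ----------
    contig_id : str
        Sequence identifier (e.g. a RefSeq accession).
    sequence : str
        Upper-case A/C/G/T/N sequence.
    circular : bool
        Whether coordinates wrap at the origin (bacterial chromosome).
    """

    contig_id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"invalid characters in sequence: {sorted(bad)!r}")
        if self.length:
            n_frac = self.sequence.count("N") / self.length
            if n_frac >= 0.10:
                warnings.warn(
                    f"{self.contig_id}: {n_frac:.0%} of bases are N; "
                    "motif statistics may be unreliable",
                    stacklevel=2,
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)``; wraps on circular contigs.

        ``start`` may be negative and ``end`` may exceed the length on a
        circular contig, as long as ``end - start <= length``.
        """
        L = self.length
        n = end - start
        if n < 0 or n > L:
            raise ValueError(f"bad interval [{start}, {end}) on contig of length {L}")
        if 0 <= start and end <= L:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError(
                f"interval [{start}, {end}) outside linear contig of length {L}"
            )
        s = start % L
        if s + n <= L:
            return self.sequence[s : s + n]
        return self.sequence[s:] + self.sequence[: s + n - L]


def make_feature_table(rows) -> pd.DataFrame:
    """Build a feature table from an iterable of dicts or tuples.

    Columns: feature_id, contig, start, end (0-based half-open), strand
    ('+'/'-'), kind ('protein_coding'/'rna'/'other').
    """
    df = pd.DataFrame(list(rows), columns=FEATURE_COLUMNS)
    return df


def validate_features(features: pd.DataFrame, genome: GenomeRecord) -> None:
    """Raise ``ValueError`` naming the first offending feature, if any."""
    L = genome.length
    for row in features.itertuples(index=False):
        if row.contig != genome.contig_id:
            raise ValueError(
                f"feature {row.feature_id}: contig {row.contig!r} does not match "
                f"genome {genome.contig_id!r}"
            )
        if row.start >= row.end:
            raise ValueError(f"feature {row.feature_id}: start >= end")
        wrapped = genome.circular and row.end > L
        if row.start < 0 or (not wrapped and row.end > L) or (wrapped and row.end - row.start > L):
            raise ValueError(
                f"feature {row.feature_id}: interval [{row.start}, {row.end}) "
                f"outside contig of length {L}"
            )
        if row.strand not in ("+", "-"):
            raise ValueError(f"feature {row.feature_id}: bad strand {row.strand!r}")
        if row.kind not in FEATURE_CLASSES:
            raise ValueError(f"feature {row.feature_id}: unknown class {row.kind!r}")


def feature_sequence(genome: GenomeRecord, row) -> str:
    """5'->3' sequence of a feature on its own strand."""
    seq = genome.fetch(row.start, row.end)
    return reverse_complement(seq) if row.strand == "-" else seq


def circular_distance(pos, origin: int, length: int):
    """Shortest distance along a circle of given length (vectorised)."""
    import numpy as np

    d = np.abs(np.asarray(pos) - origin) % length
    return np.minimum(d, length - d)
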