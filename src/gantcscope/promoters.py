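"""Promoter extraction, promoter-motif flags and conservation counts.

A "promoter" here is simply the fixed window immediately upstream of a
gene's annotated translational start codon (200 bp by default), applied
uniformly regardless of upstream gene overlap. A motif counts as "in the
promoter" when its forward-strand 5' start coordinate lies within the
window, which makes boundary-straddling occurrences unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeRecord
from .motifs import GANTC, scan_motif


@dataclass
class PromoterRecord:
    gene_id: str
    contig: str
    strand: str
    segments: list  # list of (start, end) 0-based half-open, forward coords
    truncated: bool = False
    motif_positions: list = field(default_factory=list)

    @property
    def has_motif(self) -> bool:
        return len(self.motif_positions) > 0

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)


def _split_circular(start: int, end: int, L: int) -> list[tuple[int, int]]:
    """Normalise an interval that may run off either end of a circle."""
    n = end - start
    start = int(start) % L
    end = start + n
    if end <= L:
        return [(start, end)]
    return [(start, L), (0, end - L)]


def extract_promoter(feature, genome: GenomeRecord, promoter_length: int = 200) -> PromoterRecord:
    """Window upstream of the translational start, strand-aware.

    '+' strand gene starting at g: [g - len, g); '-' strand gene ending at
    e (half-open): [e, e + len). Circular contigs wrap (two segments when
    the window crosses the junction); linear contigs truncate at the edge
    with a warning.
    """
    if promoter_length <= 0:
        raise ValueError("promoter_length must be positive")
    L = genome.length
    if feature.strand == "+":
        lo, hi = feature.start - promoter_length, feature.start
    else:
        lo, hi = feature.end, feature.end + promoter_length

    truncated = False
    if genome.circular:
        segments = _split_circular(lo, hi, L)
    else:
        clo, chi = max(lo, 0), min(hi, L)
        if (clo, chi) != (lo, hi):
            truncated = True
            warnings.warn(
                f"promoter of {feature.feature_id} truncated at contig edge "
                f"({chi - clo} of {promoter_length} bp)",
                stacklevel=2,
            )
        segments = [(clo, chi)] if chi > clo else []
    return PromoterRecord(
        gene_id=feature.feature_id,
        contig=feature.contig,
        strand=feature.strand,
        segments=segments,
        truncated=truncated,
    )


def promoter_sequence(record: PromoterRecord, genome: GenomeRecord) -> str:
    return "".join(genome.fetch(s, e) for s, e in record.segments)


def promoter_motif_flags(
    features: pd.DataFrame,
    genome: GenomeRecord,
    pattern: str = GANTC,
    promoter_length: int = 200,
) -> pd.DataFrame:
    """Per-gene promoter motif presence table.

    The window plus ``len(pattern) - 1`` downstream bases is scanned so
    that occurrences starting inside the window but extending past its
    gene-proximal edge are found; only starts inside the window count.
    For the palindromic GANTC a forward-strand scan suffices; other
    patterns are scanned on the forward strand only and the convention is
    the recorded forward-start one.
    """
    k = len(pattern)
    L = genome.length
    rows = []
    for feature in features.itertuples(index=False):
        rec = extract_promoter(feature, genome, promoter_length)
        if not rec.segments:
            rows.append(
                {"gene_id": rec.gene_id, "strand": rec.strand, "n_motifs": 0,
                 "has_motif": False, "motif_positions": "", "truncated": rec.truncated}
            )
            continue
        w_start = rec.segments[0][0]
        w_len = rec.length
        # fetch window + k-1 extra downstream bases (toward the gene)
        ext_len = w_len + (k - 1)
        if genome.circular:
            seq = genome.fetch(w_start, w_start + min(ext_len, L))
        else:
            seq = genome.fetch(w_start, min(w_start + ext_len, L))
        hits_rel = [p for p in scan_motif(seq, pattern) if p < w_len]
        hits_abs = [(w_start + p) % L if genome.circular else w_start + p for p in hits_rel]
        rec.motif_positions = hits_abs
        rows.append(
            {
                "gene_id": rec.gene_id,
                "strand": rec.strand,
                "n_motifs": len(hits_abs),
                "has_motif": len(hits_abs) > 0,
                "motif_positions": ";".join(str(p) for p in hits_abs),
                "truncated": rec.truncated,
            }
        )
    return pd.DataFrame(rows)


def conservation_counts(focal_flags: pd.Series, panel: pd.DataFrame) -> pd.DataFrame:
    """Number of species whose orthologous promoter carries the motif.

    ``panel`` is a gene x species boolean presence matrix (the focal
    species may be one of its columns); the count is the row sum.
    ``focal_flags`` is used only to check gene-id alignment.
    """
    if not panel.index.equals(focal_flags.index):
        missing = panel.index.symmetric_difference(focal_flags.index)
        raise ValueError(f"gene ids of panel and focal flags differ: {list(missing)[:5]}")
    counts = panel.astype(bool).sum(axis=1).astype(int)
    out = panel.astype(bool).copy()
    out.insert(0, "focal_has_motif", focal_flags.astype(bool))
    out["conservation_count"] = counts
    return out
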