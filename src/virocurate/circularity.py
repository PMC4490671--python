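"""Scaffold circularity detection from paired-read mappings.

A scaffold assembled from a circular (or circularly permuted) genome
shows a characteristic mapping signature: read pairs whose fragment
crossed the assembly origin map with one mate near each end of the
linearised scaffold, far beyond any plausible insert size. Detection
proceeds in two steps mirroring a bowtie2 + samtools workflow:

1. pairs are partitioned into concordant and discordant by their
   apparent span on the scaffold (discordant when the outermost
   mate-to-mate distance exceeds 900 bp, i.e. beyond the 0-900 bp
   paired-distance range used for mapping);
2. a discordant pair counts as *circularly mapped* when one mate's
   alignment lies entirely within the first ``end_window`` (1000 bp)
   of the scaffold and the other entirely within the last. Three or
   more such pairs call the scaffold circular.

Circular genomes assembled with duplicated termini are caught
independently by an exact terminal-overlap scan.

Mate containment uses the full alignment interval (not the midpoint),
and read orientation is not required by default; a strict FR mode is
available via ``require_fr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

ALIGNMENT_COLUMNS = ["pair_id", "scaffold_id", "mate1_start", "mate1_len",
                     "strand1", "mate2_start", "mate2_len", "strand2",
                     "apparent_span"]


@dataclass(frozen=True)
class CircularityCall:
    scaffold_id: str
    n_circular_pairs: int
    is_circular: bool
    method: str  # "spanning-pairs", "terminal-overlap", "both" or "none"
    short_scaffold: bool = False


def read_paired_alignments(sam_path) -> pd.DataFrame:
    """Collect per-pair alignment records from a SAM/BAM file.

    Pairs whose mates map to different scaffolds are excluded (counted in
    a warning); so are unmapped and secondary/supplementary records. The
    apparent span is the outermost distance between the two alignment
    intervals on the linearised scaffold.
    """
    import pysam

    mates: dict[str, tuple[str, int, int, str]] = {}
    rows = []
    cross = 0
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                    or not rec.is_paired):
                continue
            start = rec.reference_start + 1
            length = rec.reference_end - rec.reference_start
            strand = "-" if rec.is_reverse else "+"
            entry = (rec.reference_name, start, length, strand)
            if rec.query_name in mates:
                ref1, s1, l1, st1 = mates.pop(rec.query_name)
                if ref1 != rec.reference_name:
                    cross += 1
                    continue
                e1, e2 = s1 + l1 - 1, start + length - 1
                span = max(e1, e2) - min(s1, start) + 1
                rows.append((rec.query_name, ref1, s1, l1, st1,
                             start, length, strand, span))
            else:
                mates[rec.query_name] = entry
    if cross:
        warnings.warn(f"{cross} pairs with mates on different scaffolds "
                      "were excluded")
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def classify_pairs(alignments: pd.DataFrame, max_concordant: int = 900,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition pairs into (concordant, discordant) by apparent span.

    A pair is discordant iff its apparent span strictly exceeds
    ``max_concordant`` (900 bp: the upper end of the mapping distance
    range, chosen comfortably above the insert-size distribution).
    """
    if not len(alignments):
        empty = alignments.iloc[0:0]
        return empty.copy(), empty.copy()
    disc = alignments["apparent_span"] > max_concordant
    return (alignments.loc[~disc].reset_index(drop=True),
            alignments.loc[disc].reset_index(drop=True))


def detect_circular(scaffold_id: str, scaffold_len: int,
                    discordant: pd.DataFrame, end_window: int = 1000,
                    min_pairs: int = 3, require_fr: bool = False,
                    ) -> CircularityCall:
    """Call circularity from end-spanning discordant pairs.

    A discordant pair is circularly mapped when one mate's alignment lies
    entirely within [1, end_window] and the other's entirely within
    [scaffold_len - end_window + 1, scaffold_len]. For scaffolds shorter
    than twice the window, the windows are truncated at the midpoint and
    the call flagged ``short_scaffold``.
    """
    short = scaffold_len <= 2 * end_window
    w = min(end_window, scaffold_len // 2)
    lo_end = w
    hi_start = scaffold_len - w + 1

    n = 0
    if len(discordant):
        sub = discordant[discordant["scaffold_id"] == scaffold_id]
        for row in sub.itertuples(index=False):
            a = (row.mate1_start, row.mate1_start + row.mate1_len - 1,
                 row.strand1)
            b = (row.mate2_start, row.mate2_start + row.mate2_len - 1,
                 row.strand2)
            for first, second in ((a, b), (b, a)):
                if first[1] <= lo_end and second[0] >= hi_start:
                    if require_fr and not (first[2] == "-"
                                           and second[2] == "+"):
                        continue
                    n += 1
                    break
    return CircularityCall(scaffold_id=scaffold_id, n_circular_pairs=n,
                           is_circular=n >= min_pairs,
                           method="spanning-pairs" if n >= min_pairs
                           else "none",
                           short_scaffold=short)


def detect_terminal_overlap(sequence: str, min_overlap: int = 20,
                            ) -> int | None:
    """Longest exact direct repeat shared by the scaffold's two ends.

    Returns the overlap length (>= min_overlap) or None. Overlaps longer
    than half the sequence are not considered.
    """
    seq = sequence.upper()
    n = len(seq)
    if n <= 2 * min_overlap:
        raise ValueError("sequence shorter than twice the minimum overlap")
    for k in range(n // 2, min_overlap - 1, -1):
        if seq[:k] == seq[-k:]:
            return k
    return None


def call_scaffolds(alignments: pd.DataFrame,
                   scaffold_lengths: dict[str, int],
                   sequences: dict[str, str] | None = None,
                   max_concordant: int = 900, end_window: int = 1000,
                   min_pairs: int = 3, min_overlap: int = 20,
                   ) -> pd.DataFrame:
    """Circularity calls for every scaffold, combining both detectors."""
    _, discordant = classify_pairs(alignments, max_concordant)
    rows = []
    for sid, length in sorted(scaffold_lengths.items()):
        call = detect_circular(sid, length, discordant,
                               end_window=end_window, min_pairs=min_pairs)
        overlap = None
        if sequences and sid in sequences and length > 2 * min_overlap:
            overlap = detect_terminal_overlap(sequences[sid], min_overlap)
        method = call.method
        if overlap is not None:
            method = "both" if call.is_circular else "terminal-overlap"
        rows.append({"scaffold_id": sid,
                     "n_circular_pairs": call.n_circular_pairs,
                     "terminal_overlap": 0 if overlap is None else overlap,
                     "is_circular": call.is_circular or overlap is not None,
                     "method": method if (call.is_circular or overlap)
                     else "none",
                     "short_scaffold": call.short_scaffold})
    return pd.DataFrame(rows)
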