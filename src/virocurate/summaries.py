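"""Virome-level reporting: subsampling, composition, read-fraction tables.

Percentages follow the mixed precision conventional in virome reports:
values >= 1% to one decimal place, values < 1% to two, with an
integer-percent mode for headline figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def format_percent(numerator: float, denominator: float,
                   mode: str = "mixed") -> float:
    """Percentage with report-style rounding.

    mode="mixed": >=1% to 1 d.p., <1% to 2 d.p.; mode="1dp" always one
    decimal; mode="int" to the nearest whole percent. Half values round
    up, matching how the source tables print.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    pct = 100.0 * numerator / denominator
    if mode == "int":
        quant = "1"
    elif mode == "1dp" or (mode == "mixed" and pct >= 1.0):
        quant = "0.1"
    elif mode in ("2dp", "mixed"):
        quant = "0.01"
    else:
        raise ValueError(f"unknown rounding mode: {mode!r}")
    return float(Decimal(pct).quantize(Decimal(quant),
                                       rounding=ROUND_HALF_UP))


@dataclass
class ViromeStats:
    """Read-mapping bookkeeping for one virome."""

    virome: str
    total_reads: int
    reads_mapped_candidates: int
    reads_mapped_viral: int
    reads_mapped_other: int
    per_scaffold: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.reads_mapped_viral + self.reads_mapped_other
                != self.reads_mapped_candidates):
            raise ValueError("viral + other mapped reads must equal the "
                             "candidate-mapped total")
        for name in ("reads_mapped_candidates", "reads_mapped_viral",
                     "reads_mapped_other"):
            if getattr(self, name) > self.total_reads:
                raise ValueError(f"{name} exceeds total_reads")


def subsample_reads(reads: list, fraction: float, seed: int,
                    mode: str = "exact", paired: bool = False) -> list:
    """Random subsample of a read set (or of read pairs).

    mode="exact" keeps round(n * fraction) reads without replacement;
    mode="bernoulli" keeps each read independently with probability
    ``fraction``. With ``paired=True`` the elements of ``reads`` are
    treated as units (mates kept or dropped together). Deterministic for
    a fixed seed.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    del paired  # units are whatever the caller passes: reads or pairs
    if fraction == 1.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    n = len(reads)
    if mode == "exact":
        k = int(round(n * fraction))
        keep = np.sort(rng.choice(n, size=k, replace=False))
    elif mode == "bernoulli":
        keep = np.nonzero(rng.random(n) < fraction)[0]
    else:
        raise ValueError(f"unknown subsampling mode: {mode!r}")
    return [reads[i] for i in keep]


def normalize_composition(hits: dict[str, int],
                          genome_lengths: dict[str, int]) -> pd.DataFrame:
    """Genome-length-normalised taxonomic composition.

    Raw hit counts are biased toward long genomes (more sequence to hit),
    so each virotype's count is divided by its genome length before
    renormalising to sum to one.
    """
    rows = []
    for virotype, count in hits.items():
        length = genome_lengths.get(virotype, 0)
        if length <= 0:
            raise ValueError(f"virotype {virotype!r} lacks a positive "
                             "genome length")
        rows.append((virotype, count, length, count / length))
    df = pd.DataFrame(rows, columns=["virotype", "hit_count",
                                     "genome_length", "density"])
    total = df["density"].sum()
    if total == 0:
        raise ValueError("no hits to normalise")
    df["normalized_abundance"] = df["density"] / total
    return df.drop(columns="density")


def read_fraction_report(stats: ViromeStats,
                         highlights: dict[str, int] | None = None,
                         ) -> pd.DataFrame:
    """Read-fraction percentage table for one virome.

    Emits the candidate-mapped and viral-mapped fractions of all reads,
    the viral share of candidate-mapped reads, and, for each highlighted
    scaffold, its share of all reads (mixed precision) and of
    viral-mapped reads (mixed precision plus a whole-percent headline).
    """
    rows = []

    def _entry(label, num, den, mode="mixed"):
        if den == 0:
            warnings.warn(f"suppressing {label!r}: zero denominator")
            return
        rows.append({"quantity": label, "numerator": int(num),
                     "denominator": int(den),
                     "percent": format_percent(num, den, mode)})

    t = stats.total_reads
    _entry("candidate_mapped_of_total", stats.reads_mapped_candidates, t)
    _entry("viral_mapped_of_total", stats.reads_mapped_viral, t)
    _entry("other_mapped_of_total", stats.reads_mapped_other, t)
    _entry("viral_share_of_candidate_mapped", stats.reads_mapped_viral,
           stats.reads_mapped_candidates)
    for sid, count in (highlights or {}).items():
        _entry(f"{sid}_of_total", count, t)
        _entry(f"{sid}_of_viral_mapped", count, stats.reads_mapped_viral)
        _entry(f"{sid}_of_viral_mapped_headline", count,
               stats.reads_mapped_viral, mode="int")
    return pd.DataFrame(rows)
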