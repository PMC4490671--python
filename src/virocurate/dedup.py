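"""Pooling of multi-k-mer assemblies and redundancy removal.

No single k-mer length assembles every genome best, so each virome is
assembled several times and the contig sets pooled. Pooling creates
redundancy — the same genome assembled at two k-mer lengths — which is
removed by an all-vs-all self-comparison (Megablast-style, word size
100, >=97% identity, E <= 1e-5) followed by a single greedy sweep in
descending length order: a contig is discarded when it has a qualifying
hit (>1000 bp aligned, >=97% identity) to a strictly longer contig that
is itself still retained at the moment the sweep reaches it. Matching
against the *currently retained* set (rather than all longer contigs)
prevents cascade removal through contigs that were themselves discarded;
the all-larger behaviour is available via ``retained_only=False``.

After circularity calls are available, a length/coverage gate keeps
linear contigs >= 15 kb and circular contigs >= 10 kb with >= 10-fold
coverage as the candidate set for viral triage.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

BLAST_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                 "gapopen", "qstart", "qend", "sstart", "send",
                 "evalue", "bitscore"]


@dataclass(frozen=True)
class Contig:
    id: str
    length: int
    virome: str = ""
    kmer: int = 0
    coverage: float = 0.0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"{self.id}: length field ({self.length}) "
                             f"disagrees with sequence ({len(self.sequence)})")
        if self.length < 1000:
            raise ValueError(f"{self.id}: contigs below the 1000 bp assembly "
                             "cut-off are not admissible")


def _sort_key(c: Contig):
    return (-c.length, c.id)


def pool_assemblies(assemblies: list[list[Contig]],
                    min_len: int = 5000) -> list[Contig]:
    """Concatenate per-k-mer assemblies, keep contigs >= min_len.

    Output is sorted by descending length (ties by id, ascending), the
    order the redundancy sweep requires. Contig ids must be unique across
    assemblies (namespace them by k-mer upstream).
    """
    pooled = [c for asm in assemblies for c in asm if c.length >= min_len]
    ids = [c.id for c in pooled]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids across assemblies: {dupes}")
    return sorted(pooled, key=_sort_key)


def remove_redundancy(pooled: list[Contig], hits: pd.DataFrame,
                      min_aln: int = 1000, min_ident: float = 97.0,
                      max_e: float = 1e-5, retained_only: bool = True,
                      ) -> tuple[list[Contig], pd.DataFrame]:
    """Greedy descending-length sweep removing contigs matching larger ones.

    ``hits`` is a 12-column self-comparison table (self-vs-self rows are
    ignored). A hit qualifies per HSP: aligned length > min_aln AND
    identity >= min_ident AND E <= max_e; multiple shorter HSPs never sum
    to a qualifying match. Equal-length mutual pairs keep the
    lexicographically earlier id. Returns the retained contigs (same
    order) and a removal log of (removed, kept, hit length/identity).
    """
    by_id = {c.id: c for c in pooled}
    partners: dict[str, list[tuple[str, int, float]]] = {c.id: []
                                                         for c in pooled}
    if len(hits):
        for row in hits.itertuples(index=False):
            q, s = str(row.qseqid), str(row.sseqid)
            if q == s:
                continue
            if q not in by_id or s not in by_id:
                raise ValueError(f"hit references unknown contig: {q}/{s}")
            if (row.length > min_aln and row.pident >= min_ident
                    and row.evalue <= max_e):
                partners[q].append((s, int(row.length), float(row.pident)))
                partners[s].append((q, int(row.length), float(row.pident)))

    order = sorted(pooled, key=_sort_key)
    retained: list[Contig] = []
    retained_ids: set[str] = set()
    log_rows = []
    for c in order:
        removed_by = None
        for pid, alen, ident in sorted(partners[c.id]):
            p = by_id[pid]
            larger = (p.length > c.length
                      or (p.length == c.length and p.id < c.id))
            if not larger:
                continue
            if retained_only and pid not in retained_ids:
                continue
            removed_by = (pid, alen, ident)
            break
        if removed_by is None:
            retained.append(c)
            retained_ids.add(c.id)
        else:
            log_rows.append({"removed": c.id, "kept": removed_by[0],
                             "aln_length": removed_by[1],
                             "identity": removed_by[2]})
    log = pd.DataFrame(log_rows, columns=["removed", "kept", "aln_length",
                                          "identity"])
    return retained, log


def length_gate(contigs: list[Contig], circular_flags: dict[str, bool],
                linear_min: int = 15_000, circular_min: int = 10_000,
                min_coverage: float = 10.0,
                ) -> tuple[list[Contig], pd.DataFrame]:
    """Candidate gate: linear >= 15 kb, circular >= 10 kb, coverage >= 10x.

    Returns the candidate contigs plus a table of rejections with reasons
    (low coverage is reported even when the length gate also fails).
    """
    candidates, rejects = [], []
    for c in contigs:
        is_circ = bool(circular_flags.get(c.id, False))
        reasons = []
        if c.coverage < min_coverage:
            reasons.append("low_coverage")
        min_needed = circular_min if is_circ else linear_min
        if c.length < min_needed:
            reasons.append("below_length_gate")
        if reasons:
            rejects.append({"contig_id": c.id, "is_circular": is_circ,
                            "length": c.length, "coverage": c.coverage,
                            "reason": ";".join(reasons)})
        else:
            candidates.append(c)
    return candidates, pd.DataFrame(
        rejects, columns=["contig_id", "is_circular", "length", "coverage",
                          "reason"])


def find_exact_containments(contigs: list[Contig], min_len: int = 1000,
                            word: int = 100) -> pd.DataFrame:
    """Naive exact-substring self-comparison (test oracle only).

    Reports a 100%-identity hit row whenever a seed ``word``-mer of a
    smaller contig occurs in a larger one and extends to >= min_len.
    Quadratic; intended for planted-redundancy fixtures, not real data.
    """
    rows = []
    ordered = sorted([c for c in contigs if c.sequence is not None],
                     key=_sort_key)
    for i, big in enumerate(ordered):
        for small in ordered[i + 1:]:
            seq, sub = big.sequence.upper(), small.sequence.upper()
            if len(sub) < min_len:
                continue
            best = None
            step = max(1, word)
            for qs in range(0, len(sub) - word + 1, step):
                pos = seq.find(sub[qs:qs + word])
                while pos != -1:
                    a, b = qs, pos
                    while a > 0 and b > 0 and sub[a - 1] == seq[b - 1]:
                        a, b = a - 1, b - 1
                    ea, eb = qs + word, pos + word
                    while (ea < len(sub) and eb < len(seq)
                           and sub[ea] == seq[eb]):
                        ea, eb = ea + 1, eb + 1
                    ln = ea - a
                    if best is None or ln > best[0]:
                        best = (ln, a, b)
                    pos = seq.find(sub[qs:qs + word], pos + 1)
            if best and best[0] >= min_len:
                ln, a, b = best
                rows.append((small.id, big.id, 100.0, ln, 0, 0, a + 1,
                             a + ln, b + 1, b + ln, 0.0, 2.0 * ln))
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)
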