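"""Putative host assignment and CRISPR spacer cross-matching.

Temperate phages that integrate into a host chromosome carry an
attachment site (attP) that is an exact copy of part of a host tRNA gene
(attB). An exact, 100%-identity match between a virus scaffold and a
taxon-annotated tRNA database therefore points at the host lineage — but
only for scaffolds that actually encode an integrase, so assignment is
gated on integrase annotation. Because tRNA genes are conserved across
species, assignments are capped at a broad rank (phylum or class).

CRISPR arrays carried on phage genomes are cross-matched against the
assembled virome: an exact, full-length spacer occurrence on another
scaffold links the array's carrier to a phage it (or its host) has
encountered. Array *detection* is an upstream input; this module only
matches the given spacers.

Matching is exact on both strands (seed table + maximal extension),
which reproduces what a BLASTN search filtered at 100% identity reports
for ungapped exact hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TRNAGene:
    """A tRNA gene with its source lineage (at least phylum and class)."""

    id: str
    phylum: str
    taxon_class: str
    sequence: str

    def __post_init__(self) -> None:
        if not 50 <= len(self.sequence) <= 200:
            warnings.warn(f"tRNA {self.id} length {len(self.sequence)} "
                          "outside the typical 50-200 bp range")


@dataclass
class CRISPRArray:
    """A repeat-spacer array located on one scaffold (coordinates 1-based)."""

    array_id: str
    scaffold_id: str
    repeat_consensus: str
    spacers: list[str]
    spacer_coords: list[tuple[int, int]] = field(default_factory=list)
    locus_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.spacers) < 1:
            raise ValueError("a CRISPR array must contain at least one spacer")


ATTP_COLUMNS = ["scaffold_id", "trna_id", "match_len", "scaffold_start",
                "scaffold_end", "trna_start", "trna_end", "strand"]

SPACER_COLUMNS = ["array_id", "array_scaffold", "spacer_index",
                  "target_scaffold", "target_start", "target_end",
                  "strand", "match_len"]


def find_attp(scaffolds: dict[str, str], trna_db: list[TRNAGene],
              min_len: int = 25) -> pd.DataFrame:
    """Find all maximal 100%-identity matches >= min_len bp, both strands.

    A single seed table over every tRNA (forward and reverse-complement)
    is built once, so each scaffold is scanned in one pass regardless of
    database size. Coordinates are 1-based on the forward scaffold; for
    '-' strand matches the tRNA interval refers to the forward tRNA
    sequence.
    """
    k = min_len
    probes: list[tuple[TRNAGene, str, str]] = []
    index: dict[str, list[tuple[int, int]]] = {}
    for trna in trna_db:
        fwd = trna.sequence.upper()
        for strand, probe in (("+", fwd), ("-", revcomp(fwd))):
            if len(probe) < k:
                continue
            pi = len(probes)
            probes.append((trna, strand, probe))
            for i in range(len(probe) - k + 1):
                index.setdefault(probe[i:i + k], []).append((pi, i))

    rows = []
    for sid, seq in scaffolds.items():
        seq = seq.upper()
        seen: set[tuple[int, int, int]] = set()
        for s in range(len(seq) - k + 1):
            for pi, p in index.get(seq[s:s + k], ()):
                trna, strand, probe = probes[pi]
                a, b = s, p
                while a > 0 and b > 0 and seq[a - 1] == probe[b - 1]:
                    a -= 1
                    b -= 1
                e_s, e_p = s + k, p + k
                while (e_s < len(seq) and e_p < len(probe)
                       and seq[e_s] == probe[e_p]):
                    e_s += 1
                    e_p += 1
                key = (pi, a, b)
                if key in seen:
                    continue
                seen.add(key)
                ln = e_s - a
                if strand == "+":
                    t_start, t_end = b + 1, b + ln
                else:
                    t_end = len(probe) - b
                    t_start = t_end - ln + 1
                rows.append((sid, trna.id, ln, a + 1, a + ln,
                             t_start, t_end, strand))
    return pd.DataFrame(rows, columns=ATTP_COLUMNS)


def assign_hosts(matches: pd.DataFrame, gene_annotations: pd.DataFrame,
                 trna_db: list[TRNAGene], rank_cap: str = "class",
                 integrase_keywords: tuple[str, ...] = ("integrase",),
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn attP/tRNA matches into host assignments, gated on integrase.

    ``gene_annotations`` is a GFF3-style table whose ``attributes`` column
    is scanned for the integrase keywords. Returns ``(assignments,
    unassigned)``: matches on scaffolds lacking an integrase gene are
    reported in the side table, never assigned. Scaffolds matching tRNAs
    from more than one phylum are flagged ambiguous (all taxa reported).
    """
    taxa = {t.id: (t.phylum, t.taxon_class) for t in trna_db}
    has_integrase: dict[str, str] = {}
    if len(gene_annotations):
        for row in gene_annotations.itertuples(index=False):
            attrs = str(row.attributes).lower()
            if any(k in attrs for k in integrase_keywords):
                gid = ""
                for fieldv in str(row.attributes).split(";"):
                    if fieldv.startswith("ID="):
                        gid = fieldv[3:]
                has_integrase.setdefault(row.seqid, gid)

    assigned, side = [], []
    if not len(matches):
        return (pd.DataFrame(columns=["scaffold_id", "host_taxon", "rank",
                                      "trna_id", "match_len",
                                      "integrase_gene", "ambiguous"]),
                pd.DataFrame(columns=list(matches.columns) + ["reason"]))
    for sid, grp in matches.groupby("scaffold_id", sort=True):
        if sid not in has_integrase:
            for _, m in grp.iterrows():
                side.append({**m.to_dict(), "reason": "no integrase gene"})
            continue
        phyla = {taxa[t][0] for t in grp["trna_id"] if t in taxa}
        ambiguous = len(phyla) > 1
        best = grp.sort_values(["match_len", "trna_id"],
                               ascending=[False, True])
        reported: set[str] = set()
        for _, m in best.iterrows():
            phylum, cls = taxa.get(m["trna_id"], ("unknown", "unknown"))
            taxon = cls if rank_cap == "class" and cls else phylum
            if taxon in reported:
                continue
            reported.add(taxon)
            assigned.append({"scaffold_id": sid, "host_taxon": taxon,
                             "rank": rank_cap, "trna_id": m["trna_id"],
                             "match_len": int(m["match_len"]),
                             "integrase_gene": has_integrase[sid],
                             "ambiguous": ambiguous})
    return pd.DataFrame(assigned), pd.DataFrame(side)


def match_spacers(arrays: list[CRISPRArray], contigs: dict[str, str],
                  both_strands: bool = True) -> pd.DataFrame:
    """Exact full-length spacer occurrences across the assembled contigs.

    Matches falling inside the source array's own locus are excluded.
    Spacers shorter than 15 bp trigger a warning (high chance-match risk)
    but are still searched.
    """
    rows = []
    for arr in arrays:
        for idx, spacer in enumerate(arr.spacers):
            spacer = spacer.upper()
            if len(spacer) < 15:
                warnings.warn(f"spacer {arr.array_id}:{idx} is only "
                              f"{len(spacer)} bp; exact matches of this "
                              "length arise frequently by chance")
            probes = [("+", spacer)]
            if both_strands:
                probes.append(("-", revcomp(spacer)))
            for sid, seq in contigs.items():
                seq = seq.upper()
                for strand, probe in probes:
                    start = seq.find(probe)
                    while start != -1:
                        s1, e1 = start + 1, start + len(probe)
                        inside_own = (sid == arr.scaffold_id
                                      and arr.locus_interval is not None
                                      and s1 <= arr.locus_interval[1]
                                      and e1 >= arr.locus_interval[0])
                        if not inside_own:
                            rows.append((arr.array_id, arr.scaffold_id, idx,
                                         sid, s1, e1, strand, len(probe)))
                        start = seq.find(probe, start + 1)
    return pd.DataFrame(rows, columns=SPACER_COLUMNS)


def write_trna_fasta(trna_db: list[TRNAGene], path) -> None:
    """FASTA with structured headers: ``id|phylum|class``."""
    with open(path, "w") as fh:
        for t in trna_db:
            fh.write(f">{t.id}|{t.phylum}|{t.taxon_class}\n{t.sequence}\n")


def read_trna_fasta(path) -> list[TRNAGene]:
    from Bio import SeqIO
    db = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()[0].split("|")
        if len(parts) < 3:
            raise ValueError(f"tRNA header {rec.description!r} lacks "
                             "'id|phylum|class' structure")
        db.append(TRNAGene(id=parts[0], phylum=parts[1],
                           taxon_class=parts[2], sequence=str(rec.seq)))
    return db
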