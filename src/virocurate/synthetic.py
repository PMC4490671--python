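"""Synthetic virome communities with planted ground truth.

Every downstream stage of the curation pipeline (redundancy removal,
circularity detection, contamination triage, genome clustering, host
linking) is exercised here against communities whose composition is known
exactly: each synthetic scaffold carries a class label (viral, cellular,
plasmid-rich or mitochondrion-rich), a circularity flag, and optionally a
planted redundant copy, an attP segment copied verbatim from a tRNA gene,
or a CRISPR array whose spacer recurs verbatim on another scaffold.

Sequences are uniform random nucleotides; "genes" are fixed-length windows
laid head-to-tail. The downstream contracts are over coordinates and
tabular hit counts, not sequence content, so no attempt is made to model
sequence evolution, abundance distributions or base-call error.

Read pairs emulate a 100 bp paired-end library with a 400 bp insert. For
circular genomes the sequenced fragment may cross the origin of the
linearised scaffold, producing the end-spanning "discordant" pairs that
the circularity detector keys on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hosts import CRISPRArray, TRNAGene

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: class-conditional hit regimes, as fractions of gene / Pfam-hit counts.
#: viral scaffolds must clear the >=50% RefSeq-virus and >=10% POGs-10
#: gates; cellular scaffolds carry rRNA (Silva) hits; the plasmid and
#: mitochondrion regimes exceed the 50% ACLAME / mitochondrion ratios.
CLASS_REGIMES: dict[str, dict[str, float]] = {
    "viral": {"pfam": 0.55, "refseq_virus": 0.70, "pogs10": 0.25,
              "pogs7": 0.0, "aclame": 0.10, "mito": 0, "silva": 0},
    "cellular": {"pfam": 0.60, "refseq_virus": 0.10, "pogs10": 0.0,
                 "pogs7": 0.0, "aclame": 0.20, "mito": 0, "silva": 2},
    "plasmid": {"pfam": 0.60, "refseq_virus": 0.20, "pogs10": 0.0,
                "pogs7": 0.0, "aclame": 0.70, "mito": 0, "silva": 0},
    "mitochondrial": {"pfam": 0.60, "refseq_virus": 0.10, "pogs10": 0.0,
                      "pogs7": 0.0, "aclame": 0.10, "mito": 0.8, "silva": 0},
}

BLAST_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                 "gapopen", "qstart", "qend", "sstart", "send",
                 "evalue", "bitscore"]


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic virome community.

    Defaults mirror the sequencing design the pipeline targets: 100 bp
    paired-end reads, 400 +/- 80 bp inserts, a 60-650 bp concordant
    range, and ~40x mean scaffold coverage.
    """

    n_viral: int = 0
    n_cellular: int = 0
    n_plasmidlike: int = 0
    n_mitolike: int = 0
    length_range: tuple[int, int] = (16_000, 40_000)
    fraction_circular: float = 0.1
    genes_per_kb: float = 1000.0 / 900.0  # 900 bp head-to-tail gene windows
    coverage: float = 40.0
    read_length: int = 100
    insert_mean: float = 400.0
    insert_sd: float = 80.0
    concordant_range: tuple[int, int] = (60, 650)
    n_redundant: int = 0
    n_attp: int = 0
    n_crispr: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_viral, self.n_cellular, self.n_plasmidlike,
                  self.n_mitolike, self.n_redundant, self.n_attp,
                  self.n_crispr)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.length_range[0] < 1000:
            raise ValueError("minimum scaffold length must be >= 1000 bp")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be (min, max)")
        if not 0.0 <= self.fraction_circular <= 1.0:
            raise ValueError("fraction_circular must lie in [0, 1]")

    @property
    def gene_length(self) -> int:
        return int(round(1000.0 / self.genes_per_kb))

    @property
    def n_total(self) -> int:
        return (self.n_viral + self.n_cellular + self.n_plasmidlike
                + self.n_mitolike)


@dataclass
class PlantedTruth:
    """Ground-truth record for one synthetic scaffold (the test oracle)."""

    scaffold_id: str
    class_label: str
    is_circular: bool
    length: int
    coverage: float
    redundant_of: str | None = None
    redundant_interval: tuple[int, int] | None = None  # 1-based on donor
    attp_donor: str | None = None
    attp_interval: tuple[int, int] | None = None  # 1-based on scaffold
    integrase_gene: str | None = None
    spacer_targets: list[tuple[str, int, str]] = field(default_factory=list)


@dataclass
class SyntheticCommunity:
    spec: CommunitySpec
    records: list[SeqRecord]
    truth: list[PlantedTruth]
    trna_db: list[TRNAGene]
    arrays: list[CRISPRArray]

    def sequences(self) -> dict[str, str]:
        return {r.id: str(r.seq) for r in self.records}

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append({
                "scaffold_id": t.scaffold_id,
                "class_label": t.class_label,
                "is_circular": t.is_circular,
                "length": t.length,
                "coverage": t.coverage,
                "redundant_of": t.redundant_of or "",
                "attp_donor": t.attp_donor or "",
                "integrase_gene": t.integrase_gene or "",
                "spacer_targets": ";".join(
                    f"{a}:{i}:{s}" for a, i, s in t.spacer_targets),
            })
        return pd.DataFrame(rows)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(f">{rec.id}\n")
                seq = str(rec.seq)
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def _splice(seq: str, pos0: int, insert: str) -> str:
    """Overwrite ``seq`` with ``insert`` at 0-based ``pos0`` (no resize)."""
    return seq[:pos0] + insert + seq[pos0 + len(insert):]


def generate_trna_db(n: int, seed: int = 0) -> list[TRNAGene]:
    """Random tRNA gene database with taxon-annotated entries (60-90 bp)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A]))
    lineages = [("Actinobacteria", "Actinomycetia"),
                ("Proteobacteria", "Alphaproteobacteria"),
                ("Proteobacteria", "Gammaproteobacteria"),
                ("Firmicutes", "Bacilli"),
                ("Cyanobacteria", "Cyanophyceae"),
                ("Haptophyta", "Haptophyceae")]
    db = []
    for i in range(n):
        phylum, cls = lineages[i % len(lineages)]
        length = int(rng.integers(60, 91))
        db.append(TRNAGene(id=f"tRNA_{i + 1:04d}", phylum=phylum,
                           taxon_class=cls, sequence=_random_seq(rng, length)))
    return db


def _free_position(rng: np.random.Generator, length: int, size: int,
                   occupied: list[tuple[int, int]]) -> int:
    """0-based start for a planted motif avoiding previously planted ones."""
    for _ in range(200):
        pos = int(rng.integers(0, length - size + 1))
        if all(pos + size <= a or pos >= b for a, b in occupied):
            occupied.append((pos, pos + size))
            return pos
    raise RuntimeError("could not place planted motif without overlap")


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Generate a synthetic community with planted, fully recorded truth.

    Deterministic for a fixed spec (including seed). Each scaffold draws
    from its own random stream derived from the root seed, so adding
    scaffolds never perturbs the sequence of an existing one.
    """
    if spec.n_total == 0:
        raise ValueError("community must contain at least one genome")

    root = np.random.SeedSequence(spec.seed)
    plan: list[tuple[str, str, bool]] = []
    for label, prefix, count in [("viral", "VIR", spec.n_viral),
                                 ("cellular", "CEL", spec.n_cellular),
                                 ("plasmid", "PLA", spec.n_plasmidlike),
                                 ("mitochondrial", "MIT", spec.n_mitolike)]:
        n_circ = int(round(count * spec.fraction_circular))
        for i in range(count):
            plan.append((f"{prefix}_{i + 1:04d}", label, i < n_circ))

    streams = root.spawn(len(plan) + spec.n_redundant + 4)
    seqs: dict[str, str] = {}
    truth: dict[str, PlantedTruth] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    for (sid, label, circ), ss in zip(plan, streams):
        rng = np.random.default_rng(ss)
        length = int(rng.integers(spec.length_range[0],
                                  spec.length_range[1] + 1))
        seqs[sid] = _random_seq(rng, length)
        occupied[sid] = []
        truth[sid] = PlantedTruth(scaffold_id=sid, class_label=label,
                                  is_circular=circ, length=length,
                                  coverage=spec.coverage)

    viral_ids = [sid for sid, lab, _ in plan if lab == "viral"]
    aux = np.random.default_rng(streams[len(plan)])

    # planted attP segments: verbatim tRNA substrings on integrase scaffolds
    trna_db = generate_trna_db(max(spec.n_attp * 2, 6), seed=spec.seed)
    if spec.n_attp > len(viral_ids):
        raise ValueError("n_attp exceeds the number of viral scaffolds")
    for k in range(spec.n_attp):
        sid = viral_ids[k]
        trna = trna_db[k % len(trna_db)]
        size = int(aux.integers(28, min(61, len(trna.sequence) + 1)))
        t0 = int(aux.integers(0, len(trna.sequence) - size + 1))
        segment = trna.sequence[t0:t0 + size]
        pos = _free_position(aux, truth[sid].length, size, occupied[sid])
        seqs[sid] = _splice(seqs[sid], pos, segment)
        gene_idx = int(aux.integers(1, truth[sid].length // spec.gene_length))
        truth[sid].attp_donor = trna.id
        truth[sid].attp_interval = (pos + 1, pos + size)
        truth[sid].integrase_gene = f"{sid}_g{gene_idx}"

    # planted CRISPR arrays, one spacer copied verbatim onto another phage
    arrays: list[CRISPRArray] = []
    if spec.n_crispr:
        if len(viral_ids) < 2:
            raise ValueError("CRISPR planting needs at least two viral "
                             "scaffolds (array carrier and target)")
        arng = np.random.default_rng(streams[len(plan) + 1])
        for k in range(spec.n_crispr):
            carrier = viral_ids[k % len(viral_ids)]
            target = viral_ids[(k + 1) % len(viral_ids)]
            repeat = _random_seq(arng, 29)
            n_spacers = int(arng.integers(5, 14))
            spacers = [_random_seq(arng, 32) for _ in range(n_spacers)]
            locus = repeat + repeat.join(spacers) + repeat
            pos = _free_position(arng, truth[carrier].length, len(locus),
                                 occupied[carrier])
            seqs[carrier] = _splice(seqs[carrier], pos, locus)
            spacer_coords = []
            off = pos + 29
            for sp in spacers:
                spacer_coords.append((off + 1, off + len(sp)))
                off += len(sp) + 29
            idx = int(arng.integers(0, n_spacers))
            tpos = _free_position(arng, truth[target].length, 32,
                                  occupied[target])
            seqs[target] = _splice(seqs[target], tpos, spacers[idx])
            array_id = f"CR_{k + 1:03d}"
            arrays.append(CRISPRArray(
                array_id=array_id, scaffold_id=carrier,
                repeat_consensus=repeat, spacers=list(spacers),
                spacer_coords=spacer_coords,
                locus_interval=(pos + 1, pos + len(locus))))
            truth[carrier].spacer_targets.append((array_id, idx, target))

    # planted near-identical redundancy: verbatim substrings as new
    # contigs; donors are distinct so planted copies never overlap each other
    order = [sid for sid, _, _ in plan]
    if spec.n_redundant > len(order):
        raise ValueError("n_redundant exceeds the number of scaffolds")
    donor_rng = np.random.default_rng(streams[len(plan) + 2])
    donors = [order[i] for i in donor_rng.choice(len(order),
                                                 size=spec.n_redundant,
                                                 replace=False)]
    for k in range(spec.n_redundant):
        rng = np.random.default_rng(streams[len(plan) + 3 + k])
        donor = donors[k]
        dlen = truth[donor].length
        size = max(5000, dlen // 2)
        if size >= dlen:
            size = dlen - 1
        start = int(rng.integers(0, dlen - size + 1))
        rid = f"RED_{k + 1:04d}"
        seqs[rid] = seqs[donor][start:start + size]
        truth[rid] = PlantedTruth(
            scaffold_id=rid, class_label=truth[donor].class_label,
            is_circular=False, length=size, coverage=spec.coverage,
            redundant_of=donor, redundant_interval=(start + 1, start + size))

    records = [SeqRecord(Seq(seqs[sid]), id=sid, description="")
               for sid in list(order) + [t for t in truth if t not in order]]
    return SyntheticCommunity(spec=spec, records=records,
                              truth=list(truth.values()),
                              trna_db=trna_db, arrays=arrays)


# ---------------------------------------------------------------------------
# paired-read simulation

def pairs_for_coverage(spec: CommunitySpec, length: int) -> int:
    """Read-pair count giving the spec's mean fold-coverage on a scaffold."""
    return int(round(spec.coverage * length / (2 * spec.read_length)))


def simulate_paired_reads(genome: str, is_circular: bool, n_pairs: int,
                          spec: CommunitySpec,
                          scaffold_id: str = "scaffold",
                          rng: np.random.Generator | None = None,
                          emit_reads: bool = True,
                          ) -> tuple[list[tuple[SeqRecord, SeqRecord]],
                                     pd.DataFrame]:
    """Simulate FR read pairs and their alignments on the linearised scaffold.

    Fragments are drawn uniformly on the genome. On a circular genome a
    fragment whose interval crosses the origin has its two mates reported
    at wrapped (linearised) coordinates, so the pair appears to span the
    scaffold ends. A fragment is nudged into the inter-mate gap when a
    single mate would itself straddle the origin, which preserves the
    number of origin-crossing fragments exactly.

    Returns ``(reads, alignments)`` where alignments is a table of
    1-based mate positions plus the apparent span (outermost distance).
    """
    L = len(genome)
    rl = spec.read_length
    if n_pairs <= 0:
        return [], _empty_alignments()
    if L <= spec.insert_mean + 4 * spec.insert_sd:
        raise ValueError("genome too short for the configured insert size")

    if rng is None:
        rng = np.random.default_rng(spec.seed)
    inserts = np.rint(rng.normal(spec.insert_mean, spec.insert_sd, n_pairs))
    inserts = np.clip(inserts, 2 * rl, L).astype(int)
    if is_circular:
        starts = rng.integers(0, L, n_pairs)
    else:
        starts = np.array([int(rng.integers(0, L - ins + 1))
                           for ins in inserts])

    doubled = genome + genome  # wrap-around extraction
    reads: list[tuple[SeqRecord, SeqRecord]] = []
    rows = []
    for i, (s, ins) in enumerate(zip(starts, inserts)):
        s, ins = int(s), int(ins)
        if is_circular and s + ins > L:
            # keep the fragment origin-crossing but neither mate split
            s = min(max(s, L - ins + rl), L - rl)
        m1 = doubled[s:s + rl]
        m2_start = s + ins - rl
        m2 = doubled[m2_start:m2_start + rl]
        p1 = s % L + 1
        p2 = m2_start % L + 1
        e1, e2 = p1 + rl - 1, p2 + rl - 1
        span = max(e1, e2) - min(p1, p2) + 1
        pid = f"{scaffold_id}_p{i + 1}"
        if emit_reads:
            r1 = SeqRecord(Seq(m1), id=pid, description="/1")
            r1.letter_annotations["phred_quality"] = [40] * rl
            r2 = SeqRecord(Seq(m2).reverse_complement(), id=pid,
                           description="/2")
            r2.letter_annotations["phred_quality"] = [40] * rl
            reads.append((r1, r2))
        rows.append((pid, scaffold_id, p1, rl, "+", p2, rl, "-", span))
    aln = pd.DataFrame(rows, columns=["pair_id", "scaffold_id",
                                      "mate1_start", "mate1_len", "strand1",
                                      "mate2_start", "mate2_len", "strand2",
                                      "apparent_span"])
    return reads, aln


def _empty_alignments() -> pd.DataFrame:
    return pd.DataFrame(columns=["pair_id", "scaffold_id", "mate1_start",
                                 "mate1_len", "strand1", "mate2_start",
                                 "mate2_len", "strand2", "apparent_span"])


def write_sam(alignments: pd.DataFrame, scaffold_lengths: dict[str, int],
              path, read_length: int | None = None) -> None:
    """Write simulated alignments as a headerful SAM (one @SQ per scaffold)."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": sid, "LN": int(ln)}
                     for sid, ln in sorted(scaffold_lengths.items())]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for row in alignments.itertuples(index=False):
            for first in (True, False):
                a = pysam.AlignedSegment()
                a.query_name = row.pair_id
                pos = row.mate1_start if first else row.mate2_start
                mpos = row.mate2_start if first else row.mate1_start
                ln = row.mate1_len if first else row.mate2_len
                rev = (row.strand1 if first else row.strand2) == "-"
                mrev = (row.strand2 if first else row.strand1) == "-"
                flag = 0x1 | (0x40 if first else 0x80)
                if rev:
                    flag |= 0x10
                if mrev:
                    flag |= 0x20
                a.flag = flag
                a.reference_id = tid[row.scaffold_id]
                a.reference_start = pos - 1
                a.next_reference_id = tid[row.scaffold_id]
                a.next_reference_start = mpos - 1
                a.cigarstring = f"{ln}M"
                a.query_sequence = "N" * ln
                a.query_qualities = pysam.qualitystring_to_array("I" * ln)
                left = min(row.mate1_start, row.mate2_start)
                tlen = row.apparent_span
                a.template_length = tlen if pos == left else -tlen
                a.mapping_quality = 60
                out.write(a)


def write_fastq_pairs(reads, path1, path2) -> None:
    from Bio import SeqIO
    SeqIO.write([r1 for r1, _ in reads], str(path1), "fastq")
    SeqIO.write([r2 for _, r2 in reads], str(path2), "fastq")


# ---------------------------------------------------------------------------
# class-conditional hit tables

def emit_self_hits(community: SyntheticCommunity) -> pd.DataFrame:
    """BLAST-tabular rows for the planted redundant-contig containments."""
    rows = []
    for t in community.truth:
        if t.redundant_of is None:
            continue
        a, b = t.redundant_interval
        ln = t.length
        rows.append((t.scaffold_id, t.redundant_of, 100.0, ln, 0, 0,
                     1, ln, a, b, 0.0, 2.0 * ln))
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def emit_hit_tables(truth: list[PlantedTruth], seed: int = 0,
                    gene_length: int = 900,
                    ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Emit per-database BLAST-tabular hit tables and a GFF3-style gene table.

    Counts are deterministic functions of each scaffold's class regime:
    a viral scaffold gets RefSeq-virus hits on 70% and POGs-10 hits on
    25% of its Pfam-hit genes (clearing the >=50% / >=10% triage gates);
    cellular scaffolds get Silva rRNA hits; plasmid-rich and
    mitochondrion-rich scaffolds exceed the corresponding 50% ratios.
    """
    if not truth:
        tables = {db: pd.DataFrame(columns=BLAST_COLUMNS)
                  for db in ("pfam", "refseq_virus", "pogs10", "pogs7",
                             "aclame", "mito", "silva")}
        genes = pd.DataFrame(columns=["seqid", "source", "type", "start",
                                      "end", "score", "strand", "frame",
                                      "attributes"])
        return tables, genes

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x417]))
    hit_rows: dict[str, list] = {db: [] for db in
                                 ("pfam", "refseq_virus", "pogs10", "pogs7",
                                  "aclame", "mito", "silva")}
    gene_rows = []
    for t in truth:
        if t.class_label not in CLASS_REGIMES:
            raise ValueError(f"unknown class label: {t.class_label!r}")
        regime = CLASS_REGIMES[t.class_label]
        n_genes = t.length // gene_length
        gene_ids = [f"{t.scaffold_id}_g{i + 1}" for i in range(n_genes)]
        for i, gid in enumerate(gene_ids):
            start = i * gene_length + 1
            product = ("phage integrase" if gid == t.integrase_gene
                       else "hypothetical protein")
            gene_rows.append((t.scaffold_id, "synth", "CDS", start,
                              start + gene_length - 1, ".", "+", "0",
                              f"ID={gid};product={product}"))

        n_pfam = int(round(regime["pfam"] * n_genes))
        pfam_genes = sorted(rng.choice(n_genes, size=n_pfam, replace=False))
        subsets = {"pfam": pfam_genes}
        for db, frac in [("refseq_virus", regime["refseq_virus"]),
                         ("pogs10", regime["pogs10"]),
                         ("pogs7", regime["pogs7"]),
                         ("aclame", regime["aclame"])]:
            k = int(math.ceil(frac * n_pfam)) if frac else 0
            subsets[db] = (sorted(rng.choice(pfam_genes, size=k,
                                             replace=False)) if k else [])
        for db, idxs in subsets.items():
            for gi in idxs:
                gid = gene_ids[gi]
                ident = float(np.round(rng.uniform(35, 95), 1))
                alen = int(rng.integers(80, 280))
                hit_rows[db].append((gid, f"{db}|ref{int(rng.integers(1e6))}",
                                     ident, alen, 0, 0, 1, alen, 1, alen,
                                     1e-10, float(np.round(
                                         rng.uniform(60, 240), 1))))
        # scaffold-level nucleotide searches (rRNA and mitochondrion).
        # Silva is an absolute count; the mitochondrion regime is a
        # fraction of Pfam-hit genes, since triage normalises to Pfam.
        scaffold_level = {"silva": int(regime["silva"]),
                          "mito": int(math.ceil(regime["mito"] * n_pfam))}
        for db in ("silva", "mito"):
            for _ in range(scaffold_level[db]):
                alen = int(rng.integers(100, 400))
                hit_rows[db].append((t.scaffold_id,
                                     f"{db}|ref{int(rng.integers(1e6))}",
                                     float(np.round(rng.uniform(80, 99), 1)),
                                     alen, 0, 0, 1, alen, 1, alen, 1e-12,
                                     float(np.round(rng.uniform(100, 400), 1))))

    tables = {db: pd.DataFrame(rows, columns=BLAST_COLUMNS)
              for db, rows in hit_rows.items()}
    genes = pd.DataFrame(gene_rows, columns=["seqid", "source", "type",
                                             "start", "end", "score",
                                             "strand", "frame", "attributes"])
    return tables, genes


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        genes.to_csv(fh, sep="\t", header=False, index=False)
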