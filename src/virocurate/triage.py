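"""Viral/contaminant triage of candidate scaffolds from database-hit ratios.

Virus-size-fraction assemblies carry cellular, plasmid and mitochondrial
contamination. Because most genuinely viral genes have no database
match, raw hit counts are not comparable between scaffolds; each
database's gene-hit count is therefore normalised to the number of
genes with a Pfam-A (HMMER) hit before applying the decision rules:

* coverage < 10x               -> rejected (chimera risk);
* any Silva SSU/LSU rRNA hit   -> flagged cellular, for manual review;
* mitochondrion hits > 50% of Pfam hits -> mitochondrion review queue;
* ACLAME plasmid hits > 50% of Pfam hits -> plasmid review queue;
* any hit to the phage-exclusive POGs-7 families -> viral;
* RefSeq-virus hits >= 50% AND POGs-10 hits >= 10% of Pfam hits -> viral;
* otherwise ambiguous.

Contamination flags take precedence over the automatic viral call: a
scaffold with an rRNA hit goes to review even if it also satisfies the
viral rule. Review labels are not final; a manual-decision table can
override them downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .summaries import format_percent

LABELS = ("viral", "cellular_review", "plasmid_review", "mito_review",
          "low_coverage_reject", "ambiguous")


@dataclass(frozen=True)
class GeneHitProfile:
    """Per-scaffold hit counts: the sufficient statistic for triage."""

    scaffold_id: str
    n_genes: int
    n_pfam: int
    n_refseq_virus: int = 0
    n_pogs10: int = 0
    n_pogs7: int = 0
    n_aclame: int = 0
    n_mito: int = 0    # scaffold-level tblastx hits
    n_silva: int = 0   # scaffold-level tblastx hits
    coverage: float = 0.0

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_pfam, self.n_refseq_virus,
                  self.n_pogs10, self.n_pogs7, self.n_aclame,
                  self.n_mito, self.n_silva)
        if any(c < 0 for c in counts):
            raise ValueError("hit counts must be non-negative")
        if self.n_pfam > self.n_genes:
            raise ValueError("Pfam-hit genes cannot exceed gene predictions")
        for name in ("n_refseq_virus", "n_pogs10", "n_pogs7", "n_aclame"):
            if getattr(self, name) > self.n_genes:
                raise ValueError(f"{name} exceeds the gene count")


@dataclass(frozen=True)
class TriageResult:
    scaffold_id: str
    label: str
    flags: tuple[str, ...]
    rationale: str


def triage_scaffold(p: GeneHitProfile, min_cov: float = 10.0,
                    virus_refseq_frac: float = 0.5,
                    virus_pogs_frac: float = 0.1,
                    plasmid_frac: float = 0.5,
                    mito_frac: float = 0.5) -> TriageResult:
    """Label one scaffold by the precedence-ordered decision rules.

    Ratio rules evaluate false when there are no Pfam hits (no division
    by zero); this is noted in the rationale.
    """
    flags: list[str] = []
    notes: list[str] = []
    if p.n_pfam == 0:
        notes.append("no Pfam hits: ratio rules vacuously false")

    if p.coverage < min_cov:
        return TriageResult(p.scaffold_id, "low_coverage_reject",
                            ("coverage",),
                            f"coverage {p.coverage:.1f}x < {min_cov:g}x")
    if p.n_silva >= 1:
        flags.append("silva")
        return TriageResult(p.scaffold_id, "cellular_review", tuple(flags),
                            f"{p.n_silva} Silva SSU/LSU hit(s)")
    if p.n_pfam > 0 and p.n_mito / p.n_pfam > mito_frac:
        flags.append("mito_ratio")
        return TriageResult(p.scaffold_id, "mito_review", tuple(flags),
                            f"mito/Pfam = {p.n_mito}/{p.n_pfam} "
                            f"> {mito_frac:g}")
    if p.n_pfam > 0 and p.n_aclame / p.n_pfam > plasmid_frac:
        flags.append("aclame_ratio")
        return TriageResult(p.scaffold_id, "plasmid_review", tuple(flags),
                            f"ACLAME/Pfam = {p.n_aclame}/{p.n_pfam} "
                            f"> {plasmid_frac:g}")
    if p.n_pogs7 >= 1:
        flags.append("pogs7")
        return TriageResult(p.scaffold_id, "viral", tuple(flags),
                            f"{p.n_pogs7} hit(s) to phage-exclusive POGs-7")
    if (p.n_pfam > 0
            and p.n_refseq_virus / p.n_pfam >= virus_refseq_frac
            and p.n_pogs10 / p.n_pfam >= virus_pogs_frac):
        flags.append("refseq_pogs10")
        return TriageResult(p.scaffold_id, "viral", tuple(flags),
                            f"RefSeq-virus {p.n_refseq_virus}/{p.n_pfam} and "
                            f"POGs-10 {p.n_pogs10}/{p.n_pfam} of Pfam hits")
    return TriageResult(p.scaffold_id, "ambiguous", tuple(flags),
                        "; ".join(notes) or "no rule fired")


def triage_batch(profiles: list[GeneHitProfile], **thresholds,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triage a candidate set; return per-scaffold results and a summary.

    The summary gives per-database gene-hit totals and their percentage
    of all gene predictions (one decimal place, as such tables are
    conventionally printed), plus the confirmed-viral fraction of the
    candidate scaffolds.
    """
    if not profiles:
        raise ValueError("empty profile batch")
    ids = [p.scaffold_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scaffold ids in batch")
    results = [triage_scaffold(p, **thresholds) for p in profiles]
    res_df = pd.DataFrame([{"scaffold_id": r.scaffold_id, "label": r.label,
                            "flags": ";".join(r.flags),
                            "rationale": r.rationale} for r in results])
    totals = {
        "gene_predictions": sum(p.n_genes for p in profiles),
        "pfam": sum(p.n_pfam for p in profiles),
        "refseq_virus": sum(p.n_refseq_virus for p in profiles),
        "pogs10": sum(p.n_pogs10 for p in profiles),
        "pogs7": sum(p.n_pogs7 for p in profiles),
        "silva": sum(p.n_silva for p in profiles),
    }
    summary = gene_hit_summary(totals["gene_predictions"],
                               {k: v for k, v in totals.items()
                                if k != "gene_predictions"})
    n_viral = sum(r.label == "viral" for r in results)
    extra = [{"quantity": "candidate_scaffolds", "count": len(profiles),
              "percent_of_genes": float("nan")},
             {"quantity": "viral_scaffolds_confirmed", "count": n_viral,
              "percent_of_genes": format_percent(n_viral, len(profiles),
                                                 mode="1dp")}]
    for label in LABELS:
        extra.append({"quantity": f"label_{label}",
                      "count": sum(r.label == label for r in results),
                      "percent_of_genes": float("nan")})
    summary = pd.concat([summary, pd.DataFrame(extra)], ignore_index=True)
    return res_df, summary


def gene_hit_summary(n_gene_predictions: int,
                     db_counts: dict[str, int]) -> pd.DataFrame:
    """Per-database gene-hit counts as percentages of gene predictions."""
    if n_gene_predictions <= 0:
        raise ValueError("gene prediction total must be positive")
    rows = [{"quantity": "gene_predictions", "count": n_gene_predictions,
             "percent_of_genes": float("nan")}]
    for db, count in db_counts.items():
        rows.append({"quantity": f"{db}_gene_hits", "count": count,
                     "percent_of_genes": format_percent(
                         count, n_gene_predictions, mode="1dp")})
    return pd.DataFrame(rows)


def profiles_from_tables(gene_calls: pd.DataFrame,
                         hit_tables: dict[str, pd.DataFrame],
                         coverage: dict[str, float],
                         max_e: float = 1e-5) -> list[GeneHitProfile]:
    """Assemble per-scaffold profiles from BLAST tabular hits + gene calls.

    Gene-level databases are counted as distinct genes with >= 1 hit at
    E <= max_e (gene ids must be ``<scaffold>_g<i>``); Silva and
    mitochondrion tables are scaffold-level rows.
    """
    genes_per_scaffold = gene_calls.groupby("seqid").size().to_dict()

    def gene_counts(df: pd.DataFrame) -> dict[str, int]:
        if not len(df):
            return {}
        ok = df[df["evalue"] <= max_e]
        scaffold = ok["qseqid"].str.rsplit("_g", n=1).str[0]
        return ok.groupby(scaffold)["qseqid"].nunique().to_dict()

    def scaffold_counts(df: pd.DataFrame) -> dict[str, int]:
        if not len(df):
            return {}
        ok = df[df["evalue"] <= max_e]
        return ok.groupby("qseqid").size().to_dict()

    per_db = {db: gene_counts(hit_tables.get(db, pd.DataFrame()))
              for db in ("pfam", "refseq_virus", "pogs10", "pogs7",
                         "aclame")}
    silva = scaffold_counts(hit_tables.get("silva", pd.DataFrame()))
    mito = scaffold_counts(hit_tables.get("mito", pd.DataFrame()))

    profiles = []
    for sid in sorted(genes_per_scaffold):
        profiles.append(GeneHitProfile(
            scaffold_id=sid,
            n_genes=int(genes_per_scaffold[sid]),
            n_pfam=per_db["pfam"].get(sid, 0),
            n_refseq_virus=per_db["refseq_virus"].get(sid, 0),
            n_pogs10=per_db["pogs10"].get(sid, 0),
            n_pogs7=per_db["pogs7"].get(sid, 0),
            n_aclame=per_db["aclame"].get(sid, 0),
            n_mito=mito.get(sid, 0),
            n_silva=silva.get(sid, 0),
            coverage=float(coverage.get(sid, 0.0))))
    return profiles
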