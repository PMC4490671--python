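"""Whole-genome comparison of circular genome scaffolds.

Genomes that share no marker genes can still be related through the
large fraction of unannotated sequence, so relatedness is measured
directly from an all-vs-all translated search: qualifying hits
(>30% identity, >=30 aa, E < 0.01) have their bitscores summed per
genome pair into S(a,b), and similarity is the Dice coefficient

    D(a,b) = 2 S(a,b) / (S(a,a) + S(b,b)),

i.e. the shared signal normalised by the self-comparison scores. The
dissimilarity 1 - D feeds a neighbor-joining tree, and genome groups are
the single-linkage components of the graph with edges D >= threshold.

Hits from both search directions (a->b and b->a) are summed into the
same pair by default; a directional mode keeps only query->subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components


@dataclass
class DiceMatrix:
    ids: list[str]
    S: pd.DataFrame          # summed bitscores, symmetric
    D: pd.DataFrame          # Dice similarities in [0, 1]
    dissim: pd.DataFrame     # 1 - D, zero diagonal
    flagged: list[str] = field(default_factory=list)  # zero self-score


@dataclass
class NJTree:
    newick: str
    ids: list[str]
    raw_branch_lengths: dict[str, float] = field(default_factory=dict)


def filter_hits(hits: pd.DataFrame, min_ident: float = 30.0,
                min_len: int = 30, max_e: float = 0.01) -> pd.DataFrame:
    """Keep qualifying hits: identity > min_ident (strict), aligned
    length >= min_len, E-value < max_e (strict)."""
    if not len(hits):
        return hits.copy()
    keep = ((hits["pident"] > min_ident) & (hits["length"] >= min_len)
            & (hits["evalue"] < max_e))
    return hits.loc[keep].reset_index(drop=True)


def summed_scores(hits: pd.DataFrame, genomes: list[str],
                  directional: bool = False) -> pd.DataFrame:
    """Sum hit bitscores per genome pair into a symmetric matrix.

    S[a, b] accumulates every hit with {query, subject} = {a, b}; with
    ``directional=True`` only query->subject rows count toward [a, b]
    (the matrix is then symmetrised by averaging). The diagonal comes
    from self-comparison hits and anchors the Dice denominator.
    """
    idx = {g: i for i, g in enumerate(genomes)}
    S = np.zeros((len(genomes), len(genomes)))
    for row in hits.itertuples(index=False):
        q, s = str(row.qseqid), str(row.sseqid)
        if q not in idx or s not in idx:
            raise ValueError(f"hit references unknown genome: {q}/{s}")
        i, j = idx[q], idx[s]
        if i == j:
            S[i, i] += row.bitscore
        elif directional:
            S[i, j] += row.bitscore
        else:
            S[i, j] += row.bitscore
            S[j, i] += row.bitscore
    if directional:
        S = (S + S.T) / 2.0
    return pd.DataFrame(S, index=genomes, columns=genomes)


def dice_matrix(S: pd.DataFrame) -> DiceMatrix:
    """Dice similarity and its dissimilarity transform from summed scores.

    Genomes with zero self-score cannot be normalised; their Dice
    entries are defined as 0 and the genome is flagged.
    """
    ids = list(S.index)
    self_scores = np.diag(S.values).astype(float)
    flagged = [g for g, v in zip(ids, self_scores) if v <= 0]
    if flagged:
        warnings.warn(f"genomes with zero self-score: {flagged}")
    denom = self_scores[:, None] + self_scores[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.where(denom > 0, 2.0 * S.values / denom, 0.0)
    for k, v in enumerate(self_scores):
        if v <= 0:
            D[k, :] = 0.0
            D[:, k] = 0.0
        else:
            D[k, k] = 1.0
    D_df = pd.DataFrame(D, index=ids, columns=ids)
    dis = 1.0 - D_df
    np.fill_diagonal(dis.values, 0.0)
    return DiceMatrix(ids=ids, S=S, D=D_df, dissim=dis, flagged=flagged)


# ---------------------------------------------------------------------------
# neighbor joining

def _fmt(x: float) -> str:
    return f"{x:.10g}"


def nj_tree(dissim: pd.DataFrame) -> NJTree:
    """Neighbor-joining tree from a dissimilarity matrix (Saitou & Nei).

    Deterministic: when several pairs minimise the Q-criterion, the
    lexicographically smallest pair of cluster labels (each cluster
    labelled by its smallest leaf id) is joined. Negative branch lengths
    are clamped to zero with the deficit transferred to the sibling
    branch; the raw lengths are retained in ``raw_branch_lengths``.

    Fewer than three taxa yield a trivial tree with a warning.
    """
    ids = list(dissim.index)
    D = dissim.values.astype(float)
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = len(ids)
    raw: dict[str, float] = {}

    if n == 0:
        raise ValueError("empty matrix")
    if n == 1:
        warnings.warn("fewer than three taxa: trivial tree")
        return NJTree(newick=f"{ids[0]};", ids=ids)
    if n == 2:
        warnings.warn("fewer than three taxa: trivial tree")
        h = D[0, 1] / 2.0
        return NJTree(newick=f"({ids[0]}:{_fmt(h)},{ids[1]}:{_fmt(h)});",
                      ids=ids, raw_branch_lengths={ids[0]: h, ids[1]: h})

    # active clusters: label -> (newick fragment, smallest leaf id)
    labels = list(ids)
    newick = {g: g for g in ids}
    key = {g: g for g in ids}
    dist = {(a, b): D[i, j] for i, a in enumerate(ids)
            for j, b in enumerate(ids) if i < j}

    def d(a: str, b: str) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    def clamp(name_i: str, li: float, name_j: str, lj: float):
        raw[name_i], raw[name_j] = li, lj
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        return li, lj

    step = 0
    while len(labels) > 3:
        m = len(labels)
        r = {a: sum(d(a, b) for b in labels if b != a) for a in labels}
        best = None
        for x in range(m):
            for y in range(x + 1, m):
                a, b = labels[x], labels[y]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                tie = tuple(sorted((key[a], key[b])))
                cand = (q, tie)
                if best is None or cand < best[0:2]:
                    best = (q, tie, a, b)
        _, _, a, b = best
        dab = d(a, b)
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = clamp(f"{key[a]}#{step}", la, f"{key[b]}#{step}", lb)
        new = f"U{step}"
        step += 1
        for c in labels:
            if c in (a, b):
                continue
            dist[(new, c)] = (d(a, c) + d(b, c) - dab) / 2.0
        newick[new] = (f"({newick[a]}:{_fmt(la)},{newick[b]}:{_fmt(lb)})")
        key[new] = min(key[a], key[b])
        labels = [c for c in labels if c not in (a, b)] + [new]

    a, b, c = sorted(labels, key=lambda x: key[x])
    la = (d(a, b) + d(a, c) - d(b, c)) / 2.0
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2.0
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2.0
    for name, ln in ((key[a], la), (key[b], lb), (key[c], lc)):
        raw.setdefault(name, ln)
    la, lb, lc = (max(0.0, v) for v in (la, lb, lc))
    nwk = (f"({newick[a]}:{_fmt(la)},{newick[b]}:{_fmt(lb)},"
           f"{newick[c]}:{_fmt(lc)});")
    return NJTree(newick=nwk, ids=ids, raw_branch_lengths=raw)


def cluster_groups(D: pd.DataFrame, threshold: float = 0.05,
                   ) -> tuple[list[list[str]], list[str]]:
    """Single-linkage genome groups: components of the D >= threshold graph.

    Returns (groups of size >= 2, singletons), each group sorted by id,
    groups ordered by their first member.
    """
    ids = list(D.index)
    adj = (D.values >= threshold).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, comp = connected_components(adj, directed=False)
    buckets: dict[int, list[str]] = {}
    for g, c in zip(ids, comp):
        buckets.setdefault(int(c), []).append(g)
    groups = sorted((sorted(v) for v in buckets.values() if len(v) > 1),
                    key=lambda g: g[0])
    singles = sorted(g for v in buckets.values() if len(v) == 1 for g in v)
    return groups, singles
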