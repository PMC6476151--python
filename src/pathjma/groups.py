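"""Gene group (pathway) construction for candidate prediction models.

Candidate models are defined by groups of gene columns of an expression
matrix.  Groups can come from a pathway database in GMT format (possibly
overlapping), from a sequential near-equal partition of the columns, or from
ranking genes by the magnitude of their marginal correlation with the
phenotype (the marginal-correlation comparator construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneGroups",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "groups_from_gmt",
    "groups_sequential",
    "groups_by_marginal_correlation",
    "groups_to_tsv",
    "groups_from_tsv",
    "unassigned_genes",
    "multi_membership_fraction",
]


class GmtParseError(ValueError):
    """Raised when a GMT line cannot be parsed."""


@dataclass
class GeneGroups:
    """K gene groups over the columns of an expression matrix.

    Parameters
    ----------
    group_names : list of str
        One identifier per group (e.g. pathway names).
    members : list of ndarray
        For each group, the integer column indices of its member genes.
    n_genes_total : int
        Number of columns of the associated expression matrix.
    allow_overlap : bool
        Whether a gene may belong to several groups.  When False the groups
        must be pairwise disjoint and cover ``0..n_genes_total-1``.
    """

    group_names: list[str]
    members: list[np.ndarray]
    n_genes_total: int
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        self.members = [np.asarray(m, dtype=np.intp) for m in self.members]
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if len(self.group_names) != len(self.members):
            raise ValueError("group_names and members have different lengths")
        if len(self.members) == 0:
            raise ValueError("at least one group is required")
        seen_all: set[int] = set()
        for name, idx in zip(self.group_names, self.members):
            if idx.size == 0:
                raise ValueError(f"group {name!r} is empty")
            if np.unique(idx).size != idx.size:
                raise ValueError(f"group {name!r} contains duplicate gene indices")
            if idx.min() < 0 or idx.max() >= self.n_genes_total:
                raise ValueError(
                    f"group {name!r} has indices outside 0..{self.n_genes_total - 1}"
                )
            if not self.allow_overlap and seen_all.intersection(idx.tolist()):
                raise ValueError(
                    f"group {name!r} overlaps another group but allow_overlap is False"
                )
            seen_all.update(idx.tolist())
        if not self.allow_overlap and len(seen_all) != self.n_genes_total:
            raise ValueError(
                "disjoint groups must cover every gene column "
                f"({len(seen_all)} of {self.n_genes_total} covered)"
            )

    @property
    def K(self) -> int:
        """Number of groups."""
        return len(self.members)

    @property
    def sizes(self) -> np.ndarray:
        """Group sizes m_j."""
        return np.array([m.size for m in self.members])


def read_gmt(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Parse a Broad-style GMT file into ``(name, description, genes)`` records.

    Each non-blank line must have at least three tab-separated fields:
    set name, description, then one or more member gene identifiers.
    """
    records: list[tuple[str, str, list[str]]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes), got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not name:
                raise GmtParseError(f"{path}: line {lineno}: empty gene-set name")
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            records.append((name, desc, genes))
    return records


def write_gmt(records, path: str | Path) -> None:
    """Write ``(name, description, genes)`` records as a GMT file."""
    with open(path, "wt", encoding="utf-8") as fh:
        for name, desc, genes in records:
            fh.write("\t".join([name, desc, *genes]) + "\n")


def groups_from_gmt(
    gmt_path: str | Path,
    gene_ids: list[str],
    unmatched: str = "drop",
) -> GeneGroups:
    """Build overlapping gene groups from a GMT pathway file.

    Pathway member identifiers are matched (case-sensitively) against
    ``gene_ids``, the ordered column identifiers of the expression matrix.
    Pathways with no matched gene are dropped (and logged).  Genes matched by
    no pathway are excluded from every candidate model by default
    (``unmatched='drop'``) or pooled into one extra ``__remainder__`` group
    (``unmatched='remainder'``).
    """
    if unmatched not in ("drop", "remainder"):
        raise ValueError("unmatched must be 'drop' or 'remainder'")
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("gene_ids is empty")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene_ids contains duplicates")
    col = {g: i for i, g in enumerate(gene_ids)}

    names: list[str] = []
    members: list[np.ndarray] = []
    dropped = 0
    for name, _desc, genes in read_gmt(gmt_path):
        idx = sorted({col[g] for g in genes if g in col})
        if not idx:
            dropped += 1
            logger.info("pathway %r dropped: no member gene in the expression matrix", name)
            continue
        names.append(name)
        members.append(np.asarray(idx, dtype=np.intp))
    if not names:
        raise ValueError(
            f"{gmt_path}: no pathway shares any gene with the expression matrix"
        )
    if dropped:
        logger.info("%d pathway(s) dropped with zero matched genes", dropped)

    groups = GeneGroups(names, members, len(gene_ids), allow_overlap=True)
    leftover = unassigned_genes(groups)
    if leftover.size:
        logger.info("%d gene(s) belong to no pathway", leftover.size)
        if unmatched == "remainder":
            groups = GeneGroups(
                names + ["__remainder__"],
                members + [leftover],
                len(gene_ids),
                allow_overlap=True,
            )
    return groups


def groups_sequential(p: int, K: int) -> GeneGroups:
    """Partition ``p`` gene columns into ``K`` contiguous near-equal blocks.

    Block sizes differ by at most one; blocks are disjoint and cover
    ``0..p-1`` in order.
    """
    if not 1 <= K <= p:
        raise ValueError(f"need 1 <= K <= p, got K={K}, p={p}")
    blocks = np.array_split(np.arange(p, dtype=np.intp), K)
    names = [f"block_{j + 1}" for j in range(K)]
    return GeneGroups(names, blocks, p, allow_overlap=False)


def groups_by_marginal_correlation(
    X: np.ndarray, y: np.ndarray, K: int
) -> GeneGroups:
    """Rank genes by |Pearson correlation with y| and split into K blocks.

    Group 1 holds the most strongly correlated genes.  Zero-variance genes
    get correlation 0 (ranked last); ties are broken by original column
    order (stable sort), so the construction is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    if K < 1:
        raise ValueError("K must be >= 1")
    sy = y.std()
    if sy == 0:
        raise ValueError("phenotype has zero variance")
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * (y - y.mean())[:, None]).mean(axis=0) / (sx * sy)
    r[~np.isfinite(r)] = 0.0  # zero-variance gene -> correlation 0
    order = np.argsort(-np.abs(r), kind="stable").astype(np.intp)
    blocks = np.array_split(order, min(K, X.shape[1]))
    if len(blocks) < K:
        raise ValueError(f"cannot form {K} non-empty groups from {X.shape[1]} genes")
    names = [f"corr_rank_{j + 1}" for j in range(K)]
    return GeneGroups(names, blocks, X.shape[1], allow_overlap=False)


def unassigned_genes(groups: GeneGroups) -> np.ndarray:
    """Column indices covered by none of the groups."""
    covered = np.zeros(groups.n_genes_total, dtype=bool)
    for m in groups.members:
        covered[m] = True
    return np.flatnonzero(~covered).astype(np.intp)


def multi_membership_fraction(groups: GeneGroups) -> float:
    """Fraction of covered genes that belong to two or more groups."""
    counts = np.zeros(groups.n_genes_total, dtype=int)
    for m in groups.members:
        counts[m] += 1
    covered = counts > 0
    if not covered.any():
        return 0.0
    return float((counts >= 2).sum() / covered.sum())


def groups_to_tsv(groups: GeneGroups, path: str | Path, gene_ids: list[str]) -> None:
    """Export group definitions as two-column TSV (group_name, gene_id)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("group_name\tgene_id\n")
        for name, idx in zip(groups.group_names, groups.members):
            for i in idx:
                fh.write(f"{name}\t{gene_ids[i]}\n")


def groups_from_tsv(
    path: str | Path, gene_ids: list[str], allow_overlap: bool = True
) -> GeneGroups:
    """Re-import group definitions written by :func:`groups_to_tsv`."""
    col = {g: i for i, g in enumerate(gene_ids)}
    by_name: dict[str, list[int]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("group_name"):
            raise ValueError(f"{path}: missing 'group_name\\tgene_id' header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                name, gene = line.rstrip("\n").split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: expected 2 fields") from exc
            if gene not in col:
                raise ValueError(f"{path}: line {lineno}: unknown gene id {gene!r}")
            by_name.setdefault(name, []).append(col[gene])
    names = list(by_name)
    members = [np.asarray(sorted(v), dtype=np.intp) for v in by_name.values()]
    return GeneGroups(names, members, len(gene_ids), allow_overlap=allow_overlap)
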