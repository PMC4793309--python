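"""Target structural-similarity network and pathway over-representation.

Whole-chain similarity between two targets is measured by sequence-guided
superposition: a global BLOSUM62 alignment picks corresponding Cα pairs, and
the Kabsch RMSD over those pairs scores the pair.  Targets closer than a
threshold (4 Å by default) are linked in the network.

Pathway enrichment is a local hypergeometric upper-tail test of the target
gene set against each pathway of a user-supplied GMT annotation, with
Benjamini–Hochberg (default) or Bonferroni adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .search import kabsch
from .structures import Structure

logger = logging.getLogger(__name__)


def _aligner(gap: float = -5.0) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = gap
    al.extend_gap_score = gap
    return al


def pairwise_rmsd(a: Structure, b: Structure, gap: float = -5.0) -> float | None:
    """Sequence-alignment-guided Cα RMSD; None when <3 residues align."""
    seq_a = a.sequence.replace("X", "A")
    seq_b = b.sequence.replace("X", "A")
    aln = _aligner(gap).align(seq_a, seq_b)[0]
    ia: list[int] = []
    ib: list[int] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        ia.extend(range(a0, a1))
        ib.extend(range(b0, b1))
    if len(ia) < 3:
        return None
    _, rmsd = kabsch(a.ca_coords()[ia], b.ca_coords()[ib])
    return rmsd


def build_network(
    structures: Mapping[str, Structure],
    categories: Mapping[str, str] | None = None,
    threshold: float = 4.0,
) -> nx.Graph:
    """Graph with an edge wherever pairwise RMSD < *threshold* (strict)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    g = nx.Graph()
    categories = categories or {}
    ids = list(structures)
    for sid in ids:
        g.add_node(sid, category=categories.get(sid, "new"))
    for i, sa in enumerate(ids):
        for sb in ids[i + 1:]:
            r = pairwise_rmsd(structures[sa], structures[sb])
            if r is not None and r < threshold:
                g.add_edge(sa, sb, rmsd=round(r, 4))
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\trmsd\n")
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['rmsd']:.4f}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# Pathway enrichment
# ---------------------------------------------------------------------------

@dataclass
class PathwayDB:
    pathways: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("empty background gene universe")
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name} is empty")
            if not genes <= self.background:
                raise ValueError(f"pathway {name} has genes outside the background")


@dataclass
class EnrichmentResult:
    pathway: str
    count: int
    percentage: float
    p_raw: float
    p_adj: float
    method: str
    significant: bool


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> PathwayDB:
    """GMT format: one pathway per line (name, description, member genes...)."""
    pathways: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip().split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        pathways[fields[0]] = set(fields[2:])
    bg = set(background) if background is not None else set().union(*pathways.values())
    return PathwayDB(pathways=pathways, background=bg)


def adjust_p(p_values: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment preserving input order (BH or Bonferroni)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return []
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method.lower()]
    return list(multipletests(p, method=key)[1])


def enrich(
    target_genes: set[str],
    db: PathwayDB,
    method: str = "bh",
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of *target_genes* in each pathway.

    P(X ≥ k) with k = overlap, K = pathway size, n = mapped targets,
    N = background size; percentage = k / n × 100 (denominator is the targets
    that map into the annotation background).  Results sorted by adjusted p.
    """
    mapped = target_genes & db.background
    dropped = target_genes - db.background
    if dropped:
        logger.warning("%d target genes outside the background dropped: %s",
                       len(dropped), sorted(dropped)[:5])
    if not mapped:
        raise ValueError("no target genes map into the annotation background")
    N, n = len(db.background), len(mapped)
    names = list(db.pathways)
    p_raw = []
    counts = []
    for name in names:
        K = len(db.pathways[name])
        k = len(mapped & db.pathways[name])
        counts.append(k)
        p_raw.append(float(hypergeom.sf(k - 1, N, K, n)))
    p_adj = adjust_p(p_raw, method)
    results = [
        EnrichmentResult(
            pathway=name,
            count=k,
            percentage=100.0 * k / n,
            p_raw=pr,
            p_adj=pa,
            method=method,
            significant=pa < alpha,
        )
        for name, k, pr, pa in zip(names, counts, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.pathway))
    return results


def write_enrichment_table(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\tcount\tpercentage\tp_raw\tp_adj\tmethod\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.pathway}\t{r.count}\t{r.percentage:.1f}\t{r.p_raw:.4g}\t"
                f"{r.p_adj:.4g}\t{r.method}\t{int(r.significant)}\n"
            )
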