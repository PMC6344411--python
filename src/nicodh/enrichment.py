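"""COG enrichment testing and Simpson-coefficient co-occurrence networks.

Enrichment asks, per COG, whether genes inside CODH-anchored directons carry
it more often than the rest of the protein-coding genes of the CODH-encoding
genomes.  The test is the one-sided (enrichment) Fisher exact test — the
hypergeometric upper tail P(X >= a) with margins fixed, computed via
log-factorial sums — followed by Benjamini–Hochberg FDR control; a COG is
flagged enriched when p < 0.05 and q < 0.05.  The CODH COGs themselves
(COG1151, COG1152) are excluded from testing.

The co-occurrence network scores every feature pair (enriched COGs,
structural-group labels, family-level taxonomies) over the locus x feature
boolean matrix with the Simpson overlap coefficient |u ∩ v| / min(|u|, |v|),
emitting edges at coefficient >= 0.4; COG features present in fewer than 25
loci are dropped (the floor applies to COGs only).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .context import ContextLocus

DEFAULT_ALPHA = 0.05
DEFAULT_FDR = 0.05
DEFAULT_TAU = 0.4
DEFAULT_MIN_COG_LOCI = 25
EXCLUDED_COGS = frozenset({"COG1151", "COG1152"})

#: feature-kind namespaces used for FeatureMatrix column labels
COG_PREFIX = "COG:"
GROUP_PREFIX = "SG:"
FAMILY_PREFIX = "FAM:"


@dataclass(frozen=True)
class ContingencyTable:
    """Gene counts over all CODH-encoding genomes.

    a: directon genes with the COG; b: directon genes without it;
    c: non-directon genes with it; d: non-directon genes without it.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


@dataclass
class EnrichmentResult:
    cog: str
    table: ContingencyTable
    p: float
    q: float
    enriched: bool


def _lgamma(n: int) -> float:
    return math.lgamma(n + 1)


def fisher_exact_greater(table: ContingencyTable) -> float:
    """One-sided Fisher exact p-value for enrichment (upper tail).

    With margins fixed, p = P(X >= a) under the hypergeometric law; terms are
    accumulated from log-factorials for numerical range.  Zero margins
    (a+b = 0 or a+c = 0) give p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b  # directon genes
    col1 = a + c  # genes with the COG
    if row1 == 0 or col1 == 0:
        return 1.0
    log_denom = _lgamma(n) - _lgamma(row1) - _lgamma(n - row1)
    total = 0.0
    for k in range(a, min(row1, col1) + 1):
        log_num = (
            _lgamma(col1) - _lgamma(k) - _lgamma(col1 - k)
            + _lgamma(n - col1) - _lgamma(row1 - k) - _lgamma(n - col1 - row1 + k)
        )
        total += math.exp(log_num - log_denom)
    return min(total, 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=DEFAULT_FDR, method="fdr_bh")
    return [float(x) for x in q]


def find_enriched_cogs(
    context_loci: Sequence[ContextLocus],
    genes_by_replicon: Mapping[str, Sequence],
    annotations: Mapping[str, set[str]],
    alpha: float = DEFAULT_ALPHA,
    fdr: float = DEFAULT_FDR,
    excluded_cogs: frozenset[str] = EXCLUDED_COGS,
) -> tuple[set[str], list[EnrichmentResult]]:
    """Test every annotated COG for enrichment inside CODH directons.

    The contingency unit is the protein-coding gene across all supplied
    genomes: inside any CODH directon vs outside.  A gene carrying a COG
    several times counts once.  Returns the enriched id set plus the full
    per-COG result list (sorted by COG id).
    """
    directon_genes = set()
    for locus in context_loci:
        directon_genes.update(locus.directon_protein_ids)
    all_genes = [
        g.protein_id
        for genes in genes_by_replicon.values()
        for g in genes
    ]
    n_total = len(all_genes)
    n_directon = len(directon_genes)

    genes_with_cog: dict[str, set[str]] = {}
    for pid in all_genes:
        for cog in annotations.get(pid, set()):
            genes_with_cog.setdefault(cog, set()).add(pid)

    tested = sorted(set(genes_with_cog) - excluded_cogs)
    results: list[EnrichmentResult] = []
    for cog in tested:
        carriers = genes_with_cog[cog]
        a = len(carriers & directon_genes)
        b = n_directon - a
        c = len(carriers) - a
        d = n_total - n_directon - c
        tab = ContingencyTable(a, b, c, d)
        results.append(EnrichmentResult(cog, tab, fisher_exact_greater(tab),
                                        q=1.0, enriched=False))
    qs = bh_adjust([r.p for r in results])
    enriched = set()
    for r, q in zip(results, qs):
        r.q = q
        r.enriched = r.p < alpha and r.q < fdr
        if r.enriched:
            enriched.add(r.cog)
    return enriched, results


def simpson_coefficient(loci_u: Iterable, loci_v: Iterable) -> float:
    """Overlap coefficient |u ∩ v| / min(|u|, |v|); undefined on empty sets."""
    u, v = set(loci_u), set(loci_v)
    if not u or not v:
        raise ValueError("Simpson coefficient undefined for empty locus sets")
    return len(u & v) / min(len(u), len(v))


def build_feature_matrix(loci: Sequence[ContextLocus],
                         enriched_cogs: set[str]) -> pd.DataFrame:
    """Locus x feature boolean matrix.

    Columns are namespaced: ``COG:`` enriched COGs present in the locus,
    ``SG:`` the CODH structural group, ``FAM:`` the genome's family taxon.
    Every row has at least one true cell (its structural group).
    """
    rows = {}
    for locus in loci:
        feats = {COG_PREFIX + c for c in (locus.cogs & enriched_cogs)}
        if locus.group_label:
            feats.add(GROUP_PREFIX + locus.group_label)
        if locus.family:
            feats.add(FAMILY_PREFIX + locus.family)
        rows[locus.codh_protein_id] = feats
    columns = sorted(set().union(*rows.values())) if rows else []
    mat = pd.DataFrame(
        [[col in feats for col in columns] for feats in rows.values()],
        index=list(rows), columns=columns, dtype=bool,
    )
    return mat


@dataclass(frozen=True)
class NetworkEdge:
    u: str
    v: str
    simpson: float
    u_kind: str
    v_kind: str
    u_count: int
    v_count: int


def _kind(label: str) -> str:
    for prefix, kind in ((COG_PREFIX, "cog"), (GROUP_PREFIX, "group"),
                         (FAMILY_PREFIX, "family")):
        if label.startswith(prefix):
            return kind
    return "other"


def build_network(matrix: pd.DataFrame, tau: float = DEFAULT_TAU,
                  min_cog_loci: int = DEFAULT_MIN_COG_LOCI) -> list[NetworkEdge]:
    """Simpson-scored feature pairs passing the edge threshold.

    COG columns present in fewer than *min_cog_loci* loci are dropped first
    (the floor is scoped to COGs; group and taxonomy columns always stay);
    features with empty locus sets are skipped rather than scored.
    """
    counts = matrix.sum(axis=0)
    keep = [
        col for col in matrix.columns
        if int(counts[col]) > 0
        and (not col.startswith(COG_PREFIX) or int(counts[col]) >= min_cog_loci)
    ]
    locus_sets = {col: set(matrix.index[matrix[col]]) for col in keep}
    edges = []
    for u, v in itertools.combinations(sorted(keep), 2):
        s = simpson_coefficient(locus_sets[u], locus_sets[v])
        if s >= tau:
            edges.append(NetworkEdge(
                u=u, v=v, simpson=s, u_kind=_kind(u), v_kind=_kind(v),
                u_count=len(locus_sets[u]), v_count=len(locus_sets[v]),
            ))
    return edges


def edges_to_dataframe(edges: Sequence[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"u": e.u, "v": e.v, "simpson": e.simpson, "u_kind": e.u_kind,
          "v_kind": e.v_kind, "u_count": e.u_count, "v_count": e.v_count}
         for e in edges],
        columns=["u", "v", "simpson", "u_kind", "v_kind", "u_count", "v_count"],
    )


def edges_to_graph(edges: Sequence[NetworkEdge]) -> nx.Graph:
    """Undirected co-occurrence graph with node kind/locus-count attributes."""
    g = nx.Graph()
    for e in edges:
        g.add_node(e.u, kind=e.u_kind, locus_count=e.u_count)
        g.add_node(e.v, kind=e.v_kind, locus_count=e.v_count)
        g.add_edge(e.u, e.v, simpson=e.simpson)
    return g


def enrichment_to_dataframe(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"cog": r.cog, "a": r.table.a, "b": r.table.b, "c": r.table.c,
          "d": r.table.d, "p": r.p, "q": r.q, "enriched": r.enriched}
         for r in results],
        columns=["cog", "a", "b", "c", "d", "p", "q", "enriched"],
    )
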