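"""Rank-based gene-set enrichment for topic characterisation.

For every topic, genes are ordered by their per-topic probability phi_k and
each annotation term is tested with a one-sided two-sample
Kolmogorov-Smirnov test: are the per-topic probabilities of the term's
member genes stochastically greater than those of non-members (i.e. does
the term concentrate at the top of the topic's ranking)?

Terms usually live in a DAG (e.g. an ontology) whose parent terms inherit
all genes of their descendants, so raw tests on related terms are highly
correlated.  Two decorrelation schemes are provided alongside the plain
per-term test:

* ``classic`` — independent KS test per term;
* ``elim``   — terms are processed most-specific first; once a term tests
  significant, its genes are eliminated from all its ancestors before they
  are tested;
* ``weight`` — a comparative variant: when a child term achieves a smaller
  raw p-value than its parent, the child's genes are removed from the
  parent's member set and the parent is re-tested, so generic ancestors are
  not flagged merely for containing one strong specific descendant.

On a DAG with no edges all three methods coincide.  P-values are
Bonferroni-corrected per topic, and terms can be partitioned into those
significant in exactly one topic ("unique") or in a minority of topics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .lda import TopicModel


@dataclass
class GeneSetDAG:
    """Term metadata, term -> gene annotations and an acyclic parent graph.

    After loading, annotations are upward-closed: every ancestor contains
    all genes of its descendants.
    """

    terms: dict[str, tuple[str, str]]  # term_id -> (name, namespace)
    term_genes: dict[str, set[str]]
    parents: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.term_genes:
            self.terms.setdefault(t, (t, ""))
        self.parents = {t: set(p) for t, p in self.parents.items()}
        for t in self.terms:
            self.parents.setdefault(t, set())
        g = self.parent_graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("term relationships contain a cycle")
        self._propagate()

    def parent_graph(self) -> nx.DiGraph:
        """Directed graph with edges parent -> child."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(p, child)
        return g

    def _propagate(self) -> None:
        """Push genes upward so ancestors contain their descendants' genes."""
        g = self.parent_graph()
        for t in self.terms:
            self.term_genes.setdefault(t, set())
        # reverse topological order: children before parents
        for node in reversed(list(nx.topological_sort(g))):
            for parent in self.parents.get(node, ()):
                self.term_genes[parent] |= self.term_genes[node]

    def children(self, term: str) -> set[str]:
        return {t for t, ps in self.parents.items() if term in ps}

    def depths(self) -> dict[str, int]:
        """Longest path length from any root; specific terms are deepest."""
        g = self.parent_graph()
        depth = {t: 0 for t in self.terms}
        for node in nx.topological_sort(g):
            for child in g.successors(node):
                depth[child] = max(depth[child], depth[node] + 1)
        return depth


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """GMT: one term per line, ``term_id<TAB>description<TAB>gene...``."""
    out: dict[str, tuple[str, set[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        term, desc, genes = parts[0], parts[1], parts[2:]
        if term in out:
            raise ValueError(f"duplicate term in GMT: {term}")
        out[term] = (desc, {g for g in genes if g})
    return out


def write_gmt(term_genes: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for term in sorted(term_genes):
        desc = (descriptions or {}).get(term, term)
        lines.append("\t".join([term, desc] + sorted(term_genes[term])))
    Path(path).write_text("\n".join(lines) + "\n")


def load_gene_set_dag(gmt_path: str | Path,
                      dag_edges_path: str | Path | None = None,
                      term_meta_path: str | Path | None = None) -> GeneSetDAG:
    """Build a GeneSetDAG from a GMT file plus optional edge/metadata TSVs.

    Edge file: two columns ``child_id<TAB>parent_id``.  Metadata file:
    ``term_id<TAB>name<TAB>namespace``.
    """
    gmt = read_gmt(gmt_path)
    terms = {t: (desc, "") for t, (desc, _) in gmt.items()}
    term_genes = {t: set(genes) for t, (_, genes) in gmt.items()}
    parents: dict[str, set[str]] = {}
    if dag_edges_path is not None:
        df = pd.read_csv(dag_edges_path, sep="\t", header=None, dtype=str,
                         comment="#")
        for child, parent in zip(df.iloc[:, 0], df.iloc[:, 1]):
            parents.setdefault(child, set()).add(parent)
    if term_meta_path is not None:
        meta = pd.read_csv(term_meta_path, sep="\t", header=None, dtype=str)
        for _, row in meta.iterrows():
            name = row.iloc[1] if len(row) > 1 else row.iloc[0]
            ns = row.iloc[2] if len(row) > 2 else ""
            terms[row.iloc[0]] = (name, ns)
    return GeneSetDAG(terms, term_genes, parents)


# ---------------------------------------------------------------------------
# Ranking and testing
# ---------------------------------------------------------------------------

def rank_genes(m: TopicModel, topic: int) -> list[tuple[str, float]]:
    """Genes of one topic sorted by per-topic probability, descending.

    ``topic`` is 1-based.  Ties break lexicographically by gene id.
    """
    if not (1 <= topic <= m.K):
        raise ValueError(f"topic must be in 1..{m.K}")
    row = m.phi[topic - 1]
    order = sorted(range(len(row)), key=lambda i: (-row[i], m.gene_ids[i]))
    return [(m.gene_ids[i], float(row[i])) for i in order]


def ks_term_test(ranked: list[tuple[str, float]], term_genes: set[str],
                 min_term_size: int = 3,
                 max_term_fraction: float = 0.5) -> float | None:
    """One-sided KS p-value that member genes score higher than non-members.

    Returns None (skip) when fewer than ``min_term_size`` members are in the
    ranked universe or the term covers more than ``max_term_fraction`` of it.
    A term covering the whole universe has no contrast and returns p = 1.
    """
    scores = {g: s for g, s in ranked}
    members = np.array([s for g, s in ranked if g in term_genes])
    others = np.array([s for g, s in ranked if g not in term_genes])
    if members.size == len(scores):
        return 1.0
    if members.size < min_term_size:
        return None
    if members.size > max_term_fraction * len(scores):
        return None
    # alternative='less': the members' empirical CDF lies below the others',
    # i.e. member scores are stochastically greater (enriched at the top)
    res = ks_2samp(members, others, alternative="less")
    return float(res.pvalue)


def _depth_order(dag: GeneSetDAG) -> list[str]:
    depth = dag.depths()
    return sorted(dag.terms, key=lambda t: (-depth[t], t))


def enrich_topic(m: TopicModel, topic: int, dag: GeneSetDAG,
                 method: str = "weight", sig_threshold: float = 0.01,
                 min_term_size: int = 3,
                 max_term_fraction: float = 0.5) -> pd.DataFrame:
    """Test every term of the DAG against one topic's gene ranking.

    Returns a DataFrame with columns topic, term_id, name, p_raw,
    p_bonferroni, n_genes_in_term, method.  Bonferroni multiplies by the
    number of terms actually tested for this topic.
    """
    if method not in ("classic", "elim", "weight"):
        raise ValueError(f"unknown method {method!r}")
    ranked = rank_genes(m, topic)
    universe = {g for g, _ in ranked}

    working = {t: (dag.term_genes[t] & universe) for t in dag.terms}
    order = _depth_order(dag)
    kw = dict(min_term_size=min_term_size, max_term_fraction=max_term_fraction)

    p_raw: dict[str, float] = {}
    if method == "classic":
        for t in order:
            p = ks_term_test(ranked, working[t], **kw)
            if p is not None:
                p_raw[t] = p
    elif method == "elim":
        # most specific terms first; significant terms eliminate their genes
        # from all their ancestors before those are tested
        anc = {t: nx.ancestors(dag.parent_graph(), t) for t in dag.terms}
        for t in order:
            p = ks_term_test(ranked, working[t], **kw)
            if p is None:
                continue
            p_raw[t] = p
            if p < sig_threshold:
                for a in anc[t]:
                    working[a] = working[a] - working[t]
    else:  # weight (comparative child-vs-parent down-weighting)
        original = {t: set(working[t]) for t in dag.terms}
        for t in order:
            p = ks_term_test(ranked, working[t], **kw)
            if p is None:
                continue
            # children were processed earlier (they are deeper); a child with
            # a stronger signal claims its genes away from the parent
            removed = False
            for c in sorted(dag.children(t)):
                if c in p_raw and p_raw[c] < p:
                    working[t] = working[t] - original[c]
                    removed = True
            if removed:
                p2 = ks_term_test(ranked, working[t], **kw)
                p = p2 if p2 is not None else 1.0
            p_raw[t] = p

    m_tests = len(p_raw)
    rows = []
    for t in sorted(p_raw):
        rows.append({
            "topic": topic, "term_id": t, "name": dag.terms[t][0],
            "p_raw": p_raw[t],
            "p_bonferroni": min(1.0, m_tests * p_raw[t]),
            "n_genes_in_term": len(dag.term_genes[t] & universe),
            "method": method,
        })
    return pd.DataFrame(rows, columns=["topic", "term_id", "name", "p_raw",
                                       "p_bonferroni", "n_genes_in_term",
                                       "method"])


def enrich_all_topics(m: TopicModel, dag: GeneSetDAG, method: str = "weight",
                      sig_threshold: float = 0.01, **kw) -> pd.DataFrame:
    tables = [enrich_topic(m, k, dag, method, sig_threshold, **kw)
              for k in range(1, m.K + 1)]
    return pd.concat(tables, ignore_index=True)


def partition_unique_terms(table: pd.DataFrame, alpha: float = 0.05,
                           n_topics: int | None = None) -> pd.DataFrame:
    """Flag terms significant in exactly one topic, and the minority list.

    ``unique_to_topic`` marks rows whose term passes Bonferroni significance
    (< alpha) in exactly one topic.  ``in_minority`` marks significant rows
    of terms significant in strictly fewer than half the topics (the
    boundary count of exactly K/2 is excluded).
    """
    if table["topic"].nunique() < 2:
        raise ValueError("need enrichment tables for at least 2 topics")
    K = n_topics if n_topics is not None else int(table["topic"].nunique())
    sig = table[table["p_bonferroni"] < alpha]
    counts = sig.groupby("term_id")["topic"].nunique()
    out = table.copy()
    is_sig = out["p_bonferroni"] < alpha
    n_sig = out["term_id"].map(counts).fillna(0)
    out["unique_to_topic"] = is_sig & (n_sig == 1)
    out["in_minority"] = is_sig & (n_sig < K / 2)
    return out


def enrichment_to_tsv(table: pd.DataFrame) -> str:
    return table.to_csv(sep="\t", index=False)


def significant_terms_dot(table: pd.DataFrame, dag: GeneSetDAG,
                          alpha: float = 0.05) -> str:
    """DOT subgraph of significant terms, coloured by their best topic."""
    palette = ["#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
               "#a65628", "#f781bf", "#999999"]
    sig = table[table["p_bonferroni"] < alpha]
    best = sig.loc[sig.groupby("term_id")["p_raw"].idxmin()]
    lines = ["digraph significant_terms {"]
    kept = set(best["term_id"])
    for _, row in best.sort_values("term_id").iterrows():
        col = palette[(int(row["topic"]) - 1) % len(palette)]
        lines.append(f'  "{row["term_id"]}" [label="{row["name"]}\\n'
                     f'topic {row["topic"]}", color="{col}"];')
    for child in sorted(kept):
        for parent in sorted(dag.parents.get(child, ())):
            if parent in kept:
                lines.append(f'  "{parent}" -> "{child}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
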