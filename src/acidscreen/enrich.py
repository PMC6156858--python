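"""Classic-Fisher GO term over-representation analysis.

The gene universe is every quantified gene (CPM > 1 in at least 3 samples by
default); the study set is the significantly differentially expressed genes
(adjusted p < alpha). Annotations are closed under the true-path rule (a gene
annotated to a term is annotated to all its ancestors), terms annotated to
fewer than 5 universe genes are excluded before testing, each remaining term
gets a one-sided Fisher exact (hypergeometric upper-tail) p-value, and the
1000 lowest-p terms are kept. Term p-values are reported raw: significance is
judged at alpha without multiple-testing correction, matching the classic
algorithm's convention.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "AnnotationMap",
    "define_universe",
    "filter_de",
    "propagate_annotations",
    "fisher_term_test",
    "run_enrichment",
]


class AnnotationMap:
    """Gene->term and term->gene views of a propagated annotation set."""

    def __init__(self, gene_to_terms: dict[str, frozenset[str]]):
        self.gene_to_terms = gene_to_terms
        term_to_genes: dict[str, set[str]] = {}
        for gene, terms in gene_to_terms.items():
            for t in terms:
                term_to_genes.setdefault(t, set()).add(gene)
        self.term_to_genes = {t: frozenset(g) for t, g in term_to_genes.items()}

    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_to_terms)

    def terms(self) -> frozenset[str]:
        return frozenset(self.term_to_genes)

    def __eq__(self, other):
        return (
            isinstance(other, AnnotationMap) and self.gene_to_terms == other.gene_to_terms
        )


def define_universe(counts: pd.DataFrame, cpm_min: float = 1.0, min_samples: int = 3):
    """Quantified-gene universe: CPM > cpm_min in at least min_samples samples.

    CPM(g, s) = 1e6 * count(g, s) / library_size(s).
    """
    if counts.shape[1] < min_samples:
        raise ValueError(f"need >= {min_samples} samples, got {counts.shape[1]}")
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    cpm = counts * 1e6 / lib
    keep = (cpm > cpm_min).sum(axis=1) >= min_samples
    return frozenset(counts.index[keep])


def filter_de(table: pd.DataFrame, alpha: float = 0.05, fc_threshold: float = 2.0):
    """Split a DE table into the significant and the high-fold-change sets.

    significant = {padj < alpha} (strict); high-fc = significant genes with
    |log2fc| > log2(fc_threshold) (strict), i.e. fold change > 2 in either
    direction at the default.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if "padj" not in table.columns:
        raise ValueError("DE table lacks a padj column")
    sig_mask = table["padj"] < alpha
    significant = frozenset(table.loc[sig_mask, "gene_id"])
    lfc_cut = np.log2(fc_threshold)
    high_fc = frozenset(
        table.loc[sig_mask & (table["log2fc"].abs() > lfc_cut), "gene_id"]
    )
    return significant, high_fc


def propagate_annotations(raw: pd.DataFrame, ontology: nx.DiGraph) -> AnnotationMap:
    """Close direct annotations under the true-path rule.

    A gene annotated to a term becomes annotated to every ancestor of that
    term (edges run child->parent, so ancestors are the terms reachable by
    following edges). Idempotent by construction.
    """
    unknown = sorted(set(raw["term"]) - set(ontology.nodes))
    if unknown:
        raise ValueError(f"annotation terms not in ontology: {unknown}")
    # cache ancestor closures per term; nx.descendants follows edge direction
    closure: dict[str, frozenset[str]] = {}
    gene_to_terms: dict[str, set[str]] = {}
    for gene, term in raw[["gene", "term"]].itertuples(index=False):
        if term not in closure:
            closure[term] = frozenset(nx.descendants(ontology, term)) | {term}
        gene_to_terms.setdefault(gene, set()).update(closure[term])
    return AnnotationMap({g: frozenset(t) for g, t in gene_to_terms.items()})


def fisher_term_test(
    term: str, study: frozenset, universe: frozenset, annotations: AnnotationMap
) -> float:
    """One-sided (over-representation) Fisher exact p-value for one term.

    Equals the hypergeometric upper tail P(X >= k) for k study genes
    annotated to the term, drawn from a universe of N genes of which K are
    annotated. A term with no universe annotations returns p = 1.
    """
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    annotated = annotations.term_to_genes.get(term, frozenset()) & universe
    K = len(annotated)
    if K == 0:
        return 1.0
    N = len(universe)
    n = len(study)
    k = len(annotated & study)
    return float(hypergeom.sf(k - 1, N, K, n))


def run_enrichment(
    study: frozenset,
    universe: frozenset,
    annotations: AnnotationMap,
    min_annotated: int = 5,
    alpha: float = 0.05,
    top_n: int = 1000,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Test every sufficiently annotated term and rank by p-value.

    Terms with fewer than ``min_annotated`` universe genes are excluded
    before testing; survivors are sorted by ascending p (ties broken by term
    id for reproducibility), ranked 1.., truncated to ``top_n``. The
    ``significant`` column marks p < alpha (raw, uncorrected).
    """
    if not study:
        raise ValueError("study set is empty")
    study = frozenset(study) & frozenset(universe)
    rows = []
    for term in sorted(annotations.term_to_genes):
        in_universe = annotations.term_to_genes[term] & universe
        if len(in_universe) < min_annotated:
            continue
        p = fisher_term_test(term, study, universe, annotations)
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, term),
                "n_universe": len(in_universe),
                "n_study": len(in_universe & study),
                "p_fisher": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "n_universe", "n_study", "p_fisher"]
    )
    out = out.sort_values(["p_fisher", "term_id"], kind="mergesort").head(top_n)
    out = out.reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["significant"] = out["p_fisher"] < alpha
    return out
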