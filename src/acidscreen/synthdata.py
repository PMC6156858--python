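"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the five input classes the pipeline consumes: plate-
reader screens (with known per-compound inhibition), dose-response series
(with known 4PL parameters), a rooted ontology DAG, gene->term annotations
with a differential-expression table (with terms of known enrichment), and a
negative-binomial count matrix (with genes of known fold change). Every
generator is a pure function of its arguments, including the seed: the same
call produces bitwise-identical output.

Default study conditions mirror a 1280-compound single-dose screen in 96-well
plates with quadruplicate negative (vehicle) and positive (cytotoxic QC)
control wells per plate, a positive control leaving ~20% viability, a 70%
inhibition hit threshold, and bulk RNA-seq in two conditions with biological
triplicates.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "OntologySpec",
    "DESpec",
    "gen_screen_plates",
    "gen_dose_response",
    "gen_ontology",
    "gen_annotations_and_de",
    "gen_counts",
    "four_pl",
]

#: Fractional viability knocked out by the positive control (QC compound
#: leaves ~20% viability, i.e. ~80% inhibition).
DEFAULT_POS_EFFECT = 0.8

#: Arbitrary plate-reader signal of an untreated well; the normalization is
#: anchor-based, so the absolute scale is irrelevant downstream.
DEFAULT_NEG_SIGNAL = 10_000.0


def _well_labels(wells_per_plate: int) -> list[str]:
    """Row-major well labels (A1..H12 for a 96-well plate)."""
    n_cols = 12 if wells_per_plate % 12 == 0 else wells_per_plate
    n_rows = math.ceil(wells_per_plate / n_cols)
    labels = []
    for r in range(n_rows):
        for c in range(n_cols):
            if len(labels) == wells_per_plate:
                break
            labels.append(f"{string.ascii_uppercase[r]}{c + 1}")
    return labels


def gen_screen_plates(
    n_compounds: int = 1280,
    wells_per_plate: int = 96,
    n_neg: int = 4,
    n_pos: int = 4,
    noise_cv: float = 0.05,
    seed: int = 0,
    hit_fraction: float = 0.043,
    hit_range: tuple[float, float] = (85.0, 120.0),
    nonhit_range: tuple[float, float] = (0.0, 40.0),
    hit_threshold: float = 70.0,
    pos_effect: float = DEFAULT_POS_EFFECT,
    neg_signal: float = DEFAULT_NEG_SIGNAL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a single-dose screen, one compound per well.

    Each plate carries its own ``n_neg`` untreated and ``n_pos`` positive
    control wells (placed after the compound wells); compounds fill the
    remaining wells across as many plates as needed. A compound with true
    inhibition ``t`` (percent) produces signal
    ``neg_signal * (1 - t/100 * pos_effect)``, so anchor normalization
    against the plate controls recovers ``t`` exactly in the noiseless case.
    Well noise is multiplicative log-normal with coefficient of variation
    ``noise_cv``.

    Returns
    -------
    (plates, truth)
        ``plates``: long-format table (plate_id, well, role, compound_id,
        intensity). ``truth``: per-compound (compound_id, true_inhibition,
        is_true_hit) with ``is_true_hit = true_inhibition > hit_threshold``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_compounds <= 0 or wells_per_plate <= 0 or n_neg <= 0 or n_pos <= 0:
        raise ValueError("counts must be positive")
    if n_neg < 2 or n_pos < 2:
        raise ValueError("need >= 2 control wells per role for Z-factor QC")
    compounds_per_plate = wells_per_plate - n_neg - n_pos
    if compounds_per_plate < 1:
        raise ValueError("wells_per_plate must exceed n_neg + n_pos")

    rng = np.random.default_rng(seed)
    compound_ids = [f"C{i + 1:04d}" for i in range(n_compounds)]
    is_hit = rng.random(n_compounds) < hit_fraction
    true_inhibition = np.where(
        is_hit,
        rng.uniform(*hit_range, n_compounds),
        rng.uniform(*nonhit_range, n_compounds),
    )
    truth = pd.DataFrame(
        {
            "compound_id": compound_ids,
            "true_inhibition": true_inhibition,
            "is_true_hit": true_inhibition > hit_threshold,
        }
    )

    labels = _well_labels(wells_per_plate)
    n_plates = math.ceil(n_compounds / compounds_per_plate)
    rows = []
    for p in range(n_plates):
        plate_id = f"P{p + 1:03d}"
        start = p * compounds_per_plate
        plate_compounds = compound_ids[start : start + compounds_per_plate]
        idx = 0
        for cid in plate_compounds:
            t = true_inhibition[start + idx]
            signal = neg_signal * (1.0 - t / 100.0 * pos_effect)
            rows.append((plate_id, labels[idx], "compound", cid, signal))
            idx += 1
        ctrl_start = compounds_per_plate  # controls sit in the fixed tail block
        for j in range(n_neg):
            rows.append((plate_id, labels[ctrl_start + j], "neg", "", neg_signal))
        for j in range(n_pos):
            rows.append(
                (
                    plate_id,
                    labels[ctrl_start + n_neg + j],
                    "pos",
                    "",
                    neg_signal * (1.0 - pos_effect),
                )
            )
    plates = pd.DataFrame(
        rows, columns=["plate_id", "well", "role", "compound_id", "intensity"]
    )
    if noise_cv > 0:
        # log-normal with unit mean and the requested CV
        sigma2 = math.log(1.0 + noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=len(plates))
        plates["intensity"] = plates["intensity"] * noise
    return plates, truth


def four_pl(dose, top: float, bottom: float, ic50: float, hill: float):
    """Four-parameter logistic response: bottom + (top-bottom)/(1+(d/ic50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, dose / ic50, 0.0)
        power = np.zeros_like(ratio)
        pos = ratio > 0
        power[pos] = ratio[pos] ** hill
        # d = 0 with a negative hill diverges; the limit of the response is bottom
        zero_div = (dose == 0) & (hill < 0)
    out = bottom + (top - bottom) / (1.0 + power)
    return np.where(zero_div, bottom, out)


def gen_dose_response(
    params_4pl: tuple[float, float, float, float],
    doses,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a viability dose-response series from a 4PL curve.

    ``params_4pl`` is (top, bottom, ic50, hill) with ic50 in µM and
    viability in percent; Gaussian noise with sd ``noise_sd`` (viability
    units) is added per well.
    """
    top, bottom, ic50, hill = params_4pl
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if hill == 0:
        raise ValueError("hill slope must be nonzero")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be nonnegative")
    rng = np.random.default_rng(seed)
    viability = four_pl(doses, top, bottom, ic50, hill)
    if noise_sd > 0:
        viability = viability + rng.normal(0.0, noise_sd, size=doses.shape)
    return pd.DataFrame({"dose_uM": doses, "viability": viability})


@dataclass(frozen=True)
class OntologySpec:
    """Shape of a synthetic rooted term DAG (edges child->parent)."""

    n_terms: int = 200
    max_parents: int = 2
    depth: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 1 or self.max_parents < 1 or self.depth < 1:
            raise ValueError("n_terms, max_parents and depth must be >= 1")


def gen_ontology(spec: OntologySpec) -> nx.DiGraph:
    """Generate a rooted DAG of terms with edges directed child -> parent.

    Terms are placed on levels 0 (the single root) through ``spec.depth``;
    each non-root term draws 1..max_parents parents from strictly shallower
    levels, so the graph is acyclic, every term reaches the root, and the
    root is the unique node with out-degree 0.
    """
    rng = np.random.default_rng(spec.seed)
    terms = [f"T{i + 1:07d}" for i in range(spec.n_terms)]
    g = nx.DiGraph()
    depth = min(spec.depth, spec.n_terms - 1) if spec.n_terms > 1 else 0
    levels: dict[str, int] = {terms[0]: 0}
    g.add_node(terms[0], name="term 1 (root)", level=0)
    for i, term in enumerate(terms[1:], start=1):
        # spread terms across levels 1..depth, guaranteeing each is occupied
        level = (i - 1) % depth + 1 if i <= depth else int(rng.integers(1, depth + 1))
        shallower = [t for t, lv in levels.items() if lv < level]
        k = min(int(rng.integers(1, spec.max_parents + 1)), len(shallower))
        parents = rng.choice(len(shallower), size=k, replace=False)
        g.add_node(term, name=f"term {i + 1} (level {level})", level=level)
        for j in parents:
            g.add_edge(term, shallower[j])
        levels[term] = level
    return g


@dataclass(frozen=True)
class DESpec:
    """Planted differential-expression and term-enrichment design.

    ``enrichment_odds`` is the odds ratio by which genes directly annotated
    to a planted term are more likely to be differentially expressed;
    padj values are assigned so that exactly the DE genes pass ``alpha``.
    """

    n_genes: int = 2000
    frac_de: float = 0.1
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    planted_terms: tuple[str, ...] = ()
    enrichment_odds: float = 20.0
    alpha: float = 0.05
    annotations_per_gene: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.frac_de < 1:
            raise ValueError("frac_de must lie in (0, 1)")
        if self.frac_de * self.n_genes < 1:
            raise ValueError("frac_de * n_genes must be >= 1")
        if self.enrichment_odds <= 0:
            raise ValueError("enrichment_odds must be positive")


def _solve_baseline_rate(frac_de: float, frac_planted: float, odds: float) -> float:
    """Baseline DE probability p0 such that the mixture hits frac_de overall.

    Planted-pool genes get p1 with odds(p1) = odds * odds(p0).
    """
    if odds == 1.0 or frac_planted == 0.0:
        return frac_de

    def mixture(p0):
        p1 = odds * p0 / (1.0 + (odds - 1.0) * p0)
        return frac_planted * p1 + (1.0 - frac_planted) * p0 - frac_de

    lo, hi = 1e-12, frac_de
    if mixture(hi) < 0:  # odds < 1 shifts mass away from planted genes
        hi = 1.0 - 1e-12
    return float(brentq(mixture, lo, hi))


def gen_annotations_and_de(
    ontology: nx.DiGraph, spec: DESpec
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Generate direct gene->term annotations and a matching DE table.

    Genes are annotated to leaf-ward terms (deeper half of the DAG); DE
    membership is enriched among genes directly annotated to the planted
    terms at ``spec.enrichment_odds``. Ancestor propagation (true-path rule)
    is left to the enrichment stage. Returns (annotations, de_table,
    planted_terms).
    """
    rng = np.random.default_rng(spec.seed)
    planted = list(spec.planted_terms)
    missing = [t for t in planted if t not in ontology]
    if missing:
        raise ValueError(f"planted terms not in ontology: {missing}")

    levels = nx.get_node_attributes(ontology, "level")
    max_level = max(levels.values()) if levels else 0
    cutoff = max(1, max_level // 2)
    candidates = sorted(
        t for t in ontology.nodes if levels.get(t, max_level) >= cutoff
    )
    candidates = sorted(set(candidates) | set(planted))
    if not candidates:
        candidates = sorted(ontology.nodes)

    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    k = min(spec.annotations_per_gene, len(candidates))
    ann_rows = []
    planted_set = set(planted)
    in_pool = np.zeros(spec.n_genes, dtype=bool)
    for i, gene in enumerate(genes):
        picks = rng.choice(len(candidates), size=k, replace=False)
        terms = [candidates[j] for j in picks]
        ann_rows.extend((gene, t) for t in terms)
        in_pool[i] = any(t in planted_set for t in terms)
    annotations = pd.DataFrame(ann_rows, columns=["gene", "term"])

    frac_planted = float(in_pool.mean())
    p0 = _solve_baseline_rate(spec.frac_de, frac_planted, spec.enrichment_odds)
    p1 = spec.enrichment_odds * p0 / (1.0 + (spec.enrichment_odds - 1.0) * p0)
    de_prob = np.where(in_pool, p1, p0)
    is_de = rng.random(spec.n_genes) < de_prob

    padj = np.where(
        is_de,
        rng.uniform(spec.alpha * 1e-6, spec.alpha * 0.9, spec.n_genes),
        rng.uniform(spec.alpha * 1.02, 1.0, spec.n_genes),
    )
    pvalue = padj * rng.uniform(0.05, 1.0, spec.n_genes)
    sign = rng.choice([-1.0, 1.0], spec.n_genes)
    lfc = np.where(
        is_de,
        sign * np.abs(rng.normal(spec.lfc_mean, spec.lfc_sd, spec.n_genes)),
        rng.normal(0.0, 0.15, spec.n_genes),
    )
    de_table = pd.DataFrame(
        {"gene_id": genes, "log2fc": lfc, "pvalue": pvalue, "padj": padj, "is_de": is_de}
    )
    return annotations, de_table, planted


def gen_counts(
    n_genes: int = 2000,
    n_conditions: int = 2,
    n_replicates: int = 3,
    nb_dispersion: float = 0.05,
    de_gene_ids=(),
    lfc: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial count matrix, genes x samples.

    Genes listed in ``de_gene_ids`` have their mean multiplied by ``2**lfc``
    in condition 2; other conditions share the baseline mean. Variance
    follows the standard NB parameterization var = mu + dispersion * mu^2.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    de_mask = np.isin(genes, list(de_gene_ids))
    base_mean = rng.lognormal(mean=math.log(100.0), sigma=1.0, size=n_genes)
    n_param = 1.0 / nb_dispersion
    data = {}
    for c in range(1, n_conditions + 1):
        mu = base_mean * (2.0**lfc) ** (de_mask & (c == 2))
        p = n_param / (n_param + mu)
        for r in range(1, n_replicates + 1):
            data[f"cond{c}_rep{r}"] = rng.negative_binomial(n_param, p)
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    return counts
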