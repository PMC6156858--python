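"""End-to-end orchestration: screen -> enrichment -> communities -> expression.

A single global seed fans out into named per-stage streams (stable hashes of
the stage names), so any stage can be rerun in isolation and reruns with the
same configuration are byte-identical. ``demo`` generates the full synthetic
input set at small scale and runs the pipeline on it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, enrich, exprviz, gograph, io, screen, synthdata

__all__ = ["RunConfig", "derive_seed", "run_all", "demo", "simulate_inputs"]

log = logging.getLogger("acidscreen")


def derive_seed(seed: int, name: str) -> int:
    """Deterministic per-stage seed below 2**31 from (global seed, name)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run.

    Numeric defaults are the study's stated analysis settings: hit threshold
    70% inhibition, gene/term alpha 0.05, fold-change cut 2, minimum 5
    annotated genes per tested term, top 1000 terms, at most 200 spin states.
    """

    plates: str = "plates.csv"
    doses: str | None = None
    de_table: str = "de.tsv"
    counts: str = "counts.tsv"
    ontology: str = "go.obo"
    annotations: str = "annotations.tsv"
    out_dir: str = "run"
    threshold: float = 70.0
    alpha: float = 0.05
    fc_threshold: float = 2.0
    cpm_min: float = 1.0
    min_samples: int = 3
    min_annotated: int = 5
    top_n: int = 1000
    max_spins: int = 200
    gamma: float = 1.0
    edge_mode: str = "contracted"
    scale_mode: str = "unit_interval"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.threshold < 130:
            raise ValueError("threshold must lie in (0, 130)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold <= 0 or self.gamma <= 0:
            raise ValueError("fc_threshold and gamma must be positive")
        if min(self.min_annotated, self.top_n, self.max_spins, self.min_samples) < 1:
            raise ValueError("count parameters must be >= 1")
        if self.edge_mode not in ("contracted", "rep-ancestry"):
            raise ValueError("edge_mode must be 'contracted' or 'rep-ancestry'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_all(config: RunConfig) -> Path:
    """Run every stage on the configured inputs; returns the run directory.

    Writes: screen_results.tsv, hits.tsv, (fits.tsv), enrichment.tsv,
    significant_terms.txt, partition.tsv, representatives.tsv,
    collapsed.graphml, collapsed.dot, scaled_matrix.tsv, pca.tsv,
    community_profiles.tsv, heatmap_row_order.tsv and manifest.json.
    """
    config.validate()
    inputs = {
        "plates": config.plates,
        "de_table": config.de_table,
        "counts": config.counts,
        "ontology": config.ontology,
        "annotations": config.annotations,
    }
    if config.doses:
        inputs["doses"] = config.doses
    for name, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"{name} input not found: {path}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "acidscreen",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {},
        "parameters": dataclasses.asdict(config),
        "stages": {},
    }

    # --- screen ------------------------------------------------------------
    log.info("stage screen: normalizing %s", config.plates)
    plates = io.read_plates(config.plates)
    results = screen.normalize_screen(plates)
    results["hit"] = results["pct_inhibition"] > config.threshold
    results.to_csv(out / "screen_results.tsv", sep="\t", index=False)
    hits = screen.call_hits(results, threshold=config.threshold)
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    manifest["stages"]["screen"] = {
        "n_compounds": int(len(results)),
        "n_hits": int(len(hits)),
        "mean_zfactor": float(results.groupby("plate_id")["zfactor"].first().mean()),
    }

    if config.doses:
        log.info("stage confirm: fitting dose-response curves from %s", config.doses)
        dr = pd.read_csv(config.doses)
        fit_rows = []
        for (cid, line), grp in dr.groupby(["compound_id", "cell_line"], sort=True):
            try:
                fit = screen.fit_4pl(grp["dose_uM"].to_numpy(), grp["viability"].to_numpy())
            except (ValueError, screen.NoResponseError) as err:
                log.warning("fit failed for %s/%s: %s", cid, line, err)
                continue
            fit_rows.append(
                {
                    "compound_id": cid,
                    "cell_line": line,
                    "top": fit.top,
                    "bottom": fit.bottom,
                    "ic50_uM": fit.ic50,
                    "hill": fit.hill,
                    "rss": fit.rss,
                    "converged": fit.converged,
                }
            )
        fits = pd.DataFrame(fit_rows)
        fits.to_csv(out / "fits.tsv", sep="\t", index=False)
        manifest["stages"]["confirm"] = {"n_fits": int(len(fits))}

    # --- enrichment ---------------------------------------------------------
    log.info("stage enrich: universe + classic Fisher")
    counts = io.read_counts(config.counts)
    universe = enrich.define_universe(counts, cpm_min=config.cpm_min, min_samples=config.min_samples)
    de = io.read_de_table(config.de_table)
    significant, high_fc = enrich.filter_de(de, alpha=config.alpha, fc_threshold=config.fc_threshold)
    ontology = io.read_obo(config.ontology) if str(config.ontology).endswith(".obo") else io.read_edge_list(config.ontology)
    raw_ann = io.read_annotations(config.annotations)
    ann = enrich.propagate_annotations(raw_ann, ontology)
    study = significant & universe
    names = {t: str(d.get("name", t)) for t, d in ontology.nodes(data=True)}
    table = enrich.run_enrichment(
        study,
        universe,
        ann,
        min_annotated=config.min_annotated,
        alpha=config.alpha,
        top_n=config.top_n,
        term_names=names,
    )
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    sig_terms = sorted(table.loc[table["significant"], "term_id"])
    (out / "significant_terms.txt").write_text("".join(t + "\n" for t in sig_terms))
    manifest["stages"]["enrich"] = {
        "n_universe": len(universe),
        "n_significant_genes": len(significant),
        "n_high_fc_genes": len(high_fc),
        "n_terms_tested": int(len(table)),
        "n_significant_terms": len(sig_terms),
    }

    # --- communities ---------------------------------------------------------
    log.info("stage communities: spin-glass on %d significant terms", len(sig_terms))
    if not sig_terms:
        raise RuntimeError("enrich stage produced no significant terms")
    sub = gograph.build_subgraph(sig_terms, ontology)
    spin_seed = derive_seed(config.seed, "spinglass")
    tie_seed = derive_seed(config.seed, "tiebreak")
    manifest["stage_seeds"] = {"spinglass": spin_seed, "tiebreak": tie_seed}
    partition = gograph.spinglass_partition(
        sub, gamma=config.gamma, max_spins=config.max_spins, seed=spin_seed
    )
    scores = gograph.authority_scores(sub)
    reps = gograph.select_representatives(partition, scores, seed=tie_seed)
    collapsed = gograph.collapse(
        sub, partition, reps, sig_terms, edge_mode=config.edge_mode, ontology=ontology
    )
    pd.DataFrame(
        sorted(partition.items()), columns=["term", "community"]
    ).to_csv(out / "partition.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(lab, reps[lab], names.get(reps[lab], reps[lab])) for lab in sorted(reps)],
        columns=["community", "representative", "representative_name"],
    ).to_csv(out / "representatives.tsv", sep="\t", index=False)
    gograph.export_graphml(collapsed, out / "collapsed.graphml")
    gograph.export_dot(collapsed, out / "collapsed.dot")
    manifest["stages"]["communities"] = {
        "n_graph_nodes": sub.number_of_nodes(),
        "n_graph_edges": sub.number_of_edges(),
        "n_communities": len(set(partition.values())),
    }

    # --- expression summaries -------------------------------------------------
    log.info("stage expr: transform, PCA, community profiles")
    transformed = exprviz.vst(counts)
    scaled = exprviz.scale_rows(transformed, mode=config.scale_mode)
    scaled.values.to_csv(out / "scaled_matrix.tsv", sep="\t", index_label="gene")
    coords, var_explained = exprviz.pca_top_variance(transformed)
    pca_out = coords.copy()
    pca_out.to_csv(out / "pca.tsv", sep="\t", index_label="sample")
    profiles, row_order = exprviz.community_profiles(scaled, ann, partition)
    profiles.to_csv(out / "community_profiles.tsv", sep="\t")
    row_order.to_csv(out / "heatmap_row_order.tsv", sep="\t", index=False)
    manifest["stages"]["expr"] = {
        "n_scaled_genes": int(scaled.values.shape[0]),
        "pc1_pct_variance": float(var_explained[0]),
        "pc2_pct_variance": float(var_explained[1]),
        "n_profiled_communities": int(len(profiles)),
        "n_heatmap_rows": int(len(row_order)),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


DEMO_IC50S = {"HCT116": 3.4, "AA-HCT116": 1.72, "RPE1": 10.0}
DEMO_DOSES = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 15.0)


def simulate_inputs(
    seed: int,
    out_dir,
    n_compounds: int = 300,
    n_terms: int = 200,
    n_genes: int = 2000,
    n_replicates: int = 3,
    n_planted_terms: int = 8,
    noise_cv: float = 0.05,
    dose_noise_sd: float = 2.0,
) -> dict:
    """Write the full synthetic input set; returns paths plus ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    plates, truth = synthdata.gen_screen_plates(
        n_compounds=n_compounds, noise_cv=noise_cv, seed=derive_seed(seed, "plates")
    )
    io.write_plates(plates, out / "plates.csv")
    truth.to_csv(out / "screen_truth.tsv", sep="\t", index=False)

    ontology = synthdata.gen_ontology(
        synthdata.OntologySpec(n_terms=n_terms, seed=derive_seed(seed, "ontology"))
    )
    io.write_obo(ontology, out / "go.obo")
    io.write_edge_list(ontology, out / "go_edges.tsv")

    # plant leaf terms (no children): specific processes whose propagated
    # annotation sets stay small enough to be over-representable
    leaves = sorted(t for t in ontology.nodes if ontology.in_degree(t) == 0)
    rng = np.random.default_rng(derive_seed(seed, "planting"))
    planted = sorted(
        leaves[i]
        for i in rng.choice(len(leaves), size=min(n_planted_terms, len(leaves)), replace=False)
    )
    ann, de, planted = synthdata.gen_annotations_and_de(
        ontology,
        synthdata.DESpec(
            n_genes=n_genes,
            planted_terms=tuple(planted),
            seed=derive_seed(seed, "annotations"),
        ),
    )
    io.write_annotations(ann, out / "annotations.tsv")
    io.write_de_table(de.drop(columns=["is_de"]), out / "de.tsv")
    (out / "planted_terms.txt").write_text("".join(t + "\n" for t in planted))
    de_genes = list(de.loc[de["is_de"], "gene_id"])

    counts = synthdata.gen_counts(
        n_genes=n_genes,
        n_replicates=n_replicates,
        de_gene_ids=de_genes,
        seed=derive_seed(seed, "counts"),
    )
    io.write_counts(counts, out / "counts.tsv")

    # dose-response confirmation series for one verified hit across cell lines
    dr_rows = []
    for i, (line, ic50) in enumerate(sorted(DEMO_IC50S.items())):
        dr = synthdata.gen_dose_response(
            (100.0, 0.0, ic50, 1.5),
            DEMO_DOSES,
            noise_sd=dose_noise_sd,
            seed=derive_seed(seed, f"doses-{line}"),
        )
        dr["compound_id"] = "VP"
        dr["cell_line"] = line
        dr_rows.append(dr)
    pd.concat(dr_rows)[["compound_id", "cell_line", "dose_uM", "viability"]].to_csv(
        out / "doses.csv", index=False
    )

    return {
        "dir": out,
        "truth": truth,
        "planted_terms": planted,
        "de_genes": de_genes,
        "ontology": ontology,
    }


def demo(seed: int = 0, out_dir="demo_run") -> Path:
    """Generate synthetic inputs at small scale and run the whole pipeline."""
    out = Path(out_dir)
    inputs_dir = out / "inputs"
    simulate_inputs(seed, inputs_dir)
    config = RunConfig(
        plates=str(inputs_dir / "plates.csv"),
        doses=str(inputs_dir / "doses.csv"),
        de_table=str(inputs_dir / "de.tsv"),
        counts=str(inputs_dir / "counts.tsv"),
        ontology=str(inputs_dir / "go.obo"),
        annotations=str(inputs_dir / "annotations.tsv"),
        out_dir=str(out / "results"),
        seed=seed,
    )
    run_all(config)
    return out
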