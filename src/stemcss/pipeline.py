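"""End-to-end orchestration: single-cell discovery through outcome stats.

The pipeline chains the stages in their scientific order:

1. single-cell data (simulated or loaded) are log-normalized;
2. Ro/e quantifies cluster enrichment across tissue and MSI groups;
3. differential expression feeds the 8q-intersection marker call for the
   LAPTM4B-type cluster and the two stem-like signature derivations;
4. the expression-inferred arm scorer flags the 8q gain;
5. bulk samples (simulated from the discovered signatures, or loaded) are
   scored by median signature expression and stratified into CSS1-4;
6. survival (KM, log-rank, Cox), the combined LAPTM4B-LGR5 predictor's
   ROC/AUC, per-gene mutation enrichment and TMB contrasts close the loop.

Every run is deterministic given the seed, and the full parameter set is
echoed into a provenance record sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .cnv import MarkerCallResult, call_cluster_marker, infer_arm_scores
from .containers import ExpressionMatrix, GeneSignature
from .enrichment import diff_expr, gene_set_auc, roe
from .signatures import (
    assign_css,
    build_signature,
    combined_marker_score,
    extract_gene,
    score_samples,
)
from .simulate import default_bulk_config, default_sc_config, simulate_bulk, simulate_sc
from .survival import cox_fit, km_estimate, logrank, mutation_enrichment, roc_auc, tmb_compare

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, stage parameters, and the master seed.

    Any path left as ``None`` switches that layer to simulation with the
    package's default study conditions (seeded by ``seed``).
    """

    seed: int = 0
    # single-cell inputs
    sc_matrix: Optional[str] = None
    sc_format: str = "mtx"
    sc_cells: Optional[str] = None
    sc_loci: Optional[str] = None
    # bulk inputs
    bulk_matrix: Optional[str] = None
    bulk_clinical: Optional[str] = None
    bulk_mutations: Optional[str] = None
    # cluster roles
    lgr5_cluster: str = "stem_lgr5"
    laptm4b_cluster: str = "stem_laptm4b"
    # thresholds
    lfc_min: float = 2.0
    fdr_max: float = 0.01
    signature_lfc_min: float = 0.5
    signature_fdr_max: float = 0.01
    top_fraction: float = 0.05
    gain_threshold: float = 0.1
    window: int = 101
    min_coverage: float = 0.5
    arm: str = "8q"
    lgr5_gene: str = "LGR5"
    laptm4b_gene: str = "LAPTM4B"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate_paths(self) -> None:
        for name in ("sc_matrix", "sc_cells", "sc_loci", "bulk_matrix", "bulk_clinical", "bulk_mutations"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")


@dataclass
class PipelineResult:
    roe_tissue: pd.DataFrame
    roe_msi: Optional[pd.DataFrame]
    stemness_by_cluster: pd.DataFrame
    arm_scores: pd.DataFrame
    markers: MarkerCallResult
    signature_lgr5: GeneSignature
    signature_laptm4b: GeneSignature
    css_calls: pd.DataFrame
    km_by_subtype: dict
    logrank_css2_vs_css4: tuple
    cox_css2_vs_css4: pd.DataFrame
    auc_table: pd.DataFrame
    mutation_table: Optional[pd.DataFrame]
    tmb_table: Optional[pd.DataFrame]
    provenance: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write every result table as TSV plus a provenance YAML."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.roe_tissue.rename_axis("cluster").to_csv(out / "roe_tissue.tsv", sep="\t")
        if self.roe_msi is not None:
            self.roe_msi.rename_axis("cluster").to_csv(out / "roe_msi.tsv", sep="\t")
        self.stemness_by_cluster.to_csv(out / "stemness_by_cluster.tsv", sep="\t")
        self.arm_scores.to_csv(out / "arm_scores.tsv", sep="\t", index=False)
        pd.Series(self.markers.markers, name="gene").to_csv(
            out / "markers.tsv", sep="\t", index=False
        )
        for sig in (self.signature_lgr5, self.signature_laptm4b):
            pd.Series(sig.genes, name="gene").to_csv(
                out / f"signature_{sig.name}.tsv", sep="\t", index=False
            )
        self.css_calls.rename_axis("sample").to_csv(out / "css_calls.tsv", sep="\t")
        for label, table in self.km_by_subtype.items():
            table.to_csv(out / f"km_{label}.tsv", sep="\t", index=False)
        self.cox_css2_vs_css4.rename_axis("covariate").to_csv(out / "cox.tsv", sep="\t")
        self.auc_table.to_csv(out / "auc.tsv", sep="\t", index=False)
        if self.mutation_table is not None:
            self.mutation_table.to_csv(out / "mutation_enrichment.tsv", sep="\t")
        if self.tmb_table is not None:
            self.tmb_table.to_csv(out / "tmb_compare.tsv", sep="\t", index=False)
        with open(out / "provenance.yaml", "w") as fh:
            yaml.safe_dump(self.provenance, fh, sort_keys=True)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full discovery-to-outcome pipeline; see the module docstring."""
    config.validate_paths()
    provenance = {"config": config.to_dict()}

    # ----- single-cell layer -------------------------------------------
    with _stage("load_single_cell"):
        if config.sc_matrix is None:
            sim = simulate_sc(default_sc_config(config.seed))
            counts, cells, loci = sim.counts, sim.cells, sim.loci
            provenance["sc_source"] = "simulated(default_sc_config)"
        else:
            counts = sio.read_expression(config.sc_matrix, format=config.sc_format)
            cells = sio.read_cell_annotation(config.sc_cells)
            loci = sio.read_loci(config.sc_loci)
            provenance["sc_source"] = str(config.sc_matrix)
        cells = cells.loc[counts.units]
        lognorm = counts.log_normalize()

    with _stage("roe"):
        roe_tissue = roe(pd.crosstab(cells["cluster"], cells["tissue"]))
        roe_msi = (
            roe(pd.crosstab(cells["cluster"], cells["msi"])) if "msi" in cells else None
        )

    with _stage("differential_expression"):
        clusters = cells["cluster"]
        tumor_mask = cells["tissue"] == "tumor"
        epi_units = cells.index[tumor_mask]
        other_units = cells.index[~tumor_mask]
        lap_units = cells.index[clusters == config.laptm4b_cluster]
        lgr_units = cells.index[clusters == config.lgr5_cluster]
        rest_of_epi_lap = cells.index[tumor_mask & (clusters != config.laptm4b_cluster)]
        rest_of_epi_lgr = cells.index[tumor_mask & (clusters != config.lgr5_cluster)]
        de_epi_vs_other = diff_expr(lognorm, epi_units, other_units)
        de_lap_vs_rest = diff_expr(lognorm, lap_units, rest_of_epi_lap)
        de_lap_vs_sib = diff_expr(lognorm, lap_units, lgr_units)
        de_lgr_vs_rest = diff_expr(lognorm, lgr_units, rest_of_epi_lgr)

    with _stage("arm_scores"):
        reference = sorted(cells.loc[~tumor_mask, "cluster"].unique())
        arm_scores = infer_arm_scores(
            lognorm,
            cells,
            loci,
            reference_clusters=reference,
            window=config.window,
            gain_threshold=config.gain_threshold,
        )

    with _stage("marker_call"):
        markers = call_cluster_marker(
            de_lap_vs_rest,
            de_lap_vs_sib,
            loci,
            arm=config.arm,
            lfc_min=config.lfc_min,
            fdr_max=config.fdr_max,
        )

    with _stage("signatures"):
        signature_lgr5 = build_signature(
            de_epi_vs_other,
            de_lgr_vs_rest,
            config.signature_lfc_min,
            config.signature_fdr_max,
            name="LGR5_stem",
        )
        signature_laptm4b = build_signature(
            de_epi_vs_other,
            de_lap_vs_rest,
            config.signature_lfc_min,
            config.signature_fdr_max,
            name="LAPTM4B_stem",
        )

    with _stage("stemness_scores"):
        by_cluster = {}
        for sig in (signature_lgr5, signature_laptm4b):
            auc = gene_set_auc(lognorm, sig, top_fraction=config.top_fraction)
            by_cluster[sig.name] = auc.groupby(clusters, observed=True).mean()
        stemness_by_cluster = pd.DataFrame(by_cluster).rename_axis("cluster")

    # ----- bulk layer --------------------------------------------------
    with _stage("load_bulk"):
        if config.bulk_matrix is None:
            bulk_sim = simulate_bulk(
                default_bulk_config(config.seed),
                signatures=(signature_lgr5, signature_laptm4b),
            )
            bulk, clinical, mutations = (
                bulk_sim.expression,
                bulk_sim.clinical,
                bulk_sim.mutations,
            )
            provenance["bulk_source"] = "simulated(default_bulk_config)"
        else:
            bulk = sio.read_expression(config.bulk_matrix, format="tsv", is_log=True)
            clinical = sio.read_clinical(config.bulk_clinical)
            mutations = (
                sio.read_mutations(config.bulk_mutations)
                if config.bulk_mutations
                else None
            )
            provenance["bulk_source"] = str(config.bulk_matrix)

    with _stage("css_assignment"):
        scores_l = score_samples(bulk, signature_lgr5, config.min_coverage)
        scores_b = score_samples(bulk, signature_laptm4b, config.min_coverage)
        css_calls = assign_css(scores_l, scores_b)

    with _stage("survival"):
        merged = clinical.join(css_calls["subtype"])
        km_by_subtype = {
            str(label): km_estimate(block["dfs_months"], block["dfs_event"])
            for label, block in merged.groupby("subtype", observed=True)
        }
        lr = logrank(
            merged["dfs_months"], merged["dfs_event"], merged["subtype"], "CSS2", "CSS4"
        )
        pair = merged[merged["subtype"].isin(["CSS2", "CSS4"])].copy()
        pair["css2"] = (pair["subtype"] == "CSS2").astype(float)
        cox = cox_fit(pair, "dfs_months", "dfs_event", ["css2"])

    with _stage("combined_predictor"):
        lap = extract_gene(bulk, config.laptm4b_gene)
        lgr = extract_gene(bulk, config.lgr5_gene)
        combined = combined_marker_score(lap, lgr)
        labels = merged.loc[combined.index, "dfs_event"].astype(int)
        rows = []
        for name, score in (
            ("combined_laptm4b_minus_lgr5", combined),
            ("laptm4b", lap),
            ("lgr5_inverted", -lgr),
        ):
            auc, _ = roc_auc(score, labels)
            rows.append({"predictor": name, "auc": auc, "positive_class": "recurrence"})
        auc_table = pd.DataFrame(rows)

    with _stage("mutations"):
        if mutations is not None:
            mutation_table = mutation_enrichment(
                mutations, css_calls["subtype"], "CSS2", "CSS4"
            )
            tmb_table = (
                tmb_compare(clinical["tmb"], css_calls["subtype"])
                if "tmb" in clinical
                else None
            )
        else:
            mutation_table, tmb_table = None, None

    provenance["n_cells"] = int(counts.shape[0])
    provenance["n_bulk_samples"] = int(bulk.shape[0])
    provenance["signature_sizes"] = {
        signature_lgr5.name: len(signature_lgr5),
        signature_laptm4b.name: len(signature_laptm4b),
    }
    return PipelineResult(
        roe_tissue=roe_tissue,
        roe_msi=roe_msi,
        stemness_by_cluster=stemness_by_cluster,
        arm_scores=arm_scores,
        markers=markers,
        signature_lgr5=signature_lgr5,
        signature_laptm4b=signature_laptm4b,
        css_calls=css_calls,
        km_by_subtype=km_by_subtype,
        logrank_css2_vs_css4=lr,
        cox_css2_vs_css4=cox,
        auc_table=auc_table,
        mutation_table=mutation_table,
        tmb_table=tmb_table,
        provenance=provenance,
    )
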