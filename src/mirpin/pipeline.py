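"""End-to-end orchestration: differential expression in both feature classes,
consensus pairing, network construction, GO enrichment, and optional ROC
marker evaluation, with a machine-readable run manifest.

The two differential-expression runs share one q threshold but use separate
fold-change thresholds (2.5 for miRNAs, 1.9 for genes by default). The ROC
stage deliberately takes an independent expression matrix: markers are
evaluated on data that played no part in network construction.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .consensus import consensus_pairs, pairs_table
from .diffexpr import SamConfig, de_table, select_differential
from .enrichment import KeywordRule, enrich_pin, enrichment_table
from .fixtures import EXPECTED_ROW_COUNTS, load_fixture
from .io import UsageError
from .network import build_pins, summary_table
from .roc import roc_table
from .simulate import SyntheticTruth

SURVIVAL_KEYWORDS = ("apoptosis", "cell death", "cell proliferation")


@dataclass
class PipelineConfig:
    mirna_expr: str
    mirna_labels: str
    gene_expr: str
    gene_labels: str
    target_dbs: dict[str, str]  # source name -> path
    ppi: str
    ontology_terms: str
    annotations: str
    out_dir: str
    ontology_edges: str | None = None  # None => ontology_terms is an OBO file
    roc_expr: str | None = None
    roc_labels: str | None = None
    truth: str | None = None
    q_threshold: float = 1e-6
    fc_threshold_mirna: float = 2.5
    fc_threshold_gene: float = 1.9
    min_support: int = 2
    min_pin_size: int = 6
    min_level: int = 5
    alpha: float = 1e-4
    se_mode: str = "observed"
    n_permutations: int = 1000
    seed: int = 0
    expression_scale: str = "linear"

    def validate(self) -> None:
        if not 0.0 <= self.q_threshold <= 1.0:
            raise UsageError("q_threshold must lie in [0, 1]")
        for thr in (self.fc_threshold_mirna, self.fc_threshold_gene):
            if thr < 1.0:
                raise UsageError("fold-change thresholds must be >= 1")
        if self.min_support < 1:
            raise UsageError("min_support must be >= 1")
        if self.min_pin_size < 1 or self.min_level < 0:
            raise UsageError("invalid network-size or level filter")
        if not 0.0 < self.alpha <= 1.0:
            raise UsageError("alpha must lie in (0, 1]")
        if self.se_mode not in ("observed", "null"):
            raise UsageError("se_mode must be 'observed' or 'null'")
        if (self.roc_expr is None) != (self.roc_labels is None):
            raise UsageError("roc_expr and roc_labels must be given together")
        if self.roc_expr is not None and self.roc_expr == self.mirna_expr:
            raise UsageError("ROC expression must be an independent matrix")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    config.validate()
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "stages": {},
    }
    t0 = time.perf_counter()

    def stage(name: str, **info) -> None:
        info["elapsed_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][name] = info

    def fail(name: str, path: str, exc: Exception) -> Exception:
        return RuntimeError(f"stage {name!r} failed on {path}: {exc}")

    scale = config.expression_scale
    try:
        mirna_expr, mirna_labels = io.read_expression_matrix(
            config.mirna_expr, config.mirna_labels, scale_hint=scale)
    except Exception as exc:
        raise fail("de_mirna", config.mirna_expr, exc) from exc
    try:
        gene_expr, gene_labels = io.read_expression_matrix(
            config.gene_expr, config.gene_labels, scale_hint=scale)
    except Exception as exc:
        raise fail("de_gene", config.gene_expr, exc) from exc

    mirna_cfg = SamConfig(q_threshold=config.q_threshold,
                          fc_threshold=config.fc_threshold_mirna,
                          n_permutations=config.n_permutations, seed=config.seed)
    gene_cfg = dataclasses.replace(mirna_cfg, fc_threshold=config.fc_threshold_gene)
    de_mirna = de_table(mirna_expr, mirna_labels, mirna_cfg)
    up_m, down_m = select_differential(de_mirna, mirna_cfg)
    pre_fc_m = int((de_mirna["q"] <= config.q_threshold).sum())
    stage("de_mirna", n_features=len(de_mirna), n_q_pass=pre_fc_m,
          n_up=len(up_m), n_down=len(down_m))

    de_gene = de_table(gene_expr, gene_labels, gene_cfg)
    up_g, down_g = select_differential(de_gene, gene_cfg)
    pre_fc_g = int((de_gene["q"] <= config.q_threshold).sum())
    stage("de_gene", n_features=len(de_gene), n_q_pass=pre_fc_g,
          n_up=len(up_g), n_down=len(down_g))

    records = []
    for source, path in sorted(config.target_dbs.items()):
        try:
            records.extend(io.read_target_db(path, source))
        except Exception as exc:
            raise fail("consensus", path, exc) from exc
    pairs = consensus_pairs(up_m, down_m, up_g, down_g, records,
                            min_support=config.min_support)
    stage("consensus", n_records=len(records), n_pairs=len(pairs))

    try:
        ppi = io.read_ppi_edges(config.ppi)
    except Exception as exc:
        raise fail("networks", config.ppi, exc) from exc
    pins = build_pins(pairs, ppi)
    stage("networks", n_ppi_edges=len(ppi), n_networks=len(pins))

    try:
        ontology, annotations = io.read_ontology_and_annotations(
            config.ontology_terms, config.annotations,
            edges_path=config.ontology_edges)
    except Exception as exc:
        raise fail("enrichment", config.ontology_terms, exc) from exc
    results = []
    for pin in pins:
        results.extend(enrich_pin(
            pin, annotations, ontology,
            min_pin_size=config.min_pin_size, min_level=config.min_level,
            alpha=config.alpha))
    stage("enrichment", n_terms=len(annotations.mapping), n_hits=len(results))

    roc = None
    if config.roc_expr is not None:
        try:
            roc_mat, roc_lab = io.read_expression_matrix(
                config.roc_expr, config.roc_labels, scale_hint=scale)
        except Exception as exc:
            raise fail("roc", config.roc_expr, exc) from exc
        evaluated = sorted((up_m | down_m) & set(roc_mat.feature_ids))
        roc = roc_table(roc_mat, roc_lab, evaluated, se_mode=config.se_mode)
        stage("roc", n_markers=len(roc))

    tables = {
        "de_mirna": de_mirna.reset_index(drop=True),
        "de_gene": de_gene.reset_index(drop=True),
        "pairs": pairs_table(pairs),
        "networks": summary_table(pins),
        "enrichment": enrichment_table(results),
        "roc": roc,
        "pins": pins,
    }
    out_dir = Path(config.out_dir)
    manifest["outputs"] = io.write_outputs(tables, out_dir)

    if config.truth:
        truth = SyntheticTruth.from_json(Path(config.truth).read_text())
        found = {(p.mirna_id, p.gene_id) for p in pairs}
        planted = set(map(tuple, truth.planted_pairs))
        recovered = len(found & planted)
        manifest["truth"] = {
            "planted_pairs": len(planted),
            "recovered_pairs": recovered,
            "recovery_fraction": recovered / len(planted) if planted else None,
            "extra_pairs": len(found - planted),
        }
        if truth.planted_term and truth.planted_term_mirna:
            hub_hits = [r for r in results if r.mirna_id == truth.planted_term_mirna]
            manifest["truth"]["planted_term_rank"] = next(
                (i + 1 for i, r in enumerate(hub_hits) if r.term_id == truth.planted_term),
                None,
            )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def config_for_study(sim_dir: str | Path, out_dir: str | Path, seed: int = 0,
                     **overrides) -> PipelineConfig:
    """Convenience config pointing at a ``simulate_study`` output directory."""
    sim = Path(sim_dir)
    sources = sorted(p.stem.removeprefix("targets_") for p in sim.glob("targets_*.tsv"))
    defaults = dict(
        mirna_expr=str(sim / "mirna_expr.tsv"),
        mirna_labels=str(sim / "mirna_labels.tsv"),
        gene_expr=str(sim / "gene_expr.tsv"),
        gene_labels=str(sim / "gene_labels.tsv"),
        target_dbs={s: str(sim / f"targets_{s}.tsv") for s in sources},
        ppi=str(sim / "ppi.tsv"),
        ontology_terms=str(sim / "ontology_terms.tsv"),
        ontology_edges=str(sim / "ontology_edges.tsv"),
        annotations=str(sim / "annotations.gmt"),
        roc_expr=str(sim / "roc_expr.tsv"),
        roc_labels=str(sim / "roc_labels.tsv"),
        truth=str(sim / "truth.json") if (sim / "truth.json").exists() else None,
        out_dir=str(out_dir),
        seed=seed,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def reproduce_paper_counts() -> dict:
    """Recompute the count-based claims of the source study from the packaged
    supplementary-table fixtures and compare them with the printed values."""
    s1 = load_fixture("S1").rows
    s4 = load_fixture("S4").rows
    s5 = load_fixture("S5").rows
    s6 = load_fixture("S6").rows
    keyword_hits = {
        acc
        for acc, name in zip(s6["accession"], s6["term_name"])
        if any(k in name.lower() for k in SURVIVAL_KEYWORDS)
    }
    report = {
        "s1_down_mirnas": {"computed": int((s1["fold_change"] < 1).sum()), "expected": 89},
        "s1_up_mirnas": {"computed": int((s1["fold_change"] > 1).sum()), "expected": 1},
        "s2_down_genes": {"computed": len(load_fixture("S2").rows),
                          "expected": EXPECTED_ROW_COUNTS["S2"]},
        "s3_up_genes": {"computed": len(load_fixture("S3").rows),
                        "expected": EXPECTED_ROW_COUNTS["S3"]},
        "s4_roc_mirnas": {"computed": len(s4), "expected": EXPECTED_ROW_COUNTS["S4"]},
        "s5_networks": {"computed": len(s5), "expected": 18},
        "s5_total_consistent": {
            "computed": int((s5["total"] == s5["l0_count"] + s5["l1_count"]).sum()),
            "expected": 18,
        },
        "s6_survival_keyword_mirnas": {"computed": len(keyword_hits), "expected": 7},
    }
    for entry in report.values():
        entry["match"] = entry["computed"] == entry["expected"]
    return report
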