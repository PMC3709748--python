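"""Synthetic study generator with planted ground truth.

Every pipeline input — two-group expression for miRNAs and genes, three
target-prediction databases, a PPI graph and a GO-like ontology with GMT
annotations — can be generated with known planted structure, so each stage
is testable end-to-end without any external download.

The default study emulates the source design: 11 normal vs 110 tumor
samples on the gene side, 11 normal vs 128 tumor for miRNA discovery, and a
separate 15 normal vs 101 tumor miRNA matrix for marker (ROC) evaluation.
Expression noise is Gaussian in log2 space (lognormal on the linear scale),
the simplest model consistent with array-like data; differential features
receive a ±log2_effect group shift, split evenly between up and down.
Planted miRNA-target pairs are written into exactly ``support_per_planted``
of the sources, decoys into a single source, so the two-of-three consensus
recovers precisely the planted pairs. The PPI wires each planted target to
dedicated level-1 neighbor genes (background random edges touch only
non-planted genes), and the ontology plants one term at a configurable
depth whose annotation overlaps one designated network.

All generators run on a single seeded NumPy generator per call and are
byte-reproducible given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    NORMAL,
    TUMOR,
    AnnotationSet,
    ExpressionMatrix,
    GroupLabels,
    Ontology,
    TargetRecord,
    TermRecord,
    UsageError,
    ppi_edge,
    write_expression_matrix,
    write_gmt,
    write_group_labels,
    write_ppi_edges,
    write_target_db,
)

TRUTH_SCHEMA_VERSION = 1


@dataclass
class SyntheticTruth:
    planted_up_mirnas: list[str] = field(default_factory=list)
    planted_down_mirnas: list[str] = field(default_factory=list)
    planted_up_genes: list[str] = field(default_factory=list)
    planted_down_genes: list[str] = field(default_factory=list)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_ppi_module: dict[str, list[str]] = field(default_factory=dict)
    planted_term: str | None = None
    planted_term_mirna: str | None = None
    seed: int | None = None

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["planted_pairs"] = [list(p) for p in self.planted_pairs]
        payload["schema_version"] = TRUTH_SCHEMA_VERSION
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        payload.pop("schema_version", None)
        payload["planted_pairs"] = [tuple(p) for p in payload["planted_pairs"]]
        return cls(**payload)


def simulate_expression(
    n_features: int,
    n_normal: int,
    n_tumor: int,
    de_fraction: float,
    log2_effect: float,
    noise_sd: float,
    seed: int,
    *,
    prefix: str = "f",
) -> tuple[ExpressionMatrix, GroupLabels, SyntheticTruth]:
    """Two-group lognormal expression with planted differential features.

    Baselines are Uniform(4, 10) in log2; planted features (the first
    ``round(de_fraction * n_features)``, split evenly up/down) get a
    ±log2_effect shift in the tumor group. Values are exported linear.
    """
    if n_normal < 2 or n_tumor < 2:
        raise UsageError("need at least 2 samples per group")
    if not 0.0 <= de_fraction <= 1.0:
        raise UsageError("de_fraction must lie in [0, 1]")
    if noise_sd <= 0:
        raise UsageError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    features = [f"{prefix}{i:04d}" for i in range(n_features)]
    samples = [f"{prefix}N{i:03d}" for i in range(n_normal)] + [
        f"{prefix}T{i:03d}" for i in range(n_tumor)
    ]
    n_de = round(de_fraction * n_features)
    n_up = n_de // 2
    shifts = np.zeros(n_features)
    shifts[:n_up] = log2_effect
    shifts[n_up:n_de] = -log2_effect

    baseline = rng.uniform(4.0, 10.0, size=n_features)
    log2 = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_features, n_normal + n_tumor))
    log2[:, n_normal:] += shifts[:, None]
    values = pd.DataFrame(np.power(2.0, log2), index=features, columns=samples)
    matrix = ExpressionMatrix(values, scale_hint="linear")
    labels = GroupLabels(
        {s: NORMAL for s in samples[:n_normal]} | {s: TUMOR for s in samples[n_normal:]}
    )
    truth = SyntheticTruth(seed=seed)
    up, down = features[:n_up], features[n_up:n_de]
    if prefix.startswith("g"):
        truth.planted_up_genes, truth.planted_down_genes = up, down
    else:
        truth.planted_up_mirnas, truth.planted_down_mirnas = up, down
    return matrix, labels, truth


def simulate_target_databases(
    mirnas: Sequence[str],
    genes: Sequence[str],
    planted_pairs: Sequence[tuple[str, str]],
    n_sources: int,
    support_per_planted: int,
    decoy_rate: float,
    seed: int,
) -> dict[str, list[TargetRecord]]:
    """Per-source prediction lists with controlled consensus support.

    Planted pairs land in exactly ``support_per_planted`` randomly chosen
    sources. Decoy pairs (drawn uniformly from non-planted miRNA x gene
    combinations at rate ``decoy_rate``) land in exactly one source, so they
    can never reach a 2-source consensus.
    """
    if support_per_planted > n_sources:
        raise UsageError("support_per_planted cannot exceed n_sources")
    mirna_set, gene_set = set(mirnas), set(genes)
    for m, g in planted_pairs:
        if m not in mirna_set or g not in gene_set:
            raise UsageError(f"planted pair ({m}, {g}) references unknown feature")
    rng = np.random.default_rng(seed)
    source_names = [f"db{chr(ord('A') + i)}" for i in range(n_sources)]
    records: dict[str, list[TargetRecord]] = {s: [] for s in source_names}
    for m, g in planted_pairs:
        chosen = rng.choice(n_sources, size=support_per_planted, replace=False)
        for idx in chosen:
            records[source_names[idx]].append(TargetRecord(m, g, source_names[idx]))
    planted = set(map(tuple, planted_pairs))
    n_decoys = rng.binomial(len(mirnas) * len(genes), decoy_rate) if decoy_rate > 0 else 0
    made = 0
    while made < n_decoys:
        m = mirnas[rng.integers(len(mirnas))]
        g = genes[rng.integers(len(genes))]
        if (m, g) in planted:
            continue
        src = source_names[rng.integers(n_sources)]
        records[src].append(TargetRecord(m, g, src))
        made += 1
    for src in source_names:  # collapse accidental duplicates
        records[src] = sorted(set(records[src]))
    return records


def simulate_ppi(
    genes: Sequence[str],
    planted_targets: Sequence[str],
    neighbors_per_target: int,
    background_edge_prob: float,
    seed: int,
) -> tuple[set[tuple[str, str]], dict[str, list[str]]]:
    """Background random graph plus a deterministic shell around planted targets.

    Each planted target is wired to ``neighbors_per_target`` dedicated
    neighbor genes drawn (without reuse) from the non-planted pool;
    Erdos-Renyi background edges are added among the remaining non-planted
    genes only, so planted networks keep their designed size.
    Returns (canonical edge set, target -> neighbor list).
    """
    if not 0.0 <= background_edge_prob <= 1.0:
        raise UsageError("background_edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    planted = list(planted_targets)
    pool = [g for g in genes if g not in set(planted)]
    needed = neighbors_per_target * len(planted)
    if needed > len(pool):
        raise UsageError("not enough non-planted genes for dedicated neighbors")
    chosen = rng.choice(len(pool), size=needed, replace=False) if needed else np.array([], int)
    neighbor_genes = [pool[i] for i in chosen]
    module: dict[str, list[str]] = {}
    edges: set[tuple[str, str]] = set()
    for i, target in enumerate(planted):
        nbrs = neighbor_genes[i * neighbors_per_target:(i + 1) * neighbors_per_target]
        module[target] = sorted(nbrs)
        for nbr in nbrs:
            e = ppi_edge(target, nbr)
            if e:
                edges.add(e)
    background_pool = [g for g in pool if g not in set(neighbor_genes)]
    if background_edge_prob > 0 and len(background_pool) > 1:
        arr = np.array(background_pool)
        mask = rng.random((len(arr), len(arr))) < background_edge_prob
        for i, j in zip(*np.nonzero(np.triu(mask, k=1))):
            e = ppi_edge(str(arr[i]), str(arr[j]))
            if e:
                edges.add(e)
    return edges, module


def simulate_ontology(
    depth: int,
    branching: int,
    n_genes: int,
    planted_term_level: int,
    planted_overlap: int,
    seed: int,
    *,
    genes: Sequence[str] | None = None,
    pin_genes: Sequence[str] = (),
    planted_term_size: int = 30,
    annotation_size_range: tuple[int, int] = (5, 30),
) -> tuple[Ontology, AnnotationSet, SyntheticTruth]:
    """A rooted is_a tree with one planted enriched term.

    The tree has ``branching`` children per node down to ``depth``; extra
    random is_a edges are added from deeper to strictly shallower nodes so
    the DAG is not a plain tree, but never to a node shallower than the
    planted term's parents (shortest-path levels are preserved for it). The
    planted term sits at ``planted_term_level`` and is annotated with
    ``planted_overlap`` genes from ``pin_genes`` plus random fillers up to
    ``planted_term_size``; all other terms at level >= 1 receive uniform
    random annotations.
    """
    if planted_term_level > depth:
        raise UsageError("planted_term_level cannot exceed depth")
    if planted_overlap > len(pin_genes) and pin_genes:
        raise UsageError("planted_overlap larger than the designated network")
    if planted_overlap and not pin_genes:
        raise UsageError("planted_overlap requires pin_genes")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"g{i:04d}" for i in range(n_genes)]
    genes = list(genes)

    levels: list[list[str]] = [["T:root"]]
    terms: dict[str, TermRecord] = {
        "T:root": TermRecord("T:root", "synthetic root process", "synthetic", ())
    }
    counter = 0
    for lvl in range(1, depth + 1):
        layer = []
        for parent in levels[lvl - 1]:
            for _ in range(branching):
                counter += 1
                tid = f"T:{counter:05d}"
                terms[tid] = TermRecord(tid, f"synthetic process {counter}", "synthetic", (parent,))
                layer.append(tid)
        levels.append(layer)
    planted_term = levels[planted_term_level][0]

    # extra is_a edges: deeper node -> node exactly one level shallower, so no
    # shortest path ever shrinks below the tree level
    extra_candidates = [
        (child, parent)
        for lvl in range(2, depth + 1)
        for child in levels[lvl]
        for parent in levels[lvl - 1]
        if parent not in terms[child].parents
    ]
    if extra_candidates:
        take = rng.choice(len(extra_candidates), size=min(len(extra_candidates), counter // 4),
                          replace=False)
        for idx in take:
            child, parent = extra_candidates[idx]
            rec = terms[child]
            terms[child] = TermRecord(rec.term_id, rec.name, rec.namespace,
                                      tuple(sorted(set(rec.parents) | {parent})))
    ontology = Ontology(terms)

    mapping: dict[str, frozenset[str]] = {}
    lo, hi = annotation_size_range
    for lvl in range(1, depth + 1):
        for tid in levels[lvl]:
            if tid == planted_term:
                continue
            size = int(rng.integers(lo, hi + 1))
            idx = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
            mapping[tid] = frozenset(genes[i] for i in idx)
    overlap_genes = list(pin_genes)[:planted_overlap]
    # fillers avoid every designated-network gene so the overlap is exact
    filler_pool = [g for g in genes if g not in set(pin_genes)]
    n_filler = max(planted_term_size - len(overlap_genes), 0)
    fill_idx = rng.choice(len(filler_pool), size=min(n_filler, len(filler_pool)), replace=False)
    mapping[planted_term] = frozenset(overlap_genes) | frozenset(filler_pool[i] for i in fill_idx)
    annotations = AnnotationSet(mapping)
    truth = SyntheticTruth(planted_term=planted_term, seed=seed)
    return ontology, annotations, truth


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level generator settings; defaults mirror the emulated design."""

    n_mirnas: int = 100
    n_genes: int = 500
    mirna_normal: int = 11
    mirna_tumor: int = 128
    gene_normal: int = 11
    gene_tumor: int = 110
    roc_normal: int = 15
    roc_tumor: int = 101
    de_fraction: float = 0.1
    log2_effect: float = 3.0
    noise_sd: float = 0.5
    targets_per_mirna: int = 6
    n_sources: int = 3
    support_per_planted: int = 2
    decoy_rate: float = 0.002
    neighbors_per_target: int = 3
    background_edge_prob: float = 0.002
    ontology_depth: int = 6
    ontology_branching: int = 2
    planted_term_level: int = 5
    planted_overlap: int = 15
    planted_term_size: int = 30

    def validate(self) -> None:
        if self.support_per_planted > self.n_sources:
            raise UsageError("support_per_planted cannot exceed n_sources")
        if self.planted_term_level > self.ontology_depth:
            raise UsageError("planted_term_level cannot exceed ontology_depth")
        n_planted = round(self.de_fraction * self.n_mirnas)
        if self.targets_per_mirna and n_planted:
            n_planted_genes = round(self.de_fraction * self.n_genes)
            if self.targets_per_mirna > n_planted_genes // 2:
                raise UsageError("not enough planted genes for targets_per_mirna")


def _plant_pairs(config: SimulationConfig, truth: SyntheticTruth) -> list[tuple[str, str]]:
    """Pair each planted miRNA with opposite-direction planted genes, round-robin."""
    pairs: list[tuple[str, str]] = []
    for mirnas, genes in (
        (truth.planted_down_mirnas, truth.planted_up_genes),
        (truth.planted_up_mirnas, truth.planted_down_genes),
    ):
        if not genes:
            continue
        cursor = 0
        for m in mirnas:
            for _ in range(config.targets_per_mirna):
                pairs.append((m, genes[cursor % len(genes)]))
                cursor += 1
    return sorted(set(pairs))


def simulate_study(
    config: SimulationConfig, seed: int, out_dir: str | Path | None = None
) -> tuple[dict[str, object], SyntheticTruth]:
    """Generate every pipeline input coherently; optionally write to disk.

    Returns (inputs, truth). ``inputs`` holds in-memory objects keyed
    mirna_expr/mirna_labels/gene_expr/gene_labels/targets/ppi/ontology/
    annotations/roc_expr/roc_labels. With ``out_dir`` the same content is
    written as TSV/GMT files plus truth.json; file output is byte-reproducible
    given (config, seed).
    """
    config.validate()
    root = np.random.default_rng(seed)
    sub = [int(s) for s in root.integers(0, 2**31 - 1, size=6)]

    mirna_expr, mirna_labels, t_mir = simulate_expression(
        config.n_mirnas, config.mirna_normal, config.mirna_tumor,
        config.de_fraction, config.log2_effect, config.noise_sd, sub[0], prefix="mir",
    )
    gene_expr, gene_labels, t_gene = simulate_expression(
        config.n_genes, config.gene_normal, config.gene_tumor,
        config.de_fraction, config.log2_effect, config.noise_sd, sub[1], prefix="g",
    )
    truth = SyntheticTruth(
        planted_up_mirnas=t_mir.planted_up_mirnas,
        planted_down_mirnas=t_mir.planted_down_mirnas,
        planted_up_genes=t_gene.planted_up_genes,
        planted_down_genes=t_gene.planted_down_genes,
        seed=seed,
    )
    truth.planted_pairs = _plant_pairs(config, truth)

    targets = simulate_target_databases(
        mirna_expr.feature_ids, gene_expr.feature_ids, truth.planted_pairs,
        config.n_sources, config.support_per_planted, config.decoy_rate, sub[2],
    )
    planted_target_genes = sorted({g for _, g in truth.planted_pairs})
    ppi, module = simulate_ppi(
        gene_expr.feature_ids, planted_target_genes,
        config.neighbors_per_target, config.background_edge_prob, sub[3],
    )
    truth.planted_ppi_module = module

    # the designated enriched network: the planted miRNA with the most targets
    per_mirna: dict[str, set[str]] = {}
    for m, g in truth.planted_pairs:
        per_mirna.setdefault(m, set()).add(g)
    hub = max(sorted(per_mirna), key=lambda m: len(per_mirna[m])) if per_mirna else None
    hub_nodes = sorted(
        per_mirna[hub] | {n for g in per_mirna[hub] for n in module.get(g, [])}
    ) if hub else []
    ontology, annotations, t_onto = simulate_ontology(
        config.ontology_depth, config.ontology_branching, config.n_genes,
        config.planted_term_level,
        config.planted_overlap if hub else 0, sub[4],
        genes=gene_expr.feature_ids, pin_genes=hub_nodes,
        planted_term_size=config.planted_term_size,
    )
    truth.planted_term = t_onto.planted_term if hub else None
    truth.planted_term_mirna = hub

    roc_expr, roc_labels, _ = simulate_expression(
        config.n_mirnas, config.roc_normal, config.roc_tumor,
        config.de_fraction, config.log2_effect, config.noise_sd, sub[5], prefix="mir",
    )

    inputs: dict[str, object] = {
        "mirna_expr": mirna_expr, "mirna_labels": mirna_labels,
        "gene_expr": gene_expr, "gene_labels": gene_labels,
        "targets": targets, "ppi": ppi,
        "ontology": ontology, "annotations": annotations,
        "roc_expr": roc_expr, "roc_labels": roc_labels,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression_matrix(mirna_expr, out / "mirna_expr.tsv")
        write_group_labels(mirna_labels, out / "mirna_labels.tsv")
        write_expression_matrix(gene_expr, out / "gene_expr.tsv")
        write_group_labels(gene_labels, out / "gene_labels.tsv")
        for src, records in targets.items():
            write_target_db(records, out / f"targets_{src}.tsv")
        write_ppi_edges(ppi, out / "ppi.tsv")
        with open(out / "ontology_terms.tsv", "w", encoding="utf-8") as fh:
            fh.write("term_id\tname\tnamespace\n")
            for tid in sorted(ontology.terms):
                t = ontology.terms[tid]
                fh.write(f"{t.term_id}\t{t.name}\t{t.namespace or ''}\n")
        with open(out / "ontology_edges.tsv", "w", encoding="utf-8") as fh:
            fh.write("child\tparent\n")
            for tid in sorted(ontology.terms):
                for parent in ontology.terms[tid].parents:
                    fh.write(f"{tid}\t{parent}\n")
        write_gmt(annotations, out / "annotations.gmt",
                  {t: ontology.terms[t].name for t in annotations.mapping})
        write_expression_matrix(roc_expr, out / "roc_expr.tsv")
        write_group_labels(roc_labels, out / "roc_labels.tsv")
        (out / "truth.json").write_text(truth.to_json())
    return inputs, truth
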