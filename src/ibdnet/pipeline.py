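"""End-to-end orchestration: association scan -> gene sets -> both pathway
methods -> ranking -> cross-phenotype comparison -> disease network.

Per configured case/control contrast the pipeline runs QC and the allelic
scan, derives the risk-gene list, and feeds it to Method 1 (seed-pathway
enrichment + complementary pathway network + edge-betweenness communities)
and Method 2 (shell-expanded protein network + centralities + combined
ranking + MCL clusters + pathway ranking). Cross-contrast outputs are
pairwise SNP Venn tables, per-contrast method-consensus merges, and the
disease-disease network over merged pathway profiles. Every written file
is listed in a manifest with its SHA-256 hash; a run log records the
seed, thresholds and record counts. The pipeline itself is deterministic
given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import assoc, clustering, enrichment, graph_metrics, netbuild, ranking_compare
from .io import GeneSetDB, read_genotypes, read_gmt, read_interactions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    genotypes: str
    interactions: str
    gmt: str
    out_dir: str
    contrasts: list[tuple[str, str]]  # (case label, control label)
    snp_annotation: str | None = None  # TSV: snp, chrom, locus, a1, a2
    qc: assoc.QcThresholds = field(default_factory=assoc.QcThresholds)
    alpha: float = 0.05
    caps: netbuild.ShellCaps = field(default_factory=netbuild.ShellCaps)
    min_score: float = 0.400
    weights: graph_metrics.ScoreWeights = field(default_factory=graph_metrics.ScoreWeights)
    mcl_params: clustering.MclParams = field(default_factory=clustering.MclParams)
    top_seeds: int = 10
    min_jaccard: float = 0.05
    min_significant: int = 3  # contrasts below this SNP count are skipped
    alias: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for p in (self.genotypes, self.interactions, self.gmt):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if not self.contrasts:
            raise ValueError("no contrasts configured")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs: dict = {
            "genotypes": raw["genotypes"],
            "interactions": raw["interactions"],
            "gmt": raw["gmt"],
            "out_dir": raw["out_dir"],
            "contrasts": [tuple(c) for c in raw["contrasts"]],
        }
        if "qc" in raw:
            kwargs["qc"] = assoc.QcThresholds(**raw["qc"])
        if "caps" in raw:
            kwargs["caps"] = netbuild.ShellCaps(**raw["caps"])
        if "weights" in raw:
            kwargs["weights"] = graph_metrics.ScoreWeights(**raw["weights"])
        if "mcl" in raw:
            kwargs["mcl_params"] = clustering.MclParams(**raw["mcl"])
        for key in ("alpha", "min_score", "top_seeds", "min_jaccard",
                    "min_significant", "alias", "seed", "snp_annotation"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest[path.name] = _sha256(path)


def _edges_frame(g: nx.Graph, weight_key: str) -> pd.DataFrame:
    rows = [
        {"node_a": u, "node_b": v, weight_key: d.get(weight_key, 1.0)}
        for u, v, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", weight_key]).sort_values(
        ["node_a", "node_b"]
    )


def _method1(tag: str, genes: list[str], db: GeneSetDB, cfg: PipelineConfig,
             out: Path, manifest: dict) -> set[str]:
    seeds = enrichment.enrich(genes, db, top=cfg.top_seeds)
    _write_tsv(
        pd.DataFrame([vars(r) for r in seeds]),
        out / f"{tag}_m1_seed_pathways.tsv", manifest,
    )
    scaffold = enrichment.pathway_graph(db, min_jaccard=cfg.min_jaccard)
    comp = enrichment.complementary_network([r.set_id for r in seeds], scaffold)
    _write_tsv(_edges_frame(comp, enrichment.JACCARD),
               out / f"{tag}_m1_pathway_network.tsv", manifest)
    roles = pd.DataFrame(
        [{"pathway": n, "role": comp.nodes[n][enrichment.ROLE]} for n in sorted(comp)]
    )
    _write_tsv(roles, out / f"{tag}_m1_pathway_roles.tsv", manifest)
    if comp.number_of_nodes():
        communities = clustering.edge_betweenness_communities(comp)
        _write_tsv(
            pd.DataFrame(
                sorted(communities.assignment.items()), columns=["pathway", "community"]
            ),
            out / f"{tag}_m1_communities.tsv", manifest,
        )
    return set(comp.nodes)


def _method2(tag: str, genes: list[str], db: GeneSetDB, cfg: PipelineConfig,
             interactions, out: Path, manifest: dict) -> set[str]:
    proteins, unmapped = netbuild.map_genes_to_proteins(genes, cfg.alias)
    net = netbuild.expand_seed_network(
        interactions, proteins, caps=cfg.caps, min_score=cfg.min_score
    )
    _write_tsv(_edges_frame(net, netbuild.CONFIDENCE),
               out / f"{tag}_m2_network.tsv", manifest)
    roles = pd.DataFrame(
        [{"protein": n, "role": net.nodes[n][netbuild.ROLE]} for n in sorted(net)]
    )
    _write_tsv(roles, out / f"{tag}_m2_node_roles.tsv", manifest)
    records = graph_metrics.centrality_records(net, weights=cfg.weights)
    _write_tsv(pd.DataFrame([vars(r) for r in records]),
               out / f"{tag}_m2_centralities.tsv", manifest)
    clusters = clustering.mcl(net, cfg.mcl_params)
    _write_tsv(
        pd.DataFrame(sorted(clusters.assignment.items()), columns=["protein", "cluster"]),
        out / f"{tag}_m2_clusters.tsv", manifest,
    )
    combined = {r.node: r.combined for r in records}
    pranks = ranking_compare.pathway_rank(db, combined, net.nodes)
    _write_tsv(
        pd.DataFrame(
            [
                {"set_id": p.set_id, "mean_combined": p.mean_combined,
                 "n_contributing": len(p.contributing), "rank": p.rank}
                for p in pranks
            ]
        ),
        out / f"{tag}_m2_ranked_pathways.tsv", manifest,
    )
    return {p.set_id for p in pranks}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    log_lines = [f"seed={config.seed}", f"alpha={config.alpha}",
                 f"qc={config.qc}", f"min_score={config.min_score}"]

    snp_meta = None
    if config.snp_annotation:
        ann = pd.read_csv(config.snp_annotation, sep="\t", dtype=str)
        from .io import SnpMeta

        snp_meta = {
            row.snp: SnpMeta(row.snp, row.chrom, row.locus, row.a1, row.a2)
            for row in ann.itertuples(index=False)
        }
    matrix = read_genotypes(config.genotypes, snp_meta=snp_meta)
    interactions = read_interactions(config.interactions, min_score=config.min_score)
    db = read_gmt(config.gmt)
    log_lines.append(
        f"inputs: {matrix.n_samples} samples x {matrix.n_snps} SNPs, "
        f"{len(interactions)} interactions, {len(db)} gene sets"
    )

    snp_lists: dict[str, list[str]] = {}
    profiles: dict[str, set[str]] = {}
    stage = "setup"
    try:
        for case, control in config.contrasts:
            tag = case.lower()
            stage = f"association[{case} vs {control}]"
            kept, report = assoc.qc_filter(matrix, config.qc, control_group=control)
            _write_tsv(report, out / f"{tag}_qc_report.tsv", manifest)
            results = assoc.run_association(
                matrix, case, control, alpha=config.alpha, snp_ids=kept
            )
            _write_tsv(assoc.association_frame(results),
                       out / f"{tag}_association.tsv", manifest)
            snp_lists[case] = [r.snp.snp_id for r in results]
            log_lines.append(
                f"{case} vs {control}: {len(kept)}/{matrix.n_snps} SNPs passed QC, "
                f"{len(results)} significant at alpha={config.alpha}"
            )
            if len(results) < config.min_significant:
                logger.warning(
                    "%s: only %d significant SNPs (<%d); contrast skipped downstream",
                    case, len(results), config.min_significant,
                )
                log_lines.append(f"{case}: skipped downstream (too few SNPs)")
                continue
            genes = list(dict.fromkeys(r.snp.locus or r.snp.snp_id for r in results))
            (out / f"{tag}_genes.txt").write_text("\n".join(genes) + "\n")
            manifest[f"{tag}_genes.txt"] = _sha256(out / f"{tag}_genes.txt")

            stage = f"method1[{case}]"
            m1 = _method1(tag, genes, db, config, out, manifest)
            stage = f"method2[{case}]"
            m2 = _method2(tag, genes, db, config, interactions, out, manifest)

            stage = f"merge[{case}]"
            common, only1, only2 = ranking_compare.merge_methods(m1, m2)
            _write_tsv(
                pd.DataFrame(
                    [{"pathway": p, "region": reg}
                     for reg, ps in (("common", common), ("method1_only", only1),
                                     ("method2_only", only2))
                     for p in sorted(ps)]
                ),
                out / f"{tag}_method_merge.tsv", manifest,
            )
            profiles[case] = m1 | m2

        stage = "venn"
        cases = list(snp_lists)
        for i in range(len(cases)):
            for j in range(i + 1, len(cases)):
                a, b = cases[i], cases[j]
                regions = ranking_compare.venn_regions({a: snp_lists[a], b: snp_lists[b]})
                _write_tsv(
                    pd.DataFrame(
                        [{"region": "+".join(k), "n": len(v), "items": ",".join(sorted(v))}
                         for k, v in regions.items()]
                    ),
                    out / f"venn_{a.lower()}_{b.lower()}.tsv", manifest,
                )

        stage = "disease_network"
        if len(profiles) >= 2:
            dd = ranking_compare.disease_network(profiles)
            _write_tsv(_edges_frame(dd, "weight"), out / "disease_network.tsv", manifest)
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage} failed: {exc}") from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest["run.log"] = _sha256(out / "run.log")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
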