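"""Full-pipeline orchestration: simulate -> classify -> duplication ->
kaks/tree -> expression -> report.

A single config object drives all stages; outputs are plain TSV/JSON and
deterministic given (inputs, config, seed). Logs (tool version, config
hash, per-stage wall time) go to stderr and never into result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import classify_superfamily, subgroup_dreb
from .duplication import (
    classify_duplication,
    compute_edges,
    tandem_clusters,
)
from .expression import evaluate_fixture_recovery
from .io import write_fasta, write_gff3, write_newick, write_report
from .molevo import (
    bootstrap_support,
    divergence_time,
    ng86,
    pair_alignment,
)
from .motifs import find_domains_by_consensus
from .synthetic import (
    FixtureSpec,
    make_expression_fixture,
    make_genome_fixture,
    make_two_clade_alignment,
    mutate_cds_pair,
)

log = logging.getLogger("drebtools")


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    window: int = 200_000
    clock_rate: float = 6.1e-9
    bootstrap_reps: int = 200
    noise_sigma: float = 0.2
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "classify", "duplication", "kaks", "tree", "expression",
        ]
    )
    fixture: FixtureSpec = field(default_factory=FixtureSpec)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "fixture" in data and isinstance(data["fixture"], dict):
            fx = dict(data["fixture"])
            fx["tandem_clusters"] = [tuple(t) for t in fx.get("tandem_clusters", [])]
            fx["kaks_targets"] = [tuple(t) for t in fx.get("kaks_targets", [])]
            data["fixture"] = FixtureSpec(**fx)
        return cls(**data)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # parameter hash, not path hash
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and write the report.

    Returns the report dict (also written to ``<outdir>/report.json``).
    """
    known = {"simulate", "classify", "duplication", "kaks", "tree", "expression"}
    unknown = set(config.stages) - known
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    need_sim = {"classify", "duplication", "kaks", "tree", "expression"}
    if set(config.stages) & need_sim and "simulate" not in config.stages:
        raise ValueError("downstream stages need the simulate stage (or inputs)")

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("drebtools %s | config %s", __version__, config.config_hash())
    report: dict = {"version": __version__, "config_hash": config.config_hash()}
    fixture = None

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        spec = FixtureSpec(**{**asdict(config.fixture), "seed": config.seed})
        spec.tandem_clusters = [tuple(t) for t in spec.tandem_clusters]
        spec.kaks_targets = [tuple(t) for t in spec.kaks_targets]
        fixture = make_genome_fixture(spec)
        write_fasta(fixture.proteins, out / "proteins.faa")
        write_fasta(fixture.cds, out / "cds.fna")
        write_gff3(fixture.genes, out / "genes.gff3")
        fixture.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        log.info("simulate: %d genes in %.2f s", len(fixture.genes),
                 time.perf_counter() - t0)

    classified = {}
    if "classify" in config.stages:
        t0 = time.perf_counter()
        rows = []
        for protein in fixture.proteins:
            hits = find_domains_by_consensus(protein)
            cg = classify_superfamily(protein, hits)
            if cg.superfamily == "DREB-candidate":
                cg = subgroup_dreb(cg, protein)
            classified[protein.id] = cg
            rows.append(
                dict(protein_id=protein.id, superfamily=cg.superfamily,
                     subgroup=cg.subgroup, n_ap2_domains=cg.n_ap2_domains,
                     has_b3=cg.has_b3,
                     **{f"flag_{k}": v for k, v in cg.flags.items()})
            )
        pd.DataFrame(rows).to_csv(out / "classified.tsv", sep="\t", index=False)
        counts = pd.Series(
            [c.superfamily for c in classified.values()]
        ).value_counts().to_dict()
        report["classification"] = {
            "counts": counts,
            "n_proteins": len(classified),
            "subgroups": pd.Series(
                [c.subgroup for c in classified.values()]
            ).value_counts().to_dict(),
        }
        truth = fixture.truth
        match = all(
            classified[r.protein_id].superfamily == r.superfamily
            and classified[r.protein_id].subgroup == r.subgroup
            for r in truth.itertuples()
        )
        report["classification"]["matches_truth"] = bool(match)
        log.info("classify: %d proteins in %.2f s", len(rows),
                 time.perf_counter() - t0)

    if "duplication" in config.stages:
        t0 = time.perf_counter()
        prot_map = {p.id: p for p in fixture.proteins}
        edges = compute_edges(fixture.genes, prot_map)
        clusters = tandem_clusters(fixture.genes, edges, window=config.window)
        labels = classify_duplication(fixture.genes, clusters, edges,
                                      window=config.window)
        cluster_rows = [
            dict(cluster=c.cluster_id, gene=gid, chromosome=c.chromosome,
                 start=span[0], end=span[1])
            for c in clusters
            for gid, span in zip(c.members, c.spans)
        ]
        pd.DataFrame(
            cluster_rows, columns=["cluster", "gene", "chromosome", "start", "end"]
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        truth_clusters = {
            tuple(sorted(sub.gene_id))
            for cid, sub in fixture.truth.groupby("cluster_id")
            if cid
        }
        found = {tuple(sorted(c.members)) for c in clusters}
        report["duplication"] = {
            "n_clusters": len(clusters),
            "labels": pd.Series(list(labels.values())).value_counts().to_dict(),
            "matches_truth": bool(found == truth_clusters),
        }
        log.info("duplication: %d clusters in %.2f s", len(clusters),
                 time.perf_counter() - t0)

    if "kaks" in config.stages:
        t0 = time.perf_counter()
        targets = config.fixture.kaks_targets or [(300, 0.10, 0.03)]
        rows = []
        for i, (n_codons, ks_t, ka_t) in enumerate(targets):
            a, b = mutate_cds_pair(int(n_codons), float(ks_t), float(ka_t),
                                   seed=config.seed + i)
            res = ng86(pair_alignment(a, b))
            t = divergence_time(res.ks, config.clock_rate) if res.ks is not None else None
            rows.append(
                dict(pair=f"target_{i + 1}", n_codons=int(n_codons),
                     target_ks=ks_t, target_ka=ka_t,
                     ks=res.ks, ka=res.ka, ratio=res.ratio,
                     t_mya=None if t is None else t.t_mya)
            )
        pd.DataFrame(rows).to_csv(out / "kaks.tsv", sep="\t", index=False)
        report["kaks"] = rows
        log.info("kaks: %d pairs in %.2f s", len(rows), time.perf_counter() - t0)

    if "tree" in config.stages:
        t0 = time.perf_counter()
        alignment, (clade_a, _clade_b) = make_two_clade_alignment(seed=config.seed)
        result = bootstrap_support(alignment, n_reps=config.bootstrap_reps,
                                   seed=config.seed)
        newick = write_newick(result.tree)
        (out / "tree.nwk").write_text(newick + "\n", encoding="utf-8")
        supports = [n.support for n in result.tree.preorder()
                    if n.support is not None]
        report["tree"] = {
            "newick": newick,
            "n_replicates": result.n_replicates,
            "n_skipped": result.n_skipped,
            "min_support": min(supports) if supports else None,
        }
        log.info("tree: bootstrap %d reps in %.2f s", config.bootstrap_reps,
                 time.perf_counter() - t0)

    if "expression" in config.stages:
        t0 = time.perf_counter()
        patterns = config.fixture.expression_patterns or None
        matrix, design, truth = make_expression_fixture(
            patterns=patterns, seed=config.seed, sigma=config.noise_sigma
        )
        matrix.to_csv(out / "fpkm.tsv", sep="\t")
        design.to_csv(out / "design.tsv", sep="\t")
        truth.to_csv(out / "expression_truth.tsv", sep="\t")
        recovery = evaluate_fixture_recovery(matrix, design, truth)
        recovery.to_csv(out / "expression_calls.tsv", sep="\t")
        report["expression"] = {
            "n_genes": int(len(recovery)),
            "recovered_fraction": float(recovery["recovered"].mean()),
        }
        log.info("expression: %d genes in %.2f s", len(recovery),
                 time.perf_counter() - t0)

    write_report(report, out / "report.json")
    return report
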