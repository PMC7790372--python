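"""End-to-end pipeline orchestration with manifests and fixed seeds.

``run_pipeline`` executes the stages in order — simulate/load, filter,
all-vs-all, SSN, cluster, pivot, transfer, motifs+fingerprints, predict,
with optional small-world/representative and structure branches — writing
every stage's outputs under one directory and recording a manifest of
parameters and content hashes.  Reruns with identical configuration and
seeds reproduce identical hashes (the manifest carries no timestamps).

Configuration is a flat INI/TOML-style text file with one section per
stage; every stage seed is derived deterministically from the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nat_groups  # noqa: F401  (re-export convenience)
from .align import ScoringParams, all_vs_all, write_hits_tsv
from .clustering import (
    Clustering,
    ClusteringParams,
    clustering_f1,
    detect_clusters,
    write_membership_tsv,
    write_summary_tsv,
)
from .motifs import (
    GroupFingerprint,
    discover_motifs,
    letter_background,
    write_meme_minimal,
    write_regex_table,
)
from .network import (
    build_ssn,
    write_edge_tsv,
    write_graphml,
    write_node_table,
    write_xgmml,
)
from .pivot import analyze_topology, contract, write_topology_tsv
from .prediction import (
    predict_nat_candidates,
    transfer_annotations,
    write_candidate_report,
    write_candidate_tsv,
)
from .records import SequenceRecord, read_fasta, write_fasta
from .redundancy import filter_short, redundancy_filter
from .smallworld import (
    grid_scan,
    select_phylogeny_component,
    select_representatives,
    write_grid_tsv,
)
from .structure import build_dendrogram, separation_threshold
from .synthetic import (
    FamilySpec,
    generate_superfamily,
    generate_zscore_matrix,
    mutate_sequence,
    random_scaffold,
    blosum62_background,
    write_truth_tsv,
)

logger = logging.getLogger(__name__)

DEFAULT_GRID = (
    (1e-5, 5.0),
    (1e-5, 10.0),
    (1e-10, 10.0),
    (1e-15, 15.0),
)


@dataclass
class PipelineConfig:
    """All pipeline parameters in one place."""

    input_fasta: str | None = None  # None -> built-in synthetic demo
    family_specs: list[FamilySpec] | None = None
    identity_steps: tuple[float, ...] = (0.9,)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    evalue_cutoff: float = 1e-5
    ssn_evalue_max: float = 1e-5
    ssn_score_min: float = 5.0
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    motif_max: int = 25
    motif_widths: tuple[int, ...] = tuple(range(5, 11))
    motif_shuffles: int = 20
    prediction_alpha: float = 0.01
    smallworld_grid: tuple[tuple[float, float], ...] = DEFAULT_GRID
    smallworld_n_ref: int = 10
    k_representatives: int = 3
    structure_mu_within: float = 20.0
    structure_mu_between: float = 5.0
    structure_sd: float = 1.0
    run_smallworld: bool = True
    run_structure: bool = True
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def demo_family_specs(seed: int = 0) -> list[FamilySpec]:
    """Three-family demo superfamily exercising every pipeline stage.

    Families A and B carry curated labels.  Family C is uncharacterized:
    its scaffold is unrelated, but it shares family A's α1-α2 motif with
    a single modal-residue change (F -> L at the mutation-sensitive first
    position) and A's β6-β7 motif exactly.  Cross alignments anchored on
    the two shared motifs push a handful of A-C pairs past the SSN
    thresholds, making C a sparsely connected pivot neighbour of A — the
    situation the candidate-prediction stage is built for.
    """
    rng = np.random.default_rng(seed)
    bg = blosum62_background()
    a_motifs = [
        ("a1a2", "FPVEYSDKWY", 20),
        ("b4", "LYIMTLGVL", 60),
        ("b5", "AIYLHVQ", 95),
        ("b6b7", "HSYLPYYYS", 125),
    ]
    c_shared = "L" + a_motifs[0][1][1:]  # F->L at the mutation-sensitive position
    c_scaffold = random_scaffold(150, bg, rng)
    specs = [
        FamilySpec("famA", 10, motifs=a_motifs, target_within_identity=0.8,
                   labelled_fraction=0.3, label="NAT-A"),
        FamilySpec("famB", 10, motifs=[("a1a2", "YEQSSWGWDD", 25),
                                       ("b4", "VLYCYEIQ", 70),
                                       ("b5", "KVMLTVFK", 110)],
                   target_within_identity=0.8, labelled_fraction=0.3,
                   label="NAT-B"),
        FamilySpec("famC", 10, scaffold=c_scaffold,
                   motifs=[("a1a2", c_shared, 20),
                           ("b4", "WDERTNQAG", 60),
                           ("b6b7", a_motifs[3][1], 125)],
                   target_within_identity=0.8, labelled_fraction=0.0),
    ]
    return specs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.outdir = outdir
        self.data: dict = {
            "seed": config.seed,
            "parameters": {
                "identity_steps": list(config.identity_steps),
                "evalue_cutoff": config.evalue_cutoff,
                "ssn": [config.ssn_evalue_max, config.ssn_score_min],
                "clustering": {
                    "min_size": config.clustering.min_size,
                    "penalty": config.clustering.penalty,
                    "overlap_omega": config.clustering.overlap_omega,
                    "min_density": config.clustering.min_density,
                },
                "motifs": {
                    "max": config.motif_max,
                    "widths": list(config.motif_widths),
                    "shuffles": config.motif_shuffles,
                },
                "alpha": config.prediction_alpha,
            },
            "stages": [],
        }

    def record(self, name: str, outputs: Sequence[Path], info: dict | None = None) -> None:
        self.data["stages"].append(
            {
                "name": name,
                "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
                "info": info or {},
            }
        )
        logger.info("stage %s done: %s", name, info or {})

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
        return path


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every configured stage; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)

    # --- simulate or load -------------------------------------------------
    truth = None
    if config.input_fasta is not None:
        records = read_fasta(config.input_fasta)
        manifest.record("load", [], {"n_sequences": len(records)})
    else:
        specs = config.family_specs or demo_family_specs(config.stage_seed("demo"))
        records, truth = generate_superfamily(specs, seed=config.stage_seed("simulate"))
        fasta = outdir / "dataset.fasta"
        write_fasta(records, fasta)
        truth_path = outdir / "truth.tsv"
        write_truth_tsv(truth, truth_path)
        manifest.record(
            "simulate", [fasta, truth_path],
            {"n_sequences": len(records), "n_families": len(truth.families)},
        )

    # --- filter -----------------------------------------------------------
    kept = filter_short(records)
    representatives, assignment = redundancy_filter(
        kept, config.identity_steps, config.scoring
    )
    reps_path = outdir / "representatives.fasta"
    write_fasta(representatives, reps_path)
    assign_path = outdir / "assignment.tsv"
    with open(assign_path, "w") as fh:
        fh.write("seq_id\trepresentative\n")
        for seq_id in sorted(assignment):
            fh.write(f"{seq_id}\t{assignment[seq_id]}\n")
    manifest.record(
        "filter", [reps_path, assign_path],
        {"n_input": len(records), "n_representatives": len(representatives)},
    )

    # --- all-vs-all -------------------------------------------------------
    hits = all_vs_all(representatives, config.scoring, config.evalue_cutoff)
    hits_path = outdir / "hits.tsv"
    write_hits_tsv(hits, hits_path)
    manifest.record("allvsall", [hits_path], {"n_hits": len(hits)})

    # --- SSN ----------------------------------------------------------------
    ssn = build_ssn(hits, config.ssn_evalue_max, config.ssn_score_min, representatives)
    edge_path = outdir / "ssn_edges.tsv"
    write_edge_tsv(ssn, edge_path)
    graphml_path = outdir / "ssn.graphml"
    write_graphml(ssn.graph, graphml_path)
    nodes_path = outdir / "ssn_nodes.tsv"
    write_node_table(ssn, nodes_path)
    manifest.record(
        "ssn", [edge_path, graphml_path, nodes_path],
        {
            "n_nodes": ssn.n_nodes,
            "n_edges": ssn.n_edges,
            "convergence_ratio": round(ssn.convergence_ratio, 6),
        },
    )

    # --- clustering ---------------------------------------------------------
    clustering = detect_clusters(ssn.graph, config.clustering)
    memb_path = outdir / "clusters_membership.tsv"
    write_membership_tsv(clustering, representatives, memb_path)
    info: dict = {"n_clusters": len(clustering)}
    if truth is not None:
        info["clustering_f1"] = round(
            clustering_f1(
                clustering,
                {r.id: truth.membership[r.id] for r in representatives},
            ),
            4,
        )
    manifest.record("cluster", [memb_path], info)

    # --- pivot --------------------------------------------------------------
    pivot = contract(ssn, clustering)
    topology = analyze_topology(pivot)
    pivot_graphml = outdir / "pivot.graphml"
    write_graphml(pivot, pivot_graphml)
    pivot_xgmml = outdir / "pivot.xgmml"
    write_xgmml(pivot, pivot_xgmml, name="pivot")
    topo_path = outdir / "pivot_topology.tsv"
    write_topology_tsv(pivot, topology, topo_path)
    manifest.record(
        "pivot", [pivot_graphml, pivot_xgmml, topo_path],
        {"n_nodes": pivot.number_of_nodes(), "n_edges": pivot.number_of_edges()},
    )

    # --- annotation transfer -----------------------------------------------
    transfer = transfer_annotations(clustering, representatives)
    ann_path = outdir / "annotations.tsv"
    with open(ann_path, "w") as fh:
        fh.write("seq_id\tlabel\tprovenance\n")
        for seq_id in sorted(transfer.annotations):
            label, prov = transfer.annotations[seq_id]
            fh.write(f"{seq_id}\t{label}\t{prov}\n")
    summary_path = outdir / "clusters_summary.tsv"
    write_summary_tsv(clustering, summary_path)
    n_transferred = sum(
        1 for _, prov in transfer.annotations.values() if prov == "transferred"
    )
    manifest.record(
        "transfer", [ann_path, summary_path], {"n_transferred": n_transferred}
    )

    # --- motifs and fingerprints ---------------------------------------------
    by_id = {rec.id: rec for rec in representatives}
    background = letter_background(representatives)
    groups: dict[str, list[str]] = {}
    for cluster in clustering.clusters:
        if cluster.label not in ("uncharacterized", "mixed"):
            groups.setdefault(cluster.label, []).extend(sorted(cluster.members))
    fingerprints: list[GroupFingerprint] = []
    motif_paths = []
    for label in sorted(groups):
        members = [by_id[m] for m in groups[label]]
        if len(members) < 5:
            logger.warning("group %s has < 5 sequences; skipping motifs", label)
            continue
        found = discover_motifs(
            members,
            max_motifs=config.motif_max,
            width_range=config.motif_widths,
            seed=config.stage_seed(f"motifs:{label}"),
            n_shuffle=config.motif_shuffles,
            background=background,
        )
        if not found:
            continue
        labelled = [(f"el{i + 1}", m) for i, m in enumerate(found)]
        fingerprints.append(GroupFingerprint(name=label, motifs=labelled))
        meme_path = outdir / f"motifs_{label}.meme.txt"
        write_meme_minimal(found, background, meme_path)
        motif_paths.append(meme_path)
    regex_path = outdir / "fingerprints.tsv"
    write_regex_table(fingerprints, regex_path)
    manifest.record(
        "motifs", motif_paths + [regex_path], {"n_groups": len(fingerprints)}
    )

    # --- prediction -----------------------------------------------------------
    if not groups:
        raise RuntimeError(
            "prediction stage failed: no known-NAT cluster "
            "(no cluster carries a curated functional label)"
        )
    predict_paths = []
    if fingerprints:
        try:
            reports = predict_nat_candidates(
                pivot,
                clustering,
                fingerprints,
                representatives,
                alpha=config.prediction_alpha,
                background=background,
                discovery_seed=config.stage_seed("predict"),
                discovery_kwargs={
                    "width_range": config.motif_widths,
                    "n_shuffle": config.motif_shuffles,
                    "background": background,
                },
            )
        except ValueError as exc:
            raise RuntimeError(f"prediction stage failed: {exc}") from exc
        cand_tsv = outdir / "candidates.tsv"
        write_candidate_tsv(reports, cand_tsv)
        cand_txt = outdir / "candidates.txt"
        write_candidate_report(reports, cand_txt)
        predict_paths = [cand_tsv, cand_txt]
        manifest.record(
            "predict", predict_paths,
            {"n_candidates": len(reports),
             "verdicts": sorted(r.verdict for r in reports)},
        )
    else:
        manifest.record("predict", [], {"n_candidates": 0, "skipped": "no fingerprints"})

    # --- smallworld / representatives -----------------------------------------
    if config.run_smallworld and len(hits) > 0:
        rows = grid_scan(
            hits,
            config.smallworld_grid,
            records=representatives,
            n_ref=config.smallworld_n_ref,
            seed=config.stage_seed("smallworld"),
        )
        grid_path = outdir / "smallworld_grid.tsv"
        write_grid_tsv(rows, grid_path)
        chosen, fallback = select_phylogeny_component(rows)
        reps = select_representatives(
            clustering,
            chosen.component,
            representatives,
            k=config.k_representatives,
            seed=config.stage_seed("representatives"),
        )
        phylo_path = outdir / "phylogeny_representatives.fasta"
        chosen_ids = sorted(i for picks in reps.values() for i in picks)
        write_fasta([by_id[i] for i in chosen_ids], phylo_path)
        manifest.record(
            "smallworld", [grid_path, phylo_path],
            {
                "chosen": [chosen.evalue_max, chosen.score_min],
                "component_size": chosen.largest_component_size,
                "sigma": round(chosen.sigma, 4),
                "fallback": fallback,
            },
        )

    # --- structure branch -------------------------------------------------------
    if config.run_structure and truth is not None:
        zmatrix = generate_zscore_matrix(
            truth,
            config.structure_mu_within,
            config.structure_mu_between,
            config.structure_sd,
            seed=config.stage_seed("structure"),
        )
        z_path = outdir / "zscores.csv"
        zmatrix.to_csv(z_path)
        newick_path = outdir / "structure_dendrogram.nwk"
        newick_path.write_text(build_dendrogram(zmatrix) + "\n")
        sep = separation_threshold(zmatrix)
        manifest.record(
            "structure", [z_path, newick_path], {"separation_threshold": sep}
        )

    path = manifest.write()
    logger.info("manifest written to %s", path)
    return manifest.data


# ---------------------------------------------------------------------------
# Config file parsing


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML config file with one section per stage."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = PipelineConfig()
    inp = raw.get("input", {})
    cfg.input_fasta = inp.get("fasta")
    flt = raw.get("filter", {})
    cfg.identity_steps = tuple(flt.get("identity_steps", cfg.identity_steps))
    sc = raw.get("scoring", {})
    cfg.scoring = ScoringParams(
        matrix=sc.get("matrix", "BLOSUM62"),
        gap_open=sc.get("gap_open", 11),
        gap_extend=sc.get("gap_extend", 1),
        lam=sc.get("lambda", 0.267),
        K=sc.get("K", 0.041),
    )
    ssn = raw.get("ssn", {})
    cfg.evalue_cutoff = ssn.get("evalue_cutoff", cfg.evalue_cutoff)
    cfg.ssn_evalue_max = ssn.get("evalue_max", cfg.ssn_evalue_max)
    cfg.ssn_score_min = ssn.get("score_min", cfg.ssn_score_min)
    cl = raw.get("clustering", {})
    cfg.clustering = ClusteringParams(
        min_size=cl.get("min_size", 10),
        penalty=cl.get("penalty", 2.0),
        overlap_omega=cl.get("overlap_omega", 0.8),
        min_density=cl.get("min_density", "auto"),
    )
    mo = raw.get("motifs", {})
    cfg.motif_max = mo.get("max_motifs", cfg.motif_max)
    if "widths" in mo:
        cfg.motif_widths = tuple(mo["widths"])
    cfg.motif_shuffles = mo.get("n_shuffle", cfg.motif_shuffles)
    pred = raw.get("prediction", {})
    cfg.prediction_alpha = pred.get("alpha", cfg.prediction_alpha)
    sw = raw.get("smallworld", {})
    cfg.run_smallworld = sw.get("enabled", cfg.run_smallworld)
    cfg.smallworld_n_ref = sw.get("n_ref", cfg.smallworld_n_ref)
    cfg.k_representatives = sw.get("k", cfg.k_representatives)
    if "grid" in sw:
        cfg.smallworld_grid = tuple((float(e), float(s)) for e, s in sw["grid"])
    st = raw.get("structure", {})
    cfg.run_structure = st.get("enabled", cfg.run_structure)
    cfg.structure_mu_within = st.get("mu_within", cfg.structure_mu_within)
    cfg.structure_mu_between = st.get("mu_between", cfg.structure_mu_between)
    cfg.structure_sd = st.get("sd", cfg.structure_sd)
    cfg.seed = raw.get("seed", 0)
    return cfg
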