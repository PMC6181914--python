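"""End-to-end orchestration: simulate -> filter -> profile -> align -> tree ->
conservation -> motif discovery -> classification, with a reproducible run
directory (stage outputs, checksums, manifest).

The pipeline exercises every stage on synthetic families, mirroring the
workflow used for the real superfamily: a seed alignment builds a profile
HMM, the pool is aligned back to the profile, the implied match-column
alignment drives tree building and conservation scoring, and candidate
specificity-determining positions are selected and used to classify every
sequence.  All randomness derives from one master seed with per-stage
derived streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import conservation, hmm, io_filters, phylo, synthetic
from .classifier import (
    CladeReference,
    MotifSpec,
    classify,
    load_clade_reference,
)
from .substitution import SubstitutionModel

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "outdir", "n_leaves", "seq_length", "n_clades", "gamma_alpha",
    "motif_noise_eps", "indel_rate", "motif_table", "min_length",
    "cluster_identity", "run_clustering", "match_gap_threshold",
    "pseudocount_weight", "seed_rows", "essential_coverage",
    "bootstrap_replicates", "pd_subset_k", "n_gamma_categories",
    "min_grade", "k_max", "min_gain", "run_classification",
}


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    outdir: str = "cpa_run"
    # synthetic family
    n_leaves: int = 120
    seq_length: int = 400
    n_clades: int = 4
    gamma_alpha: float = 1.0
    motif_noise_eps: float = 0.0
    indel_rate: float = 0.005
    motif_table: str = "reference"      # "reference" | "discovery"
    # filters
    min_length: int = 300
    run_clustering: bool = False
    cluster_identity: float = 0.70
    # profile
    match_gap_threshold: float = 0.5
    pseudocount_weight: float = 1.0
    seed_rows: int = 40
    essential_coverage: float = 0.70
    # trees
    bootstrap_replicates: int = 100
    pd_subset_k: int = 30
    # conservation / discovery
    n_gamma_categories: int = 8
    min_grade: int = 8
    k_max: int = 8
    min_gain: float = 0.0
    run_classification: bool = True

    def __post_init__(self):
        if self.motif_table not in ("reference", "discovery"):
            raise ValueError("motif_table must be 'reference' or 'discovery'")
        if self.run_classification and self.motif_table not in ("reference", "discovery"):
            raise ValueError("classification requires a motif table")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to the run dir)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    model = SubstitutionModel.lg()
    manifest: dict = {"config": asdict(config), "stages": {}, "checksums": {}}

    def record(stage: str, **info):
        manifest["stages"][stage] = {"status": "completed", **info}
        log.info("[stage %s | seed %s] completed", stage, config.seed)

    try:
        # -- simulate ---------------------------------------------------------------
        tree = synthetic.simulate_tree(config.n_leaves, _stage_seed(config.seed, "tree"))
        clades = synthetic.assign_clades(tree, config.n_clades,
                                         _stage_seed(config.seed, "clades"))
        if config.motif_table == "reference":
            table = synthetic.reference_motif_table()
            names = list(table)
            clade_map = {f"clade{i + 1:02d}": names[i % len(names)] for i in range(config.n_clades)}
            table = {f"clade{i + 1:02d}": table[clade_map[f"clade{i + 1:02d}"]]
                     for i in range(config.n_clades)}
        else:
            table = synthetic.default_motif_table(config.n_clades)
        params = synthetic.SimulationParams(
            n_leaves=config.n_leaves, seq_length=config.seq_length,
            gamma_alpha=config.gamma_alpha, n_clades=config.n_clades,
            clade_motif_table=table, motif_noise_eps=config.motif_noise_eps,
            indel_rate=config.indel_rate, seed=_stage_seed(config.seed, "family"),
        )
        family = synthetic.simulate_family(tree, clades, params, model)
        synthetic.write_family(family, out / "simulate")
        record("simulate", n_leaves=len(family.ids), msa_length=len(family.msa_rows[0]))

        # -- filter -----------------------------------------------------------------
        kept, dropped = io_filters.length_filter(family.records, config.min_length)
        io_filters.write_fasta(kept, out / "filtered.fasta")
        record("filter", kept=len(kept), dropped=len(dropped))
        if config.run_clustering:
            clusters = io_filters.greedy_identity_cluster(kept, config.cluster_identity)
            io_filters.write_cluster_table(clusters, out / "clusters.tsv")
            record("cluster", n_clusters=len(clusters))

        # -- profile ----------------------------------------------------------------
        seed_rows = family.msa_rows[: config.seed_rows]
        profile = hmm.build_profile(seed_rows, config.match_gap_threshold,
                                    config.pseudocount_weight, model.frequencies)
        (out / "profile.json").write_text(profile.to_json())
        # planted columns in match-state space (1-based)
        col_to_match = {c: k + 1 for k, c in enumerate(profile.column_map)}
        try:
            motif_match_cols = tuple(col_to_match[c] for c in family.truth.motif_columns)
            aux_match_col = col_to_match[family.truth.aux_column]
        except KeyError as exc:
            raise RuntimeError(f"planted column {exc} not a match state") from exc
        spec = MotifSpec(motif_match_cols, aux_match_col)
        record("profile", n_match=profile.n_match)

        # -- align ------------------------------------------------------------------
        maps = {}
        with open(out / "alignment_maps.tsv", "w") as fh:
            fh.write("query_id\tquery_pos\tmatch_column\n")
            for rec in kept:
                amap, score = hmm.viterbi_align(profile, rec.residues)
                maps[rec.id] = amap
                for row in amap.to_tsv_rows(rec.id):
                    fh.write(row + "\n")
        covered, low_cov = io_filters.essential_coverage_filter(
            maps, kept, list(spec.columns), spec.columns[6], config.essential_coverage)
        record("align", aligned=len(maps), coverage_kept=len(covered),
               coverage_dropped=len(low_cov))

        # -- implied match-column alignment ----------------------------------------
        ids = [r.id for r in covered]
        match_rows = []
        for rec in covered:
            amap = maps[rec.id]
            row = []
            for k in range(1, profile.n_match + 1):
                qi = amap.query_index_of_column(k)
                row.append("-" if qi is None else rec.residues[qi])
            match_rows.append("".join(row))
        io_filters.write_fasta(
            [io_filters.SequenceRecord(i, r) for i, r in zip(ids, match_rows)],
            out / "match_alignment.fasta")

        # -- tree -------------------------------------------------------------------
        dm = phylo.pairwise_distances(ids, match_rows, model)
        dm.to_tsv(out / "distances.tsv")
        nj = phylo.nj_tree(dm)
        phylo.write_newick(nj, out / "nj_tree.nwk")
        k = min(config.pd_subset_k, len(ids))
        subset = phylo.select_diverse_subset(nj, max(2, k))
        (out / "pd_subset.txt").write_text("\n".join(subset) + "\n")
        sub_idx = [ids.index(s) for s in subset]
        boot = phylo.bootstrap_supports(
            [ids[i] for i in sub_idx], [match_rows[i] for i in sub_idx],
            config.bootstrap_replicates, _stage_seed(config.seed, "bootstrap"), model)
        phylo.write_newick(boot, out / "bootstrap_tree.nwk")
        record("tree", n_leaves=len(ids), pd_subset=len(subset),
               bootstrap_replicates=config.bootstrap_replicates)

        # -- conservation + discovery ----------------------------------------------
        labels = dict(zip(family.truth.table["leaf_id"], family.truth.table["clade"]))
        profile_rates = conservation.site_rates(
            nj, ids, match_rows, model, config.n_gamma_categories)
        profile_rates.to_tsv(out / "conservation.tsv")
        cands = conservation.candidate_sdp(profile_rates, config.min_grade)
        cands.to_csv(out / "candidates.tsv", sep="\t", index=False)
        label_list = [labels[i] for i in ids]
        selected = conservation.discover_motif(
            cands["column"].tolist(), match_rows, label_list,
            config.k_max, config.min_gain) if len(cands) else []
        planted_match0 = {c - 1 for c in spec.columns}  # 0-based in match space
        recovered = sorted(planted_match0 & set(selected))
        (out / "discovered_columns.tsv").write_text(
            "column_match_1based\tplanted\n" +
            "".join(f"{c + 1}\t{int(c in planted_match0)}\n" for c in selected))
        record("discover", candidates=len(cands), selected=len(selected),
               planted_recovered=len(recovered))

        # -- classification ---------------------------------------------------------
        if config.run_classification:
            reference = load_clade_reference() if config.motif_table == "reference" else None
            truth = family.truth.table.set_index("leaf_id")
            n_calls = n_correct = 0
            with open(out / "classification.tsv", "w") as fh:
                header = ["query_id"] + [f"s{i}" for i in range(1, 9)] + [
                    "aux", "family", "electrogenicity", "selectivity",
                    "clade", "margin", "flags"]
                fh.write("\t".join(header) + "\n")
                for rec in covered:
                    result = classify(rec.id, rec.residues, profile, spec, reference,
                                      config.essential_coverage)
                    row = result.to_row()
                    fh.write("\t".join(str(row[h]) for h in header) + "\n")
                    for phenotype in ("family", "electrogenicity", "selectivity"):
                        n_calls += 1
                        n_correct += int(getattr(result, phenotype)
                                         == truth.loc[rec.id, phenotype])
            accuracy = n_correct / n_calls if n_calls else float("nan")
            record("classify", n_queries=len(covered),
                   phenotype_call_accuracy=round(accuracy, 4))
    except Exception as exc:
        stage = len(manifest["stages"])
        log.error("pipeline halted after %d stages: %s", stage, exc)
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
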