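"""Seeded simulation studies quantifying what the pipeline recovers.

Two study families, both run on synthetic data from :mod:`cpakit.synthetic`:

* planted-motif discovery — simulate a clade-structured family, score
  conservation on the (known) generating tree, filter candidates, run greedy
  discovery against the clade labels and count how many of the 8 planted
  columns were recovered;
* phenotype accuracy — plant clade motifs drawn from the packaged clade
  reference, extract each leaf's motif states from the true alignment
  columns, apply the classifier rules, and score the calls (family,
  electrogenicity, selectivity) against the truth table.

The generating tree (not a re-estimated one) is used for conservation
scoring so the studies measure discovery and rule performance, not tree
error; the full estimate-everything path is exercised by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from . import conservation, synthetic
from .classifier import MotifAssignment, classify_assignment, load_clade_reference
from .substitution import SubstitutionModel


def random_additive_tree(rng: np.random.Generator, n_leaves: int) -> dendropy.Tree:
    """Random binary topology with uniform(0.05, 1.0) branch lengths."""
    tree = synthetic.simulate_tree(n_leaves, int(rng.integers(2**31 - 1)))
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.05, 1.0))
    return tree


def patristic_matrix(tree: dendropy.Tree):
    """Leaf labels and the pairwise path-length matrix (dendropy's own
    patristic distances, independent of this package's tree code)."""
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return labels, mat


@dataclass
class RecoveryStudy:
    recovered_per_family: list
    n_candidates_per_family: list
    n_planted: int = 8

    @property
    def runs_with_at_least(self) -> dict:
        return {k: sum(r >= k for r in self.recovered_per_family)
                for k in range(self.n_planted + 1)}

    @property
    def mean_recovered(self) -> float:
        return float(np.mean(self.recovered_per_family))


def motif_recovery_study(
    n_families: int = 20,
    seed: int = 0,
    eps: float = 0.05,
    n_leaves: int = 120,
    seq_length: int = 400,
    n_clades: int = 4,
    model: SubstitutionModel | None = None,
) -> RecoveryStudy:
    """Planted-column recovery of the discovery stage over seeded families."""
    model = model or SubstitutionModel.lg()
    rng = np.random.default_rng(seed)
    recovered, n_cands = [], []
    for _ in range(n_families):
        s1, s2, s3 = (int(x) for x in rng.integers(2**31 - 1, size=3))
        tree = synthetic.simulate_tree(n_leaves, s1)
        clades = synthetic.assign_clades(tree, n_clades, s2)
        params = synthetic.SimulationParams(
            n_leaves=n_leaves, seq_length=seq_length, n_clades=n_clades,
            motif_noise_eps=eps, indel_rate=0.0, seed=s3)
        family = synthetic.simulate_family(tree, clades, params, model)
        labels = [clades[i] for i in family.ids]
        profile = conservation.site_rates(tree, family.ids, family.msa_rows, model)
        cands = conservation.candidate_sdp(profile)
        planted = set(family.truth.motif_columns)
        if len(cands):
            selected = conservation.discover_motif(
                cands["column"].tolist(), family.msa_rows, labels, k_max=8)
        else:
            selected = []
        recovered.append(len(planted & set(selected)))
        n_cands.append(len(cands))
    return RecoveryStudy(recovered, n_cands)


def phenotype_accuracy_study(
    n_families: int = 5,
    seed: int = 0,
    eps: float = 0.0,
    n_leaves: int = 120,
    seq_length: int = 400,
    model: SubstitutionModel | None = None,
) -> tuple[float, int]:
    """Fraction of phenotype calls matching truth; returns (accuracy, n_calls).

    Clade motifs come from the packaged clade reference (both families, both
    electrogenicity classes, both selectivities); motif states are read off
    the true alignment columns, so the score isolates the decision rules and
    the noise process.
    """
    model = model or SubstitutionModel.lg()
    reference = load_clade_reference()
    ref_table = synthetic.reference_motif_table(reference=reference)
    names = list(ref_table)
    n_clades = len(names)
    rng = np.random.default_rng(seed)
    correct = total = 0
    for _ in range(n_families):
        s1, s2, s3 = (int(x) for x in rng.integers(2**31 - 1, size=3))
        tree = synthetic.simulate_tree(n_leaves, s1)
        clades = synthetic.assign_clades(tree, n_clades, s2)
        table = {f"clade{i + 1:02d}": ref_table[names[i]] for i in range(n_clades)}
        params = synthetic.SimulationParams(
            n_leaves=n_leaves, seq_length=seq_length, n_clades=n_clades,
            clade_motif_table=table, motif_noise_eps=eps, seed=s3)
        family = synthetic.simulate_family(tree, clades, params, model)
        for _, row in family.truth.table.iterrows():
            m = MotifAssignment(tuple(row["motif_states"]), aux=row["aux_state"])
            result = classify_assignment(row["leaf_id"], m, reference)
            for phenotype in ("family", "electrogenicity", "selectivity"):
                total += 1
                correct += int(getattr(result, phenotype) == row[phenotype])
    return correct / total, total
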