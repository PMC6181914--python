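"""Synthetic clade-structured protein families with planted motif states.

The generator emulates the statistical shape of a transporter superfamily:
a Yule tree, monophyletic clades, sequences evolved along the tree under the
LG model with gamma-distributed site-rate heterogeneity, and a fixed set of
motif columns overwritten with clade-specific states (optionally perturbed
with a per-cell noise probability).  Indels (deletions and explicit insertion
columns) occur only outside the motif columns, so column-level truth is exact
by construction.  Everything is driven by one seed: identical parameters give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .classifier import (
    CladeReference,
    MotifAssignment,
    classify_assignment,
    load_clade_reference,
)
from .io_filters import SequenceRecord
from .substitution import (
    AMINO_ACIDS,
    SubstitutionModel,
    decode_states,
    encode_sequence,
)

DEFAULT_BRANCH_LENGTH_MEAN = 0.2  # expected substitutions/site per edge

# per-column state pools for the discovery benchmark: every state polar or
# charged (so the candidate filters cannot exclude a planted column a priori)
# and distinct per clade (each planted column individually separates clades)
_POLAR_POOLS = (
    ("S", "T", "N", "Q", "C", "Y"),
    ("T", "N", "S", "Q", "Y", "C"),
    ("D", "E", "S", "N", "T", "Q"),
    ("S", "T", "Q", "N", "Y", "C"),
    ("E", "Q", "D", "N", "S", "T"),
    ("N", "D", "Q", "E", "S", "T"),
    ("D", "E", "N", "Q", "S", "T"),
    ("R", "K", "H", "Q", "N", "S"),
)
_POLAR_AUX_POOL = ("S",)  # constant: the benchmark plants signal only at the 8 columns


def default_motif_columns(seq_length: int) -> tuple[tuple, int]:
    """Motif (8) and auxiliary column indices (0-based), EcNhaA-like spacing
    scaled to ``seq_length`` (four consecutive TM-4 columns, a TM-5 triplet
    one helix-turn below, a distant TM-10 column, and the TM-3 auxiliary)."""
    base = (131, 132, 133, 134, 159, 163, 164, 300)
    aux = 108
    scale = seq_length / 400.0
    cols = []
    prev = -1
    for b in base:
        c = max(prev + 1, min(int(round(b * scale)), seq_length - 1))
        cols.append(c)
        prev = c
    a = min(int(round(aux * scale)), seq_length - 1)
    if a in cols:
        a = max(0, min(c for c in cols) - 5)
    return tuple(cols), a


def default_motif_table(n_clades: int) -> dict[str, tuple[tuple, str]]:
    """All-polar/charged clade motif table for the discovery benchmark."""
    if n_clades < 1:
        raise ValueError("need at least one clade")
    table = {}
    for i in range(n_clades):
        states = tuple(pool[i % len(pool)] for pool in _POLAR_POOLS)
        table[f"clade{i + 1:02d}"] = (states, _POLAR_AUX_POOL[i % len(_POLAR_AUX_POOL)])
    return table


def reference_motif_table(
    clade_names=("NhaA", "NhaP-II K+-specific", "Kef-like", "animal-NHA-like"),
    reference: CladeReference | None = None,
) -> dict[str, tuple[tuple, str]]:
    """Clade motif table drawn from the packaged clade reference.

    The default four clades cover both families, both electrogenicity classes,
    both selectivities and the TM-3 glutamate signature.
    """
    reference = reference or load_clade_reference()
    table = {}
    for name in clade_names:
        rec = reference.get(name)
        aux = rec.aux if rec.aux != "-" else "P"
        states = tuple("A" if s == "X" else s for s in rec.consensus)
        table[name] = (states, aux)
    return table


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic family."""

    n_leaves: int = 120
    seq_length: int = 400
    gamma_alpha: float = 2.0
    n_clades: int = 4
    clade_motif_table: dict = None
    motif_columns: tuple = None       # 0-based columns in the ungapped ancestor
    aux_column: int = None
    motif_noise_eps: float = 0.0
    indel_rate: float = 0.005
    indel_mean_len: float = 3.0
    branch_length_mean: float = DEFAULT_BRANCH_LENGTH_MEAN
    seed: int = 0

    def __post_init__(self):
        if self.n_clades < 1:
            raise ValueError("n_clades must be >= 1")
        if not 0 <= self.motif_noise_eps <= 1:
            raise ValueError("motif_noise_eps must lie in [0, 1]")
        if self.clade_motif_table is None:
            object.__setattr__(self, "clade_motif_table", default_motif_table(self.n_clades))
        if self.motif_columns is None or self.aux_column is None:
            cols, aux = default_motif_columns(self.seq_length)
            object.__setattr__(self, "motif_columns", cols)
            object.__setattr__(self, "aux_column", aux)
        cols = list(self.motif_columns) + [self.aux_column]
        if len(set(cols)) != len(cols):
            raise ValueError("motif/aux columns must be pairwise distinct")
        if min(cols) < 0 or max(cols) >= self.seq_length:
            raise ValueError("motif columns must lie within seq_length")
        for clade, (states, aux) in self.clade_motif_table.items():
            if len(states) != 8:
                raise ValueError(f"clade {clade}: need 8 motif states")
            for s in tuple(states) + (aux,):
                if s not in AMINO_ACIDS:
                    raise ValueError(f"clade {clade}: invalid state {s!r}")


@dataclass
class TruthTable:
    """Ground truth for one simulated family."""

    table: pd.DataFrame      # leaf_id, clade, motif_states, aux_state, family, electrogenicity, selectivity
    motif_columns: tuple     # 0-based columns in the emitted (gapped) MSA
    aux_column: int

    def phenotypes(self, leaf_id: str) -> tuple[str, str, str]:
        row = self.table.set_index("leaf_id").loc[leaf_id]
        return row["family"], row["electrogenicity"], row["selectivity"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class FamilyData:
    ids: list
    msa_rows: list            # gapped rows, equal length
    records: list             # unaligned SequenceRecord list
    truth: TruthTable
    tree: dendropy.Tree
    params: SimulationParams


# -- tree and clades ----------------------------------------------------------------


def simulate_tree(
    n_leaves: int, seed: int, branch_length_mean: float = DEFAULT_BRANCH_LENGTH_MEAN
) -> dendropy.Tree:
    """Yule (pure-birth) topology with exponential branch lengths.

    Deterministic given ``seed``; leaves are labelled t0001..tNNNN in the
    order they were created.
    """
    if n_leaves < 2:
        raise ValueError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    tips = [tree.seed_node]
    while len(tips) < n_leaves:
        idx = int(rng.integers(len(tips)))
        node = tips.pop(idx)
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        tips.extend([left, right])
    for i, tip in enumerate(tips, start=1):
        tip.taxon = taxon_namespace.new_taxon(f"t{i:04d}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        edge.length = float(rng.exponential(branch_length_mean))
    return tree


def assign_clades(tree: dendropy.Tree, n_clades: int, seed: int) -> dict[str, str]:
    """Partition leaves into ``n_clades`` monophyletic clades.

    Starting from the root's subtree, the clade with the largest leaf count
    is preferentially (size-weighted random) replaced by its child subtrees
    until the requested number of clades exists; each clade is therefore the
    full leaf set below one node.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if n_clades > len(leaves):
        raise ValueError("cannot form more clades than leaves")
    rng = np.random.default_rng(seed)
    groups = [tree.seed_node]
    while len(groups) < n_clades:
        splittable = [n for n in groups if not n.is_leaf()]
        sizes = np.array([len(list(n.leaf_iter())) - 1 for n in splittable], dtype=float)
        pick = splittable[int(rng.choice(len(splittable), p=sizes / sizes.sum()))]
        groups.remove(pick)
        groups.extend(pick.child_nodes())
    mapping = {}
    for i, node in enumerate(groups, start=1):
        for lf in node.leaf_iter():
            mapping[lf.taxon.label] = f"clade{i:02d}"
    return mapping


# -- sequence evolution -------------------------------------------------------------


def _evolve_states(
    tree: dendropy.Tree,
    seq_length: int,
    gamma_alpha: float,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Leaf label -> integer state vector, evolved along the tree."""
    rates = rng.gamma(gamma_alpha, 1.0 / gamma_alpha, size=seq_length)
    root_states = model.sample_equilibrium(rng, seq_length)
    states = {tree.seed_node: root_states}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            parent_states = states[node]
        else:
            t = node.edge.length or 0.0
            parent_states = states[node.parent_node]
            if t > 0:
                probs = model.transition_rows(parent_states, t * rates)
                u = rng.random(seq_length)
                parent_states = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
            states[node] = parent_states
        if node.is_leaf():
            out[node.taxon.label] = states[node].copy()
    return out


def simulate_family(
    tree: dendropy.Tree,
    clades: dict[str, str],
    params: SimulationParams,
    model: SubstitutionModel | None = None,
) -> FamilyData:
    """Evolve a family along ``tree`` and plant clade motif states.

    Returns the true (gapped) MSA, the unaligned sequences, and a TruthTable
    whose phenotypes come from applying the classifier rules to each clade's
    planted consensus.  Deterministic for fixed params.
    """
    model = model or SubstitutionModel.lg()
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [clades.get(lf) for lf in leaves if lf not in clades]
    if missing or any(clades[lf] not in params.clade_motif_table for lf in leaves):
        absent = sorted({clades.get(lf, "<unassigned>") for lf in leaves
                         if clades.get(lf) not in params.clade_motif_table})
        raise ValueError(f"clade motif table lacks entries for: {absent}")
    rng = np.random.default_rng(params.seed)
    L = params.seq_length
    leaf_states = _evolve_states(tree, L, params.gamma_alpha, model, rng)

    special = list(params.motif_columns) + [params.aux_column]
    planted: dict[str, np.ndarray] = {}
    for leaf in leaves:
        states = leaf_states[leaf]
        motif_states, aux_state = params.clade_motif_table[clades[leaf]]
        for col, s in zip(params.motif_columns, motif_states):
            states[col] = AMINO_ACIDS.index(s)
        states[params.aux_column] = AMINO_ACIDS.index(aux_state)
        if params.motif_noise_eps > 0:
            for col in special:
                if rng.random() < params.motif_noise_eps:
                    current = states[col]
                    alt = int(rng.integers(19))
                    states[col] = alt if alt < current else alt + 1
        planted[leaf] = states

    # deletions (gaps in the row) and insertions (extra residues after a
    # column), both only outside motif/aux columns
    eligible = np.ones(L, dtype=bool)
    eligible[special] = False
    deleted = {leaf: np.zeros(L, dtype=bool) for leaf in leaves}
    insertions: dict[str, dict[int, str]] = {leaf: {} for leaf in leaves}
    if params.indel_rate > 0:
        p_geom = 1.0 / max(params.indel_mean_len, 1.0)
        for leaf in leaves:
            starts = np.where((rng.random(L) < params.indel_rate / 2) & eligible)[0]
            for s in starts:
                length = int(rng.geometric(p_geom))
                c = s
                while c < L and length > 0:
                    if eligible[c]:
                        deleted[leaf][c] = True
                        length -= 1
                        c += 1
                    else:
                        break  # deletions never cross a motif column
            ins_at = np.where(rng.random(L) < params.indel_rate / 2)[0]
            for pos in ins_at:
                length = int(rng.geometric(p_geom))
                residues = decode_states(model.sample_equilibrium(rng, length))
                insertions[leaf][int(pos)] = residues

    # insertion block width after each ancestor column
    widths = np.zeros(L + 1, dtype=int)  # block b goes before column b
    for leaf in leaves:
        for pos, residues in insertions[leaf].items():
            widths[pos + 1] = max(widths[pos + 1], len(residues))

    rows = []
    for leaf in leaves:
        chars = []
        states = planted[leaf]
        for c in range(L):
            if widths[c]:
                ins = insertions[leaf].get(c - 1, "")
                chars.append(ins.ljust(widths[c], "-"))
            chars.append("-" if deleted[leaf][c] else AMINO_ACIDS[states[c]])
        if widths[L]:
            chars.append(insertions[leaf].get(L - 1, "").ljust(widths[L], "-"))
        rows.append("".join(chars))

    offsets = np.cumsum(widths)  # emitted index of ancestor column c = c + offsets[c]
    emitted_motif = tuple(int(c + offsets[c]) for c in params.motif_columns)
    emitted_aux = int(params.aux_column + offsets[params.aux_column])

    truth_rows = []
    for leaf, row in zip(leaves, rows):
        motif_states, aux_state = params.clade_motif_table[clades[leaf]]
        consensus = MotifAssignment(tuple(motif_states), aux=aux_state)
        result = classify_assignment(leaf, consensus)
        observed = "".join(row[c] for c in emitted_motif)
        truth_rows.append({
            "leaf_id": leaf, "clade": clades[leaf],
            "motif_states": observed,
            "aux_state": row[emitted_aux],
            "family": result.family,
            "electrogenicity": result.electrogenicity,
            "selectivity": result.selectivity,
        })
    truth = TruthTable(pd.DataFrame(truth_rows), emitted_motif, emitted_aux)
    records = [
        SequenceRecord(leaf, row.replace("-", ""), f"synthetic {clades[leaf]}")
        for leaf, row in zip(leaves, rows)
    ]
    return FamilyData(list(leaves), rows, records, truth, tree, params)


def write_family(family: FamilyData, outdir) -> dict:
    """Write aligned/unaligned FASTA, Newick, truth TSV and a JSON manifest."""
    from pathlib import Path

    from .io_filters import write_fasta
    from .phylo import write_newick

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        [SequenceRecord(i, r) for i, r in zip(family.ids, family.msa_rows)],
        outdir / "true_msa.fasta",
    )
    write_fasta(family.records, outdir / "sequences.fasta")
    write_newick(family.tree, outdir / "tree.nwk")
    family.truth.to_tsv(outdir / "truth.tsv")
    params = asdict(family.params)
    params["clade_motif_table"] = {
        k: ["".join(v[0]), v[1]] for k, v in params["clade_motif_table"].items()
    }
    manifest = {
        "params": params,
        "n_leaves": len(family.ids),
        "msa_length": len(family.msa_rows[0]),
        "motif_columns_emitted": list(family.truth.motif_columns),
        "aux_column_emitted": family.truth.aux_column,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
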