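"""Tree-aware conservation scoring and specificity-determining-position search.

Per-column evolutionary rates are empirical-Bayes posterior means over a
discrete gamma prior: the gamma shape is chosen on a grid by maximising the
summed log-likelihood (Felsenstein pruning under the packaged LG model), then
each column's rate is the posterior mean of the category rates.  Rates are
binned into nine equal-frequency conservation grades (9 = most conserved),
highly conserved polar/charged columns become motif candidates, and a greedy
forward selection over normalised mutual information with clade labels
extracts a minimal discriminating column set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .substitution import SubstitutionModel, discrete_gamma_rates, encode_sequence

log = logging.getLogger(__name__)

CHARGED = frozenset("DEKRH")
POLAR = frozenset("STNQYCW")

DEFAULT_ALPHA_GRID = np.linspace(0.2, 5.0, 25)


# -- pruning likelihoods ------------------------------------------------------------


def _column_log_likelihoods(
    tree: dendropy.Tree,
    leaf_codes: dict[str, np.ndarray],
    rate: float,
    model: SubstitutionModel,
) -> np.ndarray:
    """log-likelihood of every column under branch lengths scaled by ``rate``.

    ``leaf_codes`` maps leaf label -> integer codes (length = n columns, -1
    for gap/unknown, treated as missing data).  Scaled pruning: partials are
    renormalised per column with the log-scale accumulated.
    """
    some = next(iter(leaf_codes.values()))
    ncols = len(some)
    pi = model.frequencies
    partial: dict = {}
    logscale: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            codes = leaf_codes[node.taxon.label]
            p = np.ones((ncols, 20))
            obs = codes >= 0
            p[obs, :] = 0.0
            p[obs, codes[obs]] = 1.0
            partial[node] = p
            logscale[node] = np.zeros(ncols)
        else:
            p = np.ones((ncols, 20))
            ls = np.zeros(ncols)
            for child in node.child_nodes():
                t = (child.edge.length or 0.0) * rate
                P = model.transition_matrix(t)
                p = p * (partial[child] @ P.T)
                ls = ls + logscale[child]
                del partial[child], logscale[child]
            scale = p.max(axis=1)
            scale[scale == 0] = 1.0
            partial[node] = p / scale[:, None]
            logscale[node] = ls + np.log(scale)
    root = tree.seed_node
    lik = partial[root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(lik, 1e-300)) + logscale[root]


def _leaf_code_map(tree: dendropy.Tree, ids: list[str], rows: list[str]) -> dict:
    row_of = {i: r for i, r in zip(ids, rows)}
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [lf for lf in leaves if lf not in row_of]
    if missing:
        raise ValueError(f"tree leaves absent from alignment: {sorted(missing)}")
    return {lf: encode_sequence(row_of[lf]) for lf in leaves}


def site_likelihood(
    tree: dendropy.Tree,
    column: dict[str, str],
    rate_multiplier: float = 1.0,
    model: SubstitutionModel | None = None,
) -> float:
    """Felsenstein-pruning likelihood of a single column.

    ``column`` maps leaf label -> residue (gaps '-'/'X' = missing data,
    uniform partial likelihood).  Branch lengths are scaled by
    ``rate_multiplier``.
    """
    model = model or SubstitutionModel.lg()
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [lf for lf in leaves if lf not in column]
    if missing:
        raise ValueError(f"column lacks leaves: {sorted(missing)}")
    codes = {lf: encode_sequence(column[lf]) for lf in leaves}
    return float(np.exp(_column_log_likelihoods(tree, codes, rate_multiplier, model))[0])


# -- empirical Bayes site rates -----------------------------------------------------


@dataclass
class ConservationProfile:
    """Per-column posterior-mean rate, grade, gap fraction, modal residue."""

    table: pd.DataFrame  # columns: column (0-based), rate, grade, gap_fraction, modal_residue, degenerate
    alpha: float = float("nan")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["column"] = out["column"] + 1  # 1-based on disk
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def site_rates(
    tree: dendropy.Tree,
    ids: list[str],
    rows: list[str],
    model: SubstitutionModel | None = None,
    n_gamma_categories: int = 8,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
) -> ConservationProfile:
    """Posterior-mean relative rate per column (dataset mean 1).

    The gamma shape alpha is chosen from ``alpha_grid`` by maximising the
    total log-likelihood with equal category priors; each column's rate is
    then sum_c r_c L_c / sum_c L_c.  All-gap columns are flagged degenerate,
    get NaN rates and are excluded from the mean-1 normalisation.
    """
    model = model or SubstitutionModel.lg()
    codes = _leaf_code_map(tree, ids, rows)
    mat = np.stack([codes[lf] for lf in codes])
    ncols = mat.shape[1]
    degenerate = (mat < 0).all(axis=0)

    best = None
    for alpha in np.asarray(alpha_grid, dtype=float):
        rates = discrete_gamma_rates(alpha, n_gamma_categories)
        col_ll = np.stack([
            _column_log_likelihoods(tree, codes, r, model) for r in rates
        ])  # (ncat, ncols)
        m = col_ll.max(axis=0)
        mix = m + np.log(np.mean(np.exp(col_ll - m[None, :]), axis=0))
        total = mix[~degenerate].sum()
        if best is None or total > best[0]:
            weights = np.exp(col_ll - m[None, :])
            post_mean = (rates[:, None] * weights).sum(axis=0) / weights.sum(axis=0)
            best = (total, float(alpha), post_mean)
    _, alpha_hat, post = best
    post = post.astype(float)
    post[degenerate] = np.nan
    valid = ~degenerate
    post[valid] = post[valid] / post[valid].mean()

    gaps = np.array([[c in "-X" or c not in "ACDEFGHIKLMNPQRSTVWY" for c in r] for r in
                     (row.upper() for row in rows)])
    gap_fraction = gaps.mean(axis=0)
    modal = []
    arr = np.array([list(r.upper()) for r in rows])
    for c in range(ncols):
        col = [ch for ch in arr[:, c] if ch in "ACDEFGHIKLMNPQRSTVWY"]
        if col:
            vals, cnts = np.unique(col, return_counts=True)
            modal.append(vals[np.argmax(cnts)])  # ties: alphabetical (np.unique is sorted)
        else:
            modal.append("-")
    table = pd.DataFrame({
        "column": np.arange(ncols),
        "rate": post,
        "gap_fraction": gap_fraction,
        "modal_residue": modal,
        "degenerate": degenerate,
    })
    if np.isfinite(post).sum() >= 9:
        table["grade"] = conservation_grades(post)
    else:  # too few columns to grade; rates still meaningful
        log.info("fewer than 9 scorable columns: grades undefined (0)")
        table["grade"] = 0
    return ConservationProfile(table[["column", "rate", "grade", "gap_fraction",
                                      "modal_residue", "degenerate"]], alpha_hat)


def conservation_grades(rates: np.ndarray) -> np.ndarray:
    """Equal-frequency 9-grade binning; grade 9 = most conserved (lowest rate).

    NaN rates receive grade 0 (undefined).  Ties resolve by column index
    (stable sort), so grading is deterministic.
    """
    rates = np.asarray(rates, dtype=float)
    finite = np.isfinite(rates)
    if finite.sum() < 9:
        raise ValueError("need at least 9 finite rates for 9-grade binning")
    grades = np.zeros(len(rates), dtype=int)
    order = np.argsort(rates[finite], kind="stable")
    idx = np.where(finite)[0][order]  # most conserved first
    for g, chunk in enumerate(np.array_split(idx, 9)):
        grades[chunk] = 9 - g
    return grades


# -- candidate filtering and association --------------------------------------------


def candidate_sdp(
    profile: ConservationProfile,
    min_grade: int = 8,
    residue_classes: frozenset = CHARGED | POLAR,
    max_gap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Candidate specificity-determining positions.

    Columns with conservation grade >= ``min_grade`` whose modal residue is
    polar or charged and whose gap fraction is <= ``max_gap_fraction``;
    hydrophobic consensus columns are excluded because in a membrane protein
    they mark packing, not transport chemistry.
    """
    t = profile.table
    keep = (
        (t["grade"] >= min_grade)
        & t["modal_residue"].isin(sorted(residue_classes))
        & (t["gap_fraction"] <= max_gap_fraction)
        & ~t["degenerate"]
    )
    out = t[keep].copy()
    out["residue_class"] = [
        "charged" if r in CHARGED else "polar" for r in out["modal_residue"]
    ]
    return out.reset_index(drop=True)


def _nmi(symbols: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in normalised mutual information I(X;Y)/H(Y)."""
    n = len(labels)
    if n == 0:
        return 0.0
    ys, yi = np.unique(labels, return_inverse=True)
    if len(ys) < 2:
        return 0.0
    xs, xi = np.unique(symbols, return_inverse=True)
    joint = np.zeros((len(xs), len(ys)))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = (joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum()
    hy = -(py[py > 0] * np.log(py[py > 0])).sum()
    return float(max(mi, 0.0) / hy) if hy > 0 else 0.0


def clade_association(
    rows: list[str], columns, labels: list[str]
) -> pd.DataFrame:
    """Normalised mutual information of each column's residues with labels.

    Gap rows are excluded per column.  A single label class yields score 0
    (with a warning): nothing can be associated with a constant.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        log.warning("constant labels: association scores are 0 by definition")
    arr = np.array([list(r.upper()) for r in rows])
    scores = []
    for c in columns:
        col = arr[:, c]
        ok = np.array([ch in "ACDEFGHIKLMNPQRSTVWY" for ch in col])
        scores.append(_nmi(col[ok], labels[ok]) if ok.any() else 0.0)
    return pd.DataFrame({"column": list(columns), "association": scores})


def discover_motif(
    candidate_columns,
    rows: list[str],
    labels: list[str],
    k_max: int = 8,
    min_gain: float = 0.0,
) -> list[int]:
    """Greedy forward selection of columns maximising joint-state NMI.

    Selection stops at ``k_max`` columns or when the best gain drops below
    ``min_gain``.  Equal gains resolve to the column with higher
    single-column association, then the smaller column index, so that once
    the joint information saturates the remaining picks are still the most
    label-associated candidates rather than arbitrary ones.
    Returns the selected columns in pick order.
    """
    candidates = list(candidate_columns)
    if not candidates:
        raise ValueError("no candidate columns to select from")
    labels = np.asarray(labels)
    arr = np.array([list(r.upper()) for r in rows])
    marginal = {
        c: s for c, s in zip(
            candidates,
            clade_association(rows, candidates, list(labels))["association"])
    }
    selected: list[int] = []
    joint = np.array([""] * len(labels), dtype=object)
    current = 0.0
    while len(selected) < min(k_max, len(candidates)):
        best = None
        for c in candidates:
            if c in selected:
                continue
            trial = joint + "|" + arr[:, c]
            score = _nmi(trial, labels)
            # quantise so float jitter around equal gains cannot outrank the
            # marginal-association tie-break
            gain = round(score - current, 9)
            key = (gain, marginal[c], -c)
            if best is None or key > best[0]:
                best = (key, c, score, trial)
        gain = best[0][0]
        if gain < min_gain - 1e-12:
            break
        _, c, current, joint = best
        selected.append(c)
    return selected
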