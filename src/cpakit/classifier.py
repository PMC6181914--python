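"""The eight-position CPA motif: extraction from profile alignments and
rule-based prediction of family, electrogenicity and ion selectivity.

The motif spans four positions on the unwound segment of TM-4 (EcNhaA
A131/T132/D133/I134), three on TM-5 ([E/-] at 159, the ND/DD pair 163/164)
and one on TM-10 (K300), plus an auxiliary TM-3 position (EcNhaA 108; a
conserved glutamate there marks the mammalian-NHA-like electroneutral CPA2s).
The decision rules:

* family    — CPA1 iff E at position 5 *and* R at position 8 (the conserved
              TM-5/TM-10 salt bridge of CPA1s); a lone half-signature or a
              gapped position 5/8 is reported as ambiguous, never guessed.
* electro-  — CPA1s are electroneutral.  Otherwise a transporter is called
  genicity    electrogenic iff it carries K at position 8 and D or E at
              position 6 (the two-proton carrier configuration).
* ion       — K-selective iff S or T at position 1 or 4; Na-selective iff
  selectivity both 1 and 4 are nonpolar; otherwise unknown.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

from .hmm import AlignmentMap, ProfileHMM, viterbi_align

ACIDIC = frozenset("DE")
NONPOLAR = frozenset("AVLIMFWPGC")
HYDROXYL = frozenset("ST")

# flags
GAPPED_MOTIF = "GAPPED_MOTIF"
MIXED_SIGNATURE = "MIXED_SIGNATURE"
POS7_NOT_ACIDIC = "POS7_NOT_ACIDIC"
NHA_LIKE_E_TM3 = "NHA_LIKE_E_TM3"
AMBIGUOUS_CLADE = "AMBIGUOUS_CLADE"
COVERAGE_FAIL = "COVERAGE_FAIL"

ECNHAA_MOTIF_RESIDUES = (131, 132, 133, 134, 159, 163, 164, 300)
ECNHAA_AUX_RESIDUE = 108
INTER_SEGMENT_SPACINGS = (23, 156)  # mean residues between segments 5->6 and 7->8


@dataclass(frozen=True)
class MotifSpec:
    """Anchors of the 8 motif positions (plus the TM-3 auxiliary position)
    as 1-based match columns of a reference profile."""

    columns: tuple          # 8 match columns, strictly increasing
    aux_column: int
    ecnhaa_residues: tuple = ECNHAA_MOTIF_RESIDUES
    aux_ecnhaa_residue: int = ECNHAA_AUX_RESIDUE
    spacing_means: tuple = INTER_SEGMENT_SPACINGS

    def __post_init__(self):
        if len(self.columns) != 8:
            raise ValueError("a motif spec must anchor exactly 8 positions")
        if list(self.columns) != sorted(set(self.columns)):
            raise ValueError("motif columns must be strictly increasing")

    @classmethod
    def ecnhaa_numbering(cls) -> "MotifSpec":
        """Spec for a profile whose match columns equal EcNhaA residue numbers."""
        return cls(ECNHAA_MOTIF_RESIDUES, ECNHAA_AUX_RESIDUE)


@dataclass(frozen=True)
class MotifAssignment:
    """Motif states observed in one query ('-' = deleted position)."""

    states: tuple           # 8 single-character states
    aux: str = "-"
    query_positions: tuple = (None,) * 8  # 1-based query residue numbers
    aux_position: int | None = None

    def __post_init__(self):
        if len(self.states) != 8:
            raise ValueError("a motif assignment carries exactly 8 states")
        for s, p in zip(self.states, self.query_positions):
            if s != "-" and p is not None and p < 1:
                raise ValueError("query positions are 1-based")

    @property
    def as_string(self) -> str:
        return "".join(self.states)

    def state(self, index: int) -> str:
        """State at motif position ``index`` (1-based, 1..8)."""
        return self.states[index - 1]


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    assignment: MotifAssignment | None
    family: str             # CPA1 | CPA2 | ambiguous
    electrogenicity: str    # electrogenic | electroneutral | unknown
    selectivity: str        # Na | K | unknown
    clade: str | None = None
    clade_margin: float | None = None
    flags: tuple = ()

    def to_row(self) -> dict:
        a = self.assignment
        row = {"query_id": self.query_id}
        for i in range(8):
            row[f"s{i + 1}"] = a.states[i] if a else "-"
        row["aux"] = a.aux if a else "-"
        row.update(family=self.family, electrogenicity=self.electrogenicity,
                   selectivity=self.selectivity,
                   clade=self.clade or "",
                   margin="" if self.clade_margin is None else f"{self.clade_margin:g}",
                   flags=";".join(self.flags))
        return row


# -- clade reference ----------------------------------------------------------------


@dataclass(frozen=True)
class CladeRecord:
    name: str
    family: str
    consensus: tuple        # 8 states; 'X' = unknown
    aux: str
    electrogenicity_annotation: str
    selectivity_annotation: str
    provenance: str
    representatives: tuple


@dataclass(frozen=True)
class CladeReference:
    """The curated 6 CPA1 + 9 CPA2 clades with consensus motif states."""

    records: tuple

    def __post_init__(self):
        names = [r.name for r in self.records]
        if len(names) != len(set(names)):
            raise ValueError("clade names must be unique")
        for r in self.records:
            if len(r.consensus) != 8:
                raise ValueError(f"clade {r.name} lacks 8 consensus states")

    def __len__(self) -> int:
        return len(self.records)

    def by_family(self, family: str) -> list[CladeRecord]:
        return [r for r in self.records if r.family == family]

    def get(self, name: str) -> CladeRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)


def load_clade_reference() -> CladeReference:
    """Load the packaged clade table (consensus motif states + phenotypes)."""
    path = resources.files("cpakit.data").joinpath("clade_reference.tsv")
    records = []
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            if not row.get("clade"):
                raise ValueError("corrupted clade reference: missing clade name")
            records.append(CladeRecord(
                name=row["clade"],
                family=row["family"],
                consensus=tuple(row[f"s{i}"] for i in range(1, 9)),
                aux=row["aux"],
                electrogenicity_annotation=row["electrogenicity_annotation"],
                selectivity_annotation=row["selectivity_annotation"],
                provenance=row["provenance"],
                representatives=tuple(r for r in row["representatives"].split(";") if r and r != "-"),
            ))
    ref = CladeReference(tuple(records))
    if len(ref.by_family("CPA1")) != 6 or len(ref.by_family("CPA2")) != 9:
        raise ValueError("clade reference integrity check failed (expect 6 CPA1 + 9 CPA2)")
    return ref


# -- extraction ---------------------------------------------------------------------


def extract_motif(
    alignment_map: AlignmentMap, query: str, spec: MotifSpec
) -> MotifAssignment:
    """Read the motif states of ``query`` off its profile alignment."""
    M = alignment_map.n_match_columns
    for col in list(spec.columns) + [spec.aux_column]:
        if not 1 <= col <= M:
            raise ValueError(f"motif column {col} outside profile range 1..{M}")
    states, positions = [], []
    for col in spec.columns:
        qi = alignment_map.query_index_of_column(col)
        if qi is None:
            states.append("-")
            positions.append(None)
        else:
            states.append(query[qi].upper())
            positions.append(qi + 1)
    aqi = alignment_map.query_index_of_column(spec.aux_column)
    return MotifAssignment(
        states=tuple(states),
        aux=query[aqi].upper() if aqi is not None else "-",
        query_positions=tuple(positions),
        aux_position=None if aqi is None else aqi + 1,
    )


# -- decision rules -----------------------------------------------------------------


def classify_family(m: MotifAssignment) -> tuple[str, tuple]:
    """CPA1 iff E5 and R8; half-signatures and gapped anchors are ambiguous."""
    s5, s8 = m.state(5), m.state(8)
    flags = []
    if "-" in m.states[4:8]:
        flags.append(GAPPED_MOTIF)
        return "ambiguous", tuple(flags)
    if s5 == "E" and s8 == "R":
        return "CPA1", tuple(flags)
    if s5 != "E" and s8 != "R":
        return "CPA2", tuple(flags)
    flags.append(MIXED_SIGNATURE)
    return "ambiguous", tuple(flags)


def classify_electrogenicity(m: MotifAssignment, family: str) -> tuple[str, tuple]:
    """CPA1 -> electroneutral; otherwise electrogenic iff K8 and D/E at 6.

    For a family-ambiguous motif the CPA2-style rule is still evaluated: the
    mammalian-NHA-like signature (D/E6 + D7 + R8 + TM-3 glutamate) is exactly
    such a case and is flagged — the TM-3 glutamate is thought to fix the
    protonation state of position 6, keeping transport electroneutral.
    """
    s6, s7, s8 = m.state(6), m.state(7), m.state(8)
    flags = []
    if s7 not in ACIDIC and s7 != "-":
        flags.append(POS7_NOT_ACIDIC)  # likely transport-deficient
    if s6 in ACIDIC and s7 == "D" and s8 == "R" and m.aux == "E":
        flags.append(NHA_LIKE_E_TM3)
    if family == "CPA1":
        return "electroneutral", tuple(flags)
    if s6 == "-" or s8 == "-":
        return "unknown", tuple(flags)
    if s8 == "K" and s6 in ACIDIC:
        return "electrogenic", tuple(flags)
    return "electroneutral", tuple(flags)


def classify_selectivity(m: MotifAssignment, family: str | None = None) -> tuple[str, tuple]:
    """K iff S/T at position 1 or 4; Na iff both 1 and 4 nonpolar."""
    s1, s4 = m.state(1), m.state(4)
    if s1 == "-" and s4 == "-":
        return "unknown", (GAPPED_MOTIF,)
    if s1 in HYDROXYL or s4 in HYDROXYL:
        return "K", ()
    if s1 in NONPOLAR and s4 in NONPOLAR:
        return "Na", ()
    return "unknown", ()


def assign_clade(
    m: MotifAssignment, reference: CladeReference
) -> tuple[str, float, tuple]:
    """Nearest reference clade by Hamming distance of the 8 motif states.

    'X' consensus states (unknowns) match anything.  Returns (clade, margin,
    flags); margin = second-best distance minus best distance.  Exact ties
    resolve to the lexicographically first clade name and are flagged.
    """
    if not reference.records:
        raise ValueError("no reference clades loaded")
    scored = []
    for rec in reference.records:
        dist = sum(
            1 for s, c in zip(m.states, rec.consensus)
            if c != "X" and s != c
        )
        scored.append((dist, rec.name))
    scored.sort()
    best_dist, best_name = scored[0]
    flags = []
    margin = (scored[1][0] - best_dist) if len(scored) > 1 else float("inf")
    if len(scored) > 1 and scored[1][0] == best_dist:
        flags.append(AMBIGUOUS_CLADE)
    return best_name, float(margin), tuple(flags)


def classify_assignment(
    query_id: str,
    m: MotifAssignment,
    reference: CladeReference | None = None,
) -> ClassificationResult:
    """Apply the full rule cascade to an already-extracted motif."""
    family, f_flags = classify_family(m)
    electro, e_flags = classify_electrogenicity(m, family)
    select, s_flags = classify_selectivity(m, family)
    clade = margin = None
    c_flags: tuple = ()
    if reference is not None:
        clade, margin, c_flags = assign_clade(m, reference)
    flags = tuple(dict.fromkeys(f_flags + e_flags + s_flags + c_flags))
    return ClassificationResult(query_id, m, family, electro, select,
                                clade, margin, flags)


def classify(
    query_id: str,
    query: str,
    hmm: ProfileHMM,
    spec: MotifSpec,
    reference: CladeReference | None = None,
    min_coverage: float = 0.70,
    essential_columns=None,
) -> ClassificationResult:
    """Align a raw sequence to the reference profile and classify it.

    Queries whose alignment covers fewer than ``min_coverage`` of the
    essential columns (default: the motif anchors), or that delete the
    position-7 anchor, are reported ambiguous with a COVERAGE_FAIL flag.
    """
    amap, _score = viterbi_align(hmm, query)
    essential = list(essential_columns) if essential_columns is not None else \
        list(spec.columns) + [spec.aux_column]
    aligned = sum(1 for c in essential if amap.query_index_of_column(c) is not None)
    anchor_ok = amap.query_index_of_column(spec.columns[6]) is not None
    if aligned / len(essential) < min_coverage or not anchor_ok:
        return ClassificationResult(query_id, None, "ambiguous", "unknown",
                                    "unknown", flags=(COVERAGE_FAIL,))
    m = extract_motif(amap, query, spec)
    return classify_assignment(query_id, m, reference)
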