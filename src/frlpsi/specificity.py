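"""Classification of paralog-group-specific alignment columns.

A column is FRL-specific when the residues observed in the far-red-light
paralogs are conserved and disjoint from those in the visible-light
isoforms — the signature of a substitution fixed at the birth of the FRL
paralog.  The rule is explicit and configurable: per-group gap tolerance,
a noise frequency below which rare residues are ignored, a dominance
threshold for the FRL consensus, and optional conservative-substitution
classes ({ILVM}, {FYW}, {ST}, {DE}, {KR}, {NQ}) so that columns such as a
Val/Ile mixture facing a conserved VL Thr still count as FRL-specific.

Frequencies use raw sequence counts (no phylogenetic down-weighting), so
duplicated sequences change the verdict; this keeps the rule auditable
against a by-eye alignment reading.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .asr import AncestralReconstruction
from .seqio import GAP, UNKNOWN, GroupedAlignment

SIMILARITY_CLASSES = (
    frozenset("ILVM"),
    frozenset("FYW"),
    frozenset("ST"),
    frozenset("DE"),
    frozenset("KR"),
    frozenset("NQ"),
)


class ColumnStatus(str, Enum):
    GROUP_SPECIFIC = "GROUP_SPECIFIC"
    SHARED_CONSERVED = "SHARED_CONSERVED"
    VARIABLE = "VARIABLE"
    GAP_DOMINATED = "GAP_DOMINATED"


@dataclass(frozen=True)
class SpecificityRule:
    """Thresholds defining "conserved in FRL but not VL"."""

    min_frl_dominance: float = 0.90
    max_noise_freq: float = 0.05
    max_gap_fraction: float = 0.50
    allow_similarity_class: bool = True

    def __post_init__(self) -> None:
        for name in ("min_frl_dominance", "max_noise_freq", "max_gap_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class ColumnClassification:
    column: int  # 1-based
    status: ColumnStatus
    frl_residues: Counter
    vl_residues: Counter
    frl_filtered: frozenset  # FRL residue set after noise filtering
    vl_filtered: frozenset
    frl_consensus: str | None
    ancestral_state: str | None = None
    ancestral_conserved: bool | None = None  # None = not evaluated


def _column_stats(residues: list[str]) -> tuple[Counter, float]:
    """Residue counts (X excluded as uninformative) and gap fraction."""
    n = len(residues)
    gaps = sum(1 for r in residues if r == GAP)
    counts = Counter(r for r in residues if r not in (GAP, UNKNOWN))
    return counts, (gaps / n if n else 1.0)


def _filtered_set(counts: Counter, max_noise_freq: float) -> frozenset:
    total = sum(counts.values())
    if total == 0:
        return frozenset()
    return frozenset(r for r, c in counts.items() if c / total > max_noise_freq)


def _consensus(counts: Counter) -> str | None:
    if not counts:
        return None
    top = max(counts.values())
    return min(r for r, c in counts.items() if c == top)  # ties alphabetical


def classify_column(
    col: int, frl: list[str], vl: list[str], rule: SpecificityRule
) -> ColumnClassification:
    frl_counts, frl_gap = _column_stats(frl)
    vl_counts, vl_gap = _column_stats(vl)
    frl_set = _filtered_set(frl_counts, rule.max_noise_freq)
    vl_set = _filtered_set(vl_counts, rule.max_noise_freq)
    consensus = _consensus(frl_counts)

    def make(status: ColumnStatus) -> ColumnClassification:
        return ColumnClassification(
            column=col,
            status=status,
            frl_residues=frl_counts,
            vl_residues=vl_counts,
            frl_filtered=frl_set,
            vl_filtered=vl_set,
            frl_consensus=consensus,
        )

    if frl_gap > rule.max_gap_fraction or vl_gap > rule.max_gap_fraction:
        return make(ColumnStatus.GAP_DOMINATED)
    if frl_set and not (frl_set & vl_set):
        # disjoint after noise filtering; now require FRL conservation
        frl_total = sum(frl_counts.values())
        if len(frl_set) == 1:
            (res,) = frl_set
            if frl_counts[res] / frl_total >= rule.min_frl_dominance:
                return make(ColumnStatus.GROUP_SPECIFIC)
        elif rule.allow_similarity_class:
            for cls in SIMILARITY_CLASSES:
                if frl_set <= cls:
                    freq = sum(frl_counts[r] for r in frl_set) / frl_total
                    if freq >= rule.min_frl_dominance:
                        return make(ColumnStatus.GROUP_SPECIFIC)
        return make(ColumnStatus.VARIABLE)
    # not disjoint: shared conservation if one residue dominates both groups
    frl_total = sum(frl_counts.values())
    vl_total = sum(vl_counts.values())
    if consensus is not None and frl_total and vl_total:
        if (
            frl_counts[consensus] / frl_total >= rule.min_frl_dominance
            and vl_counts[consensus] / vl_total >= rule.min_frl_dominance
        ):
            return make(ColumnStatus.SHARED_CONSERVED)
    return make(ColumnStatus.VARIABLE)


def classify_columns(
    aln: GroupedAlignment, rule: SpecificityRule | None = None
) -> list[ColumnClassification]:
    """One classification per alignment column (outgroup rows ignored)."""
    rule = rule or SpecificityRule()
    aln.require_groups()
    frl_ids = set(aln.group_members("FRL"))
    vl_ids = set(aln.group_members("VL"))
    out = []
    for col in range(1, aln.n_columns + 1):
        residues = aln.column(col)
        frl = [r for sid, r in residues if sid in frl_ids]
        vl = [r for sid, r in residues if sid in vl_ids]
        out.append(classify_column(col, frl, vl, rule))
    return out


def score_ancestral_conservation(
    cols: list[ColumnClassification],
    anc: AncestralReconstruction,
    colmap: dict[int, int] | None = None,
) -> tuple[int, int, float | None]:
    """Score how many group-specific columns the ancestor retains.

    *colmap* maps 1-based alignment columns to 1-based sites of the
    reconstructed sequence; columns absent from the map (insertions relative
    to the ancestor) count as specific but not ancestral-conserved.  When
    *colmap* is None the reconstruction is assumed to cover the alignment
    column-for-column.

    Returns (n_specific, n_conserved, fraction); the fraction is None when
    no column is group-specific.  Each column's ``ancestral_state`` and
    ``ancestral_conserved`` fields are filled in place.
    """
    n_specific = 0
    n_conserved = 0
    for c in cols:
        if c.status is not ColumnStatus.GROUP_SPECIFIC:
            continue
        n_specific += 1
        site = colmap.get(c.column) if colmap is not None else c.column
        if site is None or not 1 <= site <= anc.site_count:
            c.ancestral_conserved = False
            continue
        state = anc.map_sequence[site - 1]
        c.ancestral_state = state
        c.ancestral_conserved = state in c.frl_filtered
        if c.ancestral_conserved:
            n_conserved += 1
    fraction = n_conserved / n_specific if n_specific else None
    return n_specific, n_conserved, fraction


def per_subunit_summary(
    classified: dict[str, tuple[GroupedAlignment, list[ColumnClassification]]]
) -> list[dict]:
    """Summarise specific-residue burden per subunit alignment.

    The denominator is the ungapped length of the FRL consensus sequence
    (columns where the FRL group is not gap-dominated), mirroring a
    per-subunit "fraction of the protein that is FRL-specific".  Sorted by
    percent descending.
    """
    rows = []
    for subunit, (aln, cols) in classified.items():
        frl_ids = set(aln.group_members("FRL"))
        length = 0
        for col in range(1, aln.n_columns + 1):
            frl = [r for sid, r in aln.column(col) if sid in frl_ids]
            gaps = sum(1 for r in frl if r == GAP)
            if frl and gaps / len(frl) <= 0.5:
                length += 1
        n_specific = sum(1 for c in cols if c.status is ColumnStatus.GROUP_SPECIFIC)
        rows.append(
            {
                "subunit": subunit,
                "n_specific": n_specific,
                "sequence_length": length,
                "percent_specific": 100.0 * n_specific / length if length else 0.0,
            }
        )
    rows.sort(key=lambda r: -r["percent_specific"])
    return rows


def write_classification_tsv(
    classified: dict[str, list[ColumnClassification]], path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "subunit\tcolumn\tstatus\tfrl_set\tvl_set\tancestral_state\tancestral_conserved\n"
        )
        for subunit, cols in classified.items():
            for c in cols:
                fh.write(
                    "\t".join(
                        [
                            subunit,
                            str(c.column),
                            c.status.value,
                            "".join(sorted(c.frl_filtered)) or ".",
                            "".join(sorted(c.vl_filtered)) or ".",
                            c.ancestral_state or ".",
                            {True: "yes", False: "no", None: "."}[c.ancestral_conserved],
                        ]
                    )
                    + "\n"
                )
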