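"""Alignment, group-label, and tree I/O plus sequence-set curation.

Photosystem I subunit alignments mix far-red-light (FRL) paralogs such as
PsaB2 with their visible-light (VL) isoforms and, where available, outgroup
sequences.  This module reads such alignments together with a per-sequence
group-label table, curates raw sequence sets (fragment removal, greedy
redundancy reduction to an identity threshold), computes pairwise identities,
and maps alignment columns to ungapped sequence positions.

Conventions: alignment columns are 1-based; sequence positions are 1-based
and ungapped; residues are read case-insensitively; ``X`` is an unknown
residue that never counts as identical to anything.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GROUPS = ("FRL", "VL", "OUTGROUP")
GAP = "-"
UNKNOWN = "X"

_VALID_CHARS = set("ACDEFGHIKLMNPQRSTVWY" + GAP + UNKNOWN)


class SeqIOError(ValueError):
    """Raised for malformed alignments, labels, or trees."""


@dataclass
class GroupedAlignment:
    """An alignment whose rows carry FRL / VL / OUTGROUP group labels."""

    records: list[tuple[str, str]]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise SeqIOError("alignment has no sequences")
        n = len(self.records[0][1])
        for sid, seq in self.records:
            if len(seq) != n:
                raise SeqIOError(
                    f"unequal lengths: record '{sid}' has {len(seq)} columns, "
                    f"expected {n}"
                )
            bad = set(seq.upper()) - _VALID_CHARS
            if bad:
                raise SeqIOError(
                    f"record '{sid}' contains invalid characters: {sorted(bad)}"
                )
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqIOError(f"duplicate sequence ids: {dupes}")
        missing = [sid for sid in ids if sid not in self.group_of]
        if missing:
            raise SeqIOError(f"unlabeled sequence ids: {missing}")
        for sid in ids:
            g = self.group_of[sid]
            if g not in GROUPS:
                raise SeqIOError(f"unknown group '{g}' for '{sid}'")
        # normalise case once
        self.records = [(sid, seq.upper()) for sid, seq in self.records]

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def sequence_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def sequence(self, sid: str) -> str:
        for s, seq in self.records:
            if s == sid:
                return seq
        raise KeyError(sid)

    def group_members(self, group: str) -> list[str]:
        return [sid for sid, _ in self.records if self.group_of[sid] == group]

    def column(self, col: int) -> list[tuple[str, str]]:
        """Residues of 1-based column *col* as (sequence_id, residue)."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(col)
        return [(sid, seq[col - 1]) for sid, seq in self.records]

    def require_groups(self) -> None:
        if not self.group_members("FRL") or not self.group_members("VL"):
            raise SeqIOError(
                "classification requires at least one FRL and one VL sequence"
            )


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-separated ``sequence_id<TAB>group`` table.

    Lines starting with ``#`` and blank lines are ignored.
    """
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SeqIOError(f"{path}:{lineno}: expected 'id<TAB>group'")
        sid, group = parts[0].strip(), parts[1].strip().upper()
        if group not in GROUPS:
            raise SeqIOError(f"{path}:{lineno}: unknown group '{group}'")
        labels[sid] = group
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, group in labels.items():
            fh.write(f"{sid}\t{group}\n")


def read_alignment(path: str | Path, labels: str | Path | Mapping[str, str]) -> GroupedAlignment:
    """Read an aligned FASTA plus its group-label table."""
    if isinstance(labels, (str, Path)):
        labels = read_labels(labels)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise SeqIOError(f"no sequences in {path}")
    return GroupedAlignment(records=records, group_of=dict(labels))


def write_alignment(aln: GroupedAlignment, path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Plain (possibly unaligned) FASTA as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs),
        str(path),
        "fasta",
    )


# --- trees -----------------------------------------------------------------


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise SeqIOError(f"negative branch length {edge.length}")
    return tree


def check_tree_matches_alignment(tree: dendropy.Tree, aln: GroupedAlignment) -> None:
    leaf_names = {leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()}
    seq_ids = set(aln.sequence_ids)
    missing = sorted(leaf_names ^ seq_ids)
    if missing:
        raise SeqIOError(f"tree/alignment name mismatch: {missing}")


# --- identity and redundancy ----------------------------------------------


def _ungapped(seq: str) -> str:
    return seq.replace(GAP, "")


def pairwise_identity(
    a: str, b: str, mode: str = "aligned_columns"
) -> tuple[int, int, float]:
    """Count identical residues between two sequences.

    ``aligned_columns``: *a* and *b* are rows of the same alignment; identity
    is counted over columns where neither has a gap.  ``shorter_length``: the
    sequences are globally aligned first and the identical-residue count is
    normalized by the shorter ungapped length.  ``X`` never matches.
    """
    a, b = a.upper(), b.upper()
    if mode == "aligned_columns":
        if len(a) != len(b):
            raise SeqIOError("aligned_columns mode requires equal lengths")
        pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
        n_compared = len(pairs)
        n_identical = sum(1 for x, y in pairs if x == y and x != UNKNOWN)
    elif mode == "shorter_length":
        ua, ub = _ungapped(a), _ungapped(b)
        n_compared = min(len(ua), len(ub))
        # canonical argument order: co-optimal alignments can differ in
        # match count, and this keeps identity(a, b) == identity(b, a)
        n_identical = _global_alignment_matches(*sorted((ua, ub)))
    else:
        raise ValueError(f"unknown mode '{mode}'")
    if n_compared == 0:
        raise SeqIOError("identity fraction undefined: no compared positions")
    return n_identical, n_compared, n_identical / n_compared


def _make_aligner() -> Align.PairwiseAligner:
    # match +1, mismatch 0, linear gap -1: a simple, reproducible scheme
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def _global_alignment_matches(a: str, b: str) -> int:
    if not a or not b:
        return 0
    aligner = _make_aligner()
    alignment = aligner.align(a, b)[0]
    n = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        n += sum(
            1
            for x, y in zip(a[a0:a1], b[b0:b1])
            if x == y and x != UNKNOWN
        )
    return n


def remove_fragments(
    seqs: Sequence[tuple[str, str]], min_length_fraction: float = 0.70
) -> list[tuple[str, str]]:
    """Drop sequences shorter than a fraction of the median ungapped length."""
    if not seqs:
        return []
    lengths = [len(_ungapped(s)) for _, s in seqs]
    cutoff = min_length_fraction * statistics.median(lengths)
    return [(sid, s) for (sid, s), n in zip(seqs, lengths) if n >= cutoff]


def reduce_redundancy(
    seqs: Sequence[tuple[str, str]], threshold: float = 0.98
) -> list[tuple[str, str]]:
    """Greedy redundancy reduction to an identity *threshold*.

    Sequences are visited longest first (ties broken by id); a sequence is
    retained iff its global-alignment identity to every previously retained
    sequence is below the threshold.  Output preserves the kept order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(seqs, key=lambda r: (-len(_ungapped(r[1])), r[0]))
    kept: list[tuple[str, str]] = []
    for sid, seq in order:
        redundant = False
        for _, kseq in kept:
            _, _, frac = pairwise_identity(seq, kseq, mode="shorter_length")
            if frac >= threshold:
                redundant = True
                break
        if not redundant:
            kept.append((sid, seq))
    return kept


# --- column maps ------------------------------------------------------------


def column_map(aln: GroupedAlignment, sid: str) -> dict[int, int]:
    """Map 1-based alignment columns to 1-based ungapped positions of *sid*.

    Columns where the sequence has a gap are absent from the map.
    """
    seq = aln.sequence(sid)
    out: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(seq, 1):
        if ch != GAP:
            pos += 1
            out[col] = pos
    return out
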