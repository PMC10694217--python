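"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions of a far-red-light photosystem I
comparison without any external data: grouped alignments with planted
group-specific columns, sequences simulated down known trees under a known
substitution model (so true ancestral states are available), and pairs of
synthetic cofactor coordinate sets with a known in-plane rotation about a
chosen tetrapyrrole ring.

All generators are deterministic under a fixed seed.  The cofactor template
is an idealized planar chlorin built from simple polar geometry with
chemical-component-dictionary-style atom names (NA-ND pyrrole nitrogens,
ring E with the OBD keto oxygen); it reproduces the topology needed by the
geometry stage, not real chlorophyll bond lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import asr
from ._lg_data import AMINO_ACIDS, LG_FREQUENCIES
from .seqio import GroupedAlignment
from .structio import Atom, Chain, Cofactor, Residue, StructureModel


# --- grouped alignments with planted specific columns -----------------------


@dataclass
class AlignmentSpec:
    """Study conditions for a planted-column alignment.

    Defaults are the calibration conditions used throughout: 30+30
    sequences, 200 columns, 10 planted group-specific columns, i.i.d.
    background drawn from LG equilibrium frequencies shared across groups.
    """

    seed: int = 0
    n_frl: int = 30
    n_vl: int = 30
    n_columns: int = 200
    n_planted_specific: int = 10
    background_frequencies: np.ndarray = field(
        default_factory=lambda: np.array(LG_FREQUENCIES)
    )
    #: fraction of planted columns using a two-residue similarity-class pair
    #: (e.g. Val/Ile vs a conserved VL Thr) instead of a single residue
    class_pair_fraction: float = 0.3


#: (class pair, disjoint VL residue) motifs for class-planted columns,
#: modelled on observed substitutions such as Val/Ile-666 facing a VL Thr
_CLASS_MOTIFS = [(("V", "I"), "T"), (("S", "T"), "G"), (("F", "Y"), "L")]


def generate_grouped_alignment(
    spec: AlignmentSpec,
) -> tuple[GroupedAlignment, list[dict]]:
    """Planted alignment plus its truth table.

    Background columns are i.i.d. from the background frequencies, shared
    across groups; planted columns are group-disjoint by construction and
    satisfy the default specificity rule.  The truth table lists each
    planted column with its FRL residues and VL residue.
    """
    if spec.n_planted_specific > spec.n_columns:
        raise ValueError("cannot plant more specific columns than columns")
    rng = np.random.default_rng(spec.seed)
    freqs = spec.background_frequencies / spec.background_frequencies.sum()
    n_seqs = spec.n_frl + spec.n_vl
    cols = rng.choice(
        len(AMINO_ACIDS), size=(spec.n_columns, n_seqs), p=freqs
    )
    planted_cols = sorted(
        rng.choice(spec.n_columns, size=spec.n_planted_specific, replace=False) + 1
    )
    truth = []
    aa = AMINO_ACIDS
    for col in planted_cols:
        if rng.random() < spec.class_pair_fraction:
            pair, vl_res = _CLASS_MOTIFS[rng.integers(len(_CLASS_MOTIFS))]
            frl_states = rng.choice([aa.index(p) for p in pair], size=spec.n_frl)
            frl_set = set(pair)
        else:
            i, j = rng.choice(len(aa), size=2, replace=False)
            frl_states = np.full(spec.n_frl, i)
            vl_res = aa[j]
            frl_set = {aa[i]}
        cols[col - 1, : spec.n_frl] = frl_states
        cols[col - 1, spec.n_frl :] = aa.index(vl_res)
        truth.append({"column": int(col), "frl_residues": frl_set, "vl_residue": vl_res})
    records = []
    group_of = {}
    for k in range(n_seqs):
        sid = f"frl_{k:02d}" if k < spec.n_frl else f"vl_{k - spec.n_frl:02d}"
        group_of[sid] = "FRL" if k < spec.n_frl else "VL"
        records.append((sid, "".join(aa[i] for i in cols[:, k])))
    return GroupedAlignment(records=records, group_of=group_of), truth


# --- trees and simulated sequences ------------------------------------------


@dataclass
class TreeSpec:
    seed: int = 0
    n_leaves: int = 12
    topology: str = "random"  # or "balanced" or "shallow"
    min_branch_length: float = 0.05
    max_branch_length: float = 0.30
    leaf_prefix: str = "t"


def generate_tree(spec: TreeSpec) -> dendropy.Tree:
    """A rooted binary tree with uniform random branch lengths."""
    rng = np.random.default_rng(spec.seed)
    taxa = dendropy.TaxonNamespace(
        [f"{spec.leaf_prefix}{i:02d}" for i in range(spec.n_leaves)]
    )
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for tax in taxa:
        node = dendropy.Node(taxon=tax)
        nodes.append(node)
    if spec.topology == "balanced":
        # pair adjacent nodes level by level; an odd node is carried up
        while len(nodes) > 1:
            nxt = [
                _join(nodes[i], nodes[i + 1])
                for i in range(0, len(nodes) - 1, 2)
            ]
            if len(nodes) % 2:
                nxt.append(nodes[-1])
            nodes = nxt
    elif spec.topology == "shallow":
        # an early radiation: three-leaf clades hanging directly off the
        # root, which keeps every leaf informative about the root state
        clades = []
        for i in range(0, len(nodes), 3):
            group = nodes[i : i + 3]
            while len(group) > 1:
                group = [_join(group[0], group[1])] + group[2:]
            clades.append(group[0])
        root = dendropy.Node()
        for c in clades:
            root.add_child(c)
        nodes = [root]
    elif spec.topology == "random":
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            nodes = (
                [n for k, n in enumerate(nodes) if k not in (i, j)]
                + [_join(nodes[i], nodes[j])]
            )
    else:
        raise ValueError(f"unknown topology '{spec.topology}'")
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(
                rng.uniform(spec.min_branch_length, spec.max_branch_length)
            )
    asr.name_internal_nodes(tree)
    return tree


def _join(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
    parent = dendropy.Node()
    parent.add_child(a)
    parent.add_child(b)
    return parent


def generate_tree_and_sequences(
    spec: TreeSpec,
    model: asr.SubstitutionModel | None = None,
    n_sites: int = 300,
) -> tuple[dendropy.Tree, GroupedAlignment, dict[str, str]]:
    """Tree, leaf alignment (all labelled FRL), and true node sequences."""
    model = model or asr.lg_model()
    tree = generate_tree(spec)
    seqs = asr.simulate_evolution(tree, model, n_sites, seed=spec.seed + 1)
    leaf_names = [
        leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()
    ]
    records = [(name, seqs[name]) for name in sorted(leaf_names)]
    aln = GroupedAlignment(records=records, group_of={n: "FRL" for n in leaf_names})
    return tree, aln, seqs


# --- the planted two-group case study ---------------------------------------


@dataclass
class CaseStudySpec:
    """A two-clade tree (FRL paralogs vs VL isoforms) with planted columns.

    ``n_conserved_planted`` columns are fixed across the whole FRL clade and
    therefore retained by the ancestor; ``n_nonconserved_planted`` columns
    place the derived residue in all FRL leaves except one basal lineage
    that sits on a very short branch off the FRL ancestor and keeps the
    ancestral residue — the classifier filters the basal residue as noise
    (it is one leaf among many) while the reconstruction correctly assigns
    the ancestor the basal state, mirroring how a late-fixed substitution
    is group-specific today yet absent from the group's ancestor.
    """

    seed: int = 0
    n_frl: int = 30
    n_vl: int = 30
    n_columns: int = 200
    n_conserved_planted: int = 7
    n_nonconserved_planted: int = 3
    basal_branch: float = 0.01
    derived_stem: float = 1.0


def generate_case_study(
    spec: CaseStudySpec, model: asr.SubstitutionModel | None = None
) -> tuple[dendropy.Tree, GroupedAlignment, list[dict]]:
    """Returns (tree, grouped alignment, truth table).

    Truth rows: {column, frl_residue, vl_residue, ancestral_conserved}.
    """
    if spec.n_frl < 6 or spec.n_vl < 2:
        raise ValueError("need at least 6 FRL and 2 VL leaves")
    n_planted = spec.n_conserved_planted + spec.n_nonconserved_planted
    if n_planted > spec.n_columns:
        raise ValueError("cannot plant more columns than exist")
    model = model or asr.lg_model()
    rng = np.random.default_rng(spec.seed)

    frl_names = [f"frl_{i:02d}" for i in range(spec.n_frl)]
    vl_names = [f"vl_{i:02d}" for i in range(spec.n_vl)]
    taxa = dendropy.TaxonNamespace(frl_names + vl_names)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def leaf(name):
        return dendropy.Node(taxon=taxa.get_taxon(name))

    def random_clade(names, lo=0.05, hi=0.3):
        nodes = [leaf(n) for n in names]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [
                _join(nodes[i], nodes[j])
            ]
        for node in _subtree_iter(nodes[0]):
            if node is not nodes[0]:
                node.edge.length = float(rng.uniform(lo, hi))
        return nodes[0]

    basal = leaf(frl_names[0])
    derived = random_clade(frl_names[1:])
    frl_mrca = _join(basal, derived)
    basal.edge.length = spec.basal_branch
    derived.edge.length = spec.derived_stem
    vl_clade = random_clade(vl_names)
    root = _join(frl_mrca, vl_clade)
    frl_mrca.edge.length = 0.5
    vl_clade.edge.length = 0.5
    tree.seed_node = root
    tree.is_rooted = True
    asr.name_internal_nodes(tree)
    frl_mrca.label = "frl_ancestor"

    seqs = asr.simulate_evolution(tree, model, spec.n_columns, seed=spec.seed + 1)
    seq_arrays = {name: list(seqs[name]) for name in frl_names + vl_names}

    planted_cols = sorted(
        rng.choice(spec.n_columns, size=n_planted, replace=False) + 1
    )
    conserved_cols = planted_cols[: spec.n_conserved_planted]
    truth = []
    aa = AMINO_ACIDS
    for col in planted_cols:
        r, v, g = [aa[i] for i in rng.choice(len(aa), size=3, replace=False)]
        conserved = col in conserved_cols
        for name in frl_names:
            seq_arrays[name][col - 1] = r
        if not conserved:
            # the basal lineage keeps the ancestral residue g; one leaf out
            # of n_frl stays below the noise threshold of the classifier
            seq_arrays[frl_names[0]][col - 1] = g
        for name in vl_names:
            seq_arrays[name][col - 1] = v
        truth.append(
            {
                "column": int(col),
                "frl_residue": r,
                "vl_residue": v,
                "ancestral_conserved": conserved,
            }
        )
    # Shared ancestry can fix a background column in one clade and not the
    # other, which is indistinguishable from a planted column; break the
    # disjointness of any such column so the truth table is exact.
    from .specificity import ColumnStatus, SpecificityRule, classify_column

    rule = SpecificityRule()
    planted_set = set(planted_cols)
    for col in range(1, spec.n_columns + 1):
        if col in planted_set:
            continue
        frl = [seq_arrays[n][col - 1] for n in frl_names]
        vl = [seq_arrays[n][col - 1] for n in vl_names]
        verdict = classify_column(col, frl, vl, rule)
        if verdict.status is ColumnStatus.GROUP_SPECIFIC:
            shared = verdict.frl_consensus
            for name in vl_names[:2]:
                seq_arrays[name][col - 1] = shared
    records = [(n, "".join(seq_arrays[n])) for n in frl_names + vl_names]
    group_of = {n: "FRL" for n in frl_names} | {n: "VL" for n in vl_names}
    return tree, GroupedAlignment(records=records, group_of=group_of), truth


def _subtree_iter(node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.child_nodes())


def generate_site_call_bundle(
    seed: int = 0,
) -> tuple[dict, list, dict[str, str]]:
    """A planted case study wired to the eight chlorophyll-site configs.

    Builds a large planted alignment (one synthetic "subunit"), assigns its
    planted columns to site-supporting roles mirroring the support structure
    of the real complex — B7 with two tyrosine-like H-bond donors plus seven
    stabilizers, B37 with three donors plus five stabilizers, B30 with three
    donors plus three stabilizers, the A0B rotation with its three helix
    residues, B38 with a cavity residue the ancestor does not retain, A21
    with a loop donor and mostly non-conserved stabilizers, and A23/B19
    supported by columns that are not group-specific at all — and returns
    (inputs, site configs, expected ancestral calls).

    inputs = {"tree", "alignment", "truth"}; expected calls follow from the
    call rule applied to the planted conservation pattern: the rotation and
    sites B7/B37/B30 ancestral, B38/A21/A23/B19 not.
    """
    from .sites import SiteConfig, SupportingResidue

    spec = CaseStudySpec(
        seed=seed,
        n_columns=300,
        n_conserved_planted=27,
        n_nonconserved_planted=4,
    )
    tree, aln, truth = generate_case_study(spec)
    conserved = [t["column"] for t in truth if t["ancestral_conserved"]]
    nonconserved = [t["column"] for t in truth if not t["ancestral_conserved"]]
    planted = {t["column"] for t in truth}
    background = [c for c in range(1, spec.n_columns + 1) if c not in planted]
    sub = "synthetic_subunit"

    def take(pool, n, role):
        out = [SupportingResidue(sub, pool.pop(0), role) for _ in range(n)]
        return out

    configs = [
        SiteConfig("A0B_rotation", take(conserved, 3, "hbond_donor")),
        SiteConfig("B7", take(conserved, 2, "hbond_donor") + take(conserved, 7, "stabilizer")),
        SiteConfig("B37", take(conserved, 3, "hbond_donor") + take(conserved, 5, "stabilizer")),
        SiteConfig("B38", take(nonconserved, 1, "cavity")),
        SiteConfig("B30", take(conserved, 3, "hbond_donor") + take(conserved, 3, "stabilizer")),
        SiteConfig(
            "A21",
            take(nonconserved, 1, "hbond_donor")
            + take(nonconserved, 2, "stabilizer")
            + take(conserved, 1, "stabilizer"),
        ),
        SiteConfig("A23", [SupportingResidue(sub, background[0], "hbond_donor")]),
        SiteConfig("B19", [SupportingResidue(sub, background[1], "hbond_donor")]),
    ]
    expected = {
        "A0B_rotation": "Y",
        "B7": "Y",
        "B37": "Y",
        "B38": "N",
        "B30": "Y",
        "A21": "N",
        "A23": "N",
        "B19": "N",
    }
    inputs = {"tree": tree, "alignment": aln, "truth": truth, "subunit": sub}
    return inputs, configs, expected


# --- synthetic cofactor geometry --------------------------------------------


def chlorin_template(chain: str = "X", number: int = 901) -> Cofactor:
    """Idealized planar chlorin in the xy-plane, centred at the origin.

    Four pyrrole rings A-D (each a pentagon carrying its nitrogen NA-ND)
    around a central MG, methine bridges CHA-CHD, and the isocyclic ring E
    fused to ring C, carrying the keto oxygen OBD.
    """
    atoms = [Atom("MG", "MG", np.zeros(3))]
    ring_angles = {"A": 45.0, "B": 135.0, "C": 225.0, "D": 315.0}

    def polar(radius, angle_deg):
        a = math.radians(angle_deg)
        return np.array([radius * math.cos(a), radius * math.sin(a), 0.0])

    for ring, ang in ring_angles.items():
        n_pos = polar(2.05, ang)
        atoms.append(Atom(f"N{ring}", "N", n_pos))
        centroid = polar(3.1, ang)
        # pentagon of ring carbons around the ring centroid; the nitrogen
        # occupies the inward vertex, carbons fill the remaining four
        for k, name in enumerate((f"C1{ring}", f"C2{ring}", f"C3{ring}", f"C4{ring}")):
            vertex = ang + 180.0 + 72.0 * (k + 1)  # skip the N vertex
            atoms.append(Atom(name, "C", centroid + polar(1.2, vertex)))
    for name, ang in (("CHA", 0.0), ("CHB", 90.0), ("CHC", 180.0), ("CHD", 270.0)):
        atoms.append(Atom(name, "C", polar(3.6, ang)))
    # ring E: fused outside ring C toward the CHD methine
    out_dir = polar(1.0, 247.5)
    by_name = {a.name: a for a in atoms}
    cad = by_name["C3C"].xyz + 1.45 * out_dir
    cbd = by_name["CHD"].xyz + 1.45 * out_dir
    atoms.append(Atom("CAD", "C", cad))
    atoms.append(Atom("CBD", "C", cbd))
    atoms.append(Atom("OBD", "O", cad + 1.25 * polar(1.0, 225.0)))
    return Cofactor("CLA", chain, number, atoms)


def _backbone_shell(
    chain_id: str = "X", n_residues: int = 20, radius: float = 9.5
) -> Chain:
    """A ring of glycine-like decoy residues surrounding the cofactor."""
    residues = []
    for i in range(n_residues):
        ang = 2 * math.pi * i / n_residues
        z = 2.5 * math.sin(3 * ang)
        ca = np.array([radius * math.cos(ang), radius * math.sin(ang), z])
        atoms = [
            Atom("N", "N", ca + np.array([-0.8, 0.9, 0.4])),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + np.array([1.0, 0.6, -0.3])),
            Atom("O", "O", ca + np.array([1.3, 1.7, -0.4])),
        ]
        residues.append(Residue(i + 1, "", "GLY", atoms))
    return Chain(chain_id, residues)


@dataclass
class GeometrySpec:
    seed: int = 0
    rotation_deg: float = 5.0
    pivot_ring: str = "E"
    noise_sd: float = 0.0
    n_decoy_residues: int = 20
    #: arbitrary rigid motion applied to the whole mobile structure so the
    #: local superposition stage does real work
    scramble: bool = True


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def generate_rotated_cofactor_pair(
    spec: GeometrySpec,
) -> tuple[StructureModel, StructureModel, dict]:
    """A reference/mobile structure pair with a known cofactor rotation.

    The mobile cofactor is rotated by ``rotation_deg`` about the macrocycle
    normal through the pivot-ring centroid, Gaussian coordinate noise of
    ``noise_sd`` A is added to every mobile atom, and (optionally) the whole
    mobile structure is given a random rigid motion.  Returns (reference,
    mobile, truth) with truth = {"angle_deg", "pivot_ring"}.
    """
    rng = np.random.default_rng(spec.seed)
    cof = chlorin_template()
    shell = _backbone_shell(n_residues=spec.n_decoy_residues)
    ref = StructureModel("synthetic_ref", chains=[shell], cofactors=[cof])

    pivot_centroid = cof.ring_coordinates(spec.pivot_ring).mean(axis=0)
    R = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), spec.rotation_deg)

    def rotated(xyz):
        return R @ (xyz - pivot_centroid) + pivot_centroid

    mob_cof = Cofactor(
        cof.component_id,
        cof.chain,
        cof.number,
        [Atom(a.name, a.element, rotated(a.xyz)) for a in cof.atoms],
    )
    mob_shell = Chain(
        shell.chain_id,
        [
            Residue(
                r.author_number,
                r.insertion_code,
                r.name,
                [Atom(a.name, a.element, a.xyz.copy()) for a in r.atoms],
            )
            for r in shell.residues
        ],
    )
    mobile = StructureModel("synthetic_mobile", chains=[mob_shell], cofactors=[mob_cof])

    def all_atoms(model):
        for ch in model.chains:
            for res in ch.residues:
                yield from res.atoms
        for c in model.cofactors:
            yield from c.atoms

    if spec.noise_sd > 0:
        for a in all_atoms(mobile):
            a.xyz = a.xyz + rng.normal(0.0, spec.noise_sd, size=3)
    if spec.scramble:
        Rg = _rotation_about_axis(rng.normal(size=3), float(rng.uniform(10, 170)))
        tg = rng.uniform(-20, 20, size=3)
        for a in all_atoms(mobile):
            a.xyz = Rg @ a.xyz + tg
    truth = {"angle_deg": spec.rotation_deg, "pivot_ring": spec.pivot_ring}
    return ref, mobile, truth


# --- PDB output for fixtures -------------------------------------------------


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as minimal PDB text."""
    lines = []
    serial = 1
    for ch in model.chains:
        for res in ch.residues:
            for a in res.atoms:
                lines.append(_pdb_line("ATOM", serial, a, res.name, ch.chain_id, res.author_number))
                serial += 1
    for cof in model.cofactors:
        for a in cof.atoms:
            lines.append(_pdb_line("HETATM", serial, a, cof.component_id, cof.chain, cof.number))
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _pdb_line(record, serial, atom, resname, chain, resnum) -> str:
    name = atom.name if len(atom.name) == 4 else f" {atom.name}"
    return (
        f"{record:<6}{serial:>5} {name:<4} {resname:<3}{chain:>2}{resnum:>4}    "
        f"{atom.xyz[0]:8.3f}{atom.xyz[1]:8.3f}{atom.xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2}"
    )
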