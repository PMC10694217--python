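"""Marginal ancestral sequence reconstruction on a fixed rooted tree.

Implements time-reversible amino-acid substitution models (LG by default,
Poisson for analytically tractable checks), Felsenstein's pruning algorithm
for site likelihoods, marginal per-site posterior reconstruction at any
internal node (an inside/outside pass), and forward simulation of sequence
evolution down the tree.  Among-site rate variation is modelled, when
enabled, by a discrete gamma with equal-probability mean-rate categories.

The model is a fixed input: no branch-length or model-parameter optimisation
is performed here.  Gaps and ``X`` are treated as missing data (an all-ones
conditional vector), never as a 21st state.

The rate matrix is ``Q[i, j] = s[i, j] * pi[j]`` for ``i != j`` with rows
summing to zero, rescaled so the expected rate at equilibrium is one
substitution per site; transition matrices ``P(t) = exp(Qt)`` are computed
through the symmetric eigendecomposition of ``diag(sqrt(pi)) Q
diag(1/sqrt(pi))``, which is exact for reversible models and keeps ``P(t)``
stochastic to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._lg_data import AMINO_ACIDS, LG_EXCHANGEABILITIES, LG_FREQUENCIES
from .seqio import GAP, UNKNOWN, GroupedAlignment

N_STATES = 20
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class ASRError(ValueError):
    pass


@dataclass
class SubstitutionModel:
    """A reversible amino-acid replacement model with optional gamma rates."""

    exchangeabilities: np.ndarray
    equilibrium_frequencies: np.ndarray
    gamma_shape: float | None = None
    n_rate_categories: int = 4
    name: str = "custom"

    # derived, filled in __post_init__
    _evals: np.ndarray = field(init=False, repr=False)
    _evecs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.equilibrium_frequencies, dtype=float)
        if S.shape != (N_STATES, N_STATES):
            raise ASRError("exchangeability matrix must be 20x20")
        if not np.allclose(S, S.T):
            raise ASRError("exchangeability matrix must be symmetric")
        if np.any(S < 0) or np.any(np.diag(S) != 0):
            raise ASRError("exchangeabilities must be non-negative, zero diagonal")
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise ASRError("frequencies must be 20 positive reals")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()  # expected rate at equilibrium
        Q /= mu
        self.exchangeabilities = S
        self.equilibrium_frequencies = pi
        # symmetric similarity transform: B = D Q D^-1 with D = diag(sqrt(pi))
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)  # symmetrise residual rounding
        evals, evecs = np.linalg.eigh(B)
        self._evals = evals
        self._evecs = evecs
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ASRError("gamma_shape must be positive")
        if self.n_rate_categories < 1:
            raise ASRError("n_rate_categories must be >= 1")

    @property
    def rate_matrix(self) -> np.ndarray:
        d = np.sqrt(self.equilibrium_frequencies)
        return (self._evecs * self._evals) @ self._evecs.T / d[:, None] * d[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one, entries clipped at zero."""
        if t < 0:
            raise ASRError("branch length must be non-negative")
        d = np.sqrt(self.equilibrium_frequencies)
        expB = (self._evecs * np.exp(self._evals * t)) @ self._evecs.T
        P = expB / d[:, None] * d[None, :]
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """Equal-probability mean rates of the discrete gamma (or a single 1)."""
        if self.gamma_shape is None:
            return np.array([1.0]), np.array([1.0])
        k = self.n_rate_categories
        a = self.gamma_shape
        # category boundaries at gamma quantiles; mean rate within each
        # category via the incomplete-gamma identity (Yang 1994)
        bounds = gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
        lower = np.concatenate([[0.0], bounds])
        upper = np.concatenate([bounds, [np.inf]])
        upper_i = np.where(np.isinf(upper), 1.0, gammainc(a + 1, a * upper))
        lower_i = gammainc(a + 1, a * lower)
        rates = (upper_i - lower_i) * k
        return rates, np.full(k, 1.0 / k)


def lg_model(gamma_shape: float | None = None, n_rate_categories: int = 4) -> SubstitutionModel:
    return SubstitutionModel(
        np.array(LG_EXCHANGEABILITIES),
        np.array(LG_FREQUENCIES),
        gamma_shape=gamma_shape,
        n_rate_categories=n_rate_categories,
        name="LG",
    )


def poisson_model(gamma_shape: float | None = None) -> SubstitutionModel:
    S = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
    return SubstitutionModel(
        S, np.full(N_STATES, 1.0 / N_STATES), gamma_shape=gamma_shape, name="Poisson"
    )


@dataclass
class AncestralReconstruction:
    """Per-site posteriors over amino acids at one internal node."""

    node_name: str
    per_site_posterior: np.ndarray  # (n_sites, 20)
    map_sequence: str

    @property
    def site_count(self) -> int:
        return self.per_site_posterior.shape[0]


# --- tree plumbing ----------------------------------------------------------


def _leaf_name(node: dendropy.Node) -> str:
    return node.taxon.label.replace(" ", "_")


def name_internal_nodes(tree: dendropy.Tree) -> None:
    """Assign stable names (root, node1, node2, ...) to unnamed internal nodes."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            node.label = "root" if node.parent_node is None else f"node{i}"
            i += 1


def find_node(tree: dendropy.Tree, name: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        label = _leaf_name(node) if node.is_leaf() else node.label
        if label == name:
            return node
    available = [n.label for n in tree.preorder_internal_node_iter() if n.label]
    raise ASRError(f"node '{name}' not found; internal nodes: {available}")


def mrca_of_group(tree: dendropy.Tree, aln: GroupedAlignment, group: str = "FRL") -> dendropy.Node:
    """The most recent common ancestor of all leaves labelled *group*."""
    members = set(aln.group_members(group))
    if not members:
        raise ASRError(f"no sequences labelled {group}")
    taxa = [n.taxon for n in tree.leaf_node_iter() if _leaf_name(n) in members]
    if len(taxa) != len(members):
        found = {_leaf_name(n) for n in tree.leaf_node_iter()}
        raise ASRError(f"leaves missing from tree: {sorted(members - found)}")
    node = tree.mrca(taxa=taxa)
    if node is None:
        raise ASRError("MRCA computation failed")
    return node


def _encode(aln: GroupedAlignment) -> dict[str, np.ndarray]:
    """Per-sequence conditional-likelihood matrices (n_sites, 20)."""
    out = {}
    for sid, seq in aln.records:
        L = np.zeros((len(seq), N_STATES))
        for i, ch in enumerate(seq):
            if ch in (GAP, UNKNOWN):
                L[i, :] = 1.0  # missing data
            else:
                L[i, _AA_INDEX[ch]] = 1.0
        out[sid] = L
    return out


def _check_leaves(tree: dendropy.Tree, aln: GroupedAlignment) -> None:
    leaves = {_leaf_name(n) for n in tree.leaf_node_iter()}
    ids = set(aln.sequence_ids)
    if leaves != ids:
        raise ASRError(
            f"tree/alignment mismatch; tree-only: {sorted(leaves - ids)}, "
            f"alignment-only: {sorted(ids - leaves)}"
        )


def _edge_length(node: dendropy.Node) -> float:
    t = node.edge.length
    return 0.0 if t is None else float(t)


def _inside_pass(
    tree: dendropy.Tree, leaf_L: dict[str, np.ndarray], model: SubstitutionModel, rate: float
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray], np.ndarray]:
    """Post-order conditional likelihoods.

    Returns (L, child_message, log_scale) where ``L[id(node)]`` is the
    (n_sites, 20) conditional likelihood of the data below the node given its
    state, ``child_message[id(node)]`` is ``L(node) @ P(t_node).T`` seen from
    the parent, and ``log_scale`` accumulates per-site scaling factors.
    """
    n_sites = next(iter(leaf_L.values())).shape[0]
    L: dict[int, np.ndarray] = {}
    msg: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_sites)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = _leaf_name(node)
            L[id(node)] = leaf_L[name]
        else:
            prod = np.ones((n_sites, N_STATES))
            for child in node.child_nodes():
                prod *= msg[id(child)]
            scale = prod.max(axis=1)
            scale[scale == 0] = 1.0
            prod /= scale[:, None]
            log_scale += np.log(scale)
            L[id(node)] = prod
        if node.parent_node is not None:
            P = model.transition_matrix(rate * _edge_length(node))
            msg[id(node)] = L[id(node)] @ P.T
    return L, msg, log_scale


def tree_log_likelihood(
    tree: dendropy.Tree, aln: GroupedAlignment, model: SubstitutionModel
) -> tuple[float, np.ndarray]:
    """Total and per-site log-likelihood by pruning, gamma-averaged."""
    _check_leaves(tree, aln)
    leaf_L = _encode(aln)
    rates, weights = model.rate_categories()
    pi = model.equilibrium_frequencies
    n_sites = aln.n_columns
    site_like = np.zeros(n_sites)
    # average in likelihood space with shared scaling handled per category
    per_cat = []
    for rate in rates:
        L, _, log_scale = _inside_pass(tree, leaf_L, model, rate)
        root_like = L[id(tree.seed_node)] @ pi
        per_cat.append(np.log(root_like) + log_scale)
    M = np.array(per_cat)  # (k, n_sites)
    mx = M.max(axis=0)
    site_log = mx + np.log((weights[:, None] * np.exp(M - mx)).sum(axis=0))
    return float(site_log.sum()), site_log


def site_likelihood(
    tree: dendropy.Tree, aln: GroupedAlignment, model: SubstitutionModel, site: int
) -> float:
    """Log-likelihood of a single 1-based alignment site."""
    if not 1 <= site <= aln.n_columns:
        raise ASRError(f"site {site} out of range 1..{aln.n_columns}")
    _, per_site = tree_log_likelihood(tree, aln, model)
    return float(per_site[site - 1])


def _outside_pass(
    tree: dendropy.Tree,
    L: dict[int, np.ndarray],
    msg: dict[int, np.ndarray],
    model: SubstitutionModel,
    rate: float,
    pi: np.ndarray,
    n_sites: int,
) -> dict[int, np.ndarray]:
    """Pre-order outside weights W; W(root) = pi, rows rescaled per site."""
    W: dict[int, np.ndarray] = {}
    root = tree.seed_node
    W[id(root)] = np.broadcast_to(pi, (n_sites, N_STATES)).copy()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children = node.child_nodes()
        for child in children:
            out = W[id(node)].copy()
            for sib in children:
                if sib is not child:
                    out *= msg[id(sib)]
            P = model.transition_matrix(rate * _edge_length(child))
            Wc = out @ P
            scale = Wc.max(axis=1)
            scale[scale == 0] = 1.0
            W[id(child)] = Wc / scale[:, None]
        # (scaling factors cancel in the per-site posterior normalisation)
    return W


def reconstruct_marginal(
    tree: dendropy.Tree,
    aln: GroupedAlignment,
    model: SubstitutionModel,
    node: str | dendropy.Node,
) -> AncestralReconstruction:
    """Marginal posterior state distributions at an internal node.

    The posterior at the node is proportional to the product of the
    conditional likelihood of the data below it and the outside weight of
    the rest of the tree flowing through it, averaged over gamma categories.
    """
    _check_leaves(tree, aln)
    if isinstance(node, str):
        node = find_node(tree, node)
    if node.is_leaf():
        raise ASRError("reconstruction target must be an internal node")
    leaf_L = _encode(aln)
    rates, weights = model.rate_categories()
    pi = model.equilibrium_frequencies
    n_sites = aln.n_columns
    cat_post = []
    cat_loglike = []
    for rate in rates:
        L, msg, log_scale = _inside_pass(tree, leaf_L, model, rate)
        W = _outside_pass(tree, L, msg, model, rate, pi, n_sites)
        joint = L[id(node)] * W[id(node)]
        tot = joint.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        cat_post.append(joint / tot)  # scaling cancels within a category
        root_like = L[id(tree.seed_node)] @ pi
        cat_loglike.append(np.log(root_like) + log_scale)
    # per-site category weights proportional to weight * category likelihood
    M = np.array(cat_loglike)
    mx = M.max(axis=0)
    wts = weights[:, None] * np.exp(M - mx)
    wts /= wts.sum(axis=0)
    post = np.zeros((n_sites, N_STATES))
    for k in range(len(rates)):
        post += wts[k][:, None] * cat_post[k]
    post /= post.sum(axis=1, keepdims=True)
    map_idx = post.argmax(axis=1)  # argmax takes the first max: alphabetical
    map_seq = "".join(AMINO_ACIDS[i] for i in map_idx)
    name = node.label or "<unnamed>"
    return AncestralReconstruction(node_name=name, per_site_posterior=post, map_sequence=map_seq)


def simulate_evolution(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int | np.random.Generator,
) -> dict[str, str]:
    """Simulate sequences at every node of the tree.

    The root state is drawn from the equilibrium frequencies; each child is
    drawn from P(rate * branch length) given its parent.  With gamma rates a
    category is drawn once per site and applied on every branch.  Returns a
    map node name -> sequence covering leaves and internal nodes.
    """
    if n_sites < 1:
        raise ASRError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    name_internal_nodes(tree)
    rates, weights = model.rate_categories()
    site_rates = rates[rng.choice(len(rates), size=n_sites, p=weights)]
    pi = model.equilibrium_frequencies
    root = tree.seed_node
    states: dict[int, np.ndarray] = {
        id(root): rng.choice(N_STATES, size=n_sites, p=pi)
    }
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            t = _edge_length(node)
            parent_states = states[id(node.parent_node)]
            child_states = np.empty(n_sites, dtype=int)
            if t == 0:
                child_states[:] = parent_states
            else:
                for rate in np.unique(site_rates):
                    P = model.transition_matrix(rate * t)
                    sel = site_rates == rate
                    ps = parent_states[sel]
                    u = rng.random(ps.shape[0])
                    cum = P.cumsum(axis=1)
                    child_states[sel] = (u[:, None] > cum[ps]).sum(axis=1)
            states[id(node)] = child_states
        name = _leaf_name(node) if node.is_leaf() else node.label
        out[name] = "".join(AMINO_ACIDS[i] for i in states[id(node)])
    return out


def write_reconstruction(rec: AncestralReconstruction, fasta_path, tsv_path) -> None:
    """Write the MAP sequence (FASTA) and per-site posteriors (TSV)."""
    from .seqio import write_fasta

    write_fasta([(rec.node_name, rec.map_sequence)], fasta_path)
    with open(tsv_path, "w") as fh:
        fh.write("site\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i, row in enumerate(rec.per_site_posterior, 1):
            fh.write(str(i) + "\t" + "\t".join(f"{p:.6f}" for p in row) + "\n")
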