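"""Synthetic virus-genome datasets with known ground truth.

Generates the statistical structure the comparison pipeline assumes:
``n`` sequences evolved along a random tree under the Jukes-Cantor (JC69)
substitution model, with the generating tree and its patristic distance
matrix returned alongside the sequences. Because no indels are simulated,
the sequences double as their own true multiple alignment, so a JC
reference matrix can be computed without running an aligner and every
downstream stage can be validated against exact ground truth.

Tree models: a Yule (pure-birth) topology with i.i.d. exponential branch
lengths (mean = ``scale`` expected substitutions per site), or a Kingman
coalescent with exponential waiting times scaled the same way. One seed
drives tree shape, root sequence and substitutions through a single
``numpy`` generator stream, so a dataset replays bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .seqio import SequenceRecord, SequenceSet, write_fasta, write_newick
from .distances import write_matrix_csv

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset.

    ``scale`` is the expected branch length in substitutions per site.
    """

    n_taxa: int = 10
    length: int = 3000
    tree_model: str = "yule"  # or "coalescent"
    scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.length < 10:
            raise ValueError("sequence length must be >= 10")
        if self.scale <= 0:
            raise ValueError("branch-length scale must be > 0")
        if self.tree_model not in ("yule", "coalescent"):
            raise ValueError(f"unknown tree model {self.tree_model!r}")


@dataclass
class SyntheticDataset:
    sequences: SequenceSet
    true_tree: dendropy.Tree
    true_matrix: DistanceMatrix
    spec: SimulationSpec = field(default=None)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "sequences.fasta")
        write_newick(self.true_tree, outdir / "true_tree.nwk")
        write_matrix_csv(self.true_matrix, outdir / "true_matrix.csv")


def _yule_tree(n: int, scale: float, rng: np.random.Generator,
               taxa: dendropy.TaxonNamespace) -> dendropy.Tree:
    """Yule topology: repeatedly split a uniformly chosen extant lineage;
    every edge gets an i.i.d. Exponential(mean=scale) length."""
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    a, b = dendropy.Node(), dendropy.Node()
    root.add_child(a)
    root.add_child(b)
    tips = [a, b]
    while len(tips) < n:
        i = int(rng.integers(len(tips)))
        node = tips.pop(i)
        c, d = dendropy.Node(), dendropy.Node()
        node.add_child(c)
        node.add_child(d)
        tips.extend([c, d])
    for i, tip in enumerate(tips):
        tip.taxon = taxa.get_taxon(f"t{i + 1}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.exponential(scale))
    tree.is_rooted = True
    return tree


def _coalescent_tree(n: int, scale: float, rng: np.random.Generator,
                     taxa: dendropy.TaxonNamespace) -> dendropy.Tree:
    """Kingman coalescent: merge uniform random pairs with exponential
    waiting times of rate C(k, 2), node heights scaled by ``scale``."""
    nodes = []
    for i in range(n):
        nd = dendropy.Node(taxon=taxa.get_taxon(f"t{i + 1}"))
        nd.height = 0.0
        nodes.append(nd)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += float(rng.exponential(1.0 / (k * (k - 1) / 2.0))) * scale
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = dendropy.Node()
        parent.height = t
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - a.height
        b.edge.length = t - b.height
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def _patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    # accumulate distances leaf-to-root, then pair distances via LCA
    pdm = tree.phylogenetic_distance_matrix()
    out = np.zeros((n, n))
    for tx1 in pdm.taxon_iter():
        for tx2 in pdm.taxon_iter():
            out[index[tx1.label], index[tx2.label]] = pdm.patristic_distance(tx1, tx2)
    return DistanceMatrix(tuple(labels), out)


def evolve_sequences(tree: dendropy.Tree, length: int, rng: np.random.Generator) -> dict[str, str]:
    """JC69 evolution: along a branch of length t each site substitutes,
    with probability p(t) = (3/4)(1 - exp(-4t/3)), to a uniformly chosen
    different base."""
    seqs_by_id: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs_by_id[id(root)] = rng.integers(0, 4, size=length, dtype=np.int8)
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            parent_seq = seqs_by_id[id(node.parent_node)]
            t = node.edge.length or 0.0
            p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            seq = parent_seq.copy()
            hit = rng.random(length) < p
            n_hit = int(hit.sum())
            if n_hit:
                # uniformly chosen different base: offset 1..3 mod 4
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
            seqs_by_id[id(node)] = seq
            del parent_seq
        node_seq = seqs_by_id[id(node)]
        if node.is_leaf():
            out[node.taxon.label] = "".join(_BASES[node_seq])
    return out


def simulate(spec: SimulationSpec) -> SyntheticDataset:
    """Draw a random tree and evolve sequences along it under JC69."""
    rng = np.random.default_rng(spec.seed)
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(spec.n_taxa)])
    if spec.tree_model == "yule":
        tree = _yule_tree(spec.n_taxa, spec.scale, rng, taxa)
    else:
        tree = _coalescent_tree(spec.n_taxa, spec.scale, rng, taxa)
    matrix = _patristic_matrix(tree)
    leaf_seqs = evolve_sequences(tree, spec.length, rng)
    labels = list(matrix.labels)
    records = [SequenceRecord(id=l, seq=leaf_seqs[l]) for l in labels]
    seqs = SequenceSet(records=records, aligned=True)
    return SyntheticDataset(sequences=seqs, true_tree=tree, true_matrix=matrix, spec=spec)


def recovery_experiment(spec: SimulationSpec, schemes=None) -> "pandas.DataFrame":
    """Simulate one dataset and score each encoding against ground truth.

    For every scheme: the Euclidean distance between its normalized matrix
    and the normalized true patristic matrix, the RF distance between its
    NJ tree and the generating tree, and the Spearman rank correlation
    between its distances and the true distances.
    """
    import pandas as pd
    from scipy.stats import spearmanr

    from .distances import matrix_euclidean, normalize_minmax
    from .encoders import SCHEMES, EncodingSpec, descriptor_batch
    from .distances import pairwise_euclidean, jukes_cantor_matrix
    from .njtree import neighbor_joining
    from .tree_metrics import rf_distance

    ds = simulate(spec)
    truth = normalize_minmax(ds.true_matrix)
    true_tree = ds.true_tree
    rows = []
    queries: dict[str, DistanceMatrix] = {}
    for name in (schemes or SCHEMES):
        espec = EncodingSpec(name)
        descs = descriptor_batch(espec, ds.sequences)
        queries[name] = normalize_minmax(
            pairwise_euclidean(descs, ds.sequences.ids)
        )
    queries["jc_true_alignment"] = normalize_minmax(jukes_cantor_matrix(ds.sequences))
    for name, q in queries.items():
        tree = neighbor_joining(q)
        rf = rf_distance(tree, true_tree).value if spec.n_taxa >= 4 else float("nan")
        rho = float(
            spearmanr(q.reorder(truth.labels).offdiag(), truth.offdiag()).statistic
        )
        rows.append(
            {
                "scheme": name,
                "euclidean_to_truth": matrix_euclidean(truth, q),
                "rf_to_true_tree": rf,
                "spearman_to_truth": rho,
            }
        )
    return pd.DataFrame(rows).sort_values("euclidean_to_truth").reset_index(drop=True)


def ranking_sweep(
    base_seed: int,
    n_replicates: int = 20,
    taxa_range: tuple[int, int] = (8, 16),
    length_range: tuple[int, int] = (3000, 5000),
    scale: float = 0.1,
    schemes=None,
) -> "pandas.DataFrame":
    """Rank every encoding against a JC alignment reference over replicates.

    Each replicate simulates a dataset (taxa count and length cycle through
    their ranges deterministically), builds the normalized JC matrix of the
    true alignment as the reference, and ranks the encodings by the
    Euclidean distance between normalized matrices (rank 1 = most similar).
    The spectral schemes (fps, cgrdft) are compared via their power spectra
    even-scaled to the longest sequence, which is how those methods are
    defined; all other schemes go through moment vectors.

    Returns a long-format frame with one row per (replicate, scheme).
    """
    import pandas as pd

    from .distances import (
        jukes_cantor_matrix,
        matrix_euclidean,
        normalize_minmax,
        pairwise_euclidean,
    )
    from .encoders import SCHEMES, EncodingSpec, descriptor_batch

    schemes = tuple(schemes or SCHEMES)
    lo_n, hi_n = taxa_range
    lo_l, hi_l = length_range
    rows = []
    for i in range(n_replicates):
        n = lo_n + i % (hi_n - lo_n + 1)
        length = lo_l + (i % 5) * (hi_l - lo_l) // 4 if hi_l > lo_l else lo_l
        ds = simulate(
            SimulationSpec(n_taxa=n, length=length, scale=scale,
                           seed=base_seed + i)
        )
        ref = normalize_minmax(jukes_cantor_matrix(ds.sequences))
        m_spec = max(len(r) for r in ds.sequences) - 1
        dists = {}
        for s in schemes:
            kwargs = {"m": m_spec} if s in ("fps", "cgrdft") else {}
            descs = descriptor_batch(EncodingSpec(s), ds.sequences, **kwargs)
            q = normalize_minmax(pairwise_euclidean(descs, ds.sequences.ids))
            dists[s] = matrix_euclidean(ref, q)
        order = sorted(dists, key=lambda k: (dists[k], k))
        for rank, s in enumerate(order, 1):
            rows.append(
                {"replicate": i, "seed": base_seed + i, "n_taxa": n,
                 "length": length, "scheme": s, "euclidean": dists[s],
                 "rank": rank}
            )
    return pd.DataFrame(rows)
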