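"""Structural networks: generators, file I/O, and degree utilities.

The structural substrate of the oscillator model is a nonnegative square
coupling matrix ``A`` in which ``A[j, k]`` is the coupling from node ``k``
onto node ``j``.  The node degree ``n_j`` is the row sum ``sum_k A[j, k]``
(weighted) or the count of nonzero couplings (binary).  Degrees carry no
``1/N`` normalisation here; the ``S/N`` coupling prefactor of the dynamical
model lives in :mod:`netphase.simulate` and :mod:`netphase.analytic` so that
every module shares a single convention.

Two generator families are provided:

* :func:`gilbert_random` -- Gilbert G(N, p) graphs with
  ``p = (1 + eps) * log(N) / N``, i.e. just above the connectivity
  threshold, giving an approximately Poisson (homogeneous) degree
  distribution.
* :func:`scale_free` -- uncorrelated configuration-model graphs with a
  power-law degree distribution ``P(k) ~ k**(-gamma)`` and a structural
  cutoff ``k_max = sqrt(<k> N)``, which guarantees the stub-matching wiring
  is free of degree-degree correlations.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Network",
    "gilbert_random",
    "scale_free",
    "degrees",
    "load_network",
    "save_network",
    "load_coordinates",
    "largest_component",
]


@dataclass
class Network:
    """A weighted (or binary) structural network.

    Parameters
    ----------
    adjacency
        Nonnegative square matrix; ``adjacency[j, k]`` couples node ``k``
        onto node ``j``.  The diagonal must be zero (no self-coupling).
    node_ids
        Ordered node labels; defaults to ``"0" .. "N-1"``.
    coordinates
        Optional ``(N, 3)`` Euclidean positions in millimetres, used to
        derive distance-proportional conduction delays.
    """

    adjacency: np.ndarray
    node_ids: list[str] | None = None
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        if np.any(A < 0):
            raise ValueError("adjacency entries must be nonnegative")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-coupling)")
        self.adjacency = A
        if self.node_ids is None:
            self.node_ids = [str(i) for i in range(A.shape[0])]
        else:
            self.node_ids = [str(i) for i in self.node_ids]
        if len(self.node_ids) != A.shape[0]:
            raise ValueError(
                f"{len(self.node_ids)} node ids for {A.shape[0]} nodes"
            )
        if self.coordinates is not None:
            C = np.asarray(self.coordinates, dtype=float)
            if C.shape != (A.shape[0], 3):
                raise ValueError(
                    f"coordinates must have shape ({A.shape[0]}, 3), got {C.shape}"
                )
            self.coordinates = C

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def is_undirected(self) -> bool:
        return bool(np.array_equal(self.adjacency, self.adjacency.T))

    def degrees(self, mode: str = "weighted") -> np.ndarray:
        return degrees(self, mode=mode)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean node distances (mm); requires coordinates."""
        if self.coordinates is None:
            raise ValueError("network has no coordinates")
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


def degrees(network: Network, mode: str = "weighted") -> np.ndarray:
    """Per-node degree ``n_j``.

    ``weighted`` returns ``sum_k A[j, k]``; ``binary`` counts nonzero
    couplings.
    """
    A = network.adjacency
    if mode == "weighted":
        return A.sum(axis=1)
    if mode == "binary":
        return (A > 0).sum(axis=1).astype(float)
    raise ValueError(f"unknown degree mode {mode!r}; use 'weighted' or 'binary'")


def gilbert_random(n_nodes: int, epsilon: float = 0.1, seed: int | None = None) -> Network:
    """Gilbert random graph G(N, p) with ``p = (1 + epsilon) log(N) / N``.

    With small positive ``epsilon`` the graph sits just above the
    connectivity threshold and has an approximately Poisson degree
    distribution with mean ``(N - 1) p``.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    p = (1.0 + epsilon) * np.log(n_nodes) / n_nodes
    if p > 1.0 + 1e-12:
        raise ValueError(
            f"edge probability p = (1+eps)·log(N)/N = {p:.4f} exceeds 1 for "
            f"N={n_nodes}, eps={epsilon}; increase n_nodes or decrease epsilon"
        )
    p = min(p, 1.0)
    rng = np.random.default_rng(seed)
    A = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    A[iu] = rng.random(iu[0].size) < p
    A = A + A.T
    return Network(A)


def scale_free(
    n_nodes: int,
    gamma: float = 2.5,
    min_degree: int = 3,
    seed: int | None = None,
    max_tries: int = 200,
) -> Network:
    """Uncorrelated scale-free network (configuration model, stub matching).

    Degrees are drawn from ``P(k) ~ k**(-gamma)`` on
    ``[min_degree, k_max]`` with structural cutoff
    ``k_max = sqrt(<k> N)``, then wired by random stub matching.
    The default ``min_degree=3`` puts the mean degree near 5 at N=100,
    matching the mean connectivity of the Gilbert family so the two model
    families differ in degree *heterogeneity*, not density.
    Self-loops and multi-edges are removed by degree-preserving edge swaps,
    so the realised graph is simple with exactly the sampled degree
    sequence.
    """
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4")
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    if not (2.0 <= gamma <= 3.0):
        warnings.warn(
            f"degree exponent gamma={gamma} outside the usual range [2, 3]",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    # provisional support to estimate <k>, then apply the structural cutoff
    k = np.arange(min_degree, n_nodes, dtype=float)
    pk = k ** (-gamma)
    pk /= pk.sum()
    kbar = float((k * pk).sum())
    cutoff = int(np.sqrt(kbar * n_nodes))
    cutoff = max(cutoff, min_degree + 1)
    cutoff = min(cutoff, n_nodes - 1)
    k = np.arange(min_degree, cutoff + 1)
    pk = k.astype(float) ** (-gamma)
    pk /= pk.sum()

    for _ in range(max_tries):
        deg = rng.choice(k, size=n_nodes, p=pk)
        if deg.sum() % 2:
            continue
        if not nx.is_graphical(deg.tolist()):
            continue
        try:
            A = _stub_match(deg, rng)
        except RuntimeError:
            continue
        return Network(A)
    raise RuntimeError(
        "could not realise a simple graph with the sampled degree sequence "
        f"after {max_tries} attempts"
    )


def _stub_match(deg: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random stub matching with swap-repair of self-loops and multi-edges."""
    n = deg.size
    stubs = np.repeat(np.arange(n), deg)
    rng.shuffle(stubs)
    edges = [tuple(sorted(pair)) for pair in stubs.reshape(-1, 2)]
    cnt = Counter(edges)

    def is_bad(e: tuple[int, int]) -> bool:
        return e[0] == e[1] or cnt[e] > 1

    m = len(edges)
    budget = 200 * m
    while budget > 0:
        bad = [i for i, e in enumerate(edges) if is_bad(e)]
        if not bad:
            break
        for i in bad:
            e1 = edges[i]
            if not is_bad(e1):
                continue
            for _ in range(50):
                budget -= 1
                j = int(rng.integers(m))
                if j == i:
                    continue
                e2 = edges[j]
                u, v = e1
                # random pairing orientation for the double-edge swap
                x, y = (e2 if rng.random() < 0.5 else e2[::-1])
                f1 = tuple(sorted((u, x)))
                f2 = tuple(sorted((v, y)))
                if f1[0] == f1[1] or f2[0] == f2[1] or f1 == f2:
                    continue
                if cnt[f1] > 0 or cnt[f2] > 0:
                    continue
                cnt[e1] -= 1
                cnt[e2] -= 1
                cnt[f1] += 1
                cnt[f2] += 1
                edges[i] = f1
                edges[j] = f2
                break
            else:
                continue
    else:
        raise RuntimeError("edge-swap repair did not converge")

    A = np.zeros((n, n))
    for u, v in edges:
        A[u, v] = 1.0
        A[v, u] = 1.0
    return A


def largest_component(network: Network) -> Network:
    """Restrict to the largest (weakly) connected component."""
    A = network.adjacency
    n_comp, labels = connected_components(
        csr_matrix(A + A.T), directed=False
    )
    if n_comp == 1:
        return network
    sizes = np.bincount(labels)
    keep = np.flatnonzero(labels == sizes.argmax())
    coords = None if network.coordinates is None else network.coordinates[keep]
    ids = [network.node_ids[i] for i in keep]
    return Network(A[np.ix_(keep, keep)], node_ids=ids, coordinates=coords)


# ---------------------------------------------------------------------------
# file I/O
#
# dense format:   whitespace- or comma-delimited numeric square matrix,
#                 one row per node
# edge list:      3-column TSV (source, target, weight); the weight column
#                 may be omitted and defaults to 1; an optional
#                 "# nodes:<TAB>id..." comment preserves node order and
#                 isolated nodes across a save/load round trip
# coordinates:    4-column TSV (id, x, y, z) in mm
# ---------------------------------------------------------------------------


def load_network(path: str | Path, format: str | None = None) -> Network:
    """Load a network from a dense matrix or edge-list file.

    ``format`` is ``"dense"`` or ``"edgelist"``; when omitted it is guessed
    from the extension (``.tsv``/``.edges`` -> edge list, otherwise dense).
    """
    path = Path(path)
    if format is None:
        format = "edgelist" if path.suffix in {".tsv", ".edges"} else "dense"
    if format == "dense":
        return _load_dense(path)
    if format == "edgelist":
        return _load_edgelist(path)
    raise ValueError(f"unknown network format {format!r}; use 'dense' or 'edgelist'")


def _load_dense(path: Path) -> Network:
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                first = line
                break
    delimiter = "," if "," in first else None
    A = np.loadtxt(path, delimiter=delimiter, comments="#")
    A = np.atleast_2d(A)
    if A.shape[0] != A.shape[1]:
        raise ValueError(
            f"dense matrix in {path} is not square: shape {A.shape}"
        )
    if np.any(A < 0):
        rows = np.unique(np.where(A < 0)[0])
        raise ValueError(f"negative weights in {path} at row(s) {rows.tolist()}")
    return Network(A)


def _load_edgelist(path: Path) -> Network:
    order: list[str] = []
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("# nodes:"):
                    order = line[len("# nodes:") :].strip().split("\t")
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                src, tgt, w = parts[0], parts[1], 1.0
            elif len(parts) == 3:
                src, tgt = parts[0], parts[1]
                w = float(parts[2])
            else:
                raise ValueError(
                    f"edge list {path} line {lineno}: expected 2 or 3 "
                    f"tab-separated columns, got {len(parts)}"
                )
            if w < 0:
                raise ValueError(
                    f"edge list {path} line {lineno}: negative weight {w}"
                )
            rows.append((src, tgt, w))
    if not order:
        seen: dict[str, None] = {}
        for src, tgt, _ in rows:
            seen.setdefault(src)
            seen.setdefault(tgt)
        order = list(seen)
    index = {nid: i for i, nid in enumerate(order)}
    A = np.zeros((len(order), len(order)))
    for src, tgt, w in rows:
        A[index[tgt], index[src]] = w  # source -> target couples onto target
    return Network(A, node_ids=order)


def save_network(network: Network, path: str | Path, format: str = "dense") -> None:
    """Save a network; ``load_network(save_network(x))`` is lossless."""
    path = Path(path)
    if format == "dense":
        np.savetxt(path, network.adjacency, fmt="%.17g", delimiter=" ")
        return
    if format == "edgelist":
        with open(path, "w") as fh:
            fh.write("# nodes:" + "\t".join(network.node_ids) + "\n")
            A = network.adjacency
            for j, k in zip(*np.nonzero(A)):
                fh.write(
                    f"{network.node_ids[k]}\t{network.node_ids[j]}\t{float(A[j, k])!r}\n"
                )
        return
    raise ValueError(f"unknown network format {format!r}; use 'dense' or 'edgelist'")


def load_coordinates(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Load node coordinates from a 4-column TSV (id, x, y, z in mm)."""
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"coordinates {path} line {lineno}: expected 4 columns"
                )
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return ids, np.asarray(rows)
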