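"""Object-transition graphs and their combinatorics.

The experimental design presents 15 recurring objects as nodes of a transition
graph. Two canonical graphs are used:

* the *modular* graph — three communities of five objects; within each
  community every pair is linked except the two "boundary" (linking) objects,
  which instead each carry one of the three between-community edges, arranged
  as a ring over communities.  Every node has degree 4, so first-order
  transition probabilities are uniform and only *higher-order* (community)
  structure distinguishes it from the control graph;
* the *complete* graph — every object linked to every other (degree 14), used
  for the unstructured control condition.  It carries a counterfactual
  community labeling (the same 5/5/5 partition) so that control analyses can
  be run with identical code paths.

Object pairs are classified by community membership × adjacency into
SA (same community, adjacent), DA (different, adjacent — the "linking" pairs),
SN (same, non-adjacent) and DN (different, non-adjacent).  On the modular
graph the 105 unordered pairs split 27/3/3/72.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

N_OBJECTS = 15
N_COMMUNITIES = 3
COMMUNITY_SIZE = 5
COMMUNITY_LABELS = ("A", "B", "C")

PAIR_TYPES = ("SA", "DA", "SN", "DN")

__all__ = [
    "CommunityGraph",
    "N_OBJECTS",
    "PAIR_TYPES",
    "build_modular_graph",
    "build_complete_graph",
    "classify_pairs",
    "pair_type_matrix",
    "automorphism_group",
]


@dataclass(frozen=True)
class CommunityGraph:
    """A 15-node object-transition graph with community and role annotations.

    Attributes
    ----------
    adjacency:
        Symmetric boolean (15, 15) matrix with zero diagonal.
    community_of:
        Length-15 array of community labels ("A"/"B"/"C").  For the complete
        graph this is a counterfactual labeling used by control analyses.
    role_of:
        Length-15 array with entries "internal" or "boundary".  Boundary
        (linking) nodes carry a between-community edge.
    boundary_partner:
        Mapping node -> label of the neighboring community its between-
        community edge reaches (boundary nodes only).
    name:
        "modular" or "complete".
    """

    adjacency: np.ndarray
    community_of: np.ndarray
    role_of: np.ndarray
    boundary_partner: dict[int, str] = field(default_factory=dict)
    name: str = "modular"

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=bool)
        if A.shape != (N_OBJECTS, N_OBJECTS):
            raise ValueError(f"adjacency must be {N_OBJECTS}x{N_OBJECTS}")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        object.__setattr__(self, "adjacency", A)
        object.__setattr__(self, "community_of", np.asarray(self.community_of))
        object.__setattr__(self, "role_of", np.asarray(self.role_of))

    @property
    def node_ids(self) -> np.ndarray:
        return np.arange(N_OBJECTS)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def neighbors(self, node: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[node])

    def community_index(self) -> np.ndarray:
        """Communities as integers 0..2 (in label order)."""
        labels = sorted(set(self.community_of.tolist()))
        lut = {lab: i for i, lab in enumerate(labels)}
        return np.array([lut[c] for c in self.community_of])

    def same_community_matrix(self) -> np.ndarray:
        c = self.community_index()
        return c[:, None] == c[None, :]

    def to_networkx(self) -> nx.Graph:
        G = nx.from_numpy_array(self.adjacency.astype(int))
        for i in range(N_OBJECTS):
            G.nodes[i]["community"] = str(self.community_of[i])
            G.nodes[i]["role"] = str(self.role_of[i])
        return G

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())


def build_modular_graph() -> CommunityGraph:
    """Build the canonical 15-node modular (structured-condition) graph.

    Nodes 0-4, 5-9 and 10-14 form communities A, B and C.  Within each
    community all pairs are linked except the two boundary nodes (local
    indices 0 and 4).  Between-community edges form a directed ring over
    communities: node 4 of community c links to node 0 of community c+1
    (mod 3).  Every node then has degree exactly 4 and the graph has 30
    undirected edges.
    """
    A = np.zeros((N_OBJECTS, N_OBJECTS), dtype=bool)
    community = np.repeat(list(COMMUNITY_LABELS), COMMUNITY_SIZE)
    role = np.full(N_OBJECTS, "internal", dtype=object)
    partner: dict[int, str] = {}

    for c in range(N_COMMUNITIES):
        nodes = np.arange(COMMUNITY_SIZE * c, COMMUNITY_SIZE * (c + 1))
        for i, j in itertools.combinations(nodes, 2):
            A[i, j] = A[j, i] = True
        lo, hi = nodes[0], nodes[-1]
        A[lo, hi] = A[hi, lo] = False  # the two boundary nodes are non-adjacent
        role[lo] = role[hi] = "boundary"

    for c in range(N_COMMUNITIES):
        nc = (c + 1) % N_COMMUNITIES
        a = COMMUNITY_SIZE * c + (COMMUNITY_SIZE - 1)
        b = COMMUNITY_SIZE * nc
        A[a, b] = A[b, a] = True
        partner[a] = COMMUNITY_LABELS[nc]
        partner[b] = COMMUNITY_LABELS[c]

    return CommunityGraph(A, community, role, partner, name="modular")


def build_complete_graph() -> CommunityGraph:
    """Build the complete (unstructured-condition) graph on 15 nodes.

    All 105 pairs are adjacent.  The counterfactual community labeling
    partitions nodes 5/5/5 exactly as the modular graph does, and the roles
    of the modular graph are retained, so control analyses can apply the
    identical pair classification.
    """
    A = ~np.eye(N_OBJECTS, dtype=bool)
    modular = build_modular_graph()
    return CommunityGraph(
        A,
        modular.community_of.copy(),
        modular.role_of.copy(),
        dict(modular.boundary_partner),
        name="complete",
    )


def classify_pairs(graph: CommunityGraph) -> dict[tuple[int, int], str]:
    """Label all 105 unordered object pairs as SA, DA, SN or DN.

    S/D: same/different community; A/N: adjacent/non-adjacent on the graph.
    The four sets partition the pairs.
    """
    same = graph.same_community_matrix()
    out: dict[tuple[int, int], str] = {}
    for i, j in itertools.combinations(range(N_OBJECTS), 2):
        s = "S" if same[i, j] else "D"
        a = "A" if graph.adjacency[i, j] else "N"
        out[(i, j)] = s + a
    return out


def pair_type_matrix(graph: CommunityGraph) -> np.ndarray:
    """Pair types as a symmetric (15, 15) object array; diagonal is None."""
    M = np.full((N_OBJECTS, N_OBJECTS), None, dtype=object)
    for (i, j), t in classify_pairs(graph).items():
        M[i, j] = M[j, i] = t
    return M


def _community_symmetries() -> list[tuple[tuple[int, ...], bool]]:
    """The 6 symmetries of the between-community ring (rotations/reflections).

    Each entry is (community permutation, reversed) where ``reversed`` records
    whether ring orientation flips (boundary nodes then swap roles within
    each community).
    """
    syms = []
    for r in range(N_COMMUNITIES):
        rot = tuple((c + r) % N_COMMUNITIES for c in range(N_COMMUNITIES))
        syms.append((rot, False))
        refl = tuple((r - c) % N_COMMUNITIES for c in range(N_COMMUNITIES))
        syms.append((refl, True))
    return syms


def automorphism_group(graph: CommunityGraph) -> list[np.ndarray]:
    """All node permutations preserving adjacency and community structure.

    For the modular graph the group factorizes as (ring symmetries of the
    three communities) × (arbitrary permutations of the three internal nodes
    within each community): 6 × 6³ = 1296 elements.  Each candidate is
    verified against the adjacency matrix before being returned, so the
    construction cannot silently admit a non-automorphism.

    Used to average per-observer object-distance matrices without assuming
    shared activity patterns across observers.
    """
    if graph.name != "modular":
        raise ValueError("automorphism_group is defined for the modular graph only")

    A = graph.adjacency
    internal_local = (1, 2, 3)  # local indices of internal nodes
    boundary_local = (0, 4)

    perms: list[np.ndarray] = []
    internal_perms = list(itertools.permutations(internal_local))
    for comm_perm, reverse in _community_symmetries():
        for ip in itertools.product(internal_perms, repeat=N_COMMUNITIES):
            p = np.empty(N_OBJECTS, dtype=int)
            for c in range(N_COMMUNITIES):
                tc = comm_perm[c]
                # boundary nodes: orientation-preserving maps keep local 0->0,
                # 4->4; orientation-reversing maps swap them
                b_src = boundary_local if not reverse else boundary_local[::-1]
                p[COMMUNITY_SIZE * c + b_src[0]] = COMMUNITY_SIZE * tc + 0
                p[COMMUNITY_SIZE * c + b_src[1]] = COMMUNITY_SIZE * tc + 4
                for k, loc in enumerate(internal_local):
                    p[COMMUNITY_SIZE * c + loc] = COMMUNITY_SIZE * tc + ip[c][k]
            if _preserves(A, p):
                perms.append(p)
    if len(perms) != 1296:
        raise RuntimeError(
            f"automorphism construction yielded {len(perms)} elements, expected 1296"
        )
    return perms


def _preserves(A: np.ndarray, p: np.ndarray) -> bool:
    """True if permutation p (p[i] = image of node i) preserves adjacency."""
    return bool(np.array_equal(A[np.ix_(p, p)], A))
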