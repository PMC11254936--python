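"""Network topologies for coupled dynamical systems.

The adjacency convention throughout the package is ``A[i, j]`` = influence of
node *j* on node *i* (receiver-first).  Links may carry signs through per-link
type labels (``"excitatory"`` / ``"inhibitory"``), inherited from the type of
the *source* node, as in signed neuronal networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"


@dataclass
class NetworkTopology:
    """A directed, optionally signed or weighted network.

    Attributes
    ----------
    n : int
        Node count.
    A : ndarray of shape (n, n)
        Real adjacency matrix, zero diagonal. ``A[i, j]`` couples node j into
        node i.
    link_types : ndarray of shape (n, n) of str, or None
        Per-link labels; empty string where there is no link.  When present,
        every nonzero ``A[i, j]`` carries a label.
    directed : bool
    node_ids : list of str
    """

    n: int
    A: np.ndarray
    link_types: np.ndarray | None = None
    directed: bool = True
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (self.n, self.n):
            raise ValueError(f"adjacency shape {self.A.shape} != ({self.n}, {self.n})")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("adjacency contains non-finite entries")
        if np.any(np.diag(self.A) != 0.0):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if not self.node_ids:
            self.node_ids = [f"n{i}" for i in range(self.n)]
        if len(self.node_ids) != self.n:
            raise ValueError("node_ids length mismatch")
        if self.link_types is not None:
            self.link_types = np.asarray(self.link_types, dtype=object)
            missing = (self.A != 0) & (self.link_types == "")
            if np.any(missing):
                raise ValueError("every nonzero link needs a type label")

    @property
    def types_present(self) -> list[str]:
        """Distinct link-type labels in use (sorted), or [] if untyped."""
        if self.link_types is None:
            return []
        labels = set(self.link_types[self.A != 0].tolist())
        return sorted(labels)

    def edges(self, link_type: str | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (receiver, sender, weight) arrays, optionally of one type."""
        mask = self.A != 0
        if link_type is not None:
            if self.link_types is None:
                raise ValueError("network has no link types")
            mask &= self.link_types == link_type
        recv, send = np.nonzero(mask)
        return recv, send, self.A[recv, send]


def generate_network(
    kind: str,
    n: int,
    density: float = 0.15,
    seed: int = 0,
) -> NetworkTopology:
    """Generate a random directed network.

    kind:
      ``"signed"``   -- unit weights; exactly floor(n/2) nodes are excitatory and
                        the rest inhibitory; each outgoing link is labelled by its
                        source node's type.
      ``"weighted"`` -- nonzero weights i.i.d. uniform on the open interval (0, 1).
      ``"binary"``   -- 0/1 weights.

    Links are drawn as a directed Erdos-Renyi graph with the given density
    (self-loops excluded).  Reproducible under a fixed seed.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    if kind not in ("signed", "weighted", "binary"):
        raise ValueError(f"unknown network kind {kind!r}")
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < density
    np.fill_diagonal(mask, False)
    # guarantee every node receives at least one link so its interaction term
    # is observable in the activity data
    for i in range(n):
        if not mask[i].any():
            j = int(rng.integers(n - 1))
            mask[i, j + (j >= i)] = True
    A = mask.astype(float)
    link_types = None
    if kind == "weighted":
        w = rng.uniform(0.0, 1.0, size=(n, n))
        w[w == 0.0] = 0.5  # keep weights strictly inside (0, 1)
        A = np.where(mask, w, 0.0)
    elif kind == "signed":
        node_type = np.array([INHIBITORY] * n, dtype=object)
        exc = rng.permutation(n)[: n // 2]
        node_type[exc] = EXCITATORY
        link_types = np.full((n, n), "", dtype=object)
        recv, send = np.nonzero(mask)
        link_types[recv, send] = node_type[send]
    return NetworkTopology(n=n, A=A, link_types=link_types, directed=True)


# ---------------------------------------------------------------------------
# adjacency I/O: dense CSV (header = node ids) and 3-column edge lists
# ---------------------------------------------------------------------------

def write_adjacency_csv(topo: NetworkTopology, path: str) -> None:
    df = pd.DataFrame(topo.A, index=topo.node_ids, columns=topo.node_ids)
    df.to_csv(path)


def read_adjacency_csv(path: str) -> NetworkTopology:
    df = pd.read_csv(path, index_col=0)
    A = df.to_numpy(dtype=float)
    return NetworkTopology(n=A.shape[0], A=A, node_ids=[str(c) for c in df.columns])


def write_edge_list(topo: NetworkTopology, path: str) -> None:
    recv, send, w = topo.edges()
    rows = {"src": [topo.node_ids[j] for j in send],
            "dst": [topo.node_ids[i] for i in recv],
            "weight": w}
    if topo.link_types is not None:
        rows["type"] = [topo.link_types[i, j] for i, j in zip(recv, send)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_edge_list(path: str, node_ids: list[str] | None = None) -> NetworkTopology:
    df = pd.read_csv(path)
    if node_ids is None:
        node_ids = sorted(set(df["src"].astype(str)) | set(df["dst"].astype(str)))
    index = {v: k for k, v in enumerate(node_ids)}
    n = len(node_ids)
    A = np.zeros((n, n))
    link_types = np.full((n, n), "", dtype=object) if "type" in df.columns else None
    for _, row in df.iterrows():
        i, j = index[str(row["dst"])], index[str(row["src"])]
        A[i, j] = float(row["weight"])
        if link_types is not None:
            link_types[i, j] = str(row["type"])
    return NetworkTopology(n=n, A=A, link_types=link_types, node_ids=list(node_ids))
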