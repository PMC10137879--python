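"""Cohort-graph construction: similarity kernel, adjacency, propagation operator.

Subjects are nodes; the weighted edge between subjects i and j is a
Gaussian kernel of the Euclidean distance between their vectorized
connectomes,

    W_ij = exp(-d(f_i, f_j)^2 / (2 sigma^2)),

so identical connectomes get weight 1 and the weight decays to 0 with
distance, at a rate set by the coefficient sigma.  The graph is fully
connected (every off-diagonal pair receives a kernel weight).  Each GCN
layer propagates node features with the renormalized operator

    S = D~^{-1/2} (A + I) D~^{-1/2},

the first-order approximation to spectral graph convolution, where D~ is
the degree matrix of A + I.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .connectome import CohortManifest, FeatureVector

#: Kernel-coefficient grid searched when optimizing graph construction.
SIGMA_GRID = (0.7, 1.0, 1.3, 1.6, 1.9, 2.2)
#: Published optimum for the motor-outcome cohort.
DEFAULT_SIGMA = 1.6

KERNELS = ("gaussian", "exp_distance")


class GraphError(ValueError):
    """Invalid graph construction input."""


def edge_weight(
    f_i: np.ndarray, f_j: np.ndarray, sigma: float, kernel: str = "gaussian"
) -> float:
    """Similarity weight between two subjects' feature vectors.

    ``gaussian`` is exp(-d^2 / (2 sigma^2)); ``exp_distance`` is the
    alternative exp(-d / (2 sigma^2)).  Both are symmetric, lie in (0, 1],
    equal 1 iff d == 0, and decrease strictly with distance.
    """
    if sigma <= 0:
        raise GraphError(f"sigma must be positive, got {sigma}")
    f_i = np.asarray(f_i, dtype=float).ravel()
    f_j = np.asarray(f_j, dtype=float).ravel()
    if f_i.shape != f_j.shape:
        raise GraphError(f"feature vectors differ in length: {f_i.size} vs {f_j.size}")
    d = float(np.linalg.norm(f_i - f_j))
    return _kernel_of_distance(d, sigma, kernel)


def _kernel_of_distance(d, sigma: float, kernel: str):
    if kernel == "gaussian":
        return np.exp(-(np.asarray(d) ** 2) / (2.0 * sigma**2))
    if kernel == "exp_distance":
        return np.exp(-np.asarray(d) / (2.0 * sigma**2))
    raise GraphError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")


def kernel_matrix(X: np.ndarray, sigma: float, kernel: str = "gaussian") -> np.ndarray:
    """Pairwise kernel adjacency of the rows of X; symmetric, zero diagonal."""
    if sigma <= 0:
        raise GraphError(f"sigma must be positive, got {sigma}")
    D = squareform(pdist(np.asarray(X, dtype=float), metric="euclidean"))
    A = np.asarray(_kernel_of_distance(D, sigma, kernel), dtype=float)
    np.fill_diagonal(A, 0.0)
    return A


def propagation_operator(A: np.ndarray) -> np.ndarray:
    """Renormalized operator S = D~^{-1/2} (A + I) D~^{-1/2}.

    Self-loops contribute exactly 1 (A's diagonal is required to be zero),
    every row of A + I has positive degree, and all eigenvalues of S lie
    in [-1, 1].
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise GraphError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T, rtol=0, atol=1e-10):
        raise GraphError("adjacency matrix is not symmetric")
    if np.any(A < 0):
        raise GraphError("adjacency matrix has negative weights")
    A_tilde = A.copy()
    np.fill_diagonal(A_tilde, 0.0)
    A_tilde += np.eye(A.shape[0])
    deg = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return A_tilde * np.outer(inv_sqrt, inv_sqrt)


@dataclass
class PopulationGraph:
    """The cohort graph fed to the GCN.

    ``X`` holds one feature row per subject, ``A`` the kernel adjacency and
    ``S`` the renormalized propagation operator.  ``y`` carries integer
    labels (positive=1, negative=0, unlabeled=-1); the boolean masks
    ``train_labeled`` / ``test_labeled`` / ``unlabeled`` are disjoint and
    cover all nodes.  Labels of test and unlabeled nodes are never read
    during training (transductive contract).
    """

    X: np.ndarray
    A: np.ndarray
    S: np.ndarray
    sigma: float
    node_ids: list[str]
    y: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        for name in ("X", "A", "S"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise GraphError(f"{name} has {arr.shape[0]} rows for {n} nodes")
        required = {"train_labeled", "test_labeled", "unlabeled"}
        if set(self.masks) != required:
            raise GraphError(f"masks must be exactly {sorted(required)}")
        total = np.zeros(n, dtype=int)
        for m in self.masks.values():
            total += np.asarray(m, dtype=bool)
        if not np.all(total == 1):
            raise GraphError("masks must be disjoint and cover all nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def with_masks(
        self, train_idx: Sequence[int], test_idx: Sequence[int]
    ) -> "PopulationGraph":
        """Same graph, new labeled train/test split; unlabeled nodes keep their mask."""
        n = self.n_nodes
        train = np.zeros(n, dtype=bool)
        test = np.zeros(n, dtype=bool)
        train[list(train_idx)] = True
        test[list(test_idx)] = True
        unlabeled = ~(train | test)
        return replace(
            self, masks={"train_labeled": train, "test_labeled": test, "unlabeled": unlabeled}
        )


def build_graph(
    features: Sequence[FeatureVector],
    manifest: CohortManifest,
    sigma: float = DEFAULT_SIGMA,
    kernel: str = "gaussian",
    standardize: bool = False,
    test_ids: Sequence[str] = (),
) -> PopulationGraph:
    """Assemble the fully connected cohort graph from per-subject features.

    Features and manifest must cover the same subject ids; node order
    follows the manifest.  Labeled subjects listed in ``test_ids`` get the
    test mask; remaining labeled subjects are training nodes.  With
    ``standardize`` each feature column is z-scored before the distance
    (default off: raw mean-FA weights enter the kernel unscaled).
    """
    if len(manifest) < 2:
        raise GraphError("need at least 2 subjects to build a cohort graph")
    by_id = {f.subject_id: f for f in features}
    if len(by_id) != len(features):
        raise GraphError("duplicate subject ids in features")
    feat_ids, man_ids = set(by_id), set(manifest.subject_ids)
    if feat_ids != man_ids:
        raise GraphError(
            "feature/manifest subject mismatch: "
            f"missing features for {sorted(man_ids - feat_ids)}, "
            f"extra features for {sorted(feat_ids - man_ids)}"
        )
    ordered = [by_id[sid] for sid in manifest.subject_ids]
    lengths = {f.values.size for f in ordered}
    if len(lengths) > 1:
        raise GraphError(f"inconsistent feature lengths: {sorted(lengths)}")
    X = np.vstack([f.values for f in ordered])
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    A = kernel_matrix(X, sigma, kernel)
    S = propagation_operator(A)

    y = manifest.y
    test = np.zeros(len(manifest), dtype=bool)
    unknown = set(test_ids) - man_ids
    if unknown:
        raise GraphError(f"test_ids not in cohort: {sorted(unknown)}")
    id_pos = {sid: i for i, sid in enumerate(manifest.subject_ids)}
    for sid in test_ids:
        if y[id_pos[sid]] < 0:
            raise GraphError(f"test subject {sid!r} is unlabeled")
        test[id_pos[sid]] = True
    labeled = y >= 0
    masks = {
        "train_labeled": labeled & ~test,
        "test_labeled": test,
        "unlabeled": ~labeled,
    }
    return PopulationGraph(
        X=X, A=A, S=S, sigma=float(sigma), node_ids=manifest.subject_ids, y=y, masks=masks
    )


def write_graph(graph: PopulationGraph, out_dir: str | Path) -> Path:
    """Export adjacency (CSV), edge list (TSV) and masks (CSV) for inspection."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "adjacency.csv", graph.A, delimiter=",", fmt="%.10g")
    n = graph.n_nodes
    with open(out_dir / "edges.tsv", "w") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        for i in range(n):
            for j in range(i + 1, n):
                fh.write(f"{graph.node_ids[i]}\t{graph.node_ids[j]}\t{graph.A[i, j]:.10g}\n")
    with open(out_dir / "masks.csv", "w") as fh:
        fh.write("subject_id,train_labeled,test_labeled,unlabeled\n")
        for i, sid in enumerate(graph.node_ids):
            cols = ",".join(str(int(graph.masks[k][i])) for k in ("train_labeled", "test_labeled", "unlabeled"))
            fh.write(f"{sid},{cols}\n")
    return out_dir
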