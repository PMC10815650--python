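"""Consensus clustering over restarted KL-NMF runs and rank selection.

Because multiplicative-update NMF converges to a seed-dependent local
optimum, cluster membership is assessed over many seeded restarts: the
consensus matrix ``C`` holds, for every sample pair, the fraction of runs in
which the pair landed in the same cluster.  A stable rank produces a
near-binary ``C`` whose induced distances ``Y = 1 - C`` are almost
ultrametric; the cophenetic correlation coefficient

    c = sum_{i<j} (Y_ij - ybar)(Z_ij - zbar)
        / sqrt( sum (Y_ij - ybar)^2 * sum (Z_ij - zbar)^2 )

between ``Y`` and the dendrogram (cophenetic) distances ``Z`` of its
average-linkage tree quantifies that stability; the rank with the largest
coefficient is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .nmf import KLNMF

__all__ = [
    "ConsensusNMF",
    "ConsensusResults",
    "RankSelection",
    "consensus_cluster",
    "cophenetic_coefficient",
    "select_rank",
    "kmeans_silhouette",
    "adjusted_rand_index",
]


def cophenetic_coefficient(C: np.ndarray) -> float:
    """Cophenetic correlation of a consensus matrix.

    ``Y_ij = 1 - C_ij`` for i<j is clustered by average linkage; the returned
    value is the Pearson-form correlation between the Y distances and the
    cophenetic distances of the resulting dendrogram, in [-1, 1].

    Raises
    ------
    ValueError
        If ``C`` is not a valid consensus matrix, has fewer than 3 samples,
        or all off-diagonal entries are equal (zero variance: the
        correlation is undefined).
    """
    C = np.asarray(C, dtype=float)
    m = C.shape[0]
    if C.ndim != 2 or C.shape[1] != m:
        raise ValueError("consensus matrix must be square")
    if m < 3:
        raise ValueError("need at least 3 samples")
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("consensus matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-12):
        raise ValueError("consensus diagonal must be 1")
    if C.min() < -1e-12 or C.max() > 1 + 1e-12:
        raise ValueError("consensus entries must lie in [0, 1]")
    Y = squareform(1.0 - C, checks=False)
    if np.ptp(Y) == 0:
        raise ValueError(
            "all off-diagonal consensus entries are equal; "
            "cophenetic correlation undefined"
        )
    Z = hierarchy.cophenet(hierarchy.linkage(Y, method="average"))
    yc = Y - Y.mean()
    zc = Z - Z.mean()
    denom = np.sqrt(np.sum(yc**2) * np.sum(zc**2))
    if denom == 0:
        raise ValueError("zero variance in dendrogram distances")
    return float(np.sum(yc * zc) / denom)


@dataclass
class ConsensusResults:
    """Consensus of ``n_runs`` seeded factorizations at one rank."""

    model: "ConsensusNMF"
    rank: int
    consensus_matrix: np.ndarray
    run_labels: np.ndarray  # (n_runs, n_samples)
    n_runs: int
    base_seed: int

    _cophenetic: float | None = field(default=None, repr=False)

    @property
    def cophenetic(self) -> float:
        if self._cophenetic is None:
            self._cophenetic = cophenetic_coefficient(self.consensus_matrix)
        return self._cophenetic

    def labels(self) -> np.ndarray:
        """Consensus sample labels: average-linkage cut of 1 - C into k groups."""
        Y = squareform(1.0 - self.consensus_matrix, checks=False)
        link = hierarchy.linkage(Y, method="average")
        return hierarchy.fcluster(link, t=self.rank, criterion="maxclust") - 1

    def summary(self) -> str:
        try:
            c = f"{self.cophenetic:.4f}"
        except ValueError:
            c = "undefined (constant consensus)"
        sizes = np.bincount(self.labels()).tolist()
        return "\n".join(
            [
                "Consensus KL-NMF clustering",
                "===========================",
                f"rank:                  {self.rank}",
                f"restarts:              {self.n_runs} (seeds {self.base_seed}..{self.base_seed + self.n_runs - 1})",
                f"cophenetic coefficient: {c}",
                f"consensus cluster sizes: {sizes}",
            ]
        )

    def plot_consensus(self, ax=None):
        """Heatmap of the consensus matrix, samples ordered by the dendrogram."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        Y = squareform(1.0 - self.consensus_matrix, checks=False)
        order = hierarchy.leaves_list(hierarchy.linkage(Y, method="average"))
        im = ax.imshow(self.consensus_matrix[np.ix_(order, order)], vmin=0, vmax=1)
        ax.set_xlabel("sample")
        ax.set_ylabel("sample")
        ax.set_title(f"consensus, rank {self.rank}")
        ax.figure.colorbar(im, ax=ax, label="co-clustering frequency")
        return ax


@dataclass
class ConsensusNMF:
    """Consensus clustering model: restarted KL-NMF at a fixed rank.

    Each restart uses seed ``base_seed + run`` and contributes one argmax
    labeling; ``C[u, v]`` is the fraction of runs placing u and v together,
    so every entry is a multiple of ``1/n_runs``.
    """

    A: np.ndarray
    rank: int
    n_runs: int = 50
    max_iter: int = 2000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        # validates A and the rank range
        self._nmf = KLNMF(self.A, self.rank, max_iter=self.max_iter, tol=self.tol)

    def fit(self, base_seed: int = 0) -> ConsensusResults:
        m = self._nmf.A.shape[1]
        labels = np.empty((self.n_runs, m), dtype=int)
        C = np.zeros((m, m))
        for run in range(self.n_runs):
            lab = self._nmf.fit(seed=base_seed + run).labels()
            labels[run] = lab
            C += lab[:, None] == lab[None, :]
        C /= self.n_runs
        return ConsensusResults(
            model=self,
            rank=self.rank,
            consensus_matrix=C,
            run_labels=labels,
            n_runs=self.n_runs,
            base_seed=base_seed,
        )


def consensus_cluster(
    A: np.ndarray,
    k: int,
    n_runs: int = 50,
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ConsensusResults:
    """Functional shorthand for ``ConsensusNMF(...).fit(base_seed)``."""
    return ConsensusNMF(A, k, n_runs=n_runs, max_iter=max_iter, tol=tol).fit(base_seed)


@dataclass
class RankSelection:
    """Cophenetic coefficients across candidate ranks and the chosen rank.

    The chosen rank attains the maximum coefficient; ties break to the
    smallest rank.
    """

    ranks: list[int]
    coefficients: dict[int, float]
    chosen: int
    results: dict[int, ConsensusResults]

    def summary(self) -> str:
        lines = ["Rank selection by cophenetic coefficient", "=" * 40]
        for k in self.ranks:
            mark = "  <- chosen" if k == self.chosen else ""
            lines.append(f"rank {k}: c = {self.coefficients[k]:.4f}{mark}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Cophenetic coefficient against rank."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ranks, [self.coefficients[k] for k in self.ranks], "o-")
        ax.axvline(self.chosen, ls="--", color="grey")
        ax.set_xlabel("rank")
        ax.set_ylabel("cophenetic coefficient")
        ax.set_xticks(self.ranks)
        return ax


def select_rank(
    A: np.ndarray,
    ranks: list[int],
    n_runs: int = 50,
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> RankSelection:
    """Consensus-cluster ``A`` at each candidate rank and pick the most stable."""
    if not ranks:
        raise ValueError("ranks must be non-empty")
    coeffs: dict[int, float] = {}
    results: dict[int, ConsensusResults] = {}
    for k in ranks:
        res = consensus_cluster(
            A, k, n_runs=n_runs, base_seed=base_seed, max_iter=max_iter, tol=tol
        )
        results[k] = res
        coeffs[k] = res.cophenetic
    best = max(coeffs.values())
    chosen = min(k for k in ranks if coeffs[k] == best)
    return RankSelection(ranks=list(ranks), coefficients=coeffs, chosen=chosen, results=results)


def kmeans_silhouette(
    A: np.ndarray, k: int, n_restarts: int = 100, seed: int = 0
) -> float:
    """Mean silhouette of the best k-means clustering of the sample columns.

    Used as a model-free robustness check on the NMF cluster number: k-means
    (Euclidean, best of ``n_restarts`` by within-cluster sum of squares) is
    run on the same matrix given to the factorization.
    """
    A = np.asarray(A, dtype=float)
    m = A.shape[1]
    if k < 2:
        raise ValueError("silhouette requires k >= 2")
    if k >= m:
        raise ValueError(f"k must be < number of samples ({m})")
    X = A.T
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    return float(silhouette_score(X, km.labels_, metric="euclidean"))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement of two partitions (1 = identical)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    if labels_a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(adjusted_rand_score(labels_a, labels_b))
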