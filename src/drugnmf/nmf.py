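"""KL-divergence non-negative matrix factorization with multiplicative updates.

The model approximates a non-negative genes x samples matrix ``A`` by the
product ``W @ H`` of a genes x rank metagene matrix ``W`` and a rank x samples
loading matrix ``H``, minimizing the generalized Kullback-Leibler divergence

    D(A || WH) = sum_ij ( A_ij log(A_ij / (WH)_ij) - A_ij + (WH)_ij )

by the classical multiplicative update rules.  Each sample is assigned to the
metagene with the largest loading, which is what turns the factorization into
a clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-10  # guards every denominator and the log argument

__all__ = ["kl_divergence", "update_step", "assign_clusters", "KLNMF", "KLNMFResults", "nmf_factorize"]


def _check_nonneg(name: str, M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.size and M.min() < 0:
        raise ValueError(f"{name} has negative entries")
    return M


def kl_divergence(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(A || WH), with the 0*log(0) := 0 convention."""
    A = _check_nonneg("A", A)
    W = _check_nonneg("W", W)
    H = _check_nonneg("H", H)
    if W.shape[1] != H.shape[0] or A.shape != (W.shape[0], H.shape[1]):
        raise ValueError(
            f"shape mismatch: A {A.shape}, W {W.shape}, H {H.shape}"
        )
    WH = W @ H
    pos = A > 0
    div = float(np.sum(WH) - np.sum(A))
    div += float(np.sum(A[pos] * np.log(A[pos] / np.maximum(WH[pos], EPS))))
    return div


def update_step(
    A: np.ndarray, W: np.ndarray, H: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative update of W (with current H) then H (with new W).

    The rules are

        W_ia <- W_ia * sum_u H_au A_iu/(WH)_iu / sum_v H_av
        H_au <- H_au * sum_i W_ia A_iu/(WH)_iu / sum_k W_ka

    and never increase D(A || WH).
    """
    A = _check_nonneg("A", A)
    W = _check_nonneg("W", W)
    H = _check_nonneg("H", H)
    if W.shape[1] != H.shape[0] or A.shape != (W.shape[0], H.shape[1]):
        raise ValueError(
            f"shape mismatch: A {A.shape}, W {W.shape}, H {H.shape}"
        )
    R = A / np.maximum(W @ H, EPS)
    W = W * (R @ H.T) / np.maximum(H.sum(axis=1), EPS)
    R = A / np.maximum(W @ H, EPS)
    H = H * (W.T @ R) / np.maximum(W.sum(axis=0), EPS)[:, None]
    return W, H


def assign_clusters(H: np.ndarray) -> np.ndarray:
    """Label each sample (column of H) by its largest metagene loading.

    Ties go to the smallest metagene index, so labels are deterministic.
    """
    H = np.asarray(H, dtype=float)
    if H.size == 0:
        raise ValueError("empty loading matrix")
    if H.min() < 0:
        raise ValueError("H has negative entries")
    return np.argmax(H, axis=0)


@dataclass
class KLNMFResults:
    """Fitted factorization: ``A ~ W @ H`` at the given rank.

    ``divergence_trace`` records D(A||WH) after every full update step and is
    non-increasing; ``converged`` reports whether the relative-change stopping
    rule fired before the iteration cap.
    """

    model: "KLNMF"
    W: np.ndarray
    H: np.ndarray
    rank: int
    divergence_trace: list[float]
    n_iter: int
    seed: int
    converged: bool

    @property
    def divergence(self) -> float:
        return self.divergence_trace[-1]

    def labels(self) -> np.ndarray:
        """Per-sample cluster labels by argmax loading."""
        return assign_clusters(self.H)

    def summary(self) -> str:
        lines = [
            "KL-NMF factorization",
            "====================",
            f"matrix:         {self.model.A.shape[0]} genes x {self.model.A.shape[1]} samples",
            f"rank:           {self.rank}",
            f"seed:           {self.seed}",
            f"iterations:     {self.n_iter} ({'converged' if self.converged else 'iteration cap reached'})",
            f"final D(A||WH): {self.divergence:.6g}",
            f"cluster sizes:  {np.bincount(self.labels(), minlength=self.rank).tolist()}",
        ]
        return "\n".join(lines)


@dataclass
class KLNMF:
    """KL-divergence NMF model for a non-negative matrix at a fixed rank.

    Parameters
    ----------
    A : ndarray (n_genes, n_samples)
        Non-negative data matrix.
    rank : int
        Number of metagenes/clusters, ``1 <= rank <= min(n, m)``.
    max_iter, tol
        The fit iterates multiplicative updates until the relative divergence
        change over a 10-iteration window drops below ``tol`` or ``max_iter``
        steps have run.
    """

    A: np.ndarray
    rank: int
    max_iter: int = 2000
    tol: float = 1e-6
    _window: int = field(default=10, repr=False)

    def __post_init__(self) -> None:
        self.A = _check_nonneg("A", self.A)
        n, m = self.A.shape
        if not 1 <= self.rank <= min(n, m):
            raise ValueError(
                f"rank {self.rank} out of range for a {n}x{m} matrix"
            )

    def fit(self, seed: int = 0) -> KLNMFResults:
        """Run seeded multiplicative updates to (local) convergence.

        W and H start uniform(0, 1) scaled by sqrt(mean(A)/rank) so that the
        initial product is on the scale of the data.
        """
        n, m = self.A.shape
        rng = np.random.default_rng(seed)
        scale = np.sqrt(max(self.A.mean(), EPS) / self.rank)
        W = rng.uniform(size=(n, self.rank)) * scale
        H = rng.uniform(size=(self.rank, m)) * scale
        trace: list[float] = []
        converged = False
        for it in range(1, self.max_iter + 1):
            W, H = update_step(self.A, W, H)
            trace.append(kl_divergence(self.A, W, H))
            if it > self._window:
                prev, cur = trace[-1 - self._window], trace[-1]
                if abs(prev - cur) < self.tol * max(abs(prev), EPS):
                    converged = True
                    break
        return KLNMFResults(
            model=self,
            W=W,
            H=H,
            rank=self.rank,
            divergence_trace=trace,
            n_iter=len(trace),
            seed=seed,
            converged=converged,
        )


def nmf_factorize(
    A: np.ndarray, k: int, seed: int, max_iter: int = 2000, tol: float = 1e-6
) -> KLNMFResults:
    """Functional shorthand for ``KLNMF(A, k, max_iter, tol).fit(seed)``."""
    return KLNMF(A, k, max_iter=max_iter, tol=tol).fit(seed)
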