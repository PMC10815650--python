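"""Synthetic study generators with planted ground truth.

Everything the pipeline consumes can be generated here with a seed, so no
download is ever required: a non-negative genes x samples matrix with k
planted sample clusters (for the factorization branch), a two-class
normal/tumor matrix with planted differentially expressed genes (for the
feature-selection branch), drug labels with replicates, and a toy
drug-interaction edge table.

Default dimensions emulate the PC3 drug-induced profiling setting this
package targets: 12 normal and 44 drug-induced tumor samples, 38 unique
drugs (6 drugs with 2 replicate samples each), and a gene space collapsed to
9,357 symbols.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionStudy, write_expression
from .interactions import canonical_pair

# Study-scale defaults
DEFAULT_N_GENES = 9357
DEFAULT_N_NORMAL = 12
DEFAULT_N_TUMOR = 44
DEFAULT_N_REPLICATE_DRUGS = 6  # 38 unique drugs across 44 tumor samples

CLUSTER_BOOST = 5.0  # added to a sample's own-cluster loading in H*

__all__ = [
    "SyntheticStudy",
    "make_nmf_study",
    "make_two_class_study",
    "make_interaction_edges",
    "make_drug_assignment",
]


@dataclass
class SyntheticStudy:
    """A generated expression study together with its planted truth."""

    expression: ExpressionStudy
    true_sample_labels: list[int]
    true_de_genes: set[str] = field(default_factory=set)
    true_edges: pd.DataFrame | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)
    true_W: np.ndarray | None = None  # ground-truth factors (planted-cluster
    true_H: np.ndarray | None = None  # generator only)

    def __post_init__(self) -> None:
        if len(self.true_sample_labels) != self.expression.n_samples:
            raise ValueError("label list length != number of samples")
        missing = self.true_de_genes - set(self.expression.gene_ids)
        if missing:
            raise ValueError(f"planted DE genes not in expression: {sorted(missing)[:5]}")

    def write(self, prefix: str) -> dict[str, str]:
        """Write expression/metadata/edges as TSV and the truth as JSON.

        Returns the mapping of artifact name to path.
        """
        paths = {
            "expression": f"{prefix}.expression.tsv",
            "metadata": f"{prefix}.metadata.tsv",
            "truth": f"{prefix}.truth.json",
        }
        write_expression(self.expression, paths["expression"], paths["metadata"])
        if self.true_edges is not None:
            paths["edges"] = f"{prefix}.edges.tsv"
            self.true_edges.to_csv(paths["edges"], sep="\t", index=False)
        truth = {
            "true_sample_labels": list(map(int, self.true_sample_labels)),
            "true_de_genes": sorted(self.true_de_genes),
            "seed": self.seed,
            "params": self.params,
        }
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2)
        return paths


def make_drug_assignment(
    n_tumor: int, n_replicate_drugs: int = DEFAULT_N_REPLICATE_DRUGS, prefix: str = "drug"
) -> list[str]:
    """Assign a drug name to each tumor sample.

    The first ``n_replicate_drugs`` drugs receive two replicate samples each;
    every remaining sample gets its own drug, mirroring a library in which a
    few compounds are profiled in duplicate.
    """
    if not 0 <= 2 * n_replicate_drugs <= n_tumor:
        raise ValueError("n_replicate_drugs inconsistent with n_tumor")
    drugs: list[str] = []
    d = 0
    for _ in range(n_replicate_drugs):
        d += 1
        drugs += [f"{prefix}_{d:03d}"] * 2
    while len(drugs) < n_tumor:
        d += 1
        drugs.append(f"{prefix}_{d:03d}")
    return drugs


def make_nmf_study(
    n_genes: int = 200,
    n_samples: int = DEFAULT_N_TUMOR,
    k: int = 2,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_replicate_drugs: int = DEFAULT_N_REPLICATE_DRUGS,
) -> SyntheticStudy:
    """Non-negative matrix with k planted sample clusters.

    Ground-truth factors W* (uniform(0,1)) and H* (uniform(0,1)) are drawn,
    then each sample's own-cluster entry of H* is boosted by +5 so cluster
    structure lives in the sample loadings, matching the factorization model
    under test.  ``A = W* H* + noise`` with Gaussian noise of sd ``noise_sd``
    and the result truncated at zero; cluster labels are balanced
    round-robin (sample u belongs to cluster u mod k).  All tumor samples
    carry drug names via :func:`make_drug_assignment`.
    """
    if n_genes < 1 or n_samples < 1:
        raise ValueError("dimensions must be positive")
    if not 1 <= k <= n_samples:
        raise ValueError(f"k={k} must satisfy 1 <= k <= n_samples={n_samples}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    labels = [u % k for u in range(n_samples)]
    W = rng.uniform(size=(n_genes, k))
    H = rng.uniform(size=(k, n_samples))
    H[labels, np.arange(n_samples)] += CLUSTER_BOOST
    A = W @ H
    if noise_sd > 0:
        A = A + rng.normal(scale=noise_sd, size=A.shape)
    A = np.maximum(A, 0.0)
    n_rep = n_replicate_drugs if 2 * n_replicate_drugs <= n_samples else 0
    study = ExpressionStudy(
        values=A,
        gene_ids=[f"gene_{i:05d}" for i in range(n_genes)],
        sample_ids=[f"sample_{u:03d}" for u in range(n_samples)],
        sample_class=["tumor"] * n_samples,
        sample_drug=make_drug_assignment(n_samples, n_rep),
    )
    return SyntheticStudy(
        expression=study,
        true_sample_labels=labels,
        seed=seed,
        true_W=W,
        true_H=H,
        params={
            "generator": "make_nmf_study",
            "n_genes": n_genes,
            "n_samples": n_samples,
            "k": k,
            "noise_sd": noise_sd,
            "n_replicate_drugs": n_rep,
        },
    )


def make_two_class_study(
    n_genes: int = DEFAULT_N_GENES,
    n_de: int = 30,
    effect: float = 3.0,
    n_norm: int = DEFAULT_N_NORMAL,
    n_tumor: int = DEFAULT_N_TUMOR,
    seed: int = 0,
    n_replicate_drugs: int = DEFAULT_N_REPLICATE_DRUGS,
) -> SyntheticStudy:
    """Two-class (normal/tumor) matrix with ``n_de`` planted DE genes.

    Background expression is Normal(mean 8, sd 1) truncated at zero — the
    scale of log2 microarray intensities.  For the planted genes the tumor
    mean is shifted by ``effect`` standard deviations.  Tumor samples carry
    drug names; class labels are recorded in the study metadata.
    """
    if not 0 <= n_de <= n_genes:
        raise ValueError("need 0 <= n_de <= n_genes")
    if n_norm < 2 or n_tumor < 2:
        raise ValueError("each class needs at least 2 samples")
    rng = np.random.default_rng(seed)
    m = n_norm + n_tumor
    values = rng.normal(loc=8.0, scale=1.0, size=(n_genes, m))
    de_rows = rng.choice(n_genes, size=n_de, replace=False)
    values[np.ix_(de_rows, np.arange(n_norm, m))] += effect
    values = np.maximum(values, 0.0)
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    n_rep = n_replicate_drugs if 2 * n_replicate_drugs <= n_tumor else 0
    study = ExpressionStudy(
        values=values,
        gene_ids=gene_ids,
        sample_ids=[f"normal_{u:02d}" for u in range(n_norm)]
        + [f"tumor_{u:02d}" for u in range(n_tumor)],
        sample_class=["normal"] * n_norm + ["tumor"] * n_tumor,
        sample_drug=[None] * n_norm + make_drug_assignment(n_tumor, n_rep),
    )
    return SyntheticStudy(
        expression=study,
        true_sample_labels=[0] * n_norm + [1] * n_tumor,
        true_de_genes={gene_ids[i] for i in de_rows},
        seed=seed,
        params={
            "generator": "make_two_class_study",
            "n_genes": n_genes,
            "n_de": n_de,
            "effect": effect,
            "n_norm": n_norm,
            "n_tumor": n_tumor,
            "n_replicate_drugs": n_rep,
        },
    )


def make_interaction_edges(
    drugs: list[str],
    p_edge: float,
    gene_pool: list[str],
    seed: int = 0,
    source: str = "synthetic",
) -> pd.DataFrame:
    """Toy drug-interaction edge table: Erdos-Renyi over unordered drug pairs.

    Each pair is kept independently with probability ``p_edge``; a kept edge
    receives 1-5 common target genes sampled without replacement from
    ``gene_pool``.  No self-edges, no duplicate pairs.
    """
    if len(drugs) < 2:
        raise ValueError("need at least 2 drugs")
    if not 0 <= p_edge <= 1:
        raise ValueError("p_edge must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    pool = list(gene_pool)
    for i in range(len(drugs)):
        for j in range(i + 1, len(drugs)):
            if rng.uniform() < p_edge:
                a, b = canonical_pair(drugs[i], drugs[j])
                n_common = int(rng.integers(1, 6)) if pool else 0
                genes = (
                    rng.choice(pool, size=min(n_common, len(pool)), replace=False)
                    if pool
                    else []
                )
                rows.append(
                    {
                        "drug_a": a,
                        "drug_b": b,
                        "common_genes": ",".join(sorted(map(str, genes))),
                        "source": source,
                    }
                )
    return pd.DataFrame(rows, columns=["drug_a", "drug_b", "common_genes", "source"])
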