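"""Drug-drug interaction mapping onto expression-derived clusters.

Interaction evidence arrives as a local tab-separated edge table
(``drug_a``, ``drug_b``, ``common_genes`` comma-joined, ``source``, optional
``score``) — e.g. an export from STITCH or DrugBank's interaction checker.
Live database queries are deliberately excluded: database versions drift,
which breaks reproducibility.

Given a sample clustering, every drug maps to the set of clusters that
contain at least one of its replicate samples (a drug whose replicates split
across clusters keeps multi-cluster membership).  Each interaction edge whose
drugs are both mapped is then flagged ``within`` (the cluster sets share a
cluster) or ``between``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .expression import ExpressionStudy, TUMOR

__all__ = [
    "InteractionEdge",
    "ClusterInteractionReport",
    "canonical_pair",
    "load_edges",
    "edges_from_frame",
    "drug_cluster_map",
    "enumerate_interactions",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order a drug pair lexicographically (case-insensitive key)."""
    a, b = str(a).strip(), str(b).strip()
    return (a, b) if (a.casefold(), a) <= (b.casefold(), b) else (b, a)


@dataclass(frozen=True)
class InteractionEdge:
    """An unordered interacting drug pair with its common target genes."""

    drug_a: str
    drug_b: str
    common_genes: frozenset[str] = frozenset()
    source: str = "other"
    score: float | None = None

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.drug_a, self.drug_b)
        if a.casefold() == b.casefold():
            raise ValueError(f"self-interaction {a!r}")
        object.__setattr__(self, "drug_a", a)
        object.__setattr__(self, "drug_b", b)
        object.__setattr__(
            self, "common_genes", frozenset(g for g in self.common_genes if g)
        )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.drug_a, self.drug_b, self.source)


def _parse_genes(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    return frozenset(g.strip() for g in str(cell).split(",") if g.strip())


def edges_from_frame(frame: pd.DataFrame) -> list[InteractionEdge]:
    """Validate and canonicalize an in-memory edge table.

    Duplicate (pair, source) rows collapse to one edge with the union of
    their gene sets and the maximum score.
    """
    required = {"drug_a", "drug_b"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"edge table missing column(s): {sorted(missing)}")
    merged: dict[tuple, InteractionEdge] = {}
    for rownum, row in enumerate(frame.itertuples(index=False), start=1):
        rec = row._asdict()
        score = rec.get("score")
        if score is not None and pd.isna(score):
            score = None
        try:
            edge = InteractionEdge(
                drug_a=rec["drug_a"],
                drug_b=rec["drug_b"],
                common_genes=_parse_genes(rec.get("common_genes")),
                source=str(rec.get("source") or "other"),
                score=float(score) if score is not None else None,
            )
        except ValueError as exc:
            raise ValueError(f"edge table row {rownum}: {exc}") from None
        prev = merged.get(edge.key)
        if prev is not None:
            scores = [s for s in (prev.score, edge.score) if s is not None]
            edge = InteractionEdge(
                drug_a=edge.drug_a,
                drug_b=edge.drug_b,
                common_genes=prev.common_genes | edge.common_genes,
                source=edge.source,
                score=max(scores) if scores else None,
            )
        merged[edge.key] = edge
    return sorted(merged.values(), key=lambda e: e.key)


def load_edges(path: str, min_score: float | None = None) -> list[InteractionEdge]:
    """Read a tab-separated edge table; optionally drop edges below a score."""
    frame = pd.read_csv(path, sep="\t", dtype={"drug_a": str, "drug_b": str})
    edges = edges_from_frame(frame)
    if min_score is not None:
        edges = [e for e in edges if e.score is not None and e.score >= min_score]
    return edges


def drug_cluster_map(
    sample_labels, study: ExpressionStudy
) -> dict[str, frozenset[int]]:
    """Map each drug to the set of clusters holding >= 1 of its samples.

    ``sample_labels`` aligns with ``study.sample_ids``.  Samples without a
    class are treated as drug-induced when they carry a drug name; tumor
    samples lacking a drug name are an error.  Multi-cluster membership is
    preserved, never majority-collapsed.
    """
    labels = list(sample_labels)
    if len(labels) != study.n_samples:
        raise ValueError("label list length != number of samples")
    classes = study.sample_class or [None] * study.n_samples
    drugs = study.sample_drug or [None] * study.n_samples
    mapping: dict[str, set[int]] = {}
    for sid, cls, drug, lab in zip(study.sample_ids, classes, drugs, labels):
        if drug is None:
            if cls == TUMOR:
                raise ValueError(f"tumor sample {sid!r} has no drug name")
            continue
        mapping.setdefault(drug, set()).add(int(lab))
    return {d: frozenset(cs) for d, cs in sorted(mapping.items())}


@dataclass
class ClusterInteractionReport:
    """Interaction edges classified as within- or between-cluster."""

    drug_clusters: dict[str, frozenset[int]]
    records: list[dict] = field(default_factory=list)
    unplaced: list[InteractionEdge] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c = {"within": 0, "between": 0, "unplaced": len(self.unplaced)}
        for rec in self.records:
            c[rec["relation"]] += 1
        return c

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug_a": r["edge"].drug_a,
                "drug_b": r["edge"].drug_b,
                "clusters_a": ",".join(map(str, sorted(r["clusters_a"]))),
                "clusters_b": ",".join(map(str, sorted(r["clusters_b"]))),
                "relation": r["relation"],
                "common_genes": ",".join(sorted(r["edge"].common_genes)),
                "source": r["edge"].source,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "drug_a",
                "drug_b",
                "clusters_a",
                "clusters_b",
                "relation",
                "common_genes",
                "source",
            ],
        )

    def summary(self) -> str:
        c = self.counts
        by_source: dict[str, int] = {}
        for r in self.records:
            by_source[r["edge"].source] = by_source.get(r["edge"].source, 0) + 1
        lines = [
            "Cluster interaction report",
            "==========================",
            f"drugs mapped:    {len(self.drug_clusters)}",
            f"within-cluster:  {c['within']}",
            f"between-cluster: {c['between']}",
            f"unplaced edges:  {c['unplaced']}",
        ]
        for src, cnt in sorted(by_source.items()):
            lines.append(f"  source {src}: {cnt}")
        return "\n".join(lines)


def enumerate_interactions(
    drug_clusters: dict[str, frozenset[int]], edges: list[InteractionEdge]
) -> ClusterInteractionReport:
    """Classify each edge by the cluster membership of its two drugs.

    An edge is ``within`` when the drugs share at least one cluster (so a
    drug whose replicates span clusters counts as within for any shared
    cluster) and ``between`` otherwise; edges touching an unmapped drug are
    listed separately as unplaced.  Output order is deterministic:
    (drug_a, drug_b, source).
    """
    report = ClusterInteractionReport(drug_clusters=dict(drug_clusters))
    for edge in sorted(edges, key=lambda e: e.key):
        ca = drug_clusters.get(edge.drug_a)
        cb = drug_clusters.get(edge.drug_b)
        if ca is None or cb is None:
            report.unplaced.append(edge)
            continue
        report.records.append(
            {
                "edge": edge,
                "clusters_a": ca,
                "clusters_b": cb,
                "relation": "within" if ca & cb else "between",
            }
        )
    return report
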