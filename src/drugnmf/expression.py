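"""Expression tables: containers, I/O, probe collapsing and class splitting.

The central container is :class:`ExpressionStudy`, a genes x samples matrix
with per-sample annotations (``normal``/``tumor`` class and, for drug-induced
tumor samples, the inducing drug).  All tabular I/O is plain tab-separated
UTF-8 text with a ``.`` decimal point: a header row of sample ids and a first
column of gene (or probe) ids.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NORMAL = "normal"
TUMOR = "tumor"

__all__ = [
    "ExpressionStudy",
    "read_expression",
    "write_expression",
    "read_probe_map",
    "collapse_probes",
    "make_nonnegative",
    "split_by_class",
]


@dataclass
class ExpressionStudy:
    """A genes x samples expression matrix with sample annotations.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Finite expression values; rows are genes (or probes), columns samples.
    gene_ids, sample_ids : sequences of unique str
        Row and column identifiers.
    sample_class : sequence of {"normal", "tumor"} or None
        Per-sample class; ``None`` when the study carries no class metadata.
    sample_drug : sequence of (str or None) or None
        Inducing drug per sample.  Every tumor sample must name a drug;
        normal samples must not.
    provenance : dict
        Record of transforms applied (e.g. a non-negativity shift).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    sample_class: list[str] | None = None
    sample_drug: list[str | None] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        n, m = self.values.shape
        if n != len(self.gene_ids):
            raise ValueError(
                f"row count {n} != number of gene ids {len(self.gene_ids)}"
            )
        if m != len(self.sample_ids):
            raise ValueError(
                f"column count {m} != number of sample ids {len(self.sample_ids)}"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.sample_class is not None:
            if len(self.sample_class) != m:
                raise ValueError("sample_class length mismatch")
            bad_cls = set(self.sample_class) - {NORMAL, TUMOR}
            if bad_cls:
                raise ValueError(f"unknown sample class(es): {sorted(bad_cls)}")
            drugs = self.sample_drug or [None] * m
            for sid, cls, drug in zip(self.sample_ids, self.sample_class, drugs):
                if cls == TUMOR and not drug:
                    raise ValueError(f"tumor sample {sid!r} has no drug name")
                if cls == NORMAL and drug:
                    raise ValueError(f"normal sample {sid!r} has a drug name")

    # -- convenience ------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def metadata_frame(self) -> pd.DataFrame:
        m = self.n_samples
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "class": self.sample_class if self.sample_class is not None else [""] * m,
                "drug": [d or "" for d in (self.sample_drug or [None] * m)],
            }
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionStudy":
        """Row-subset the study to ``gene_ids``, preserving the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"gene ids not in study: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return replace(self, values=self.values[rows], gene_ids=list(gene_ids))

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionStudy":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"sample ids not in study: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return replace(
            self,
            values=self.values[:, cols],
            sample_ids=list(sample_ids),
            sample_class=[self.sample_class[c] for c in cols]
            if self.sample_class is not None
            else None,
            sample_drug=[self.sample_drug[c] for c in cols]
            if self.sample_drug is not None
            else None,
        )


def _parse_matrix(text: str, path: str) -> tuple[np.ndarray, list[str], list[str]]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected a header row and at least one gene row")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(sample_ids) + 1:
            raise ValueError(
                f"{path}: line {lineno} has {len(parts) - 1} values, "
                f"expected {len(sample_ids)}"
            )
        gene_ids.append(parts[0])
        row = []
        for col, cell in zip(sample_ids, parts[1:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at gene {parts[0]!r}, "
                    f"sample {col!r}"
                ) from None
        rows.append(row)
    return np.array(rows, dtype=float), gene_ids, sample_ids


def read_expression(path: str, metadata_path: str | None = None) -> ExpressionStudy:
    """Read a tab-separated genes x samples matrix, optionally with metadata.

    The metadata companion is a tab-separated table with columns
    ``sample_id``, ``class`` and ``drug`` (empty drug for normals).
    """
    with open(path, encoding="utf-8") as fh:
        values, gene_ids, sample_ids = _parse_matrix(fh.read(), str(path))
    sample_class = sample_drug = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
        meta = meta.set_index("sample_id")
        missing = [s for s in sample_ids if s not in meta.index]
        if missing:
            raise ValueError(f"metadata missing sample(s): {missing[:5]}")
        sample_class = [meta.loc[s, "class"] for s in sample_ids]
        sample_drug = [meta.loc[s, "drug"] or None for s in sample_ids]
    return ExpressionStudy(values, gene_ids, sample_ids, sample_class, sample_drug)


def write_expression(
    study: ExpressionStudy, path: str, metadata_path: str | None = None
) -> None:
    """Write the matrix (and optionally metadata) as tab-separated text.

    Values are written in ``repr`` precision so a read round-trips exactly.
    """
    buf = io.StringIO()
    buf.write("gene_id\t" + "\t".join(study.sample_ids) + "\n")
    for gid, row in zip(study.gene_ids, study.values):
        buf.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
    if metadata_path is not None:
        study.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def read_probe_map(path: str) -> dict[str, str]:
    """Read a two-column tab-separated probe_id -> gene_symbol map.

    A missing/empty symbol marks an unannotated probe; duplicate probe ids
    are an error.
    """
    mapping: dict[str, str] = {}
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    probe_col, symbol_col = frame.columns[:2]
    for _, row in frame.iterrows():
        probe = row[probe_col]
        if probe in mapping:
            raise ValueError(f"duplicate probe id {probe!r}")
        mapping[probe] = row[symbol_col]
    return mapping


def collapse_probes(study: ExpressionStudy, probe_map: dict[str, str]) -> ExpressionStudy:
    """Collapse probe rows to unique gene symbols by the maxMean rule.

    For symbols measured by several probes the probe with the highest mean
    across samples is kept; probes without a symbol are dropped.  This is the
    common microarray convention when a collapse rule is not dictated by the
    upstream platform.
    """
    means = study.values.mean(axis=1)
    best: dict[str, int] = {}
    for i, probe in enumerate(study.gene_ids):
        symbol = probe_map.get(probe, "")
        if not symbol:
            continue
        j = best.get(symbol)
        if j is None or means[i] > means[j]:
            best[symbol] = i
    if not best:
        raise ValueError("no probe mapped to a gene symbol; empty result")
    symbols = sorted(best)
    rows = [best[s] for s in symbols]
    return replace(study, values=study.values[rows], gene_ids=symbols)


def make_nonnegative(study: ExpressionStudy) -> ExpressionStudy:
    """Shift the whole matrix so its minimum is zero (no-op if already >= 0).

    A single global shift preserves every within-column difference exactly,
    and keeps one row per gene so feature selection and the factorization
    share a gene space.  The applied shift is recorded in ``provenance``.
    """
    lo = float(study.values.min()) if study.values.size else 0.0
    if lo >= 0:
        return study
    prov = dict(study.provenance)
    prov["nonnegative_shift"] = -lo
    return replace(study, values=study.values - lo, provenance=prov)


def split_by_class(study: ExpressionStudy) -> tuple[ExpressionStudy, ExpressionStudy]:
    """Partition samples into (normal, tumor) studies sharing the gene rows."""
    if study.sample_class is None:
        raise ValueError("study has no sample class metadata")
    normal_ids = [s for s, c in zip(study.sample_ids, study.sample_class) if c == NORMAL]
    tumor_ids = [s for s, c in zip(study.sample_ids, study.sample_class) if c == TUMOR]
    if not normal_ids or not tumor_ids:
        raise ValueError("both classes must be present to split")
    return study.subset_samples(normal_ids), study.subset_samples(tumor_ids)
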