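"""End-to-end pipeline: two branches from expression to interaction report.

Branch ``all_features`` clusters the drug-induced (tumor) samples on the
full gene space: non-negativity transform, consensus KL-NMF over a rank
sweep, consensus labels at the chosen rank, then drug-to-cluster mapping and
interaction enumeration.  Branch ``feature_selected`` first reduces the gene
space to the top genes separating normal from tumor (Fisher or FSV), then
runs the same clustering tail on the reduced tumor matrix.

Every stage seed derives deterministically from the master seed by a fixed
offset, and every written artifact is checksummed into a JSON run manifest,
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .consensus import adjusted_rand_index, select_rank
from .expression import (
    ExpressionStudy,
    collapse_probes,
    make_nonnegative,
    read_expression,
    read_probe_map,
    split_by_class,
)
from .features import fisher_select, fsv_select
from .interactions import drug_cluster_map, enumerate_interactions, load_edges
from .synthetic import make_interaction_edges, make_nmf_study, make_two_class_study

log = logging.getLogger("drugnmf")

# fixed stage offsets from the master seed, recorded in the manifest
SEED_OFFSETS = {"synthetic": 0, "consensus": 1000, "fsv": 2000, "edges": 3000}

__all__ = ["PipelineConfig", "run_pipeline", "compare_clusterings"]


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    Exactly one of ``expression`` (with optional metadata/probe map/edges
    paths) or ``synthetic`` (generator name + parameters) must be supplied.
    """

    branch: str = "all_features"  # all_features | feature_selected | both
    expression: str | None = None
    metadata: str | None = None
    probe_map: str | None = None
    edges: str | None = None
    synthetic: dict | None = None
    feature_method: str = "fisher"  # fisher | fsv
    n_features: int = 30
    ranks: list[int] = field(default_factory=lambda: [2, 3, 4, 5])
    n_runs: int = 50
    seed: int = 0
    out: str = "out"

    def __post_init__(self) -> None:
        if self.branch not in {"all_features", "feature_selected", "both"}:
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.feature_method not in {"fisher", "fsv"}:
            raise ValueError(f"unknown feature method {self.feature_method!r}")
        if (self.expression is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of an expression path or synthetic generator "
                "parameters must be supplied"
            )

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig):
    """Resolve the study and edge table from paths or the generators."""
    edges = None
    if cfg.synthetic is not None:
        params = dict(cfg.synthetic)
        gen = params.pop("generator", "nmf")
        params.setdefault("seed", cfg.seed + SEED_OFFSETS["synthetic"])
        edge_params = params.pop("edges", None)
        if gen == "nmf":
            synth = make_nmf_study(**params)
        elif gen == "two_class":
            synth = make_two_class_study(**params)
        else:
            raise ValueError(f"unknown synthetic generator {gen!r}")
        study = synth.expression
        if edge_params is not None:
            drugs = sorted({d for d in (study.sample_drug or []) if d})
            edge_params = dict(edge_params)
            edge_params.setdefault("seed", cfg.seed + SEED_OFFSETS["edges"])
            edge_params.setdefault("gene_pool", list(study.gene_ids[:50]))
            from .interactions import edges_from_frame

            edges = edges_from_frame(make_interaction_edges(drugs, **edge_params))
    else:
        study = read_expression(cfg.expression, cfg.metadata)
        if cfg.probe_map is not None:
            study = collapse_probes(study, read_probe_map(cfg.probe_map))
        if cfg.edges is not None:
            edges = load_edges(cfg.edges)
    return study, edges


def _clustering_tail(
    study: ExpressionStudy, edges, cfg: PipelineConfig, outdir: Path, tag: str, outputs: dict
):
    """Rank sweep -> consensus labels -> interaction report, writing artifacts."""
    tumor = study
    if study.sample_class is not None and "normal" in study.sample_class:
        _, tumor = split_by_class(study)
    tumor = make_nonnegative(tumor)
    ranks = [k for k in cfg.ranks if k <= tumor.n_samples]
    log.info("[%s] rank sweep %s on %dx%d", tag, ranks, tumor.n_genes, tumor.n_samples)
    selection = select_rank(
        tumor.values, ranks, n_runs=cfg.n_runs, base_seed=cfg.seed + SEED_OFFSETS["consensus"]
    )
    best = selection.results[selection.chosen]
    labels = best.labels()

    rank_path = outdir / f"{tag}.rank_selection.json"
    rank_path.write_text(
        json.dumps(
            {
                "ranks": selection.ranks,
                "cophenetic": {str(k): selection.coefficients[k] for k in selection.ranks},
                "chosen": selection.chosen,
            },
            indent=2,
        )
    )
    outputs[f"{tag}.rank_selection"] = rank_path

    cons_path = outdir / f"{tag}.consensus.tsv"
    pd.DataFrame(
        best.consensus_matrix, index=tumor.sample_ids, columns=tumor.sample_ids
    ).to_csv(cons_path, sep="\t")
    outputs[f"{tag}.consensus"] = cons_path

    clus_path = outdir / f"{tag}.clusters.tsv"
    pd.DataFrame(
        {
            "sample_id": tumor.sample_ids,
            "cluster": labels,
            "drug": [d or "" for d in (tumor.sample_drug or [None] * tumor.n_samples)],
        }
    ).to_csv(clus_path, sep="\t", index=False)
    outputs[f"{tag}.clusters"] = clus_path

    report = None
    if edges is not None and tumor.sample_drug is not None:
        dmap = drug_cluster_map(labels, tumor)
        report = enumerate_interactions(dmap, edges)
        rep_path = outdir / f"{tag}.interactions.tsv"
        report.to_frame().to_csv(rep_path, sep="\t", index=False)
        outputs[f"{tag}.interactions"] = rep_path
        summ_path = outdir / f"{tag}.interactions_summary.json"
        by_source: dict[str, int] = {}
        for r in report.records:
            by_source[r["edge"].source] = by_source.get(r["edge"].source, 0) + 1
        summ_path.write_text(
            json.dumps({"counts": report.counts, "by_source": by_source}, indent=2)
        )
        outputs[f"{tag}.interactions_summary"] = summ_path
    return labels, selection, report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured branch(es); returns artifacts and paths.

    Raises with the failing stage named; artifacts written before the
    failure are flagged partial in the exception message.
    """
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "load_inputs"
    result: dict = {}
    try:
        study, edges = _load_inputs(cfg)
        expr_path = outdir / "expression.tsv"
        meta_path = outdir / "metadata.tsv"
        from .expression import write_expression

        write_expression(study, str(expr_path), str(meta_path))
        outputs["expression"] = expr_path
        outputs["metadata"] = meta_path

        branch_labels: dict[str, np.ndarray] = {}
        study_for_tail = study

        if cfg.branch in {"all_features", "both"}:
            stage = "all_features"
            labels, selection, report = _clustering_tail(
                study_for_tail, edges, cfg, outdir, "all_features", outputs
            )
            branch_labels["all_features"] = labels
            result["all_features"] = {"rank_selection": selection, "report": report}

        if cfg.branch in {"feature_selected", "both"}:
            stage = "feature_selection"
            if study.sample_class is None or "normal" not in study.sample_class:
                raise ValueError(
                    "feature_selected branch needs a two-class (normal/tumor) study"
                )
            base = make_nonnegative(study)
            if cfg.feature_method == "fisher":
                fs = fisher_select(base, cfg.n_features)
            else:
                fs, _ = fsv_select(
                    base, cfg.n_features, seed=cfg.seed + SEED_OFFSETS["fsv"]
                )
            sel_path = outdir / "selected_genes.txt"
            sel_path.write_text("\n".join(fs.selected) + "\n")
            outputs["selected_genes"] = sel_path
            scores_path = outdir / "gene_scores.tsv"
            fs.score_frame().to_csv(scores_path, sep="\t", index=False)
            outputs["gene_scores"] = scores_path
            result["feature_selection"] = fs

            stage = "feature_selected"
            reduced = study.subset_genes(fs.selected)
            labels, selection, report = _clustering_tail(
                reduced, edges, cfg, outdir, "feature_selected", outputs
            )
            branch_labels["feature_selected"] = labels
            result["feature_selected"] = {"rank_selection": selection, "report": report}

        if len(branch_labels) == 2:
            stage = "compare"
            _, tumor = (
                split_by_class(study)
                if study.sample_class is not None and "normal" in study.sample_class
                else (None, study)
            )
            table, ari = compare_clusterings(
                branch_labels["all_features"],
                branch_labels["feature_selected"],
                tumor.sample_drug or [None] * tumor.n_samples,
            )
            cmp_path = outdir / "branch_comparison.tsv"
            table.to_csv(cmp_path, sep="\t", index=False)
            outputs["branch_comparison"] = cmp_path
            result["comparison_ari"] = ari

        stage = "manifest"
        manifest = {
            "config": asdict(cfg),
            "stage_seeds": {k: cfg.seed + off for k, off in SEED_OFFSETS.items()},
            "version": _package_version(),
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
        }
        man_path = outdir / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, default=str))
        outputs["manifest"] = man_path
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r} "
            f"(partial outputs: {sorted(map(str, outputs.values()))}): {exc}"
        ) from exc
    result["outputs"] = outputs
    return result


def _package_version() -> str:
    try:
        return _pkg_version("drugnmf")
    except Exception:  # not installed (e.g. run from a source tree)
        return "unknown"


def compare_clusterings(labels_a, labels_b, drugs) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate two clusterings of the same samples by drug.

    For every (cluster in A, cluster in B) pair, lists the drugs whose
    samples fall in both; also returns the adjusted Rand index between the
    labelings.  Invariant to permuting cluster ids.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape or len(labels_a) != len(list(drugs)):
        raise ValueError("labelings and drug list must cover the same samples")
    rows = []
    pairs = sorted({(int(a), int(b)) for a, b in zip(labels_a, labels_b)})
    for ca, cb in pairs:
        mask = (labels_a == ca) & (labels_b == cb)
        overlap = sorted({d for d, m in zip(drugs, mask) if m and d})
        rows.append(
            {
                "cluster_a": ca,
                "cluster_b": cb,
                "n_samples": int(mask.sum()),
                "drugs": ",".join(overlap),
            }
        )
    table = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "n_samples", "drugs"])
    ari = adjusted_rand_index(labels_a, labels_b)
    return table, ari


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
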