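"""End-to-end orchestration: LFQ processing -> training sets -> integration
-> evaluation, with file I/O, run logging and summary reports.

Every run writes a structured ``run_log.json`` recording resolved
parameters, seeds, input hashes, bin borders and stage timings, so any
output file can be re-created from the log alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import NA_REP
from .bayes import (
    BinSpec,
    PriorSpec,
    integrate,
    make_default_bin_specs,
    rank_genes,
    write_ranked_table,
)
from .evaluate import cross_validate, cutoff_metrics, rank_to_metrics_table, roc_auc
from .lfq import (
    category_fractions,
    classify_enriched,
    fold_change_table,
    read_lfq,
    write_fold_change_table,
)
from .training import build_training_sets, load_positive_set, read_annotations, validate_training_sets

EVIDENCE_TRACKS = (
    "mtrna_fc",
    "mitocarta_score",
    "rna_domain",
    "coexpression_score",
    "ppi_count",
)


@dataclass
class RunConfig:
    """Paths and parameters of one full pipeline run."""

    lfq_path: str
    samples_path: str
    annotations_path: str
    positives_path: str
    out_dir: str
    threshold_fc: float = 3.0  # linear fold-change for the enrichment call
    n_bins: int = 5
    n_expected: int = 300
    n_genes: int | None = None  # None: size of the gene universe in the inputs
    cutoff_score: float = 1.69
    k_folds: int = 10
    seed: int = 0
    pseudo_count_mode: str = "negative"
    averaging_mode: str = "hierarchical"

    def validate(self) -> None:
        for name in ("lfq_path", "samples_path", "annotations_path", "positives_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name.replace('_path', '')} file not found: {p}")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def build_evidence(combined_fc: pd.Series, annotations: pd.DataFrame) -> pd.DataFrame:
    """Assemble the five evidence tracks over the gene universe.

    The universe is the annotation table's index; the crosslinking
    fold-change track is missing for genes not detected by mass
    spectrometry. Flags become 0/1 so every track is numeric.
    """
    evidence = pd.DataFrame(index=annotations.index)
    evidence["mtrna_fc"] = combined_fc.reindex(annotations.index)
    evidence["mitocarta_score"] = pd.to_numeric(annotations["mitocarta_score"], errors="coerce")
    evidence["rna_domain"] = annotations["rna_domain"].astype(bool).astype(float)
    evidence["coexpression_score"] = pd.to_numeric(
        annotations["coexpression_score"], errors="coerce"
    )
    evidence["ppi_count"] = pd.to_numeric(annotations["ppi_count"], errors="coerce")
    evidence.index.name = "gene_id"
    return evidence


def write_evidence_dir(evidence: pd.DataFrame, outdir: str | Path) -> None:
    """One two-column TSV (gene_id, value) per evidence track."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for col in evidence.columns:
        evidence[col].rename("value").to_csv(
            outdir / f"{col}.tsv", sep="\t", na_rep=NA_REP, float_format="%.6f"
        )


def read_evidence_dir(indir: str | Path) -> pd.DataFrame:
    indir = Path(indir)
    files = sorted(indir.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no evidence tables (*.tsv) in {indir}")
    cols = {}
    for f in files:
        s = pd.read_csv(f, sep="\t", index_col=0, na_values=[NA_REP])["value"]
        cols[f.stem] = s
    evidence = pd.DataFrame(cols)
    evidence.index.name = "gene_id"
    return evidence


def bin_specs_to_dict(specs: dict[str, BinSpec]) -> dict:
    return {
        name: {"kind": s.kind, "borders": [float(b) for b in s.borders]}
        for name, s in specs.items()
    }


def read_bin_specs(path: str | Path) -> dict[str, BinSpec]:
    """Bin specification config: ``{track: {kind: ..., borders: [...]}}``."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return {
        name: BinSpec(name=name, kind=entry.get("kind", "continuous"),
                      borders=tuple(entry.get("borders", [])))
        for name, entry in payload.items()
    }


def report_identified_set(
    ranked: pd.DataFrame,
    annotations: pd.DataFrame,
    cutoff_score: float | None = None,
    n_top: int | None = None,
    mito_col: str = "is_mitocarta",
    rna_col: str = "is_rna_go",
) -> dict:
    """Annotation breakdown of the selected set (mitochondrial x RNA GO-term).

    The four categories partition the selection, so their counts sum to
    ``n_selected``. Select either by score cutoff or by list length.
    """
    if (cutoff_score is None) == (n_top is None):
        raise ValueError("give exactly one of cutoff_score or n_top")
    if cutoff_score is not None:
        selected = ranked.index[ranked["mtRNA_score"] >= cutoff_score]
    else:
        selected = ranked.sort_values("rank").index[: n_top]
    missing = set(selected) - set(annotations.index)
    if missing:
        raise KeyError(f"selected genes absent from annotation table: {sorted(missing)}")
    sub = annotations.loc[list(selected)]
    mito = sub[mito_col].astype(bool)
    rna = sub[rna_col].astype(bool)
    return {
        "n_selected": int(len(selected)),
        "mito_and_rna_go": int((mito & rna).sum()),
        "mito_only": int((mito & ~rna).sum()),
        "rna_go_only": int((~mito & rna).sum()),
        "neither": int((~mito & ~rna).sum()),
    }


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the paths of the written reports."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "config": asdict(config),
        "input_sha256": {
            "lfq": _sha256(config.lfq_path),
            "samples": _sha256(config.samples_path),
            "annotations": _sha256(config.annotations_path),
            "positives": _sha256(config.positives_path),
        },
        "stages": {},
    }
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise StageError(name, exc) from exc
                return False

        return _Timer()

    threshold_log2 = float(np.log2(config.threshold_fc))

    with stage("process-lfq"):
        matrix = read_lfq(config.lfq_path, config.samples_path)
        annotations = read_annotations(config.annotations_path)
        fc = fold_change_table(matrix, averaging_mode=config.averaging_mode)
        write_fold_change_table(fc, out / "fold_changes.tsv")
        categories = {}
        for approach in matrix.approaches_present():
            enriched = classify_enriched(fc, approach, threshold=threshold_log2)
            categories[approach] = category_fractions(enriched, annotations).as_dict()
        (out / "category_counts.json").write_text(json.dumps(categories, indent=1) + "\n")
        log["stages"]["process-lfq"] = {
            "threshold_log2_fc": threshold_log2,
            "n_genes_in_matrix": int(len(fc)),
        }

    with stage("build-training"):
        positives = load_positive_set(config.positives_path, universe=annotations.index)
        training = build_training_sets(annotations, positives, seed=config.seed)
        training.to_json(out / "training.json")
        log["stages"]["build-training"] = validate_training_sets(training, annotations.index)

    with stage("integrate"):
        evidence = build_evidence(fc["combined_log2_fc"], annotations)
        write_evidence_dir(evidence, out / "evidence")
        bin_specs = make_default_bin_specs(evidence, n_bins=config.n_bins)
        prior = PriorSpec(
            n_expected=config.n_expected,
            n_genes=config.n_genes or len(evidence),
        )
        result, model = integrate(
            evidence, training, bin_specs=bin_specs, prior=prior,
            pseudo_count_mode=config.pseudo_count_mode,
        )
        ranked = rank_genes(result, fc_tie_break=evidence["mtrna_fc"], sets=training)
        write_ranked_table(ranked, out / "ranked.tsv")
        log["stages"]["integrate"] = {
            "bin_specs": bin_specs_to_dict(bin_specs),
            "oprior_log2": prior.oprior_log2,
            "prior_odds": prior.prior_odds,
        }

    with stage("evaluate"):
        metrics = cutoff_metrics(ranked, training, config.cutoff_score, prior)
        roc = roc_auc(ranked["mtRNA_score"], training.labels())
        roc.to_frame().to_csv(out / "roc_points.tsv", sep="\t", index=False, float_format="%.6f")
        rank_table = rank_to_metrics_table(ranked, training, prior)
        rank_table.to_csv(out / "rank_metrics.tsv", sep="\t", index=False, float_format="%.6f")
        breakdown = report_identified_set(ranked, annotations, cutoff_score=config.cutoff_score)
        cv = cross_validate(
            evidence, training, bin_specs=bin_specs, prior=prior,
            k=config.k_folds, seed=config.seed, fc_tie_break=evidence["mtrna_fc"],
            pseudo_count_mode=config.pseudo_count_mode,
        )
        cv.heldout.to_csv(out / "cv_heldout_ranks.tsv", sep="\t")
        report = {
            "cutoff": metrics.as_dict(),
            "training_roc_auc": roc.auc,
            "crossval_pooled_auc": cv.auc,
            "identified_set": breakdown,
        }
        (out / "metrics.json").write_text(json.dumps(report, indent=1) + "\n")
        log["stages"]["evaluate"] = {
            "k_folds": config.k_folds,
            "cv_seed": config.seed,
            "crossval_pooled_auc": cv.auc,
        }

    log["timings_s"] = timings
    (out / "run_log.json").write_text(json.dumps(log, indent=1) + "\n")
    return {
        "out_dir": str(out),
        "fold_changes": str(out / "fold_changes.tsv"),
        "category_counts": str(out / "category_counts.json"),
        "training": str(out / "training.json"),
        "ranked": str(out / "ranked.tsv"),
        "metrics": str(out / "metrics.json"),
        "run_log": str(out / "run_log.json"),
    }
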