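"""Label-free quantification (LFQ) processing for crosslinking proteomics.

Turns raw MaxQuant-style LFQ intensity tables into per-approach log2
fold-changes of crosslinked over control samples, calls enriched proteins at
a fold-change threshold, and combines the mitochondrial (MXL) and whole-cell
(WCXL) crosslinking approaches into a single mtRNA-interaction evidence
value per gene.

Pipeline order: :func:`log2_transform_and_impute` ->
:func:`average_replicates` per (approach, condition) ->
:func:`compute_fold_change` -> :func:`classify_enriched` /
:func:`combine_approaches`. :func:`fold_change_table` runs the whole chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import NA_REP, percent, round_half_up

APPROACHES = ("MXL", "WCXL", "WCXL_EtBr")
CONDITIONS = ("crosslinked", "control")

#: log2(3): a protein must be at least three-fold more intense in the
#: crosslinked condition to be called enriched.
ENRICHMENT_THRESHOLD = float(np.log2(3.0))

SAMPLE_SHEET_COLUMNS = ["sample_id", "approach", "condition", "biological_rep", "technical_rep"]


@dataclass
class LfqMatrix:
    """Protein x sample LFQ intensities plus the sample sheet describing columns.

    Parameters
    ----------
    intensities:
        genes x samples frame; NaN marks a missing (not quantified) value.
        Linear scale on input, log2 scale after transformation.
    samples:
        one row per sample column with ``sample_id``, ``approach``
        (MXL / WCXL / WCXL_EtBr), ``condition`` (crosslinked / control) and
        1-based ``biological_rep`` / ``technical_rep``. For WCXL_EtBr the
        "control" rows are the crosslinked, ethidium-bromide-treated samples:
        the comparison there is crosslinked over crosslinked+EtBr.
    is_log2:
        whether intensities have already been log2 transformed.
    present_mask:
        boolean frame marking cells that carried a measured value before any
        imputation; survives transformation so downstream code can tell
        imputed cells apart.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    is_log2: bool = False
    present_mask: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"sample sheet lacks columns: {missing_cols}")
        sheet_ids = list(self.samples["sample_id"])
        if len(set(sheet_ids)) != len(sheet_ids):
            raise ValueError("duplicate sample_id in sample sheet")
        unknown = [c for c in self.intensities.columns if c not in set(sheet_ids)]
        orphans = [s for s in sheet_ids if s not in set(self.intensities.columns)]
        if unknown or orphans:
            raise ValueError(
                f"sample sheet / matrix mismatch: columns without metadata {unknown}, "
                f"metadata without columns {orphans}"
            )
        bad_app = set(self.samples["approach"]) - set(APPROACHES)
        if bad_app:
            raise ValueError(f"unknown approach(es) {sorted(bad_app)}; expected {APPROACHES}")
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown condition(s) {sorted(bad_cond)}; expected {CONDITIONS}")
        key = self.samples[["approach", "condition", "biological_rep", "technical_rep"]]
        if key.duplicated().any():
            raise ValueError("(approach, condition, biological_rep, technical_rep) not unique")
        if self.present_mask is None:
            self.present_mask = self.intensities.notna()

    @property
    def gene_ids(self) -> pd.Index:
        return self.intensities.index

    def sample_ids(self, approach: str, condition: str) -> list[str]:
        sheet = self.samples
        sel = sheet[(sheet["approach"] == approach) & (sheet["condition"] == condition)]
        return list(sel["sample_id"])

    def approaches_present(self) -> list[str]:
        return [a for a in APPROACHES if a in set(self.samples["approach"])]


@dataclass(frozen=True)
class CategoryCounts:
    """Annotation breakdown of an enriched protein set."""

    n_enriched: int
    n_mito: int
    n_rna_go: int
    n_mito_and_rna_go: int

    def __post_init__(self) -> None:
        if not (
            self.n_mito_and_rna_go <= min(self.n_mito, self.n_rna_go) <= self.n_enriched
        ):
            raise ValueError(f"inconsistent category counts: {self}")

    @property
    def pct_mito(self) -> int:
        return percent(self.n_mito, self.n_enriched)

    @property
    def pct_rna_go(self) -> int:
        return percent(self.n_rna_go, self.n_enriched)

    @property
    def pct_mito_and_rna_go(self) -> int:
        return percent(self.n_mito_and_rna_go, self.n_enriched)

    def as_dict(self) -> dict:
        return {
            "n_enriched": self.n_enriched,
            "n_mito": self.n_mito,
            "n_rna_go": self.n_rna_go,
            "n_mito_and_rna_go": self.n_mito_and_rna_go,
            "pct_mito": self.pct_mito,
            "pct_rna_go": self.pct_rna_go,
            "pct_mito_and_rna_go": self.pct_mito_and_rna_go,
        }


def read_lfq(lfq_path: str | Path, samples_path: str | Path) -> LfqMatrix:
    """Read a tab-separated LFQ table (first column = gene id) and sample sheet."""
    intensities = pd.read_csv(lfq_path, sep="\t", index_col=0, na_values=[NA_REP])
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    return LfqMatrix(intensities=intensities, samples=samples)


def log2_transform_and_impute(matrix: LfqMatrix) -> LfqMatrix:
    """log2-transform linear intensities and impute missing cells.

    Missing values become the lowest log2 intensity measured anywhere in the
    matrix (global floor), so an unquantified protein is treated as sitting
    at the detection limit. Imputed cells stay flagged in ``present_mask``.
    """
    if matrix.is_log2:
        raise ValueError("matrix is already on the log2 scale")
    values = matrix.intensities
    present = values.notna()
    if not present.to_numpy().any():
        raise ValueError("nothing to impute from: matrix has no present values")
    if (values.to_numpy() <= 0)[present.to_numpy()].any():
        raise ValueError("non-positive LFQ intensity present; expected strictly positive values")
    log2_vals = np.log2(values.where(present))
    floor = float(np.nanmin(log2_vals.to_numpy()))
    log2_vals = log2_vals.fillna(floor)
    return LfqMatrix(
        intensities=log2_vals,
        samples=matrix.samples.copy(),
        is_log2=True,
        present_mask=present,
    )


def average_replicates(
    matrix: LfqMatrix,
    approach: str,
    condition: str,
    mode: str = "hierarchical",
) -> pd.Series:
    """Per-protein mean log2 LFQ for one (approach, condition).

    ``hierarchical`` (default) averages technical replicates within each
    biological replicate first, then averages the biological-replicate means,
    so unequal technical-replicate counts cannot bias the estimate. ``flat``
    averages all samples directly.
    """
    if not matrix.is_log2:
        raise ValueError("matrix must be log2-transformed and imputed first")
    if mode not in ("hierarchical", "flat"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    sample_ids = matrix.sample_ids(approach, condition)
    if not sample_ids:
        raise ValueError(f"no samples for approach={approach!r}, condition={condition!r}")
    block = matrix.intensities[sample_ids]
    if mode == "flat":
        return block.mean(axis=1)
    sheet = matrix.samples.set_index("sample_id").loc[sample_ids]
    biorep_means = block.T.groupby(sheet["biological_rep"]).mean().T
    return biorep_means.mean(axis=1)


def compute_fold_change(xl_mean: pd.Series | float, control_mean: pd.Series | float):
    """log2 fold-change of crosslinked over control: difference of log2 means."""
    return xl_mean - control_mean


def detected_in_approach(matrix: LfqMatrix, approach: str) -> pd.Series:
    """True where a protein carried at least one measured value in the approach."""
    sheet = matrix.samples
    cols = list(sheet.loc[sheet["approach"] == approach, "sample_id"])
    if not cols:
        raise ValueError(f"approach {approach!r} absent from sample sheet")
    assert matrix.present_mask is not None
    return matrix.present_mask[cols].any(axis=1)


def fold_change_table(
    matrix: LfqMatrix,
    averaging_mode: str = "hierarchical",
) -> pd.DataFrame:
    """Full fold-change table for every approach present in the sample sheet.

    Returns a frame indexed by gene id with, per approach A, columns
    ``log2_fc_A`` and ``detected_A``, plus ``combined_log2_fc`` (see
    :func:`combine_approaches`). Input may be linear (it will be transformed)
    or already log2+imputed.
    """
    if not matrix.is_log2:
        matrix = log2_transform_and_impute(matrix)
    out = pd.DataFrame(index=matrix.gene_ids)
    for approach in matrix.approaches_present():
        xl = average_replicates(matrix, approach, "crosslinked", averaging_mode)
        ctrl = average_replicates(matrix, approach, "control", averaging_mode)
        out[f"log2_fc_{approach}"] = compute_fold_change(xl, ctrl)
        out[f"detected_{approach}"] = detected_in_approach(matrix, approach)
    out["combined_log2_fc"] = combine_approaches(out)
    return out


def classify_enriched(
    fc_table: pd.DataFrame,
    approach: str,
    threshold: float = ENRICHMENT_THRESHOLD,
) -> set[str]:
    """Detected proteins with log2 fold-change >= threshold (boundary included)."""
    col = f"log2_fc_{approach}"
    if col not in fc_table.columns:
        raise ValueError(f"approach {approach!r} not in fold-change table")
    detected = fc_table.get(f"detected_{approach}", pd.Series(True, index=fc_table.index))
    hit = detected & (fc_table[col] >= threshold)
    return set(fc_table.index[hit])


def combine_approaches(fc_table: pd.DataFrame) -> pd.Series:
    """mtRNA-interaction evidence value: mean of MXL and WCXL log2 fold-changes.

    Where only one approach detected the protein its value is used alone;
    where neither did the result is missing (such genes fall into the
    missing-data bin downstream). WCXL_EtBr is reported but never enters the
    combined value.
    """
    parts = []
    for approach in ("MXL", "WCXL"):
        col = f"log2_fc_{approach}"
        if col in fc_table.columns:
            detected = fc_table.get(f"detected_{approach}", pd.Series(True, index=fc_table.index))
            parts.append(fc_table[col].where(detected))
    if not parts:
        return pd.Series(np.nan, index=fc_table.index, name="combined_log2_fc")
    combined = pd.concat(parts, axis=1).mean(axis=1)
    combined.name = "combined_log2_fc"
    return combined


def category_fractions(
    enriched: set[str],
    annotations: pd.DataFrame,
    mito_col: str = "is_mitocarta",
    rna_col: str = "is_rna_go",
) -> CategoryCounts:
    """Annotation breakdown (mitochondrial x RNA GO-term) of an enriched set."""
    missing = sorted(set(enriched) - set(annotations.index))
    if missing:
        raise KeyError(f"enriched genes absent from annotation table: {missing}")
    genes = sorted(enriched)
    sub = annotations.loc[genes]
    mito = sub[mito_col].astype(bool)
    rna = sub[rna_col].astype(bool)
    return CategoryCounts(
        n_enriched=len(genes),
        n_mito=int(mito.sum()),
        n_rna_go=int(rna.sum()),
        n_mito_and_rna_go=int((mito & rna).sum()),
    )


def overlap_sensitivity(n_hits_in_reference: int, n_reference: int) -> float:
    """Fraction of a reference gene set recovered by a hit list, to 3 decimals."""
    if n_reference <= 0:
        raise ValueError("reference set must be non-empty")
    if not 0 <= n_hits_in_reference <= n_reference:
        raise ValueError(
            f"hits in reference ({n_hits_in_reference}) must lie in [0, {n_reference}]"
        )
    return round_half_up(n_hits_in_reference / n_reference, 3)


def write_fold_change_table(fc_table: pd.DataFrame, path: str | Path) -> None:
    fc_table.to_csv(path, sep="\t", na_rep=NA_REP, float_format="%.6f")
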