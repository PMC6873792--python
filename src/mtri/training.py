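"""Positive and negative training sets for the evidence integration.

The positive set is a curated list of genes with literature evidence for
interaction with mitochondrial mRNA, tRNA or rRNA. The negative set is built
by GO-flag logic from the annotation table and has two equal-size halves:

* mitochondrial genes very unlikely to touch RNA — mitochondrion GO-term AND
  (TCA-cycle OR OXPHOS GO-term) AND NOT RNA-binding GO-term; every such gene
  is taken;
* cellular RNA binders very unlikely to be mitochondrial — RNA-binding
  GO-term AND NOT mitochondrion GO-term; sampled uniformly (seeded, without
  replacement) down to the size of the first half so both contaminant
  classes contribute equally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import rng_from

ANNOTATION_FLAG_COLUMNS = ["is_mito_go", "is_rna_go", "is_tca_go", "is_oxphos_go"]


@dataclass
class TrainingSets:
    """Curated positives plus the two rule-built negative categories."""

    positives: list[str]
    negatives_mito_nonrna: list[str]
    negatives_rna_nonmito: list[str]
    seed: int

    @property
    def negatives(self) -> list[str]:
        return list(self.negatives_mito_nonrna) + list(self.negatives_rna_nonmito)

    @property
    def all_genes(self) -> list[str]:
        return list(self.positives) + self.negatives

    def labels(self) -> pd.Series:
        """1 for positives, 0 for negatives, indexed by gene id."""
        lab = pd.Series(0, index=pd.Index(self.all_genes, name="gene_id"), dtype=int)
        lab.loc[self.positives] = 1
        return lab

    def to_json(self, path: str | Path) -> None:
        payload = {
            "positives": list(self.positives),
            "negatives_mito_nonrna": list(self.negatives_mito_nonrna),
            "negatives_rna_nonmito": list(self.negatives_rna_nonmito),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainingSets":
        payload = json.loads(Path(path).read_text())
        return cls(
            positives=payload["positives"],
            negatives_mito_nonrna=payload["negatives_mito_nonrna"],
            negatives_rna_nonmito=payload["negatives_rna_nonmito"],
            seed=int(payload["seed"]),
        )


def build_negative_set(
    annotations: pd.DataFrame,
    seed: int,
    exclude: set[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Build both negative categories from GO flags (see module docstring).

    ``exclude`` removes genes (typically the positives) from both categories
    before sizing, so the returned sets can never overlap a curated positive
    list that carries noisy flags.
    """
    missing = [c for c in ANNOTATION_FLAG_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table lacks flag columns: {missing}")
    exclude = exclude or set()
    flags = annotations[ANNOTATION_FLAG_COLUMNS].astype(bool)
    cat1_mask = flags["is_mito_go"] & (flags["is_tca_go"] | flags["is_oxphos_go"]) & ~flags["is_rna_go"]
    cat2_mask = flags["is_rna_go"] & ~flags["is_mito_go"]
    category1 = sorted(set(annotations.index[cat1_mask]) - exclude)
    pool = sorted(set(annotations.index[cat2_mask]) - exclude)
    if len(pool) < len(category1):
        raise ValueError(
            f"RNA-non-mitochondrial pool ({len(pool)}) smaller than the "
            f"mitochondrial non-RNA category ({len(category1)}); cannot balance"
        )
    rng = rng_from(seed, 0xC2)
    category2 = sorted(rng.choice(pool, size=len(category1), replace=False))
    return category1, [str(g) for g in category2]


def load_positive_set(path: str | Path, universe: pd.Index | None = None) -> list[str]:
    """Read one gene id per line; de-duplicate preserving order."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = [ln for ln in lines if ln and not ln.startswith("#")]
    if not ids:
        raise ValueError(f"positive-set file {path} is empty")
    seen: dict[str, None] = {}
    for g in ids:
        if g in seen:
            warnings.warn(f"duplicate positive-set id {g!r} dropped", stacklevel=2)
        seen.setdefault(g)
    unique = list(seen)
    if universe is not None:
        unknown = [g for g in unique if g not in universe]
        if unknown:
            raise KeyError(f"positive-set ids absent from the gene universe: {unknown}")
    return unique


def build_training_sets(
    annotations: pd.DataFrame,
    positives: list[str],
    seed: int,
) -> TrainingSets:
    """Assemble and validate a full TrainingSets from positives + annotations."""
    cat1, cat2 = build_negative_set(annotations, seed=seed, exclude=set(positives))
    sets = TrainingSets(
        positives=list(positives),
        negatives_mito_nonrna=cat1,
        negatives_rna_nonmito=cat2,
        seed=seed,
    )
    validate_training_sets(sets, annotations.index)
    return sets


def validate_training_sets(sets: TrainingSets, universe: pd.Index) -> dict:
    """Check disjointness and universe membership; return a size report."""
    pos = set(sets.positives)
    cat1 = set(sets.negatives_mito_nonrna)
    cat2 = set(sets.negatives_rna_nonmito)
    if not pos:
        raise ValueError("positive training set is empty")
    if not cat1 or not cat2:
        raise ValueError("a negative training category is empty")
    for name, a, b in [
        ("positives/negatives_mito_nonrna", pos, cat1),
        ("positives/negatives_rna_nonmito", pos, cat2),
        ("negative categories", cat1, cat2),
    ]:
        overlap = a & b
        if overlap:
            raise ValueError(f"training sets overlap ({name}): {sorted(overlap)}")
    stray = (pos | cat1 | cat2) - set(universe)
    if stray:
        raise KeyError(f"training genes absent from the gene universe: {sorted(stray)}")
    return {
        "n_positives": len(pos),
        "n_negatives_mito_nonrna": len(cat1),
        "n_negatives_rna_nonmito": len(cat2),
        "n_negatives": len(cat1) + len(cat2),
        "seed": sets.seed,
    }


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-gene annotation/evidence table (TSV, first column gene_id)."""
    table = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if table.index.duplicated().any():
        dupes = sorted(table.index[table.index.duplicated()].unique())
        raise ValueError(f"duplicate gene ids in annotation table: {dupes[:10]}")
    for col in table.columns:
        if col.startswith("is_") or col == "rna_domain":
            table[col] = table[col].astype(bool)
    return table
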