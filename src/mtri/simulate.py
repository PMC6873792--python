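"""Synthetic study generator.

Emulates the statistical structure the analysis assumes: a gene universe
with a designated set of true mitochondrial-RNA interactors (a subset of the
mitochondrial genes), a surplus of mitochondrial non-RNA genes and of
cytosolic RNA binders (the two contaminant classes the negative training set
encodes), LFQ matrices in which true interactors are intensity-shifted in
crosslinked samples (full effect in the mitochondrial-crosslinking approach
MXL, attenuated in whole-cell crosslinking WCXL, where cytosolic RNA binders
also co-purify), and four annotation tracks (localization score, RNA-binding
domain flag, co-expression, interaction counts) with class-conditional
signal. Tracks are conditionally independent given the gene's class by
default — the same assumption the naive-Bayes integration makes — with an
optional correlation knob.

Everything is deterministic under (config, seed); sub-stages draw from
independently derived streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import NA_REP, rng_from
from .lfq import LfqMatrix
from .training import TrainingSets, build_training_sets


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults mirror the real study's design: 20129 protein-coding genes of
    which 300 interact with mtRNA, three biological x two technical
    replicates per condition, a 24-gene positive training set and 124 genes
    per negative category. ``lfq_effect`` is the log2 intensity shift of
    true interactors in crosslinked samples (2.5 ~ a 5.7-fold enrichment,
    comfortably above the log2(3) calling threshold); ``lfq_noise_sd`` is
    replicate noise on the log2 scale.
    """

    n_genes: int = 20129
    n_true: int = 300
    seed: int = 0

    # LFQ generation
    lfq_effect: float = 2.5
    lfq_noise_sd: float = 0.8
    missing_rate_background: float = 0.6
    missing_rate_detected: float = 0.1
    n_bioreps: int = 3
    n_techreps: int = 2
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    wcxl_attenuation: float = 0.7
    contaminant_shift: float = 1.0
    intensity_dependent_missingness: bool = False

    # universe composition (fractions of n_genes)
    frac_mito_extra: float = 0.06
    frac_cyto_rna: float = 0.08

    # annotation tracks
    mito_flag_tpr: float = 0.90
    mito_flag_fpr: float = 0.02
    mitocarta_score_shift: float = 2.0
    rna_domain_tpr: float = 0.70
    rna_domain_fpr: float = 0.05
    coexpr_shift: float = 1.5
    coexpr_sd: float = 1.0
    ppi_lambda_pos: float = 3.0
    ppi_lambda_neg: float = 0.3
    go_flag_fpr: float = 0.0
    go_flag_fnr: float = 0.0
    track_correlation: float = 0.0

    # training sets
    training_pos_size: int = 24
    training_neg_size_per_category: int = 124

    def __post_init__(self) -> None:
        # n_true = 0 is allowed: it yields a universe with no interactors,
        # which downstream evaluation rejects as single-class
        if not 0 <= self.n_true < self.n_genes:
            raise ValueError(f"need 0 <= n_true ({self.n_true}) < n_genes ({self.n_genes})")
        rates = {
            "missing_rate_background": self.missing_rate_background,
            "missing_rate_detected": self.missing_rate_detected,
            "mito_flag_tpr": self.mito_flag_tpr,
            "mito_flag_fpr": self.mito_flag_fpr,
            "rna_domain_tpr": self.rna_domain_tpr,
            "rna_domain_fpr": self.rna_domain_fpr,
            "go_flag_fpr": self.go_flag_fpr,
            "go_flag_fnr": self.go_flag_fnr,
            "frac_mito_extra": self.frac_mito_extra,
            "frac_cyto_rna": self.frac_cyto_rna,
        }
        for name, val in rates.items():
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        for name, val in {
            "n_bioreps": self.n_bioreps,
            "n_techreps": self.n_techreps,
            "training_pos_size": self.training_pos_size,
            "training_neg_size_per_category": self.training_neg_size_per_category,
        }.items():
            if val < 1:
                raise ValueError(f"{name} must be >= 1, got {val}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def null_config(n_genes: int = 5000, n_true: int = 300, seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with every class-conditional effect removed.

    GO flags stay exact (they define the training sets), but no evidence
    track carries signal, so any ranking of interactors is chance.
    """
    base = dict(
        n_genes=n_genes,
        n_true=n_true,
        seed=seed,
        lfq_effect=0.0,
        contaminant_shift=0.0,
        missing_rate_detected=0.6,
        missing_rate_background=0.6,
        mito_flag_tpr=0.15,
        mito_flag_fpr=0.15,
        mitocarta_score_shift=0.0,
        rna_domain_tpr=0.10,
        rna_domain_fpr=0.10,
        coexpr_shift=0.0,
        ppi_lambda_pos=1.0,
        ppi_lambda_neg=1.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _gene_ids(n: int) -> pd.Index:
    width = max(5, len(str(n)))
    return pd.Index([f"G{i:0{width}d}" for i in range(1, n + 1)], name="gene_id")


def generate_universe(config: SimulationConfig) -> pd.DataFrame:
    """Assign ground-truth roles: interactor, mitochondrial, cytosolic RNA binder.

    Interactors are always mitochondrial; the three signal-bearing roles are
    disjoint apart from that containment.
    """
    rng = rng_from(config.seed, 1)
    genes = _gene_ids(config.n_genes)
    n_mito_extra = int(round(config.frac_mito_extra * config.n_genes))
    n_cyto = int(round(config.frac_cyto_rna * config.n_genes))
    if config.n_true + n_mito_extra + n_cyto > config.n_genes:
        raise ValueError("signal classes exceed the gene universe; lower the fractions")
    order = rng.permutation(config.n_genes)
    interactors = order[: config.n_true]
    mito_extra = order[config.n_true : config.n_true + n_mito_extra]
    cyto = order[config.n_true + n_mito_extra : config.n_true + n_mito_extra + n_cyto]
    truth = pd.DataFrame(
        {
            "is_mtRNA_interactor": False,
            "is_mitochondrial": False,
            "is_cytosolic_rna_binder": False,
        },
        index=genes,
    )
    truth.iloc[interactors, truth.columns.get_loc("is_mtRNA_interactor")] = True
    truth.iloc[np.concatenate([interactors, mito_extra]), truth.columns.get_loc("is_mitochondrial")] = True
    truth.iloc[cyto, truth.columns.get_loc("is_cytosolic_rna_binder")] = True
    return truth


def _one_approach_lfq(
    truth: pd.DataFrame, config: SimulationConfig, approach: str,
    baseline: np.ndarray, salt: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = rng_from(config.seed, 2, salt)
    n = len(truth)
    interactor = truth["is_mtRNA_interactor"].to_numpy()
    cyto = truth["is_cytosolic_rna_binder"].to_numpy()
    if approach == "MXL":
        xl_shift = np.where(interactor, config.lfq_effect, 0.0)
        signal_class = interactor
    else:  # WCXL
        xl_shift = np.where(interactor, config.wcxl_attenuation * config.lfq_effect, 0.0)
        xl_shift = xl_shift + np.where(cyto, config.contaminant_shift, 0.0)
        signal_class = interactor | cyto
    columns, meta_rows = [], []
    values = {}
    for condition in ("crosslinked", "control"):
        shift = xl_shift if condition == "crosslinked" else 0.0
        # missingness follows per-sample abundance: the enriched (shifted)
        # cells of signal genes are reliably quantified, everything else is
        # at contaminant level and drops out at the background rate
        p_miss = np.where(
            signal_class & (condition == "crosslinked"),
            config.missing_rate_detected,
            config.missing_rate_background,
        )
        for b in range(1, config.n_bioreps + 1):
            for t in range(1, config.n_techreps + 1):
                sid = f"{approach}_{condition}_b{b}_t{t}"
                log2_val = baseline + shift + rng.normal(0.0, config.lfq_noise_sd, size=n)
                if config.intensity_dependent_missingness:
                    # lower-intensity cells are likelier to drop out
                    z = (log2_val - np.mean(log2_val)) / (np.std(log2_val) + 1e-12)
                    p_cell = np.clip(p_miss - 0.2 * z, 0.0, 1.0)
                else:
                    p_cell = p_miss
                present = rng.random(n) >= p_cell
                linear = np.where(present, np.exp2(log2_val), np.nan)
                values[sid] = linear
                columns.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "approach": approach,
                        "condition": condition,
                        "biological_rep": b,
                        "technical_rep": t,
                    }
                )
    intensities = pd.DataFrame(values, index=truth.index)[columns]
    return intensities, pd.DataFrame(meta_rows)


def generate_lfq(truth: pd.DataFrame, config: SimulationConfig) -> LfqMatrix:
    """Linear-scale LFQ matrix covering both crosslinking approaches.

    True interactors get the full ``lfq_effect`` shift in MXL crosslinked
    samples and an attenuated one in WCXL, where cytosolic RNA binders also
    receive the contaminant shift. Non-interactors' expected fold-change is
    zero. Missingness is applied per cell at the detected/background rates.
    """
    baseline = rng_from(config.seed, 2, 0).normal(
        config.baseline_mean, config.baseline_sd, size=len(truth)
    )
    parts, sheets = [], []
    for salt, approach in ((1, "MXL"), (2, "WCXL")):
        intens, sheet = _one_approach_lfq(truth, config, approach, baseline, salt)
        parts.append(intens)
        sheets.append(sheet)
    return LfqMatrix(
        intensities=pd.concat(parts, axis=1),
        samples=pd.concat(sheets, ignore_index=True),
    )


def generate_annotations(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Per-gene annotation/evidence table with class-conditional signal.

    GO flags derive from the ground truth (with optional flip noise); the
    TCA/OXPHOS flags are planted on exactly ``training_neg_size_per_category``
    mitochondrial non-RNA genes so the rule-built negative set has the
    intended size. The four evidence tracks are drawn independently given
    the class unless ``track_correlation`` > 0.
    """
    rng = rng_from(config.seed, 3)
    n = len(truth)
    interactor = truth["is_mtRNA_interactor"].to_numpy()
    mito = truth["is_mitochondrial"].to_numpy()
    rna_true = interactor | truth["is_cytosolic_rna_binder"].to_numpy()

    def noisy(flag: np.ndarray) -> np.ndarray:
        if config.go_flag_fpr == 0 and config.go_flag_fnr == 0:
            return flag.copy()
        flip_up = rng.random(n) < config.go_flag_fpr
        flip_down = rng.random(n) < config.go_flag_fnr
        return np.where(flag, ~flip_down, flip_up)

    is_mito_go = noisy(mito)
    is_rna_go = noisy(rna_true)

    # plant the TCA/OXPHOS labels on a fixed-size subset of the negative pool
    pool = np.flatnonzero(mito & ~rna_true & ~interactor)
    n_cat1 = config.training_neg_size_per_category
    if len(pool) < n_cat1:
        raise ValueError(
            f"only {len(pool)} mitochondrial non-RNA genes; cannot plant "
            f"{n_cat1} TCA/OXPHOS genes — raise frac_mito_extra or n_genes"
        )
    chosen = rng.choice(pool, size=n_cat1, replace=False)
    is_tca = np.zeros(n, dtype=bool)
    is_oxphos = np.zeros(n, dtype=bool)
    which = rng.integers(0, 3, size=n_cat1)  # 0 TCA, 1 OXPHOS, 2 both
    is_tca[chosen[(which == 0) | (which == 2)]] = True
    is_oxphos[chosen[(which == 1) | (which == 2)]] = True

    is_mitocarta = np.where(
        mito, rng.random(n) < config.mito_flag_tpr, rng.random(n) < config.mito_flag_fpr
    )
    latent = rng.normal(0.0, 1.0, size=n)
    mitocarta_score = np.where(
        mito,
        rng.normal(config.mitocarta_score_shift, 1.0, size=n),
        rng.normal(0.0, 1.0, size=n),
    )
    mitocarta_score = np.where(is_mitocarta, mitocarta_score + config.track_correlation * latent, np.nan)
    rna_domain = np.where(
        rna_true,
        rng.random(n) < config.rna_domain_tpr,
        rng.random(n) < config.rna_domain_fpr,
    )
    coexpression = rng.normal(0.0, config.coexpr_sd, size=n)
    coexpression = coexpression + np.where(interactor, config.coexpr_shift, 0.0)
    coexpression = coexpression + config.track_correlation * latent
    ppi = np.where(
        interactor,
        rng.poisson(config.ppi_lambda_pos, size=n),
        rng.poisson(config.ppi_lambda_neg, size=n),
    )
    return pd.DataFrame(
        {
            "is_mito_go": is_mito_go,
            "is_rna_go": is_rna_go,
            "is_tca_go": is_tca,
            "is_oxphos_go": is_oxphos,
            "is_mitocarta": is_mitocarta,
            "mitocarta_score": mitocarta_score,
            "rna_domain": rna_domain,
            "coexpression_score": coexpression,
            "ppi_count": ppi.astype(float),
        },
        index=truth.index,
    )


def generate_training_sets(
    truth: pd.DataFrame, annotations: pd.DataFrame, config: SimulationConfig
) -> TrainingSets:
    """Positives sampled from the true interactors; negatives rule-built."""
    rng = rng_from(config.seed, 4)
    interactors = list(truth.index[truth["is_mtRNA_interactor"]])
    if len(interactors) < config.training_pos_size:
        raise ValueError(
            f"only {len(interactors)} true interactors; cannot draw "
            f"{config.training_pos_size} positives"
        )
    positives = sorted(rng.choice(interactors, size=config.training_pos_size, replace=False))
    return build_training_sets(annotations, [str(g) for g in positives], seed=config.seed)


@dataclass
class SyntheticStudy:
    """All artefacts of one simulated study."""

    config: SimulationConfig
    truth: pd.DataFrame
    lfq: LfqMatrix
    annotations: pd.DataFrame
    training: TrainingSets

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the study in the TSV/JSON formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "lfq": outdir / "lfq.tsv",
            "samples": outdir / "samples.tsv",
            "annotations": outdir / "annotations.tsv",
            "positives": outdir / "positives.txt",
            "truth": outdir / "truth.tsv",
            "training": outdir / "training.json",
        }
        self.lfq.intensities.to_csv(paths["lfq"], sep="\t", na_rep=NA_REP, float_format="%.6f")
        self.lfq.samples.to_csv(paths["samples"], sep="\t", index=False)
        self.annotations.to_csv(paths["annotations"], sep="\t", na_rep=NA_REP, float_format="%.6f")
        paths["positives"].write_text("\n".join(self.training.positives) + "\n")
        self.truth.to_csv(paths["truth"], sep="\t")
        self.training.to_json(paths["training"])
        return paths


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run all generator stages in order under one seed."""
    truth = generate_universe(config)
    lfq = generate_lfq(truth, config)
    annotations = generate_annotations(truth, config)
    training = generate_training_sets(truth, annotations, config)
    return SyntheticStudy(
        config=config, truth=truth, lfq=lfq, annotations=annotations, training=training
    )


def scaled_config(n_genes: int, seed: int = 0, **overrides) -> SimulationConfig:
    """Default study scaled to a smaller universe, keeping class proportions.

    ``n_true`` scales with the universe (floor 40 so the 24-gene positive
    set remains drawable). The per-category negative-set size shrinks only
    when the mitochondrial non-RNA pool of a small universe cannot supply
    the study's 124 genes.
    """
    n_true = max(40, int(round(300 * n_genes / 20129)))
    cfg = SimulationConfig(n_genes=n_genes, n_true=n_true, seed=seed, **overrides)
    pool = int(round(cfg.frac_mito_extra * n_genes))
    if "training_neg_size_per_category" not in overrides:
        cfg = replace(cfg, training_neg_size_per_category=min(124, max(20, int(0.8 * pool))))
    return cfg


__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "generate_universe",
    "generate_lfq",
    "generate_annotations",
    "generate_training_sets",
    "generate_study",
    "null_config",
    "scaled_config",
]
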