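"""File formats, preprocessing and run configuration.

Count tables are TSV/CSV with taxa as rows (the feature-table convention):
first column taxon IDs, header row of sample IDs.  A ``samples_as_rows``
flag handles the transposed layout explicitly — orientation is never
guessed.  Metadata tables are one row per sample with a sample-ID column.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AbundanceTable, CovariateSet, DataValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full differential-abundance run."""

    counts_path: str = ""
    metadata_path: str = ""
    variable: str = ""
    zero_covariates: list[str] = field(default_factory=list)  # U columns
    abundance_covariates: list[str] = field(default_factory=list)  # V columns
    rho: float = 0.5
    fdr_level: float = 0.05
    prevalence_min: float = 0.05
    em_tol: float = 1e-6
    em_max_iter: int = 100
    seed: int = 0
    output_path: str = "results.tsv"
    samples_as_rows: bool = False
    allow_real: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must lie in (0, 1)")
        if not 0.0 <= self.prevalence_min < 1.0:
            raise ValueError("prevalence_min must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str)


def read_counts(
    path: str | Path,
    samples_as_rows: bool = False,
    allow_real: bool = False,
) -> AbundanceTable:
    """Read and validate a count table.

    Non-numeric, negative or (in strict mode) non-integer entries are
    rejected with the offending row and column named.  With
    ``allow_real=True`` non-negative reals are rounded with a warning,
    for pre-normalized inputs.
    """
    df = _read_table(path)
    if df.empty:
        raise DataValidationError(f"{path}: empty count table")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise DataValidationError(
                f"{path}: non-numeric count at row {bad!r}, column {col!r}"
            ) from None
    if samples_as_rows:
        df = df.T
        values = values.T
    taxon_ids = list(df.index.astype(str))
    sample_ids = list(df.columns.astype(str))
    if len(set(taxon_ids)) != len(taxon_ids):
        raise DataValidationError(f"{path}: duplicate taxon IDs")
    if len(set(sample_ids)) != len(sample_ids):
        raise DataValidationError(f"{path}: duplicate sample IDs")
    counts = values.T  # samples x taxa
    if np.any(counts < 0):
        i, k = np.argwhere(counts < 0)[0]
        raise DataValidationError(
            f"{path}: negative count at taxon {taxon_ids[k]!r}, "
            f"sample {sample_ids[i]!r}"
        )
    if np.any(counts != np.floor(counts)):
        if not allow_real:
            i, k = np.argwhere(counts != np.floor(counts))[0]
            raise DataValidationError(
                f"{path}: non-integer count at taxon {taxon_ids[k]!r}, sample "
                f"{sample_ids[i]!r}; pass allow_real to round"
            )
        logger.warning("%s: rounding non-integer counts to the nearest integer", path)
        counts = np.rint(counts)
    return AbundanceTable(counts=counts, sample_ids=sample_ids, taxon_ids=taxon_ids)


def read_metadata(
    path: str | Path,
    table: AbundanceTable,
    variable: str,
    zero_covariates: list[str] | None = None,
    abundance_covariates: list[str] | None = None,
) -> tuple[CovariateSet, AbundanceTable]:
    """Read sample metadata and assemble the covariate designs.

    Joins on sample IDs (order-insensitive), codes a two-level categorical
    variable of interest as 0/1, dummy-codes categorical covariates and adds
    intercept columns.  Samples with missing values in any used column are
    dropped (with a logged count), never imputed.  Returns the covariates
    and the count table restricted to the joined samples, in table order.
    """
    meta = _read_table(path)
    meta.index = meta.index.astype(str)
    if variable not in meta.columns:
        raise DataValidationError(f"{path}: missing variable column {variable!r}")
    zero_covariates = zero_covariates or []
    abundance_covariates = abundance_covariates or []
    for col in [variable, *zero_covariates, *abundance_covariates]:
        if col not in meta.columns:
            raise DataValidationError(f"{path}: missing covariate column {col!r}")

    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise DataValidationError(
            f"{path}: metadata missing {len(missing)} samples, e.g. {missing[:5]}"
        )
    used = [variable, *dict.fromkeys(zero_covariates + abundance_covariates)]
    meta = meta.loc[table.sample_ids, used]
    complete = meta.notna().all(axis=1) & (meta != "").all(axis=1)
    if not complete.all():
        logger.warning(
            "dropping %d samples with missing metadata", int((~complete).sum())
        )
        keep = np.asarray(complete.values, dtype=bool)
        table = table.select_samples(keep)
        meta = meta.loc[complete]

    def encode(col: str) -> np.ndarray:
        series = meta[col]
        numeric = pd.to_numeric(series, errors="coerce")
        if numeric.notna().all():
            return numeric.to_numpy(dtype=float)
        levels = sorted(series.unique())
        if len(levels) != 2:
            raise DataValidationError(
                f"column {col!r} has {len(levels)} categories; "
                "dummy-code multi-level factors explicitly"
            )
        logger.info("coding %r: %s -> 0, %s -> 1", col, levels[0], levels[1])
        return (series == levels[1]).to_numpy(dtype=float)

    X = encode(variable)
    if np.ptp(X) == 0:
        raise DataValidationError(f"variable {variable!r} is constant")
    n = len(meta)
    U = np.column_stack([np.ones(n)] + [encode(c) for c in zero_covariates])
    V = np.column_stack([np.ones(n)] + [encode(c) for c in abundance_covariates])
    return CovariateSet(X=X, U=U, V=V), table


def prevalence_filter(
    table: AbundanceTable, threshold: float
) -> tuple[AbundanceTable, list[str]]:
    """Drop taxa present in strictly less than ``threshold`` of samples.

    A taxon observed in exactly ``threshold * n`` samples is retained.
    Idempotent; returns the filtered table and the list of dropped taxa.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    n = table.n_samples
    prevalence = (table.counts > 0).sum(axis=0)
    # strict "less than" rule with a fuzz guard so exact boundaries survive
    keep = prevalence >= threshold * n - 1e-9
    dropped = [t for t, k in zip(table.taxon_ids, keep) if not k]
    if dropped:
        logger.info("prevalence filter (< %.3g) dropped: %s", threshold, dropped[:20])
    if all(keep):
        return table, []
    return table.select_taxa(keep), dropped


def write_results(results, path: str | Path, config: RunConfig | None = None) -> None:
    """Write the per-taxon result TSV plus a JSON run-metadata sidecar.

    The sidecar (``<path>.meta.json``) records the configuration, the bias
    estimate and its variance, the MCI endpoints, iteration counts and the
    package version.
    """
    from . import __version__

    path = Path(path)
    df = results.table
    cols = [
        "taxon", "delta_tilde", "delta_hat", "se", "t",
        "pvalue", "qvalue", "significant",
    ]
    if df.empty:
        logger.warning("empty result set; writing header-only output")
    out = df[cols] if not df.empty else pd.DataFrame(columns=cols)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")

    meta = {
        "version": __version__,
        "config": dataclasses.asdict(config) if config is not None else None,
        "rho": results.settings.rho,
        "fdr_level": results.settings.fdr_level,
        "gamma_hat": results.bias.gamma_hat,
        "var_gamma_hat": results.bias.var_gamma_hat,
        "mci_interval": list(results.bias.interval),
        "mci_window_size": results.bias.window_size,
        "em_iterations": results.fit.n_iter,
        "em_converged": bool(results.fit.converged),
        "n_taxa_tested": int(np.sum(results.fit.estimable)),
        "dropped_taxa": results.dropped_taxa,
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def write_counts(table: AbundanceTable, path: str | Path) -> None:
    """Write a count table in the canonical taxa-as-rows TSV layout."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(
        table.counts.T, index=table.taxon_ids, columns=table.sample_ids
    )
    df.index.name = "taxon"
    df.to_csv(path, sep=sep)
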