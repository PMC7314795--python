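"""CSV/TSV readers and writers for feature tables.

Layout convention: one header row; the sample-identifier column first, the
batch-label column (if present) second, then one column per feature.  Comma
or tab delimiter is inferred from the file extension (.csv / .tsv).  Batch
labels are read as opaque strings and never coerced to numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import BatchDesign, FeatureTable


def _sep_for(path: Path) -> str:
    if path.suffix.lower() == ".tsv":
        return "\t"
    return ","


def read_feature_table(
    path: str | Path,
    sample_col: str = "sample_id",
    batch_col: Optional[str] = None,
    covariate_cols: Optional[Sequence[str]] = None,
    outcome_col: Optional[str] = None,
    drop_incomplete: bool = False,
) -> tuple[FeatureTable, Optional[BatchDesign], Optional[np.ndarray]]:
    """Read a feature table, returning (table, design, outcome).

    Every column not designated as sample id, batch, covariate or outcome is
    parsed as a feature, in file order.  Rows with missing values are a hard
    error unless ``drop_incomplete`` is set, in which case they are removed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={sample_col: str})
    for col in [sample_col] + ([batch_col] if batch_col else []):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path.name}")
    if batch_col:
        df[batch_col] = df[batch_col].astype("string")
    covariate_cols = list(covariate_cols or [])
    if outcome_col and outcome_col in covariate_cols:
        raise ValueError(
            f"outcome column {outcome_col!r} must not be passed as a covariate"
        )
    for col in covariate_cols + ([outcome_col] if outcome_col else []):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path.name}")

    dup = df[sample_col][df[sample_col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated sample ids: {sorted(set(dup))}")
    if batch_col and df[batch_col].isna().any():
        bad = df.loc[df[batch_col].isna(), sample_col].tolist()
        raise ValueError(f"missing batch label for samples {bad}")

    reserved = {sample_col, batch_col, outcome_col, *covariate_cols} - {None}
    feature_names = [c for c in df.columns if c not in reserved]
    if not feature_names:
        raise ValueError("no feature columns found")

    if df[feature_names].isna().any().any():
        if drop_incomplete:
            df = df.dropna(subset=feature_names).reset_index(drop=True)
        else:
            mask = df[feature_names].isna()
            r, c = np.argwhere(mask.to_numpy())[0]
            raise ValueError(
                f"missing value at sample {df[sample_col].iloc[r]!r}, "
                f"feature {feature_names[c]!r} (use drop_incomplete to drop rows)"
            )

    try:
        values = df[feature_names].to_numpy(dtype=float)
    except (TypeError, ValueError):
        for c in feature_names:
            coerced = pd.to_numeric(df[c], errors="coerce")
            if coerced.isna().any():
                r = int(np.flatnonzero(coerced.isna())[0])
                raise ValueError(
                    f"non-numeric value {df[c].iloc[r]!r} at sample "
                    f"{df[sample_col].iloc[r]!r}, feature {c!r}"
                ) from None
        raise

    table = FeatureTable(df[sample_col].tolist(), feature_names, values)
    design = None
    if batch_col:
        design = BatchDesign(
            labels=df[batch_col].to_numpy(dtype=object),
            covariates=df[covariate_cols].to_numpy(dtype=float)
            if covariate_cols
            else None,
            covariate_names=covariate_cols or None,
        )
    outcome = None
    if outcome_col:
        outcome = df[outcome_col].to_numpy(dtype=float)
    return table, design, outcome


def write_feature_table(
    table: FeatureTable,
    design: Optional[BatchDesign],
    path: str | Path,
    batch_col: str = "batch",
    sample_col: str = "sample_id",
) -> None:
    """Write sample id, batch label (if any), then features, at full precision."""
    if table.n_features < 1:
        raise ValueError("refusing to write a table with no features")
    path = Path(path)
    df = pd.DataFrame({sample_col: table.sample_ids})
    if design is not None:
        if design.n_samples != table.n_samples:
            raise ValueError("table and design disagree on sample count")
        df[batch_col] = design.labels
    for j, name in enumerate(table.feature_names):
        df[name] = table.values[:, j]
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
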