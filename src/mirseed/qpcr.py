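"""ddCt quantification, 3-SD outlier exclusion and adjusted correlations.

Ct tables are tidy long-format frames with columns (sample, assay, ct,
group). Quantification is the classical ddCt scheme: per-sample
dCt = Ct(target) - Ct(housekeeper); per-group mean dCt; ddCt relative to a
reference group; fold change = 2**(-ddCt). Outliers are samples whose dCt
lies strictly outside mean ± 3 SD, with mean and SD computed once over all
samples pooled for that gene. Group contrasts use Student's t-test (two
groups) or one-way ANOVA (more); correlations are Pearson, optionally
age/sex-adjusted by residualizing both variables on the adjusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, SchemaError, ValidationError

CT_COLUMNS = ("sample", "assay", "ct", "group")
OUTLIER_SD = 3.0


def read_ct_tsv(path) -> pd.DataFrame:
    """Read a long-format Ct table and validate its schema."""
    df = pd.read_csv(path, sep="\t")
    return validate_ct(df)


def validate_ct(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"Ct table missing columns {missing}")
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if (ct <= 0).any() or not np.isfinite(ct.dropna()).all():
        raise ValidationError("Ct values must be finite and > 0")
    return df


def delta_ct(table: pd.DataFrame, target: str, housekeeper: str) -> pd.Series:
    """Per-sample dCt = Ct(target) - Ct(housekeeper).

    Samples missing either assay are excluded (with a warning); a
    housekeeper absent from the whole table is a configuration error.
    """
    validate_ct(table)
    wide = table.pivot_table(index="sample", columns="assay", values="ct", aggfunc="mean")
    if housekeeper not in wide.columns:
        raise ConfigError(f"housekeeper assay {housekeeper!r} absent from Ct table")
    if target not in wide.columns:
        raise ConfigError(f"target assay {target!r} absent from Ct table")
    dct = wide[target] - wide[housekeeper]
    dropped = list(dct.index[dct.isna()])
    if dropped:
        warnings.warn(f"samples excluded for missing Ct values: {dropped}")
    return dct.dropna()


def outlier_filter(
    dct: pd.Series, n_sd: float = OUTLIER_SD
) -> tuple[pd.Series, list]:
    """Exclude samples whose dCt is strictly outside mean ± n_sd * SD.

    Mean and SD are computed in a single pass over all samples pooled
    (no re-iteration); values at exactly n_sd SD are kept. With fewer than
    3 samples the filter is skipped with a warning.
    """
    if len(dct) < 3:
        warnings.warn("fewer than 3 samples; outlier filter skipped")
        return dct, []
    mean, sd = float(dct.mean()), float(dct.std(ddof=1))
    if sd == 0:
        return dct, []
    outside = (dct - mean).abs() > n_sd * sd
    return dct[~outside], list(dct.index[outside])


@dataclass(frozen=True)
class QpcrResult:
    """Group-level ddCt quantification for one target assay."""

    target: str
    housekeeper: str
    reference: str
    dct: Mapping[str, float]            # per-sample dCt after filtering
    group_means: Mapping[str, float]    # mean dCt per group
    ddct: Mapping[str, float]           # group mean - reference mean
    fold_change: Mapping[str, float]    # 2**(-ddct); reference == 1.0
    excluded: tuple                     # outlier sample ids
    test: str                           # "t-test" | "anova" | ""
    statistic: float
    p_value: float


def fold_change(
    dct: pd.Series,
    groups: Mapping[str, str] | pd.Series,
    reference: str,
    target: str = "",
    housekeeper: str = "",
    excluded: Sequence = (),
) -> QpcrResult:
    """ddCt fold changes of every group against *reference*.

    Two groups are compared by Student's t-test on dCt, more by one-way
    ANOVA. A lower mean dCt than the reference gives a fold change > 1.
    """
    all_groups = pd.Series(dict(groups))
    labels = all_groups.reindex(dct.index)
    if labels.isna().any():
        raise ValidationError(
            f"samples without group label: {list(dct.index[labels.isna()])[:5]}"
        )
    by_group = {g: dct[labels == g] for g in pd.unique(all_groups)}
    empty = [g for g, v in by_group.items() if len(v) == 0]
    if empty:
        raise ValidationError(f"group(s) with no samples after filtering: {empty}")
    by_group = {g: v for g, v in by_group.items() if len(v)}
    if reference not in by_group:
        raise ValidationError(f"reference group {reference!r} not present")
    if len(by_group) < 2:
        raise ValidationError("fold_change needs at least 2 groups")
    means = {g: float(v.mean()) for g, v in by_group.items()}
    ddct = {g: means[g] - means[reference] for g in means}
    folds = {g: float(2.0 ** (-d)) for g, d in ddct.items()}
    vectors = [v.to_numpy() for v in by_group.values()]
    if len(vectors) == 2:
        stat, p = stats.ttest_ind(*vectors)
        test = "t-test"
    else:
        stat, p = stats.f_oneway(*vectors)
        test = "anova"
    return QpcrResult(
        target=target, housekeeper=housekeeper, reference=reference,
        dct=dict(dct), group_means=means, ddct=ddct, fold_change=folds,
        excluded=tuple(excluded), test=test,
        statistic=float(stat), p_value=float(p),
    )


def quantify(
    table: pd.DataFrame,
    target: str,
    housekeeper: str,
    reference: str,
    outlier_sd: Optional[float] = OUTLIER_SD,
) -> QpcrResult:
    """Full pipeline: dCt, pooled 3-SD outlier exclusion, group fold changes."""
    dct = delta_ct(table, target, housekeeper)
    excluded: list = []
    if outlier_sd is not None:
        dct, excluded = outlier_filter(dct, n_sd=outlier_sd)
    groups = table.drop_duplicates("sample").set_index("sample")["group"]
    return fold_change(
        dct, groups, reference, target=target, housekeeper=housekeeper,
        excluded=excluded,
    )


def adjusted_correlation(
    x: Sequence[float] | pd.Series,
    y: Sequence[float] | pd.Series,
    adjust: Optional[pd.DataFrame] = None,
) -> tuple[float, float]:
    """Pearson correlation of *x* and *y*, optionally covariate-adjusted.

    With adjusters, both variables are residualized on them (plus an
    intercept) by ordinary least squares and the correlation is computed on
    the residuals — the partial correlation. Returns (r, p); (nan, nan)
    when either variable has zero variance after residualization. q-values
    across a correlation family come from :func:`mirseed.assoc.bh_fdr`.
    """
    x = pd.Series(np.asarray(x, dtype=float)) if not isinstance(x, pd.Series) else x.astype(float)
    y = pd.Series(np.asarray(y, dtype=float), index=x.index) if not isinstance(y, pd.Series) else y.astype(float)
    df = pd.DataFrame({"x": x, "y": y})
    if adjust is not None and len(adjust.columns) > 0:
        df = df.join(adjust.astype(float), how="inner")
    df = df.dropna()
    n_adj = 0 if adjust is None else adjust.shape[1]
    if len(df) < 4 + n_adj:
        raise ValidationError(f"too few complete cases ({len(df)}) for correlation")
    xv, yv = df["x"].to_numpy(), df["y"].to_numpy()
    if adjust is not None and n_adj > 0:
        Z = np.column_stack([np.ones(len(df)), df[adjust.columns].to_numpy()])
        xv = xv - Z @ np.linalg.lstsq(Z, xv, rcond=None)[0]
        yv = yv - Z @ np.linalg.lstsq(Z, yv, rcond=None)[0]
    if np.allclose(xv.std(), 0) or np.allclose(yv.std(), 0):
        return math.nan, math.nan
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)
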