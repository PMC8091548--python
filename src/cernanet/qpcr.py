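"""Relative quantification of qRT-PCR validation data.

Each sample contributes a target Ct and a reference-assay Ct (the internal
control measured in the same sample); per-sample ``dCt = Ct_target -
Ct_reference`` removes loading differences, and the group contrast is::

    ddCt = mean dCt(test) - mean dCt(control)
    fold change = 2 ** (-ddCt)

so a fold change above 1 means higher expression in the test group.  Group
differences of dCt are assessed with a one-way two-group ANOVA, which for
two groups is exactly the squared pooled t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DeltaDeltaCtResult", "delta_delta_ct", "two_group_anova"]

REQUIRED_COLUMNS = ("sample", "group", "assay", "ct", "ref_ct")


@dataclass
class DeltaDeltaCtResult:
    assay: str
    test_group: str
    control_group: str
    ddct: float
    fold_change: float
    mean_dct: dict  # group -> mean dCt
    se_dct: dict  # group -> SE of dCt
    f_statistic: float
    p_value: float


def delta_delta_ct(
    records: pd.DataFrame, control_group: str
) -> list[DeltaDeltaCtResult]:
    """2^-ddCt relative expression per assay, with per-group mean dCt +- SE
    and a two-group ANOVA on the per-sample dCt values.

    ``records`` needs columns sample, group, assay, ct, ref_ct.  Exactly two
    groups per assay are required, one of which is ``control_group``; every
    sample must carry both Ct values.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"Ct table missing columns {missing_cols}")
    if records[["ct", "ref_ct"]].isna().any().any():
        bad = records.loc[records[["ct", "ref_ct"]].isna().any(axis=1), "sample"].tolist()
        raise KeyError(f"missing Ct or reference Ct for samples {bad[:5]}")
    if (records[["ct", "ref_ct"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    results = []
    for assay, sub in records.groupby("assay", sort=True):
        groups = sorted(sub["group"].unique())
        if control_group not in groups:
            raise ValueError(f"assay {assay!r}: control group {control_group!r} absent")
        if len(groups) != 2:
            raise ValueError(f"assay {assay!r}: expected exactly 2 groups, got {groups}")
        test_group = next(g for g in groups if g != control_group)
        dct = sub["ct"] - sub["ref_ct"]
        by_group = {g: dct[sub["group"] == g].to_numpy() for g in groups}
        for g, vals in by_group.items():
            if len(vals) < 2:
                raise ValueError(f"assay {assay!r}: group {g!r} has < 2 samples")
        mean_dct = {g: float(np.mean(v)) for g, v in by_group.items()}
        se_dct = {g: float(np.std(v, ddof=1) / np.sqrt(len(v))) for g, v in by_group.items()}
        ddct = mean_dct[test_group] - mean_dct[control_group]
        f, p = two_group_anova(by_group[test_group], by_group[control_group])
        results.append(
            DeltaDeltaCtResult(
                assay=assay,
                test_group=test_group,
                control_group=control_group,
                ddct=float(ddct),
                fold_change=float(2.0 ** (-ddct)),
                mean_dct=mean_dct,
                se_dct=se_dct,
                f_statistic=f,
                p_value=p,
            )
        )
    return results


def two_group_anova(a, b) -> tuple[float, float]:
    """One-way ANOVA for two groups: F with (1, n-2) df, equal to the squared
    pooled two-sample t statistic."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ssw == 0:
        if a.mean() == b.mean():
            raise ZeroDivisionError(
                "zero within-group variance with equal means: F undefined"
            )
        return float("inf"), 0.0
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)


def results_to_frame(results: list[DeltaDeltaCtResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "assay": r.assay,
                "test_group": r.test_group,
                "control_group": r.control_group,
                "ddct": r.ddct,
                "fold_change": r.fold_change,
                "mean_dct_test": r.mean_dct[r.test_group],
                "mean_dct_control": r.mean_dct[r.control_group],
                "se_dct_test": r.se_dct[r.test_group],
                "se_dct_control": r.se_dct[r.control_group],
                "F": r.f_statistic,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)
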