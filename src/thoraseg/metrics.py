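"""Validation statistics: Dice overlap, rank correlation, group tests,
and longitudinal burden summaries."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: Bonferroni-corrected significance level for the category comparisons
BONFERRONI_ALPHA = 0.0056


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Sorenson-Dice overlap ``2|A∩B| / (|A|+|B|)``.

    Defined as 1.0 when both masks are empty.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def group_compare(
    results_by_category: dict,
    tissues: tuple[str, ...] = ("lung", "soft", "intermediate"),
    baseline_category=0,
    alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """Two-sample t-tests of each tumor category against the baseline one.

    ``results_by_category`` maps category → mapping tissue → list of
    percentages (or a DataFrame with tissue columns).  Each non-baseline
    category is compared with the baseline per tissue; significance is
    flagged at the Bonferroni-corrected ``alpha``.  Comparisons with
    degenerate (zero) pooled variance are reported as errors while the
    rest proceed.
    """
    if baseline_category not in results_by_category:
        raise ValueError(f"baseline category {baseline_category!r} missing")

    def _col(cat, tissue):
        data = results_by_category[cat]
        vals = np.asarray(
            data[tissue] if not isinstance(data, pd.DataFrame) else data[tissue].to_numpy(),
            dtype=float,
        )
        if len(vals) < 2:
            raise ValueError(f"category {cat!r} needs >= 2 observations for {tissue}")
        return vals

    rows = []
    for cat in sorted(k for k in results_by_category if k != baseline_category):
        for tissue in tissues:
            ref = _col(baseline_category, tissue)
            obs = _col(cat, tissue)
            row = {
                "category": cat,
                "tissue": tissue,
                "n_ref": len(ref),
                "n_obs": len(obs),
                "mean_ref": float(ref.mean()),
                "mean_obs": float(obs.mean()),
            }
            if ref.std(ddof=1) == 0 and obs.std(ddof=1) == 0:
                row.update(t=np.nan, p=np.nan, significant=False,
                           error="degenerate variance")
            else:
                t, p = stats.ttest_ind(obs, ref)
                row.update(t=float(t), p=float(p), significant=bool(p < alpha), error="")
            rows.append(row)
    return pd.DataFrame(rows)


def longitudinal_summary(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject lung-percentage change from baseline, with group means.

    ``results`` needs columns ``subject``, ``timepoint``, ``pct_lung`` and
    optionally ``group``.  The earliest timepoint per subject is its
    baseline; subjects with a single timepoint get empty change columns,
    and subjects missing a baseline row are skipped with a warning.
    Returns ``(per_subject, group_summary)``; group means carry SEM.
    """
    required = {"subject", "timepoint", "pct_lung"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns {sorted(missing)}")
    df = results.copy()
    if "group" not in df.columns:
        df["group"] = "all"
    rows = []
    for subject, sub in df.groupby("subject", sort=True):
        sub = sub.sort_values("timepoint")
        base = sub.iloc[0]
        if not np.isfinite(base["pct_lung"]):
            log.warning("subject %s has no usable baseline; skipped", subject)
            continue
        for _, r in sub.iterrows():
            is_base = r["timepoint"] == base["timepoint"]
            change = np.nan if is_base and len(sub) == 1 else r["pct_lung"] - base["pct_lung"]
            rel = (
                np.nan
                if (is_base and len(sub) == 1) or base["pct_lung"] == 0
                else 100.0 * (r["pct_lung"] - base["pct_lung"]) / base["pct_lung"]
            )
            rows.append(
                {
                    "subject": subject,
                    "group": r["group"],
                    "timepoint": r["timepoint"],
                    "pct_lung": r["pct_lung"],
                    "pct_lung_change": change,
                    "pct_lung_rel_change": rel,
                }
            )
    per_subject = pd.DataFrame(rows)
    if per_subject.empty:
        raise ValueError("no subjects with a baseline timepoint")
    followup = per_subject[per_subject["timepoint"] > per_subject.groupby("subject")["timepoint"].transform("min")]
    group_summary = (
        followup.groupby(["group", "timepoint"])["pct_lung_rel_change"]
        .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="count")
        .reset_index()
    )
    return per_subject, group_summary
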