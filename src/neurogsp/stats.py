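"""Group-level statistics over SDI maps: contrasts, band concordance, reliability.

Three standard analyses sit downstream of the per-subject coupling maps:

* a paired t-test per region between two conditions, Benjamini-Hochberg
  FDR-corrected across regions;
* Spearman rank correlation between frequency bands after aggregating
  region values into large-scale functional networks;
* test-retest reliability as a two-way random-effects intraclass
  correlation, treating conditions (e.g. two movie runs) as raters and
  regions as items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupContrast",
    "paired_contrast",
    "network_aggregate",
    "network_spearman",
    "icc_two_way_random",
]


@dataclass
class GroupContrast:
    """Per-region paired-contrast result between two conditions."""

    t_values: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    mask: np.ndarray
    contrast: tuple[str, str]
    alpha: float = 0.05


def paired_contrast(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    alpha: float = 0.05,
    contrast: tuple[str, str] = ("a", "b"),
) -> GroupContrast:
    """Paired t-test per region between two condition SDI matrices.

    ``maps_a`` and ``maps_b`` are (subjects, regions) matrices paired by
    row.  Negative t means lower values (stronger coupling) in condition
    ``a``.  Two-sided p-values are Benjamini-Hochberg adjusted across
    regions and the mask flags ``q <= alpha``.

    Regions whose paired differences are exactly constant have undefined t;
    a nonzero constant difference is flagged significant directly (infinite
    evidence), a zero one gets t = 0, p = 1.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"unpaired shapes {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("paired contrast needs at least 3 subject pairs")
    diff = a - b
    zero_var = np.ptp(diff, axis=0) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sp_stats.ttest_rel(a, b, axis=0)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(zero_var):
        mean_diff = diff.mean(axis=0)
        exact_null = zero_var & (mean_diff == 0)
        exact_shift = zero_var & (mean_diff != 0)
        t[exact_null], p[exact_null] = 0.0, 1.0
        t[exact_shift] = np.where(mean_diff[exact_shift] > 0, np.inf, -np.inf)
        p[exact_shift] = 0.0
        if np.any(exact_shift):
            warnings.warn(
                "zero-variance nonzero paired difference: t reported as "
                "+/-inf with p = 0",
                UserWarning,
                stacklevel=2,
            )
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return GroupContrast(
        t_values=t, p_values=p, q_values=q, mask=reject,
        contrast=contrast, alpha=alpha,
    )


def network_aggregate(
    values: np.ndarray, region_to_network: pd.Series | dict
) -> pd.Series:
    """Mean of a per-region vector within each network label.

    Every region must carry exactly one network label; unmapped regions are
    an error, not silently dropped.
    """
    mapping = pd.Series(region_to_network)
    values = np.asarray(values, dtype=float)
    if len(mapping) != len(values):
        raise ValueError(
            f"{len(mapping)} network labels for {len(values)} regions"
        )
    if mapping.isna().any():
        raise ValueError("unmapped region(s) in the network table")
    return pd.Series(values, index=mapping.values).groupby(level=0).mean()


def network_spearman(
    band_maps: dict[str, np.ndarray],
    region_to_network: pd.Series | dict,
) -> pd.DataFrame:
    """Spearman rho between band pairs on network-aggregated SDI values.

    Returns a long-format table with one row per unordered band pair:
    columns ``band_a, band_b, rho, p_value``.
    """
    if len(band_maps) < 2:
        raise ValueError("need at least two bands to correlate")
    agg = {band: network_aggregate(v, region_to_network) for band, v in band_maps.items()}
    bands = list(agg)
    rows = []
    for i, ba in enumerate(bands):
        for bb in bands[i + 1 :]:
            rho, p = sp_stats.spearmanr(agg[ba].values, agg[bb].values)
            rows.append({"band_a": ba, "band_b": bb, "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


def icc_two_way_random(
    ratings: np.ndarray, kind: str = "mean", ci: float = 0.95
) -> tuple[float, float, float]:
    """Two-way random-effects intraclass correlation with an F-based CI.

    ``ratings`` is an (items, raters) matrix with no missing cells — here
    items are brain regions and raters are conditions.  ``kind="mean"``
    returns ICC(2,k), the reliability of the mean of the k raters (the
    default use: two movie runs averaged); ``kind="single"`` returns
    ICC(2,1).  Delegates to :func:`pingouin.intraclass_corr`.

    Returns ``(estimate, ci_low, ci_high)``.
    """
    import pingouin as pg  # deferred: pingouin import is slow

    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an (items, raters) matrix, >= 2 raters")
    if x.shape[0] < 5:
        raise ValueError("need at least 5 items for a stable ICC")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite ratings are not supported")
    if kind not in ("single", "mean"):
        raise ValueError("kind must be 'single' or 'mean'")
    n_items, n_raters = x.shape
    long = pd.DataFrame(
        {
            "item": np.repeat(np.arange(n_items), n_raters),
            "rater": np.tile(np.arange(n_raters), n_items),
            "score": x.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=long, targets="item", raters="rater", ratings="score"
        ).set_index("Type")
    # two-way random effects, absolute agreement: labelled ICC2/ICC2k in the
    # Shrout-Fleiss scheme, ICC(A,1)/ICC(A,k) in the McGraw-Wong scheme
    candidates = (
        ("ICC2k", "ICC(A,k)") if kind == "mean" else ("ICC2", "ICC(A,1)")
    )
    key = next(k for k in candidates if k in table.index)
    row = table.loc[key]
    ci_col = next(c for c in table.columns if c.startswith("CI95"))
    lo, hi = row[ci_col]
    if ci != 0.95:
        raise NotImplementedError("only the 95% confidence interval is exposed")
    return float(row["ICC"]), float(lo), float(hi)
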