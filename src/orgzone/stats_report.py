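"""Seeding arithmetic, robust outlier removal, correlation and reporting.

The seeding calculator implements the co-culture convention ``PBMCs needed =
V (ul) x 22,000 x n`` with an epithelial density of 20,000 cells/ul (an
approximate convention back-derived from the printed 10 ul -> ~200,000-cell
pairing), giving the 1.1 : 1 effector-to-target ratio of the assay.

ROUT (Robust regression and OUTlier removal) is specialized here to the
location-only model appropriate for univariate per-organoid distributions:
the robust centre is the median, the robust spread (RSDR) is the 68.27th
percentile of absolute residuals with an n/(n-K) small-sample correction
(K = 1), and points are flagged largest-residual-first by an FDR step at
rate Q using two-tailed t P-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

PBMC_PER_UL = 22_000
EPITHELIAL_PER_UL = 20_000   # approximate convention (10 ul dome ~ 200,000 cells)


@dataclass
class SeedingPlan:
    """PBMC/epithelial cell numbers for co-culture domes.

    ``pbmcs_needed = V x 22,000 x n`` exactly (integer arithmetic, no
    rounding); ``epithelial_cells`` uses the approximate 20,000 cells/ul
    convention and ``et_ratio`` is the resulting effector : target pair.
    """

    volume_ul: float
    n_samples: int
    pbmcs_needed: int
    epithelial_cells: int
    et_ratio: tuple


@dataclass
class OutlierResult:
    """Partition of a sample into kept and flagged values.

    ``kept`` and ``flagged`` partition the input; ``center`` is the median
    and ``spread`` the RSDR used for the t statistics.
    """

    kept: np.ndarray
    flagged: np.ndarray
    outlier_mask: np.ndarray
    q: float
    center: float
    spread: float


def pbmc_seeding(volume_ul, n_samples=1):
    """Number of PBMCs for ``n_samples`` domes of ``volume_ul`` microlitres.

    Exact: 10 ul, n=1 gives 220,000 PBMCs to ~200,000 epithelial cells; a
    25 ul dome gives 550,000 to 500,000.
    """
    if volume_ul < 0 or n_samples < 0:
        raise ValueError("volume and sample count must be nonnegative")
    if int(n_samples) != n_samples:
        raise ValueError("n_samples must be an integer")
    n_samples = int(n_samples)
    pbmcs = volume_ul * PBMC_PER_UL * n_samples
    epithelial = volume_ul * EPITHELIAL_PER_UL
    pbmcs = int(pbmcs) if float(pbmcs).is_integer() else pbmcs
    epithelial = int(epithelial) if float(epithelial).is_integer() else epithelial
    ratio = (PBMC_PER_UL / EPITHELIAL_PER_UL, 1.0)  # 1.1 : 1 per dome
    return SeedingPlan(volume_ul=volume_ul, n_samples=n_samples,
                       pbmcs_needed=pbmcs, epithelial_cells=epithelial,
                       et_ratio=ratio)


def rout_outliers(values, q=0.02):
    """Location-only ROUT outlier detection at FDR rate ``q`` (default 2%).

    Residuals are taken from the median; RSDR is the 68.27th percentile of
    the absolute residuals times n/(n-K) with K = 1 (floored at a tiny
    positive value so a majority of identical points still exposes gross
    outliers).  Points are examined from the largest absolute residual down;
    the i-th largest is flagged while its two-tailed t P-value (df = n-K)
    is below ``q * (n - i + 1) / n``, stopping at the first point that is
    not.  Flagging depends only on residual magnitudes, so the partition is
    permutation invariant.
    """
    values = np.asarray(values, float).ravel()
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if not 0.0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    center = float(np.median(values))
    resid = values - center
    absr = np.abs(resid)
    rsdr = float(np.percentile(absr, 68.27)) * n / (n - 1)
    if rsdr <= 0:
        scale = max(1.0, float(np.max(absr)))
        rsdr = 1e-12 * scale      # spread floor for degenerate samples
    order = np.argsort(-absr, kind="stable")
    mask = np.zeros(n, bool)
    for i, idx in enumerate(order, start=1):
        t = absr[idx] / rsdr
        p = 2.0 * stats.t.sf(t, df=n - 1)
        if p < q * (n - i + 1) / n:
            mask[idx] = True
        else:
            break
    if mask.any():
        log.info("rout_outliers: flagged %d of %d values (Q=%.3f)",
                 int(mask.sum()), n, q)
    return OutlierResult(kept=values[~mask], flagged=values[mask],
                         outlier_mask=mask, q=q, center=center, spread=rsdr)


def linreg_r2(x, y):
    """Ordinary least squares fit; returns (slope, intercept, R^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def ttest_two_sample(a, b, **kwargs):
    """Thin pass-through to an unpaired two-sample t-test."""
    return stats.ttest_ind(a, b, **kwargs)


def anova_oneway(*groups):
    """Thin pass-through to one-way ANOVA."""
    return stats.f_oneway(*groups)


# ---------------------------------------------------------------------------
# report bundle

_COUNT_KEYS = ("condition", "timepoint_h")


def _check_keys(count_table, killing_table, col="condition"):
    if count_table is None or killing_table is None:
        return
    if len(count_table) == 0 or len(killing_table) == 0:
        return
    if col not in count_table.columns or col not in killing_table.columns:
        return
    a = set(count_table[col].unique())
    b = set(killing_table[col].unique())
    if a != b:
        raise ValueError(
            f"mismatched '{col}' keys between count and killing tables: "
            f"{sorted(a.symmetric_difference(b))}")


def build_report(count_table=None, killing_table=None, integrity_table=None,
                 outdir=None):
    """Tidy summary bundle of the pipeline outputs.

    Returns a dict of DataFrames: ``zone_counts`` (phenotype-by-zone count
    matrix per condition and timepoint), ``fold_matrix`` (condition x
    timepoint NT-normalized folds, heat-map ready) and
    ``integrity_summary`` (mean class fractions per condition and
    timepoint).  Empty inputs give empty but schema-valid frames.  Output is
    deterministic: rows and columns are sorted, and with ``outdir`` given the
    frames are written as byte-stable CSV files.
    """
    _check_keys(count_table, killing_table)
    report = {}

    if count_table is not None and len(count_table):
        keys = [k for k in _COUNT_KEYS if k in count_table.columns]
        zc = (count_table.pivot_table(index=keys + ["phenotype"], columns="zone",
                                      values="count", aggfunc="sum", fill_value=0)
                          .sort_index())
        zc.columns = [f"zone_{z}" for z in zc.columns]
        report["zone_counts"] = zc.reset_index()
    else:
        report["zone_counts"] = pd.DataFrame(columns=["phenotype"])

    if killing_table is not None and len(killing_table) and "fold" in killing_table:
        fm = (killing_table.pivot_table(index="condition", columns="timepoint_h",
                                        values="fold", aggfunc="mean")
                           .sort_index())
        fm.columns = [f"t{int(t)}h" if float(t).is_integer() else f"t{t}h"
                      for t in fm.columns]
        report["fold_matrix"] = fm.reset_index()
    else:
        report["fold_matrix"] = pd.DataFrame(columns=["condition"])

    if integrity_table is not None and len(integrity_table):
        keys = [k for k in _COUNT_KEYS if k in integrity_table.columns]
        cols = [c for c in ("fraction_panck", "fraction_caspase", "fraction_other")
                if c in integrity_table.columns]
        if keys:
            summary = (integrity_table.groupby(keys, sort=True)[cols]
                                      .mean().reset_index())
        else:
            summary = integrity_table[cols].mean().to_frame().T
        report["integrity_summary"] = summary
    else:
        report["integrity_summary"] = pd.DataFrame(
            columns=["fraction_panck", "fraction_caspase", "fraction_other"])

    if outdir is not None:
        import os
        os.makedirs(outdir, exist_ok=True)
        for name, df in report.items():
            df.to_csv(os.path.join(outdir, f"{name}.csv"), index=False,
                      float_format="%.10g")
    return report
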