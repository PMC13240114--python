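"""Stable-isotope niche statistics: pooled means, baseline offsets, standard
ellipse areas (SEA/SEAc) and convex-hull total areas (TA).

Samples are skin d13C (permil VPDB) / d15N (permil AIR) observations tagged
with location, collection year and sex.  The standard ellipse area is
SEA = pi * sqrt(lambda1 * lambda2) with lambda the eigenvalues of the 2x2
sample covariance (it covers ~40% of a bivariate normal — the "core"
niche); SEAc = SEA * (n-1)/(n-2) corrects for small samples.  TA is the
shoelace area of the convex hull of all points (the total niche).
Cross-ecoregion comparisons first express one group on the other region's
isoscape baseline via zooplankton-derived offsets.  Secular d13C depletion
(Suess/Laws effects) is consumed as user-supplied per-year offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import ttest_ind

from .errors import InsufficientDataError, UndefinedStatisticError

__all__ = [
    "NicheMetrics",
    "BaselineOffset",
    "read_isotope_csv",
    "pooled_stats",
    "baseline_offsets",
    "apply_baseline_shift",
    "apply_suess_offsets",
    "niche_metrics",
    "compare_groups",
]

_SANITY = {"d13C": (-30.0, -10.0), "d15N": (0.0, 25.0)}


@dataclass
class NicheMetrics:
    """Group-level bivariate niche summary (areas in permil^2)."""

    group: str
    n: int
    mean_d13C: float
    mean_d15N: float
    sd_d13C: float
    sd_d15N: float
    sea: float
    seac: float
    ta: float


@dataclass
class BaselineOffset:
    """Permil offsets that re-express one ecoregion on another's baseline."""

    d13C_offset: float
    d15N_offset: float

    def rounded(self, decimals: int = 1) -> tuple[float, float]:
        return (round(self.d13C_offset, decimals), round(self.d15N_offset, decimals))


def read_isotope_csv(path) -> pd.DataFrame:
    """Read ``sample_id,location,year,sex,d13C,d15N[,corrected]`` with sanity
    warnings (not rejections) for implausible delta values."""
    df = pd.read_csv(path)
    for col in ("sample_id", "location", "year", "d13C", "d15N"):
        if col not in df.columns:
            raise InsufficientDataError(f"isotope CSV missing column {col}")
    if "corrected" not in df.columns:
        df["corrected"] = False
    for col, (lo, hi) in _SANITY.items():
        bad = (df[col] < lo) | (df[col] > hi)
        if bad.any():
            warnings.warn(f"{int(bad.sum())} {col} values outside [{lo}, {hi}] permil")
    return df


def pooled_stats(samples: pd.DataFrame, by=("location", "year")) -> pd.DataFrame:
    """Mean, SD (n-1) and n per group plus a pooled row per top-level group.

    The pooled mean is the n-weighted mean of group means, identical to the
    grand mean of the raw values.
    """
    by = list(by)
    rows = []
    for keys, grp in samples.groupby(by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(by, keys))
        row.update(
            n=len(grp),
            mean_d13C=grp["d13C"].mean(),
            mean_d15N=grp["d15N"].mean(),
            sd_d13C=grp["d13C"].std(ddof=1),
            sd_d15N=grp["d15N"].std(ddof=1),
        )
        rows.append(row)
    if len(by) > 1:
        for key, grp in samples.groupby(by[0]):
            rows.append(
                {
                    by[0]: key,
                    by[1]: "all",
                    "n": len(grp),
                    "mean_d13C": grp["d13C"].mean(),
                    "mean_d15N": grp["d15N"].mean(),
                    "sd_d13C": grp["d13C"].std(ddof=1),
                    "sd_d15N": grp["d15N"].std(ddof=1),
                }
            )
    return pd.DataFrame(rows)


def baseline_offsets(zoo_means_from, zoo_means_to) -> BaselineOffset:
    """Offsets to add to the *from* ecoregion's whale values so they sit on
    the *to* ecoregion's zooplankton baseline.

    Each offset is (to - from) for that isotope; e.g. shifting from a
    baseline with d13C -23.61 onto one with -21.89 adds +1.72 permil.
    """
    c_from, n_from = zoo_means_from
    c_to, n_to = zoo_means_to
    off = BaselineOffset(float(c_to) - float(c_from), float(n_to) - float(n_from))
    if not (np.isfinite(off.d13C_offset) and np.isfinite(off.d15N_offset)):
        raise UndefinedStatisticError("non-finite baseline offsets")
    return off


def apply_baseline_shift(
    samples: pd.DataFrame, offset: BaselineOffset, location: str
) -> pd.DataFrame:
    """Add the offsets to one location's values; flags rows as adjusted."""
    out = samples.copy()
    sel = out["location"] == location
    out.loc[sel, "d13C"] = out.loc[sel, "d13C"] + offset.d13C_offset
    out.loc[sel, "d15N"] = out.loc[sel, "d15N"] + offset.d15N_offset
    out["baseline_adjusted"] = out.get("baseline_adjusted", False) | sel
    return out


def apply_suess_offsets(samples: pd.DataFrame, year_offsets: dict[int, float]) -> pd.DataFrame:
    """Apply user-supplied per-collection-year d13C offsets (e.g. Suess/Laws
    corrections to a reference year) and set the ``corrected`` flag."""
    out = samples.copy()
    off = out["year"].map(lambda y: year_offsets.get(int(y), 0.0))
    out["d13C"] = out["d13C"] + off
    out["corrected"] = True
    return out


def niche_metrics(samples: pd.DataFrame, group: str = "") -> NicheMetrics:
    """SEA, SEAc and convex-hull TA for one group of (d13C, d15N) points.

    Needs n >= 3 non-collinear points for TA; SEAc uses the (n-1)/(n-2)
    correction, so n >= 4 is recommended for a stable core-niche estimate.
    Collinear points give TA = 0 with a warning.
    """
    pts = samples[["d13C", "d15N"]].to_numpy(dtype=float)
    n = len(pts)
    if n < 3:
        raise InsufficientDataError("niche metrics need n >= 3 samples")
    cov = np.cov(pts, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(cov)
    sea = float(np.pi * np.sqrt(max(eig[0], 0.0) * max(eig[1], 0.0)))
    seac = sea * (n - 1) / (n - 2)
    try:
        ta = float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        warnings.warn("collinear isotope points: hull area set to 0")
        ta = 0.0
    return NicheMetrics(
        group=group,
        n=n,
        mean_d13C=float(pts[:, 0].mean()),
        mean_d15N=float(pts[:, 1].mean()),
        sd_d13C=float(pts[:, 0].std(ddof=1)),
        sd_d15N=float(pts[:, 1].std(ddof=1)),
        sea=sea,
        seac=float(seac),
        ta=ta,
    )


def compare_groups(a: pd.DataFrame, b: pd.DataFrame, equal_var: bool = False) -> pd.DataFrame:
    """Two-sample t-tests (Welch by default) per isotope between two groups.

    Returns one row per isotope with T, degrees of freedom and p.
    """
    rows = []
    for iso in ("d13C", "d15N"):
        x = a[iso].to_numpy(dtype=float)
        y = b[iso].to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise InsufficientDataError("t-test needs n >= 2 per group")
        if np.std(x) == 0 and np.std(y) == 0:
            raise UndefinedStatisticError("zero variance in both groups")
        res = ttest_ind(x, y, equal_var=equal_var)
        rows.append(
            {
                "isotope": iso,
                "T": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)
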