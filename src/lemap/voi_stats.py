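"""First-order histogram statistics inside a VOI and group comparison.

Eleven descriptive statistics of the voxel-value distribution within a VOI:
mean, median, standard deviation, variance, root mean square (RMS), the
5th/25th/75th/95th percentiles, and the number of zero crossings and of mean
crossings. The same machinery serves the entropy map (values in nats) and
the parallel Hounsfield-unit workflow (raw CT values).

Conventions (fixed for reproducibility):

* variance is the population (1/N) variance — a VOI is the full population
  of its voxels — so rms^2 == mean^2 + variance holds exactly;
* percentiles use linear interpolation between order statistics;
* crossing counts are taken on the in-VOI voxel sequence in canonical raster
  scan order (C-order over the (x, y, z) array, last axis fastest): a mean
  crossing is a consecutive pair strictly straddling the VOI mean, and a
  zero crossing is the same count on the mean-centered sequence — the two
  are therefore equal by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .entropy_core import EntropyMap
from .volume_io import Mask, Volume

__all__ = [
    "STAT_NAMES",
    "HistogramStats",
    "GroupComparison",
    "histogram_stats_from_values",
    "extract_histogram_stats",
    "hounsfield_stats",
    "global_entropy",
    "compare_groups",
]

logger = logging.getLogger(__name__)

#: the 11 named histogram statistics, in reporting order
STAT_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "std_dev",
    "variance",
    "rms",
    "p5",
    "p25",
    "p75",
    "p95",
    "n_zero_crossings",
    "n_mean_crossings",
)


@dataclass(frozen=True)
class HistogramStats:
    """The 11 first-order statistics of the values inside one VOI."""

    mean: float
    median: float
    std_dev: float
    variance: float
    rms: float
    p5: float
    p25: float
    p75: float
    p95: float
    n_zero_crossings: int
    n_mean_crossings: int
    voi_voxel_count: int = 0
    source_stage: str = "raw"

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in STAT_NAMES}
        d["voi_voxel_count"] = self.voi_voxel_count
        d["source_stage"] = self.source_stage
        return d

    def values_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STAT_NAMES], dtype=float)


def _count_crossings(seq: np.ndarray, level: float) -> int:
    """Number of consecutive pairs strictly straddling ``level``."""
    s = seq - level
    return int(np.count_nonzero(s[:-1] * s[1:] < 0))


def histogram_stats_from_values(
    values: Sequence[float] | np.ndarray,
    source_stage: str = "raw",
) -> HistogramStats:
    """Compute the 11 statistics from a 1D value sequence (scan order)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty VOI: no values to summarize")
    mean = float(v.mean())
    var = float(v.var())  # population (1/N)
    std = math.sqrt(var)
    rms = math.sqrt(float(np.mean(v * v)))
    p5, p25, med, p75, p95 = (float(x) for x in np.percentile(v, [5, 25, 50, 75, 95]))
    n_mean = _count_crossings(v, mean)
    n_zero = _count_crossings(v - mean, 0.0)  # equal to n_mean by construction
    return HistogramStats(
        mean=mean, median=med, std_dev=std, variance=var, rms=rms,
        p5=p5, p25=p25, p75=p75, p95=p95,
        n_zero_crossings=n_zero, n_mean_crossings=n_mean,
        voi_voxel_count=int(v.size), source_stage=source_stage,
    )


def _voi_values(m: Volume, voi: Mask) -> np.ndarray:
    m.require_same_grid(voi, what="VOI")
    if voi.n_voxels == 0:
        raise ValueError("empty VOI")
    vals = m.data[voi.data]  # C-order raster through the VOI
    bad = ~np.isfinite(vals)
    if bad.any():
        logger.info("dropping %d missing-border voxel(s) from VOI", int(bad.sum()))
        vals = vals[~bad]
        if vals.size == 0:
            raise ValueError("VOI covers only missing (excluded-border) voxels")
    return vals


def extract_histogram_stats(m: EntropyMap | Volume, voi: Mask) -> HistogramStats:
    """The 11 histogram statistics of an entropy map inside the tumor VOI.

    VOI voxels lying in an excluded border (exclude-border padding) are
    dropped with a logged count.
    """
    stage = m.stage if isinstance(m, EntropyMap) else "raw"
    return histogram_stats_from_values(_voi_values(m, voi), source_stage=stage)


def hounsfield_stats(ct: Volume, voi: Mask) -> HistogramStats:
    """Same 11 statistics computed on raw Hounsfield units inside the VOI."""
    return histogram_stats_from_values(_voi_values(ct, voi), source_stage="hounsfield")


def global_entropy(v: Volume, voi: Mask, n_bins: int = 64, log_base: str | float = "e") -> float:
    """First-order Shannon entropy of the in-VOI intensity histogram.

    The in-VOI values are discretized into ``n_bins`` equal-width bins over
    their min–max range and H = -sum p_b log(p_b) is returned in the chosen
    base ('e' for nats, 2 for bits). A constant VOI has entropy 0.

    This is an equal-width-binned first-order entropy, an approximation of
    (not a replica of) values produced by external radiomics software, whose
    binning and base are implementation-specific.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    vals = _voi_values(v, voi)
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(vals, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / vals.size
    ent = float(-(p * np.log(p)).sum())
    if log_base in ("e", math.e):
        return ent
    return ent / math.log(float(log_base))


@dataclass
class GroupComparison:
    """Per-statistic nonparametric comparison between two subject groups."""

    table: pd.DataFrame
    group_labels: tuple[str, str]
    alpha: float = 0.05

    @property
    def significant(self) -> list[str]:
        t = self.table
        return list(t.loc[(~t["degenerate"]) & (t["p_value"] < self.alpha), "statistic"])


def compare_groups(
    stats_by_subject: Sequence[HistogramStats],
    labels: Sequence,
    alpha: float = 0.05,
    fdr: bool = False,
) -> GroupComparison:
    """Compare the 11 statistics between two groups of subjects.

    Each statistic is z-score standardized across all subjects and the two
    groups are compared with a two-sided Mann–Whitney U test (exact null
    distribution for small samples without ties, normal approximation with
    tie correction otherwise — scipy's automatic policy). Raw p-values are
    reported; ``fdr=True`` adds Benjamini–Hochberg adjusted p-values.

    A statistic that is identical across all subjects leaves the test
    undefined; it is flagged ``degenerate`` with a NaN p-value, not an error.
    """
    if len(stats_by_subject) != len(labels):
        raise ValueError("stats_by_subject and labels must have equal length")
    uniq = sorted(set(labels), key=str)
    if len(uniq) != 2:
        raise ValueError(f"exactly two group labels required, got {uniq}")
    labels = np.asarray([uniq.index(l) for l in labels])
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")

    X = np.vstack([s.values_vector() for s in stats_by_subject])
    rows = []
    for j, name in enumerate(STAT_NAMES):
        col = X[:, j].astype(float)
        sd = col.std()
        degenerate = sd == 0
        z = (col - col.mean()) / sd if not degenerate else np.zeros_like(col)
        a, b = z[labels == 0], z[labels == 1]
        if degenerate:
            u, p = math.nan, math.nan
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append({
            "statistic": name,
            f"median_{uniq[0]}": float(np.median(col[labels == 0])),
            f"median_{uniq[1]}": float(np.median(col[labels == 1])),
            "u_statistic": u,
            "p_value": p,
            "degenerate": bool(degenerate),
        })
    table = pd.DataFrame(rows)
    if fdr:
        ok = ~table["degenerate"]
        adj = np.full(len(table), math.nan)
        if ok.any():
            adj[np.where(ok)[0]] = sps.false_discovery_control(
                table.loc[ok, "p_value"].to_numpy(), method="bh"
            )
        table["p_value_fdr"] = adj
    return GroupComparison(table=table, group_labels=(str(uniq[0]), str(uniq[1])), alpha=alpha)


def stats_table(
    stats_list: Sequence[HistogramStats],
    subject_ids: Sequence | None = None,
    voi_names: Sequence | None = None,
) -> pd.DataFrame:
    """Tabulate stats: one row per subject per VOI, fixed column names."""
    rows = []
    for i, s in enumerate(stats_list):
        row = {"subject": subject_ids[i] if subject_ids is not None else i}
        if voi_names is not None:
            row["voi"] = voi_names[i]
        row.update(s.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
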