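"""Rigidity-versus-compactness analysis of predicted dimers.

Significant predictions that share the same motif pair, orientation and
left-right ordering within one target dataset, differing only in spacing,
are grouped.  Spacings are recomputed between the proximal edges of the
*trimmed* motifs (flanking columns with information content <= 0.25 bit
removed), which makes spacing comparable across motifs with uninformative
flanks.  A group with a single distinct spacing is a rigid dimer; groups
with several spacings are flexible.  The analysis reports, per group, the
number of distinct spacings, their mean and standard deviation, plus Pearson
correlations of flexibility measures against mean spacing and a two-sided
Mann-Whitney U test comparing mean spacings of rigid versus flexible groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr

from .complexes import reported_spacing
from .enrichment import EnrichmentResult
from .motifs import Motif, TrimmedView, trim_motif

logger = logging.getLogger(__name__)


@dataclass
class SpacingGroup:
    """Predictions of one motif pair + orientation in one dataset."""

    orientation_key: tuple
    dataset: str
    spacings: list[int] = field(default_factory=list)  # distinct, trimmed
    best_p: float = 1.0

    @property
    def n_spacings(self) -> int:
        return len(self.spacings)

    @property
    def mean_spacing(self) -> float:
        return float(np.mean(self.spacings))

    @property
    def sd_spacing(self) -> float:
        if len(self.spacings) < 2:
            return 0.0
        return float(np.std(self.spacings, ddof=1))


def group_predictions(results: list[EnrichmentResult],
                      trims: dict[str, TrimmedView]) -> list[SpacingGroup]:
    """Partition significant results by (pair, orientation, ordering, dataset).

    ``trims`` maps motif ids to their trimmed views; results involving a
    fully trimmed motif have no defined trimmed spacing and are dropped with
    a warning.  Groups are ranked by their best (smallest) raw p-value.
    """
    groups: dict[tuple, SpacingGroup] = {}
    for r in results:
        c = r.complex
        tl, tr = trims.get(c.left_id), trims.get(c.right_id)
        if tl is None or tr is None:
            logger.warning("no trimmed view for %s; skipped in flexibility analysis",
                           r.signature)
            continue
        s = reported_spacing(c, tl, tr)
        if s is None:
            logger.warning("%s involves a fully trimmed motif; skipped", r.signature)
            continue
        key = (c.orientation_key, r.target_name)
        g = groups.setdefault(key, SpacingGroup(c.orientation_key, r.target_name))
        if s not in g.spacings:
            g.spacings.append(s)
        g.best_p = min(g.best_p, r.p_raw)
    out = sorted(groups.values(), key=lambda g: (g.best_p, g.orientation_key, g.dataset))
    for g in out:
        g.spacings.sort()
    return out


def trims_for(motifs: list[Motif], ic_cutoff: float = 0.25) -> dict[str, TrimmedView]:
    return {m.id: trim_motif(m, ic_cutoff) for m in motifs}


@dataclass
class FlexibilityStats:
    table: pd.DataFrame
    r_count_vs_mean: float
    p_count_vs_mean: float
    r_sd_vs_mean: float
    p_sd_vs_mean: float
    mannwhitney_p: float
    n_rigid: int
    n_flexible: int


def flexibility_stats(groups: list[SpacingGroup]) -> FlexibilityStats:
    """Per-group spacing statistics and the rigidity-compactness correlations.

    Pearson r is computed between the number of distinct spacings and the
    mean spacing, and between the spacing SD and the mean spacing; the
    Mann-Whitney U test compares mean spacings of rigid (one spacing) and
    flexible (several spacings) groups, two-sided (exact for small samples
    without ties, normal approximation with tie correction otherwise).
    Undefined statistics (constant input, missing class) are reported as NaN.
    """
    rows = [{
        "pair": "/".join(g.orientation_key[:2]),
        "orientation": f"{g.orientation_key[2]}{g.orientation_key[3]}",
        "dataset": g.dataset,
        "n_spacings": g.n_spacings,
        "mean_spacing": g.mean_spacing,
        "sd_spacing": g.sd_spacing,
        "best_p": g.best_p,
    } for g in groups]
    table = pd.DataFrame(rows)

    def _pearson(x, y) -> tuple[float, float]:
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            return math.nan, math.nan
        r, p = pearsonr(x, y)
        return float(r), float(p)

    n = table["n_spacings"].to_numpy(float) if len(table) else np.empty(0)
    mean = table["mean_spacing"].to_numpy(float) if len(table) else np.empty(0)
    sd = table["sd_spacing"].to_numpy(float) if len(table) else np.empty(0)
    r_nm, p_nm = _pearson(n, mean)
    r_sm, p_sm = _pearson(sd, mean)

    rigid = mean[n == 1]
    flexible = mean[n > 1]
    if rigid.size and flexible.size:
        mw_p = float(mannwhitneyu(flexible, rigid, alternative="two-sided",
                                  method="auto").pvalue)
    else:
        mw_p = math.nan
    return FlexibilityStats(table, r_nm, p_nm, r_sm, p_sm, mw_p,
                            int(rigid.size), int(flexible.size))


def iqr_outlier_filter(groups: list[SpacingGroup],
                       k: float = 5.0) -> tuple[list[SpacingGroup], list[SpacingGroup]]:
    """Drop groups whose mean spacing exceeds Q3 + k*IQR (linear-interpolation
    quantiles); returns (kept, removed)."""
    if len(groups) < 4:
        return list(groups), []
    means = np.array([g.mean_spacing for g in groups])
    q1, q3 = np.percentile(means, [25, 75])
    cutoff = q3 + k * (q3 - q1)
    kept = [g for g, m in zip(groups, means) if m <= cutoff]
    removed = [g for g, m in zip(groups, means) if m > cutoff]
    return kept, removed
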