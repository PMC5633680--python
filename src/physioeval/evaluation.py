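"""Quality metrics and statistical comparison of correction strategies.

Test-retest reproducibility is quantified by the one-way random-effects
intra-class correlation ICC = (MS_b - MS_w) / (MS_b + (k-1) MS_w) over
subjects x k runs, and by the Dice coefficient of thresholded maps between
runs. Network quality uses the separability index SI = (WNC - BNC) /
(WNC + BNC) and atlas-based sensitivity/specificity restricted to gray
matter. Strategies and TR conditions are compared with a two-factor
within-subject ANOVA (factors "Method" and "TR") and follow-up paired
t-tests, uncorrected by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BinaryMap, MetricMap, NetworkAtlas

__all__ = [
    "icc",
    "classify_icc",
    "dice",
    "ConnectivitySummary",
    "separability",
    "sens_spec",
    "two_factor_rm_anova",
    "followup_paired_t",
]


def icc(values: np.ndarray) -> float:
    """One-way random-effects ICC from a subjects x k-runs table.

    MS_b is the inter-subject mean square (k times the variance of subject
    means), MS_w the within-subject inter-session mean square.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x k table with >= 2 subjects and k >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells in the ICC table")
    n, k = x.shape
    subj_means = x.mean(axis=1)
    grand = x.mean()
    ms_b = k * ((subj_means - grand) ** 2).sum() / (n - 1)
    ms_w = ((x - subj_means[:, None]) ** 2).sum() / (n * (k - 1))
    denom = ms_b + (k - 1) * ms_w
    if denom == 0:
        raise ValueError("all values identical: ICC undefined")
    return float((ms_b - ms_w) / denom)


_ICC_BINS = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0 + np.finfo(float).eps, "excellent"),
)


def classify_icc(value: float) -> str:
    """Reproducibility category: poor [<0.2), fair [0.2,0.4), moderate
    [0.4,0.6), substantial [0.6,0.8), excellent [0.8,1]. Negative ICC is
    'poor'."""
    if value > 1.0:
        raise ValueError("ICC cannot exceed 1")
    if value >= 1.0:
        return "excellent"
    for upper, label in _ICC_BINS:
        if value < upper:
            return label
    return "excellent"


def dice(a: Union[BinaryMap, np.ndarray], b: Union[BinaryMap, np.ndarray]) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); two empty maps count as perfect
    agreement (both runs report no suprathreshold voxels) with a warning."""
    ma = a.members if isinstance(a, BinaryMap) else np.asarray(a, dtype=bool)
    mb = b.members if isinstance(b, BinaryMap) else np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError("maps live on different grids")
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        warnings.warn("both maps empty: Dice defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (na + nb)


@dataclass
class ConnectivitySummary:
    """Within- and between-network mean connectivity and their contrast."""

    wnc: float
    bnc: float
    si: float


def separability(z_map: MetricMap, atlas: NetworkAtlas,
                 network_id: int) -> ConnectivitySummary:
    """Separability index of a network from a (corrected) z-map.

    WNC is the mean corrected z inside the network, BNC the mean over the
    voxels of all remaining networks; SI = (WNC - BNC) / (WNC + BNC).
    """
    net = atlas.labels == network_id
    if not net.any():
        raise ValueError(f"network {network_id} not present in the atlas")
    other = (atlas.labels > 0) & ~net
    wnc = float(np.nanmean(z_map.values[net]))
    bnc = float(np.nanmean(z_map.values[other]))
    if wnc + bnc == 0:
        warnings.warn("WNC + BNC = 0: separability undefined", stacklevel=2)
        return ConnectivitySummary(wnc=wnc, bnc=bnc, si=np.nan)
    return ConnectivitySummary(wnc=wnc, bnc=bnc, si=(wnc - bnc) / (wnc + bnc))


def sens_spec(binary_map: Union[BinaryMap, np.ndarray], atlas: NetworkAtlas,
              network_id: int) -> Tuple[float, float]:
    """Sensitivity and specificity of a thresholded map against an atlas
    network, with specificity computed over gray-matter voxels only."""
    members = (binary_map.members if isinstance(binary_map, BinaryMap)
               else np.asarray(binary_map, dtype=bool))
    net = atlas.labels == network_id
    if not net.any():
        raise ValueError(f"network {network_id} is empty: sensitivity undefined")
    outside = atlas.gm_mask & ~net
    tp = int((members & net).sum())
    fn = int((~members & net).sum())
    tn = int((~members & outside).sum())
    fp = int((members & outside).sum())
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp) if (tn + fp) else np.nan
    return float(sensitivity), float(specificity)


def two_factor_rm_anova(table: pd.DataFrame, value: str = "value",
                        subject: str = "subject", method: str = "strategy",
                        tr: str = "condition") -> Dict[str, Dict[str, float]]:
    """Two-factor within-subject ANOVA with Method and TR as factors.

    Requires a complete balanced design; replicate cells (e.g. two runs) are
    averaged. Returns per-factor F, p and the (numerator, denominator)
    degrees of freedom — (levels-1, (levels-1)(n-1)).
    """
    from statsmodels.stats.anova import AnovaRM

    df = table[[subject, method, tr, value]].copy()
    cells = df.groupby([subject, method, tr], observed=True)[value].count()
    n_m = df[method].nunique()
    n_t = df[tr].nunique()
    n_s = df[subject].nunique()
    if len(cells) != n_s * n_m * n_t:
        raise ValueError("incomplete design: every subject needs every "
                         "strategy x condition cell")
    res = AnovaRM(df, depvar=value, subject=subject, within=[method, tr],
                  aggregate_func="mean").fit()
    tbl = res.anova_table
    out = {}
    for row, label in ((method, "Method"), (tr, "TR"),
                       (f"{method}:{tr}", "Method:TR")):
        if row in tbl.index:
            out[label] = {
                "F": float(tbl.loc[row, "F Value"]),
                "p": float(tbl.loc[row, "Pr > F"]),
                "df_num": float(tbl.loc[row, "Num DF"]),
                "df_den": float(tbl.loc[row, "Den DF"]),
            }
    return out


def followup_paired_t(table: pd.DataFrame, value: str = "value",
                      subject: str = "subject", factor: str = "strategy",
                      holm: bool = False) -> pd.DataFrame:
    """All pairwise paired two-sided t-tests between factor levels.

    Values are first averaged per subject x level across any other factors.
    Identical paired samples (zero-variance differences) get p = 1 by
    convention and are flagged. Uncorrected p-values match the convention of
    reporting follow-up tests without adjustment; a Holm column is appended
    on request.
    """
    wide = table.groupby([subject, factor], observed=True)[value].mean().unstack(factor)
    if wide.shape[0] < 3:
        raise ValueError("need at least 3 subjects for paired t-tests")
    levels = list(wide.columns)
    rows = []
    for a, b in combinations(levels, 2):
        d = wide[a] - wide[b]
        if np.allclose(d, d.iloc[0]):
            if np.allclose(d, 0.0):
                rows.append({"level_a": a, "level_b": b, "t": 0.0, "p": 1.0,
                             "zero_variance": True})
                continue
        t, p = stats.ttest_rel(wide[a], wide[b])
        if np.isnan(p):
            t, p = 0.0, 1.0
            flagged = True
        else:
            flagged = False
        rows.append({"level_a": a, "level_b": b, "t": float(t), "p": float(p),
                     "zero_variance": flagged})
    out = pd.DataFrame(rows)
    if holm:
        out["p_holm"] = _holm(out["p"].to_numpy())
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj
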