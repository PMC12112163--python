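"""Group-comparison statistics: Shapiro-Wilk normality screening and Dunn's
non-parametric pairwise test with Bonferroni adjustment.

Dunn's test follows the standard formulation: all observations are ranked
jointly (mid-ranks for ties), and for each pair of groups

    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

where T = sum(t^3 - t) / (12 (N - 1)) corrects for ties.  Two-sided p-values
come from the normal distribution; Bonferroni multiplies by the number of
comparisons (capped at 1).
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["shapiro_by_group", "dunn_test", "bonferroni"]


def bonferroni(p, m: int):
    """Bonferroni-adjusted p-value(s): min(1, p * m)."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def shapiro_by_group(values: Sequence[float], groups: Sequence,
                     min_n: int = 3) -> pd.DataFrame:
    """Shapiro-Wilk W and p per group; groups below ``min_n`` are skipped
    (flagged in the ``note`` column)."""
    df = pd.DataFrame({"value": values, "group": groups})
    rows = []
    for g, sub in df.groupby("group", sort=True):
        x = sub["value"].to_numpy(dtype=float)
        if len(x) < min_n:
            rows.append({"group": g, "n": len(x), "W": np.nan, "p": np.nan,
                         "normal": None, "note": f"skipped (n < {min_n})"})
            continue
        if np.ptp(x) == 0:
            rows.append({"group": g, "n": len(x), "W": np.nan, "p": np.nan,
                         "normal": None, "note": "degenerate (zero variance)"})
            continue
        w, p = sps.shapiro(x)
        rows.append({"group": g, "n": len(x), "W": w, "p": p,
                     "normal": bool(p > 0.05), "note": ""})
    return pd.DataFrame(rows)


def dunn_test(values: Sequence[float], groups: Sequence,
              adjust: str = "bonferroni", min_n: int = 3) -> pd.DataFrame:
    """Dunn's pairwise z-test on joint ranks.

    Returns a table (group_a, group_b, z, p, p_adj); groups with fewer than
    ``min_n`` observations are excluded.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": list(groups)})
    sizes = df.groupby("group", sort=True).size()
    keep = sizes[sizes >= min_n].index
    df = df[df["group"].isin(keep)]
    if len(keep) < 2:
        return pd.DataFrame(columns=["group_a", "group_b", "z", "p", "p_adj"])

    ranks = sps.rankdata(df["value"].to_numpy())
    df = df.assign(rank=ranks)
    n_tot = len(df)
    # tie correction
    _, counts = np.unique(df["value"].to_numpy(), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    mean_ranks: Dict = df.groupby("group")["rank"].mean().to_dict()
    ns: Dict = df.groupby("group").size().to_dict()
    m = len(keep) * (len(keep) - 1) // 2
    rows = []
    for a, b in combinations(sorted(keep), 2):
        se = np.sqrt(var_base * (1.0 / ns[a] + 1.0 / ns[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = float(bonferroni(p, m)) if adjust == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p, "p_adj": p_adj})
    return pd.DataFrame(rows)
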