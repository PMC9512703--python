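"""Hypergeometric over-representation and phosphosite-activity inference."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffsol import bh_adjust

__all__ = [
    "AnnotationSets",
    "hypergeometric_ora",
    "site_activity",
    "permutation_site_activity",
]

MIN_SUBGROUP = 5
ACTIVITY_THRESHOLD = 2.0  # on -log10(p)


@dataclass
class AnnotationSets:
    """GMT-style annotation sets plus foreground/background id sets."""

    sets: dict[str, set[str]]
    foreground: set[str]
    background: set[str]

    def __post_init__(self) -> None:
        self.foreground = set(self.foreground)
        self.background = set(self.background)
        if not self.foreground <= self.background:
            raise ValueError("foreground must be a subset of the background")


def hypergeometric_ora(
    ann: AnnotationSets, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per annotation set, BH corrected.

    Sets are intersected with the background before testing; sets disjoint
    from the background are reported untestable (NaN p).  ``p`` is the
    probability of an overlap >= the observed one.
    """
    if not ann.foreground or not ann.background:
        raise ValueError("foreground and background must be non-empty")
    N = len(ann.background)
    n = len(ann.foreground)
    rows = []
    for set_id, members in ann.sets.items():
        in_bg = members & ann.background
        K = len(in_bg)
        k = len(in_bg & ann.foreground)
        if K == 0:
            p = np.nan
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_id": set_id,
                "set_size": K,
                "overlap": k,
                "foreground_size": n,
                "background_size": N,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set_id")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["enriched"] = out["q_value"] < q_threshold
    return out


def site_activity(
    matrix: pd.DataFrame,
    labels: pd.Series,
    subgroup: str,
    threshold: float = ACTIVITY_THRESHOLD,
) -> pd.DataFrame:
    """Z-test of a subgroup's fold changes against all sites, per condition.

    z = (mean_subgroup - mean_all) / (sd_all / sqrt(n_subgroup)); the
    reported score is -log10 of the two-sided normal p, signed by z.
    Conditions with fewer than ``MIN_SUBGROUP`` subgroup measurements or
    zero overall spread are untestable (NaN, never zero).
    """
    members = labels.index[labels == subgroup]
    rows = []
    for cond in matrix.columns:
        col = matrix[cond].dropna()
        sub = col.loc[col.index.intersection(members)]
        n = len(sub)
        sd_all = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        if n < MIN_SUBGROUP or sd_all == 0:
            rows.append({"condition": cond, "n_subgroup": n, "z": np.nan,
                         "p_value": np.nan, "signed_neglog10_p": np.nan,
                         "significant": False})
            continue
        z = (sub.mean() - col.mean()) / (sd_all / np.sqrt(n))
        p = 2.0 * stats.norm.sf(abs(z))
        score = -np.log10(max(p, 1e-300)) * np.sign(z)
        rows.append(
            {
                "condition": cond,
                "n_subgroup": n,
                "z": float(z),
                "p_value": float(p),
                "signed_neglog10_p": float(score),
                "significant": bool(abs(score) > threshold),
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def permutation_site_activity(
    matrix: pd.DataFrame,
    labels: pd.Series,
    subgroup: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-null alternative: p from shuffled subgroup membership."""
    rng = np.random.default_rng(seed)
    members = labels.index[labels == subgroup]
    rows = []
    for cond in matrix.columns:
        col = matrix[cond].dropna()
        sub = col.loc[col.index.intersection(members)]
        n = len(sub)
        if n < MIN_SUBGROUP or len(col) <= n:
            rows.append({"condition": cond, "n_subgroup": n, "p_value": np.nan})
            continue
        obs = abs(sub.mean() - col.mean())
        vals = col.to_numpy()
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            pick = rng.choice(vals, size=n, replace=False)
            null[i] = abs(pick.mean() - vals.mean())
        p = (1.0 + np.sum(null >= obs)) / (n_permutations + 1.0)
        rows.append({"condition": cond, "n_subgroup": n, "p_value": float(p)})
    return pd.DataFrame(rows).set_index("condition")
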