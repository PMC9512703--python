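"""Pulldown (co-IP) quantification arithmetic.

Interactors are proteins enriched in the wild-type bait eluate over the
tag-only control.  Mutant/WT eluate ratios are corrected for sample input
and for the amount of bait captured per construct before comparing
phosphodeficient and phosphomimetic constructs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffsol import moderated_diff

__all__ = [
    "PulldownExperiment",
    "define_interactors",
    "corrected_fold_changes",
    "compare_pairs",
]

INTERACTOR_FC = 1.0     # log2
INTERACTOR_PADJ = 0.01


@dataclass
class PulldownExperiment:
    """Eluate/input intensities per construct with bait-capture amounts.

    Frames are proteins x samples with a (construct, replicate) MultiIndex
    on columns; ``bait_amount`` is constructs x replicates.
    """

    eluate: pd.DataFrame
    input_: pd.DataFrame
    bait_amount: pd.DataFrame
    tag_only: str = "tag"

    def __post_init__(self) -> None:
        nontag = [c for c in self.bait_amount.index if c != self.tag_only]
        if (self.bait_amount.loc[nontag] <= 0).any().any():
            raise ValueError("bait_amount must be positive for bait constructs")

    def construct_columns(self, construct: str) -> pd.DataFrame:
        if construct not in self.eluate.columns.get_level_values(0):
            raise KeyError(f"construct {construct!r} not measured")
        return self.eluate[construct]


def define_interactors(
    log2_eluate_wt: pd.DataFrame,
    log2_eluate_tag: pd.DataFrame,
    fc_threshold: float = INTERACTOR_FC,
    p_threshold: float = INTERACTOR_PADJ,
) -> tuple[pd.Index, pd.DataFrame]:
    """Bait-specific interactors: up in WT eluate vs tag-only control.

    Inputs are normalized log2 intensity frames (proteins x replicates).
    Returns the interactor index and the full differential table.
    """
    res = moderated_diff(
        log2_eluate_wt,
        log2_eluate_tag,
        paired=False,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
    )
    interactors = res.index[
        (res["log2fc"] > fc_threshold) & (res["adj_p"] < p_threshold)
    ]
    return interactors, res


def corrected_fold_changes(
    exp: PulldownExperiment, mutant: str, wt: str
) -> pd.DataFrame:
    """Per-protein, per-replicate corrected log2(mutant/WT) eluate ratio.

    corrected = (eluate_mut / eluate_wt)
              / (input_mut / input_wt)      [sample-input adjustment]
              / (bait_mut / bait_wt)        [bait-capture adjustment]

    Proteins with a zero anywhere in the denominator chain get NaN for the
    affected replicate (excluded from downstream medians).
    """
    elu_m = exp.construct_columns(mutant)
    elu_w = exp.construct_columns(wt)
    inp_m = exp.input_[mutant]
    inp_w = exp.input_[wt]
    reps = elu_m.columns.intersection(elu_w.columns)
    out = {}
    for rep in reps:
        raw = elu_m[rep] / elu_w[rep].replace(0, np.nan)
        input_ratio = inp_m[rep] / inp_w[rep].replace(0, np.nan)
        bait_ratio = (
            exp.bait_amount.loc[mutant, rep] / exp.bait_amount.loc[wt, rep]
        )
        corrected = raw / input_ratio.replace(0, np.nan) / bait_ratio
        out[rep] = np.log2(corrected.where(corrected > 0))
    return pd.DataFrame(out)


def compare_pairs(
    deficient: pd.DataFrame,
    mimetic: pd.DataFrame,
    interactors: pd.Index,
    mode: str = "per_replicate",
) -> dict:
    """Two-sample t-test of corrected interactor ratios between constructs.

    ``mode="per_replicate"`` (default) takes the median corrected log2
    ratio over interactors within each replicate and compares those medians
    between constructs; ``mode="per_protein"`` compares per-protein medians
    across replicates instead.
    """
    if len(interactors) == 0:
        raise ValueError("interactor set is empty")
    d = deficient.loc[deficient.index.intersection(interactors)]
    m = mimetic.loc[mimetic.index.intersection(interactors)]
    if d.shape[1] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 replicates per construct")
    if mode == "per_replicate":
        xs = d.median(axis=0, skipna=True).to_numpy()
        ys = m.median(axis=0, skipna=True).to_numpy()
    elif mode == "per_protein":
        xs = d.median(axis=1, skipna=True).dropna().to_numpy()
        ys = m.median(axis=1, skipna=True).dropna().to_numpy()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    t, p = stats.ttest_ind(ys, xs, equal_var=True)
    return {
        "t": float(t),
        "p_value": float(p),
        "effect": float(np.mean(ys) - np.mean(xs)),
        "n_deficient": len(xs),
        "n_mimetic": len(ys),
        "mode": mode,
    }
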