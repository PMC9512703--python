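"""Phosphopeptide preprocessing and phosphosite category assignment.

Peptides are filtered on MS quality metrics, collapsed to unique
phosphorylation patterns (summing intensities over labeling/oxidation
variants), filtered for replicate reproducibility, and — after the
differential tests — mapped to per-site categories on two axes: solubility
(soluble / insoluble) and RNA association (facilitates / represses).  Any
conflict between significant supporting peptides makes a site ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import IntensityTable

__all__ = [
    "PhosphoPeptideTable",
    "qc_and_collapse",
    "build_site_map",
    "assign_site_categories",
    "mono_multi_fisher",
]

SOL_UP = "soluble"
SOL_DOWN = "insoluble"
RNA_DOWN = "facilitates_RNA"   # significantly MORE RNA-bound (RBF down)
RNA_UP = "represses_RNA"
NOT_CHANGING = "not_changing"
AMBIGUOUS = "ambiguous"


@dataclass
class PhosphoPeptideTable:
    """Peptide x sample intensities plus peptide metadata.

    ``peptides`` is indexed like ``values`` and carries ``protein_id``,
    ``phospho_pattern`` (e.g. ``"S362"`` or ``"S361+S368"``), ``loc_prob``,
    ``n_phospho``, and the QC columns ``signal_to_interference`` and
    ``precursor_to_threshold``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    peptides: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.peptides.index):
            raise ValueError("peptide metadata does not match intensity rows")

    def to_intensity_table(self, log2: bool = False) -> IntensityTable:
        return IntensityTable(
            values=self.values,
            samples=self.samples,
            features=self.peptides[["protein_id"]],
            log2=log2,
        )


def _replicate_solubility_sd(
    values: pd.DataFrame, samples: pd.DataFrame, lysate: str = "preserved"
) -> pd.Series:
    """s.d. across replicates of raw log2(NP40/SDS) in one lysate."""
    ratios = {}
    for (lys, rep), grp in samples.groupby(["lysate", "replicate"]):
        if lys != lysate:
            continue
        np40 = grp.index[grp["detergent"] == "NP40"]
        sds = grp.index[grp["detergent"] == "SDS"]
        if len(np40) == 1 and len(sds) == 1:
            num = values[np40[0]].where(values[np40[0]] > 0)
            den = values[sds[0]].where(values[sds[0]] > 0)
            ratios[rep] = np.log2(num / den)
    return pd.DataFrame(ratios).std(axis=1, ddof=1)


def qc_and_collapse(
    raw: PhosphoPeptideTable,
    s2i_min: float = 0.5,
    p2t_min: float = 4.0,
    sd_max: float = 1.0,
    sd_on: str = "solubility",
) -> PhosphoPeptideTable:
    """Quality filter, pattern collapse, reproducibility filter.

    Rows failing signal-to-interference / precursor-to-threshold cutoffs or
    not quantified (> 0) in every sample are removed; surviving rows are
    collapsed by (protein, phospho pattern) with intensities summed across
    modification variants; collapsed rows whose replicate-wise log2
    solubility s.d. is >= ``sd_max`` are removed (``sd_on="intensity"``
    applies the s.d. filter to log2 intensities instead).
    """
    need = {"signal_to_interference", "precursor_to_threshold"}
    if not need <= set(raw.peptides.columns):
        raise ValueError(f"missing QC columns {sorted(need - set(raw.peptides.columns))}")

    keep = (
        (raw.peptides["signal_to_interference"] >= s2i_min)
        & (raw.peptides["precursor_to_threshold"] >= p2t_min)
        & (raw.values > 0).all(axis=1)
    )
    values = raw.values.loc[keep]
    meta = raw.peptides.loc[keep]

    grouped = values.groupby(
        [meta["protein_id"], meta["phospho_pattern"]], sort=False
    ).sum()
    agg = {c: "first" for c in meta.columns}
    for qc in ("signal_to_interference", "precursor_to_threshold", "loc_prob"):
        if qc in agg:
            agg[qc] = "min"
    meta2 = meta.groupby(
        [meta["protein_id"], meta["phospho_pattern"]], sort=False
    ).agg(agg)
    new_ids = pd.Index(
        [f"{p}_{pat}" for p, pat in grouped.index], name="peptide_id"
    )
    grouped.index = new_ids
    meta2.index = new_ids

    if sd_on == "solubility":
        sd = _replicate_solubility_sd(grouped, raw.samples)
    elif sd_on == "intensity":
        sd = np.log2(grouped.where(grouped > 0)).std(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown sd_on {sd_on!r}")
    ok = sd.fillna(np.inf) < sd_max
    return PhosphoPeptideTable(
        values=grouped.loc[ok], samples=raw.samples, peptides=meta2.loc[ok]
    )


# ---------------------------------------------------------------------------
# site mapping and categories


def build_site_map(
    peptides: pd.DataFrame, loc_prob_min: float = 0.75
) -> dict[str, set[str]]:
    """Peptide id -> set of site labels ("<protein>:<site>").

    Multi-phospho patterns ("S361+S368") contribute one site per position.
    Peptides whose localization probability is below ``loc_prob_min`` get a
    grouped ambiguous-location label joining the candidate sites with ``|``
    (e.g. ``"S218|T219"``).
    """
    site_map: dict[str, set[str]] = {}
    for pep_id, row in peptides.iterrows():
        prot = row["protein_id"]
        sites = str(row["phospho_pattern"]).split("+")
        prob = row.get("loc_prob", 1.0)
        if prob is not None and not pd.isna(prob) and prob < loc_prob_min and len(sites) > 1:
            labels = {f"{prot}:{'|'.join(sites)}"}
        else:
            labels = {f"{prot}:{s}" for s in sites}
        if not labels:
            raise ValueError(f"peptide {pep_id} maps to zero sites")
        site_map[pep_id] = labels
    return site_map


def _axis_category(
    calls: pd.Series, up_label: str, down_label: str
) -> str | None:
    """Unanimity rule over significant supporting-peptide calls."""
    ups = int((calls == "up").sum())
    downs = int((calls == "down").sum())
    if ups and downs:
        return AMBIGUOUS
    if ups:
        return up_label
    if downs:
        return down_label
    return None


def assign_site_categories(
    sol_results: pd.DataFrame,
    rna_results: pd.DataFrame,
    site_map: dict[str, set[str]],
) -> pd.DataFrame:
    """Per-site category on the solubility and RNA axes.

    A site is ``soluble``/``insoluble`` iff all significant supporting
    peptides agree in solubility direction (up = more soluble);
    ``facilitates_RNA`` iff they unanimously shift toward more RNA-bound
    (negative RBF log2FC), ``represses_RNA`` for the opposite;
    ``not_changing`` iff no supporting peptide is significant on either
    axis; ``ambiguous`` on any within-axis conflict.
    """
    missing = [p for p in sol_results.index if p not in site_map]
    if missing:
        raise ValueError(f"peptides without site mapping: {missing[:5]}...")

    per_site: dict[str, list[str]] = {}
    for pep, sites in site_map.items():
        for s in sites:
            per_site.setdefault(s, []).append(pep)

    rows = []
    for site, peps in per_site.items():
        peps_sol = sol_results.loc[sol_results.index.intersection(peps)]
        peps_rna = rna_results.loc[rna_results.index.intersection(peps)]
        sol_cat = _axis_category(peps_sol["call"], SOL_UP, SOL_DOWN)
        rna_cat = _axis_category(peps_rna["call"], RNA_UP, RNA_DOWN)
        protein_id, _, site_label = site.partition(":")
        rows.append(
            {
                "site": site,
                "protein_id": protein_id,
                "site_label": site_label,
                "sol_category": sol_cat,
                "rna_category": rna_cat,
                "category": (
                    NOT_CHANGING if sol_cat is None and rna_cat is None
                    else AMBIGUOUS if AMBIGUOUS in (sol_cat, rna_cat)
                    else ",".join(c for c in (sol_cat, rna_cat) if c)
                ),
                "n_peptides": len(peps),
                "supporting_peptides": ";".join(sorted(peps)),
            }
        )
    return pd.DataFrame(rows).set_index("site").sort_index()


def mono_multi_fisher(
    peptides: pd.DataFrame, in_category: pd.Series
) -> tuple[float, float, pd.DataFrame]:
    """Two-sided Fisher test: mono- vs multi-phosphorylation by membership.

    ``in_category`` is a boolean series aligned to ``peptides``.  Returns
    (odds ratio, p, 2x2 table) comparing mono-phosphorylated status inside
    vs outside the category.
    """
    mono = peptides["n_phospho"] == 1
    tab = pd.crosstab(mono, in_category.reindex(peptides.index))
    tab = tab.reindex(index=[True, False], columns=[True, False], fill_value=0)
    odds, p = stats.fisher_exact(tab.to_numpy(), alternative="two-sided")
    return float(odds), float(p), tab
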