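"""End-to-end orchestration on simulated data with planted ground truth.

Runs simulate -> normalize -> differential solubility -> phosphosite
categories -> sequence features -> enrichment/activity, writing stage TSVs
plus a JSON summary containing class/category counts and confusion
matrices against the planted truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .diffsol import (
    classify_proteins,
    compute_solubility,
    diff_phospho_vs_protein,
    moderated_diff,
)
from .enrich import AnnotationSets, hypergeometric_ora, site_activity
from .normalization import (
    filter_protein_table,
    fit_apply_normalization,
    select_calibration_subset,
)
from .phospho import assign_site_categories, build_site_map, qc_and_collapse
from .seqfeat import extract_window, window_properties
from .simulate import (
    PhosphoSimSpec,
    SimulationConfig,
    simulate_perturbation_matrix,
    simulate_phospho_dataset,
    simulate_sequences,
    simulate_solubility_dataset,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    phospho: PhosphoSimSpec = field(default_factory=PhosphoSimSpec)
    fc_threshold: float = 0.5
    p_threshold: float = 0.01
    s2i_min: float = 0.5
    p2t_min: float = 4.0
    sd_max: float = 1.0
    half_width: int = 15
    phospho_charge: float = -2.0
    norm_method: str = "glog"
    calib_low: float = 0.8
    calib_high: float = 1.2
    n_sequences: int = 50
    sequence_length: int = 101
    out_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _detergent_frames(norm_table, lysate):
    meta = norm_table.samples
    np40 = meta.index[(meta["detergent"] == "NP40") & (meta["lysate"] == lysate)]
    sds = meta.index[(meta["detergent"] == "SDS") & (meta["lysate"] == lysate)]
    order = meta.loc[np40, "replicate"].sort_values().index
    order_s = meta.loc[sds, "replicate"].sort_values().index
    a = norm_table.values[order]
    b = norm_table.values[order_s]
    a.columns = meta.loc[order, "replicate"].to_numpy()
    b.columns = meta.loc[order_s, "replicate"].to_numpy()
    return a, b


def _confusion(truth: pd.Series, called: pd.Series) -> dict:
    tab = pd.crosstab(truth, called.reindex(truth.index))
    return {str(k): {str(c): int(v) for c, v in row.items()} for k, row in tab.iterrows()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full simulated workflow; returns the summary dict."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _save(df: pd.DataFrame, name: str) -> None:
        if out is not None:
            sio.write_tsv(df, out / name)

    summary: dict = {
        "seed": config.simulation.seed,
        "config_hash": config.config_hash(),
    }

    # --- proteome ---------------------------------------------------------
    table, truth = simulate_solubility_dataset(config.simulation)
    table = filter_protein_table(table)
    truth.proteins = truth.proteins.loc[table.values.index]
    calib = select_calibration_subset(table, config.calib_low, config.calib_high)
    norm, model = fit_apply_normalization(table, calib, method=config.norm_method)
    profile = compute_solubility(norm)

    diffs = {}
    for lysate in ("preserved", "digested"):
        a, b = _detergent_frames(norm, lysate)
        diffs[lysate] = moderated_diff(
            a, b, paired=True,
            fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
        )
    rnase = moderated_diff(
        profile.lysate("preserved"), profile.lysate("digested"), paired=True,
        fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
    )
    classes = classify_proteins(
        diffs["preserved"], diffs["digested"], rnase,
        fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
    )
    _save(classes, "protein_classes.tsv")
    _save(diffs["preserved"], "diff_preserved.tsv")
    _save(rnase, "diff_rnase.tsv")

    truth_cls = truth.proteins["solubility_class"]
    summary["protein_class_counts"] = (
        classes["solubility_class"].value_counts().to_dict()
    )
    summary["protein_class_confusion"] = _confusion(
        truth_cls, classes["solubility_class"]
    )

    # --- phosphopeptides --------------------------------------------------
    pep_table, pep_truth = simulate_phospho_dataset(truth, config.phospho)
    pep_table = qc_and_collapse(
        pep_table, config.s2i_min, config.p2t_min, config.sd_max
    )
    pep_it = pep_table.to_intensity_table()
    pep_calib = select_calibration_subset(
        pep_it, config.calib_low, config.calib_high
    )
    pep_norm, _ = fit_apply_normalization(
        pep_it, pep_calib, method=config.norm_method
    )
    pep_profile = compute_solubility(pep_norm)
    pep2prot = pep_table.peptides["protein_id"]
    sol_res = diff_phospho_vs_protein(
        pep_profile, profile, pep2prot, mode="solubility",
        fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
    )
    rna_res = diff_phospho_vs_protein(
        pep_profile, profile, pep2prot, mode="rna_bound",
        fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
    )
    site_map = build_site_map(pep_table.peptides)
    categories = assign_site_categories(sol_res, rna_res, site_map)
    _save(sol_res, "phospho_diff_solubility.tsv")
    _save(rna_res, "phospho_diff_rna.tsv")
    _save(categories, "site_categories.tsv")

    pep_kept = pep_truth.peptides.loc[
        pep_truth.peptides.index.intersection(sol_res.index)
    ]
    sol_call_cat = sol_res["call"].map(
        {"up": "soluble", "down": "insoluble", "not_changing": "not_changing"}
    )
    summary["phospho_category_counts"] = (
        categories["category"].value_counts().to_dict()
    )
    summary["phospho_sol_confusion"] = _confusion(
        pep_kept["intended_sol_category"], sol_call_cat
    )

    # --- sequence features ------------------------------------------------
    composition = {"G": 0.4, "S": 0.2, "E": 0.1, "K": 0.1, "P": 0.05,
                   "A": 0.05, "Y": 0.05, "L": 0.05}
    seqs = simulate_sequences(
        config.n_sequences, config.sequence_length, composition,
        seed=config.simulation.seed, half_width=config.half_width,
    )
    wrows = []
    for rec in seqs:
        win, start, _ = extract_window(rec["sequence"], rec["site"],
                                       config.half_width)
        props = window_properties(
            win, [rec["site"] - start + 1], phospho_charge=config.phospho_charge
        )
        wrows.append({"id": rec["id"], "site": rec["site"],
                      **{k: v for k, v in vars(props).items()
                         if k not in ("protein_id", "site")}})
    windows = pd.DataFrame(wrows).set_index("id")
    _save(windows, "window_properties.tsv")
    summary["n_windows"] = int(len(windows))

    # --- enrichment and activity -----------------------------------------
    insoluble_truth = set(truth_cls.index[truth_cls != "predominantly_soluble"])
    background = set(truth_cls.index)
    foreground = set(
        classes.index[classes["solubility_class"] != "predominantly_soluble"]
    )
    rng = np.random.default_rng(config.simulation.seed)
    random_set = set(
        rng.choice(sorted(background), size=min(100, len(background)),
                   replace=False)
    )
    ann = AnnotationSets(
        sets={"planted_insoluble": insoluble_truth, "random": random_set},
        foreground=foreground,
        background=background,
    )
    ora = hypergeometric_ora(ann)
    _save(ora, "ora.tsv")
    summary["ora_enriched"] = ora["enriched"].to_dict()

    matrix, labels, _ = simulate_perturbation_matrix(
        n_sites=500, n_conditions=8, subgroup_shift=0.5,
        seed=config.simulation.seed,
    )
    act = site_activity(matrix, labels, "soluble")
    _save(act, "site_activity.tsv")
    summary["n_significant_conditions"] = int(act["significant"].sum())

    if out is not None:
        sio.write_json(summary, out / "summary.json")
    return summary
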