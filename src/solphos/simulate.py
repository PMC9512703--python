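"""Synthetic data with planted ground truth for every pipeline stage.

All generators are deterministic given a seed.  A single global seed is
expanded into independent per-stage streams with
``numpy.random.SeedSequence(seed, spawn_key=(STAGE,))`` where STAGE is the
fixed index in ``STAGE_KEYS`` — re-running any one stage with the same seed
reproduces it bit for bit regardless of the other stages.

The solubility design mirrors a 2x2 layout: mild (NP-40) vs strong (SDS)
detergent crossed with RNA-preserved vs RNA-digested lysate, three
replicates each.  Intensities carry lognormal multiplicative noise
(additive Gaussian on log2).  A majority class behaves identically in both
detergents; minority classes carry an insoluble subpool (NP-40 depleted)
that is either rescued by RNA digestion or not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .normalization import IntensityTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "stage_rng",
    "simulate_solubility_dataset",
    "simulate_phospho_dataset",
    "simulate_sequences",
    "simulate_perturbation_matrix",
    "simulate_image",
    "SimulatedImage",
]

STAGE_KEYS = {
    "proteins": 0,
    "phospho": 1,
    "sequences": 2,
    "perturbations": 3,
    "image": 4,
}

CLASSES = (
    "predominantly_soluble",
    "rnase_sensitive_insoluble",
    "rnase_insensitive_insoluble",
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage child generator from the global seed (fixed derivation)."""
    ss = np.random.SeedSequence(seed, spawn_key=(STAGE_KEYS[stage],))
    return np.random.default_rng(ss)


@dataclass
class SimulationConfig:
    n_proteins: int = 5000
    n_replicates: int = 3
    # published class percentages (81.5 / 5.5 / 13.5) sum to 100.5 due to
    # rounding; they are rescaled here so the fractions sum to exactly 1
    class_fractions: tuple[float, float, float] = (
        0.815 / 1.005, 0.055 / 1.005, 0.135 / 1.005
    )
    insoluble_effect: float = -1.0
    rnase_rescue_effect: float = 1.0
    noise_sd: float = 0.15
    baseline_log_intensity_range: tuple[float, float] = (10.0, 16.0)
    seed: int = 0

    def validate(self) -> None:
        for name in ("insoluble_effect", "rnase_rescue_effect", "noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite config value for {name}")
        lo, hi = self.baseline_log_intensity_range
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError(
                "non-finite config value for baseline_log_intensity_range"
            )
        fr = np.asarray(self.class_fractions, dtype=float)
        if not np.all(np.isfinite(fr)):
            raise ValueError("non-finite config value for class_fractions")
        if (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("class_fractions must be non-negative and sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth for one simulated artifact (one section per stage)."""

    config: SimulationConfig | None = None
    proteins: pd.DataFrame | None = None
    peptides: pd.DataFrame | None = None
    sites: pd.DataFrame | None = None
    images: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out: dict = {}
        if self.config is not None:
            out["config"] = asdict(self.config)
        for name in ("proteins", "peptides", "sites", "images"):
            df = getattr(self, name)
            if df is not None:
                out[name] = df.reset_index().to_dict(orient="list")
        return out


def _np40_effect(cls: str, lysate: str, cfg: SimulationConfig) -> float:
    if cls == "predominantly_soluble":
        return 0.0
    eff = cfg.insoluble_effect
    if cls == "rnase_sensitive_insoluble" and lysate == "digested":
        eff += cfg.rnase_rescue_effect
    return eff


def _sample_frame(n_replicates: int) -> pd.DataFrame:
    rows = []
    for lysate in ("preserved", "digested"):
        for detergent in ("NP40", "SDS"):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{detergent}_{lysate}_r{rep}",
                        "detergent": detergent,
                        "lysate": lysate,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_solubility_dataset(
    config: SimulationConfig,
) -> tuple[IntensityTable, GroundTruth]:
    """Protein-level 2x2 solubility profiling dataset with planted classes."""
    config.validate()
    rng = stage_rng(config.seed, "proteins")
    n = config.n_proteins
    class_idx = rng.choice(3, size=n, p=np.asarray(config.class_fractions))
    classes = np.array(CLASSES)[class_idx]
    lo, hi = config.baseline_log_intensity_range
    baseline = rng.uniform(lo, hi, size=n)
    peptide_counts = rng.integers(2, 15, size=n)

    samples = _sample_frame(config.n_replicates)
    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="feature_id")
    cols = {}
    for sid, meta in samples.iterrows():
        if meta["detergent"] == "SDS":
            eff = np.zeros(n)
        else:
            eff = np.array(
                [_np40_effect(c, meta["lysate"], config) for c in classes]
            )
        noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else 0.0
        cols[sid] = 2.0 ** (baseline + eff + noise)
    values = pd.DataFrame(cols, index=ids)
    features = pd.DataFrame(
        {"protein_id": ids, "unique_peptide_count": peptide_counts}, index=ids
    )
    truth = GroundTruth(
        config=config,
        proteins=pd.DataFrame(
            {
                "solubility_class": classes,
                "baseline_log2": baseline,
                "insoluble_effect": [
                    _np40_effect(c, "preserved", config) for c in classes
                ],
            },
            index=ids,
        ),
    )
    table = IntensityTable(values=values, samples=samples, features=features)
    return table, truth


# ---------------------------------------------------------------------------
# phosphopeptides


@dataclass
class PhosphoSimSpec:
    """Planted-effect specification for the phosphopeptide simulator."""

    mean_sites_per_protein: float = 0.6
    fraction_sol_shifted: float = 0.1
    sol_shift: float = 1.0
    fraction_rna_shifted: float = 0.1
    rna_shift: float = 1.0
    qc_fail_fraction: float = 0.1
    emit_variants: bool = False
    substoichiometric_log2: tuple[float, float] = (2.0, 6.0)


def simulate_phospho_dataset(
    proteome_truth: GroundTruth,
    spec: PhosphoSimSpec | None = None,
    seed: int | None = None,
):
    """Phosphopeptide table tied to an existing simulated proteome.

    Peptide solubility follows the parent protein's planted effects plus a
    per-peptide planted solubility and/or RNA-bound shift; a configurable
    fraction fails MS quality control.  Returns
    ``(PhosphoPeptideTable, GroundTruth)`` — the table type lives in
    :mod:`solphos.phospho`.
    """
    from .phospho import PhosphoPeptideTable

    if proteome_truth.proteins is None or len(proteome_truth.proteins) == 0:
        raise ValueError("empty proteome: run simulate_solubility_dataset first")
    spec = spec or PhosphoSimSpec()
    cfg = proteome_truth.config
    if seed is None:
        seed = cfg.seed
    rng = stage_rng(seed, "phospho")

    prot = proteome_truth.proteins
    n_sites = rng.poisson(spec.mean_sites_per_protein, size=len(prot))
    rows = []
    values_rows = []
    samples = _sample_frame(cfg.n_replicates)
    residues = np.array(list("STY"))
    res_p = np.array([0.863, 0.125, 0.012])

    for pid, k in zip(prot.index, n_sites):
        if k == 0:
            continue
        info = prot.loc[pid]
        positions = np.sort(rng.choice(np.arange(20, 500), size=k, replace=False))
        for pos in positions:
            res = rng.choice(residues, p=res_p)
            site = f"{res}{pos}"
            pep_id = f"{pid}_{site}"
            sol_shift = (
                rng.choice([-spec.sol_shift, spec.sol_shift])
                if rng.random() < spec.fraction_sol_shifted
                else 0.0
            )
            rna_shift = (
                rng.choice([-spec.rna_shift, spec.rna_shift])
                if rng.random() < spec.fraction_rna_shifted
                else 0.0
            )
            qc_fail = rng.random() < spec.qc_fail_fraction
            base = info["baseline_log2"] - rng.uniform(
                *spec.substoichiometric_log2
            )
            ch = {}
            for sid, meta in samples.iterrows():
                if meta["detergent"] == "SDS":
                    eff = 0.0
                else:
                    eff = (
                        _np40_effect(
                            info["solubility_class"], meta["lysate"], cfg
                        )
                        + sol_shift
                    )
                    # RNA-axis shift enters the preserved lysate only, so
                    # RBF = S_pres - S_dig moves by exactly rna_shift
                    if meta["lysate"] == "preserved":
                        eff += rna_shift
                noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0
                ch[sid] = 2.0 ** (base + eff + noise)
            s2i = rng.uniform(0.1, 0.5) if qc_fail else rng.uniform(0.5, 1.0)
            p2t = rng.uniform(1.0, 4.0) if qc_fail else rng.uniform(4.0, 30.0)
            rows.append(
                {
                    "peptide_id": pep_id,
                    "protein_id": pid,
                    "phospho_pattern": site,
                    "loc_prob": float(rng.uniform(0.8, 1.0)),
                    "n_phospho": 1,
                    "signal_to_interference": s2i,
                    "precursor_to_threshold": p2t,
                    "variant": "base",
                    "sol_shift": sol_shift,
                    "rna_shift": rna_shift,
                    "qc_fail": qc_fail,
                }
            )
            values_rows.append(ch)
            if spec.emit_variants and rng.random() < 0.3:
                # oxidized variant carrying part of the signal; collapsing
                # must restore the total
                frac = rng.uniform(0.2, 0.5)
                rows.append({**rows[-1], "peptide_id": pep_id + "_ox",
                            "variant": "ox"})
                values_rows.append({k: v * frac for k, v in ch.items()})
                for k in values_rows[-2]:
                    values_rows[-2][k] *= 1.0 - frac

    if not rows:
        raise ValueError("no phosphopeptides generated; increase site rate")
    meta = pd.DataFrame(rows).set_index("peptide_id")
    values = pd.DataFrame(values_rows, index=meta.index)

    truth_cols = ["protein_id", "phospho_pattern", "sol_shift", "rna_shift",
                  "qc_fail", "variant"]
    truth_pep = meta[truth_cols].copy()
    # an RNA-axis shift enters the preserved lysate, so the expected
    # preserved-lysate solubility call reflects the sum of both shifts
    pres_shift = truth_pep["sol_shift"] + truth_pep["rna_shift"]
    truth_pep["intended_sol_category"] = np.select(
        [pres_shift > 0, pres_shift < 0],
        ["soluble", "insoluble"],
        default="not_changing",
    )
    truth_pep["intended_rna_category"] = np.select(
        [truth_pep["rna_shift"] < 0, truth_pep["rna_shift"] > 0],
        ["facilitates_RNA", "represses_RNA"],
        default="not_changing",
    )
    truth = GroundTruth(config=cfg, proteins=proteome_truth.proteins,
                        peptides=truth_pep)
    table = PhosphoPeptideTable(
        values=values,
        samples=samples,
        peptides=meta.drop(columns=["sol_shift", "rna_shift", "qc_fail"]),
    )
    return table, truth


# ---------------------------------------------------------------------------
# sequences


AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def simulate_sequences(
    n: int,
    length: int,
    composition: dict[str, float],
    seed: int = 0,
    half_width: int = 15,
    allow_edge_sites: bool = False,
) -> list[dict]:
    """Random sequences over the 20-letter alphabet with annotated sites.

    Site positions are uniform in ``[half_width + 1, length - half_width]``
    (full windows) unless ``allow_edge_sites``.  Returns records with
    ``id``, ``sequence`` and ``site`` (1-based position).
    """
    letters = sorted(composition)
    freqs = np.array([composition[a] for a in letters], dtype=float)
    if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("composition frequencies must be >= 0 and sum to 1")
    unknown = set(letters) - set(AA_ALPHABET)
    if unknown:
        raise ValueError(f"unknown residues in composition: {sorted(unknown)}")
    if length < 2 * half_width + 1 and not allow_edge_sites:
        raise ValueError(
            f"length {length} < {2 * half_width + 1} requires allow_edge_sites"
        )
    rng = stage_rng(seed, "sequences")
    records = []
    for i in range(n):
        seq = "".join(rng.choice(list(letters), size=length, p=freqs))
        if allow_edge_sites:
            site = int(rng.integers(1, length + 1))
        else:
            site = int(rng.integers(half_width + 1, length - half_width + 1))
        records.append({"id": f"SEQ{i:04d}", "sequence": seq, "site": site})
    return records


# ---------------------------------------------------------------------------
# perturbation matrix


def simulate_perturbation_matrix(
    n_sites: int,
    n_conditions: int,
    subgroup_shift: float,
    subgroup_size: int = 25,
    shifted_conditions: list[int] | None = None,
    sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Site x condition log fold changes with a mean-shifted subgroup.

    Returns ``(matrix, labels, truth)`` where ``labels`` marks the first
    ``subgroup_size`` sites as ``"soluble"`` (the designated subgroup) and
    the rest ``"not_changing"``; the subgroup mean is moved by
    ``subgroup_shift`` in ``shifted_conditions`` (default: all).
    """
    if n_sites < subgroup_size:
        raise ValueError("n_sites must be >= subgroup size")
    rng = stage_rng(seed, "perturbations")
    mat = rng.normal(0.0, sd, size=(n_sites, n_conditions))
    if shifted_conditions is None:
        shifted_conditions = list(range(n_conditions))
    for c in shifted_conditions:
        mat[:subgroup_size, c] += subgroup_shift
    sites = pd.Index([f"site{i:05d}" for i in range(n_sites)], name="site")
    conds = [f"cond{j:03d}" for j in range(n_conditions)]
    labels = pd.Series(
        ["soluble"] * subgroup_size + ["not_changing"] * (n_sites - subgroup_size),
        index=sites,
        name="subgroup",
    )
    truth = pd.DataFrame(
        {
            "condition": conds,
            "planted_shift": [
                subgroup_shift if j in shifted_conditions else 0.0
                for j in range(n_conditions)
            ],
        }
    ).set_index("condition")
    return pd.DataFrame(mat, index=sites, columns=conds), labels, truth


# ---------------------------------------------------------------------------
# images


@dataclass
class SimulatedImage:
    intensity: np.ndarray
    labels: np.ndarray
    nucleus_mask: np.ndarray
    background_roi: tuple[int, int, int, int]  # (row, col, height, width)
    pixel_size_nm: float
    truth: pd.DataFrame


def simulate_image(
    shape: tuple[int, int] = (512, 512),
    nucleoli: list[tuple[tuple[float, float], float, float]] = (),
    nucleoplasm_intensity: float = 100.0,
    background: float = 0.0,
    noise_sd: float = 0.0,
    pixel_size_nm: float = 424.0 / 6.0,
    seed: int = 0,
    rim_margin: int = 10,
) -> SimulatedImage:
    """Noisy image of disk-shaped nucleoli on a nucleoplasm plateau.

    ``nucleoli`` is a list of ``((row, col), radius_px, mean_intensity)``.
    The nucleus is the rectangle covering all nucleoli plus ``rim_margin``;
    outside it the image sits at ``background``.  The background ROI is a
    square in the top-left corner, kept clear of the nucleus.  True
    partition coefficients are
    ``(nucleolus - background) / (nucleoplasm - background)``.
    """
    rng = stage_rng(seed, "image")
    h, w = shape
    img = np.full(shape, float(background))
    labels = np.zeros(shape, dtype=np.int32)
    rr, cc = np.mgrid[0:h, 0:w]

    disks = []
    for (cy, cx), radius, _ in nucleoli:
        if cy - radius < 0 or cx - radius < 0 or cy + radius >= h or cx + radius >= w:
            raise ValueError("nucleolus extends outside the frame")
        disks.append((rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2)
    for i, a in enumerate(disks):
        for b in disks[i + 1:]:
            if (a & b).any():
                raise ValueError("nucleoli overlap")

    if nucleoli:
        ys = [cy for (cy, _), r, _ in nucleoli]
        xs = [cx for (_, cx), r, _ in nucleoli]
        rs = [r for _, r, _ in nucleoli]
        y0 = max(0, int(min(y - r for y, r in zip(ys, rs))) - rim_margin)
        y1 = min(h, int(max(y + r for y, r in zip(ys, rs))) + rim_margin + 1)
        x0 = max(0, int(min(x - r for x, r in zip(xs, rs))) - rim_margin)
        x1 = min(w, int(max(x + r for x, r in zip(xs, rs))) + rim_margin + 1)
    else:
        y0, y1, x0, x1 = h // 2, h, w // 2, w
    nucleus = np.zeros(shape, dtype=bool)
    nucleus[y0:y1, x0:x1] = True
    img[nucleus] = nucleoplasm_intensity

    records = []
    denom = nucleoplasm_intensity - background
    for lab, (disk, ((_, _), radius, mean_int)) in enumerate(
        zip(disks, nucleoli), start=1
    ):
        img[disk] = mean_int
        labels[disk] = lab
        records.append(
            {
                "label": lab,
                "radius_px": radius,
                "area_px2": int(disk.sum()),
                "nucleolus_intensity": mean_int,
                "true_k": (mean_int - background) / denom if denom != 0 else np.nan,
                "background": background,
            }
        )

    roi_size = min(64, y0 if y0 > 0 else h // 8, x0 if x0 > 0 else w // 8)
    roi_size = max(roi_size, 4)
    if y0 < roi_size and x0 < roi_size:
        raise ValueError("no room for a background ROI outside the nucleus")
    roi = (0, 0, roi_size, roi_size)

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)

    truth = pd.DataFrame(records).set_index("label") if records else pd.DataFrame()
    return SimulatedImage(
        intensity=img,
        labels=labels,
        nucleus_mask=nucleus,
        background_roi=roi,
        pixel_size_nm=pixel_size_nm,
        truth=truth,
    )
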