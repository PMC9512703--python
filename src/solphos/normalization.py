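"""Intensity tables and calibration-subset variance-stabilizing normalization.

Normalization parameters (per-sample scale, generalized-log parameter,
per-sample offset on the log2 scale) are estimated only on a calibration
subset of features whose raw mild/strong-detergent ratio is close to one
("predominantly soluble" features), then applied to every feature.  Output
is on the log2 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IntensityTable",
    "NormalizationModel",
    "filter_protein_table",
    "select_calibration_subset",
    "fit_apply_normalization",
]

DETERGENTS = ("NP40", "SDS")
LYSATES = ("preserved", "digested")


@dataclass
class IntensityTable:
    """Features x samples intensity matrix with sample metadata.

    ``values`` is indexed by feature id; ``samples`` is indexed by sample id
    (one row per column of ``values``) with columns ``detergent``,
    ``lysate`` and ``replicate``.  ``features`` carries optional per-feature
    metadata such as ``protein_id`` and ``unique_peptide_count``.
    ``log2`` marks tables already on the log2 scale.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame | None = None
    log2: bool = False

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata does not match value columns")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = {"detergent", "lysate", "replicate"} - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns {sorted(missing)}")
        if not self.log2 and (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("raw intensities must be non-negative")

    # -- convenience -------------------------------------------------------

    def sample_ids(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        return list(self.samples.index[mask])

    def detergent_pairs(self) -> list[tuple[str, int, str, str]]:
        """(lysate, replicate, np40_sample, sds_sample) for matched pairs."""
        pairs = []
        for (lys, rep), grp in self.samples.groupby(["lysate", "replicate"]):
            np40 = grp.index[grp["detergent"] == "NP40"]
            sds = grp.index[grp["detergent"] == "SDS"]
            if len(np40) == 1 and len(sds) == 1:
                pairs.append((lys, int(rep), np40[0], sds[0]))
        return pairs

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.copy()
        if self.features is not None:
            df = pd.concat([self.features, df], axis=1)
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t", na_rep="")
        meta_path = Path(path).with_suffix(".samples.tsv")
        self.samples.rename_axis("sample_id").to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, log2: bool = False) -> "IntensityTable":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        meta_path = Path(path).with_suffix(".samples.tsv")
        samples = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        value_cols = [c for c in df.columns if c in samples.index]
        feat_cols = [c for c in df.columns if c not in samples.index]
        features = df[feat_cols] if feat_cols else None
        return cls(
            values=df[value_cols],
            samples=samples.loc[value_cols],
            features=features,
            log2=log2,
        )


def filter_protein_table(
    table: IntensityTable, min_unique_peptides: int = 2
) -> IntensityTable:
    """Keep proteins with >= ``min_unique_peptides`` unique peptides and a
    nonzero quantification in every sample of every replicate."""
    if table.features is None or "unique_peptide_count" not in table.features:
        raise ValueError("table has no unique_peptide_count feature metadata")
    ok = table.features["unique_peptide_count"] >= min_unique_peptides
    ok &= (table.values > 0).all(axis=1)
    return IntensityTable(
        values=table.values.loc[ok],
        samples=table.samples,
        features=table.features.loc[ok],
        log2=table.log2,
    )


def select_calibration_subset(
    table: IntensityTable,
    low: float = 0.8,
    high: float = 1.2,
    per_replicate: bool = False,
) -> pd.Index:
    """Features whose raw NP-40/SDS ratio sits in [low, high].

    The mean ratio across all matched detergent pairs defines membership by
    default; ``per_replicate=True`` demands every pair's ratio in range.
    Zeros are treated as missing: features with any missing pair are
    excluded from calibration (but still get normalized later).
    """
    pairs = table.detergent_pairs()
    if not pairs:
        raise ValueError("table contains no matched NP40/SDS sample pairs")
    ratios = {}
    for lys, rep, np40, sds in pairs:
        num = table.values[np40].replace(0, np.nan)
        den = table.values[sds].replace(0, np.nan)
        ratios[(lys, rep)] = num / den
    rmat = pd.DataFrame(ratios)
    complete = rmat.notna().all(axis=1)
    if per_replicate:
        in_range = ((rmat >= low) & (rmat <= high)).all(axis=1)
    else:
        mean_ratio = rmat.mean(axis=1)
        in_range = (mean_ratio >= low) & (mean_ratio <= high)
    chosen = table.values.index[complete & in_range]
    if len(chosen) == 0:
        raise ValueError(
            f"no feature has a mean NP40/SDS ratio within [{low}, {high}]; "
            "widen the bounds"
        )
    return chosen


@dataclass
class NormalizationModel:
    """Per-sample affine parameters plus a glog transform parameter.

    ``scales`` divide raw intensities; ``offsets`` are subtracted on the
    log2 scale; ``glog_c`` is the arsinh-family softening constant (0 means
    a pure log2 transform).  After applying the model, per-sample medians of
    the calibration features agree to within 1e-6 by construction.
    """

    scales: pd.Series
    offsets: pd.Series
    glog_c: float
    method: str
    calibration: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        y = values / self.scales
        if self.glog_c > 0:
            t = np.log2((y + np.sqrt(y**2 + self.glog_c**2)) / 2.0)
        else:
            t = np.log2(y.where(y > 0))
        return t - self.offsets

    def to_json(self, path: str | Path) -> None:
        blob = {
            "scales": self.scales.to_dict(),
            "offsets": self.offsets.to_dict(),
            "glog_c": self.glog_c,
            "method": self.method,
            "calibration": list(self.calibration),
            "diagnostics": self.diagnostics,
        }
        Path(path).write_text(json.dumps(blob, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            scales=pd.Series(blob["scales"]),
            offsets=pd.Series(blob["offsets"]),
            glog_c=blob["glog_c"],
            method=blob["method"],
            calibration=blob["calibration"],
            diagnostics=blob["diagnostics"],
        )


def fit_apply_normalization(
    table: IntensityTable,
    calibration: pd.Index,
    method: str = "glog",
) -> tuple[IntensityTable, NormalizationModel]:
    """Fit per-sample parameters on the calibration subset; apply to all.

    ``method="glog"`` uses a generalized-log (arsinh-family) transform whose
    softening constant is set well below the calibration intensity range, so
    high-intensity behavior matches log2; ``method="median"`` is the pure
    median-scaling log2 fallback for exactness checks.  For tables already
    on the log2 scale only the per-sample offsets are (re)fit, making
    re-normalization idempotent.
    """
    if len(calibration) == 0:
        raise ValueError("calibration subset is empty")
    calib = table.values.loc[calibration]

    if table.log2:
        scales = pd.Series(1.0, index=table.samples.index)
        glog_c = 0.0
        med = calib.median(axis=0)
        offsets = med - med.mean()
        norm_vals = table.values - offsets
    else:
        if (calib <= 0).all(axis=0).any():
            bad = calib.columns[(calib <= 0).all(axis=0)]
            raise ValueError(
                f"samples with all-zero calibration intensities: {list(bad)}"
            )
        # per-sample scale: median ratio to the feature-wise geometric mean
        logc = np.log2(calib.where(calib > 0))
        ref = logc.mean(axis=1)
        scales = 2.0 ** (logc.sub(ref, axis=0)).median(axis=0)
        if method == "glog":
            scaled = (calib / scales).to_numpy(dtype=float)
            pos = scaled[scaled > 0]
            glog_c = float(np.quantile(pos, 0.01)) * 1e-3 if pos.size else 0.0
        elif method == "median":
            glog_c = 0.0
        else:
            raise ValueError(f"unknown method {method!r}")
        model0 = NormalizationModel(
            scales=scales,
            offsets=pd.Series(0.0, index=table.samples.index),
            glog_c=glog_c,
            method=method,
        )
        tcal = model0.transform(calib)
        med = tcal.median(axis=0)
        offsets = med - med.mean()
        norm_vals = model0.transform(table.values) - offsets

    model = NormalizationModel(
        scales=scales,
        offsets=offsets,
        glog_c=glog_c,
        method=method,
        calibration=[str(f) for f in calibration],
    )
    tcal = norm_vals.loc[calibration]
    model.diagnostics = _variance_mean_trend(tcal)
    norm = IntensityTable(
        values=norm_vals,
        samples=table.samples,
        features=table.features,
        log2=True,
    )
    return norm, model


def _variance_mean_trend(log_values: pd.DataFrame) -> dict:
    """Spearman correlation of per-feature mean vs s.d. (calibration rows)."""
    mean = log_values.mean(axis=1)
    sd = log_values.std(axis=1, ddof=1)
    ok = mean.notna() & sd.notna()
    if ok.sum() < 3 or sd[ok].nunique() <= 1:
        rho = float("nan")
    else:
        rho = float(mean[ok].rank().corr(sd[ok].rank()))
    return {"variance_mean_spearman": rho, "n_calibration": int(ok.sum())}
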