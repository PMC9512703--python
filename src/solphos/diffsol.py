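"""Solubility statistics and moderated differential testing.

Solubility of a feature is S = log2(NP-40) - log2(SDS) per replicate and
lysate; the RNA-bound fraction is RBF = S_preserved - S_digested (more
negative = more of the insoluble subpool depends on RNA).  Differential
calls use a moderated t-statistic: per-feature residual variances are
shrunk toward a common prior estimated across features by the
method-of-moments on log residual variances (Smyth 2004), and p-values are
Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .normalization import IntensityTable

__all__ = [
    "SolubilityProfile",
    "bh_adjust",
    "squeeze_var",
    "moderated_diff",
    "compute_solubility",
    "compute_rna_bound",
    "classify_proteins",
    "diff_phospho_vs_protein",
]

DEFAULT_FC = 0.5
DEFAULT_PADJ = 0.01


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment (NaNs propagate)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage


def _trigamma_inverse(x: float, tol: float = 1e-10) -> float:
    """Solve trigamma(y) = x by Newton iteration (Smyth 2004 appendix)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < tol:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Estimate prior df d0 and prior variance s0^2; return posterior s2.

    Method-of-moments fit of a scaled F-distribution to the residual
    variances via moments of log(s2).  Returns ``(d0, s0sq, s2_post)``;
    ``d0`` may be ``inf`` when variances are effectively constant.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 >= 0)
    if df <= 0 or ok.sum() < 2:
        raise ValueError("need residual df > 0 and >= 2 finite variances")
    z = np.log(np.maximum(s2[ok], 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
    s2_post = _posterior_var(s2, df, d0, s0sq)
    return d0, s0sq, s2_post


def _posterior_var(
    s2: np.ndarray, df: float, d0: float, s0sq: float
) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0sq)
    if d0 == 0:
        return np.asarray(s2, dtype=float)
    return (d0 * s0sq + df * s2) / (d0 + df)


# ---------------------------------------------------------------------------
# moderated differential test


def moderated_diff(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    paired: bool = False,
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_PADJ,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-feature moderated test of group_a vs group_b (effect = a - b).

    ``group_a``/``group_b`` are features x replicates frames sharing an
    index.  ``prior_df`` overrides the estimated empirical-Bayes prior df
    (0 recovers the ordinary t-test, ``inf`` full pooling).  Returns a frame
    with log2fc, t, df, df_prior, s2_prior, p_value, adj_p and call in
    {"up", "down", "not_changing"}.
    """
    if not group_a.index.equals(group_b.index):
        group_b = group_b.reindex(group_a.index)
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired design requires equal replicate counts")
        d = a - b
        n = d.shape[1]
        if n < 2:
            raise ValueError("need >= 2 replicates")
        effect = d.mean(axis=1)
        s2 = d.var(axis=1, ddof=1)
        df = n - 1
        se_factor = 1.0 / np.sqrt(n)
    else:
        na, nb = a.shape[1], b.shape[1]
        if na < 2 or nb < 2:
            raise ValueError("need >= 2 replicates per group")
        effect = a.mean(axis=1) - b.mean(axis=1)
        s2 = (
            (na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)
        ) / (na + nb - 2)
        df = na + nb - 2
        se_factor = np.sqrt(1.0 / na + 1.0 / nb)

    usable = np.isfinite(effect) & np.isfinite(s2)
    if not usable.all():
        warnings.warn(
            f"{(~usable).sum()} features with zero residual df or missing "
            "values excluded from the moderated test"
        )
    if prior_df is None:
        d0, s0sq, _ = squeeze_var(s2[usable], df)
    elif prior_df == 0:
        d0, s0sq = 0.0, float("nan")
    elif np.isinf(prior_df):
        d0 = np.inf
        s0sq = float(np.exp(np.mean(np.log(np.maximum(s2[usable], 1e-300)))))
    else:
        d0 = float(prior_df)
        _, s0sq, _ = squeeze_var(s2[usable], df)

    s2_post = _posterior_var(s2, df, d0, s0sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (np.sqrt(s2_post) * se_factor)
    df_total = df if d0 == 0 else (np.inf if np.isinf(d0) else df + d0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(usable, p, np.nan)
    # identical groups: zero effect and zero variance -> no evidence
    degenerate = usable & (effect == 0) & ~np.isfinite(t)
    p = np.where(degenerate, 1.0, p)
    adj = bh_adjust(p)

    call = np.where(
        (np.abs(effect) > fc_threshold) & (adj < p_threshold) & usable,
        np.where(effect > 0, "up", "down"),
        "not_changing",
    )
    return pd.DataFrame(
        {
            "log2fc": effect,
            "t": t,
            "df": float(df),
            "df_prior": d0,
            "s2_prior": s0sq,
            "p_value": p,
            "adj_p": adj,
            "call": call,
        },
        index=group_a.index.rename("feature_id"),
    )


# ---------------------------------------------------------------------------
# solubility profiles


@dataclass
class SolubilityProfile:
    """Per-feature, per-(lysate, replicate) log2 solubility values.

    ``s`` is a frame indexed by feature with a (lysate, replicate)
    MultiIndex on columns.
    """

    s: pd.DataFrame

    def lysate(self, lysate: str) -> pd.DataFrame:
        if lysate not in self.s.columns.get_level_values(0):
            raise KeyError(f"no {lysate!r} lysate in profile")
        return self.s[lysate]

    def rna_bound(self) -> pd.DataFrame:
        return compute_rna_bound(self)


def compute_solubility(norm_table: IntensityTable) -> SolubilityProfile:
    """S = log2(NP40) - log2(SDS) per (lysate, replicate) from a log2 table."""
    if not norm_table.log2:
        raise ValueError("compute_solubility expects a normalized log2 table")
    meta = norm_table.samples
    cols: dict[tuple[str, int], pd.Series] = {}
    for (lysate, rep), grp in meta.groupby(["lysate", "replicate"]):
        np40 = grp.index[grp["detergent"] == "NP40"]
        sds = grp.index[grp["detergent"] == "SDS"]
        if len(np40) != 1 or len(sds) != 1:
            raise ValueError(
                f"unmatched NP40/SDS columns for lysate={lysate} "
                f"replicate={rep}: {list(grp.index)}"
            )
        cols[(lysate, int(rep))] = (
            norm_table.values[np40[0]] - norm_table.values[sds[0]]
        )
    s = pd.DataFrame(cols)
    s.columns = pd.MultiIndex.from_tuples(s.columns, names=["lysate", "replicate"])
    return SolubilityProfile(s=s.sort_index(axis=1))


def compute_rna_bound(profile: SolubilityProfile) -> pd.DataFrame:
    """RBF = S_preserved - S_digested per replicate (log2 units)."""
    lysates = set(profile.s.columns.get_level_values(0))
    if not {"preserved", "digested"} <= lysates:
        raise ValueError(f"both lysates required, have {sorted(lysates)}")
    pres = profile.s["preserved"]
    dig = profile.s["digested"]
    common = pres.columns.intersection(dig.columns)
    return pres[common] - dig[common]


# ---------------------------------------------------------------------------
# protein classification


CLASS_SOLUBLE = "predominantly_soluble"
CLASS_SENSITIVE = "rnase_sensitive_insoluble"
CLASS_INSENSITIVE = "rnase_insensitive_insoluble"


def classify_proteins(
    preserved_diff: pd.DataFrame,
    digested_diff: pd.DataFrame,
    rnase_diff: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_PADJ,
) -> pd.DataFrame:
    """Three-way solubility class per protein.

    A protein maintains an insoluble subpool iff its preserved-lysate
    solubility is significantly below zero (log2FC <= -fc_threshold, BH
    adjusted p < p_threshold in the NP40-vs-SDS test).  An insoluble
    protein is RNase sensitive iff it additionally gains solubility upon
    RNA digestion (S_preserved - S_digested significantly <=
    -fc_threshold).  Also reports gained/lost-solubility flags from the
    RNase contrast alone.
    """
    idx = preserved_diff.index
    if not (idx.equals(digested_diff.index) and idx.equals(rnase_diff.index)):
        raise ValueError("result lists must share feature ids")

    def _sig_down(d: pd.DataFrame) -> pd.Series:
        return (d["log2fc"] <= -fc_threshold) & (d["adj_p"] < p_threshold)

    def _sig_up(d: pd.DataFrame) -> pd.Series:
        return (d["log2fc"] >= fc_threshold) & (d["adj_p"] < p_threshold)

    insoluble = _sig_down(preserved_diff)
    gained = _sig_down(rnase_diff)
    lost = _sig_up(rnase_diff)
    cls = np.where(
        insoluble,
        np.where(gained, CLASS_SENSITIVE, CLASS_INSENSITIVE),
        CLASS_SOLUBLE,
    )
    return pd.DataFrame(
        {
            "solubility_class": cls,
            "insoluble_preserved": insoluble,
            "insoluble_digested": _sig_down(digested_diff),
            "gained_solubility": gained,
            "lost_solubility": lost,
        },
        index=idx,
    )


# ---------------------------------------------------------------------------
# phosphopeptide vs parent protein


def diff_phospho_vs_protein(
    peptide_profiles: SolubilityProfile,
    protein_profiles: SolubilityProfile,
    peptide_to_protein: pd.Series,
    mode: str = "solubility",
    lysate: str = "preserved",
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_PADJ,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated test of peptide S (or RBF) against the parent protein's.

    Replicates are paired by index (same plex).  Orphan peptides whose
    protein has no profile are excluded and listed in the result attribute
    ``orphans``.
    """
    if mode == "solubility":
        pep = peptide_profiles.lysate(lysate)
        prot = protein_profiles.lysate(lysate)
    elif mode == "rna_bound":
        pep = peptide_profiles.rna_bound()
        prot = protein_profiles.rna_bound()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    mapping = peptide_to_protein.reindex(pep.index)
    orphans = pep.index[~mapping.isin(prot.index) | mapping.isna()]
    keep = pep.index.difference(orphans, sort=False)
    pep = pep.loc[keep]
    parent = prot.loc[mapping.loc[keep].to_numpy()]
    parent.index = keep

    res = moderated_diff(
        pep,
        parent,
        paired=True,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
        prior_df=prior_df,
    )
    res.attrs["orphans"] = list(orphans)
    res["protein_id"] = mapping.loc[keep].to_numpy()
    return res
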