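"""Differential enrichment statistics for feature abundance matrices.

Three tools, applicable to any feature universe (KEGG orthologs, modules,
enzyme genes, genera) and any two-arm sample contrast:

* an odds-ratio (OR) score comparing a feature's share of total abundance
  between arms, with the classification thresholds OR > 2 (case-enriched)
  and OR < 0.5 (control-enriched), both strict;
* two-sided Wilcoxon rank-sum tests per feature with Benjamini–Hochberg
  q-values computed within the tested universe;
* per-feature Z-score profiles (row-standardized abundances).

The OR for feature k is

    OR(k) = [Σ_{s∈case} A_sk / Σ_{s∈case} Σ_{i≠k} A_si] /
            [Σ_{s∈ctrl} A_sk / Σ_{s∈ctrl} Σ_{i≠k} A_si]

with the case arm in the numerator so OR > 2 reads "case-enriched"; the
``orientation="printed"`` switch puts the control arm in the numerator
instead (the literal reciprocal). When any of the four sums is zero it is
replaced by half the smallest nonzero sum of its kind (feature sums and
complement sums separately) so every OR stays finite and classifiable;
``zero_mode="exact"`` returns 0/inf/nan instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix

AF_ENRICHED = "AF_enriched"
CTR_ENRICHED = "CTR_enriched"
NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class Contrast:
    """A two-arm sample comparison over one metadata column."""

    name: str
    column: str  # "group" or "subtype"
    control: Tuple[str, ...]
    case: Tuple[str, ...]


#: the study's three contrasts: all AF vs controls, paroxysmal vs persistent,
#: persistent < 12 months vs > 12 months
DEFAULT_CONTRASTS = (
    Contrast("CTR_vs_AF", "group", ("CTR",), ("AF",)),
    Contrast("PAF_vs_psAF", "subtype", ("PAF",), ("PersLt12m", "PersGt12m")),
    Contrast("PersLt12m_vs_PersGt12m", "subtype", ("PersLt12m",), ("PersGt12m",)),
)


def contrast_samples(meta: pd.DataFrame, contrast: Contrast):
    col = meta[contrast.column]
    ctrl = meta.loc[col.isin(contrast.control), "sample_id"].tolist()
    case = meta.loc[col.isin(contrast.case), "sample_id"].tolist()
    return ctrl, case


def odds_ratio_table(abund: AbundanceMatrix, meta: pd.DataFrame,
                     contrast: Contrast = DEFAULT_CONTRASTS[0],
                     orientation: str = "case_numerator",
                     zero_mode: str = "pseudo") -> pd.Series:
    """OR for every feature in the matrix (vectorized)."""
    if orientation not in ("case_numerator", "printed"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    ctrl, case = contrast_samples(meta, contrast)
    if not ctrl or not case:
        raise ValueError(f"contrast {contrast.name}: both arms must be non-empty")
    values = abund.data
    s_ctrl = values[ctrl].sum(axis=1).to_numpy(dtype=float)
    s_case = values[case].sum(axis=1).to_numpy(dtype=float)
    if s_ctrl.sum() == 0 and s_case.sum() == 0:
        raise ValueError("abundance matrix is all zero; odds ratio undefined")
    c_ctrl = s_ctrl.sum() - s_ctrl  # complement: all features but k
    c_case = s_case.sum() - s_case
    if zero_mode == "pseudo":
        s_all = np.concatenate([s_ctrl, s_case])
        c_all = np.concatenate([c_ctrl, c_case])
        s_pseudo = 0.5 * s_all[s_all > 0].min()
        c_pseudo = 0.5 * c_all[c_all > 0].min() if (c_all > 0).any() else s_pseudo
        s_ctrl = np.where(s_ctrl > 0, s_ctrl, s_pseudo)
        s_case = np.where(s_case > 0, s_case, s_pseudo)
        c_ctrl = np.where(c_ctrl > 0, c_ctrl, c_pseudo)
        c_case = np.where(c_case > 0, c_case, c_pseudo)
    elif zero_mode != "exact":
        raise ValueError(f"unknown zero_mode: {zero_mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_case = s_case / c_case
        ratio_ctrl = s_ctrl / c_ctrl
        if orientation == "case_numerator":
            or_values = ratio_case / ratio_ctrl
        else:
            or_values = ratio_ctrl / ratio_case
    return pd.Series(or_values, index=values.index, name="or_value")


def odds_ratio(abund: AbundanceMatrix, meta: pd.DataFrame, feature,
               contrast: Contrast = DEFAULT_CONTRASTS[0],
               orientation: str = "case_numerator",
               zero_mode: str = "pseudo") -> float:
    """OR for one feature; see module docstring for the formula."""
    table = odds_ratio_table(abund, meta, contrast, orientation, zero_mode)
    if feature not in table.index:
        raise KeyError(f"feature not in matrix: {feature}")
    return float(table.loc[feature])


def classify_enrichment(or_value: float, or_high: float = 2.0,
                        or_low: float = 0.5) -> str:
    """Strict thresholds: OR > 2 case-enriched, OR < 0.5 control-enriched."""
    if np.isnan(or_value):
        return NOT_SIGNIFICANT
    if or_value > or_high:
        return AF_ENRICHED
    if or_value < or_low:
        return CTR_ENRICHED
    return NOT_SIGNIFICANT


def _wilcoxon_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 12) -> float:
    """Two-sided rank-sum p-value.

    Exact distribution for small tie-free arms; tie-corrected normal
    approximation otherwise. All-tied data is defined as p = 1.
    """
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (max(len(x), len(y)) <= exact_max_n and not has_ties) \
        else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(pvalues, method="fdr_bh")[1]


def wilcoxon_bh(abund: AbundanceMatrix, meta: pd.DataFrame,
                contrast: Contrast) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum p and BH q for a two-arm contrast.

    Returns a frame indexed by feature with p_value, q_value and per-arm
    medians. Each arm needs at least two samples.
    """
    ctrl, case = contrast_samples(meta, contrast)
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError(
            f"contrast {contrast.name}: need >= 2 samples per arm "
            f"(got {len(ctrl)} control, {len(case)} case)")
    xs = abund.data[case].to_numpy(dtype=float)
    ys = abund.data[ctrl].to_numpy(dtype=float)
    pvals = np.array([_wilcoxon_p(xs[i], ys[i]) for i in range(xs.shape[0])])
    qvals = bh_qvalues(pvals) if len(pvals) else pvals
    return pd.DataFrame({
        "p_value": pvals,
        "q_value": qvals,
        "median_ctr": np.median(ys, axis=1) if ys.size else [],
        "median_af": np.median(xs, axis=1) if xs.size else [],
    }, index=abund.data.index)


def enrichment_table(abund: AbundanceMatrix, meta: pd.DataFrame,
                     contrast: Contrast = DEFAULT_CONTRASTS[0],
                     or_high: float = 2.0, or_low: float = 0.5,
                     orientation: str = "case_numerator",
                     include_or: Optional[bool] = None) -> pd.DataFrame:
    """Full per-feature enrichment table: OR + class + Wilcoxon/BH + medians.

    The OR is computed for group-level contrasts by default; subtype
    contrasts report rank-sum statistics only (pass ``include_or=True`` to
    force it).
    """
    table = wilcoxon_bh(abund, meta, contrast)
    if include_or is None:
        include_or = contrast.column == "group"
    if include_or:
        ors = odds_ratio_table(abund, meta, contrast, orientation=orientation)
        table.insert(0, "or_value", ors)
        table.insert(1, "enrichment_class",
                     [classify_enrichment(v, or_high, or_low) for v in ors])
    table.index.name = "feature_id"
    return table


def zscore_profile(abund: AbundanceMatrix) -> pd.DataFrame:
    """Row-standardize: (value − row mean) / row sd; constant rows become 0."""
    values = abund.data.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("Z-score profile needs at least two samples")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.repeat(sd == 0, values.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=abund.data.index, columns=abund.data.columns)
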