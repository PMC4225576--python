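"""Normalization, log transformation and differential-abundance statistics.

The differential workflow mirrors a standard two-arm metabolite profiling
comparison: per cultivar and sampling day, an equal-variance two-sample
Student's t-test contrasts water-deficit (D) against irrigated (IR)
replicates; Benjamini-Hochberg adjustment is applied across metabolites
within each stratum; fold changes are D/IR ratios of untransformed group
means, displayed on a log10 scale. A metabolite's response is called
*consistent* when its fold change keeps the same direction on every tested
day and is significant on at least one of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_profiles import ProfileMatrix

__all__ = [
    "normalize_internal_standard",
    "normalize_total_intensity",
    "log_transform",
    "differential_abundance",
    "consistency_filter",
    "trait_correlation",
    "pca_scores",
    "PCAResult",
]


def normalize_internal_standard(
    pm: ProfileMatrix,
    standard_id: str,
    water_content: pd.Series | None = None,
) -> ProfileMatrix:
    """Divide every intensity by the sample's internal-standard intensity.

    Used for GC/MS profiles spiked with a standard (e.g. ribitol); when a
    per-sample tissue water content is supplied the values are additionally
    divided by it. The standard column is removed from the output.
    """
    if standard_id not in pm.values.columns:
        raise ValueError(f"internal standard {standard_id!r} not in matrix")
    std = pm.values[standard_id]
    bad = std.index[~(std > 0)]
    if len(bad):
        raise ValueError(
            f"internal standard non-positive or missing in samples: {list(bad)}"
        )
    values = pm.values.drop(columns=[standard_id]).div(std, axis=0)
    if water_content is not None:
        wc = pd.Series(water_content).reindex(values.index)
        bad = wc.index[~(wc > 0)]
        if len(bad):
            raise ValueError(f"water content non-positive or missing for: {list(bad)}")
        values = values.div(wc, axis=0)
    return pm.with_values(values)


def normalize_total_intensity(pm: ProfileMatrix, total: float = 10000.0) -> ProfileMatrix:
    """Rescale each sample so its non-missing intensities sum to ``total``.

    The LC/MS convention: peak intensities normalized to 10,000 within each
    sample. Missing entries stay missing and do not enter the sum.
    """
    sums = pm.values.sum(axis=1, skipna=True)
    counts = pm.values.notna().sum(axis=1)
    bad = sums.index[(counts == 0) | ~(sums > 0)]
    if len(bad):
        raise ValueError(f"zero or undefined intensity sum in samples: {list(bad)}")
    values = pm.values.div(sums, axis=0) * total
    return pm.with_values(values)


def log_transform(
    pm: ProfileMatrix, zero_policy: str = "half_min_offset", eps: float | None = None
) -> ProfileMatrix:
    """Elementwise log10. Missing values stay missing; negatives are an error.

    Zeros are handled per ``zero_policy``: ``half_min_offset`` (default)
    replaces them by epsilon = half the smallest positive value in the matrix
    (rank order preserved), ``error`` refuses. An explicit ``eps`` overrides
    the computed offset.
    """
    vals = pm.values.to_numpy(copy=True)
    if np.nanmin(vals, initial=np.inf) < 0:
        raise ValueError("log transform requires non-negative values")
    zeros = vals == 0
    if zeros.any():
        if zero_policy == "error":
            raise ValueError("zero intensities present and zero_policy='error'")
        if eps is None:
            positive = vals[np.isfinite(vals) & (vals > 0)]
            if positive.size == 0:
                raise ValueError("no positive values to derive a zero offset from")
            eps = 0.5 * positive.min()
        vals[zeros] = eps
    out = pd.DataFrame(np.log10(vals), index=pm.values.index, columns=pm.values.columns)
    return pm.with_values(out, scale="log10")


def _students_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample t with explicit degenerate conventions."""
    sx = np.var(x, ddof=1)
    sy = np.var(y, ddof=1)
    if sx == 0 and sy == 0:
        # no within-group variability: identical means are a non-result (p=1),
        # different means are separated with certainty under this model
        return (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def differential_abundance(
    pm: ProfileMatrix,
    days: list[int] | None = None,
    cultivars: list[str] | None = None,
    deficit: str = "D",
    irrigated: str = "IR",
    welch: bool = False,
    q_max: float = 0.05,
    p_raw: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite differential abundance D vs IR, per cultivar x day.

    Returns a tidy DataFrame with columns metabolite, cultivar, day, mean_ir,
    mean_d, fc, log10_fc, t_stat, p, q, significant_raw (p < ``p_raw``),
    significant (BH q <= ``q_max``) and consistent (same fold-change direction
    on all tested days and significant on at least one; see
    :func:`consistency_filter`).

    Strata with fewer than two replicates per group are skipped with a
    warning. Fold changes are computed on the untransformed intensity scale;
    a zero IR mean leaves fc undefined (NaN), never infinite.
    """
    if pm.scale != "intensity":
        raise ValueError("differential abundance expects untransformed intensities")
    meta = pm.samples
    if cultivars is None:
        cultivars = sorted(meta["cultivar"].unique())
    if days is None:
        days = sorted(meta["day"].unique())
    rows = []
    for cultivar in cultivars:
        for day in days:
            sel = (meta["cultivar"] == cultivar) & (meta["day"] == day)
            d_ids = meta.index[sel & (meta["treatment"] == deficit)]
            ir_ids = meta.index[sel & (meta["treatment"] == irrigated)]
            stratum = []
            for metabolite in pm.metabolites:
                x = pm.values.loc[d_ids, metabolite].dropna().to_numpy()
                y = pm.values.loc[ir_ids, metabolite].dropna().to_numpy()
                if len(x) < 2 or len(y) < 2:
                    continue
                mean_d, mean_ir = float(np.mean(x)), float(np.mean(y))
                fc = mean_d / mean_ir if mean_ir > 0 else np.nan
                if welch:
                    t, p = stats.ttest_ind(x, y, equal_var=False)
                    t, p = float(t), float(p)
                    if np.isnan(p):
                        t, p = _students_t(x, y)
                else:
                    t, p = _students_t(x, y)
                stratum.append(
                    dict(
                        metabolite=metabolite,
                        cultivar=cultivar,
                        day=day,
                        mean_ir=mean_ir,
                        mean_d=mean_d,
                        fc=fc,
                        log10_fc=np.log10(fc) if fc > 0 else np.nan,
                        t_stat=t,
                        p=p,
                    )
                )
            if not stratum:
                warnings.warn(
                    f"stratum ({cultivar}, day {day}) skipped: <2 replicates per group"
                )
                continue
            sdf = pd.DataFrame(stratum)
            sdf["q"] = multipletests(sdf["p"].to_numpy(), method="fdr_bh")[1]
            rows.append(sdf)
    if not rows:
        raise ValueError("no stratum had enough replicates")
    out = pd.concat(rows, ignore_index=True)
    out["significant_raw"] = out["p"] < p_raw
    out["significant"] = out["q"] <= q_max
    consistent = consistency_filter(out)
    key = list(zip(out["metabolite"], out["cultivar"]))
    out["consistent"] = [consistent.get(k, False) for k in key]
    return out


def consistency_filter(results: pd.DataFrame, gate: str = "raw") -> dict:
    """Two-part cross-day validity rule, per (metabolite, cultivar).

    True iff (i) the fold-change direction is identical on every tested day
    and (ii) the change is significant on at least one day. ``gate`` selects
    which significance column feeds rule (ii): ``"raw"`` (t-test p < 0.05,
    default) or ``"q"`` (BH q <= 0.05). An undefined fold change on any day
    fails the rule.
    """
    sig_col = {"raw": "significant_raw", "q": "significant"}[gate]
    out: dict = {}
    for key, grp in results.groupby(["metabolite", "cultivar"], sort=False):
        fc = grp["log10_fc"].to_numpy()
        if np.isnan(fc).any() or (fc == 0).any():
            out[key] = False
            continue
        signs = np.sign(fc)
        out[key] = bool((signs == signs[0]).all() and grp[sig_col].any())
    return out


def trait_correlation(
    pm: ProfileMatrix, traits: pd.DataFrame, min_n: int = 3
) -> pd.DataFrame:
    """Pearson r between every metabolite and every physiological trait.

    Pairwise-complete observations; pairs with fewer than ``min_n`` paired
    values or zero variance on either side get r = NaN. Returns columns
    metabolite_id, trait, r, n.
    """
    rows = []
    common = pm.values.index.intersection(traits.index)
    vals = pm.values.loc[common]
    tvals = traits.loc[common]
    for trait in tvals.columns:
        t = tvals[trait]
        for metabolite in vals.columns:
            m = vals[metabolite]
            ok = t.notna() & m.notna()
            n = int(ok.sum())
            if n < min_n:
                rows.append((metabolite, trait, np.nan, n))
                continue
            x, y = m[ok].to_numpy(), t[ok].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((metabolite, trait, np.nan, n))
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append((metabolite, trait, r, n))
    return pd.DataFrame(rows, columns=["metabolite_id", "trait", "r", "n"])


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # metabolites x components
    variance_fraction: np.ndarray
    imputed: bool
    dropped_constant: list[str]


def pca_scores(pm: ProfileMatrix, n_components: int | None = None) -> PCAResult:
    """Exact SVD principal-component analysis of a (log-scale) profile matrix.

    Columns are mean-centered; missing values are imputed with the column
    mean beforehand (flagged in the result); constant columns are dropped
    with a warning. Variance-explained fractions are non-increasing and sum
    to at most 1.
    """
    vals = pm.values.copy()
    imputed = bool(vals.isna().any().any())
    if imputed:
        vals = vals.fillna(vals.mean())
    variances = vals.var(axis=0, ddof=1)
    constant = list(variances.index[variances == 0])
    if constant:
        warnings.warn(f"dropping constant columns: {constant}")
        vals = vals.drop(columns=constant)
    centered = vals - vals.mean()
    u, s, vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    total = float((s**2).sum())
    frac = (s**2) / total if total > 0 else np.zeros_like(s)
    k = len(s) if n_components is None else min(n_components, len(s))
    comps = [f"PC{i+1}" for i in range(k)]
    scores = pd.DataFrame((u[:, :k] * s[:k]), index=vals.index, columns=comps)
    loadings = pd.DataFrame(vt[:k].T, index=vals.columns, columns=comps)
    return PCAResult(scores, loadings, frac[:k], imputed, constant)
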