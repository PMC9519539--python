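"""Cohort inference: permutation rank tests, BH FDR, ICC, Spearman,
TIL binning and hierarchical clustering of log densities.

Two-sidedness for the permutation Mann–Whitney test uses the symmetric
effect |U - n_a·n_b/2|. Exact enumeration of label splits is selected
automatically when C(n_a+n_b, n_a) <= ``exact_limit``; otherwise a
Monte-Carlo p with the add-one estimator (1 + hits) / (1 + n_perm) is
reported, so p is never zero. Ties get average ranks everywhere and the
Kruskal–Wallis H is tie-corrected.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

DEFAULT_N_PERM = 10_000
DEFAULT_EXACT_LIMIT = 50_000

TIL_CATEGORIES = ("<1%", "1-49%", ">=50%")


@dataclass
class CohortTestResult:
    feature_id: str
    contrast: str
    test: str
    statistic: float
    p_nominal: float
    q_bh: float | None = None
    n_per_group: tuple[int, ...] = ()
    stratum: str = ""
    notes: str = ""
    method: str = ""


def _clean(values) -> np.ndarray:
    """Drop non-finite values; the dropped count is the caller's to log."""
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for group a (average ranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    return float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2)


def perm_rank_test(
    values_a,
    values_b,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    mode: str = "auto",
    exact_limit: int = DEFAULT_EXACT_LIMIT,
    feature_id: str = "",
    contrast: str = "",
) -> CohortTestResult:
    """Two-sided permutation Mann–Whitney test."""
    a = _clean(values_a)
    b = _clean(values_b)
    n_dropped = (len(np.atleast_1d(values_a)) - len(a)) + (len(np.atleast_1d(values_b)) - len(b))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each group needs at least one finite value")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    mu = na * nb / 2.0
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2)
    effect_obs = abs(u_obs - mu)
    tol = 1e-9

    n_splits = math.comb(na + nb, na)
    use_exact = mode == "exact" or (mode == "auto" and n_splits <= exact_limit)
    if use_exact:
        hits = 0
        rank_sum_offset = na * (na + 1) / 2
        for comb in itertools.combinations(range(na + nb), na):
            u = ranks[list(comb)].sum() - rank_sum_offset
            if abs(u - mu) >= effect_obs - tol:
                hits += 1
        p = hits / n_splits
        method = f"exact ({n_splits} splits)"
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        chunk = max(1, min(n_perm, 200_000 // (na + nb)))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perm = rng.permuted(np.tile(ranks, (m, 1)), axis=1)
            u = perm[:, :na].sum(axis=1) - na * (na + 1) / 2
            hits += int((np.abs(u - mu) >= effect_obs - tol).sum())
            done += m
        p = (1 + hits) / (1 + n_perm)
        method = f"monte-carlo ({n_perm})"
    notes = f"dropped {n_dropped} non-finite" if n_dropped else ""
    return CohortTestResult(
        feature_id=feature_id,
        contrast=contrast,
        test="perm_mann_whitney",
        statistic=u_obs,
        p_nominal=float(p),
        n_per_group=(na, nb),
        notes=notes,
        method=method,
    )


def _kw_h(ranks: np.ndarray, sizes: np.ndarray, tie_factor: float) -> float:
    n = ranks.shape[-1]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    h = 0.0
    for i in range(len(sizes)):
        r = ranks[bounds[i]: bounds[i + 1]].sum()
        h += r * r / sizes[i]
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie_factor if tie_factor > 0 else 0.0


def perm_kruskal_wallis(
    groups,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    feature_id: str = "",
    contrast: str = "",
) -> CohortTestResult:
    """Permutation Kruskal–Wallis test (tie-corrected H)."""
    cleaned = [_clean(g) for g in groups]
    cleaned = [g for g in cleaned if len(g)]
    if len(cleaned) < 2:
        raise ValueError("need at least two non-empty groups")
    sizes = np.array([len(g) for g in cleaned])
    pooled = np.concatenate(cleaned)
    n = len(pooled)
    if len(np.unique(pooled)) < 2:
        warnings.warn("all values tied; p = 1", stacklevel=2)
        return CohortTestResult(
            feature_id=feature_id, contrast=contrast, test="perm_kruskal_wallis",
            statistic=0.0, p_nominal=1.0, n_per_group=tuple(sizes), notes="degenerate",
        )
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_factor = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    h_obs = _kw_h(ranks, sizes, tie_factor)
    rng = np.random.default_rng(seed)
    tol = 1e-9
    hits = 0
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    chunk = max(1, min(n_perm, 200_000 // n))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(ranks, (m, 1)), axis=1)
        h = np.zeros(m)
        for i in range(len(sizes)):
            r = perm[:, bounds[i]: bounds[i + 1]].sum(axis=1)
            h += r * r / sizes[i]
        h = (12.0 / (n * (n + 1)) * h - 3 * (n + 1)) / tie_factor
        hits += int((h >= h_obs - tol).sum())
        done += m
    p = (1 + hits) / (1 + n_perm)
    return CohortTestResult(
        feature_id=feature_id,
        contrast=contrast,
        test="perm_kruskal_wallis",
        statistic=float(h_obs),
        p_nominal=float(p),
        n_per_group=tuple(sizes),
        method=f"monte-carlo ({n_perm})",
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def bin_tils(percent: float) -> str:
    """Categorise a stromal-TIL percentage into the predefined bins."""
    if not 0 <= percent <= 100:
        raise ValueError("TIL percentage must be in [0, 100]")
    if percent < 1:
        return TIL_CATEGORIES[0]
    if percent < 50:
        return TIL_CATEGORIES[1]
    return TIL_CATEGORIES[2]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with two-sided p (average ranks for ties).

    Returns (nan, nan) when either vector is constant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# intraclass correlation (McGraw & Wong two-way estimators)

@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str
    form: str
    unit: str
    n_subjects: int
    n_raters: int


def icc(
    matrix,
    model: str = "two-way random",
    form: str = "absolute",
    unit: str = "single",
    alpha: float = 0.05,
) -> ICCResult:
    """Two-way ANOVA intraclass correlation with F-based 95% CI.

    ``model``: two-way random | two-way mixed (same point estimates;
    interpretation differs). ``form``: absolute | consistency.
    ``unit``: single | mean-of-k. Rows with missing values are dropped
    (complete-case).
    """
    if model not in ("two-way random", "two-way mixed"):
        raise ValueError(f"unknown model {model!r}")
    if form not in ("absolute", "consistency"):
        raise ValueError(f"unknown form {form!r}")
    if unit not in ("single", "mean-of-k"):
        raise ValueError(f"unknown unit {unit!r}")
    x = np.asarray(matrix, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters after removing missing rows")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if mse == 0 and msr == 0:
        est = 0.0
    elif form == "consistency":
        if unit == "single":
            est = (msr - mse) / (msr + (k - 1) * mse)
        else:
            est = (msr - mse) / msr if msr > 0 else 0.0
    else:
        denom1 = msr + (k - 1) * mse + k / n * (msc - mse)
        if unit == "single":
            est = (msr - mse) / denom1 if denom1 != 0 else 1.0
        else:
            denomk = msr + (msc - mse) / n
            est = (msr - mse) / denomk if denomk != 0 else 1.0

    lo, hi = _icc_ci(msr, msc, mse, n, k, form, unit, alpha)
    return ICCResult(float(est), float(lo), float(hi), model, form, unit, n, k)


def _icc_ci(msr, msc, mse, n, k, form, unit, alpha):
    if mse == 0:
        return (1.0, 1.0) if msr > 0 else (0.0, 0.0)
    if form == "consistency":
        f_obs = msr / mse
        fl = f_obs / sps.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = f_obs * sps.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        if unit == "single":
            return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)
        return 1 - 1 / fl, 1 - 1 / fu
    # absolute agreement: Satterthwaite df for ICC(A,1), then Spearman-Brown
    denom1 = msr + (k - 1) * mse + k / n * (msc - mse)
    est1 = (msr - mse) / denom1 if denom1 != 0 else 1.0
    if est1 >= 1.0:
        return 1.0, 1.0
    a = k * est1 / (n * (1 - est1))
    b = 1 + k * est1 * (n - 1) / (n * (1 - est1))
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den if v_den > 0 else (n - 1) * (k - 1)
    f_star_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_star_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (msr - f_star_u * mse) / (
        f_star_u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi1 = n * (f_star_l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_star_l * msr
    )
    if unit == "single":
        return lo1, hi1
    sb = lambda r: k * r / (1 + (k - 1) * r) if r < 1 else 1.0
    return sb(lo1), sb(hi1)


# ---------------------------------------------------------------------------
# clustering

@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    leaf_order: list[int]
    labels: np.ndarray
    row_ids: list[str] = field(default_factory=list)

    def newick(self) -> str:
        names = self.row_ids or [str(i) for i in range(len(self.leaf_order))]
        z = self.linkage_matrix
        n = len(names)
        heights = {i: 0.0 for i in range(n)}
        trees = {i: names[i] for i in range(n)}
        for j, (a, b, h, _) in enumerate(z):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            node = n + j
            trees[node] = f"({trees[a]}:{la:g},{trees[b]}:{lb:g})"
            heights[node] = h
        return trees[n + len(z) - 1] + ";"


def cluster_densities(
    density_matrix,
    row_ids: list[str] | None = None,
    n_clusters: int = 2,
) -> ClusterResult:
    """Complete-linkage clustering of log(1+x)-transformed densities.

    Euclidean distance on log1p values; agglomeration by complete
    linkage. SciPy's ordering makes the result deterministic (ties break
    toward the lower original index).
    """
    x = np.asarray(density_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    logged = np.log1p(x)
    z = linkage(pdist(logged, metric="euclidean"), method="complete")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return ClusterResult(
        linkage_matrix=z,
        leaf_order=[int(i) for i in leaves_list(z)],
        labels=labels,
        row_ids=row_ids or [],
    )


# ---------------------------------------------------------------------------
# the full contrast suite

#: Feature families get BH correction separately, one family per
#: analysis block; clinicopathological contrasts are reported without
#: multiple-testing correction (validating expected patterns).
CLINICOPATH_CONTRASTS = (
    ("er", ("negative", "positive")),
    ("her2", ("negative", "positive")),
    ("fibrosis", ("absent", "present")),
    ("comedonecrosis", ("absent", "present")),
    ("ki67_category", ("<14%", ">=14%")),
)


def contrast_suite(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    stratum_query: str | None = None,
    include_clinicopath: bool = True,
) -> pd.DataFrame:
    """Run case–control and clinicopathological contrasts on all features.

    ``features`` is tidy: patient_id, family, feature_id, value.
    ``metadata`` carries patient_id, outcome and covariate columns.
    BH q-values are computed within (family, contrast) for the
    case–control tests only. ``stratum_query`` is a pandas query string
    applied to metadata (e.g. ``"er == 'positive' and her2 == 'negative'"``).
    """
    md = metadata.copy()
    stratum = ""
    if stratum_query:
        md = md.query(stratum_query)
        stratum = stratum_query
    joined = features.merge(md, on="patient_id", how="inner")
    rng = np.random.default_rng(seed)
    results: list[CohortTestResult] = []

    for (family, feature), grp in joined.groupby(["family", "feature_id"], sort=False):
        vals = grp["value"].to_numpy(float)
        finite = np.isfinite(vals)
        contrasts: list[tuple[str, str, list[np.ndarray]]] = []
        cases = vals[finite & (grp["outcome"] == "case").to_numpy()]
        controls = vals[finite & (grp["outcome"] == "control").to_numpy()]
        contrasts.append(("case_vs_control", "mw", [cases, controls]))
        if include_clinicopath:
            if "grade" in grp.columns:
                gs = [
                    vals[finite & (grp["grade"] == g).to_numpy()]
                    for g in (1, 2, 3)
                ]
                contrasts.append(("grade", "kw", [g for g in gs if len(g)]))
            for col, levels in CLINICOPATH_CONTRASTS:
                if col not in grp.columns:
                    continue
                ga = vals[finite & (grp[col] == levels[0]).to_numpy()]
                gb = vals[finite & (grp[col] == levels[1]).to_numpy()]
                contrasts.append((f"{col}:{levels[0]}_vs_{levels[1]}", "mw", [ga, gb]))
        for contrast, kind, groups in contrasts:
            sub_seed = int(rng.integers(0, 2**32))
            if any(len(g) == 0 for g in groups) or len(groups) < 2:
                results.append(
                    CohortTestResult(
                        feature_id=feature, contrast=contrast,
                        test="perm_mann_whitney" if kind == "mw" else "perm_kruskal_wallis",
                        statistic=float("nan"), p_nominal=float("nan"),
                        stratum=stratum, notes="not-computable: empty group",
                    )
                )
                continue
            if kind == "mw":
                res = perm_rank_test(
                    groups[0], groups[1], n_perm=n_perm, seed=sub_seed,
                    feature_id=feature, contrast=contrast,
                )
            else:
                res = perm_kruskal_wallis(
                    groups, n_perm=n_perm, seed=sub_seed,
                    feature_id=feature, contrast=contrast,
                )
            res.stratum = stratum
            if contrast != "case_vs_control":
                res.notes = (res.notes + "; " if res.notes else "") + "no-mtc"
            res.notes = f"family={family}; " + res.notes if res.notes else f"family={family}"
            results.append(res)

    df = pd.DataFrame([vars(r) for r in results])
    if len(df):
        df["family"] = df["notes"].str.extract(r"family=([^;]*)")[0].fillna("")
        df["q_bh"] = np.nan
        cc = df["contrast"] == "case_vs_control"
        for family in df.loc[cc, "family"].unique():
            sel = cc & (df["family"] == family)
            df.loc[sel, "q_bh"] = bh_fdr(df.loc[sel, "p_nominal"].to_numpy())
    return df
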