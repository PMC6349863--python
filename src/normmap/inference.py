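"""Mass-univariate group inference on W-score maps.

Three layers of inference mirror the analysis workflow:

* per-location pooled two-sample t maps between patient groups
  (:func:`massuni_ttest`), with Benjamini–Hochberg FDR on surface vertices
  (:func:`correct_fdr`) or max-|t| permutation family-wise-error correction on
  skeleton voxels (:func:`correct_fwe_permutation`);
* an ANCOVA on global mean W-scores adjusted for age and sex, with
  Bonferroni-corrected pairwise post-hoc contrasts (:func:`global_ancova`);
* distributional checks: Lilliefors/KS normality and Bartlett's equality of
  variances (:func:`check_normality`, :func:`check_variance_homogeneity`).

The permutation scheme exchanges subject group labels under the two-group
null and records the null distribution of the maximum |t| over the analysis
mask; corrected p-values use the (b + 1)/(B + 1) estimator, or the exact
enumeration fraction when all distinct label assignments fit in the
permutation budget.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .stats import pooled_two_sample_t, t_from_sums
from .types import GlobalSummary, StatMap, WScoreMap


def _stack_wmaps(
    wmaps_a: list[WScoreMap], wmaps_b: list[WScoreMap], mask: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    if len(wmaps_a) < 2 or len(wmaps_b) < 2:
        raise DataError("each group needs at least 2 W-score maps")
    space = wmaps_a[0].space
    n_loc = wmaps_a[0].n_locations
    for wm in wmaps_a + wmaps_b:
        if wm.space != space:
            raise DataError(
                f"map for {wm.subject_id}: space {wm.space!r} != {space!r}"
            )
        if wm.n_locations != n_loc:
            raise DataError(
                f"map for {wm.subject_id}: {wm.n_locations} locations != {n_loc}"
            )
    A = np.stack([wm.w for wm in wmaps_a])
    B = np.stack([wm.w for wm in wmaps_b])
    in_mask = ~(np.isnan(A).any(axis=0) | np.isnan(B).any(axis=0))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n_loc,):
            raise DataError("mask length does not match map locations")
        in_mask &= mask
    return A, B, in_mask, space


def massuni_ttest(
    wmaps_a: list[WScoreMap],
    wmaps_b: list[WScoreMap],
    mask: np.ndarray | None = None,
    alpha: float = 0.05,
    contrast: tuple[str, str] = ("A", "B"),
) -> StatMap:
    """Uncorrected per-location pooled t map (positive t: group A > group B)."""
    A, B, in_mask, space = _stack_wmaps(wmaps_a, wmaps_b, mask)
    n_loc = A.shape[1]
    t = np.full(n_loc, np.nan)
    p = np.full(n_loc, np.nan)
    t[in_mask], p[in_mask], df = pooled_two_sample_t(A[:, in_mask], B[:, in_mask])
    significant = np.zeros(n_loc, dtype=bool)
    significant[in_mask] = p[in_mask] < alpha
    return StatMap(
        t=t,
        p=p,
        significant=significant,
        in_mask=in_mask,
        df=df,
        correction="none",
        contrast=contrast,
        alpha=alpha,
        space=space,
    )


def correct_fdr(statmap: StatMap, q: float = 0.05) -> StatMap:
    """Benjamini–Hochberg step-up over all in-mask locations.

    Flags are set for p <= p(k*) with k* the largest k such that
    p(k) <= k q / m; equivalently the BH-adjusted p is <= q.
    """
    if not 0 < q < 1:
        raise ConfigurationError("q must be in (0, 1)")
    p = statmap.p[statmap.in_mask]
    significant = np.zeros_like(statmap.significant)
    if p.size:
        reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
        significant[statmap.in_mask] = reject
    return StatMap(
        t=statmap.t.copy(),
        p=statmap.p.copy(),
        significant=significant,
        in_mask=statmap.in_mask.copy(),
        df=statmap.df,
        correction="FDR",
        contrast=statmap.contrast,
        alpha=q,
        space=statmap.space,
        grid_shape=statmap.grid_shape,
    )


def correct_fwe_permutation(
    wmaps_a: list[WScoreMap],
    wmaps_b: list[WScoreMap],
    mask: np.ndarray | None = None,
    n_perm: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
    contrast: tuple[str, str] = ("A", "B"),
    batch: int = 512,
) -> StatMap:
    """Max-|t| permutation FWE correction of the two-group contrast.

    Group labels are exchanged across subjects; each relabelling contributes
    the maximum |t| over the in-mask locations to the null distribution. The
    corrected p at a location is (1 + #{perm max >= |t_obs|}) / (n_perm + 1)
    for random permutations; when the number of distinct label assignments
    C(n, n_A) is within the permutation budget the full enumeration is used
    and p is the exact fraction of assignments with max >= |t_obs|.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    A, B, in_mask, space = _stack_wmaps(wmaps_a, wmaps_b, mask)
    na, nb = A.shape[0], B.shape[0]
    n = na + nb
    D = np.concatenate([A, B])[:, in_mask]
    t_obs_m, _, df = pooled_two_sample_t(D[:na], D[na:])
    abs_obs = np.abs(t_obs_m)

    s_tot = D.sum(axis=0)
    ss_tot = (D**2).sum(axis=0)

    n_exact = comb(n, na)
    exact = n_exact <= n_perm
    if exact:
        assignments = np.zeros((n_exact, n), dtype=float)
        for i, idx in enumerate(combinations(range(n), na)):
            assignments[np.full(na, i), list(idx)] = 1.0
        max_null = _max_abs_t(assignments, D, s_tot, ss_tot, na, n, batch)
        # exact p: fraction of all assignments (observed one included)
        p_corr_m = (max_null[:, None] >= abs_obs[None, :] - 1e-12).mean(axis=0)
    else:
        rng = np.random.default_rng(seed)
        max_null = np.empty(n_perm)
        done = 0
        while done < n_perm:
            b = min(batch, n_perm - done)
            P = np.zeros((b, n))
            for i in range(b):
                P[i, rng.permutation(n)[:na]] = 1.0
            max_null[done : done + b] = _max_abs_t(P, D, s_tot, ss_tot, na, n, batch)
            done += b
        exceed = (max_null[:, None] >= abs_obs[None, :] - 1e-12).sum(axis=0)
        p_corr_m = (1.0 + exceed) / (n_perm + 1.0)

    n_loc = in_mask.shape[0]
    t = np.full(n_loc, np.nan)
    p_corr = np.full(n_loc, np.nan)
    t[in_mask] = t_obs_m
    p_corr[in_mask] = p_corr_m
    raw_p = np.full(n_loc, np.nan)
    raw_p[in_mask] = 2.0 * sps.t.sf(abs_obs, df)
    significant = np.zeros(n_loc, dtype=bool)
    significant[in_mask] = p_corr_m < alpha
    return StatMap(
        t=t,
        p=raw_p,
        significant=significant,
        in_mask=in_mask,
        df=df,
        correction="FWE",
        contrast=contrast,
        alpha=alpha,
        space=space,
        p_corrected=p_corr,
    )


def _max_abs_t(
    P: np.ndarray,
    D: np.ndarray,
    s_tot: np.ndarray,
    ss_tot: np.ndarray,
    na: int,
    n: int,
    batch: int,
) -> np.ndarray:
    """Max |t| over locations for each relabelling row of indicator matrix P."""
    out = np.empty(P.shape[0])
    for start in range(0, P.shape[0], batch):
        Pb = P[start : start + batch]
        s_a = Pb @ D
        ss_a = Pb @ (D**2)
        t = t_from_sums(s_a, ss_a, na, s_tot, ss_tot, n)
        out[start : start + batch] = np.abs(t).max(axis=1)
    return out


def global_ancova(
    values: pd.Series | dict[str, float],
    covariates: pd.DataFrame,
    groups: list[str] | None = None,
    modality: str = "",
    run_diagnostics: bool = True,
) -> GlobalSummary:
    """ANCOVA of per-subject global means: value ~ group + age + sex.

    ``values`` maps subject_id to the subject's global mean W-score. The F
    test is the type-II test for the group factor after age and sex; pairwise
    group contrasts come from the same fitted model with Bonferroni
    multiplication by the number of pairs. Per-group Lilliefors-KS normality
    p-values and Bartlett's homogeneity test are attached when
    ``run_diagnostics`` (groups of fewer than 5 subjects skip KS).
    """
    vals = pd.Series(dict(values), name="value")
    cov = covariates.set_index("subject_id")
    missing = [s for s in vals.index if s not in cov.index]
    if missing:
        raise DataError(f"missing covariates for subjects: {missing}")
    df = cov.loc[vals.index, ["group", "age", "sex"]].copy()
    df["value"] = vals
    if groups is not None:
        df = df[df["group"].isin(groups)]
    present = sorted(df["group"].unique())
    if len(present) < 2:
        raise DataError(f"need at least 2 groups, got {present}")
    if df.groupby("group")["value"].count().min() < 2:
        raise DataError("each group needs at least 2 subjects")

    try:
        model = smf.ols("value ~ C(group) + age + sex", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    except Exception as exc:  # singular design etc.
        raise DataError(f"ANCOVA design is singular or invalid: {exc}") from exc
    f_stat = float(anova.loc["C(group)", "F"])
    f_p = float(anova.loc["C(group)", "PR(>F)"])

    pairs = list(combinations(present, 2))
    pairwise_p: dict[tuple[str, str], float] = {}
    base = present[0]
    for ga, gb in pairs:
        terms = []
        if ga != base:
            terms.append(f"C(group)[T.{ga}]")
        if gb != base:
            terms.append(f"-C(group)[T.{gb}]" if terms else f"C(group)[T.{gb}]")
        constraint = (" + ".join(terms)).replace("+ -", "- ") + " = 0"
        tt = model.t_test(constraint)
        pairwise_p[(ga, gb)] = float(np.squeeze(tt.pvalue))
    k = len(pairs)
    pairwise_bonf = {pr: min(1.0, k * p) for pr, p in pairwise_p.items()}

    ks_p: dict[str, float] = {}
    bart_stat = bart_p = float("nan")
    if run_diagnostics:
        by_group = [df.loc[df["group"] == g, "value"].to_numpy() for g in present]
        for g, v in zip(present, by_group):
            if len(v) >= 5 and np.std(v) > 0:
                ks_p[g] = check_normality(v)
        if all(np.var(v) > 0 for v in by_group):
            bart_stat, bart_p = check_variance_homogeneity(*by_group)

    return GlobalSummary(
        modality=modality,
        global_means={s: float(v) for s, v in vals.items()},
        group_of=df["group"].to_dict(),
        ancova_f=f_stat,
        ancova_p=f_p,
        pairwise_p=pairwise_p,
        pairwise_p_bonferroni=pairwise_bonf,
        ks_p=ks_p,
        bartlett_stat=bart_stat,
        bartlett_p=bart_p,
    )


def check_normality(values, method: str = "lilliefors") -> float:
    """Normality p-value of a sample.

    ``lilliefors`` (default) tests against a normal law with estimated mean
    and SD using the Lilliefors small-sample null; ``ks_standard`` is the
    plain one-sample KS test against N(0, 1), appropriate when the values are
    already nominally standardized (e.g. W-scores).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise DataError("normality check needs at least 5 values")
    if np.ptp(values) == 0:
        return 0.0  # a constant sample is maximally non-normal
    if method == "lilliefors":
        _, p = lilliefors(values, dist="norm")
        return float(p)
    if method == "ks_standard":
        _, p = sps.kstest(values, "norm")
        return float(p)
    raise ConfigurationError(f"unknown normality method {method!r}")


def check_variance_homogeneity(*groups) -> tuple[float, float]:
    """Bartlett's test of equal variances; returns (statistic, chi-square p)."""
    if len(groups) < 2:
        raise DataError("Bartlett's test needs at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise DataError(f"group {i} has fewer than 2 values")
        if np.var(g, ddof=1) == 0:
            raise DataError(f"group {i} has zero variance")
    stat, p = sps.bartlett(*arrs)
    return float(stat), float(p)


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p: min(1, n * p)."""
    return min(1.0, n_comparisons * float(p))
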