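"""Group-level statistics for laterality, HRV and EGG endpoints.

Covers the study's statistical stage: paired pre/post tests, mixed
repeated-measures ANOVA (temperature group between subjects, analysis window
within subjects) with per-window pairwise post-hoc contrasts, Spearman rank
correlations, Shapiro-Wilk normality checks, and false-discovery-rate
correction of each test family (Benjamini-Hochberg by default, a
Storey-type tail-area estimator as the alternative).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

log = logging.getLogger(__name__)

__all__ = ["TestResult", "paired_test", "mixed_anova", "posthoc_pairwise",
           "spearman", "fdr_correct", "normality_check", "one_way_anova"]


@dataclass
class TestResult:
    name: str
    statistic: float
    stat_name: str                     # "t", "F", "W", "rho"
    df: tuple | float | None
    p_raw: float
    p_corrected: float | None = None
    method: str = ""
    n: int = 0
    degenerate: bool = False
    notes: str = ""

    def as_dict(self) -> dict:
        d = {"name": self.name, "statistic": self.statistic,
             "stat_name": self.stat_name, "df": self.df, "p_raw": self.p_raw,
             "p_corrected": self.p_corrected, "method": self.method,
             "n": self.n, "degenerate": self.degenerate}
        if self.notes:
            d["notes"] = self.notes
        return d


def paired_test(pre, post, name: str = "paired") -> TestResult:
    """Two-sided paired t-test; missing pairs dropped pairwise."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    keep = np.isfinite(pre) & np.isfinite(post)
    dropped = int((~keep).sum())
    if dropped:
        log.info("paired_test %s: dropped %d incomplete pairs", name, dropped)
    pre, post = pre[keep], post[keep]
    n = pre.size
    if n < 3:
        raise ValueError("paired test needs at least 3 complete pairs")
    diff = post - pre
    if np.allclose(diff, diff[0]):
        if diff[0] == 0:
            return TestResult(name, 0.0, "t", n - 1, 1.0, method="paired t",
                              n=n, degenerate=True, notes="zero differences")
        return TestResult(name, math.inf if diff[0] > 0 else -math.inf, "t",
                          n - 1, 0.0, method="paired t", n=n, degenerate=True,
                          notes="zero variance of differences")
    t, p = sst.ttest_rel(post, pre)
    return TestResult(name, float(t), "t", n - 1, float(p),
                      method="paired t", n=n)


def mixed_anova(table: pd.DataFrame, dv: str = "value", within: str = "window",
                subject: str = "subject", between: str = "group",
                name: str = "") -> list[TestResult]:
    """Mixed repeated-measures ANOVA on a long-format table.

    Returns the between-group main effect, the within-window main effect and
    the interaction on the sphericity-assumed scale, with df shapes
    (g-1, N-g), (w-1, (N-g)(w-1)) and ((g-1)(w-1), (N-g)(w-1)).  Subjects
    with incomplete window sets are dropped listwise.
    """
    import pingouin as pg

    df = table[[subject, between, within, dv]].dropna(subset=[dv]).copy()
    n_win = df[within].nunique()
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == n_win].index
    dropped = sorted(set(df[subject]) - set(complete))
    if dropped:
        log.info("mixed_anova %s: dropped incomplete subjects %s", name, dropped)
        df = df[df[subject].isin(complete)]
    n_sub_per_grp = df.groupby(between)[subject].nunique()
    if int(n_sub_per_grp.sum()) - n_sub_per_grp.size < 1:
        raise ValueError("mixed ANOVA needs more subjects than groups")
    vals = df[dv].to_numpy(dtype=float)
    if np.allclose(vals, vals[0]):
        g = df[between].nunique()
        w = df[within].nunique()
        n_sub = df[subject].nunique()
        dfs = {f"{name} between ({between})".strip(): (g - 1, n_sub - g),
               f"{name} within ({within})".strip(): (w - 1, (n_sub - g) * (w - 1)),
               f"{name} interaction".strip(): ((g - 1) * (w - 1), (n_sub - g) * (w - 1))}
        return [TestResult(lbl, 0.0, "F", d, 1.0, method="mixed RM-ANOVA",
                           n=n_sub, degenerate=True, notes="no variance")
                for lbl, d in dfs.items()]
    aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject,
                         between=between)
    out = []
    label = {between: f"{name} between ({between})".strip(),
             within: f"{name} within ({within})".strip(),
             "Interaction": f"{name} interaction".strip()}
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    for _, row in aov.iterrows():
        out.append(TestResult(
            name=label.get(row["Source"], row["Source"]),
            statistic=float(row["F"]), stat_name="F",
            df=(int(row["DF1"]), int(row["DF2"])), p_raw=float(row[p_col]),
            method="mixed RM-ANOVA", n=int(df[subject].nunique())))
    return out


def one_way_anova(values, groups, name: str = "") -> TestResult:
    """Between-subject one-way ANOVA (one value per subject)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    levels = sorted(set(groups.tolist()))
    chunks = [values[groups == g] for g in levels]
    f, p = sst.f_oneway(*chunks)
    n = values.size
    return TestResult(name, float(f), "F", (len(levels) - 1, n - len(levels)),
                      float(p), method="one-way ANOVA", n=n)


def posthoc_pairwise(table: pd.DataFrame, dv: str = "value",
                     within: str = "window", between: str = "group",
                     fdr_method: str = "bh") -> list[TestResult]:
    """Per-window pairwise Welch t-tests between groups, FDR-corrected
    together as one family."""
    results = []
    for win, chunk in table.groupby(within, sort=False, observed=True):
        levels = sorted(chunk[between].unique().tolist())
        for a, b in itertools.combinations(levels, 2):
            x = chunk.loc[chunk[between] == a, dv].dropna().to_numpy()
            y = chunk.loc[chunk[between] == b, dv].dropna().to_numpy()
            t, p = sst.ttest_ind(x, y, equal_var=False)
            results.append(TestResult(f"{win}: {a} vs {b}", float(t), "t",
                                      None, float(p), method="Welch t",
                                      n=x.size + y.size))
    apply_fdr(results, method=fdr_method)
    return results


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sst.rankdata(x)  # mid-ranks for ties
    ry = sst.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom if denom > 0 else math.nan


def spearman(x, y, name: str = "spearman", exact_max_n: int = 9) -> TestResult:
    """Spearman rank correlation with mid-rank tie handling.

    The two-sided p value is an exact permutation enumeration for
    ``n <= exact_max_n`` and the t approximation otherwise.  Constant input
    gives an undefined (degenerate) result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 5:
        raise ValueError("spearman needs at least 5 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(name, math.nan, "rho", None, math.nan, n=n,
                          method="spearman", degenerate=True,
                          notes="constant input")
    rho = _spearman_rho(x, y)
    if n <= exact_max_n:
        ry = sst.rankdata(y)
        rx = sst.rankdata(x)
        rxc = rx - rx.mean()
        sx = math.sqrt(float(rxc @ rxc))
        perms = np.array(list(itertools.permutations(range(n))))
        ry_p = ry[perms]
        ryc = ry_p - ry_p.mean(axis=1, keepdims=True)
        sy = np.sqrt((ryc ** 2).sum(axis=1))
        rhos = (ryc @ rxc) / (sx * sy)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "spearman (exact permutation)"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
            p = 2.0 * sst.t.sf(abs(t), n - 2)
        method = "spearman (t approximation)"
    return TestResult(name, rho, "rho", n - 2, float(p), method=method, n=n)


def fdr_correct(p_values, method: str = "bh") -> np.ndarray:
    """Adjusted p values for one test family.

    ``bh``: Benjamini-Hochberg step-up adjusted p (monotone, never below the
    raw p).  ``tail-area``: a Storey-type tail-area estimator — BH scaled by
    an estimate of the null proportion pi0 at lambda = 0.5, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, p_bh, _, _ = multipletests(p, method="fdr_bh")
    if method == "bh":
        return p_bh
    if method in ("tail-area", "qvalue"):
        lam = 0.5
        pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam)) if p.size else 1.0
        pi0 = max(pi0, 1.0 / p.size)
        return np.minimum(pi0 * p_bh, 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def apply_fdr(results: list[TestResult], method: str = "bh") -> None:
    """Correct one family of TestResults in place (degenerate ones excluded)."""
    idx = [i for i, r in enumerate(results)
           if not r.degenerate and np.isfinite(r.p_raw)]
    if not idx:
        return
    adj = fdr_correct([results[i].p_raw for i in idx], method=method)
    for i, a in zip(idx, adj):
        results[i].p_corrected = float(a)
        results[i].method += f" + FDR({method})"


def normality_check(values, name: str = "shapiro") -> TestResult:
    """Shapiro-Wilk normality test (advisory; never gates the pipeline)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if not 3 <= n <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.all(v == v[0]):
        return TestResult(name, math.nan, "W", None, math.nan, n=n,
                          method="shapiro-wilk", degenerate=True,
                          notes="constant input")
    w, p = sst.shapiro(v)
    return TestResult(name, float(w), "W", None, float(p),
                      method="shapiro-wilk", n=n)


def run_pipeline(config):
    """Full disk-to-disk run; see :func:`lateroflux.pipeline.run_pipeline`."""
    from .pipeline import run_pipeline as _run

    return _run(config)
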