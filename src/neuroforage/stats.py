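"""The statistical battery for binned behavioural and anatomical tables.

Mixed (between × within) ANOVA with optional Greenhouse-Geisser
correction, Shapiro-Wilk routing between the parametric and the
Friedman/Wilcoxon branch, Holm-corrected post hocs and correlation
matrices, simple linear regression, and the noncentral-F a priori power
computation used to size a one-way design.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "StatResult",
    "CorrelationMatrix",
    "RegressionResult",
    "holm_adjust",
    "shapiro_gate",
    "mixed_anova",
    "posthoc_holm",
    "friedman_wilcoxon",
    "correlation_holm",
    "linear_regression",
    "anova_power",
    "anova_power_n",
    "one_way_error_df",
    "build_report",
]


@dataclass(frozen=True)
class StatResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    p_adj: float | None = None
    correction: str = "none"  # "none" | "Greenhouse-Geisser"

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1):
            raise ValueError("p must be in [0, 1]")
        if self.p_adj is not None and self.p_adj + 1e-12 < self.p:
            raise ValueError("p_adj must be >= p")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment.

    Sort p ascending; p_adj at rank i is the running maximum of
    min(1, (m - j + 1) * p_j) over j <= i. Never decreases a p-value and
    preserves the significance order.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


@dataclass(frozen=True)
class ShapiroDecision:
    statistic: float
    p: float
    normal: bool
    branch: str  # "parametric" | "nonparametric"


def shapiro_gate(sample, alpha: float = 0.05) -> ShapiroDecision:
    """Shapiro-Wilk normality gate routing to the analysis branch."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        return ShapiroDecision(statistic=float("nan"), p=0.0, normal=False,
                               branch="nonparametric")
    w, p = sps.shapiro(x)
    normal = p >= alpha
    return ShapiroDecision(statistic=float(w), p=float(p), normal=normal,
                           branch="parametric" if normal else "nonparametric")


def mixed_anova(table: pd.DataFrame, dv: str, between: str, within: str,
                subject: str, gg_correct: str | bool = "auto"
                ) -> list[StatResult]:
    """Mixed (split-plot) ANOVA: between-group, within-subject and interaction.

    ``gg_correct``: ``"auto"`` applies the Greenhouse-Geisser correction to
    the within and interaction terms when Mauchly's test rejects sphericity,
    ``True`` always, ``False`` never. Corrected degrees of freedom are
    non-integer (df × ε). Subjects missing a within level are dropped with
    a warning.
    """
    counts = table.groupby(subject)[within].nunique()
    n_levels = table[within].nunique()
    incomplete = counts[counts < n_levels].index.tolist()
    if incomplete:
        warnings.warn(f"dropping subjects missing within levels: {incomplete}",
                      stacklevel=2)
        table = table[~table[subject].isin(incomplete)]

    correction = True if gg_correct in ("auto", True) else False
    aov = pg.mixed_anova(data=table, dv=dv, between=between, within=within,
                         subject=subject, correction=correction)
    aov = aov.set_index("Source")
    aov.columns = [c.replace("-", "_") for c in aov.columns]

    spher_ok = True
    if gg_correct == "auto":
        try:
            spher_ok = bool(pg.sphericity(data=table, dv=dv, within=within,
                                          subject=subject)[0])
        except Exception:
            spher_ok = True
    apply_gg = (gg_correct is True) or (gg_correct == "auto" and not spher_ok)
    # pingouin reports epsilon on the within row only; it applies to the
    # interaction term as well
    eps_col = aov.get("eps")
    eps = float(eps_col.dropna().iloc[0]) if eps_col is not None \
        and eps_col.notna().any() else np.nan

    results = []
    for source, row in aov.iterrows():
        is_within_term = source != between
        use_gg = apply_gg and is_within_term and np.isfinite(eps)
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        p = float(row["p_unc"])
        if use_gg:
            df1, df2 = df1 * eps, df2 * eps
            p_gg = float(row.get("p_GG_corr", np.nan))
            p = p_gg if np.isfinite(p_gg) else float(sps.f.sf(row["F"], df1, df2))
        results.append(StatResult(
            effect=str(source), F=float(row["F"]), df1=df1, df2=df2, p=p,
            correction="Greenhouse-Geisser" if use_gg else "none"))
    return results


def posthoc_holm(table: pd.DataFrame, dv: str, group: str,
                 pairs: list[tuple] | None = None,
                 omnibus_significant: bool | None = None) -> pd.DataFrame:
    """Pairwise Welch t tests with Holm-adjusted p-values.

    ``omnibus_significant=False`` only warns — the gate is advisory, post
    hocs are still computed.
    """
    if omnibus_significant is False:
        warnings.warn("post hocs computed without a significant omnibus effect",
                      stacklevel=2)
    levels = sorted(table[group].dropna().unique())
    if pairs is None:
        pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        xa = table.loc[table[group] == a, dv].dropna()
        xb = table.loc[table[group] == b, dv].dropna()
        t, p = sps.ttest_ind(xa, xb, equal_var=False)
        rows.append({"A": a, "B": b, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_adjust(out["p"]) if len(out) else []
    return out


def friedman_wilcoxon(wide: pd.DataFrame) -> dict:
    """Friedman omnibus over complete blocks plus Holm-adjusted Wilcoxon post hocs.

    ``wide``: one row per subject, one column per condition (complete blocks).
    """
    if wide.isna().any().any():
        raise ValueError("Friedman requires complete blocks (no missing cells)")
    cols = list(wide.columns)
    if len(cols) < 3:
        raise ValueError("Friedman needs >= 3 conditions")
    arrays = [wide[c].to_numpy(dtype=float) for c in cols]
    if np.allclose(np.array(arrays), arrays[0]):
        chi2, p = 0.0, 1.0  # identical conditions: no evidence of any shift
    else:
        chi2, p = sps.friedmanchisquare(*arrays)
    posthoc = []
    for a, b in itertools.combinations(cols, 2):
        d = wide[a] - wide[b]
        if np.allclose(d, 0):
            w, pw = np.nan, 1.0
        else:
            w, pw = sps.wilcoxon(wide[a], wide[b])
        posthoc.append({"A": a, "B": b, "W": float(w), "p": float(pw)})
    ph = pd.DataFrame(posthoc)
    ph["p_adj"] = holm_adjust(ph["p"]) if len(ph) else []
    return {"chi2": float(chi2), "df": len(cols) - 1, "p": float(p),
            "posthoc": ph}


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson r with Holm-adjusted p over the distinct pairs."""

    measures: tuple[str, ...]
    r: pd.DataFrame
    p_adj: pd.DataFrame


def correlation_holm(table: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation matrix over the columns with Holm correction."""
    cols = list(table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    pairs, raw_p = [], []
    for a, b in itertools.combinations(cols, 2):
        sub = table[[a, b]].dropna()
        rr, pp = sps.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = float(rr)
        pairs.append((a, b))
        raw_p.append(float(pp))
    adj = holm_adjust(raw_p) if raw_p else []
    for (a, b), pa in zip(pairs, adj):
        p.loc[a, b] = p.loc[b, a] = float(pa)
    return CorrelationMatrix(measures=tuple(cols), r=r, p_adj=p)


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least-squares line fit; R² equals the squared Pearson r."""
    res = sps.linregress(np.asarray(x, float), np.asarray(y, float))
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            p=float(res.pvalue))


def anova_power(f: float, k: int, n: int, alpha: float = 0.05) -> float:
    """Power of a one-way fixed-effects ANOVA at effect size f (Cohen).

    Noncentrality λ = f²·k·n with df1 = k−1, df2 = k(n−1).
    """
    if n < 2:
        return 0.0
    df1, df2 = k - 1, k * (n - 1)
    lam = f ** 2 * k * n
    fcrit = sps.f.ppf(1 - alpha, df1, df2)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def anova_power_n(f: float, k: int, alpha: float = 0.05,
                  power: float = 0.8, n_max: int = 100_000) -> int:
    """Smallest per-group n whose noncentral-F power reaches the target."""
    if not (f > 0):
        raise ValueError("effect size f must be > 0")
    if not (0 < alpha < power < 1):
        raise ValueError("need 0 < alpha < power < 1")
    for n in range(2, n_max + 1):
        if anova_power(f, k, n, alpha) >= power:
            return n
    raise ValueError(f"power {power} unreachable with n <= {n_max}")


def mixed_anova_type1_error(n_reps: int = 200, k_groups: int = 3,
                            n_per_group: int = 8, n_within: int = 3,
                            alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I rate of the between-group test on null simulations.

    Each replicate draws i.i.d. standard-normal data for a balanced
    groups × within-levels design and records whether the group main
    effect rejects at ``alpha``. Used to calibrate the ANOVA chain.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        rows = []
        for g in range(k_groups):
            for s in range(n_per_group):
                vals = rng.standard_normal(n_within)
                rows.extend({"rat_id": f"g{g}s{s}", "group": f"g{g}",
                             "bin": f"b{b}", "value": float(vals[b])}
                            for b in range(n_within))
        res = mixed_anova(pd.DataFrame(rows), dv="value", between="group",
                          within="bin", subject="rat_id", gg_correct=False)
        p_group = next(r.p for r in res if r.effect == "group")
        hits += p_group < alpha
    return hits / n_reps


def one_way_error_df(group_sizes) -> int:
    """Error (denominator) degrees of freedom N − k of a one-way design."""
    sizes = [int(n) for n in group_sizes]
    if any(n < 0 for n in sizes):
        raise ValueError("group sizes must be non-negative")
    return sum(sizes) - len(sizes)


# ---------------------------------------------------------------------------
# report assembly

def build_report(outdir, *, anova_results: dict[str, list[StatResult]] | None = None,
                 posthocs: dict[str, pd.DataFrame] | None = None,
                 weekly_counts: pd.DataFrame | None = None,
                 binned: pd.DataFrame | None = None,
                 morphometry: pd.DataFrame | None = None,
                 intensity: pd.DataFrame | None = None,
                 make_figures: bool = True) -> "Path":
    """Write a deterministic Markdown report (plus binned-mean figures).

    Every significant post hoc line in the report traces back to a stored
    result table; empty inputs produce an empty-but-valid report.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["# Analysis report", ""]

    if weekly_counts is not None and len(weekly_counts):
        lines += ["## Weekly criterion-meeting counts", "",
                  weekly_counts.to_markdown(index=False), ""]
        weekly_counts.to_csv(outdir / "weekly_counts.csv", index=False)
    if anova_results:
        lines += ["## ANOVA", ""]
        rows = []
        for name, results in anova_results.items():
            for r in results:
                rows.append({"analysis": name, "effect": r.effect,
                             "F": round(r.F, 4), "df1": round(r.df1, 2),
                             "df2": round(r.df2, 2), "p": r.p,
                             "correction": r.correction})
        aov = pd.DataFrame(rows)
        aov.to_csv(outdir / "anova.csv", index=False)
        lines += [aov.to_markdown(index=False), ""]
    if posthocs:
        lines += ["## Holm-corrected post hocs", ""]
        for name, ph in posthocs.items():
            ph.to_csv(outdir / f"posthoc_{name}.csv", index=False)
            sig = ph[ph["p_adj"] < 0.05]
            lines += [f"### {name}", "",
                      (sig.to_markdown(index=False) if len(sig)
                       else "No significant pairs."), ""]
    if morphometry is not None and len(morphometry):
        morphometry.to_csv(outdir / "morphometry_summary.csv", index=False)
        lines += ["## Morphometry (per-ROI means)", "",
                  morphometry.to_markdown(index=False), ""]
    if intensity is not None and len(intensity):
        intensity.to_csv(outdir / "intensity.csv", index=False)
        lines += ["## Masked median intensities", "",
                  intensity.to_markdown(index=False), ""]
    if binned is not None and len(binned) and make_figures:
        fig_path = _binned_figure(binned, outdir)
        lines += ["## Binned group means", "",
                  f"![binned means]({fig_path.name})", ""]

    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    return report


def _binned_figure(binned: pd.DataFrame, outdir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    measures = sorted(binned["measure"].unique())[:6]
    fig, axes = plt.subplots(2, 3, figsize=(12, 6), squeeze=False)
    for ax, measure in zip(axes.ravel(), measures):
        sub = binned[binned["measure"] == measure]
        agg = sub.groupby(["group", "bin"])["value"].agg(["mean", "sem"]).reset_index()
        for group, g in agg.groupby("group"):
            ax.errorbar(g["bin"], g["mean"], yerr=g["sem"], label=group,
                        marker="o", capsize=3)
        ax.set_title(measure, fontsize=9)
        ax.tick_params(labelsize=7)
    axes[0, 0].legend(fontsize=6)
    fig.tight_layout()
    path = outdir / "binned_means.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
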