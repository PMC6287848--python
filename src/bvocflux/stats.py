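"""Pre/post-fumigation inference and report assembly.

Each plant contributes one mean emission per compound in the 2 h before
fumigation and one in the 2 h after; the effect of ozone is tested with a
classical paired t-test on the per-plant differences, two-sided, with no
multiple-testing correction by default (a Bonferroni/BH switch exists for
reuse). Significance stars follow the convention * P < 0.05, ** P < 0.01
(strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedTestResult",
    "paired_t",
    "stars_for_p",
    "build_report",
    "simulate_null_rejection_rate",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class PairedTestResult:
    compound: str
    n: int
    mean_pre: float
    mean_post: float
    t: float
    p: float
    stars: str
    degenerate: bool = False


def stars_for_p(p: float) -> str:
    """Significance stars: ``**`` if p<0.01, ``*`` if p<0.05, else none."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def paired_t(pre, post, compound: str = "") -> PairedTestResult:
    """Two-sided paired t-test on per-plant pre/post means.

    Degenerate inputs are handled explicitly: identical pairs give t=0,
    p=1; zero-variance differences with nonzero mean give p=0 flagged
    ``degenerate``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-d vectors")
    n = len(pre)
    if n < 2:
        raise ValueError("paired t-test requires at least 2 plants")
    diff = post - pre
    sd = float(np.std(diff, ddof=1))
    mean = float(np.mean(diff))
    if sd == 0.0:
        if mean == 0.0:
            t_stat, p, degen = 0.0, 1.0, False
        else:
            t_stat = float("inf") if mean > 0 else float("-inf")
            p, degen = 0.0, True
    else:
        t_stat = mean / (sd / np.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t_stat), df=n - 1))
        degen = False
    return PairedTestResult(
        compound=compound, n=n,
        mean_pre=float(np.mean(pre)), mean_post=float(np.mean(post)),
        t=float(t_stat), p=p, stars=stars_for_p(p), degenerate=degen,
    )


def adjust_pvalues(pvalues, method: str = "bonferroni"):
    """Optional multiple-testing correction (off by default in reports)."""
    p = np.asarray(pvalues, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown correction method {method!r}")


def build_report(emission_results, registry, correction=None) -> pd.DataFrame:
    """Assemble the per-compound pre/post emission report.

    ``emission_results`` is a sequence of :class:`bvocflux.flux.EmissionResult`
    covering both windows for every (plant, compound). One row per
    compound: pre/post means and standard errors across plants, paired t,
    p, stars; sorted by pre-fumigation emission, descending.
    """
    if not emission_results:
        return pd.DataFrame(columns=[
            "compound", "n", "pre_mean", "pre_se", "post_mean", "post_se",
            "t", "p", "stars", "units"])
    df = pd.DataFrame([{
        "compound": r.compound, "plant_id": r.plant_id,
        "window": r.window, "E": r.E, "units": r.units,
    } for r in emission_results])
    wide = df.pivot_table(index=["compound", "plant_id", "units"],
                          columns="window", values="E").reset_index()
    if "pre" not in wide.columns or "post" not in wide.columns:
        pre_set = set(df.loc[df["window"] == "pre", "compound"])
        post_set = set(df.loc[df["window"] == "post", "compound"])
        raise ValueError(
            "mismatched compound sets between windows: "
            f"{sorted(pre_set.symmetric_difference(post_set))}")
    incomplete = wide.loc[wide["pre"].isna() | wide["post"].isna(), "compound"]
    if len(incomplete):
        raise ValueError(
            "incomplete pre/post pairs for compounds: "
            f"{sorted(set(incomplete))}")
    rows = []
    for (compound, units), grp in wide.groupby(["compound", "units"], sort=True):
        pre = grp["pre"].to_numpy()
        post = grp["post"].to_numpy()
        res = paired_t(pre, post, compound=compound)
        rows.append({
            "compound": compound, "n": res.n,
            "pre_mean": res.mean_pre,
            "pre_se": float(np.std(pre, ddof=1) / np.sqrt(len(pre)))
            if len(pre) > 1 else 0.0,
            "post_mean": res.mean_post,
            "post_se": float(np.std(post, ddof=1) / np.sqrt(len(post)))
            if len(post) > 1 else 0.0,
            "t": res.t, "p": res.p, "stars": res.stars, "units": units,
        })
    report = pd.DataFrame(rows).sort_values(
        "pre_mean", ascending=False, kind="stable").reset_index(drop=True)
    if correction is not None and len(report):
        report["p_adj"] = adjust_pvalues(report["p"].to_numpy(), correction)
        report["stars"] = [stars_for_p(p) for p in report["p_adj"]]
    return report


def simulate_null_rejection_rate(
    n_plants: int = 10, n_reps: int = 1000, alpha: float = 0.05,
    plant_cv: float = 0.4, noise_cv: float = 0.05, seed=None,
) -> float:
    """Empirical type-I error of the paired test under the generator's null.

    Each replicate draws per-plant lognormal emission factors (mean 1,
    CV ``plant_cv``) and independent window-mean counting noise (relative
    SD ``noise_cv``) for pre and post windows with no true change, then
    applies the paired t-test at level ``alpha``.
    """
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(plant_cv**2)
    rejections = 0
    for _ in range(n_reps):
        factors = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n_plants)
        pre = factors * (1.0 + noise_cv * rng.standard_normal(n_plants))
        post = factors * (1.0 + noise_cv * rng.standard_normal(n_plants))
        if paired_t(pre, post).p < alpha:
            rejections += 1
    return rejections / n_reps
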