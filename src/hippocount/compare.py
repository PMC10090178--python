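"""Mask agreement (Dice) and method-comparison statistics.

Two assessment layers:

* **Dice scores** between binarized segmentation masks — automated vs each
  manual rater and rater vs rater on the same vignettes — with a two-sample
  t-test on the two score groups (Welch by default, paired by flag).
* **Method statistics** comparing per-partition automated neuron estimates
  with stereology counts: Shapiro–Wilk normality screens, a paired Wilcoxon
  test, Spearman correlations at subregion and partition granularity, two
  Kruskal–Wallis tests by subregion with Dunn post-hoc comparisons under
  Holm correction, and descriptive summaries per subregion.

All tests are two-sided at alpha = 0.05. The statistics themselves are
library-backed (scipy / statsmodels) except Dunn's rank-sum post-hoc test,
implemented here with the standard tie-corrected z statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "dice",
    "compare_masks",
    "dunn_test",
    "method_stats",
    "descriptive_table",
]

ALPHA = 0.05
METHOD_COLUMNS = ("partition_id", "subregion", "case", "level", "automated", "manual")


def binarize(mask: np.ndarray) -> np.ndarray:
    """Union of all instances: any positive label (or True) is foreground."""
    return np.asarray(mask) > 0


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of two binarized masks.

    Both masks empty is vacuous perfect agreement (1.0); exactly one empty
    is complete disagreement (0.0). Instance label values are irrelevant —
    masks are binarized first.
    """
    a = binarize(mask_a)
    b = binarize(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int((a & b).sum())
    return 2.0 * inter / (na + nb)


def compare_masks(
    auto_masks: list,
    rater_masks: list,
    paired: bool = False,
) -> dict:
    """Dice comparison of automated vs rater and rater vs rater masks.

    ``auto_masks`` holds one automated mask per vignette; ``rater_masks``
    holds, per vignette, the list of manual rater masks (>= 2 raters). All
    auto-vs-rater pairs and all rater-vs-rater pairs are scored, then the
    two score groups are compared with a two-sample t-test: Welch
    (independent) by default, the paired form when ``paired=True`` and the
    groups align in length.
    """
    if len(auto_masks) != len(rater_masks):
        raise ValueError("one automated mask per vignette is required")
    scores = []
    for v, (auto, raters) in enumerate(zip(auto_masks, rater_masks)):
        if len(raters) < 2:
            raise ValueError("need at least 2 rater masks per vignette")
        for i, rater in enumerate(raters):
            scores.append(
                {"vignette": v, "pair": "auto-vs-rater", "a": "auto", "b": f"r{i}",
                 "dice": dice(auto, rater)}
            )
        for i, j in itertools.combinations(range(len(raters)), 2):
            scores.append(
                {"vignette": v, "pair": "rater-vs-rater", "a": f"r{i}", "b": f"r{j}",
                 "dice": dice(raters[i], raters[j])}
            )
    table = pd.DataFrame(scores)
    g_auto = table.loc[table["pair"] == "auto-vs-rater", "dice"].to_numpy()
    g_rater = table.loc[table["pair"] == "rater-vs-rater", "dice"].to_numpy()
    if paired and len(g_auto) == len(g_rater):
        tt = stats.ttest_rel(g_auto, g_rater)
        test_used = "paired t-test"
        dof = len(g_auto) - 1
    else:
        tt = stats.ttest_ind(g_auto, g_rater, equal_var=False)
        test_used = "Welch independent-samples t-test"
        dof = float(tt.df) if hasattr(tt, "df") else len(g_auto) + len(g_rater) - 2
    return {
        "scores": table,
        "group_means": {
            "auto_vs_rater": _mean_sem(g_auto),
            "rater_vs_rater": _mean_sem(g_rater),
        },
        "test": {
            "name": test_used,
            "t": float(tt.statistic),
            "df": float(dof),
            "p": float(tt.pvalue),
        },
    }


def _mean_sem(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    return {
        "mean": float(x.mean()),
        "sem": float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
        "n": int(len(x)),
    }


def dunn_test(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's post-hoc pairwise rank comparisons with Holm correction.

    For each pair of groups the z statistic is the mean-rank difference
    scaled by ``sqrt((N(N+1)/12 - T/(12(N-1))) * (1/ni + 1/nj))`` where
    ``T = sum(t^3 - t)`` over tied value multiplicities; two-sided normal
    p-values are Holm-adjusted across all pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ranks = stats.rankdata(values)
    n_total = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    labels = pd.unique(groups)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        ra = ranks[groups == a]
        rb = ranks[groups == b]
        se = np.sqrt(base_var * (1.0 / len(ra) + 1.0 / len(rb)))
        z = (ra.mean() - rb.mean()) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "n_a": len(ra), "n_b": len(rb),
                     "z": float(z), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
        out["significant"] = out["p_holm"] < ALPHA
    return out


@dataclass
class StatsReport:
    shapiro: dict
    wilcoxon: dict
    spearman_subregion: dict
    spearman_partition: dict
    kruskal: dict
    dunn: dict
    descriptives: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "shapiro": self.shapiro,
            "wilcoxon": self.wilcoxon,
            "spearman_subregion": self.spearman_subregion,
            "spearman_partition": self.spearman_partition,
            "kruskal": self.kruskal,
            "dunn": {k: v.to_dict(orient="records") for k, v in self.dunn.items()},
            "descriptives": self.descriptives.to_dict(orient="records"),
        }


def method_stats(table: pd.DataFrame) -> StatsReport:
    """Full method-comparison report from a paired estimate/count table.

    ``table`` needs columns ``partition_id, subregion, case, level,
    automated, manual`` with complete pairs and at least 3 subregions.
    """
    missing = [c for c in METHOD_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"method table missing columns: {missing}")
    if table[["automated", "manual"]].isna().any().any():
        raise ValueError("method table has unpaired rows")
    if (table[["automated", "manual"]] < 0).any().any():
        raise ValueError("counts must be nonnegative")
    subregions = table["subregion"].unique()
    if len(subregions) < 3:
        raise ValueError("need at least 3 subregions")

    auto = table["automated"].to_numpy(dtype=float)
    manual = table["manual"].to_numpy(dtype=float)

    shapiro = {
        name: _shapiro(vals)
        for name, vals in (
            ("automated", auto),
            ("manual", manual),
            ("difference", manual - auto),
        )
    }

    diffs = manual - auto
    if np.allclose(diffs, 0):
        wil = {"W": 0.0, "p": 1.0, "degenerate": True,
               "note": "all paired differences are zero"}
    else:
        w = stats.wilcoxon(auto, manual, alternative="two-sided")
        wil = {"W": float(w.statistic), "p": float(w.pvalue), "degenerate": False}
    wil["n"] = int(len(auto))

    by_sub = table.groupby("subregion")[["automated", "manual"]].mean()
    r_sub = stats.spearmanr(by_sub["automated"], by_sub["manual"])
    r_part = stats.spearmanr(auto, manual)
    spearman_subregion = {"r": float(r_sub.statistic), "p": float(r_sub.pvalue),
                          "n": int(len(by_sub))}
    spearman_partition = {"r": float(r_part.statistic), "p": float(r_part.pvalue),
                          "n": int(len(table))}

    kruskal = {}
    dunn = {}
    groups = table["subregion"].to_numpy()
    for method, vals in (("automated", auto), ("manual", manual)):
        samples = [vals[groups == s] for s in subregions]
        if any(len(s) == 0 for s in samples):
            raise ValueError("a subregion has no data")
        kw = stats.kruskal(*samples)
        kruskal[method] = {
            "H": float(kw.statistic),
            "df": int(len(subregions) - 1),
            "p": float(kw.pvalue),
            "n": int(len(vals)),
        }
        dunn[method] = dunn_test(vals, groups)

    return StatsReport(
        shapiro=shapiro,
        wilcoxon=wil,
        spearman_subregion=spearman_subregion,
        spearman_partition=spearman_partition,
        kruskal=kruskal,
        dunn=dunn,
        descriptives=descriptive_table(table),
    )


def _shapiro(vals: np.ndarray) -> dict:
    if len(vals) < 3 or np.allclose(vals, vals[0]):
        return {"W": None, "p": None, "note": "too few or constant values"}
    s = stats.shapiro(vals)
    return {"W": float(s.statistic), "p": float(s.pvalue),
            "normal_at_0.05": bool(s.pvalue >= ALPHA)}


def descriptive_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subregion, per-method descriptives: quartiles, mean, SD, SEM, CI."""
    rows = []
    for method in ("automated", "manual"):
        for sub, grp in table.groupby("subregion"):
            x = grp[method].to_numpy(dtype=float)
            n = len(x)
            mean = float(x.mean())
            sd = float(x.std(ddof=1)) if n > 1 else 0.0
            sem = sd / np.sqrt(n) if n > 1 else 0.0
            half = float(stats.t.ppf(0.975, n - 1) * sem) if n > 1 else 0.0
            rows.append(
                {
                    "method": method,
                    "subregion": sub,
                    "n": n,
                    "p25": float(np.percentile(x, 25)),
                    "median": float(np.median(x)),
                    "p75": float(np.percentile(x, 75)),
                    "mean": mean,
                    "sd": sd,
                    "sem": sem,
                    "ci95_low": mean - half,
                    "ci95_high": mean + half,
                }
            )
    return pd.DataFrame(rows)
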