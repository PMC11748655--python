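"""Fixed-effects meta-analysis and ROC-AUC biomarker discovery.

Per-study standardized mean differences (Cohen's d on transformed
abundances) are combined with inverse-variance weights; the combined effect
is tested with a single two-tailed t-test. The ROC pipeline ranks features
by their area under the curve on transformed values, in binary or
One-vs-Rest mode, to propose biomarker candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .diffexp import DiffExpResult, get_alphaN, two_stage_bh
from .io import GlycanTable, StudyDesign
from .preprocess import preprocess_pipeline, variance_filter
from .transforms import TransformOptions, choose_transform

__all__ = [
    "fixed_effects_meta",
    "cohens_d_variance",
    "get_meta_analysis",
    "roc_auc",
    "get_roc",
]


def fixed_effects_meta(effects: np.ndarray, variances: np.ndarray,
                       sample_sizes: np.ndarray | None = None
                       ) -> tuple[float, float, float, float]:
    """Inverse-variance fixed-effects combination of effect sizes.

    ``d_combined = sum(w_i d_i) / sum(w_i)`` with ``w_i = 1/v_i`` and
    ``se = sqrt(1 / sum(w_i))``. The combined effect is tested two-tailed;
    with sample sizes given, a t reference with ``sum(n_i) - 2k`` degrees of
    freedom is used, otherwise a normal reference. Returns
    ``(d_combined, se, statistic, p)``.
    """
    d = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if d.shape != v.shape:
        raise ValueError("effects and variances must have equal length")
    if np.any(v <= 0):
        raise ValueError("variances must be strictly positive")
    w = 1.0 / v
    d_comb = float(np.sum(w * d) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    statistic = d_comb / se
    if sample_sizes is not None:
        df = int(np.sum(sample_sizes)) - 2 * len(d)
        p = float(2 * stats.t.sf(abs(statistic), df)) if df > 0 else float("nan")
    else:
        p = float(2 * stats.norm.sf(abs(statistic)))
    return d_comb, se, float(statistic), p


def cohens_d_variance(d: float, n1: int, n2: int) -> float:
    """Normal-approximation sampling variance of Cohen's d."""
    return (n1 + n2) / (n1 * n2) + d ** 2 / (2 * (n1 + n2))


def get_meta_analysis(studies: list[DiffExpResult],
                      group_sizes: list[tuple[int, int]] | None = None,
                      alpha: float | None = None) -> pd.DataFrame:
    """Combine per-study differential-abundance results feature by feature.

    Each study contributes its Cohen's d with sampling variance
    ``(n1+n2)/(n1 n2) + d^2 / (2(n1+n2))``. Features absent from some
    studies are combined over the studies that report them (``n_studies``
    records how many). Adjusted p-values use the two-stage BH procedure at
    the Bayesian-aware alpha of the pooled sample count.
    """
    if not studies:
        raise ValueError("meta-analysis needs at least one study")
    if group_sizes is None:
        group_sizes = []
        for s in studies:
            half = s.n_total // 2
            group_sizes.append((half, s.n_total - half))
    features = sorted({f for s in studies for f in s.table.index})
    n_total = sum(s.n_total for s in studies)
    used_alpha = get_alphaN(n_total) if alpha is None else alpha
    rows = []
    for fid in features:
        ds, vs, ns = [], [], []
        for s, (n1, n2) in zip(studies, group_sizes):
            if fid not in s.table.index:
                continue
            d = float(s.table.loc[fid, "effect_size"])
            if not np.isfinite(d):
                continue
            ds.append(d)
            vs.append(cohens_d_variance(d, n1, n2))
            ns.append(n1 + n2)
        if not ds:
            continue
        d_comb, se, statistic, p = fixed_effects_meta(
            np.array(ds), np.array(vs), sample_sizes=np.array(ns))
        rows.append({"feature": fid, "d_combined": d_comb, "se": se,
                     "statistic": statistic, "p": p, "n_studies": len(ds)})
    out = pd.DataFrame(rows).set_index("feature")
    p_adj, _ = two_stage_bh(out["p"].to_numpy(), alpha=used_alpha)
    out["p_adj"] = p_adj
    out["significant"] = out["p_adj"] < used_alpha
    return out


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC area under the curve: pairwise concordance with half credit for ties."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("roc_auc requires exactly two classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def get_roc(table: GlycanTable, design: StudyDesign,
            mode: str = "binary",
            transform_opts: TransformOptions | None = None,
            min_variance: float = 0.02,
            preprocess: bool = True,
            curve_points: bool = False) -> dict[str, pd.DataFrame]:
    """Rank features as biomarkers by ROC-AUC on transformed values.

    Every feature's transformed abundances are scored against the group
    labels; the orientation with AUC >= 0.5 is reported together with the
    sign used. ``binary`` mode handles two groups; ``one_vs_rest`` repeats
    the ranking once per class against everything else. Returns a mapping
    from comparison name to a ranked feature table (best first).
    """
    if mode not in ("binary", "one_vs_rest"):
        raise ValueError(f"mode must be 'binary' or 'one_vs_rest', got {mode!r}")
    design = design.subset(table.sample_ids)
    groups = design.groups
    if mode == "binary" and len(groups) != 2:
        raise ValueError("binary ROC mode requires exactly two groups")
    rel = preprocess_pipeline(table, design) if preprocess else table
    transform = choose_transform(rel, design, transform_opts or TransformOptions())
    trans = transform.table.data
    _, filtered = variance_filter(rel, min_variance)
    trans = trans.loc[[f for f in trans.index if f not in filtered]]

    samples = [s for s in trans.columns]
    labels_all = np.array([design.group_of[s] for s in samples])

    def rank_for(positive: np.ndarray, name: str) -> pd.DataFrame:
        rows = []
        for fid in trans.index:
            scores = trans.loc[fid, samples].to_numpy(dtype=float)
            auc = roc_auc(scores, positive)
            oriented = max(auc, 1.0 - auc)
            rows.append({"feature": fid, "auc": oriented,
                         "orientation": 1 if auc >= 0.5 else -1})
        df = pd.DataFrame(rows).set_index("feature")
        df = df.sort_values("auc", ascending=False, kind="mergesort")
        if curve_points:
            best = df.index[0]
            scores = trans.loc[best, samples].to_numpy(dtype=float)
            scores = scores * df.loc[best, "orientation"]
            fpr, tpr, _ = roc_curve(positive, scores)
            df.attrs["curve"] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
        return df

    out: dict[str, pd.DataFrame] = {}
    if mode == "binary":
        positive = (labels_all == groups[1]).astype(int)
        out[f"{groups[1]}_vs_{groups[0]}"] = rank_for(positive, "binary")
    else:
        for g in groups:
            positive = (labels_all == g).astype(int)
            out[f"{g}_vs_rest"] = rank_for(positive, g)
    return out
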