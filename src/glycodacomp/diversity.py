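"""Alpha and beta diversity of glycome profiles.

Alpha diversity summarizes the distribution of glycans *within* a sample —
richness (number of expressed structures), Shannon entropy (-sum p ln p) and
the Gini-Simpson index (1 - sum p^2) — and operates on relative abundances.
Beta diversity compares samples: the Aitchison distance is the Euclidean
distance between CLR/ALR-transformed profiles, the only distance consistent
with the simplex geometry (it is invariant to per-sample closure and to
perturbation by a fixed composition). Group structure in a distance matrix
is tested with ANOSIM (rank-based between- vs within-group contrast, R
statistic) and PERMANOVA (distance-based variance partitioning, pseudo-F),
both with seeded label-permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .diffexp import get_alphaN, two_stage_bh, welch_or_paired_t
from .io import GlycanTable, StudyDesign
from .preprocess import preprocess_pipeline
from .transforms import TransformOptions, choose_transform

__all__ = [
    "DistanceMatrix",
    "alpha_diversity",
    "compare_alpha",
    "aitchison_distance",
    "anosim",
    "permanova",
    "get_biodiversity",
]

#: Abundances at or below this value (percent scale) do not count as
#: "expressed" for richness; keeps structural-zero placeholders (1e-5) out.
RICHNESS_THRESHOLD = 1e-4

ALPHA_METRICS = ("richness", "shannon", "simpson")


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def alpha_diversity(table: GlycanTable, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity on relative abundances.

    ``richness`` counts features above the expression threshold; ``shannon``
    is -sum p ln p over nonzero proportions (natural log, maximal at the
    uniform glycome); ``simpson`` is the Gini-Simpson index 1 - sum p^2,
    bounded by 1 - 1/K.
    """
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown alpha metric {metric!r}; choose from {ALPHA_METRICS}")
    vals = np.nan_to_num(table.data.to_numpy(), nan=0.0)
    if metric == "richness":
        out = (vals > RICHNESS_THRESHOLD).sum(axis=0).astype(float)
    else:
        totals = vals.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("cannot compute diversity of an all-zero sample")
        p = vals / totals
        if metric == "shannon":
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(p > 0, p * np.log(p), 0.0)
            out = -plogp.sum(axis=0)
        else:
            out = 1.0 - (p ** 2).sum(axis=0)
    return pd.Series(out, index=table.sample_ids, name=metric)


def compare_alpha(table: GlycanTable, design: StudyDesign,
                  metrics: tuple[str, ...] = ALPHA_METRICS,
                  alpha: float | None = None) -> pd.DataFrame:
    """Group comparison of alpha diversity metrics.

    Two groups are compared with a two-tailed Welch's t-test, three or more
    with a one-way ANOVA; p-values are corrected across metrics with the
    two-stage BH procedure and called at the Bayesian-aware alpha.
    """
    design = design.subset(table.sample_ids)
    groups = design.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare alpha diversity")
    n_total = len(design.group_of)
    used_alpha = get_alphaN(n_total) if alpha is None else alpha
    rows = []
    for metric in metrics:
        div = alpha_diversity(table, metric)
        parts = [div[design.samples_in(g)].to_numpy() for g in groups]
        if len(groups) == 2:
            stat, _, p = welch_or_paired_t(parts[0], parts[1])
            test = "welch_t"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = stats.f_oneway(*parts)
            if np.isnan(stat):
                stat, p = 0.0, 1.0
            test = "anova"
        row = {"metric": metric, "test": test, "statistic": float(stat), "p": float(p)}
        for g in groups:
            row[f"mean_{g}"] = float(div[design.samples_in(g)].mean())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("metric")
    p_adj, _ = two_stage_bh(out["p"].to_numpy(), alpha=used_alpha)
    out["p_adj"] = p_adj
    out["significant"] = out["p_adj"] < used_alpha
    return out


def aitchison_distance(table: GlycanTable, design: StudyDesign | None = None,
                       transform_opts: TransformOptions | None = None) -> DistanceMatrix:
    """Aitchison distance: Euclidean distance after CLR/ALR transformation.

    With gamma = 0 the distance inherits the CLR's closure invariance:
    rescaling any sample's raw composition leaves all distances unchanged.
    """
    opts = transform_opts or TransformOptions(method="clr", scale="none", gamma=0.0)
    if design is None:
        design = StudyDesign(group_of={s: "all" for s in table.sample_ids})
    transform = choose_transform(table, design, opts)
    config = transform.table.data.to_numpy().T  # samples x features
    dist = squareform(pdist(config, metric="euclidean"))
    return DistanceMatrix(sample_ids=table.sample_ids, values=dist)


def _permutation_p(observed: float, permuted: np.ndarray) -> float:
    # +1 convention: p >= 1/(n_perm + 1)
    return float((1 + np.sum(permuted >= observed)) / (len(permuted) + 1))


def anosim(dist: DistanceMatrix, labels: dict[str, str] | pd.Series,
           n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    R contrasts the mean rank of between-group against within-group
    distances, normalized to [-1, 1]; R = 1 means all between-group
    distances exceed all within-group ones. The p-value compares R against
    ``n_perm`` seeded label permutations.
    """
    grouping = pd.Series(labels).loc[dist.sample_ids].to_numpy()
    if len(set(grouping)) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    n = len(grouping)
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dist.values[iu])
    denom = len(ranks) / 2.0

    def r_stat(g: np.ndarray) -> float:
        within = g[iu[0]] == g[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    observed = r_stat(grouping)
    rng = np.random.default_rng(seed)
    permuted = np.array([r_stat(rng.permutation(grouping)) for _ in range(n_perm)])
    return observed, _permutation_p(observed, permuted)


def _permanova_f(d2: np.ndarray, grouping: np.ndarray) -> float:
    """Pseudo-F from squared distances via sums of squares."""
    n = len(grouping)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    labels, counts = np.unique(grouping, return_counts=True)
    for lab, cnt in zip(labels, counts):
        idx = np.where(grouping == lab)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * cnt)
    a = len(labels)
    ss_among = ss_total - ss_within
    return float((ss_among / (a - 1)) / (ss_within / (n - a)))


def permanova(dist: DistanceMatrix, labels: dict[str, str] | pd.Series,
              n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the total sum of squared distances into among- and
    within-group components; the pseudo-F statistic is referred to its
    seeded permutation distribution.
    """
    grouping = pd.Series(labels).loc[dist.sample_ids].to_numpy()
    if len(set(grouping)) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    d2 = dist.values ** 2
    observed = _permanova_f(d2, grouping)
    rng = np.random.default_rng(seed)
    permuted = np.array([_permanova_f(d2, rng.permutation(grouping)) for _ in range(n_perm)])
    return observed, _permutation_p(observed, permuted)


def get_biodiversity(table: GlycanTable, design: StudyDesign,
                     metrics: tuple[str, ...] = ("richness", "shannon", "simpson", "beta"),
                     transform_opts: TransformOptions | None = None,
                     n_perm: int = 999, seed: int = 0,
                     alpha: float | None = None,
                     preprocess: bool = True) -> dict[str, object]:
    """Combined alpha/beta diversity report.

    Alpha metrics are compared on relative abundances; ``beta`` adds an
    Aitchison distance matrix with ANOSIM and PERMANOVA. All test p-values
    are corrected together with the two-stage BH procedure.
    """
    design = design.subset(table.sample_ids)
    rel = preprocess_pipeline(table, design) if preprocess else table
    used_alpha = get_alphaN(len(design.group_of)) if alpha is None else alpha
    alpha_metrics = tuple(m for m in metrics if m in ALPHA_METRICS)
    report: dict[str, object] = {"alpha_level": used_alpha}
    rows = []
    if alpha_metrics:
        alpha_table = compare_alpha(rel, design, metrics=alpha_metrics, alpha=used_alpha)
        report["alpha"] = alpha_table
        for metric, row in alpha_table.iterrows():
            rows.append({"test": f"alpha_{metric}", "statistic": row["statistic"], "p": row["p"]})
    if "beta" in metrics:
        opts = transform_opts or TransformOptions(method="clr", scale="uncertainty",
                                                  gamma=0.1, seed=seed)
        dist = aitchison_distance(rel, design, opts)
        report["distance"] = dist
        r, p_r = anosim(dist, design.group_of, n_perm=n_perm, seed=seed)
        f, p_f = permanova(dist, design.group_of, n_perm=n_perm, seed=seed + 1)
        rows.append({"test": "anosim_R", "statistic": r, "p": p_r})
        rows.append({"test": "permanova_F", "statistic": f, "p": p_f})
    tests = pd.DataFrame(rows).set_index("test")
    p_adj, _ = two_stage_bh(tests["p"].to_numpy(), alpha=used_alpha)
    tests["p_adj"] = p_adj
    tests["significant"] = tests["p_adj"] < used_alpha
    report["tests"] = tests
    return report
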