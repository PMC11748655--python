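"""SparCC-style cross-class correlation between two datasets sharing samples.

Correlating raw relative abundances across two compositional datasets (e.g.
the N- and O-glycome of the same samples, or a glycome against transcript
abundances) produces spurious associations driven by closure. Instead, both
tables are independently preprocessed and CLR/ALR-transformed, and Spearman
correlations are computed between every pair of transformed features.
Significance comes from the t approximation of the rank correlation, a
two-stage BH correction across all pairs, and the Bayesian-aware alpha for
the shared sample count; non-significant coefficients are masked to zero for
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import get_alphaN, two_stage_bh
from .io import GlycanTable, MotifMatrix, StudyDesign
from .preprocess import drop_all_zero_features, preprocess_pipeline, quantify_motifs
from .transforms import TransformOptions, choose_transform

__all__ = ["CrossCorrResult", "get_sparcc", "spearman_cross"]

MIN_SHARED_SAMPLES = 4


@dataclass
class CrossCorrResult:
    """Feature-pair Spearman correlations with significance masking."""

    rho: pd.DataFrame      # features_a x features_b
    p: pd.DataFrame
    p_adj: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    n_samples: int

    @property
    def masked_rho(self) -> pd.DataFrame:
        """rho with non-significant cells set to zero (the reporting form)."""
        return self.rho.where(self.significant, 0.0)


def spearman_cross(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and t-approximation p for every A-feature x B-feature pair.

    Rows are features, columns the shared samples (aligned). Ties receive
    average ranks; p comes from ``t = rho * sqrt((n-2) / (1-rho^2))`` with
    n-2 degrees of freedom.
    """
    n = a.shape[1]
    ra = np.apply_along_axis(stats.rankdata, 1, a.to_numpy(dtype=float))
    rb = np.apply_along_axis(stats.rankdata, 1, b.to_numpy(dtype=float))
    ra = (ra - ra.mean(axis=1, keepdims=True))
    rb = (rb - rb.mean(axis=1, keepdims=True))
    norm_a = np.sqrt((ra ** 2).sum(axis=1))
    norm_b = np.sqrt((rb ** 2).sum(axis=1))
    norm_a[norm_a == 0] = np.nan
    norm_b[norm_b == 0] = np.nan
    rho = (ra @ rb.T) / np.outer(norm_a, norm_b)
    rho = np.clip(np.nan_to_num(rho, nan=0.0), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, np.nan_to_num(p, nan=1.0))
    rho_df = pd.DataFrame(rho, index=a.index, columns=b.index)
    p_df = pd.DataFrame(p, index=a.index, columns=b.index)
    return rho_df, p_df


def get_sparcc(
    table_a: GlycanTable,
    table_b: GlycanTable,
    design_a: StudyDesign,
    design_b: StudyDesign | None = None,
    motifs_a: MotifMatrix | None = None,
    motifs_b: MotifMatrix | None = None,
    transform_opts: TransformOptions | None = None,
    alpha: float | None = None,
    preprocess: bool = True,
) -> CrossCorrResult:
    """Cross-correlate two compositional datasets over their shared samples.

    Each table is preprocessed and transformed independently (optionally at
    motif level), samples are aligned by sorted shared id, and the Spearman
    matrix is tested pair-wise. Non-glycomics partner data are accepted as
    long as they are non-negative; they are treated as compositional and
    transformed the same way.
    """
    design_b = design_b or design_a
    shared = sorted(set(table_a.sample_ids) & set(table_b.sample_ids))
    if len(shared) < MIN_SHARED_SAMPLES:
        raise ValueError(
            f"need at least {MIN_SHARED_SAMPLES} shared samples, got {len(shared)}"
        )
    opts = transform_opts or TransformOptions(method="clr")

    def prepare(table: GlycanTable, design: StudyDesign,
                motifs: MotifMatrix | None, seed_offset: int) -> pd.DataFrame:
        sub = table.with_data(table.data[shared])
        design = design.subset(shared)
        rel = preprocess_pipeline(sub, design) if preprocess else sub
        if motifs is not None:
            rel = drop_all_zero_features(quantify_motifs(rel, motifs))
        local = TransformOptions(**{**opts.__dict__, "seed": opts.seed + seed_offset})
        return choose_transform(rel, design, local).table.data[shared]

    ta = prepare(table_a, design_a, motifs_a, 0)
    tb = prepare(table_b, design_b, motifs_b, 1)

    rho, p = spearman_cross(ta, tb)
    n = len(shared)
    used_alpha = get_alphaN(n) if alpha is None else alpha
    p_adj_flat, _ = two_stage_bh(p.to_numpy().ravel(), alpha=used_alpha)
    p_adj = pd.DataFrame(p_adj_flat.reshape(p.shape), index=p.index, columns=p.columns)
    significant = p_adj < used_alpha
    return CrossCorrResult(rho=rho, p=p, p_adj=p_adj, significant=significant,
                           alpha=used_alpha, n_samples=n)
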