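"""Shared processing front-end for every analysis.

Every analysis in this package runs the same preparation of the relative
abundance table before log-ratio transformation:

1. collapse duplicate feature rows (mean),
2. drop features that are zero/missing in every sample,
3. Winsorize per feature (5% on either end by default),
4. structural-zero policy: a feature that is zero throughout one whole group
   keeps a small constant there (those zeros are informative), while sporadic
   zeros/missing cells become missing-markers,
5. MissForest-style iterative random-forest imputation of missing cells,
6. renormalization of each sample to a total of 100.

A variance filter and motif-level quantification are applied downstream by
the analysis functions where appropriate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .io import GlycanTable, MotifMatrix, StudyDesign

__all__ = [
    "drop_all_zero_features",
    "winsorize",
    "impute_missing",
    "replace_structural_zeros",
    "renormalize",
    "variance_filter",
    "collapse_duplicates",
    "quantify_motifs",
    "clean_up_redundant_motifs",
    "preprocess_pipeline",
]


def _intermediate(table: GlycanTable, df: pd.DataFrame) -> GlycanTable:
    # mid-pipeline tables no longer sum to 100 exactly; renormalize re-tags
    scale = "raw_intensity" if table.scale == "relative_percent" else table.scale
    return GlycanTable(data=df.copy(), scale=scale)


def drop_all_zero_features(table: GlycanTable) -> GlycanTable:
    """Remove features that are zero or missing in every sample."""
    vals = table.data.to_numpy()
    absent = np.all(np.isnan(vals) | (vals == 0), axis=1)
    return _intermediate(table, table.data.loc[~absent])


def winsorize(table: GlycanTable, limit: float = 0.05) -> GlycanTable:
    """Clip each feature's values to its [limit, 1-limit] percentile range.

    Percentiles are computed per feature across all samples with linear
    interpolation; values outside the range are replaced by the range
    boundary. ``limit=0`` is the identity.
    """
    if not 0 <= limit < 0.5:
        raise ValueError(f"winsorization limit must be in [0, 0.5), got {limit}")
    if limit == 0:
        return table.copy()
    df = table.data.copy()
    vals = df.to_numpy()
    for i in range(vals.shape[0]):
        row = vals[i]
        ok = ~np.isnan(row)
        if ok.sum() < 2:
            continue
        lo, hi = np.percentile(row[ok], [100 * limit, 100 * (1 - limit)])
        vals[i, ok] = np.clip(row[ok], lo, hi)
    df.iloc[:, :] = vals
    return _intermediate(table, df)


def replace_structural_zeros(table: GlycanTable, design: StudyDesign,
                             eps: float = 1e-5) -> GlycanTable:
    """Apply the structural-zero policy.

    A feature that is zero in *every* sample of a group is genuinely absent
    there: those cells are set to ``eps`` so the log-ratio transforms remain
    defined, and they are exempt from imputation. Any remaining zero is
    treated as missing-at-random and converted to a missing-marker for
    :func:`impute_missing`.
    """
    design.validate_table(table)
    df = table.data.copy()
    vals = df.to_numpy()
    cols = {s: j for j, s in enumerate(table.sample_ids)}
    for group in design.groups:
        idx = [cols[s] for s in design.samples_in(group) if s in cols]
        if not idx:
            continue
        block = vals[:, idx]
        structural = np.all(np.isnan(block) | (block == 0), axis=1)
        for i in np.where(structural)[0]:
            vals[i, idx] = eps
    vals[vals == 0] = np.nan
    df.iloc[:, :] = vals
    return _intermediate(table, df)


def impute_missing(table: GlycanTable, design: StudyDesign | None = None,
                   max_iter: int = 5, seed: int = 0,
                   n_estimators: int = 100, tol: float = 1e-3) -> GlycanTable:
    """Impute missing cells with iterative random-forest regression.

    Each feature with missing values is regressed on all other features
    (samples as observations), starting from median placeholders and
    iterating up to ``max_iter`` times or until the relative change of the
    imputed values drops below ``tol`` — the MissForest scheme. Deterministic
    for a fixed ``seed``.
    """
    vals = table.data.to_numpy()
    if not np.isnan(vals).any():
        return table.copy()
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        bad = [table.feature_ids[i] for i in np.where(all_missing)[0]]
        raise ValueError(
            f"features missing in every sample (drop them first): {bad}"
        )
    imputer = IterativeImputer(
        estimator=RandomForestRegressor(n_estimators=n_estimators, random_state=seed),
        max_iter=max_iter,
        tol=tol,
        initial_strategy="median",
        random_state=seed,
        sample_posterior=False,
        min_value=0.0,
    )
    # samples as rows so each feature is regressed on the other features
    filled = imputer.fit_transform(vals.T).T
    df = table.data.copy()
    df.iloc[:, :] = filled
    return _intermediate(table, df)


def renormalize(table: GlycanTable, total: float = 100.0) -> GlycanTable:
    """Scale every sample column to sum to ``total`` (percent scale)."""
    df = table.data.copy()
    sums = np.nansum(df.to_numpy(), axis=0)
    if np.any(sums <= 0):
        bad = [table.sample_ids[j] for j in np.where(sums <= 0)[0]]
        raise ValueError(f"cannot renormalize samples with non-positive total: {bad}")
    df = df * (total / sums)
    return table.with_data(df, scale="relative_percent" if total == 100.0 else table.scale)


def variance_filter(table: GlycanTable, min_variance: float = 0.02) -> tuple[GlycanTable, list[str]]:
    """Drop features whose variance across samples is below ``min_variance``.

    Variance is the sample variance (ddof=1) on the relative-percent scale.
    Returns the filtered table and the list of removed feature ids.
    """
    if table.n_samples < 2 or min_variance == 0:
        return table.copy(), []
    var = table.data.var(axis=1, ddof=1)
    removed = [str(f) for f in table.data.index[var < min_variance]]
    return _intermediate(table, table.data.loc[var >= min_variance]), removed


def collapse_duplicates(table: GlycanTable) -> GlycanTable:
    """Average rows that share a feature identifier."""
    if not table.data.index.duplicated().any():
        return table.copy()
    collapsed = table.data.groupby(level=0, sort=False).mean()
    return _intermediate(table, collapsed)


def quantify_motifs(table: GlycanTable, motif_matrix: MotifMatrix,
                    clean_redundant: bool = True) -> GlycanTable:
    """Aggregate glycan abundances to motif level.

    The abundance of motif *m* in sample *s* is the count-weighted sum
    ``sum_g counts[m, g] * abundance[g, s]`` — abundances are proportionally
    scaled and summed over all glycans carrying the motif. If motif counts
    partition each glycan exactly once, motif columns conserve the sample
    total.
    """
    if table.scale != "relative_percent":
        raise ValueError("motif quantification requires a relative-percent table")
    missing = [f for f in table.feature_ids if f not in motif_matrix.feature_ids]
    extra = [f for f in motif_matrix.feature_ids if f not in table.feature_ids]
    if missing or extra:
        raise ValueError(
            "motif matrix columns must match the table's features; "
            f"missing from motif matrix: {missing}; not in table: {extra}"
        )
    counts = motif_matrix.counts[table.feature_ids]
    motif_values = counts.to_numpy() @ table.data.to_numpy()
    out = pd.DataFrame(motif_values, index=motif_matrix.motif_ids, columns=table.sample_ids)
    motif_table = GlycanTable(data=out, scale="raw_intensity")
    if clean_redundant:
        motif_table = clean_up_redundant_motifs(motif_table, motif_matrix)
    return motif_table


def clean_up_redundant_motifs(motif_table: GlycanTable, motif_matrix: MotifMatrix,
                              atol: float = 1e-9) -> GlycanTable:
    """Collapse motifs with identical abundance profiles.

    Among motifs whose abundance profiles agree within ``atol``, only the
    largest motif — the one with the greatest total occurrence count — is
    kept; ties break lexicographically by motif id.
    """
    ids = motif_table.feature_ids
    vals = motif_table.data.to_numpy()
    totals = motif_matrix.counts.sum(axis=1)
    n = len(ids)
    # union-find over identical-profile motifs; tables are small
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.allclose(vals[i], vals[j], rtol=0, atol=atol):
                parent[find(j)] = find(i)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    keep: list[int] = []
    for members in groups.values():
        best = min(members, key=lambda i: (-float(totals.get(ids[i], 0)), ids[i]))
        keep.append(best)
    keep.sort()
    return motif_table.with_data(motif_table.data.iloc[keep])


def preprocess_pipeline(table: GlycanTable, design: StudyDesign,
                        winsor_limit: float = 0.05, eps: float = 1e-5,
                        impute_seed: int = 0, impute_max_iter: int = 5,
                        rf_estimators: int = 100) -> GlycanTable:
    """Run the full preparation chain, ending on the relative-percent scale.

    A table without zeros or missing cells only passes through duplicate
    collapsing, Winsorization and renormalization.
    """
    design.validate_table(table)
    out = collapse_duplicates(table)
    out = drop_all_zero_features(out)
    out = winsorize(out, limit=winsor_limit)
    out = replace_structural_zeros(out, design, eps=eps)
    out = impute_missing(out, design, max_iter=impute_max_iter, seed=impute_seed,
                         n_estimators=rf_estimators)
    return renormalize(out)
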