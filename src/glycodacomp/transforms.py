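"""Log-ratio transforms from the Aitchison simplex to real space.

Relative abundances live on the simplex: one part can only grow at the
expense of the others, so Euclidean statistics on raw percentages confound
closure effects with biology. The centered log-ratio (CLR) subtracts each
sample's log2 geometric mean; the additive log-ratio (ALR) subtracts the log2
abundance of a rigorously chosen reference glycan.

Both transforms are augmented with a *scale model* describing the unknown (or
measured) difference in total molecule count between samples:

``none``
    plain CLR/ALR, per-sample normalization term used as-is;
``uncertainty``
    the normalization term receives a per-sample draw from Normal(0, gamma^2)
    on the log2 scale, acknowledging that totals may differ between
    conditions (default gamma = 0.1);
``informed``
    the draw is centered on log2(zeta_group), where zeta is the measured
    per-group scale factor (mean summed ion intensity, expressed as a ratio
    to the lowest-scale group), and gamma becomes an estimate of the
    experimental error of that measurement. A sample from a group with twice
    the total material is shifted up by one log2 unit.

One draw is made per sample (scale is a per-sample property), deterministic
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _procrustes

from .io import GlycanTable, StudyDesign

__all__ = [
    "ScaleModel",
    "TransformResult",
    "TransformOptions",
    "geometric_mean_nonzero",
    "clr",
    "alr",
    "select_alr_reference",
    "compute_scale_factors",
    "choose_transform",
]

#: Variance floor for the ALR reference score (a perfectly constant candidate
#: would otherwise divide by zero).
REFERENCE_VARIANCE_FLOOR = 1e-12

PROCRUSTES_MIN_CORR = 0.9
REFERENCE_MAX_VARIANCE = 0.1
ALR_MIN_FEATURES = 50


@dataclass
class ScaleModel:
    """Scale-uncertainty / informed-scale parameters.

    gamma is the SD of the per-sample log2 scale perturbation; zeta maps each
    group to its scale factor (ratios to the lowest-scale group, so
    ``min(zeta.values()) == 1``).
    """

    kind: str = "uncertainty"  # none | uncertainty | informed
    gamma: float = 0.1
    zeta: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "uncertainty", "informed"):
            raise ValueError(f"unknown scale model kind {self.kind!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.kind == "informed":
            if not self.zeta:
                raise ValueError("informed-scale model requires zeta (group scale factors)")
            vals = np.array(list(self.zeta.values()), dtype=float)
            if np.any(vals < 1) or not np.isclose(vals.min(), 1.0):
                raise ValueError("zeta values are ratios to the lowest scale: min must be 1")

    def draw_shifts(self, samples: list[str], design: StudyDesign | None,
                    seed: int | None = None) -> np.ndarray:
        """One log2-scale shift per sample: delta_s ~ Normal(mu_s, gamma^2)."""
        if self.kind == "none":
            return np.zeros(len(samples))
        if self.kind == "uncertainty":
            mu = np.zeros(len(samples))
        else:
            if design is None:
                raise ValueError("informed-scale model needs a study design to map samples to groups")
            mu = np.array([np.log2(self.zeta[design.group_of[s]]) for s in samples])
        rng = np.random.default_rng(self.seed if seed is None else seed)
        if self.gamma == 0:
            return mu
        return rng.normal(mu, self.gamma)


@dataclass
class TransformResult:
    """A transformed table plus full provenance of how it was produced."""

    table: GlycanTable
    method: str  # "CLR" | "ALR"
    scale_model: ScaleModel
    seed: int
    reference_feature: str | None = None
    procrustes_corr: float | None = None
    reference_variance: float | None = None
    decision_log: list[str] = field(default_factory=list)

    def provenance(self) -> dict[str, object]:
        return {
            "method": self.method,
            "reference_feature": self.reference_feature,
            "procrustes_corr": self.procrustes_corr,
            "reference_variance": self.reference_variance,
            "scale_kind": self.scale_model.kind,
            "gamma": self.scale_model.gamma,
            "zeta": self.scale_model.zeta,
            "seed": self.seed,
        }


@dataclass
class TransformOptions:
    """User-facing knobs for :func:`choose_transform`."""

    method: str = "auto"  # auto | clr | alr
    glycan_class: str = "N"
    gamma: float = 0.1
    scale: str = "uncertainty"  # none | uncertainty | informed
    reference: str | None = None
    force_alr: bool = False
    seed: int = 0


def geometric_mean_nonzero(vector: np.ndarray) -> float:
    """Geometric mean of the strictly positive entries of ``vector``."""
    v = np.asarray(vector, dtype=float)
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("geometric mean undefined: no positive entries")
    return float(np.exp(np.mean(np.log(pos))))


def _check_positive(table: GlycanTable, what: str) -> np.ndarray:
    vals = table.data.to_numpy()
    if np.isnan(vals).any() or np.any(vals <= 0):
        raise ValueError(
            f"{what} requires a strictly positive table without missing cells; "
            "run the preprocessing pipeline (zero policy + imputation) first"
        )
    return vals


def clr(table: GlycanTable, scale_model: ScaleModel | None = None,
        seed: int | None = None, design: StudyDesign | None = None) -> TransformResult:
    """Centered log-ratio transform with a scale model.

    For sample ``s``: ``x'[g, s] = log2 x[g, s] - log2 gm(x[., s]) + delta_s``
    where the geometric mean runs over the positive entries and ``delta_s``
    is the scale model's per-sample log2 shift (0 for kind ``none``). Output
    is in log2 units; negative values simply mean below-geometric-mean.
    """
    model = scale_model or ScaleModel(kind="none", gamma=0.0)
    vals = _check_positive(table, "CLR")
    log2x = np.log2(vals)
    gm = np.array([np.log2(geometric_mean_nonzero(vals[:, j])) for j in range(vals.shape[1])])
    delta = model.draw_shifts(table.sample_ids, design, seed=seed)
    out = log2x - gm[None, :] + delta[None, :]
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    used_seed = model.seed if seed is None else seed
    return TransformResult(table=GlycanTable(df, scale="transformed"), method="CLR",
                           scale_model=model, seed=used_seed)


def alr(table: GlycanTable, reference_feature: str,
        scale_model: ScaleModel | None = None, seed: int | None = None,
        design: StudyDesign | None = None) -> TransformResult:
    """Additive log-ratio transform against ``reference_feature``.

    ``x'[g, s] = log2 x[g, s] - log2 x[ref, s] + delta_s``; the reference row
    is removed from the output. The scale draw is subtracted from the
    reference term, so a higher-scale group is shifted up.
    """
    model = scale_model or ScaleModel(kind="none", gamma=0.0)
    if reference_feature not in table.feature_ids:
        raise ValueError(f"reference feature {reference_feature!r} not in table")
    vals = _check_positive(table, "ALR")
    ref = table.data.loc[reference_feature].to_numpy(dtype=float)
    if ref.ndim > 1:
        raise ValueError(f"reference feature {reference_feature!r} is duplicated")
    if np.any(ref <= 0):
        raise ValueError(f"reference feature {reference_feature!r} is zero in some sample")
    delta = model.draw_shifts(table.sample_ids, design, seed=seed)
    out = np.log2(vals) - np.log2(ref)[None, :] + delta[None, :]
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    df = df.drop(index=reference_feature)
    used_seed = model.seed if seed is None else seed
    var = float(np.var(np.log2(ref), ddof=1)) if ref.size > 1 else 0.0
    return TransformResult(table=GlycanTable(df, scale="transformed"), method="ALR",
                           scale_model=model, seed=used_seed,
                           reference_feature=reference_feature, reference_variance=var)


def _clr_configuration(log2x: np.ndarray) -> np.ndarray:
    """Sample configuration of the CLR, projected to (features-1) dimensions.

    Samples are points; the CLR matrix (samples x features) is column-mean
    centered and its principal-component scores are taken (zero-padded when
    rank < features-1) so its shape matches an ALR configuration.
    """
    clr_mat = (log2x - log2x.mean(axis=0, keepdims=True)).T  # samples x features
    centered = clr_mat - clr_mat.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    n, f = clr_mat.shape
    target = f - 1
    if scores.shape[1] >= target:
        return scores[:, :target]
    return np.hstack([scores, np.zeros((n, target - scores.shape[1]))])


def procrustes_correlation(config_a: np.ndarray, config_b: np.ndarray) -> float:
    """Procrustes correlation sqrt(1 - M^2) between two sample configurations."""
    _, _, disparity = _procrustes(config_a, config_b)
    return float(np.sqrt(max(0.0, 1.0 - disparity)))


def select_alr_reference(table: GlycanTable, design: StudyDesign | None = None
                         ) -> tuple[str, float, float, pd.DataFrame]:
    """Rank candidate ALR references and return the best one.

    Each candidate r is scored by (Procrustes correlation between the ALR_r
    and CLR sample configurations) x (1 / variance of r's log2 abundances):
    a good reference reproduces the CLR geometry and is itself stable across
    samples. Returns ``(feature_id, procrustes_corr, reference_variance,
    ranked score table)``.
    """
    if table.n_features < 3:
        raise ValueError("ALR reference selection needs at least 3 features")
    vals = _check_positive(table, "ALR reference selection")
    log2x = np.log2(vals)
    clr_config = _clr_configuration(log2x)
    records = []
    for i, fid in enumerate(table.feature_ids):
        alr_mat = np.delete(log2x - log2x[i][None, :], i, axis=0).T  # samples x (f-1)
        try:
            corr = procrustes_correlation(clr_config, alr_mat)
        except ValueError:  # degenerate configuration (e.g. all-constant)
            corr = 0.0
        var = float(np.var(log2x[i], ddof=1))
        score = corr / max(var, REFERENCE_VARIANCE_FLOOR)
        records.append((fid, corr, var, score))
    ranked = pd.DataFrame(records, columns=["feature", "procrustes_corr", "variance", "score"])
    ranked = ranked.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    best = ranked.iloc[0]
    return str(best["feature"]), float(best["procrustes_corr"]), float(best["variance"]), ranked


def compute_scale_factors(design: StudyDesign) -> dict[str, float]:
    """Per-group scale factors zeta from summed ion intensities.

    The scale of a group is the mean of its samples' total ion intensities;
    zeta expresses each group scale as a ratio to the lowest one, so the
    smallest group has zeta = 1 exactly.
    """
    if design.ion_totals is None:
        raise ValueError(
            "informed-scale model requires per-sample ion totals in the design; "
            "use the scale-uncertainty model otherwise"
        )
    missing = [s for s in design.group_of if s not in design.ion_totals]
    if missing:
        raise ValueError(f"ion totals missing for samples: {missing}")
    scales = {
        g: float(np.mean([design.ion_totals[s] for s in design.samples_in(g)]))
        for g in design.groups
    }
    lowest = min(scales.values())
    return {g: v / lowest for g, v in scales.items()}


def choose_transform(table: GlycanTable, design: StudyDesign,
                     opts: TransformOptions | None = None) -> TransformResult:
    """Pick and apply CLR or ALR according to the workflow rule.

    ALR is attempted for N-glycomics tables with more than 50 features (or
    when forced); the best reference is accepted if its Procrustes
    correlation is at least 0.9 and its log2 variance at most 0.1, otherwise
    the transform falls back to CLR. The decision and diagnostics are logged
    on the returned :class:`TransformResult`.
    """
    opts = opts or TransformOptions()
    design.validate_table(table)
    if opts.scale == "informed":
        model = ScaleModel(kind="informed", gamma=opts.gamma,
                           zeta=compute_scale_factors(design), seed=opts.seed)
    else:
        model = ScaleModel(kind=opts.scale, gamma=opts.gamma, seed=opts.seed)
    log: list[str] = [f"scale model: kind={model.kind} gamma={model.gamma} zeta={model.zeta}"]

    want_alr = (
        opts.method == "alr"
        or opts.force_alr
        or (opts.method == "auto" and opts.glycan_class == "N"
            and table.n_features > ALR_MIN_FEATURES)
    )
    forced = opts.method == "alr" or opts.force_alr

    if opts.method == "clr" or not want_alr:
        log.append("CLR chosen" + ("" if opts.method == "clr" else
                                   " (ALR rule not triggered)"))
        result = clr(table, model, design=design)
        result.decision_log = log
        return result

    if opts.reference is not None:
        ref, corr, var = opts.reference, None, None
        log.append(f"ALR with user-supplied reference {ref!r}")
    else:
        try:
            ref, corr, var, _ = select_alr_reference(table, design)
        except ValueError as exc:
            log.append(f"ALR reference selection failed ({exc}); falling back to CLR")
            result = clr(table, model, design=design)
            result.decision_log = log
            return result
        log.append(f"best ALR reference {ref!r}: Procrustes corr={corr:.4f}, variance={var:.4f}")
        if not forced and (corr < PROCRUSTES_MIN_CORR or var > REFERENCE_MAX_VARIANCE):
            log.append(
                f"ALR abandoned (needs corr >= {PROCRUSTES_MIN_CORR} and "
                f"variance <= {REFERENCE_MAX_VARIANCE}); CLR chosen"
            )
            result = clr(table, model, design=design)
            result.decision_log = log
            return result
        log.append("ALR accepted" + (" (forced)" if forced else ""))
    result = alr(table, ref, model, design=design)
    result.procrustes_corr = corr
    if var is not None:
        result.reference_variance = var
    result.decision_log = log
    return result
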