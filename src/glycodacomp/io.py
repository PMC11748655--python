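"""Data model and readers/writers for glycomics abundance tables.

Comparative glycomics tables are small, dense feature-by-sample matrices of
relative abundances (percent of total integrated ion intensity per sample) or
raw ion intensities. This module defines the in-memory containers used across
the package — :class:`GlycanTable`, :class:`StudyDesign`, :class:`MotifMatrix`
— and CSV/TSV round-trip functions for them.

Missing cells are deliberately kept distinct from measured zeros: an empty/NA
cell means "not observed for reasons unrelated to biology" and is later
imputed, whereas a literal 0 is a measurement handed to the structural-zero
policy in :mod:`glycodacomp.preprocess`.
"""

from __future__ import annotations

import csv as _csv
import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GlycanTable",
    "StudyDesign",
    "MotifMatrix",
    "read_abundance_table",
    "read_design",
    "read_motif_matrix",
    "write_results",
    "read_results",
]

#: Column sums within this relative tolerance of 100 auto-detect percent scale.
RELATIVE_SCALE_RTOL = 0.01

_SCALES = ("relative_percent", "raw_intensity", "transformed")


@dataclass
class GlycanTable:
    """A feature × sample abundance matrix.

    Parameters
    ----------
    data
        DataFrame with feature identifiers as the index and sample identifiers
        as columns. Missing cells are NaN, never 0.
    scale
        One of ``"relative_percent"`` (columns sum to 100),
        ``"raw_intensity"`` or ``"transformed"`` (log2 units, may be negative).
    """

    data: pd.DataFrame
    scale: str = "raw_intensity"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}; expected one of {_SCALES}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if self.scale != "transformed" and np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative abundances in a non-transformed table")
        if self.scale == "relative_percent":
            sums = np.nansum(vals, axis=0)
            if not np.allclose(sums, 100.0, rtol=RELATIVE_SCALE_RTOL):
                bad = self.data.columns[~np.isclose(sums, 100.0, rtol=RELATIVE_SCALE_RTOL)]
                raise ValueError(
                    f"columns do not sum to 100 on the relative_percent scale: {list(bad)}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        """Matrix view, shape (n_features, n_samples)."""
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "GlycanTable":
        """Return a copy holding ``data`` (and optionally a new scale tag)."""
        return GlycanTable(data=data.copy(), scale=self.scale if scale is None else scale)

    def copy(self) -> "GlycanTable":
        return GlycanTable(data=self.data.copy(), scale=self.scale)


@dataclass
class StudyDesign:
    """Sample → group assignment plus optional pairing, scale and time info.

    ``ion_totals`` carries per-sample summed ion intensity, the basis of the
    informed-scale model; it is only meaningful when equal amounts of starting
    material were analyzed per sample.
    """

    group_of: dict[str, str]
    paired: bool = False
    pair_of: dict[str, str] | None = None
    ion_totals: dict[str, float] | None = None
    timepoint_of: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.ion_totals is not None:
            bad = [s for s, v in self.ion_totals.items() if not v > 0]
            if bad:
                raise ValueError(f"ion totals must be strictly positive; offending samples: {bad}")
        if self.paired:
            if self.pair_of is None:
                raise ValueError("paired design requires a sample -> subject pairing")
            sizes = {g: len(m) for g, m in self._members().items()}
            if len(set(sizes.values())) > 1:
                raise ValueError(f"paired design requires equal group sizes, got {sizes}")

    def _members(self) -> dict[str, list[str]]:
        members: dict[str, list[str]] = {}
        for s, g in self.group_of.items():
            members.setdefault(g, []).append(s)
        return members

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.group_of.values():
            seen.setdefault(g)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]

    def validate_table(self, table: GlycanTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"samples missing from the study design: {missing}")

    def subset(self, samples: Sequence[str]) -> "StudyDesign":
        keep = set(samples)
        pick = lambda m: {s: v for s, v in m.items() if s in keep} if m else None  # noqa: E731
        return StudyDesign(
            group_of={s: g for s, g in self.group_of.items() if s in keep},
            paired=self.paired,
            pair_of=pick(self.pair_of),
            ion_totals=pick(self.ion_totals),
            timepoint_of=pick(self.timepoint_of),
        )


@dataclass
class MotifMatrix:
    """Motif × feature occurrence counts (how often motif m occurs in glycan g)."""

    counts: pd.DataFrame  # index = motif_ids, columns = feature_ids

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("motif counts must be non-negative integers")
        self.counts = self.counts.astype(float)

    @property
    def motif_ids(self) -> list[str]:
        return [str(m) for m in self.counts.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.counts.columns]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "," if dialect == "csv" else "\t"


def read_abundance_table(path: str | Path, dialect: str = "csv") -> GlycanTable:
    """Read a feature × sample abundance table.

    The first column holds feature identifiers (opaque strings); the remaining
    columns are numeric. Empty/NA cells become NaN missing-markers, never 0.
    The scale tag is auto-detected: if every column sums to 100 within 1%, the
    table is flagged ``relative_percent``, otherwise ``raw_intensity``.
    """
    # pandas mangles duplicate headers (S1, S1.1), so check the raw header line
    with open(path, encoding="utf-8") as fh:
        header = next(_csv.reader(fh, delimiter=_sep(dialect)))
    sample_headers = [h.strip() for h in header[1:]]
    dups = sorted({h for h in sample_headers if sample_headers.count(h) > 1})
    if dups:
        raise ValueError(f"duplicate sample header(s) in {path}: {dups}")
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r} in {path}")
        df[col] = coerced
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    sums = np.nansum(df.to_numpy(), axis=0)
    scale = "relative_percent" if np.allclose(sums, 100.0, rtol=RELATIVE_SCALE_RTOL) else "raw_intensity"
    return GlycanTable(data=df, scale=scale)


def read_design(path: str | Path, dialect: str = "csv") -> StudyDesign:
    """Read a study design file.

    Expected columns: ``sample``, ``group`` and optionally ``pair``,
    ``ion_total``, ``timepoint``. Column matching is case-insensitive.
    """
    df = pd.read_csv(path, sep=_sep(dialect))
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "sample" not in df.columns or "group" not in df.columns:
        raise ValueError(f"design file {path} must contain 'sample' and 'group' columns")
    samples = df["sample"].astype(str)
    if samples.duplicated().any():
        raise ValueError(f"duplicate sample rows in design: {samples[samples.duplicated()].tolist()}")
    group_of = dict(zip(samples, df["group"].astype(str)))
    pair_of = None
    paired = False
    if "pair" in df.columns and df["pair"].notna().any():
        pair_of = dict(zip(samples, df["pair"].astype(str)))
        paired = True
    ion_totals = None
    if "ion_total" in df.columns and df["ion_total"].notna().any():
        ion_totals = dict(zip(samples, df["ion_total"].astype(float)))
    timepoint_of = None
    if "timepoint" in df.columns and df["timepoint"].notna().any():
        timepoint_of = dict(zip(samples, df["timepoint"].astype(float)))
    return StudyDesign(
        group_of=group_of, paired=paired, pair_of=pair_of,
        ion_totals=ion_totals, timepoint_of=timepoint_of,
    )


def read_motif_matrix(path: str | Path, dialect: str = "csv") -> MotifMatrix:
    """Read a motif × feature count matrix (first column = motif id)."""
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MotifMatrix(counts=df)


def write_results(result: pd.DataFrame, path: str | Path,
                  provenance: Mapping[str, object] | None = None) -> None:
    """Write a results table as CSV with a ``#``-prefixed provenance header.

    Provenance (transform method, reference feature, gamma, seed, ...) is
    stored as ``# key=value`` comment lines before the CSV header so a result
    file is self-describing yet still machine-readable.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        result.to_csv(fh, float_format=None)


def read_results(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read back a results CSV written by :func:`write_results`."""
    provenance: dict[str, str] = {}
    lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                provenance[key.strip()] = value.strip()
            else:
                lines.append(line)
    df = pd.read_csv(_stdio.StringIO("".join(lines)), index_col=0)
    return df, provenance
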