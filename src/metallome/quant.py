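"""Label-free proteome intensity tables and their two normalizations.

Two distinct normalizations are used downstream and must not be conflated:

* **median** — each sample's detected intensities are divided by that
  sample's median over detected proteins, making replicate columns
  comparable; used for per-protein differential expression.
* **total** — per-protein group means divided by the summed intensity of
  all proteins, yielding relative abundances that sum to 1; used to weight
  metal stoichiometries when reconstructing the metallome.

Zero intensities in label-free data are censoring (not detected), so they
are stored as missing, excluded from medians and means alike.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MAXQUANT_ID_COLUMNS = ("Majority protein IDs", "Protein IDs")
MAXQUANT_INTENSITY_PREFIX = "Intensity "


@dataclass
class QuantTable:
    """Proteins x samples intensity matrix with missing values as NaN."""

    data: pd.DataFrame
    replicate_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative intensities in quant table")
        detected = self.data.notna() & (self.data > 0)
        empty = [s for s in self.data.columns if not detected[s].any()]
        if empty:
            raise ValueError(f"samples with no detected protein: {empty}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup}")
        if not self.replicate_groups:
            self.replicate_groups = {s: infer_group(s) for s in self.data.columns}

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.data.columns:
            seen.setdefault(self.replicate_groups[s], None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        out = [s for s in self.data.columns if self.replicate_groups[s] == group]
        if not out:
            raise KeyError(f"no samples in group {group!r}")
        return out


@dataclass
class RelativeAbundance:
    """Per-protein fraction of total intensity for one replicate group."""

    fractions: pd.Series
    group: str

    def __post_init__(self) -> None:
        if (self.fractions < 0).any():
            raise ValueError("negative relative abundance")
        total = float(self.fractions.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"relative abundances sum to {total}, not 1")


def infer_group(sample_id: str) -> str:
    """Strip a trailing replicate index ('OA1_2' -> 'OA1')."""
    return re.sub(r"[_\-.]?(?:rep)?\d+$", "", sample_id) or sample_id


def read_quant_table(
    path: str | Path,
    dialect: str = "plain",
    replicate_groups: dict[str, str] | None = None,
) -> QuantTable:
    """Read a TSV intensity table.

    ``plain``: first column protein id, remaining columns one per sample.
    ``maxquant``: proteinGroups-style — id column "Majority protein IDs"
    (or "Protein IDs"), intensity columns prefixed "Intensity "; rows
    flagged as reverse decoys or contaminants are dropped. Zeros become
    missing either way.
    """
    df = pd.read_csv(path, sep="\t")
    if dialect == "plain":
        ids = df.iloc[:, 0].astype(str)
        mat = df.iloc[:, 1:]
    elif dialect == "maxquant":
        id_col = next((c for c in MAXQUANT_ID_COLUMNS if c in df.columns), None)
        if id_col is None:
            raise ValueError(f"no identifier column among {MAXQUANT_ID_COLUMNS}")
        keep = pd.Series(True, index=df.index)
        for flag in ("Reverse", "Potential contaminant", "Contaminant"):
            if flag in df.columns:
                keep &= df[flag].fillna("") != "+"
        df = df[keep]
        ids = df[id_col].astype(str)
        cols = [c for c in df.columns
                if c.startswith(MAXQUANT_INTENSITY_PREFIX) and c != "Intensity"]
        mat = df[cols].rename(columns=lambda c: c[len(MAXQUANT_INTENSITY_PREFIX):])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if mat.shape[1] == 0:
        raise ValueError(f"no intensity columns in {path}")
    if ids.duplicated().any():
        raise ValueError(f"duplicate protein id: {ids[ids.duplicated()].iloc[0]}")
    mat = mat.apply(pd.to_numeric).astype(float)
    mat = mat.mask(mat == 0.0)  # label-free zero == not detected
    mat.index = ids
    mat.index.name = "protein_id"
    return QuantTable(mat, replicate_groups=dict(replicate_groups or {}))


def normalize_median(table: QuantTable) -> QuantTable:
    """Divide each sample by its median over detected proteins.

    Rank order within a sample is preserved; missing values stay missing.
    Idempotent up to the first application's scale (the median of a
    median-normalized column is 1).
    """
    medians = table.data.median(axis=0, skipna=True)
    return QuantTable(table.data / medians, replicate_groups=dict(table.replicate_groups))


def normalize_total(
    table: QuantTable, group: str, order: str = "mean_then_normalize"
) -> RelativeAbundance:
    """Relative abundance of each protein within one replicate group.

    Default: per-protein mean over the group's samples (missing excluded
    from the mean; a protein missing everywhere gets 0), divided by the
    total. ``order="normalize_then_mean"`` first scales each sample to its
    own total, then averages — the two coincide on complete matrices.
    """
    samples = table.samples_of(group)
    sub = table.data[samples]
    if order == "mean_then_normalize":
        means = sub.mean(axis=1, skipna=True).fillna(0.0)
    elif order == "normalize_then_mean":
        per_sample = sub / sub.sum(axis=0, skipna=True)
        means = per_sample.mean(axis=1, skipna=True).fillna(0.0)
    else:
        raise ValueError(f"unknown order {order!r}")
    total = float(means.sum())
    if total <= 0:
        raise ValueError(f"group {group!r} has zero total intensity")
    return RelativeAbundance(fractions=means / total, group=group)


def relative_abundance_per_sample(table: QuantTable, sample: str) -> RelativeAbundance:
    """Single-sample relative abundance (one replicate's metallome input)."""
    col = table.data[sample].fillna(0.0)
    total = float(col.sum())
    if total <= 0:
        raise ValueError(f"sample {sample!r} has zero total intensity")
    return RelativeAbundance(fractions=col / total, group=table.replicate_groups[sample])


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    out = table.data.fillna(0.0)
    out.to_csv(path, sep="\t")
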