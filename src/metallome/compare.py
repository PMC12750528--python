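"""Compare proteome-inferred metallomes with measured metal quotas.

Three views, mirroring how strain-level metal physiology is usually read
out: (i) log-log correlation between inferred metallome and ICP-MS quotas
across metals, (ii) between-strain ratios with delta-method error
propagation — a quota ratio far above 1 with a metallome ratio near 1 is
the luxury-uptake signature — and (iii) per-protein differential expression
(Student's t-test on median-normalized intensities).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .homology import ProteinMetalAnnotation
from .quant import QuantTable, normalize_median
from .reconstruct import MetallomeProfile

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class QuotaTable:
    """Measured metal quotas (mmol/mol C) for one strain.

    ``data`` maps metal -> (mean, sd, n replicates).
    """

    strain: str
    data: dict[str, tuple[float, float, int]]

    def __post_init__(self) -> None:
        for metal, (mean, sd, n) in self.data.items():
            if mean <= 0:
                raise ValueError(f"{self.strain}/{metal}: quota mean must be > 0")
            if sd < 0 or n < 1:
                raise ValueError(f"{self.strain}/{metal}: invalid sd/n")

    def metals(self) -> list[str]:
        return sorted(self.data)


@dataclass
class CorrelationResult:
    r_squared: float
    n_points: int
    pairs: pd.DataFrame  # metal, quota, abundance (and logs when applicable)
    excluded: list[str]  # metals present in only one input or non-positive


@dataclass
class RatioResult:
    """Per-metal numerator/denominator ratios with propagated SD."""

    numerator: str
    denominator: str
    ratios: dict[str, tuple[float, float]]
    skipped: list[str] = field(default_factory=list)


@dataclass
class DifferentialResult:
    protein_id: str
    log2_fold_change: float
    p_value: float
    significant: bool
    metals: list[str] = field(default_factory=list)
    p_adjusted: float = float("nan")


@dataclass
class RollupResult:
    metal: str
    ratio: float
    sd: float
    p_value: float
    n_a: int
    n_b: int


def read_quota_table(path: str | Path) -> dict[str, QuotaTable]:
    """Read a quota TSV (strain, metal, mean_mmol_per_molC, sd, n)."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "metal", "mean_mmol_per_molC", "sd", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"quota table {path} missing columns: {sorted(missing)}")
    out: dict[str, QuotaTable] = {}
    for strain, sub in df.groupby("strain", sort=True):
        data = {
            row.metal: (float(row.mean_mmol_per_molC), float(row.sd), int(row.n))
            for row in sub.itertuples(index=False)
        }
        out[str(strain)] = QuotaTable(strain=str(strain), data=data)
    return out


def write_quota_table(tables: dict[str, QuotaTable], path: str | Path) -> None:
    rows = [
        (t.strain, m, mean, sd, n)
        for t in tables.values() for m, (mean, sd, n) in sorted(t.data.items())
    ]
    pd.DataFrame(rows, columns=["strain", "metal", "mean_mmol_per_molC",
                                "sd", "n"]).to_csv(path, sep="\t", index=False)


def _mean_sd_n(source: MetallomeProfile | QuotaTable, metal: str):
    if isinstance(source, QuotaTable):
        return source.data[metal]
    return (source.abundance[metal], source.sd.get(metal, 0.0), source.n_replicates)


def _metal_support(source: MetallomeProfile | QuotaTable) -> set[str]:
    if isinstance(source, QuotaTable):
        return set(source.data)
    return {m for m, v in source.abundance.items()}


def correlate(
    quota: QuotaTable,
    profile: MetallomeProfile,
    metals: list[str] | None = None,
    log_space: bool = True,
) -> CorrelationResult:
    """Pearson r^2 between measured quotas and inferred abundances.

    Computed on (log10 quota, log10 abundance) by default — metal
    abundances span orders of magnitude, and the inferred metallome's unit
    is arbitrary, so only the log-log shape is meaningful (a global
    rescaling of the profile shifts the log values and leaves r^2 alone).
    Metals absent or non-positive in either input are excluded and listed.
    """
    candidates = sorted(metals) if metals is not None else sorted(
        _metal_support(quota) | _metal_support(profile))
    rows, excluded = [], []
    for metal in candidates:
        q = quota.data.get(metal, (0.0, 0.0, 0))[0]
        a = profile.abundance.get(metal, 0.0)
        if q > 0 and a > 0:
            rows.append((metal, q, a))
        else:
            excluded.append(metal)
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} usable metal pairs; need >= 3")
    pairs = pd.DataFrame(rows, columns=["metal", "quota", "abundance"])
    if log_space:
        x, y = np.log10(pairs["quota"]), np.log10(pairs["abundance"])
        pairs["log10_quota"], pairs["log10_abundance"] = x, y
    else:
        x, y = pairs["quota"], pairs["abundance"]
    r = stats.pearsonr(x, y).statistic
    return CorrelationResult(r_squared=float(r * r), n_points=len(rows),
                             pairs=pairs, excluded=excluded)


def strain_ratio(
    a: MetallomeProfile | QuotaTable,
    b: MetallomeProfile | QuotaTable,
) -> RatioResult:
    """Per-metal ratio b/a with first-order (delta method) SD.

    SD(b/a) = (b/a) * sqrt((sd_a/a)^2 + (sd_b/b)^2). Metals not positive
    in both inputs are skipped with a warning.
    """
    name_a = a.strain if isinstance(a, QuotaTable) else a.group
    name_b = b.strain if isinstance(b, QuotaTable) else b.group
    ratios: dict[str, tuple[float, float]] = {}
    skipped: list[str] = []
    for metal in sorted(_metal_support(a) | _metal_support(b)):
        in_a = metal in _metal_support(a) and _mean_sd_n(a, metal)[0] > 0
        in_b = metal in _metal_support(b) and _mean_sd_n(b, metal)[0] > 0
        if not (in_a and in_b):
            skipped.append(metal)
            logger.warning("metal %s not positive in both %s and %s; ratio skipped",
                           metal, name_a, name_b)
            continue
        mean_a, sd_a, _ = _mean_sd_n(a, metal)
        mean_b, sd_b, _ = _mean_sd_n(b, metal)
        ratio = mean_b / mean_a
        sd = ratio * math.sqrt((sd_a / mean_a) ** 2 + (sd_b / mean_b) ** 2)
        ratios[metal] = (ratio, sd)
    return RatioResult(numerator=name_b, denominator=name_a,
                       ratios=ratios, skipped=skipped)


def _ttest(x: np.ndarray, y: np.ndarray, equal_var: bool) -> float:
    # guard the zero-variance case: scipy returns NaN for 0/0
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.pvalue)


def differential_expression(
    table: QuantTable,
    group_a: str,
    group_b: str,
    alpha: float = DEFAULT_ALPHA,
    annotations: list[ProteinMetalAnnotation] | None = None,
    equal_var: bool = True,
    adjust: str | None = None,
) -> list[DifferentialResult]:
    """Per-protein log2 fold change (B vs A) and two-sided t-test p-value.

    Intensities are median-normalized first so samples are comparable.
    Student's pooled-variance t-test by default (``equal_var=False`` for
    Welch). Proteins with fewer than two detected replicates in either
    group are reported with an undefined p-value and are never significant.
    ``adjust="bh"`` adds Benjamini-Hochberg adjusted p-values and bases the
    significance call on them.
    """
    for group in (group_a, group_b):
        table.samples_of(group)  # raises if absent
    norm = normalize_median(table)
    cols_a, cols_b = norm.data[table.samples_of(group_a)], norm.data[table.samples_of(group_b)]
    metal_map = {
        a.protein_id: sorted(m for m, c in a.stoichiometry.items() if c > 0)
        for a in (annotations or [])
    }

    results: list[DifferentialResult] = []
    for pid in norm.data.index:
        xa = cols_a.loc[pid].dropna().to_numpy()
        xb = cols_b.loc[pid].dropna().to_numpy()
        if len(xa) >= 1 and len(xb) >= 1:
            log2fc = float(np.log2(np.mean(xb) / np.mean(xa)))
        else:
            log2fc = float("nan")
        if len(xa) >= 2 and len(xb) >= 2:
            p = _ttest(xa, xb, equal_var)
        else:
            p = float("nan")
        results.append(DifferentialResult(
            protein_id=str(pid), log2_fold_change=log2fc, p_value=p,
            significant=bool(p < alpha) if not math.isnan(p) else False,
            metals=metal_map.get(str(pid), []),
        ))

    if adjust == "bh":
        defined = [r for r in results if not math.isnan(r.p_value)]
        if defined:
            _, adj, _, _ = multipletests([r.p_value for r in defined], method="fdr_bh")
            for r, q in zip(defined, adj):
                r.p_adjusted = float(q)
                r.significant = bool(q < alpha)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


def differential_table(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "protein_id": [r.protein_id for r in results],
        "log2fc": [r.log2_fold_change for r in results],
        "p": [r.p_value for r in results],
        "significant": [r.significant for r in results],
        "metals": [";".join(r.metals) for r in results],
    })


def metal_rollup_test(
    profile_a: MetallomeProfile,
    profile_b: MetallomeProfile,
    metal: str,
    equal_var: bool = True,
) -> RollupResult:
    """Group test on per-replicate total abundance of one metal.

    Answers questions like "is total Co different between strains" directly
    on the per-replicate reconstructed metallomes; p is undefined (NaN)
    when a group has fewer than two replicates, but the ratio is still
    reported.
    """
    for prof in (profile_a, profile_b):
        if prof.replicate_profiles is None:
            raise ValueError(f"profile {prof.group!r} lacks per-replicate data")
    xa = np.array([p.get(metal, 0.0) for p in profile_a.replicate_profiles])
    xb = np.array([p.get(metal, 0.0) for p in profile_b.replicate_profiles])
    if xa.mean() <= 0:
        raise ValueError(f"metal {metal} has non-positive mean in {profile_a.group}")
    ratio = float(xb.mean() / xa.mean())
    if len(xa) >= 2 and len(xb) >= 2:
        p = _ttest(xa, xb, equal_var)
        sd = ratio * math.sqrt(
            (xa.std(ddof=1) / xa.mean()) ** 2 + (xb.std(ddof=1) / xb.mean()) ** 2)
    else:
        p, sd = float("nan"), float("nan")
    return RollupResult(metal=metal, ratio=ratio, sd=sd, p_value=p,
                        n_a=len(xa), n_b=len(xb))
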