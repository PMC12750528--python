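"""Reconstruct the relative metallome from abundances and annotations.

The abundance of a metal in the expressed proteome is the sum over proteins
of relative protein abundance times the number of ions of that metal the
protein binds. The result is in arbitrary units: proteome intensities are
relative, so metallomes are comparable across metals within a species but
not across species in absolute terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .homology import ProteinMetalAnnotation
from .quant import QuantTable, RelativeAbundance, relative_abundance_per_sample

logger = logging.getLogger(__name__)


@dataclass
class MetallomeProfile:
    """Per-metal relative abundance (arbitrary units) for one group.

    ``sd`` holds the sample standard deviation (ddof=1) over per-replicate
    profiles where replicates exist; ``replicate_profiles`` keeps the
    per-replicate values for downstream group tests.
    """

    group: str
    abundance: dict[str, float]
    sd: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 1
    replicate_profiles: list[dict[str, float]] | None = None
    provenance: str = ""

    def metals(self) -> list[str]:
        return sorted(self.abundance)

    def scaled(self, factor: float) -> "MetallomeProfile":
        """Rescale (arbitrary units): abundances and SDs multiply."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return MetallomeProfile(
            group=self.group,
            abundance={m: v * factor for m, v in self.abundance.items()},
            sd={m: v * factor for m, v in self.sd.items()},
            n_replicates=self.n_replicates,
            replicate_profiles=None if self.replicate_profiles is None else [
                {m: v * factor for m, v in p.items()} for p in self.replicate_profiles
            ],
            provenance=self.provenance,
        )


@dataclass
class CountSummary:
    """Metalloprotein counts and percentages of the identified proteome."""

    total_proteins: int
    total_metalloproteins: int
    per_metal_counts: dict[str, int]
    percentages: dict[str, float]
    metalloproteome_percent: float


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 36.25 -> 36.3, not banker's 36.2)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _percent(count: int, total: int) -> float:
    exact = Decimal(100 * count) / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def compute_metallome(
    rel: RelativeAbundance, annotations: list[ProteinMetalAnnotation]
) -> MetallomeProfile:
    """abundance(m) = sum_i rel(i) * stoichiometry(i, m)."""
    totals: dict[str, float] = {}
    for ann in annotations:
        if ann.protein_id not in rel.fractions.index:
            logger.warning("annotated protein %s absent from quant table, skipped",
                           ann.protein_id)
            continue
        weight = float(rel.fractions[ann.protein_id])
        for metal, count in ann.stoichiometry.items():
            if count > 0:
                totals[metal] = totals.get(metal, 0.0) + weight * count
    return MetallomeProfile(group=rel.group, abundance=totals,
                            sd={m: 0.0 for m in totals}, n_replicates=1)


def metallome_from_quant(
    table: QuantTable, annotations: list[ProteinMetalAnnotation], group: str
) -> MetallomeProfile:
    """Per-replicate metallome profiles for a group, with mean and SD.

    Each replicate's intensities are normalized to that sample's total,
    weighted by stoichiometry, then averaged across replicates; SD is the
    sample standard deviation (ddof=1) over replicates.
    """
    samples = table.samples_of(group)
    per_rep = [
        compute_metallome(relative_abundance_per_sample(table, s), annotations).abundance
        for s in samples
    ]
    metals = sorted({m for p in per_rep for m in p})
    mean = {m: float(np.mean([p.get(m, 0.0) for p in per_rep])) for m in metals}
    if len(per_rep) > 1:
        sd = {m: float(np.std([p.get(m, 0.0) for p in per_rep], ddof=1)) for m in metals}
    else:
        sd = {m: 0.0 for m in metals}
    return MetallomeProfile(group=group, abundance=mean, sd=sd,
                            n_replicates=len(per_rep), replicate_profiles=per_rep)


def summarize_counts(
    annotations: list[ProteinMetalAnnotation], total_proteins: int
) -> CountSummary:
    """Counts and half-up one-decimal percentages of the total proteome.

    A protein binding k metals contributes to k per-metal rows but once to
    the metalloprotein total. Unannotated proteins stay in the denominator.
    """
    if total_proteins <= 0:
        raise ValueError("total_proteins must be positive")
    if total_proteins < len(annotations):
        raise ValueError(
            f"total_proteins={total_proteins} < {len(annotations)} annotations")
    metallo = [a for a in annotations if a.is_metalloprotein]
    per_metal: dict[str, int] = {}
    for ann in metallo:
        for metal, count in ann.stoichiometry.items():
            if count > 0:
                per_metal[metal] = per_metal.get(metal, 0) + 1
    return CountSummary(
        total_proteins=total_proteins,
        total_metalloproteins=len(metallo),
        per_metal_counts=per_metal,
        percentages={m: _percent(c, total_proteins) for m, c in per_metal.items()},
        metalloproteome_percent=_percent(len(metallo), total_proteins),
    )


def association_fractions(annotations: list[ProteinMetalAnnotation]) -> dict[str, float]:
    """Percentage of all (protein, metal) associations held by each metal.

    This is the pie-chart view: the denominator is the number of
    protein-metal pairs with positive stoichiometry, so a two-metal protein
    contributes two associations.
    """
    pairs: dict[str, int] = {}
    for ann in annotations:
        for metal, count in ann.stoichiometry.items():
            if count > 0:
                pairs[metal] = pairs.get(metal, 0) + 1
    total = sum(pairs.values())
    if total == 0:
        raise ValueError("no protein-metal associations")
    return {m: 100.0 * c / total for m, c in pairs.items()}


def distinct_metals(annotations: list[ProteinMetalAnnotation]) -> int:
    """Number of metals with at least one protein association."""
    return len({m for a in annotations for m, c in a.stoichiometry.items() if c > 0})


def write_profile(profile: MetallomeProfile,
                  annotations: list[ProteinMetalAnnotation],
                  path: str | Path) -> None:
    """Write a metallome profile TSV: metal, abundance, sd, n_proteins."""
    n_prot = {
        m: sum(1 for a in annotations if a.stoichiometry.get(m, 0) > 0)
        for m in profile.abundance
    }
    df = pd.DataFrame({
        "metal": profile.metals(),
        "abundance": [profile.abundance[m] for m in profile.metals()],
        "sd": [profile.sd.get(m, 0.0) for m in profile.metals()],
        "n_proteins": [n_prot.get(m, 0) for m in profile.metals()],
    })
    df.to_csv(path, sep="\t", index=False)


def write_summary(summary: CountSummary, path: str | Path) -> None:
    rows = [("Total proteins", summary.total_proteins, 100.0),
            ("Total metalloproteins", summary.total_metalloproteins,
             summary.metalloproteome_percent)]
    for metal in sorted(summary.per_metal_counts):
        rows.append((f"{metal}-containing proteins",
                     summary.per_metal_counts[metal], summary.percentages[metal]))
    pd.DataFrame(rows, columns=["category", "count", "percent"]).to_csv(
        path, sep="\t", index=False)
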