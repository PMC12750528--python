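"""Confidence filtering of fold-recognition matches and annotation transfer.

Fold recognition itself happens upstream (e.g. a PHYRE2-style server); this
module consumes its match table, keeps matches above the confidence
threshold (strictly above: a match at exactly the threshold is rejected),
and copies the chosen template chain's metal stoichiometry onto the query
protein.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .structures import TemplateStoichiometry

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_THRESHOLD = 95.0


@dataclass(frozen=True)
class HomologyMatch:
    query_id: str
    template_id: str
    chain_id: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 100.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 100]")


@dataclass
class ProteinMetalAnnotation:
    """Metal stoichiometry transferred onto an expressed protein.

    ``stoichiometry`` is empty for proteins whose template binds no metal;
    ``provenance`` records (template_id, chain_id, confidence).
    """

    protein_id: str
    stoichiometry: dict[str, int] = field(default_factory=dict)
    provenance: tuple[str, str, float] | None = None

    @property
    def is_metalloprotein(self) -> bool:
        return any(count > 0 for count in self.stoichiometry.values())


def read_match_table(path: str | Path) -> list[HomologyMatch]:
    """Read a TSV with columns query_id, template_id, chain_id, confidence."""
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "template_id": str,
                                            "chain_id": str})
    required = {"query_id", "template_id", "chain_id", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"match table {path} missing columns: {sorted(missing)}")
    return [
        HomologyMatch(row.query_id, row.template_id, row.chain_id, float(row.confidence))
        for row in df.itertuples(index=False)
    ]


def filter_matches(
    matches: list[HomologyMatch], threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
) -> list[HomologyMatch]:
    """Keep matches with confidence strictly greater than ``threshold``."""
    if not 0.0 < threshold <= 100.0:
        raise ValueError(f"threshold {threshold} outside (0, 100]")
    return [m for m in matches if m.confidence > threshold]


def transfer_annotations(
    matches: list[HomologyMatch],
    templates: dict[str, dict[str, TemplateStoichiometry]],
    policy: str = "best",
) -> list[ProteinMetalAnnotation]:
    """Transfer template stoichiometries to query proteins.

    Policy ``"best"`` uses the single highest-confidence match per query
    (ties broken by template id, then chain id); ``"union-max"`` instead
    takes, per metal, the maximum count over all passing matches — provided
    for sensitivity analysis, since a union can double-count homologous
    sites. Queries whose template is absent from the store are logged and
    left unannotated. Output is sorted by protein id and independent of
    input match order.
    """
    if policy not in ("best", "union-max"):
        raise ValueError(f"unknown policy {policy!r}")

    by_query: dict[str, list[HomologyMatch]] = {}
    for m in matches:
        by_query.setdefault(m.query_id, []).append(m)

    annotations: list[ProteinMetalAnnotation] = []
    for query_id in sorted(by_query):
        resolvable = []
        for m in by_query[query_id]:
            ts = templates.get(m.template_id, {}).get(m.chain_id)
            if ts is None:
                logger.warning("template %s/%s for query %s absent from store",
                               m.template_id, m.chain_id, query_id)
            else:
                resolvable.append((m, ts))
        if not resolvable:
            continue
        # deterministic best: highest confidence, then smallest template/chain id
        resolvable.sort(key=lambda pair: (-pair[0].confidence,
                                          pair[0].template_id, pair[0].chain_id))
        best_match, best_ts = resolvable[0]
        if policy == "best":
            stoich = {m: c for m, c in best_ts.stoichiometry.items() if c > 0}
        else:
            stoich = {}
            for _, ts in resolvable:
                for metal, count in ts.stoichiometry.items():
                    if count > 0:
                        stoich[metal] = max(stoich.get(metal, 0), count)
        annotations.append(ProteinMetalAnnotation(
            protein_id=query_id,
            stoichiometry=stoich,
            provenance=(best_match.template_id, best_match.chain_id,
                        best_match.confidence),
        ))
    return annotations


def annotate_proteome(
    matches: list[HomologyMatch],
    templates: dict[str, dict[str, TemplateStoichiometry]],
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    policy: str = "best",
) -> list[ProteinMetalAnnotation]:
    """filter_matches then transfer_annotations, in one call."""
    return transfer_annotations(filter_matches(matches, threshold), templates, policy)


def write_annotations(annotations: list[ProteinMetalAnnotation], path: str | Path) -> None:
    payload = {
        a.protein_id: {
            "stoichiometry": a.stoichiometry,
            "provenance": list(a.provenance) if a.provenance else None,
        }
        for a in annotations
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_annotations(path: str | Path) -> list[ProteinMetalAnnotation]:
    payload = json.loads(Path(path).read_text())
    out = []
    for pid in sorted(payload):
        entry = payload[pid]
        prov = entry.get("provenance")
        out.append(ProteinMetalAnnotation(
            protein_id=pid,
            stoichiometry={m: int(c) for m, c in entry["stoichiometry"].items()},
            provenance=tuple(prov) if prov else None,
        ))
    return out
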