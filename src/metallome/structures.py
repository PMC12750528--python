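"""Structure parsing and metal coordination-sphere analysis.

Template structures (PDB or mmCIF) are reduced to flat atom records, metal
ions are located, and their first coordination sphere (N/O/S atoms within a
distance cutoff) is resolved into a per-chain metal stoichiometry. Sites
with no polymer donor are flagged adventitious — crystallization-buffer ions
must not inflate the stoichiometry transferred to expressed proteins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .config import AnnotationConfig

logger = logging.getLogger(__name__)


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a template structure."""

    element: str
    position: tuple[float, float, float]
    chain_id: str
    residue_name: str
    residue_seq: int
    insertion_code: str
    is_polymer: bool
    is_water: bool
    occupancy: float
    altloc: str
    name: str = ""

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.residue_name, self.residue_seq, self.insertion_code)


@dataclass
class MetalSite:
    """A metal ion with its first-sphere donors.

    ``donors`` is sorted by distance ascending; ``adventitious`` is true iff
    no polymer donor lies within the cutoff. ``attributed_chain`` is the
    chain contributing the majority of polymer donors (lexicographically
    smallest chain on a tie, ``None`` for adventitious sites).
    """

    metal: str
    position: tuple[float, float, float]
    donors: list[tuple[AtomRecord, float]] = field(default_factory=list)
    attributed_chain: str | None = None
    adventitious: bool = True


@dataclass
class TemplateStoichiometry:
    """Metal ion counts attributed to one chain of one template."""

    template_id: str
    chain_id: str
    stoichiometry: dict[str, int] = field(default_factory=dict)


_FORMATS = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}


def parse_structure(path: str | Path, dialect: str = "pdb") -> list[AtomRecord]:
    """Read a coordinate file into flat atom records.

    Alternative locations are collapsed to the highest-occupancy conformer
    (tie broken by altloc letter, so 'A' wins). Atoms whose element cannot
    be resolved are skipped with a warning. Waters are flagged non-polymer.
    """
    path = Path(path)
    if dialect not in _FORMATS:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'pdb' or 'mmcif'")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(str(path), format=_FORMATS[dialect])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {dialect}: {exc}") from exc
    structure.setup_entities()

    records: list[AtomRecord] = []
    if len(structure) == 0:
        return records
    model = structure[0]
    for chain in model:
        for residue in chain:
            is_water = residue.is_water()
            is_polymer = residue.het_flag == "A"
            # collapse altlocs per atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name, atoms in by_name.items():
                atom = min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))
                symbol = atom.element.name
                if symbol in ("X", "") or atom.element.atomic_number == 0:
                    logger.warning(
                        "%s: unknown element for atom %s/%s %s, skipped",
                        path.name, chain.name, residue.name, name,
                    )
                    continue
                records.append(AtomRecord(
                    element=symbol,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    chain_id=chain.name,
                    residue_name=residue.name,
                    residue_seq=residue.seqid.num,
                    insertion_code=(residue.seqid.icode or "").strip(),
                    is_polymer=is_polymer and not is_water,
                    is_water=is_water,
                    occupancy=atom.occ,
                    altloc=atom.altloc or "",
                    name=name,
                ))
    return records


def detect_metal_sites(
    atoms: list[AtomRecord], config: AnnotationConfig | None = None
) -> list[MetalSite]:
    """Locate metal ions and resolve their first coordination sphere.

    Donors are atoms of the configured donor elements within ``config.cutoff``
    of the metal, excluding the metal itself, other metal-set atoms, and
    (by default) waters.
    """
    config = config or AnnotationConfig()
    metals = [a for a in atoms if a.element in config.metals]
    if not metals:
        return []

    positions = np.array([m.position for m in metals])
    if len(metals) > 1:
        dists = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() < 1e-9:
            i, j = np.unravel_index(int(dists.argmin()), dists.shape)
            raise ValueError(
                f"degenerate structure: metal atoms {metals[i].element} and "
                f"{metals[j].element} at identical coordinates {metals[i].position}"
            )

    donors_pool = [
        a for a in atoms
        if a.element in config.donors
        and a.element not in config.metals
        and (config.include_waters or not a.is_water)
    ]

    sites: list[MetalSite] = []
    if donors_pool:
        tree = cKDTree(np.array([d.position for d in donors_pool]))
        neighbour_lists = tree.query_ball_point(positions, r=config.cutoff)
    else:
        neighbour_lists = [[] for _ in metals]

    for metal_atom, neighbours in zip(metals, neighbour_lists):
        pos = np.asarray(metal_atom.position)
        donors = []
        for idx in neighbours:
            donor = donors_pool[idx]
            dist = float(np.linalg.norm(pos - np.asarray(donor.position)))
            if dist > 0:
                donors.append((donor, dist))
        donors.sort(key=lambda pair: (pair[1], pair[0].chain_id, pair[0].residue_seq))
        polymer_chains = [d.chain_id for d, _ in donors if d.is_polymer]
        if polymer_chains:
            counts: dict[str, int] = {}
            for cid in polymer_chains:
                counts[cid] = counts.get(cid, 0) + 1
            best = max(counts.values())
            attributed = min(c for c, n in counts.items() if n == best)
            adventitious = False
        else:
            attributed = None
            adventitious = True
        sites.append(MetalSite(
            metal=metal_atom.element,
            position=metal_atom.position,
            donors=donors,
            attributed_chain=attributed,
            adventitious=adventitious,
        ))
    return sites


def stoichiometry_from_sites(
    sites: list[MetalSite],
    chain_id: str,
    template_id: str = "",
    config: AnnotationConfig | None = None,
) -> TemplateStoichiometry:
    """Count non-adventitious ions attributed to ``chain_id``, per metal.

    With ``config.per_assembly`` every non-adventitious site counts
    regardless of chain; with ``config.exclude_adventitious`` false,
    buffer-ion sites are counted too (attributed to no chain, so only
    visible in assembly mode).
    """
    config = config or AnnotationConfig()
    counts: dict[str, int] = {}
    for site in sites:
        if site.adventitious and config.exclude_adventitious:
            continue
        if not config.per_assembly and site.attributed_chain != chain_id:
            continue
        counts[site.metal] = counts.get(site.metal, 0) + 1
    return TemplateStoichiometry(template_id=template_id, chain_id=chain_id,
                                 stoichiometry=counts)


def annotate_structure(
    path: str | Path,
    dialect: str = "pdb",
    config: AnnotationConfig | None = None,
    template_id: str | None = None,
) -> dict[str, TemplateStoichiometry]:
    """Parse one template and return per-chain stoichiometries."""
    config = config or AnnotationConfig()
    template_id = template_id or Path(path).stem
    atoms = parse_structure(path, dialect=dialect)
    sites = detect_metal_sites(atoms, config)
    chains = sorted({a.chain_id for a in atoms if a.is_polymer})
    return {
        cid: stoichiometry_from_sites(sites, cid, template_id=template_id, config=config)
        for cid in chains
    }


def write_annotation_store(
    store: dict[str, dict[str, TemplateStoichiometry]], path: str | Path
) -> None:
    """Serialise ``{template: {chain: stoichiometry}}`` as JSON."""
    payload = {
        template: {chain: ts.stoichiometry for chain, ts in chains.items()}
        for template, chains in store.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_annotation_store(path: str | Path) -> dict[str, dict[str, TemplateStoichiometry]]:
    payload = json.loads(Path(path).read_text())
    return {
        template: {
            chain: TemplateStoichiometry(template, chain, {m: int(c) for m, c in sto.items()})
            for chain, sto in chains.items()
        }
        for template, chains in payload.items()
    }
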