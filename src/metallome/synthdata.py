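"""Coupled synthetic data with known ground truth.

Emulates the full experimental stack end to end: template structures with
planted metal sites (donors at 2.0-2.6 A, adventitious buffer ions beyond
the cutoff), a fold-recognition match table whose confidences straddle the
95% threshold, replicate intensity matrices with log-normal noise, and
ICP-MS-style quota tables decomposed as

    quota(m) = scale * (bound(m) + free(m)) * luxury(m) * (1 + eps)

where ``bound`` is the protein-bound metallome implied by the planted
annotations, ``free`` models cytosolic ion pools invisible to the proteome
(Ca/Mg/K), and ``luxury`` models uptake beyond requirement (e.g. Fe in a
Southern-Ocean-adapted strain). All randomness flows from one seed; every
generator records the parameters it used in a manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import QuotaTable
from .homology import HomologyMatch
from .quant import QuantTable
from .structures import TemplateStoichiometry

DEFAULT_METAL_MENU = ("Mg", "Ca", "K", "Fe", "Zn", "Mn", "Cu", "Ni", "Co", "Mo")

#: Cytosolic free-ion pools as multiples of the protein-bound abundance.
DEFAULT_FREE_POOL = {"Ca": 10.0, "Mg": 5.0, "K": 10.0}

#: Per-group luxury-uptake multipliers (second group gets the Fe excess).
def _default_luxury(groups: tuple[str, ...]) -> dict[str, dict[str, float]]:
    luxury = {g: {"Mo": 3.0} for g in groups}
    if len(groups) > 1:
        luxury[groups[1]] = {"Mo": 3.0, "Fe": 2.0}
    return luxury


# --------------------------------------------------------------------------
# structures

_TETRAHEDRON = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)],
                        dtype=float) / np.sqrt(3.0)
_DONOR_CHOICES = (("SG", "S", "CYS"), ("ND1", "N", "HIS"), ("OD1", "O", "ASP"))


def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resseq: int, pos: np.ndarray, element: str, occ: float = 1.0) -> str:
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {name_field} {resname:>3s} {chain}"
            f"{resseq:>4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element.upper():>2s}")


@dataclass
class StructureBundle:
    paths: list[Path]
    stoichiometries: dict[str, dict[str, TemplateStoichiometry]]
    manifest: dict


def generate_structures(
    n_templates: int,
    metal_menu: tuple[str, ...] = DEFAULT_METAL_MENU,
    seed: int = 0,
    outdir: str | Path = ".",
    fmt: str = "pdb",
    frac_apo: float = 0.2,
    decoy_rate: float = 0.5,
    max_sites_per_chain: int = 3,
) -> StructureBundle:
    """Write minimal coordinate files with planted metal sites.

    Each planted site carries four polymer donors at 2.0-2.6 A; a fraction
    of templates are apo (no metal); decoy Na ions are placed with no
    polymer atom within reach, so they must be recovered as adventitious.
    Byte-identical output for identical arguments.
    """
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    paths: list[Path] = []
    truth: dict[str, dict[str, TemplateStoichiometry]] = {}
    for t in range(n_templates):
        template_id = f"T{t + 1:04d}"
        chains = ["A"] if rng.random() < 0.7 else ["A", "B"]
        apo = rng.random() < frac_apo
        lines: list[str] = []
        serial = 1
        resseq = 1
        truth[template_id] = {}
        for ci, chain in enumerate(chains):
            planted: dict[str, int] = {}
            n_sites = 0 if apo else int(rng.integers(1, max_sites_per_chain + 1))
            for k in range(n_sites):
                metal = str(rng.choice(metal_menu))
                center = np.array([14.0 * k, 14.0 * ci, 0.0])
                for direction in _TETRAHEDRON:
                    name, elem, res = _DONOR_CHOICES[int(rng.integers(3))]
                    dist = rng.uniform(2.0, 2.6)
                    lines.append(_pdb_line("ATOM", serial, name, res, chain,
                                           resseq, center + dist * direction, elem))
                    serial += 1
                    resseq += 1
                lines.append(_pdb_line("HETATM", serial, metal.upper(),
                                       metal.upper(), chain, 900 + k, center, metal))
                serial += 1
                planted[metal] = planted.get(metal, 0) + 1
            # inert backbone carbons so apo chains still exist as polymers
            for _ in range(2):
                pos = np.array([-8.0, 14.0 * ci, rng.uniform(-2, 2)])
                lines.append(_pdb_line("ATOM", serial, "CA", "ALA", chain,
                                       resseq, pos, "C"))
                serial += 1
                resseq += 1
            truth[template_id][chain] = TemplateStoichiometry(
                template_id=template_id, chain_id=chain, stoichiometry=planted)
        if rng.random() < decoy_rate:
            # buffer ion far from any polymer atom, with one water contact
            pos = np.array([-40.0, -40.0, -40.0])
            lines.append(_pdb_line("HETATM", serial, "NA", "NA", "S", 1, pos, "Na"))
            serial += 1
            lines.append(_pdb_line("HETATM", serial, "O", "HOH", "S", 2,
                                   pos + np.array([2.4, 0, 0]), "O"))
            serial += 1
        lines.append("END")
        path = outdir / f"{template_id}.pdb"
        path.write_text("\n".join(lines) + "\n")
        if fmt == "mmcif":
            import gemmi
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
            st.setup_entities()
            cif_path = outdir / f"{template_id}.cif"
            st.make_mmcif_document().write_file(str(cif_path))
            path.unlink()
            path = cif_path
        elif fmt != "pdb":
            raise ValueError(f"unknown fmt {fmt!r}")
        paths.append(path)

    manifest = {"op": "generate_structures", "n_templates": n_templates,
                "metal_menu": list(metal_menu), "seed": seed, "fmt": fmt,
                "frac_apo": frac_apo, "decoy_rate": decoy_rate,
                "max_sites_per_chain": max_sites_per_chain}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return StructureBundle(paths=paths, stoichiometries=truth, manifest=manifest)


# --------------------------------------------------------------------------
# proteome / ground truth

@dataclass
class GroundTruth:
    """Everything the generator planted, for closing the loop in tests."""

    seed: int
    protein_ids: list[str]
    annotations: dict[str, dict[str, int]]  # protein -> metal -> ions (empty = apo)
    matches: list[HomologyMatch]
    templates: dict[str, dict[str, TemplateStoichiometry]]
    base_abundance: dict[str, float]
    groups: tuple[str, ...] = ("OA1", "OA16")
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    free_pool: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FREE_POOL))
    luxury: dict[str, dict[str, float]] = field(default_factory=dict)
    sigma_log: float = 0.1
    quota_rel_sd: float = 0.1
    manifest: dict = field(default_factory=dict)

    def true_relative_abundance(self, group: str) -> pd.Series:
        effects = self.group_effects.get(group, {})
        raw = pd.Series({p: self.base_abundance[p] * effects.get(p, 1.0)
                         for p in self.protein_ids})
        return raw / raw.sum()

    def true_metallome(self, group: str) -> dict[str, float]:
        """Protein-bound metal abundance implied by the planted annotations."""
        rel = self.true_relative_abundance(group)
        out: dict[str, float] = {}
        for pid, stoich in self.annotations.items():
            for metal, count in stoich.items():
                out[metal] = out.get(metal, 0.0) + float(rel[pid]) * count
        return {m: v for m, v in out.items() if v > 0}

    def expected_quota(self, group: str, scale: float = 100.0) -> dict[str, float]:
        bound = self.true_metallome(group)
        luxury = self.luxury.get(group, {})
        return {
            m: scale * (b + self.free_pool.get(m, 0.0) * b) * luxury.get(m, 1.0)
            for m, b in bound.items()
        }

    def n_metalloproteins(self) -> int:
        return sum(1 for s in self.annotations.values() if s)


def _synthesize_templates(
    rng: np.random.Generator, metal_menu: tuple[str, ...], n_holo: int, n_apo: int
) -> dict[str, dict[str, TemplateStoichiometry]]:
    """In-memory template store: every menu metal present in >= 1 template."""
    templates: dict[str, dict[str, TemplateStoichiometry]] = {}
    for t in range(n_holo):
        template_id = f"T{t + 1:04d}"
        if t < len(metal_menu):  # guarantee coverage of the menu
            metals = [metal_menu[t]]
        else:
            k = int(rng.integers(1, 3))
            metals = list(rng.choice(metal_menu, size=k, replace=False))
        stoich = {str(m): int(rng.integers(1, 4)) for m in metals}
        templates[template_id] = {"A": TemplateStoichiometry(template_id, "A", stoich)}
    for t in range(n_apo):
        template_id = f"APO{t + 1:03d}"
        templates[template_id] = {"A": TemplateStoichiometry(template_id, "A", {})}
    return templates


def generate_proteome(
    n_proteins: int,
    frac_metalloproteins: float = 0.37,
    seed: int = 0,
    templates: dict[str, dict[str, TemplateStoichiometry]] | None = None,
    metal_menu: tuple[str, ...] = DEFAULT_METAL_MENU,
    groups: tuple[str, ...] = ("OA1", "OA16"),
    group_effects: dict[str, dict[str, float]] | None = None,
    free_pool: dict[str, float] | None = None,
    luxury: dict[str, dict[str, float]] | None = None,
    sigma_log: float = 0.1,
    quota_rel_sd: float = 0.1,
    decoy_fraction: float = 0.3,
    boundary_fraction: float = 0.1,
    base_sigma: float = 1.2,
) -> GroundTruth:
    """Plant a proteome and its fold-recognition match table.

    The metalloprotein fraction defaults to the ~37% seen in eukaryotic
    phytoplankton proteomes. Every metalloprotein receives one passing
    match (confidence in (95, 100]); non-metalloproteins receive either no
    match, a sub-threshold decoy, a match at exactly 95.0 (the boundary the
    strict filter must reject), or a passing match to an apo template.
    Base protein abundances are log-normal (sigma ``base_sigma`` in ln
    units), spanning the orders of magnitude typical of label-free data.
    """
    if not 0.0 <= frac_metalloproteins <= 1.0:
        raise ValueError("frac_metalloproteins must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if templates is None:
        templates = _synthesize_templates(
            rng, metal_menu, n_holo=max(len(metal_menu), 20), n_apo=5)

    holo_keys = [(t, c) for t, chains in templates.items()
                 for c, ts in chains.items()
                 if any(v > 0 for v in ts.stoichiometry.values())]
    apo_keys = [(t, c) for t, chains in templates.items()
                for c, ts in chains.items()
                if not any(v > 0 for v in ts.stoichiometry.values())]
    if not holo_keys and frac_metalloproteins > 0:
        raise ValueError("no metal-bearing template available")

    protein_ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
    n_metallo = int(round(n_proteins * frac_metalloproteins))
    metallo = set(rng.choice(protein_ids, size=n_metallo, replace=False))

    annotations: dict[str, dict[str, int]] = {}
    matches: list[HomologyMatch] = []
    for pid in protein_ids:
        if pid in metallo:
            t, c = holo_keys[int(rng.integers(len(holo_keys)))]
            conf = float(rng.uniform(95.5, 99.9))
            matches.append(HomologyMatch(pid, t, c, round(conf, 1)))
            annotations[pid] = {m: n for m, n in
                                templates[t][c].stoichiometry.items() if n > 0}
            if rng.random() < decoy_fraction:  # extra sub-threshold decoy
                td, cd = holo_keys[int(rng.integers(len(holo_keys)))]
                matches.append(HomologyMatch(pid, td, cd,
                                             round(float(rng.uniform(60, 94.9)), 1)))
        else:
            annotations[pid] = {}
            u = rng.random()
            if u < decoy_fraction:
                t, c = holo_keys[int(rng.integers(len(holo_keys)))]
                matches.append(HomologyMatch(pid, t, c,
                                             round(float(rng.uniform(60, 94.9)), 1)))
            elif u < decoy_fraction + boundary_fraction:
                t, c = holo_keys[int(rng.integers(len(holo_keys)))]
                matches.append(HomologyMatch(pid, t, c, 95.0))
            elif apo_keys and u < decoy_fraction + 2 * boundary_fraction:
                t, c = apo_keys[int(rng.integers(len(apo_keys)))]
                matches.append(HomologyMatch(pid, t, c,
                                             round(float(rng.uniform(95.5, 99.9)), 1)))
            # else: no match at all

    base = {pid: float(np.exp(rng.normal(0.0, base_sigma))) for pid in protein_ids}
    truth = GroundTruth(
        seed=seed,
        protein_ids=protein_ids,
        annotations=annotations,
        matches=matches,
        templates=templates,
        base_abundance=base,
        groups=tuple(groups),
        group_effects=dict(group_effects or {}),
        free_pool=dict(DEFAULT_FREE_POOL if free_pool is None else free_pool),
        luxury=dict(_default_luxury(tuple(groups)) if luxury is None else luxury),
        sigma_log=sigma_log,
        quota_rel_sd=quota_rel_sd,
    )
    truth.manifest["generate_proteome"] = {
        "n_proteins": n_proteins, "frac_metalloproteins": frac_metalloproteins,
        "seed": seed, "metal_menu": list(metal_menu), "groups": list(groups),
        "sigma_log": sigma_log, "quota_rel_sd": quota_rel_sd,
        "decoy_fraction": decoy_fraction, "boundary_fraction": boundary_fraction,
        "base_sigma": base_sigma,
    }
    return truth


def write_match_table(matches: list[HomologyMatch], path: str | Path) -> None:
    pd.DataFrame(
        [(m.query_id, m.template_id, m.chain_id, m.confidence) for m in matches],
        columns=["query_id", "template_id", "chain_id", "confidence"],
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# quantities

def generate_quant(
    truth: GroundTruth,
    n_replicates_per_group: int = 3,
    sigma_log: float | None = None,
    group_effects: dict[str, dict[str, float]] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    intensity_scale: float = 1e6,
) -> QuantTable:
    """Replicate intensity matrix: base x group effect x lognormal noise.

    ``intensity = scale * base_i * effect_g(i) * exp(N(0, sigma_log^2))``,
    with missing values injected completely at random at ``missing_rate``
    (the first protein of each sample is never masked, so every sample
    keeps at least one detection).
    """
    rng = np.random.default_rng(seed)
    sigma = truth.sigma_log if sigma_log is None else sigma_log
    effects = truth.group_effects if group_effects is None else group_effects
    columns: dict[str, np.ndarray] = {}
    sample_groups: dict[str, str] = {}
    base = np.array([truth.base_abundance[p] for p in truth.protein_ids])
    for group in truth.groups:
        eff = effects.get(group, {})
        eff_vec = np.array([eff.get(p, 1.0) for p in truth.protein_ids])
        for r in range(n_replicates_per_group):
            sample = f"{group}_{r + 1}"
            noise = np.exp(rng.normal(0.0, sigma, size=len(base))) if sigma > 0 \
                else np.ones(len(base))
            values = intensity_scale * base * eff_vec * noise
            if missing_rate > 0:
                mask = rng.random(len(values)) < missing_rate
                mask[0] = False
                values = np.where(mask, np.nan, values)
            columns[sample] = values
            sample_groups[sample] = group
    data = pd.DataFrame(columns, index=pd.Index(truth.protein_ids, name="protein_id"))
    truth.manifest["generate_quant"] = {
        "n_replicates_per_group": n_replicates_per_group, "sigma_log": sigma,
        "missing_rate": missing_rate, "seed": seed,
        "intensity_scale": intensity_scale,
    }
    return QuantTable(data, replicate_groups=sample_groups)


def generate_quotas(
    truth: GroundTruth,
    seed: int = 0,
    n_replicates: int = 3,
    scale: float = 100.0,
    rel_sd: float | None = None,
) -> dict[str, QuotaTable]:
    """ICP-MS-style quota tables per group.

    quota = scale * (bound + free) * luxury * (1 + eps), eps ~ N(0, rel_sd^2)
    truncated above -1; mean and sample SD are reported over ``n_replicates``
    draws. ``scale`` converts arbitrary proteome units to mmol/mol C range.
    """
    rng = np.random.default_rng(seed)
    rsd = truth.quota_rel_sd if rel_sd is None else rel_sd
    out: dict[str, QuotaTable] = {}
    for group in truth.groups:
        expected = truth.expected_quota(group, scale=scale)
        data: dict[str, tuple[float, float, int]] = {}
        for metal in sorted(expected):
            mu = expected[metal]
            if rsd > 0:
                eps = np.clip(rng.normal(0.0, rsd, size=n_replicates), -0.99, None)
                draws = mu * (1.0 + eps)
                mean = float(draws.mean())
                sd = float(draws.std(ddof=1)) if n_replicates > 1 else 0.0
            else:
                mean, sd = mu, 0.0
            data[metal] = (mean, sd, n_replicates)
        out[group] = QuotaTable(strain=group, data=data)
    truth.manifest["generate_quotas"] = {
        "seed": seed, "n_replicates": n_replicates, "scale": scale, "rel_sd": rsd,
    }
    return out
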