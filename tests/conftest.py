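"""Shared fixtures: all inputs are generated programmatically at test time."""

import numpy as np
import pandas as pd
import pytest

from metallome import QuantTable
from metallome.config import AnnotationConfig


@pytest.fixture(scope="session")
def annotation_config() -> AnnotationConfig:
    return AnnotationConfig()


@pytest.fixture
def small_quant() -> QuantTable:
    """3 proteins x 4 samples (two replicate groups), no missing values."""
    data = pd.DataFrame(
        {
            "OA1_1": [100.0, 200.0, 700.0],
            "OA1_2": [110.0, 190.0, 710.0],
            "OA16_1": [100.0, 400.0, 700.0],
            "OA16_2": [90.0, 410.0, 690.0],
        },
        index=pd.Index(["P1", "P2", "P3"], name="protein_id"),
    )
    return QuantTable(data)


def random_atoms(rng: np.random.Generator, n: int):
    """Random synthetic atom records for oracle-equivalence tests."""
    from metallome.structures import AtomRecord

    elements = ["Zn", "Fe", "Na", "N", "O", "S", "C"]
    atoms = []
    for i in range(n):
        element = elements[int(rng.integers(len(elements)))]
        is_water = element == "O" and rng.random() < 0.3
        atoms.append(AtomRecord(
            element=element,
            position=tuple(rng.uniform(0.0, 12.0, size=3)),
            chain_id="AB"[int(rng.integers(2))],
            residue_name="HOH" if is_water else "GLY",
            residue_seq=i + 1,
            insertion_code="",
            is_polymer=(not is_water) and rng.random() < 0.7,
            is_water=is_water,
            occupancy=1.0,
            altloc="",
            name=f"X{i}",
        ))
    return atoms


def brute_force_sites(atoms, config: AnnotationConfig):
    """Independent O(n^2) reimplementation of coordination-sphere detection.

    Returns, per metal atom (in input order), the donor set as frozenset of
    (chain, residue_seq, name, rounded distance), plus the adventitious flag
    and attributed chain recomputed from scratch.
    """
    out = []
    metals = [a for a in atoms if a.element in config.metals]
    for metal in metals:
        donors = []
        for other in atoms:
            if other.element not in config.donors:
                continue
            if other.element in config.metals:
                continue
            if other.is_water and not config.include_waters:
                continue
            d = float(np.linalg.norm(np.subtract(metal.position, other.position)))
            if 0.0 < d <= config.cutoff:
                donors.append((other, d))
        polymer_chains = sorted(d.chain_id for d, _ in donors if d.is_polymer)
        if polymer_chains:
            counts = {c: polymer_chains.count(c) for c in set(polymer_chains)}
            best = max(counts.values())
            attributed = min(c for c, k in counts.items() if k == best)
            adventitious = False
        else:
            attributed, adventitious = None, True
        out.append({
            "metal": metal.element,
            "donors": frozenset((d.chain_id, d.residue_seq, d.name, round(dist, 9))
                                for d, dist in donors),
            "attributed": attributed,
            "adventitious": adventitious,
        })
    return out
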