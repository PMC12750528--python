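"""Shared configuration for metal-site annotation.

The metal whitelist covers every element routinely deposited as a
protein-bound cation: alkali and alkaline-earth metals, the d-block,
post-transition metals and the metalloids As/Sb/Te (all of which turn up
in phytoplankton proteomes alongside the canonical Fe/Zn/Mn/Cu set).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

ALKALI = frozenset({"Li", "Na", "K", "Rb", "Cs"})
ALKALINE_EARTH = frozenset({"Be", "Mg", "Ca", "Sr", "Ba"})
TRANSITION = frozenset({
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "La", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
})
POST_TRANSITION = frozenset({"Al", "Ga", "In", "Sn", "Tl", "Pb", "Bi"})
METALLOIDS = frozenset({"As", "Sb", "Te"})

DEFAULT_METALS = ALKALI | ALKALINE_EARTH | TRANSITION | POST_TRANSITION | METALLOIDS

#: Elements accepted as first-sphere donor atoms.
DEFAULT_DONORS = frozenset({"N", "O", "S"})


@dataclass(frozen=True)
class AnnotationConfig:
    """Parameters of coordination-sphere detection.

    Attributes
    ----------
    metals : frozenset of element symbols treated as candidate cofactor ions.
    donors : frozenset of element symbols accepted as coordinating atoms.
    cutoff : first-shell metal-donor distance cutoff in Angstrom.
    exclude_adventitious : drop sites with no polymer donor (buffer ions)
        from downstream stoichiometry.
    include_waters : count water oxygens as donors (off by default: the
        stoichiometry is about the protein coordination sphere).
    per_assembly : attribute sites to the whole assembly instead of a single
        chain (every non-adventitious site counts for every chain queried).
    """

    metals: frozenset[str] = DEFAULT_METALS
    donors: frozenset[str] = DEFAULT_DONORS
    cutoff: float = 3.0
    exclude_adventitious: bool = True
    include_waters: bool = False
    per_assembly: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")

    def restrict(self, whitelist=None, blacklist=None) -> "AnnotationConfig":
        """Return a config with the metal set narrowed by white/blacklist."""
        metals = self.metals
        if whitelist is not None:
            metals = metals & frozenset(whitelist)
        if blacklist is not None:
            metals = metals - frozenset(blacklist)
        return replace(self, metals=metals)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnnotationConfig":
        """Load from a flat key-value YAML file; absent keys keep defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("cutoff", "exclude_adventitious", "include_waters", "per_assembly"):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("metals", "donors"):
            if key in raw:
                kwargs[key] = frozenset(raw[key])
        cfg = cls(**kwargs)
        return cfg.restrict(raw.get("metal_whitelist"), raw.get("metal_blacklist"))
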