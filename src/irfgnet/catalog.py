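"""Functional-group catalogs and SMARTS-based molecule labeling.

The package classifies 37 functional groups (the *extended* catalog); the
*original* catalog is the first 22 of these, covering the most common groups
in organic chemistry. Catalog order is canonical: index ``i`` of every label
vector and every model output refers to ``catalog.groups[i]``, always.

Group membership is decided by SMARTS substructure matching on the molecular
graph. The shipped patterns keep sibling classes disjoint where their names
demand it (a phenolic OH is Phenol, not Alcohol; an ester oxygen is not an
Ether; an amide nitrogen is not an Amine). Two mechanisms enforce this:

* recursive SMARTS environments inside the patterns themselves, and
* ``priority_exclusions``: the first atom of each pattern is the group's
  *key* atom, and a match is discarded when its key atom lies inside any raw
  match of an excluded group.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "FunctionalGroup",
    "FunctionalGroupCatalog",
    "LabelVector",
    "load_catalog",
    "match_groups",
    "label_manifest",
    "CatalogError",
    "MoleculeError",
]


class CatalogError(ValueError):
    """Unknown catalog variant or malformed catalog definition."""


class MoleculeError(ValueError):
    """SMILES string that cannot be parsed into a molecule."""


@dataclass(frozen=True)
class FunctionalGroup:
    """One catalog entry: a named group with its substructure patterns.

    The first atom of each SMARTS is the group's key atom (e.g. the hydroxyl
    oxygen for Alcohol); exclusions are evaluated against that atom.
    """

    name: str
    patterns: tuple[str, ...]
    priority_exclusions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.patterns:
            raise CatalogError(f"group {self.name!r} has no patterns")
        for p in self.patterns:
            if Chem.MolFromSmarts(p) is None:
                raise CatalogError(f"group {self.name!r}: invalid SMARTS {p!r}")


@dataclass(frozen=True)
class FunctionalGroupCatalog:
    """Ordered, immutable list of functional groups."""

    groups: tuple[FunctionalGroup, ...]
    variant: str

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise CatalogError("duplicate group names in catalog")

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": g.name,
                    "patterns": list(g.patterns),
                    "priority_exclusions": list(g.priority_exclusions),
                }
                for g in self.groups
            ],
            indent=2,
        )


@dataclass(frozen=True)
class LabelVector:
    """Binary presence/absence vector aligned to a catalog."""

    bits: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("label bits must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    def present(self, catalog: FunctionalGroupCatalog) -> list[str]:
        """Names of the groups flagged present, in catalog order."""
        return [n for n, b in zip(catalog.names, self.bits) if b]


# The canonical 37-group definition, in canonical catalog order. Key atom
# first in every pattern. `!$([X]~[!#6;!#1])` reads "no non-carbon,
# non-hydrogen neighbor".
_GROUP_DEFS: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("Alkane", ("[CX4;!$([CX4]~[!#6;!#1])]",), ()),
    ("Alkene", ("[CX3]=[CX3]",), ("Enol", "Enamine")),
    ("Alkyne", ("[CX2]#[CX2]",), ()),
    ("Arene", ("[cX3]",), ()),
    ("Haloalkane", ("[CX4][F,Cl,Br,I]",), ()),
    ("Alcohol", ("[OX2H][#6;!$([cX3])]",), ("Phenol", "Carboxylic acid", "Enol")),
    (
        "Aldehyde",
        ("[CX3H1]=[OX1]", "[CX3H2]=[OX1]"),
        ("Carboxylic acid", "Ester", "Amide", "Acid anhydride", "Acyl halide", "Carbamate"),
    ),
    ("Ketone", ("[CX3](=[OX1])([#6])[#6]",), ()),
    ("Carboxylic acid", ("[OX2H][CX3]=[OX1]",), ()),
    ("Acid anhydride", ("[OX2]([CX3]=[OX1])[CX3]=[OX1]",), ()),
    ("Acyl halide", ("[CX3](=[OX1])[F,Cl,Br,I]",), ()),
    (
        "Ester",
        ("[OX2H0]([CX3]=[OX1])[#6;!$([CX3]=[OX1])]",),
        ("Carbamate",),
    ),
    (
        "Ether",
        ("[OX2H0]([#6])[#6]",),
        ("Ester", "Acid anhydride", "Carbamate"),
    ),
    (
        "Amine",
        ("[NX3;!$([NX3]~[!#6;!#1])]",),
        ("Amide", "Thioamide", "Imide", "Enamine", "Carbamate"),
    ),
    ("Amide", ("[NX3][CX3]=[OX1]",), ("Imide", "Carbamate")),
    ("Nitrile", ("[NX1]#[CX2]",), ()),
    ("Imide", ("[NX3]([CX3]=[OX1])[CX3]=[OX1]",), ()),
    ("Imine", ("[NX2]=[CX3]",), ("Hydrazone",)),
    ("Azo compound", ("[NX2](=[NX2][#6])[#6]",), ()),
    ("Thiol", ("[SX2H][#6]",), ()),
    ("Thial", ("[CX3H1]=[SX1]", "[CX3H2]=[SX1]"), ("Thioamide",)),
    ("Phenol", ("[OX2H][cX3]",), ()),
    ("Enol", ("[OX2H][CX3]=[CX3]",), ()),
    ("Sulfone", ("[SX4](=[OX1])(=[OX1])([#6])[#6]",), ()),
    ("Sulfonic acid", ("[SX4](=[OX1])(=[OX1])[OX2H]",), ()),
    ("Hydrazine", ("[NX3][NX3]",), ()),
    ("Enamine", ("[NX3][CX3]=[CX3]",), ()),
    ("Isocyanate", ("[NX2]=[CX2]=[OX1]",), ()),
    ("Isothiocyanate", ("[NX2]=[CX2]=[SX1]",), ()),
    ("Phosphine", ("[PX3;!$([PX3]~[!#6;!#1])]",), ()),
    ("Sulfonamide", ("[SX4](=[OX1])(=[OX1])[NX3]",), ()),
    ("Sulfonate", ("[SX4](=[OX1])(=[OX1])[OX2H0][#6]",), ()),
    ("Sulfoxide", ("[SX3](=[OX1])([#6])[#6]",), ()),
    ("Thioamide", ("[NX3][CX3]=[SX1]",), ()),
    ("Hydrazone", ("[NX2](=[CX3])[NX3]",), ()),
    ("Carbamate", ("[NX3][CX3](=[OX1])[OX2]",), ()),
    ("Sulfide", ("[SX2]([#6])[#6]",), ()),
)

EXTENDED_NAMES: tuple[str, ...] = tuple(name for name, _, _ in _GROUP_DEFS)

# The original model covers the 22 most common groups: the first 22 catalog
# rows (Alkane .. Phenol). Exposed as a module-level list so an alternative
# membership can be configured.
ORIGINAL_NAMES: tuple[str, ...] = EXTENDED_NAMES[:22]


def load_catalog(variant: str = "extended37") -> FunctionalGroupCatalog:
    """Return the functional-group catalog for ``variant``.

    Parameters
    ----------
    variant
        ``"extended37"`` (all 37 groups) or ``"original22"`` (the 22 most
        common groups, a prefix of the extended catalog).
    """
    if variant == "extended37":
        wanted: Sequence[str] = EXTENDED_NAMES
    elif variant == "original22":
        wanted = ORIGINAL_NAMES
    else:
        raise CatalogError(
            f"unknown catalog variant {variant!r}; expected 'extended37' or 'original22'"
        )
    keep = set(wanted)
    groups = tuple(
        FunctionalGroup(
            name,
            patterns,
            tuple(e for e in excl if e in keep or variant == "original22"),
        )
        for name, patterns, excl in _GROUP_DEFS
        if name in keep
    )
    return FunctionalGroupCatalog(groups=groups, variant=variant)


# Exclusion patterns must see the full chemistry even in the reduced catalog
# (an original22 Alcohol still must not fire on a carboxylic OH), so raw
# matches for exclusions are always resolved against the full definition set.
_PATTERNS_BY_NAME = {name: patterns for name, patterns, _ in _GROUP_DEFS}

_COMPILED: dict[str, tuple[Chem.Mol, ...]] = {}


def _compiled(name: str) -> tuple[Chem.Mol, ...]:
    if name not in _COMPILED:
        _COMPILED[name] = tuple(
            Chem.MolFromSmarts(p) for p in _PATTERNS_BY_NAME[name]
        )
    return _COMPILED[name]


def _raw_match_atoms(mol: Chem.Mol, name: str) -> set[int]:
    atoms: set[int] = set()
    for query in _compiled(name):
        for match in mol.GetSubstructMatches(query):
            atoms.update(match)
    return atoms


def _parse_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise MoleculeError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparsable SMILES: {smiles!r}")
    return mol


def match_groups(smiles: str, catalog: FunctionalGroupCatalog) -> LabelVector:
    """Annotate a molecule with its catalog label vector.

    ``bits[i] = 1`` iff any pattern of ``catalog.groups[i]`` matches the
    molecule and the match survives the group's priority exclusions (the
    pattern's key atom does not sit inside a match of an excluded group).
    Deterministic for a given catalog.
    """
    mol = _parse_smiles(smiles)
    bits = np.zeros(len(catalog), dtype=np.int8)
    excluded_atoms_cache: dict[str, set[int]] = {}
    for i, group in enumerate(catalog.groups):
        vetoed: set[int] = set()
        for excl in group.priority_exclusions:
            if excl not in excluded_atoms_cache:
                excluded_atoms_cache[excl] = _raw_match_atoms(mol, excl)
            vetoed |= excluded_atoms_cache[excl]
        for query in _compiled(group.name):
            hit = False
            for match in mol.GetSubstructMatches(query):
                if match[0] not in vetoed:
                    hit = True
                    break
            if hit:
                bits[i] = 1
                break
    return LabelVector(bits=bits, source_id=smiles)


def label_manifest(
    manifest: pd.DataFrame, catalog: FunctionalGroupCatalog
) -> list[LabelVector]:
    """Label every molecule of a manifest table.

    ``manifest`` must have columns ``id`` and ``smiles`` with unique ids.
    Rows whose SMILES do not parse are skipped; the skip count is logged.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    if not {"id", "smiles"} <= set(manifest.columns):
        raise ValueError("manifest requires 'id' and 'smiles' columns")
    if manifest["id"].duplicated().any():
        dupes = manifest["id"][manifest["id"].duplicated()].tolist()
        raise ValueError(f"duplicate manifest ids: {dupes}")
    out: list[LabelVector] = []
    skipped = 0
    for row in manifest.itertuples(index=False):
        try:
            lv = match_groups(str(row.smiles), catalog)
        except MoleculeError:
            logger.warning("skipping %s: unparsable SMILES %r", row.id, row.smiles)
            skipped += 1
            continue
        out.append(LabelVector(bits=lv.bits, source_id=str(row.id)))
    if skipped:
        logger.warning("skipped %d of %d manifest rows", skipped, len(manifest))
    return out


def labels_to_frame(
    labels: Iterable[LabelVector], catalog: FunctionalGroupCatalog
) -> pd.DataFrame:
    """Stack label vectors into an ``id`` + one-column-per-group table."""
    labels = list(labels)
    data = np.stack([lv.bits for lv in labels]) if labels else np.zeros((0, len(catalog)))
    frame = pd.DataFrame(data, columns=catalog.names)
    frame.insert(0, "id", [lv.source_id for lv in labels])
    return frame
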