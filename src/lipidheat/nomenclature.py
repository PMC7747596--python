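"""Shorthand lipid nomenclature: parsing, formatting, and acyl-chain queries.

Analytes are written in the mass-spectrometry shorthand used throughout plant
lipidomics: a headgroup-class token followed by either the summed acyl
composition, ``PC(34:3)`` (total acyl carbons : total carbon-carbon double
bonds), or an explicit chain list, ``TAG(18:2/16:0/18:1)``.  Chain order does
not encode sn-positions.  Isobaric analytes with different chain sets are
distinguished by a trailing variant tag, e.g. ``DAG(36:3)_A`` vs
``DAG(36:3)_B``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence


class Headgroup(str, Enum):
    """Lipid headgroup classes covered by the anther lipidome profile."""

    MGDG = "MGDG"  # monogalactosyldiacylglycerol (plastidic)
    PG = "PG"      # phosphatidylglycerol (plastidic)
    SQDG = "SQDG"  # sulfoquinovosyldiacylglycerol (plastidic)
    PC = "PC"      # phosphatidylcholine
    PE = "PE"      # phosphatidylethanolamine
    PI = "PI"      # phosphatidylinositol
    PA = "PA"      # phosphatidic acid
    ASG = "ASG"    # acylated sterol glycoside (one acyl chain)
    SG = "SG"      # sterol glycoside (no acyl chain)
    SE = "SE"      # sterol ester (one acyl chain)
    DAG = "DAG"    # diacylglycerol
    TAG = "TAG"    # triacylglycerol


#: Number of acyl chains per headgroup class. SG carries no acyl chain.
_CHAIN_COUNT: dict[Headgroup, int] = {
    Headgroup.TAG: 3,
    Headgroup.DAG: 2,
    Headgroup.PC: 2,
    Headgroup.PE: 2,
    Headgroup.PI: 2,
    Headgroup.PA: 2,
    Headgroup.PG: 2,
    Headgroup.MGDG: 2,
    Headgroup.SQDG: 2,
    Headgroup.SE: 1,
    Headgroup.ASG: 1,
    Headgroup.SG: 0,
}


class LipidNameError(ValueError):
    """Raised for unparseable or internally inconsistent lipid names."""


@dataclass(frozen=True, order=True)
class AcylChain:
    """One fatty-acyl chain, e.g. 18:3 = 18 carbons, 3 double bonds."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise LipidNameError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise LipidNameError("negative double-bond count")
        if self.double_bonds >= self.carbons:
            raise LipidNameError(
                f"chain {self.carbons}:{self.double_bonds} has more double bonds than bonds"
            )

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid analyte: headgroup class plus summed (and optionally per-chain)
    acyl composition.

    ``chains`` is ``None`` when only the summed composition is known; the
    stored order of an explicit chain list is preserved for display but carries
    no positional meaning (equality normalizes it).
    """

    headgroup: Headgroup
    total_carbons: int = 0
    total_double_bonds: int = 0
    chains: Optional[tuple[AcylChain, ...]] = None
    variant_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.total_carbons < 0 or self.total_double_bonds < 0:
            raise LipidNameError("negative acyl totals")
        if self.chains is not None:
            if len(self.chains) != _CHAIN_COUNT[self.headgroup]:
                raise LipidNameError(
                    f"{self.headgroup.value} requires {_CHAIN_COUNT[self.headgroup]} "
                    f"chains, got {len(self.chains)}"
                )
            c = sum(ch.carbons for ch in self.chains)
            d = sum(ch.double_bonds for ch in self.chains)
            if (self.total_carbons, self.total_double_bonds) != (c, d):
                raise LipidNameError(
                    f"chain totals {c}:{d} inconsistent with stated totals "
                    f"{self.total_carbons}:{self.total_double_bonds}"
                )

    # -- identity ---------------------------------------------------------

    def normalized_chains(self) -> Optional[tuple[AcylChain, ...]]:
        """Chains sorted descending by carbons then double bonds (order has no
        sn meaning, so this is the canonical identity)."""
        if self.chains is None:
            return None
        return tuple(
            sorted(self.chains, key=lambda ch: (-ch.carbons, -ch.double_bonds))
        )

    def _key(self):
        return (
            self.headgroup,
            self.total_carbons,
            self.total_double_bonds,
            self.normalized_chains(),
            self.variant_tag,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, LipidSpecies):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __str__(self) -> str:
        return format_lipid_name(self)

    @property
    def chain_count(self) -> int:
        return chain_count(self)


_NAME_RE = re.compile(
    r"^(?P<cls>[A-Za-z]+)"
    r"(?:\((?P<body>[0-9:/ ]+)\))?"
    r"(?:_(?P<tag>[A-Za-z0-9]+))?$"
)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse shorthand such as ``PC(34:3)``, ``TAG(18:2/16:0/18:1)``,
    ``DAG(36:3)_A`` or bare ``SG`` into a validated :class:`LipidSpecies`.

    Raises :class:`LipidNameError` for unknown class tokens, malformed bodies,
    or chain lists inconsistent with the class's chain count.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise LipidNameError(f"cannot parse lipid name {name!r}")
    cls_token = m.group("cls")
    try:
        hg = Headgroup(cls_token)
    except ValueError:
        raise LipidNameError(f"unknown headgroup class token {cls_token!r} in {name!r}") from None
    body = m.group("body")
    tag = m.group("tag")

    if body is None:
        if hg is not Headgroup.SG:
            raise LipidNameError(f"{name!r}: class {hg.value} requires an acyl composition")
        return LipidSpecies(hg, 0, 0, None, tag)

    parts = [p.strip() for p in body.split("/")]
    pairs = []
    for p in parts:
        cd = p.split(":")
        if len(cd) != 2 or not all(s.isdigit() for s in cd):
            raise LipidNameError(f"malformed acyl token {p!r} in {name!r}")
        pairs.append((int(cd[0]), int(cd[1])))

    if len(pairs) == 1 and _CHAIN_COUNT[hg] != 1:
        # summed form CLASS(c:d)
        c, d = pairs[0]
        return LipidSpecies(hg, c, d, None, tag)
    # chain form (single-chain classes always take the chain interpretation)
    chains = tuple(AcylChain(c, d) for c, d in pairs)
    total_c = sum(ch.carbons for ch in chains)
    total_d = sum(ch.double_bonds for ch in chains)
    return LipidSpecies(hg, total_c, total_d, chains, tag)


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical shorthand for a species; inverse of :func:`parse_lipid_name`."""
    hg = species.headgroup
    if hg is Headgroup.SG and species.chains is None and species.total_carbons == 0:
        base = hg.value
    elif species.chains is not None:
        base = f"{hg.value}({'/'.join(str(ch) for ch in species.chains)})"
    else:
        base = f"{hg.value}({species.total_carbons}:{species.total_double_bonds})"
    if species.variant_tag:
        base += f"_{species.variant_tag}"
    return base


def chain_count(species: LipidSpecies) -> int:
    """Acyl chains borne by the species: 3 for TAG, 2 for diacyl classes,
    1 for SE/ASG, 0 for SG."""
    return _CHAIN_COUNT[species.headgroup]


# ---------------------------------------------------------------------------
# Unambiguous acyl assignments for summed-composition species.
#
# Only some summed compositions have a single plausible chain set; those are
# the species usable for fatty-acid decomposition. The PC/PE 34:2 entry is
# 16:0/18:2 (the only chain pair summing to 34:2 among the major fatty acids);
# the map is overridable by the caller.
# ---------------------------------------------------------------------------

def _chains(*pairs: tuple[int, int]) -> tuple[AcylChain, ...]:
    return tuple(AcylChain(c, d) for c, d in pairs)


DEFAULT_ASSIGNMENTS: dict[tuple[Headgroup, int, int], tuple[AcylChain, ...]] = {
    (Headgroup.PC, 34, 4): _chains((16, 1), (18, 3)),
    (Headgroup.PC, 34, 3): _chains((16, 0), (18, 3)),
    (Headgroup.PC, 34, 2): _chains((16, 0), (18, 2)),
    (Headgroup.PC, 34, 1): _chains((16, 0), (18, 1)),
    (Headgroup.PC, 36, 6): _chains((18, 3), (18, 3)),
    (Headgroup.PC, 36, 5): _chains((18, 2), (18, 3)),
    (Headgroup.PC, 36, 1): _chains((18, 0), (18, 1)),
    (Headgroup.PE, 34, 3): _chains((16, 0), (18, 3)),
    (Headgroup.PE, 34, 2): _chains((16, 0), (18, 2)),
    (Headgroup.PE, 34, 1): _chains((16, 0), (18, 1)),
    (Headgroup.PE, 36, 6): _chains((18, 3), (18, 3)),
    (Headgroup.PE, 36, 5): _chains((18, 2), (18, 3)),
    (Headgroup.DAG, 34, 3): _chains((16, 0), (18, 3)),
    (Headgroup.DAG, 34, 2): _chains((16, 0), (18, 2)),
    (Headgroup.DAG, 34, 1): _chains((16, 0), (18, 1)),
    (Headgroup.DAG, 36, 4): _chains((18, 2), (18, 2)),
}

#: Variant-tagged analytes carry their own chain sets.
DEFAULT_VARIANT_ASSIGNMENTS: dict[str, tuple[AcylChain, ...]] = {
    "DAG(36:3)_A": _chains((18, 3), (18, 0)),
    "DAG(36:3)_B": _chains((18, 2), (18, 1)),
    "TAG(52:4)_A": _chains((18, 3), (16, 0), (18, 1)),
    "TAG(52:4)_B": _chains((18, 2), (18, 2), (16, 0)),
    "TAG(54:7)_A": _chains((18, 2), (18, 2), (18, 3)),
    "TAG(54:7)_B": _chains((18, 1), (18, 3), (18, 3)),
}


class AmbiguousCompositionError(LipidNameError):
    """The species has no explicit chains and no unambiguous assignment."""


def assigned_chains(
    species: LipidSpecies,
    assignment: Optional[Mapping] = None,
) -> tuple[AcylChain, ...]:
    """Resolve a species to a concrete chain set.

    Explicit chains win; otherwise the variant map, then the per-class
    assignment map are consulted. Raises :class:`AmbiguousCompositionError`
    if no resolution exists.
    """
    if species.chains is not None:
        return species.chains
    name = format_lipid_name(species)
    if name in DEFAULT_VARIANT_ASSIGNMENTS:
        return DEFAULT_VARIANT_ASSIGNMENTS[name]
    amap = DEFAULT_ASSIGNMENTS if assignment is None else assignment
    key = (species.headgroup, species.total_carbons, species.total_double_bonds)
    if key in amap:
        return amap[key]
    raise AmbiguousCompositionError(
        f"{name}: fatty acyl composition is ambiguous (no chains, no assignment)"
    )


def fatty_acid_occurrences(
    species: LipidSpecies,
    fa: AcylChain,
    assignment: Optional[Mapping] = None,
) -> int:
    """Number of times fatty acid ``fa`` occurs among the species' chains.

    Requires explicit chains or an entry in the assignment map; raises
    :class:`AmbiguousCompositionError` otherwise.
    """
    chains = assigned_chains(species, assignment)
    return sum(1 for ch in chains if ch == fa)


def contains_fatty_acid(
    species: LipidSpecies,
    fa: AcylChain,
    assignment: Optional[Mapping] = None,
) -> bool:
    """True if ``fa`` occurs in the species' (explicit or assigned) chains;
    False when the composition is ambiguous."""
    try:
        return fatty_acid_occurrences(species, fa, assignment) > 0
    except AmbiguousCompositionError:
        return False
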