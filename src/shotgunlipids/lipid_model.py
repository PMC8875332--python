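"""Lipid shorthand names and structural categories.

Shotgun (flow-injection MRM) lipidomics panels report species at the
"sum composition" level: a class tag plus total acyl/alkyl carbons and
total double bonds, e.g. ``PC aa C36:4``.  Ceramides are the exception:
the panel dialect resolves the sphingoid base, e.g. ``Cer d18:1/16:0``
(d18:1 base at sn1, C16:0 N-acyl chain).  This module parses and
formats those names and assigns every species to the structural
categories the downstream profile analysis reports on:

* saturation class (SFA / MUFA / PUFA, by double-bond count),
* chain-length bin (short / medium / long, class-specific boundaries),
* double-bond profile bins (``X:n``),
* carbon-number profile bins (``Cn:X``),
* and, for ceramides, the sn1 sphingoid-base partition.

For ceramides written in the base/acyl dialect the saturation,
double-bond, carbon and chain-length descriptors refer to the N-acyl
chain — the sphingoid base is analysed separately via the sn1
partition, which keeps the two views orthogonal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence


class LipidClass(str, Enum):
    """The closed set of lipid classes covered by the panel."""

    PC_AA = "PC_AA"      # diacyl phosphatidylcholine
    PC_AE = "PC_AE"      # PC plasmalogen / ether species
    LYSO_PC = "LYSO_PC"  # lyso-phosphatidylcholine
    SM = "SM"            # sphingomyelin
    CER = "CER"          # ceramide
    TAG = "TAG"          # triacylglyceride
    CHOL = "CHOL"        # cholesterol (single-species class)


CLASS_PREFIX: Mapping[LipidClass, str] = {
    LipidClass.PC_AA: "PC aa",
    LipidClass.PC_AE: "PC ae",
    LipidClass.LYSO_PC: "Lyso-PC",
    LipidClass.SM: "SM",
    LipidClass.CER: "Cer",
    LipidClass.TAG: "TAG",
    LipidClass.CHOL: "Cholesterol",
}

SATURATION_BINS = ("SFA", "MUFA", "PUFA")
CHAIN_BINS = ("short", "medium", "long")


class LipidNameError(ValueError):
    """A species name that cannot be parsed in the panel dialect."""


class UnknownLipidClassError(LipidNameError):
    """A species name with a class prefix outside the closed class set."""


class NotCategorizableError(ValueError):
    """Raised when a category is undefined for a species (e.g. cholesterol)."""


class MissingBaseError(ValueError):
    """A ceramide operation that needs base/acyl detail got a total-form name."""


class PartitionGapError(ValueError):
    """A species falls into no bin of the configured chain-length scheme."""


class SchemeConfigurationError(ValueError):
    """The category scheme has no entry for the requested lipid class."""


@dataclass(frozen=True)
class SphingoidBase:
    """Base/acyl decomposition of a ceramide (``d18:1/16:0`` style)."""

    base_carbons: int
    base_double_bonds: int
    acyl_carbons: int
    acyl_double_bonds: int

    def __post_init__(self) -> None:
        if self.base_carbons < 12:
            raise ValueError(f"sphingoid base carbons must be >= 12, got {self.base_carbons}")
        for v, what in ((self.base_double_bonds, "base"), (self.acyl_double_bonds, "acyl")):
            if v < 0:
                raise ValueError(f"{what} double bonds must be >= 0, got {v}")
        if self.acyl_carbons < 2:
            raise ValueError(f"acyl carbons must be >= 2, got {self.acyl_carbons}")

    @property
    def label(self) -> str:
        """sn1 base label, e.g. ``C18:1``."""
        return f"C{self.base_carbons}:{self.base_double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """Parsed identity of one measured lipid species."""

    lipid_class: LipidClass
    total_carbons: int
    total_double_bonds: int
    base: Optional[SphingoidBase] = None

    def __post_init__(self) -> None:
        if self.lipid_class is LipidClass.CHOL:
            if self.total_carbons != 0 or self.total_double_bonds != 0 or self.base is not None:
                raise ValueError("cholesterol carries no chain descriptor")
            return
        if self.total_carbons < 2:
            raise ValueError(f"total carbons must be >= 2, got {self.total_carbons}")
        if self.total_double_bonds < 0:
            raise ValueError("double bonds must be >= 0")
        if 2 * self.total_double_bonds > self.total_carbons:
            raise ValueError(
                f"{self.total_double_bonds} double bonds impossible on "
                f"{self.total_carbons} carbons"
            )
        if self.base is not None:
            if self.lipid_class is not LipidClass.CER:
                raise ValueError("only ceramides carry a sphingoid base")
            if self.base.base_carbons + self.base.acyl_carbons != self.total_carbons:
                raise ValueError("base + acyl carbons must equal total carbons")
            if self.base.base_double_bonds + self.base.acyl_double_bonds != self.total_double_bonds:
                raise ValueError("base + acyl double bonds must equal total double bonds")

    @property
    def chain_carbons(self) -> int:
        """Carbon count used for chain/carbon binning.

        For ceramides in the base/acyl dialect this is the N-acyl chain
        (the sphingoid base is handled by the sn1 partition); for every
        other class it is the total chain carbon count.
        """
        if self.base is not None:
            return self.base.acyl_carbons
        return self.total_carbons

    @property
    def chain_double_bonds(self) -> int:
        """Double-bond count used for saturation/double-bond binning."""
        if self.base is not None:
            return self.base.acyl_double_bonds
        return self.total_double_bonds

    @property
    def canonical_name(self) -> str:
        return format_species_name(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_name


# ---------------------------------------------------------------------------
# parsing / formatting

_RE_CXY = re.compile(r"^C(\d+):(\d+)$")
_RE_CER_BASE = re.compile(r"^d(\d+):(\d+)/(\d+):(\d+)$")

# longest prefixes first so "PC aa" wins over "PC"
_SIMPLE_PREFIXES = (
    ("PC aa", LipidClass.PC_AA),
    ("PC ae", LipidClass.PC_AE),
    ("Lyso-PC", LipidClass.LYSO_PC),
    ("SM", LipidClass.SM),
    ("TAG", LipidClass.TAG),
)


@lru_cache(maxsize=8192)
def parse_species_name(name: str, dialect: str = "canonical") -> LipidSpecies:
    """Parse a lipid shorthand name into a :class:`LipidSpecies`.

    The canonical dialect covers ``PC aa Cnn:d``, ``PC ae Cnn:d``,
    ``Lyso-PC Cnn:d``, ``SM Cnn:d``, ``TAG Cnn:d``, ``Cholesterol`` and
    ceramides in both the base/acyl form ``Cer d18:1/16:0`` and the
    total form ``Cer Cnn:d``.
    """
    if dialect != "canonical":
        raise ValueError(f"unknown dialect {dialect!r}")
    if not name or not name.strip():
        raise LipidNameError("empty species name")
    text = name.strip()

    if text == CLASS_PREFIX[LipidClass.CHOL]:
        return LipidSpecies(LipidClass.CHOL, 0, 0)

    if text.startswith("Cer "):
        rest = text[4:]
        m = _RE_CER_BASE.match(rest)
        if m:
            bc, bd, ac, ad = map(int, m.groups())
            base = SphingoidBase(bc, bd, ac, ad)
            return LipidSpecies(LipidClass.CER, bc + ac, bd + ad, base)
        m = _RE_CXY.match(rest)
        if m:
            c, d = map(int, m.groups())
            return LipidSpecies(LipidClass.CER, c, d)
        raise LipidNameError(f"cannot parse ceramide descriptor {rest!r} in {name!r}")

    for prefix, cls in _SIMPLE_PREFIXES:
        if text.startswith(prefix + " "):
            rest = text[len(prefix) + 1:]
            m = _RE_CXY.match(rest)
            if not m:
                raise LipidNameError(f"cannot parse chain descriptor {rest!r} in {name!r}")
            c, d = map(int, m.groups())
            return LipidSpecies(cls, c, d)

    token = text.split(" C")[0] if " C" in text else text
    raise UnknownLipidClassError(f"unknown lipid class prefix {token!r} in {name!r}")


def format_species_name(species: LipidSpecies) -> str:
    """Canonical text form; inverse of :func:`parse_species_name`."""
    cls = species.lipid_class
    if cls is LipidClass.CHOL:
        return CLASS_PREFIX[cls]
    if cls is LipidClass.CER and species.base is not None:
        b = species.base
        return f"Cer d{b.base_carbons}:{b.base_double_bonds}/{b.acyl_carbons}:{b.acyl_double_bonds}"
    return f"{CLASS_PREFIX[cls]} C{species.total_carbons}:{species.total_double_bonds}"


# ---------------------------------------------------------------------------
# category schemes

@dataclass(frozen=True)
class ChainBins:
    """Chain-length boundaries for one class.

    ``short`` if carbons < ``short_below``; ``medium`` if
    ``medium_low <= carbons <= medium_high``; ``long`` if carbons >
    ``long_above``.  Gap-closed schemes satisfy ``medium_low ==
    short_below`` and ``long_above == medium_high`` so the three bins
    partition every integer carbon count.
    """

    short_below: int
    medium_low: int
    medium_high: int
    long_above: int

    def classify(self, carbons: int) -> str:
        if carbons < self.short_below:
            return "short"
        if self.medium_low <= carbons <= self.medium_high:
            return "medium"
        if carbons > self.long_above:
            return "long"
        raise PartitionGapError(
            f"carbon count {carbons} falls in no chain-length bin "
            f"(<{self.short_below} / {self.medium_low}-{self.medium_high} / >{self.long_above})"
        )


@dataclass(frozen=True)
class CategoryScheme:
    """Per-class chain-length boundaries plus the saturation rule."""

    name: str
    chain_bins: Mapping[LipidClass, ChainBins] = field(default_factory=dict)

    def bins_for(self, lipid_class: LipidClass) -> ChainBins:
        try:
            return self.chain_bins[lipid_class]
        except KeyError:
            raise SchemeConfigurationError(
                f"scheme {self.name!r} has no chain-length bins for {lipid_class.value}"
            ) from None


def _bins(short: int, mlo: int, mhi: int, llo: int) -> ChainBins:
    return ChainBins(short, mlo, mhi, llo)


#: Default scheme.  Boundaries follow the reported class definitions
#: (PC short <C32 / medium C32-C36 / long >C36; Lyso-PC and Cer <C16 /
#: C16-C20 / >C20).  The printed SM scheme (<C32 / C34-C38 / >C40)
#: leaves C32 and C40 unassigned; the default closes the gaps so the
#: three bins partition the panel.  TAG has no published boundaries;
#: the package splits its C44-C56 range at C48 and C52.
GAP_CLOSED_SCHEME = CategoryScheme(
    name="gap-closed",
    chain_bins={
        LipidClass.PC_AA: _bins(32, 32, 36, 36),
        LipidClass.PC_AE: _bins(32, 32, 36, 36),
        LipidClass.LYSO_PC: _bins(16, 16, 20, 20),
        LipidClass.SM: _bins(32, 32, 38, 38),
        LipidClass.CER: _bins(16, 16, 20, 20),
        LipidClass.TAG: _bins(48, 48, 52, 52),
    },
)

#: Literal scheme: SM bins exactly as printed, leaving C32 and C40 SM
#: species unassigned (binning those raises :class:`PartitionGapError`).
LITERAL_SCHEME = CategoryScheme(
    name="literal",
    chain_bins={**GAP_CLOSED_SCHEME.chain_bins, LipidClass.SM: _bins(32, 34, 38, 40)},
)

_SCHEMES = {s.name: s for s in (GAP_CLOSED_SCHEME, LITERAL_SCHEME)}


def category_scheme(name: str) -> CategoryScheme:
    """Look up a named chain-length scheme (``gap-closed`` or ``literal``)."""
    try:
        return _SCHEMES[name]
    except KeyError:
        raise SchemeConfigurationError(
            f"unknown scheme {name!r}; available: {sorted(_SCHEMES)}"
        ) from None


# ---------------------------------------------------------------------------
# categorisation operations

def saturation_category(species: LipidSpecies) -> str:
    """SFA (0 double bonds), MUFA (1) or PUFA (>=2).

    Ceramides in the base/acyl dialect are classified by the N-acyl
    double-bond count.
    """
    if species.lipid_class is LipidClass.CHOL:
        raise NotCategorizableError("cholesterol has no saturation category")
    d = species.chain_double_bonds
    if d == 0:
        return "SFA"
    if d == 1:
        return "MUFA"
    return "PUFA"


def chain_length_category(species: LipidSpecies, scheme: CategoryScheme = GAP_CLOSED_SCHEME) -> str:
    """short / medium / long per the class entry of *scheme*."""
    if species.lipid_class is LipidClass.CHOL:
        raise NotCategorizableError("cholesterol has no chain-length category")
    return scheme.bins_for(species.lipid_class).classify(species.chain_carbons)


def double_bond_bin(species: LipidSpecies) -> str:
    """Double-bond profile label ``X:n`` (acyl count for base/acyl Cer)."""
    return f"X:{species.chain_double_bonds}"


def carbon_bin(species: LipidSpecies, cer_carbons: str = "acyl") -> str:
    """Carbon-number profile label ``Cn:X``.

    For ceramides in the base/acyl dialect the label refers to the
    N-acyl carbon count by default (``Cer d18:1/18:0`` -> ``C18:X``),
    matching the reported medium-chain C16:X-C20:X ceramide bins;
    ``cer_carbons="total"`` switches to base+acyl totals.
    """
    if cer_carbons not in ("acyl", "total"):
        raise ValueError(f"cer_carbons must be 'acyl' or 'total', got {cer_carbons!r}")
    if species.base is not None and cer_carbons == "total":
        return f"C{species.total_carbons}:X"
    return f"C{species.chain_carbons}:X"


def sn1_base_partition(
    species_list: Iterable[LipidSpecies],
) -> dict[str, list[LipidSpecies]]:
    """Partition ceramides by sphingoid-base label (``C18:1``, ``C18:2`` ...).

    Every species must be a ceramide in the base/acyl dialect; the
    returned subsets are disjoint and exhaustive.
    """
    out: dict[str, list[LipidSpecies]] = {}
    for sp in species_list:
        if sp.lipid_class is not LipidClass.CER:
            raise ValueError(f"{sp.canonical_name} is not a ceramide")
        if sp.base is None:
            raise MissingBaseError(
                f"{sp.canonical_name} lacks base/acyl detail needed for the sn1 partition"
            )
        out.setdefault(sp.base.label, []).append(sp)
    return out


def species_categories(
    name: str,
    scheme: CategoryScheme = GAP_CLOSED_SCHEME,
) -> dict[str, str]:
    """All category labels for one species name (convenience for tables)."""
    sp = parse_species_name(name)
    cats: dict[str, str] = {}
    if sp.lipid_class is not LipidClass.CHOL:
        cats["saturation"] = saturation_category(sp)
        cats["chain"] = chain_length_category(sp, scheme)
        cats["double_bond"] = double_bond_bin(sp)
        cats["carbon"] = carbon_bin(sp)
    if sp.base is not None:
        cats["sn1_base"] = sp.base.label
    return cats
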