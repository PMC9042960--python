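"""Coordinate system, regions, masks and mutation labels on the circular mtGenome.

The human mitochondrial reference (rCRS) is a 16,569-bp circle with 1-based
coordinates.  The non-coding control region spans the origin (16024-576) and
contains the two hypervariable segments HVI and HVII that forensic and
population studies traditionally sequence.  This module provides:

* :class:`MutationCall` -- a single difference from the reference, written in
  the compact ``<ref><position><observed>`` notation used throughout the
  mtDNA literature, with point heteroplasmy encoded as a two-base IUPAC
  ambiguity code (``R`` = A/G, ``Y`` = C/T, ...);
* :class:`Region` -- a named set of coordinate intervals with origin wrap and
  an explicit site count ``L`` used as the rate denominator;
* :class:`ExclusionMask` -- indel/length-variant hotspots and poly-C tracts
  that are ignored when comparing maternal relatives;
* :class:`SiteCountConvention` -- the per-region ``L`` values, shipped in two
  presets (see :data:`SITE_COUNT_PRESETS`).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "MT_GENOME_LENGTH",
    "IUPAC_TWO_BASE",
    "MutationCall",
    "MutationKind",
    "Region",
    "ExclusionMask",
    "SiteCountConvention",
    "parse_mutation_label",
    "classify_call",
    "region_of",
    "is_excluded",
    "site_count",
    "default_regions",
    "default_mask",
    "load_region_config",
]

#: rCRS length in base pairs; positions are 1-based and circular.
MT_GENOME_LENGTH = 16569

#: The six biallelic IUPAC ambiguity codes.  Three- and four-base codes are
#: rejected: point heteroplasmy is a mixture of exactly two alleles.
IUPAC_TWO_BASE: Mapping[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

_BASES = frozenset("ACGT")
_LABEL_RE = re.compile(r"^([ACGT])(\d+)([ACGTRYSWKM])$")


class MutationKind(str, enum.Enum):
    """Classification of an observed difference from the reference."""

    HOMOPLASMIC_SUBSTITUTION = "homoplasmic_substitution"
    POINT_HETEROPLASMY = "point_heteroplasmy"


@dataclass(frozen=True)
class MutationCall:
    """One observed difference from rCRS at a single site.

    Parameters
    ----------
    position
        1-based rCRS coordinate in ``[1, 16569]``.
    ref
        Reference base at the site (A/C/G/T).
    observed
        Either a plain base different from ``ref`` (homoplasmic substitution)
        or a two-base IUPAC code containing ``ref`` (point heteroplasmy).
    maf
        Minor-allele fraction in ``[0, 1]``; meaningful for heteroplasmic
        calls, ``None`` when not measured.
    confirmed
        Whether the call passed orthogonal (e.g. Sanger) confirmation.
        Carried through from input files, never computed here.
    """

    position: int
    ref: str
    observed: str
    maf: float | None = None
    confirmed: bool | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_GENOME_LENGTH:
            raise ValueError(
                f"position {self.position} outside rCRS range [1, {MT_GENOME_LENGTH}]"
            )
        if self.ref not in _BASES:
            raise ValueError(f"invalid reference base {self.ref!r}")
        if self.observed in _BASES:
            if self.observed == self.ref:
                raise ValueError(
                    f"observed base equals reference at {self.position}: "
                    "not a mutation"
                )
        elif self.observed in IUPAC_TWO_BASE:
            if self.ref not in IUPAC_TWO_BASE[self.observed]:
                raise ValueError(
                    f"ambiguity code {self.observed} at {self.position} does not "
                    f"contain the reference base {self.ref}"
                )
        else:
            raise ValueError(
                f"invalid observed allele {self.observed!r}: must be a base or a "
                "two-base IUPAC code (RYSWKM)"
            )
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf {self.maf} outside [0, 1]")

    @property
    def heteroplasmic(self) -> bool:
        """True when the observed allele is an IUPAC ambiguity code."""
        return self.observed in IUPAC_TWO_BASE

    @property
    def alleles(self) -> frozenset[str]:
        """The constituent alleles of the observed call."""
        if self.heteroplasmic:
            return IUPAC_TWO_BASE[self.observed]
        return frozenset(self.observed)

    @property
    def kind(self) -> MutationKind:
        return classify_call(self)

    @property
    def label(self) -> str:
        """Canonical ``<ref><position><observed>`` string, e.g. ``A8470R``."""
        return f"{self.ref}{self.position}{self.observed}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_mutation_label(label: str) -> MutationCall:
    """Parse a canonical mutation label such as ``A8817G`` or ``T146Y``.

    Heteroplasmy is denoted by a two-base IUPAC code whose constituents must
    include the reference base (``A8470R`` means an A/G mixture at 8470 on an
    A reference).  ``format(parse(label)) == label`` for every valid label.

    Raises
    ------
    ValueError
        On malformed strings, out-of-range positions, observed == ref, or an
        ambiguity code not containing the reference base.
    """
    m = _LABEL_RE.match(label.strip().upper())
    if m is None:
        raise ValueError(f"malformed mutation label {label!r}")
    ref, pos, obs = m.group(1), int(m.group(2)), m.group(3)
    return MutationCall(position=pos, ref=ref, observed=obs)


def classify_call(call: MutationCall) -> MutationKind:
    """Classify a call as homoplasmic substitution or point heteroplasmy."""
    if call.heteroplasmic:
        return MutationKind.POINT_HETEROPLASMY
    return MutationKind.HOMOPLASMIC_SUBSTITUTION


@dataclass(frozen=True)
class Region:
    """A named region of the circular genome with an explicit site count.

    ``intervals`` are 1-based inclusive ``(start, end)`` pairs.  An interval
    with ``start > end`` wraps past the origin (the control region is
    ``(16024, 576)``).  ``site_count`` is the denominator ``L`` used for
    rates; it is deliberately decoupled from interval arithmetic (see
    :data:`SITE_COUNT_PRESETS`).
    """

    name: str
    intervals: tuple[tuple[int, int], ...]
    site_count: int

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"region {self.name!r} has no intervals")
        if self.site_count <= 0:
            raise ValueError(f"region {self.name!r} has non-positive site count")
        for start, end in self.intervals:
            for v in (start, end):
                if not 1 <= v <= MT_GENOME_LENGTH:
                    raise ValueError(
                        f"region {self.name!r} interval bound {v} out of range"
                    )

    def contains(self, position: int) -> bool:
        """Membership test honouring origin wrap."""
        if not 1 <= position <= MT_GENOME_LENGTH:
            raise ValueError(f"position {position} out of range")
        for start, end in self.intervals:
            if start <= end:
                if start <= position <= end:
                    return True
            else:  # wraps past the origin
                if position >= start or position <= end:
                    return True
        return False


@dataclass(frozen=True)
class ExclusionMask:
    """Sites ignored during relative comparison (indel hotspots, poly-C tracts)."""

    positions: frozenset[int] = frozenset()
    ranges: tuple[tuple[int, int], ...] = ()

    def __contains__(self, position: int) -> bool:
        if position in self.positions:
            return True
        return any(start <= position <= end for start, end in self.ranges)


class SiteCountConvention(dict):
    """Mapping of region name to analysable site count ``L``.

    A thin dict subclass so user configs can override individual entries
    while keeping failed lookups informative.
    """

    def site_count(self, region_name: str) -> int:
        try:
            return self[region_name]
        except KeyError:
            raise KeyError(
                f"unknown region {region_name!r}; known regions: "
                f"{sorted(self)}"
            ) from None


# Region intervals as printed in the source of the rate table.  The site
# counts in the ``paper_table2`` preset are the integers that the published
# per-region point estimates were actually computed with; they differ from
# the inclusive interval lengths in places (HVI 359 vs 360; whole genome
# 16596 vs 16569; control 1149).  ``strict_rcrs`` uses the arithmetic
# interval lengths and is the recommended preset for new data.
_REGION_INTERVALS: dict[str, tuple[tuple[int, int], ...]] = {
    "mtGenome": ((1, MT_GENOME_LENGTH),),
    "HVI": ((16024, 16383),),
    "HVII": ((57, 371),),
    "HVI_HVII": ((16024, 16383), (57, 371)),
    "control": ((16024, 576),),
    "coding": ((577, 16023),),
}

SITE_COUNT_PRESETS: dict[str, SiteCountConvention] = {
    "paper_table2": SiteCountConvention(
        mtGenome=16596, HVI=359, HVII=314, HVI_HVII=673, control=1149, coding=15447
    ),
    "strict_rcrs": SiteCountConvention(
        mtGenome=16569, HVI=360, HVII=315, HVI_HVII=675, control=1122, coding=15447
    ),
}

#: Single-site indel/length-variant hotspots ignored in all comparisons.
DEFAULT_MASK_POSITIONS = frozenset(
    {309, 455, 463, 573, 960, 5899, 8276, 8285, 16193}
)
#: Ranges ignored: 16180-16183 (unreliable around the 16189 poly-C) plus the
#: HVII (302-316) and HVI (16183-16194) homopolymer tracts.
DEFAULT_MASK_RANGES: tuple[tuple[int, int], ...] = (
    (16180, 16183),
    (302, 316),
    (16183, 16194),
)


def default_mask() -> ExclusionMask:
    """The default exclusion mask (indel hotspots and poly-C tracts)."""
    return ExclusionMask(positions=DEFAULT_MASK_POSITIONS, ranges=DEFAULT_MASK_RANGES)


def default_regions(preset: str = "paper_table2") -> dict[str, Region]:
    """Named regions with the site counts of the requested preset."""
    try:
        convention = SITE_COUNT_PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown site-count preset {preset!r}; available: "
            f"{sorted(SITE_COUNT_PRESETS)}"
        ) from None
    return {
        name: Region(name=name, intervals=ivals, site_count=convention[name])
        for name, ivals in _REGION_INTERVALS.items()
    }


def region_of(position: int, regions: Iterable[Region] | Mapping[str, Region] | None = None) -> set[str]:
    """Names of every region containing ``position`` (with origin wrap).

    By virtue of the interval definitions, HVI/HVII membership implies
    control-region membership and every position is in ``mtGenome``.
    """
    if regions is None:
        regions = default_regions()
    if isinstance(regions, Mapping):
        regions = regions.values()
    return {r.name for r in regions if r.contains(position)}


def is_excluded(position: int, mask: ExclusionMask | None = None) -> bool:
    """True when ``position`` falls in the exclusion mask."""
    if mask is None:
        mask = default_mask()
    return position in mask


def site_count(region_name: str, convention: SiteCountConvention | str = "paper_table2") -> int:
    """The site count ``L`` for a region under a convention or preset name."""
    if isinstance(convention, str):
        convention = SITE_COUNT_PRESETS[convention]
    return convention.site_count(region_name)


def load_region_config(path=None) -> tuple[dict[str, Region], ExclusionMask]:
    """Load region and mask definitions from a YAML config.

    Without ``path`` the packaged ``data/regions.yaml`` is used.  The schema::

        regions:
          HVI: {intervals: [[16024, 16383]], site_count: 359}
        mask:
          positions: [309, 455, ...]
          ranges: [[16180, 16183], ...]
    """
    if path is None:
        source = resources.files("mitorate").joinpath("data/regions.yaml")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    regions = {
        name: Region(
            name=name,
            intervals=tuple(tuple(iv) for iv in spec["intervals"]),
            site_count=int(spec["site_count"]),
        )
        for name, spec in cfg.get("regions", {}).items()
    }
    mask_cfg = cfg.get("mask", {})
    mask = ExclusionMask(
        positions=frozenset(int(p) for p in mask_cfg.get("positions", [])),
        ranges=tuple(tuple(r) for r in mask_cfg.get("ranges", [])),
    )
    return regions, mask
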