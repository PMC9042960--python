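"""Within-lineage comparison of mtDNA profiles and mutation-event calling.

Each sequenced individual contributes a :class:`SampleProfile`: the set of
differences between their mtDNA consensus and the rCRS reference.  Within a
maternal lineage, a variant carried (homoplasmically) by *every* sequenced
member is taken to be the lineage's ancestral haplotype; any other variant is
a candidate de-novo event.  Candidates survive to countable
:class:`MutationEvent` objects when they

* are not at a masked site (indel hotspots, poly-C tracts),
* if heteroplasmic, have a minor-allele fraction at or above the detection
  threshold (default 20 %), and
* are carried by a proper, non-empty subset of the lineage's members
  (a variant in everyone is ancestral; single-origin parsimony merges the
  same variant seen in several relatives into one event).
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import (
    ExclusionMask,
    MutationCall,
    MutationKind,
    Region,
    classify_call,
    default_mask,
    default_regions,
    region_of,
)
from .pedigree import MaternalLineage

__all__ = [
    "SampleProfile",
    "MutationEvent",
    "FilterDecision",
    "PrevalenceSummary",
    "filter_heteroplasmy",
    "infer_ancestral_profile",
    "detect_mutation_events",
    "heteroplasmy_prevalence",
    "read_variant_table",
    "read_vcf",
    "write_censored_log",
]

logger = logging.getLogger(__name__)

#: Default minor-allele-fraction detection threshold.  Calls at or above the
#: threshold are kept (a "20 % or greater" rule).
DEFAULT_MAF_THRESHOLD = 0.20


class FilterDecision(str, enum.Enum):
    KEEP = "keep"
    CENSOR = "censor"


@dataclass(frozen=True)
class SampleProfile:
    """Differences of one sample's mtDNA from rCRS, at most one per site."""

    sample_id: str
    calls: tuple[MutationCall, ...]

    def __post_init__(self) -> None:
        positions = [c.position for c in self.calls]
        if len(positions) != len(set(positions)):
            raise ValueError(
                f"profile {self.sample_id!r} has multiple calls at one position"
            )

    def call_at(self, position: int) -> MutationCall | None:
        for c in self.calls:
            if c.position == position:
                return c
        return None


@dataclass(frozen=True)
class MutationEvent:
    """A distinct germline change attributed to one maternal lineage."""

    lineage_id: str
    call: MutationCall
    carrier_ids: frozenset[str]
    kind: MutationKind
    regions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.carrier_ids:
            raise ValueError("mutation event must have at least one carrier")

    @property
    def heteroplasmic(self) -> bool:
        return self.kind is MutationKind.POINT_HETEROPLASMY


def filter_heteroplasmy(
    call: MutationCall,
    threshold: float = DEFAULT_MAF_THRESHOLD,
    missing_maf: str = "strict",
) -> FilterDecision:
    """Keep or censor a call under the minor-allele-fraction threshold.

    Homoplasmic calls are always kept.  Heteroplasmic calls are kept when
    ``maf >= threshold`` and censored otherwise.  A heteroplasmic call with
    no recorded MAF raises under ``missing_maf="strict"`` and is kept with a
    warning under ``"lenient"``.
    """
    if not call.heteroplasmic:
        return FilterDecision.KEEP
    if call.maf is None:
        if missing_maf == "strict":
            raise ValueError(
                f"heteroplasmic call {call.label} has no minor-allele fraction"
            )
        if missing_maf == "lenient":
            warnings.warn(
                f"heteroplasmic call {call.label} lacks a MAF; kept",
                stacklevel=2,
            )
            return FilterDecision.KEEP
        raise ValueError(f"invalid missing_maf policy {missing_maf!r}")
    return FilterDecision.KEEP if call.maf >= threshold else FilterDecision.CENSOR


def infer_ancestral_profile(profiles: Sequence[SampleProfile]) -> set[MutationCall]:
    """Variants fixed (homoplasmic) in every member: the lineage haplotype.

    Inference is within-lineage only: a variant shared homoplasmically by all
    sampled members is ancestral even if absent elsewhere.  A single-member
    lineage offers no comparison, so all its calls are ancestral.
    """
    if not profiles:
        raise ValueError("cannot infer ancestry from an empty lineage")
    shared: set[MutationCall] | None = None
    for profile in profiles:
        fixed = {
            MutationCall(c.position, c.ref, c.observed)  # strip maf/confirmed
            for c in profile.calls
            if not c.heteroplasmic
        }
        shared = fixed if shared is None else shared & fixed
    return shared or set()


def detect_mutation_events(
    lineage: MaternalLineage,
    profiles: Mapping[str, SampleProfile] | Sequence[SampleProfile],
    mask: ExclusionMask | None = None,
    threshold: float = DEFAULT_MAF_THRESHOLD,
    regions: Mapping[str, Region] | None = None,
    missing_maf: str = "strict",
    censored_log: list | None = None,
) -> list[MutationEvent]:
    """Call countable mutation events within one maternal lineage.

    ``profiles`` must cover every member of ``lineage``; profiles for
    non-members are ignored with a warning.  Candidates are member calls not
    in the inferred ancestral set; surviving candidates are deduplicated to
    one event per (position, observed code) with the union of carriers
    (single-origin parsimony).  Censored heteroplasmies are appended to
    ``censored_log`` as ``(sample_id, call)`` when a list is supplied.
    """
    if mask is None:
        mask = default_mask()
    if regions is None:
        regions = default_regions()
    if not isinstance(profiles, Mapping):
        # an explicit profile list is expected to match the lineage; a
        # mapping may cover the whole study and is silently subset
        profiles = {p.sample_id: p for p in profiles}
        extraneous = set(profiles) - set(lineage.member_ids)
        if extraneous:
            warnings.warn(
                f"profiles for non-members of lineage {lineage.founder_id}: "
                f"{sorted(extraneous)}; ignored",
                stacklevel=2,
            )
    member_profiles = []
    for member in sorted(lineage.member_ids):
        if member not in profiles:
            raise ValueError(
                f"missing profile for lineage member {member!r}"
            )
        member_profiles.append(profiles[member])

    ancestral = infer_ancestral_profile(member_profiles)
    ancestral_keys = {(c.position, c.observed) for c in ancestral}

    # gather surviving candidate calls per (position, observed)
    carriers: dict[tuple[int, str], set[str]] = {}
    exemplar: dict[tuple[int, str], MutationCall] = {}
    for profile in member_profiles:
        for call in profile.calls:
            key = (call.position, call.observed)
            if key in ancestral_keys:
                continue
            if call.position in mask:
                continue
            if filter_heteroplasmy(call, threshold, missing_maf) is FilterDecision.CENSOR:
                if censored_log is not None:
                    censored_log.append((profile.sample_id, call))
                continue
            carriers.setdefault(key, set()).add(profile.sample_id)
            exemplar.setdefault(key, call)

    events = []
    n_members = len(lineage.member_ids)
    for key in sorted(carriers):
        call = exemplar[key]
        carrier_ids = carriers[key]
        if len(carrier_ids) >= n_members:
            # fixed in all sampled members: ancestral, not an event (this
            # branch is reached by heteroplasmies shared by everyone)
            continue
        events.append(
            MutationEvent(
                lineage_id=lineage.founder_id,
                call=MutationCall(call.position, call.ref, call.observed, maf=call.maf),
                carrier_ids=frozenset(carrier_ids),
                kind=classify_call(call),
                regions=frozenset(region_of(call.position, regions)),
            )
        )
    return events


@dataclass(frozen=True)
class PrevalenceSummary:
    """Genome-wide point-heteroplasmy prevalence figures."""

    het_positions: frozenset[int]
    n_het_individuals: int
    n_individuals: int
    n_het_lineages: int
    n_lineages: int
    n_coding_het_lineages: int

    @property
    def frac_individuals(self) -> float:
        return self.n_het_individuals / self.n_individuals

    @property
    def frac_lineages(self) -> float:
        return self.n_het_lineages / self.n_lineages

    @property
    def frac_coding_lineages(self) -> float:
        return self.n_coding_het_lineages / self.n_lineages


def heteroplasmy_prevalence(
    events: Iterable[MutationEvent],
    n_individuals: int,
    n_lineages: int,
    coding_region_name: str = "coding",
) -> PrevalenceSummary:
    """Summarise how widespread point heteroplasmy is across the study.

    Counts distinct heteroplasmic positions, individuals carrying at least
    one heteroplasmic event, lineages containing such an individual, and the
    same lineage count restricted to coding-region events.
    """
    het = [e for e in events if e.heteroplasmic]
    positions = frozenset(e.call.position for e in het)
    individuals = set()
    lineages = set()
    coding_lineages = set()
    for e in het:
        individuals.update(e.carrier_ids)
        lineages.add(e.lineage_id)
        if coding_region_name in e.regions:
            coding_lineages.add(e.lineage_id)
    return PrevalenceSummary(
        het_positions=positions,
        n_het_individuals=len(individuals),
        n_individuals=n_individuals,
        n_het_lineages=len(lineages),
        n_lineages=n_lineages,
        n_coding_het_lineages=len(coding_lineages),
    )


def read_variant_table(source) -> dict[str, SampleProfile]:
    """Read per-sample variant calls from TSV.

    Columns: ``sample_id``, ``pos``, ``ref``, ``obs`` and optionally
    ``maf``, ``depth``, ``confirmed``.  Returns one profile per sample.
    """
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    required = {"sample_id", "pos", "ref", "obs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    profiles: dict[str, list[MutationCall]] = {}
    for row in df.itertuples(index=False):
        maf = getattr(row, "maf", None)
        maf = None if maf is None or pd.isna(maf) or maf == "" else float(maf)
        confirmed = getattr(row, "confirmed", None)
        if confirmed is not None and not pd.isna(confirmed) and confirmed != "":
            confirmed = str(confirmed).strip().lower() in {"1", "true", "yes"}
        else:
            confirmed = None
        call = MutationCall(
            position=int(row.pos),
            ref=str(row.ref).upper(),
            observed=str(row.obs).upper(),
            maf=maf,
            confirmed=confirmed,
        )
        profiles.setdefault(str(row.sample_id), []).append(call)
    return {
        sid: SampleProfile(sample_id=sid, calls=tuple(calls))
        for sid, calls in profiles.items()
    }


def read_vcf(path) -> dict[str, SampleProfile]:
    """Read biallelic SNVs from a VCF into per-sample profiles.

    Heterozygous genotypes become IUPAC heteroplasmy calls, with the MAF
    taken from the ``AF`` FORMAT field when present.  Indels and multiallelic
    records are skipped.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    iupac_rev = {frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
                 frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M"}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: dict[str, list[MutationCall]] = {s: [] for s in samples}
    for record in vcf:
        if len(record.ALT) != 1:
            continue
        ref, alt = record.REF.upper(), record.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1:
            continue
        try:
            afs = record.format("AF")
        except KeyError:
            afs = None
        for i, gt in enumerate(record.genotypes):
            alleles = set(gt[:-1])
            if alleles == {1}:
                calls[samples[i]].append(MutationCall(record.POS, ref, alt))
            elif alleles == {0, 1}:
                code = iupac_rev[frozenset({ref, alt})]
                maf = float(afs[i][0]) if afs is not None else None
                if maf is not None and maf > 0.5:
                    maf = 1.0 - maf
                calls[samples[i]].append(
                    MutationCall(record.POS, ref, code, maf=maf)
                )
    return {
        s: SampleProfile(sample_id=s, calls=tuple(c))
        for s, c in calls.items()
        if c
    }


def write_censored_log(censored: Sequence[tuple[str, MutationCall]], path) -> pd.DataFrame:
    """Write censored below-threshold calls as a TSV audit log."""
    df = pd.DataFrame(
        {
            "sample_id": [sid for sid, _ in censored],
            "label": [c.label for _, c in censored],
            "pos": [c.position for _, c in censored],
            "maf": [c.maf for _, c in censored],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
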