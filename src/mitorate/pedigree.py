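"""Pedigree ingestion, maternal-lineage extraction and transmission counting.

Mitochondrial DNA is maternally inherited, so the unit of observation for a
pedigree-based mutation-rate estimate is the mother-to-child transmission
("meiosis").  Given a pedigree and the set of sequenced individuals, each
founding mother with at least one sequenced matrilineal descendant defines a
:class:`MaternalLineage`; the denominator of the rate is the number of
distinct mother->child edges on the union of matrilineal paths from each
sequenced member back to the founder.  Using the edge *union* (rather than
summing path lengths per individual) counts each transmission exactly once
even when sampled relatives share ancestors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "MaternalLineage",
    "read_pedigree",
    "maternal_lineages",
    "count_transmissions",
    "write_lineage_table",
]

_MISSING = {"", "0", ".", "NA", "NONE", "NAN"}


@dataclass(frozen=True)
class Individual:
    """One pedigree member."""

    id: str
    mother_id: str | None = None
    father_id: str | None = None
    sex: str = "unknown"  # female / male / unknown
    sequenced: bool = False

    def __post_init__(self) -> None:
        if self.sex not in {"female", "male", "unknown"}:
            raise ValueError(f"invalid sex {self.sex!r} for {self.id}")


class Pedigree:
    """A validated collection of individuals with maternal adjacency.

    Validation enforces: unique ids, no dangling parent references, mothers
    not recorded as male, and acyclic maternal links (the maternal relation
    must form a forest).
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self._members[ind.id] = ind
        self._maternal_children: dict[str, list[str]] = {}
        for ind in self._members.values():
            for parent, role in ((ind.mother_id, "mother"), (ind.father_id, "father")):
                if parent is not None and parent not in self._members:
                    raise ValueError(
                        f"{role} {parent!r} of {ind.id!r} not in pedigree"
                    )
            if ind.mother_id is not None:
                mother = self._members[ind.mother_id]
                if mother.sex == "male":
                    raise ValueError(
                        f"individual {mother.id!r} listed as mother of "
                        f"{ind.id!r} but recorded as male"
                    )
                self._maternal_children.setdefault(mother.id, []).append(ind.id)
        self._check_maternal_acyclic()

    def _check_maternal_acyclic(self) -> None:
        for start in self._members:
            seen = {start}
            current = self._members[start].mother_id
            while current is not None:
                if current in seen:
                    raise ValueError(
                        f"matrilineal cycle detected involving {current!r}"
                    )
                seen.add(current)
                current = self._members[current].mother_id

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __getitem__(self, individual_id: str) -> Individual:
        return self._members[individual_id]

    @property
    def individuals(self) -> Mapping[str, Individual]:
        return self._members

    def maternal_children(self, individual_id: str) -> Sequence[str]:
        """Children connected to ``individual_id`` through the maternal link."""
        return tuple(self._maternal_children.get(individual_id, ()))

    def maternal_founders(self) -> list[str]:
        """Ids of individuals with no recorded mother (matrilineal roots)."""
        return [i.id for i in self._members.values() if i.mother_id is None]

    def matrilineal_descendants(self, individual_id: str) -> set[str]:
        """All descendants reachable through maternal links (excl. self)."""
        out: set[str] = set()
        stack = list(self.maternal_children(individual_id))
        while stack:
            node = stack.pop()
            if node not in out:
                out.add(node)
                stack.extend(self.maternal_children(node))
        return out


@dataclass(frozen=True)
class MaternalLineage:
    """A founding mother plus the matrilineal descent of her sequenced kin.

    ``edges`` is the union of mother->child pairs on the paths from each
    sequenced member up to the founder; unsequenced intermediate mothers
    contribute their edges exactly once.  ``n_transmissions`` is ``|edges|``.
    """

    founder_id: str
    member_ids: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @property
    def n_transmissions(self) -> int:
        return len(self.edges)


def _parse_sequenced(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "y", "t", "2"}:  # PED phenotype "2" = affected
        return True
    if s in {"0", "false", "no", "n", "f", "-9", ""}:
        return False
    raise ValueError(f"cannot interpret sequenced flag {value!r}")


_SEX_CODES = {
    "1": "male",
    "2": "female",
    "m": "male",
    "f": "female",
    "male": "male",
    "female": "female",
    "0": "unknown",
    "u": "unknown",
    "unknown": "unknown",
}


def read_pedigree(source) -> Pedigree:
    """Read a pedigree from a PED-like TSV.

    Accepts either the native header (``id``, ``mother``, ``father``,
    ``sex``, ``sequenced``) or the PED dialect (``FID``/``IID``/``PAT``/
    ``MAT``/``SEX`` plus an optional ``sequenced`` column).  Tab- or
    whitespace-delimited; lines starting with ``#`` are comments.  Missing
    parents are coded as ``0``, ``.``, ``NA`` or empty, and mark founders.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep=r"\s+", comment="#", dtype=str)
    elif isinstance(source, io.IOBase):
        df = pd.read_csv(source, sep=r"\s+", comment="#", dtype=str)
    else:
        df = pd.DataFrame(source, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "iid" in cols:  # PED dialect
        rename = {"iid": "id", "mat": "mother", "pat": "father", "sex": "sex"}
    else:
        rename = {}
    df = df.rename(columns={cols[k]: v for k, v in rename.items() if k in cols})
    df.columns = [c.lower() for c in df.columns]
    required = {"id", "mother", "father", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pedigree table missing columns: {sorted(missing)}")

    def norm_parent(v) -> str | None:
        if pd.isna(v) or str(v).strip().upper() in _MISSING:
            return None
        return str(v).strip()

    individuals = []
    for row in df.itertuples(index=False):
        sex_raw = str(row.sex).strip().lower()
        if sex_raw not in _SEX_CODES:
            raise ValueError(f"invalid sex code {row.sex!r} for {row.id!r}")
        individuals.append(
            Individual(
                id=str(row.id).strip(),
                mother_id=norm_parent(row.mother),
                father_id=norm_parent(row.father),
                sex=_SEX_CODES[sex_raw],
                sequenced=_parse_sequenced(getattr(row, "sequenced", False)),
            )
        )
    return Pedigree(individuals)


def _path_to_founder(ped: Pedigree, individual_id: str, founder_id: str) -> list[tuple[str, str]] | None:
    """Mother->child edges from ``founder_id`` down to ``individual_id``."""
    edges: list[tuple[str, str]] = []
    current = individual_id
    while current != founder_id:
        mother = ped[current].mother_id
        if mother is None:
            return None
        edges.append((mother, current))
        current = mother
    return edges


def maternal_lineages(
    ped: Pedigree, founders: Sequence[str] | None = None
) -> list[MaternalLineage]:
    """Extract one lineage per founding mother with sequenced matrilineal kin.

    Members are the sequenced matrilineal descendants of the founder (plus
    the founder herself when sequenced); males are members when sequenced but
    never transmit.  When ``founders`` is given, only those ids are used
    (each must exist); otherwise every matrilineal root is considered and
    roots with no sequenced matrilineal descendants are dropped.
    """
    if founders is None:
        # auto-discovered founders are founding mothers: male roots cannot
        # head a maternal lineage
        candidate_ids = [f for f in ped.maternal_founders() if ped[f].sex != "male"]
    else:
        for fid in founders:
            if fid not in ped:
                raise KeyError(f"requested founder {fid!r} not in pedigree")
        candidate_ids = list(founders)

    lineages = []
    for fid in candidate_ids:
        descendants = ped.matrilineal_descendants(fid)
        members = {i for i in descendants if ped[i].sequenced}
        if ped[fid].sequenced:
            members.add(fid)
        if not members:
            continue
        edges: set[tuple[str, str]] = set()
        for member in members:
            path = _path_to_founder(ped, member, fid)
            if path is not None:
                edges.update(path)
        lineages.append(
            MaternalLineage(
                founder_id=fid,
                member_ids=frozenset(members),
                edges=frozenset(edges),
            )
        )
    return sorted(lineages, key=lambda l: l.founder_id)


def count_transmissions(lineage: MaternalLineage) -> int:
    """Number of meioses observed in a lineage (distinct path edges)."""
    return lineage.n_transmissions


def write_lineage_table(lineages: Iterable[MaternalLineage], path=None) -> pd.DataFrame:
    """Tabulate lineages (founder, members, meioses); optionally write TSV."""
    df = pd.DataFrame(
        {
            "founder": [l.founder_id for l in lineages],
            "n_individuals": [len(l.member_ids) for l in lineages],
            "n_meioses": [l.n_transmissions for l in lineages],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
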