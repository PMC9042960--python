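"""Bundled study fixtures and their expansion into pipeline input files.

Two fixtures ship with the package:

* ``table1_lineages.tsv`` -- the 45-maternal-lineage summary of the study
  pedigree (meioses, individuals, mutation labels with carrier counts, and
  the three censored below-threshold heteroplasmies).  Totals: 345 meioses,
  225 sequenced individuals, 9 mutation events.
* ``table3_published_rates.tsv`` -- published mtDNA rates in their native
  units for cross-study standardization.

:func:`expand_lineage_fixture` turns the per-lineage summary into a concrete
pedigree table and per-sample variant table with exactly the summarised
meioses, member counts and mutation carriers, so the full pipeline (pedigree
reading, lineage extraction, event detection, rate estimation) can be run
end to end.  Each expanded lineage is either

* an unsequenced founding mother, a chain of ``m - s`` unsequenced
  intermediate mothers and ``s`` sequenced leaves hanging off the end of the
  chain (when meioses ``m`` >= sequenced count ``s``), or
* a fully sequenced mother-to-child chain (when ``m == s - 1``).

Both shapes have an edge-union of exactly ``m`` transmissions.  Every
sequenced individual additionally carries the lineage's ancestral haplotype
(homoplasmic A73G and A263G) so ancestral-profile inference is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO
from pathlib import Path

import pandas as pd

from .genome import parse_mutation_label

__all__ = [
    "load_table1_lineages",
    "load_table3_path",
    "expand_lineage_fixture",
    "FixtureFiles",
]

#: Homoplasmic variants shared by all members of every expanded lineage
#: (a minimal ancestral haplotype; both are common control-region variants).
ANCESTRAL_LABELS = ("A73G", "A263G")


def _data_path(name: str):
    return resources.files("mitorate").joinpath(f"data/{name}")


def load_table1_lineages() -> pd.DataFrame:
    """The per-lineage fixture as a DataFrame.

    Columns: ``lineage_id``, ``n_meioses``, ``n_individuals``, ``mutations``
    (semicolon-separated ``label:carriers[:maf]``), ``censored``
    (semicolon-separated ``label:maf``).
    """
    text = _data_path("table1_lineages.tsv").read_text()
    df = pd.read_csv(
        StringIO(text), sep="\t", comment="#", dtype={"lineage_id": str}
    )
    df["mutations"] = df["mutations"].fillna("")
    df["censored"] = df["censored"].fillna("")
    return df


def load_table3_path() -> str:
    """Filesystem path of the bundled published-rates TSV."""
    return str(_data_path("table3_published_rates.tsv"))


@dataclass(frozen=True)
class FixtureFiles:
    """In-memory pipeline inputs expanded from the lineage fixture."""

    pedigree: pd.DataFrame
    variants: pd.DataFrame

    def write(self, directory) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ped_path = directory / "pedigree.tsv"
        var_path = directory / "variants.tsv"
        self.pedigree.to_csv(ped_path, sep="\t", index=False)
        self.variants.to_csv(var_path, sep="\t", index=False)
        return ped_path, var_path


def _parse_mutation_field(value: str) -> list[tuple[str, int, float | None]]:
    out = []
    for chunk in filter(None, (c.strip() for c in value.split(";"))):
        parts = chunk.split(":")
        label, carriers = parts[0], int(parts[1])
        maf = float(parts[2]) if len(parts) > 2 else None
        out.append((label, carriers, maf))
    return out


def _parse_censored_field(value: str) -> list[tuple[str, float]]:
    out = []
    for chunk in filter(None, (c.strip() for c in value.split(";"))):
        label, maf = chunk.split(":")
        out.append((label, float(maf)))
    return out


def expand_lineage_fixture(summary: pd.DataFrame | None = None) -> FixtureFiles:
    """Expand the lineage summary into pedigree and variant tables."""
    if summary is None:
        summary = load_table1_lineages()

    ped_rows: list[dict] = []
    var_rows: list[dict] = []

    for row in summary.itertuples(index=False):
        lid = str(row.lineage_id)
        m, s = int(row.n_meioses), int(row.n_individuals)
        founder = f"L{lid}_F"
        sequenced: list[str] = []

        if m >= s:
            # caterpillar: unsequenced founder + chain of m - s unsequenced
            # mothers, with all sequenced leaves on the last chain node
            ped_rows.append(
                {"id": founder, "mother": "0", "father": "0",
                 "sex": "female", "sequenced": 0}
            )
            attach = founder
            for i in range(m - s):
                node = f"L{lid}_I{i + 1}"
                ped_rows.append(
                    {"id": node, "mother": attach, "father": "0",
                     "sex": "female", "sequenced": 0}
                )
                attach = node
            for i in range(s):
                node = f"L{lid}_S{i + 1}"
                ped_rows.append(
                    {"id": node, "mother": attach, "father": "0",
                     "sex": "female" if i % 2 == 0 else "male", "sequenced": 1}
                )
                sequenced.append(node)
        elif m == s - 1:
            # fully sequenced matrilineal chain headed by a sequenced founder
            ped_rows.append(
                {"id": founder, "mother": "0", "father": "0",
                 "sex": "female", "sequenced": 1}
            )
            attach = founder
            for i in range(s - 1):
                node = f"L{lid}_S{i + 1}"
                sex = "female" if i < s - 2 else "male"
                ped_rows.append(
                    {"id": node, "mother": attach, "father": "0",
                     "sex": sex, "sequenced": 1}
                )
                sequenced.append(node)
                attach = node
            sequenced.append(founder)  # founder last: carriers stay derived
        else:
            raise ValueError(
                f"lineage {lid}: {m} meioses cannot support {s} sequenced "
                "members (need m >= s - 1)"
            )

        # per-sample calls: ancestral haplotype everywhere
        calls: dict[str, list[tuple[str, float | None]]] = {
            sid: [(lab, None) for lab in ANCESTRAL_LABELS] for sid in sequenced
        }
        cursor = 0
        for label, carriers, maf in _parse_mutation_field(row.mutations):
            for _ in range(carriers):
                calls[sequenced[cursor]].append((label, maf))
                cursor += 1
        for label, maf in _parse_censored_field(row.censored):
            calls[sequenced[cursor]].append((label, maf))
            cursor += 1

        for sid, sample_calls in calls.items():
            for label, maf in sample_calls:
                call = parse_mutation_label(label)
                var_rows.append(
                    {
                        "sample_id": sid,
                        "pos": call.position,
                        "ref": call.ref,
                        "obs": call.observed,
                        "maf": "" if maf is None else maf,
                        "depth": "",
                        "confirmed": "",
                    }
                )

    return FixtureFiles(
        pedigree=pd.DataFrame(ped_rows),
        variants=pd.DataFrame(var_rows),
    )
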