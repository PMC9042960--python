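import io

import pytest

from mitorate import (
    detect_mutation_events,
    heteroplasmy_prevalence,
    maternal_lineages,
    read_pedigree,
    read_variant_table,
)
from mitorate.fixtures import expand_lineage_fixture


@pytest.fixture(scope="session")
def study():
    """The bundled 45-lineage study fixture, run through the full pipeline."""
    files = expand_lineage_fixture()
    ped = read_pedigree(io.StringIO(files.pedigree.to_csv(sep="\t", index=False)))
    profiles = read_variant_table(
        io.StringIO(files.variants.to_csv(sep="\t", index=False))
    )
    lineages = maternal_lineages(ped)
    events, censored = [], []
    for lineage in lineages:
        events.extend(
            detect_mutation_events(lineage, profiles, censored_log=censored)
        )
    prevalence = heteroplasmy_prevalence(
        events, n_individuals=len(profiles), n_lineages=len(lineages)
    )
    return {
        "pedigree": ped,
        "profiles": profiles,
        "lineages": lineages,
        "events": events,
        "censored": censored,
        "prevalence": prevalence,
    }
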