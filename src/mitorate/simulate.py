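"""Matrilineal pedigree and mtDNA transmission simulator with known truth.

The generator is the generative inverse of the rate estimator: maternal
lineages are grown as branching processes, each mother-to-child transmission
receives ``Poisson(mu * L)`` new mutations at uniformly chosen unmasked
sites, a fraction ``p_het`` of mutations present as point heteroplasmy with
a drawn minor-allele fraction, and heteroplasmies below the detection
threshold are censored exactly as the pipeline would censor them.  Every
simulated mutation is recorded in a :class:`TruthLog` with a ``detected``
flag precomputed from the generative model, so end-to-end runs of the
pipeline can be checked replicate by replicate.

Modelling choices: heteroplasmy is single-generation presentation (the
drawn MAF applies to the carrier only; no bottleneck-drift model), and a
homoplasmic mutation is inherited by all matrilineal descendants of its
carrier.  A ``maf_transition`` hook allows a user-supplied MAF drift
function for extensions.  Positions within a lineage are drawn without
replacement, a negligible deviation from the Poisson field at realistic
``mu * L`` (the simulator warns when multiple hits become likely).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .detection import (
    DEFAULT_MAF_THRESHOLD,
    SampleProfile,
    detect_mutation_events,
)
from .genome import (
    MT_GENOME_LENGTH,
    MutationCall,
    default_mask,
)
from .pedigree import Individual, MaternalLineage, Pedigree, maternal_lineages
from .rates import binomial_ci, mutation_rate

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "TruthLog",
    "simulate_pedigree",
    "simulate_transmissions",
    "recovery_experiment",
    "RecoveryReport",
]

_COMPLEMENTS = {"A": "G", "G": "A", "C": "T", "T": "C"}  # transition partner
_IUPAC_FOR_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_REF_BASE_CYCLE = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the simulator.

    Defaults mirror the design of the motivating study: 45 maternal
    lineages sampled over the most recent four generations, a per-site
    per-transmission mutation rate of 1.57e-6 over 16,596 analysable sites,
    7 of 9 events presenting as heteroplasmy, and a 20 % detection
    threshold.  ``maf_distribution`` is uniform on (0.05, 0.95).
    """

    n_lineages: int = 45
    n_generations: int = 6
    mean_offspring: float = 2.0
    p_female: float = 0.5
    sequenced_generations: int = 4
    p_sequenced: float = 0.5
    mu: float = 1.57e-6
    L: int = 16596
    p_het: float = 7.0 / 9.0
    maf_low: float = 0.05
    maf_high: float = 0.95
    threshold: float = DEFAULT_MAF_THRESHOLD
    n_ancestral_variants: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_female", "p_sequenced", "p_het", "threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.n_lineages <= 0 or self.n_generations <= 0:
            raise ValueError("need at least one lineage and one generation")
        if not 0 <= self.maf_low < self.maf_high <= 1:
            raise ValueError("invalid MAF distribution bounds")


@dataclass(frozen=True)
class TruthRecord:
    """One simulated germline mutation and its fate."""

    lineage_id: str
    edge: tuple[str, str]
    position: int
    label: str
    heteroplasmic: bool
    maf: float | None
    detected: bool


@dataclass
class TruthLog:
    records: list[TruthRecord] = field(default_factory=list)

    @property
    def n_detected(self) -> int:
        return sum(r.detected for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lineage_id": [r.lineage_id for r in self.records],
                "mother": [r.edge[0] for r in self.records],
                "child": [r.edge[1] for r in self.records],
                "pos": [r.position for r in self.records],
                "label": [r.label for r in self.records],
                "heteroplasmic": [r.heteroplasmic for r in self.records],
                "maf": [r.maf for r in self.records],
                "detected": [r.detected for r in self.records],
            }
        )


def simulate_pedigree(cfg: SimulationConfig, seed: int | None = None) -> Pedigree:
    """Grow a forest of matrilineal trees.

    Each lineage starts from one founding mother; every female has
    ``Poisson(mean_offspring)`` children, each female with probability
    ``p_female``.  Individuals born in the last ``sequenced_generations``
    generations are sequenced with probability ``p_sequenced`` (the founder
    counts as generation 1).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    individuals: list[Individual] = []
    first_seq_gen = max(1, cfg.n_generations - cfg.sequenced_generations + 1)

    def is_sequenced(generation: int) -> bool:
        if generation < first_seq_gen:
            return False
        return bool(rng.random() < cfg.p_sequenced)

    for li in range(cfg.n_lineages):
        founder_id = f"L{li}_G1_0"
        individuals.append(
            Individual(
                id=founder_id,
                sex="female",
                sequenced=is_sequenced(1),
            )
        )
        mothers = [founder_id]
        counter = 0
        for gen in range(2, cfg.n_generations + 1):
            next_mothers = []
            for mother in mothers:
                for _ in range(rng.poisson(cfg.mean_offspring)):
                    counter += 1
                    child_id = f"L{li}_G{gen}_{counter}"
                    female = bool(rng.random() < cfg.p_female)
                    individuals.append(
                        Individual(
                            id=child_id,
                            mother_id=mother,
                            sex="female" if female else "male",
                            sequenced=is_sequenced(gen),
                        )
                    )
                    if female:
                        next_mothers.append(child_id)
            mothers = next_mothers
            if not mothers:
                break
    return Pedigree(individuals)


def _random_call(
    position: int, rng: np.random.Generator, heteroplasmic: bool, maf: float | None
) -> MutationCall:
    ref = _REF_BASE_CYCLE[rng.integers(4)]
    alt = _COMPLEMENTS[ref]  # transitions, the dominant mtDNA mutation class
    if heteroplasmic:
        code = _IUPAC_FOR_PAIR[frozenset({ref, alt})]
        return MutationCall(position, ref, code, maf=maf)
    return MutationCall(position, ref, alt)


def simulate_transmissions(
    ped: Pedigree,
    cfg: SimulationConfig,
    seed: int | None = None,
    maf_transition: Callable[[float], float] | None = None,
) -> tuple[dict[str, SampleProfile], TruthLog]:
    """Drop mutations on every mother-to-child edge and build profiles.

    Returns profiles for sequenced individuals plus the complete
    :class:`TruthLog`.  A record's ``detected`` flag anticipates the
    pipeline: the mutation must survive the MAF threshold and be carried by
    a non-empty proper subset of the sequenced members of its lineage.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mask = default_mask()
    allowed = np.array(
        [p for p in range(1, MT_GENOME_LENGTH + 1) if p not in mask]
    )
    all_edges = [
        (lineage, mother, child)
        for lineage in _all_lineages(ped)
        for mother, child in lineage_edges(ped, lineage)
    ]
    if cfg.mu * cfg.L * max(1, len(all_edges)) > 0.1 * len(allowed):
        warnings.warn(
            "mu*L*T approaches the number of analysable sites; multiple hits "
            "per site are likely and are not modelled",
            stacklevel=2,
        )

    truth = TruthLog()
    # calls carried per individual: position -> (call, hom?)
    carried: dict[str, dict[int, MutationCall]] = {i: {} for i in ped.individuals}

    # ancestral haplotypes: distinct per lineage, shared by all members
    lineage_of: dict[str, str] = {}
    for lineage in _all_lineages(ped):
        members = {lineage.founder_id} | ped.matrilineal_descendants(lineage.founder_id)
        used_positions: set[int] = set()
        anc_positions = rng.choice(
            allowed, size=min(cfg.n_ancestral_variants, allowed.size), replace=False
        )
        anc_calls = []
        for pos in anc_positions:
            anc_calls.append(_random_call(int(pos), rng, heteroplasmic=False, maf=None))
            used_positions.add(int(pos))
        for member in members:
            lineage_of[member] = lineage.founder_id
            for call in anc_calls:
                carried[member][call.position] = call

        sequenced_members = {m for m in members if ped[m].sequenced}
        # walk edges top-down so homoplasmic inheritance accumulates
        for mother, child in _edges_topdown(ped, lineage.founder_id):
            # child inherits mother's homoplasmic variants
            for pos, call in carried[mother].items():
                if not call.heteroplasmic:
                    carried[child].setdefault(pos, call)
            n_new = rng.poisson(cfg.mu * cfg.L)
            for _ in range(n_new):
                free = np.setdiff1d(allowed, np.fromiter(used_positions, int, len(used_positions)), assume_unique=False) if used_positions else allowed
                pos = int(rng.choice(free))
                used_positions.add(pos)
                het = bool(rng.random() < cfg.p_het)
                maf = None
                if het:
                    maf = float(rng.uniform(cfg.maf_low, cfg.maf_high))
                    if maf_transition is not None:
                        maf = maf_transition(maf)
                call = _random_call(pos, rng, heteroplasmic=het, maf=maf)
                carried[child][pos] = call
                if het:
                    carriers = {child} if ped[child].sequenced else set()
                else:
                    descendants = ped.matrilineal_descendants(child) | {child}
                    carriers = {d for d in descendants if ped[d].sequenced}
                detected = (
                    bool(carriers)
                    and carriers != sequenced_members
                    and (not het or maf >= cfg.threshold)
                )
                truth.records.append(
                    TruthRecord(
                        lineage_id=lineage.founder_id,
                        edge=(mother, child),
                        position=pos,
                        label=call.label,
                        heteroplasmic=het,
                        maf=maf,
                        detected=detected,
                    )
                )

    profiles = {
        ind_id: SampleProfile(
            sample_id=ind_id, calls=tuple(sorted(carried[ind_id].values(), key=lambda c: c.position))
        )
        for ind_id, ind in ped.individuals.items()
        if ind.sequenced
    }
    return profiles, truth


def _all_lineages(ped: Pedigree) -> list[MaternalLineage]:
    """Lineages over *all* matrilineal roots (not only those with sequenced
    members), needed so mutations are simulated on every edge."""
    out = []
    for fid in ped.maternal_founders():
        if ped[fid].sex == "male":
            continue
        descendants = ped.matrilineal_descendants(fid)
        members = {m for m in descendants | {fid} if ped[m].sequenced}
        edges = set(_edges_topdown(ped, fid))
        out.append(
            MaternalLineage(
                founder_id=fid,
                member_ids=frozenset(members),
                edges=frozenset(edges),
            )
        )
    return out


def _edges_topdown(ped: Pedigree, founder_id: str) -> list[tuple[str, str]]:
    edges = []
    stack = [founder_id]
    while stack:
        node = stack.pop()
        for child in sorted(ped.maternal_children(node)):
            edges.append((node, child))
            stack.append(child)
    return edges


def lineage_edges(ped: Pedigree, lineage: MaternalLineage) -> list[tuple[str, str]]:
    """All mother->child edges below a lineage founder (in top-down order)."""
    return _edges_topdown(ped, lineage.founder_id)


@dataclass(frozen=True)
class RecoveryReport:
    """Monte-Carlo summary of estimator recovery."""

    n_replicates: int
    true_mu: float
    true_detectable_mu: float
    mean_rate_per_generation: float
    sd_rate_per_generation: float
    relative_bias: float
    mc_error_relative: float
    coverage: dict[str, float]
    mean_events: float
    mean_transmissions: float

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "true_mu": self.true_mu,
            "true_detectable_mu": self.true_detectable_mu,
            "mean_rate_per_generation": self.mean_rate_per_generation,
            "sd_rate_per_generation": self.sd_rate_per_generation,
            "relative_bias": self.relative_bias,
            "mc_error_relative": self.mc_error_relative,
            "coverage": dict(self.coverage),
            "mean_events": self.mean_events,
            "mean_transmissions": self.mean_transmissions,
        }


def detectable_fraction(cfg: SimulationConfig) -> float:
    """Analytic probability that a new mutation is detectable.

    Censoring removes heteroplasmies with MAF below the threshold; under the
    uniform MAF model that is ``p_het * (threshold - low) / (high - low)``
    (clipped to the support).
    """
    below = (min(max(cfg.threshold, cfg.maf_low), cfg.maf_high) - cfg.maf_low) / (
        cfg.maf_high - cfg.maf_low
    )
    if cfg.threshold > cfg.maf_high:
        below = 1.0
    return 1.0 - cfg.p_het * below


def recovery_experiment(
    cfg: SimulationConfig,
    n_replicates: int = 200,
    seed: int | None = None,
    conf: float = 0.95,
) -> RecoveryReport:
    """Simulate, run the full pipeline, and score estimator recovery.

    Per replicate: a fresh pedigree and transmissions are simulated, the
    pipeline (lineage extraction, within-lineage event detection) is run on
    the sequenced profiles, and the per-generation rate ``x / (n * L)`` is
    computed from detected events over observed transmissions.  The report
    gives the estimator's relative bias against the analytically detectable
    rate and the empirical coverage of the Clopper-Pearson and Wilson
    intervals for that rate.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    target = cfg.mu * detectable_fraction(cfg)
    rates = np.empty(n_replicates)
    covered = {"clopper_pearson": 0, "wilson": 0}
    events_seen = np.empty(n_replicates)
    transmissions = np.empty(n_replicates)

    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        ped = simulate_pedigree(cfg, seed=rep_seed)
        profiles, _ = simulate_transmissions(ped, cfg, seed=rep_seed + 1)
        lineages = maternal_lineages(ped)
        x = 0
        n = 0
        for lineage in lineages:
            n += lineage.n_transmissions
            events = detect_mutation_events(
                lineage, profiles, threshold=cfg.threshold
            )
            x += len(events)
        if n == 0:
            raise RuntimeError("simulated pedigree has no observed transmissions")
        rates[rep] = x / (n * cfg.L)
        events_seen[rep] = x
        transmissions[rep] = n
        for method in covered:
            low, high = binomial_ci(x, n * cfg.L, method=method, conf=conf)
            if low <= target <= high:
                covered[method] += 1

    mean_rate = float(rates.mean())
    sd_rate = float(rates.std(ddof=1))
    rel_bias = (mean_rate - target) / target if target > 0 else float("nan")
    mc_err = sd_rate / target / np.sqrt(n_replicates) if target > 0 else float("nan")
    return RecoveryReport(
        n_replicates=n_replicates,
        true_mu=cfg.mu,
        true_detectable_mu=target,
        mean_rate_per_generation=mean_rate,
        sd_rate_per_generation=sd_rate,
        relative_bias=float(rel_bias),
        mc_error_relative=float(mc_err),
        coverage={k: v / n_replicates for k, v in covered.items()},
        mean_events=float(events_seen.mean()),
        mean_transmissions=float(transmissions.mean()),
    )
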