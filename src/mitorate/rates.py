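"""Mutation-rate point estimates, binomial confidence intervals, and
cross-study rate standardization.

The pedigree estimator is a simple count ratio: with ``x`` mutation events
observed over ``n`` mother-to-child transmissions at ``L`` analysable sites,

    rate per site per generation  = x / (n * L)
    rate per site per Myr         = x * 1e6 / (n * L * g)

where ``g`` is the mean maternal generation interval in years (26.9 for the
primary estimates here).  Uncertainty treats the ``n * L`` site-transmissions
as independent Bernoulli trials; Clopper-Pearson (exact, beta quantiles) and
Wilson (score) intervals on the proportion are then scaled by ``1e6 / g`` to
the per-Myr scale.

Published rates come in several unit conventions; :func:`standardize_published_rate`
re-expresses them as mutations/site/Myr under a common generation time
(25 years by convention for cross-study tables), recomputing from raw counts
whenever a study's counts are available.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .detection import MutationEvent
from .genome import SITE_COUNT_PRESETS, SiteCountConvention, _REGION_INTERVALS
from .pedigree import MaternalLineage

__all__ = [
    "RateEstimate",
    "PublishedRate",
    "RateUnits",
    "mutation_rate",
    "binomial_ci",
    "rate_with_ci",
    "rate_table",
    "standardize_published_rate",
    "read_published_rates",
    "round_half_up",
]

#: Mean maternal generation interval (years) used for the primary estimates.
DEFAULT_GENERATION_YEARS = 26.9
#: Generation time used when standardizing across studies.
STANDARD_GENERATION_YEARS = 25.0


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Round half away from zero, as rate tables are conventionally printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RateEstimate:
    """A per-region mutation-rate estimate with confidence intervals.

    ``ci`` maps method name to a ``(low, high)`` pair in mutations/site/Myr.
    """

    region: str
    x: int
    n_transmissions: int
    site_count: int
    generation_years: float
    rate_per_generation: float
    rate_per_myr: float
    ci: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    include_heteroplasmy: bool = True

    def __post_init__(self) -> None:
        for method, (low, high) in self.ci.items():
            if low < 0:
                raise ValueError(f"{method} lower bound negative")
            if not (low <= self.rate_per_myr <= high):
                raise ValueError(
                    f"{method} interval ({low}, {high}) does not bracket "
                    f"point estimate {self.rate_per_myr}"
                )


def mutation_rate(
    x: int,
    n: int,
    L: int,
    g: float = DEFAULT_GENERATION_YEARS,
) -> RateEstimate:
    """Point estimate from ``x`` events over ``n`` transmissions, ``L`` sites."""
    if n <= 0 or L <= 0 or g <= 0:
        raise ValueError("transmissions, site count and generation time must be > 0")
    if x < 0:
        raise ValueError("event count cannot be negative")
    per_gen = x / (n * L)
    return RateEstimate(
        region="",
        x=x,
        n_transmissions=n,
        site_count=L,
        generation_years=g,
        rate_per_generation=per_gen,
        rate_per_myr=per_gen * 1e6 / g,
    )


def binomial_ci(
    x: int,
    n_trials: int,
    method: str = "clopper_pearson",
    conf: float = 0.95,
) -> tuple[float, float]:
    """95 % (by default) confidence interval for a binomial proportion.

    ``clopper_pearson`` is the exact interval from beta-distribution
    quantiles (lower bound 0 at ``x = 0``, upper bound 1 at ``x = n``);
    ``wilson`` is the closed-form score interval.
    """
    if not 0 < conf < 1:
        raise ValueError(f"confidence level {conf} outside (0, 1)")
    if not 0 <= x <= n_trials:
        raise ValueError(f"count x={x} outside [0, n={n_trials}]")
    alpha = 1.0 - conf
    if method == "clopper_pearson":
        low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n_trials - x + 1))
        high = (
            1.0
            if x == n_trials
            else float(stats.beta.ppf(1 - alpha / 2, x + 1, n_trials - x))
        )
        return low, high
    if method == "wilson":
        z = float(stats.norm.ppf(1 - alpha / 2))
        p = x / n_trials
        denom = 1 + z * z / n_trials
        centre = p + z * z / (2 * n_trials)
        half = z * math.sqrt(p * (1 - p) / n_trials + z * z / (4 * n_trials**2))
        # centre == half analytically at the boundaries; avoid fp residue
        low = 0.0 if x == 0 else max(0.0, (centre - half) / denom)
        high = 1.0 if x == n_trials else min(1.0, (centre + half) / denom)
        return low, high
    raise ValueError(f"unknown CI method {method!r}")


def rate_with_ci(
    x: int,
    n: int,
    L: int,
    g: float = DEFAULT_GENERATION_YEARS,
    methods: Sequence[str] = ("clopper_pearson", "wilson"),
    conf: float = 0.95,
    trials: str = "site_transmissions",
) -> RateEstimate:
    """Point estimate plus confidence intervals on the per-Myr scale.

    With ``trials="site_transmissions"`` (default) the binomial proportion is
    taken over ``n * L`` trials and the interval scaled by ``1e6 / g``; with
    ``trials="transmissions"`` the proportion is per transmission (``n``
    trials) and the interval scaled by ``1e6 / (L * g)``.
    """
    est = mutation_rate(x, n, L, g)
    if trials == "site_transmissions":
        n_trials, scale = n * L, 1e6 / g
    elif trials == "transmissions":
        n_trials, scale = n, 1e6 / (L * g)
    else:
        raise ValueError(f"unknown trials convention {trials!r}")
    ci = {
        m: tuple(bound * scale for bound in binomial_ci(x, n_trials, m, conf))
        for m in methods
    }
    return RateEstimate(
        region=est.region,
        x=x,
        n_transmissions=n,
        site_count=L,
        generation_years=g,
        rate_per_generation=est.rate_per_generation,
        rate_per_myr=est.rate_per_myr,
        ci=ci,
    )


def _range_label(region: str) -> str:
    ivals = _REGION_INTERVALS.get(region)
    if ivals is None:
        return ""
    return " and ".join(f"{a}–{b}" for a, b in ivals)


REPORT_REGIONS = ("mtGenome", "HVI", "HVII", "HVI_HVII", "control", "coding")


def rate_table(
    events: Iterable[MutationEvent],
    lineages: Sequence[MaternalLineage] | int,
    convention: SiteCountConvention | str = "paper_table2",
    g: float = DEFAULT_GENERATION_YEARS,
    include_heteroplasmy: bool = True,
    methods: Sequence[str] = ("clopper_pearson", "wilson"),
    regions: Sequence[str] = REPORT_REGIONS,
) -> pd.DataFrame:
    """Per-region rate report.

    ``lineages`` may be the extracted lineage list (transmissions are summed)
    or a pre-computed total transmission count.  One row per region with
    event counts split by kind, the point estimate on both scales, and the
    requested confidence intervals (per Myr).
    """
    if isinstance(convention, str):
        convention = SITE_COUNT_PRESETS[convention]
    n = (
        lineages
        if isinstance(lineages, int)
        else sum(l.n_transmissions for l in lineages)
    )
    events = list(events)
    rows = []
    for region in regions:
        L = convention.site_count(region)
        in_region = [e for e in events if region in e.regions]
        x_sub = sum(1 for e in in_region if not e.heteroplasmic)
        x_het = sum(1 for e in in_region if e.heteroplasmic)
        x = x_sub + x_het if include_heteroplasmy else x_sub
        est = rate_with_ci(x, n, L, g, methods=methods)
        row = {
            "region": region,
            "range_label": _range_label(region),
            "x_sub": x_sub,
            "x_het": x_het,
            "x": x,
            "n": n,
            "L": L,
            "g": g,
            "rate_per_gen": est.rate_per_generation,
            "rate_per_myr": est.rate_per_myr,
        }
        for method in methods:
            short = {"clopper_pearson": "cp", "wilson": "wilson"}.get(method, method)
            row[f"{short}_low"], row[f"{short}_high"] = est.ci[method]
        rows.append(row)
    return pd.DataFrame(rows)


class RateUnits(str, enum.Enum):
    PER_SITE_PER_GENERATION = "per_site_per_generation"
    PER_SITE_PER_YEAR = "per_site_per_year"
    PER_SITE_PER_MYR = "per_site_per_Myr"


@dataclass(frozen=True)
class PublishedRate:
    """A literature mutation rate in its native units.

    When the study's raw counts are available (``transmissions`` together
    with ``n_sub``/``n_het``), standardization recomputes the rate from the
    counts rather than rescaling the reported value.
    """

    study: str
    value: float | None
    units: RateUnits | str | None
    region: str | None = None
    method: str | None = None  # pedigree / phylogenetic / aDNA
    seq_range: str | None = None
    transmissions: int | None = None
    n_sub: int | None = None
    n_het: int | None = None
    generation_years: float | None = None

    @property
    def total_mutations(self) -> int | None:
        if self.n_sub is None and self.n_het is None:
            return None
        return (self.n_sub or 0) + (self.n_het or 0)

    @property
    def has_counts(self) -> bool:
        return self.transmissions is not None and self.total_mutations is not None


def standardize_published_rate(
    pr: PublishedRate,
    target_g: float = STANDARD_GENERATION_YEARS,
    convention: SiteCountConvention | str = "paper_table2",
) -> float:
    """Re-express a published rate as mutations/site/Myr at ``target_g`` years.

    Conversion rules:

    * counts available -> ``total * 1e6 / (transmissions * L * target_g)``
      with ``L`` from the convention for the study's region (takes
      precedence over any reported value);
    * per site per generation -> ``value / target_g * 1e6``;
    * per site per year -> ``value * 1e6`` (generation-free);
    * per site per Myr -> ``value * generation_years / target_g`` (identity
      when the study already assumed ``target_g``).
    """
    if isinstance(convention, str):
        convention = SITE_COUNT_PRESETS[convention]
    if pr.has_counts:
        L = convention.site_count(pr.region)
        return pr.total_mutations * 1e6 / (pr.transmissions * L * target_g)
    if pr.value is None:
        raise ValueError(f"study {pr.study!r} has neither counts nor a reported value")
    units = RateUnits(pr.units)
    if units is RateUnits.PER_SITE_PER_YEAR:
        return pr.value * 1e6
    if units is RateUnits.PER_SITE_PER_GENERATION:
        # generations are converted to years at the *target* generation time
        return pr.value / target_g * 1e6
    if units is RateUnits.PER_SITE_PER_MYR:
        if pr.generation_years is None:
            raise ValueError(
                f"study {pr.study!r}: the generation time the per-Myr rate was "
                "stated under is required to rescale it"
            )
        return pr.value * pr.generation_years / target_g
    raise ValueError(f"unknown units {pr.units!r}")  # pragma: no cover


def read_published_rates(source) -> list[PublishedRate]:
    """Read a published-rates TSV (study, type, range, counts, value, units)."""
    df = pd.read_csv(source, sep="\t", comment="#")

    def opt_int(v):
        return None if pd.isna(v) else int(v)

    def opt_float(v):
        return None if pd.isna(v) else float(v)

    def opt_str(v):
        return None if pd.isna(v) else str(v)

    rates = []
    for row in df.itertuples(index=False):
        rates.append(
            PublishedRate(
                study=str(row.study),
                value=opt_float(getattr(row, "reported_value", None)),
                units=opt_str(getattr(row, "reported_units", None)),
                region=opt_str(getattr(row, "region", None)),
                method=opt_str(getattr(row, "type", None)),
                seq_range=opt_str(getattr(row, "seq_range", None)),
                transmissions=opt_int(getattr(row, "transmissions", None)),
                n_sub=opt_int(getattr(row, "n_sub", None)),
                n_het=opt_int(getattr(row, "n_het", None)),
                generation_years=opt_float(getattr(row, "generation_years", None)),
            )
        )
    return rates
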