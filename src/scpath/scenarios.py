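"""Named POCT-deployment scenarios and comparison tables.

A scenario fixes which facilities carry point-of-care diagnostics: the
current roster, a widespread policy tier (every hospital, or every health
resource facility), or the output of a location-allocation strategy. Each
scenario is routed with the same two-stage care path and summarized; a
comparison table reports each scenario's percent decrease in mean travel
time over a designated baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .network import RoadNetwork
from .routing import (
    AccessSummary,
    HealthFacility,
    PopulatedPlace,
    care_paths,
    percent_decrease,
    summarize_access,
)

RULES = ("explicit", "all_hospitals", "all_facilities")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named POCT deployment: explicit site ids or an expansion rule."""

    name: str
    care_site: str
    rule: str = "explicit"
    poct_sites: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown scenario rule {self.rule!r}; expected {RULES}")
        if self.rule == "explicit" and not self.poct_sites:
            raise ValueError(f"scenario {self.name!r}: explicit rule needs poct_sites")


def explicit_scenario(name: str, sites: Iterable[str], care_site: str) -> ScenarioSpec:
    return ScenarioSpec(name, str(care_site), "explicit", frozenset(str(s) for s in sites))


def expand_scenario(
    spec: ScenarioSpec, facilities: Sequence[HealthFacility]
) -> frozenset[str]:
    """Resolve a scenario rule to a concrete POCT site set.

    The care center is always included as a permissible diagnosis site: a
    patient who reaches the tertiary hospital is diagnosed there rather than
    backtracking to a peripheral device.
    """
    by_kind = {}
    for f in facilities:
        by_kind.setdefault(f.kind, []).append(f.id)
    care = set(by_kind.get("care_center", []))
    if spec.rule == "explicit":
        sites = set(spec.poct_sites) | care
    elif spec.rule == "all_hospitals":
        sites = set(by_kind.get("hospital", [])) | care
    else:  # all_facilities
        sites = {f.id for f in facilities}
    if not sites:
        raise ValueError(f"scenario {spec.name!r} expands to an empty site set")
    return frozenset(sites)


def run_scenario(
    net: RoadNetwork,
    places: Sequence[PopulatedPlace],
    facilities: Sequence[HealthFacility],
    spec: ScenarioSpec,
    weighted: bool = True,
    time_matrix_df: pd.DataFrame | None = None,
) -> AccessSummary:
    """Route every place through the scenario's sites and summarize access."""
    sites = expand_scenario(spec, facilities)
    paths = care_paths(net, places, sites, spec.care_site, time_matrix_df)
    return summarize_access(paths, places, weighted=weighted)


def compare(
    baseline: tuple[str, AccessSummary],
    others: Sequence[tuple[str, AccessSummary]],
) -> pd.DataFrame:
    """Comparison table: mean (SD) per stage and percent decrease vs baseline.

    Percent decreases are computed from the unrounded means and rounded to
    one decimal; the baseline row's percent cells are NA.
    """
    base_name, base = baseline
    if base.n_routes == 0:
        raise ValueError("baseline has no routes")
    for name, s in others:
        if s.n_routes != base.n_routes:
            raise ValueError(
                f"scenario {name!r} summarizes {s.n_routes} routes but the "
                f"baseline has {base.n_routes}; rosters must match"
            )
    rows = []
    for name, s in [(base_name, base)] + list(others):
        is_base = name == base_name and s is base
        rows.append(
            {
                "scenario": name,
                "mean_diag_min": s.mean_diag_min,
                "sd_diag_min": s.sd_diag_min,
                "pct_decrease_diag": (
                    float("nan") if is_base else percent_decrease(base.mean_diag_min, s.mean_diag_min)
                ),
                "mean_care_min": s.mean_care_min,
                "sd_care_min": s.sd_care_min,
                "pct_decrease_care": (
                    float("nan") if is_base else percent_decrease(base.mean_care_min, s.mean_care_min)
                ),
                "mean_total_min": s.mean_total_min,
                "sd_total_min": s.sd_total_min,
                "pct_decrease_total": (
                    float("nan") if is_base else percent_decrease(base.mean_total_min, s.mean_total_min)
                ),
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
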