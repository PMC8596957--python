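"""End-to-end study orchestration: batches in, comparison report out.

``run_study`` takes a set of reactor batches (and optionally a synthetic
community scenario), computes every per-reactor balance, summarizes traces,
runs the community statistics, and assembles a cross-reactor comparison with
argmax rankings (best ethanol yield, highest consumption, highest peak
current).  The report is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import __version__
from .community import (
    alpha_diversity_table,
    bray_curtis,
    family_profile,
    group_difference,
    nmds,
    permanova,
)
from .stoich import BalanceReport, balance_report
from .synthetic import CommunityScenario, ReactorBatch, make_community
from .traces import find_current_peak

__all__ = ["StudyReport", "run_study"]


@dataclass
class StudyReport:
    balances: dict[str, BalanceReport]
    peaks: dict[str, dict[str, float]]
    rankings: dict[str, str | None]
    community: dict | None
    seed: int
    version: str = field(default=__version__)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "balances": {k: v.to_dict() for k, v in self.balances.items()},
            "peaks": self.peaks,
            "rankings": self.rankings,
            "community": self.community,
        }


def _argmax(values: dict[str, float | None]) -> str | None:
    present = {k: v for k, v in values.items() if v is not None}
    if not present:
        return None
    # deterministic under reordering: ties broken by reactor id
    return min(present, key=lambda k: (-present[k], k))


def run_study(
    batches: Sequence[ReactorBatch],
    community_scenario: CommunityScenario | None = None,
    seed: int = 0,
) -> StudyReport:
    """Run every analysis stage and assemble the cross-reactor report."""
    ids = [b.spec.reactor_id for b in batches]
    if len(set(ids)) != len(ids):
        raise ValueError("reactor ids must be unique")

    balances: dict[str, BalanceReport] = {}
    peaks: dict[str, dict[str, float]] = {}
    for batch in sorted(batches, key=lambda b: b.spec.reactor_id):
        balances[batch.spec.reactor_id] = balance_report(
            batch.spec, batch.panel, trace=batch.trace, c_i=batch.c_i
        )
        if batch.trace is not None:
            pk = find_current_peak(*batch.trace)
            peaks[batch.spec.reactor_id] = {
                "peak_current_A": pk.peak_current,
                "peak_time_h": pk.peak_time,
            }

    rankings = {
        "max_ethanol_yield": _argmax(
            {k: v.yields.get("ethanol") for k, v in balances.items()}
        ),
        "max_consumption": _argmax(
            {k: v.consumption_rate_pct for k, v in balances.items()}
        ),
        "max_peak_current": _argmax(
            {k: v["peak_current_A"] for k, v in peaks.items()}
        ),
    }

    community = None
    if community_scenario is not None:
        counts, tree, taxonomy, metadata = make_community(community_scenario, seed)
        alpha = alpha_diversity_table(counts, tree=tree)
        dist = bray_curtis(counts)
        ord_res = nmds(dist, k=2, seed=seed)
        perm = permanova(dist, metadata["group"].to_numpy(), n_permutations=999, seed=seed)
        profile = family_profile(counts, taxonomy)
        diffs = group_difference(profile, metadata["group"], "pre", "post")
        community = {
            "alpha_diversity": alpha.to_dict(),
            "nmds_stress": ord_res.stress,
            "nmds_coordinates": ord_res.coordinates.to_dict(),
            "permanova": {
                "r2": perm.r2,
                "pseudo_f": perm.pseudo_f,
                "p_value": perm.p_value,
                "n_permutations": perm.n_permutations,
            },
            "family_group_difference": diffs.to_dict(),
        }

    return StudyReport(
        balances=balances,
        peaks=peaks,
        rankings=rankings,
        community=community,
        seed=seed,
    )
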