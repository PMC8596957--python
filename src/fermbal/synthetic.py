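"""Synthetic reactor batches and microbial communities.

The generator produces desk-scale inputs with the statistical structure the
analysis assumes, so every stage can be exercised without the study's raw
measurements:

* reactor batches whose metabolite panel is exactly consistent with the
  configured consumption and yields, and whose chronoamperometry trace is a
  smooth single-peak pulse with configured peak height, peak time and total
  charge;
* the five-reactor endpoint fixture carrying the published batch values
  (control, −0.058 V, +0.242 V, +0.542 V, +0.842 V);
* Dirichlet-multinomial OTU tables with a configurable two-family dominance
  shift between pre- and post-treatment groups, plus a random coalescent-style
  tree and a taxon→family map.

All randomness flows through one seeded numpy Generator per call; identical
seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skbio import TreeNode

from .constants import XYLOSE_MOLAR_MASS
from .stoich import MetabolitePanel, ReactorSpec, consumed_molar_conc

__all__ = [
    "ReactorScenario",
    "CommunityScenario",
    "ReactorBatch",
    "make_reactor_batch",
    "make_paper_fixture",
    "make_community",
]


@dataclass(frozen=True)
class ReactorScenario:
    """Targets for one synthetic reactor batch.

    Yields are mol per mol xylose consumed; ``unaccounted_carbon`` is the
    fraction of consumed carbon deliberately left outside the measured pools
    (CO2 and unquantified products); biomass is back-computed to close the
    carbon balance to that fraction.
    """

    reactor_id: str
    applied_potential: float | None = None  # V vs SHE
    liquid_volume: float = 0.1  # L
    initial_substrate: float = 4.0  # g L^-1
    duration: float = 150.0  # h
    consumption_fraction: float = 0.1
    ethanol_yield: float = 0.3  # mol mol^-1
    acetate_yield: float = 0.2  # mol mol^-1
    h2_umol: float = 0.1
    c_i: float | None = 1.0  # C; None = control without electrodes
    peak_current: float = 5e-6  # A
    peak_time: float = 50.0  # h
    noise_sd: float = 0.0  # A, additive Gaussian on the trace
    unaccounted_carbon: float = 0.4  # fraction of consumed carbon

    def __post_init__(self) -> None:
        if not 0.0 <= self.consumption_fraction <= 1.0:
            raise ValueError("consumption_fraction must lie in [0, 1]")
        if self.ethanol_yield < 0 or self.acetate_yield < 0 or self.h2_umol < 0:
            raise ValueError("yields and H2 amount must be non-negative")
        if not 0.0 <= self.unaccounted_carbon <= 1.0:
            raise ValueError("unaccounted_carbon must lie in [0, 1]")
        # carbon feasibility: 2C ethanol + 2C acetate per 5C xylose
        assigned = 0.4 * (self.ethanol_yield + self.acetate_yield)
        if assigned > 1.0 + 1e-12:
            raise ValueError(
                f"infeasible yields: products claim {assigned:.2f} of consumed carbon"
            )
        if assigned > 1.0 - self.unaccounted_carbon + 1e-12:
            raise ValueError(
                "infeasible targets: ethanol+acetate carbon "
                f"({assigned:.2f}) exceeds the accounted fraction "
                f"({1.0 - self.unaccounted_carbon:.2f})"
            )


@dataclass(frozen=True)
class ReactorBatch:
    """One reactor run: spec, endpoint panel, optional trace and charge."""

    spec: ReactorSpec
    panel: MetabolitePanel
    trace: tuple[np.ndarray, np.ndarray] | None = None
    c_i: float | None = None  # integrated charge, C (recorded, not re-derived)


def _lognormal_pulse(t: np.ndarray, peak_time: float, sigma: float) -> np.ndarray:
    """Unit-peak single pulse, exactly 1 at t = peak_time, 0 at t = 0."""
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.exp(-((np.log(t[pos] / peak_time)) ** 2) / (2.0 * sigma**2))
    return out


def _solve_pulse_width(
    duration: float, peak_time: float, peak_current: float, target_charge: float
) -> float:
    """Width sigma such that the pulse's trapezoidal charge hits the target."""
    grid = np.linspace(0.0, duration, 20_001)

    def charge(sigma: float) -> float:
        return peak_current * 3600.0 * np.trapezoid(
            _lognormal_pulse(grid, peak_time, sigma), grid
        )

    lo, hi = 1e-3, 10.0
    if not charge(lo) <= target_charge <= charge(hi):
        raise ValueError(
            f"infeasible trace targets: charge {target_charge} C outside "
            f"[{charge(lo):.3g}, {charge(hi):.3g}] C for peak "
            f"{peak_current} A at {peak_time} h over {duration} h"
        )
    return brentq(lambda s: charge(s) - target_charge, lo, hi, xtol=1e-10)


def make_reactor_batch(
    scenario: ReactorScenario, seed: int, n_trace_points: int = 2001
) -> ReactorBatch:
    """Generate one reactor batch exactly consistent with its scenario.

    The panel is deterministic given the scenario; the trace is a log-normal
    shaped pulse with the configured peak height and time, scaled in width so
    its trapezoidal integral matches the target charge, plus optional additive
    Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    spec = ReactorSpec(
        reactor_id=scenario.reactor_id,
        applied_potential=scenario.applied_potential,
        liquid_volume=scenario.liquid_volume,
        initial_substrate=scenario.initial_substrate,
        duration=scenario.duration,
        substrate_molar_mass=XYLOSE_MOLAR_MASS,
    )
    consumed = consumed_molar_conc(
        scenario.initial_substrate, scenario.consumption_fraction, XYLOSE_MOLAR_MASS
    )
    ethanol = scenario.ethanol_yield * consumed
    acetate = scenario.acetate_yield * consumed
    # biomass (5 C, like xylose) absorbs the accounted-but-unmeasured carbon
    biomass_share = (
        1.0
        - scenario.unaccounted_carbon
        - 0.4 * (scenario.ethanol_yield + scenario.acetate_yield)
    )
    panel = MetabolitePanel(
        ethanol=ethanol,
        acetate=acetate,
        hydrogen=scenario.h2_umol,
        biomass=biomass_share * consumed if consumed > 0 else None,
        substrate_consumed_fraction=scenario.consumption_fraction,
    )

    trace = None
    if scenario.c_i is not None:
        sign = 1.0 if scenario.c_i >= 0 else -1.0
        sigma = _solve_pulse_width(
            scenario.duration,
            scenario.peak_time,
            abs(scenario.peak_current),
            abs(scenario.c_i),
        )
        t = np.linspace(0.0, scenario.duration, n_trace_points)
        i = sign * abs(scenario.peak_current) * _lognormal_pulse(
            t, scenario.peak_time, sigma
        )
        if scenario.noise_sd > 0:
            i = i + rng.normal(0.0, scenario.noise_sd, size=i.shape)
        trace = (t, i)

    return ReactorBatch(spec=spec, panel=panel, trace=trace, c_i=scenario.c_i)


def make_paper_fixture() -> list[ReactorBatch]:
    """The five published reactor batches as endpoint fixtures.

    Panels carry the published endpoint concentrations, H2 amounts and
    integrated charges verbatim (150-h batches, 0.1 L, 4 g L^-1 xylose).
    Biomass is included only where a published carbon share pins it down
    (control 35.1 %, +0.242 V 4.0 % of consumed carbon).  Traces are not
    synthesized here: the recorded integrated charge is used directly.
    """

    def conc(fraction: float) -> float:
        return consumed_molar_conc(4.0, fraction, XYLOSE_MOLAR_MASS)

    rows = [
        # id, potential, fraction, ethanol, acetate, H2 µmol, C_I, biomass share
        ("control", None, 0.0275, 148.0, 805.0, 0.0, None, 0.351),
        ("-0.058V", -0.058, 0.293, 567.0, 1380.0, 0.20, -0.58, None),
        ("+0.242V", 0.242, 0.184, 2093.0, 1594.0, 0.12, 0.17, 0.040),
        ("+0.542V", 0.542, 0.955, 764.0, 632.0, 0.36, 0.63, None),
        ("+0.842V", 0.842, 0.115, 2000.0, 1874.0, 0.11, 1.06, None),
    ]
    batches = []
    for rid, pot, frac, eth, ace, h2, c_i, bio_share in rows:
        spec = ReactorSpec(
            reactor_id=rid,
            applied_potential=pot,
            liquid_volume=0.1,
            initial_substrate=4.0,
            duration=150.0,
            substrate_molar_mass=XYLOSE_MOLAR_MASS,
        )
        panel = MetabolitePanel(
            ethanol=eth,
            acetate=ace,
            hydrogen=h2,
            biomass=None if bio_share is None else bio_share * conc(frac),
            substrate_consumed_fraction=frac,
        )
        batches.append(ReactorBatch(spec=spec, panel=panel, trace=None, c_i=c_i))
    return batches


# ---------------------------------------------------------------------------
# synthetic communities


@dataclass(frozen=True)
class CommunityScenario:
    """Targets for a synthetic pre/post OTU survey.

    ``dominance_abundance`` is the combined relative abundance the
    ``n_dominant_families`` reach in the post-treatment baseline; 0.95 sits in
    the middle-upper part of the dominance range such treatments produce.
    ``concentration`` is the Dirichlet precision: sample proportions converge
    to the group baseline as it grows.
    """

    n_samples_per_group: int = 3
    n_taxa: int = 50
    n_families: int = 12
    depth: int = 10_000  # reads per sample
    concentration: float = 200.0
    n_dominant_families: int = 2
    dominance_abundance: float = 0.95
    branch_rate: float = 1.0  # exponential rate for coalescent intervals

    def __post_init__(self) -> None:
        if self.dominance_abundance >= 1.0 or self.dominance_abundance <= 0.0:
            raise ValueError("dominance_abundance must lie in (0, 1)")
        if self.n_dominant_families >= self.n_families:
            raise ValueError("need fewer dominant families than families")
        if self.n_taxa < self.n_families:
            raise ValueError("need at least one taxon per family")


def _random_coalescent_tree(
    taxa: list[str], rng: np.random.Generator, rate: float
) -> TreeNode:
    """Random ultrametric tree by pairwise coalescence with exponential times."""
    nodes = [TreeNode(name=t, length=0.0) for t in taxa]
    heights = {id(n): 0.0 for n in nodes}
    height = 0.0
    k = len(nodes)
    while len(nodes) > 1:
        height += rng.exponential(1.0 / (rate * len(nodes)))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = height - heights[id(a)]
        b.length = height - heights[id(b)]
        parent = TreeNode(children=[a, b], length=0.0)
        heights[id(parent)] = height
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def make_community(
    scenario: CommunityScenario, seed: int
) -> tuple[pd.DataFrame, TreeNode, dict[str, str], pd.DataFrame]:
    """Generate (counts, tree, taxonomy, metadata) for a pre/post survey.

    Pre-treatment samples are Dirichlet-multinomial around a diffuse baseline;
    post-treatment samples use a baseline in which the dominant families'
    taxa jointly carry ``dominance_abundance`` of the mass.
    """
    rng = np.random.default_rng(seed)
    taxa = [f"otu_{i:03d}" for i in range(scenario.n_taxa)]
    families = [f"family_{chr(65 + i)}" for i in range(scenario.n_families)]
    assignment = np.concatenate(
        [
            np.arange(scenario.n_families),  # every family gets >= 1 taxon
            rng.integers(0, scenario.n_families, scenario.n_taxa - scenario.n_families),
        ]
    )
    rng.shuffle(assignment)
    taxonomy = {t: families[a] for t, a in zip(taxa, assignment)}

    baseline = rng.dirichlet(np.ones(scenario.n_taxa))
    dominant = set(families[: scenario.n_dominant_families])
    in_dom = np.array([taxonomy[t] in dominant for t in taxa])
    post_baseline = np.where(
        in_dom,
        baseline * (scenario.dominance_abundance / baseline[in_dom].sum()),
        baseline * ((1.0 - scenario.dominance_abundance) / baseline[~in_dom].sum()),
    )

    rows, names, groups = [], [], []
    for group, base in (("pre", baseline), ("post", post_baseline)):
        for r in range(scenario.n_samples_per_group):
            p = rng.dirichlet(scenario.concentration * base)
            rows.append(rng.multinomial(scenario.depth, p))
            names.append(f"{group}_{r + 1}")
            groups.append(group)
    counts = pd.DataFrame(rows, index=names, columns=taxa, dtype=np.int64)
    metadata = pd.DataFrame({"group": groups}, index=names)
    tree = _random_coalescent_tree(taxa, rng, scenario.branch_rate)
    return counts, tree, taxonomy, metadata
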