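"""Electron/carbon balance of one electro-fermentation reactor batch.

The accounting runs over a closed 150-h batch: xylose is consumed, ethanol /
acetate / H2 / biomass accumulate, and (in a microbial electrolysis cell) a
current flows at the working electrode.  From endpoint concentrations and the
integrated charge the module computes

* the substrate degradation rate,
* per-product coulombs (C = F·b·V·Δn, net-electron convention),
* charge recovered as current C_I = ∫ I dt,
* Coulombic efficiency CE = |C_I| / (F·b_xylose·n_consumed) · 100 %,
* cathodic gas recovery r_CAT = C_H2 / |C_I| · 100 %,
* carbon-conversion (CCE) and electron-conversion (ECE) shares per pool.

Concentrations are µmol L^-1 throughout; H2 is an absolute amount in µmol
(the assay samples the whole headspace, not a liquid concentration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import FARADAY, species_constants

__all__ = [
    "ReactorSpec",
    "MetabolitePanel",
    "BalanceReport",
    "consumption_rate",
    "consumed_molar_conc",
    "coulombs_from_metabolite",
    "coulombs_from_h2",
    "integrate_current",
    "coulombic_efficiency",
    "cathodic_gas_recovery",
    "product_yield",
    "carbon_shares",
    "electron_shares",
    "balance_report",
]


@dataclass(frozen=True)
class ReactorSpec:
    """Operating parameters of one reactor run.

    ``applied_potential`` is in volts vs SHE; ``None`` marks the no-potential
    control, for which CE and r_CAT are not applicable.
    """

    reactor_id: str
    liquid_volume: float  # L
    initial_substrate: float  # g L^-1
    duration: float  # h
    applied_potential: float | None = None  # V vs SHE
    substrate_molar_mass: float = 150.13  # g mol^-1 (xylose)

    def __post_init__(self) -> None:
        if self.liquid_volume <= 0:
            raise ValueError("liquid_volume must be positive")
        if self.initial_substrate <= 0:
            raise ValueError("initial_substrate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class MetabolitePanel:
    """Endpoint metabolite measurements for one reactor.

    Exactly one of ``substrate_consumed_fraction`` (dimensionless) and
    ``substrate_final`` (g L^-1) must be given.  ``hydrogen`` is an absolute
    amount in µmol; everything else is µmol L^-1.
    """

    ethanol: float = 0.0  # µmol L^-1
    acetate: float = 0.0  # µmol L^-1
    hydrogen: float = 0.0  # µmol, absolute
    biomass: float | None = None  # µmol L^-1 of C5H7O2N
    substrate_consumed_fraction: float | None = None
    substrate_final: float | None = None  # g L^-1

    def __post_init__(self) -> None:
        for name in ("ethanol", "acetate", "hydrogen"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.biomass is not None and self.biomass < 0:
            raise ValueError("biomass must be non-negative")
        given = (self.substrate_consumed_fraction is not None) + (
            self.substrate_final is not None
        )
        if given != 1:
            raise ValueError(
                "exactly one of substrate_consumed_fraction / substrate_final required"
            )
        if self.substrate_consumed_fraction is not None and not (
            0.0 <= self.substrate_consumed_fraction <= 1.0
        ):
            raise ValueError("substrate_consumed_fraction must lie in [0, 1]")

    def consumed_fraction(self, spec: ReactorSpec) -> float:
        """Fraction of the initial substrate consumed, resolved against *spec*."""
        if self.substrate_consumed_fraction is not None:
            return self.substrate_consumed_fraction
        return consumption_rate(spec.initial_substrate, self.substrate_final)


@dataclass
class BalanceReport:
    """All balance outputs for one reactor; shares are percentages."""

    reactor_id: str
    applied_potential: float | None
    consumption_rate_pct: float
    consumed_conc_umol_per_l: float
    yields: dict[str, float]  # mol per mol xylose consumed
    coulombs: dict[str, float]  # per-product C; includes c_xylose and c_i
    ce_pct: float | None  # None: not applicable (no charge measured)
    r_cat_pct: float | None
    cce_shares: dict[str, float]
    ece_shares: dict[str, float]
    cce_total_pct: float
    ece_total_pct: float
    overaccounted: bool = field(default=False)

    def to_dict(self) -> dict:
        return {
            "reactor_id": self.reactor_id,
            "applied_potential": self.applied_potential,
            "consumption_rate_pct": self.consumption_rate_pct,
            "consumed_conc_umol_per_l": self.consumed_conc_umol_per_l,
            "yields": dict(self.yields),
            "coulombs": dict(self.coulombs),
            "ce_pct": self.ce_pct,
            "r_cat_pct": self.r_cat_pct,
            "cce_shares": dict(self.cce_shares),
            "ece_shares": dict(self.ece_shares),
            "cce_total_pct": self.cce_total_pct,
            "ece_total_pct": self.ece_total_pct,
            "overaccounted": self.overaccounted,
        }


def consumption_rate(initial: float, final: float) -> float:
    """Substrate degradation as a fraction: (initial − final) / initial.

    Both arguments are g L^-1 of substrate at batch start / end.
    """
    if initial <= 0:
        raise ValueError("initial substrate must be positive")
    if final < 0:
        raise ValueError("final substrate must be non-negative")
    if final > initial:
        raise ValueError("negative consumption: final exceeds initial")
    return (initial - final) / initial


def consumed_molar_conc(
    initial: float, fraction: float, molar_mass: float = 150.13
) -> float:
    """Consumed substrate as a molar concentration, µmol L^-1."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("consumed fraction must lie in [0, 1]")
    return fraction * initial / molar_mass * 1e6


def coulombs_from_metabolite(
    delta_conc: float, volume: float, species: str
) -> float:
    """Coulombs transferred in forming a metabolite: C = F · b · V · Δn.

    ``delta_conc`` is the concentration change in µmol L^-1; ``b`` is the
    species' net electrons per mole (ethanol 3.4, acetate 0.6, H2 2,
    xylose 20).
    """
    if delta_conc < 0:
        raise ValueError("delta_conc must be non-negative")
    const = species_constants(species)
    if const.coulomb_b is None:
        raise ValueError(f"species {species!r} has no net-coulomb convention")
    return FARADAY * const.coulomb_b * volume * delta_conc * 1e-6


def coulombs_from_h2(n_h2: float) -> float:
    """Coulombs embodied in *n_h2* µmol of H2 (2 electrons per mole)."""
    if n_h2 < 0:
        raise ValueError("H2 amount must be non-negative")
    return 2.0 * FARADAY * n_h2 * 1e-6


def integrate_current(
    time_h: Sequence[float], current_a: Sequence[float]
) -> float:
    """Charge from a chronoamperometry trace: C_I = ∫ I dt (trapezoidal).

    Times are hours, currents amperes; the sign of the current is preserved,
    so a net-consuming reactor yields a negative charge.
    """
    t = np.asarray(time_h, dtype=float)
    i = np.asarray(current_a, dtype=float)
    if t.ndim != 1 or t.size < 2 or i.shape != t.shape:
        raise ValueError("trace needs >= 2 aligned (time, current) samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(i, t * 3600.0))


def coulombic_efficiency(
    c_i: float, consumed_mass: float, molar_mass: float, b_substrate: float
) -> float:
    """CE (%) = |C_I| divided by the substrate's theoretical coulombs.

    ``consumed_mass`` is grams of substrate consumed in the whole reactor
    (V · ΔC); the theoretical charge is F · b · consumed_mass / M.
    """
    if consumed_mass <= 0:
        raise ValueError("undefined CE: no substrate consumed")
    theoretical = FARADAY * b_substrate * consumed_mass / molar_mass
    return abs(c_i) / theoretical * 100.0


def cathodic_gas_recovery(c_h2: float, c_i: float) -> float:
    """r_CAT (%) — charge in recovered H2 over charge passed as current."""
    if c_i == 0:
        raise ValueError("no charge transferred: r_CAT undefined")
    return c_h2 / abs(c_i) * 100.0


def product_yield(product_conc: float, consumed_substrate_conc: float) -> float:
    """Molar yield, mol product per mol substrate *consumed* (both µmol L^-1)."""
    if consumed_substrate_conc <= 0:
        raise ValueError("yield undefined: no substrate consumed")
    return product_conc / consumed_substrate_conc


def _pool_concs(panel: MetabolitePanel) -> dict[str, float]:
    pools = {"ethanol": panel.ethanol, "acetate": panel.acetate}
    if panel.biomass is not None:
        pools["biomass"] = panel.biomass
    return pools


def carbon_shares(
    panel: MetabolitePanel, consumed_substrate_conc: float
) -> dict[str, float]:
    """Per-pool share (%) of the consumed-substrate carbon (CCE numerators).

    share(pool) = carbon_atoms(pool) · conc(pool) / (5 · consumed) · 100.
    H2 carries no carbon and does not appear.
    """
    if consumed_substrate_conc <= 0:
        raise ValueError("carbon shares undefined: no substrate consumed")
    denom = 5.0 * consumed_substrate_conc
    return {
        pool: species_constants(pool).carbon_atoms * conc / denom * 100.0
        for pool, conc in _pool_concs(panel).items()
    }


def electron_shares(
    panel: MetabolitePanel,
    consumed_substrate_conc: float,
    volume: float,
    c_i: float | None = None,
) -> dict[str, float]:
    """Per-pool share (%) of the consumed-substrate electron equivalents.

    Dissolved pools compare concentrations directly; H2 (absolute µmol) is
    compared against consumed moles = conc · volume.  When ``c_i`` is given, a
    ``current`` share |C_I| / (F · 20 · n_consumed) is included.
    """
    if consumed_substrate_conc <= 0:
        raise ValueError("electron shares undefined: no substrate consumed")
    if volume <= 0:
        raise ValueError("volume must be positive")
    denom_conc = 20.0 * consumed_substrate_conc  # e- equiv in µmol-e L^-1
    shares = {
        pool: species_constants(pool).electron_equiv * conc / denom_conc * 100.0
        for pool, conc in _pool_concs(panel).items()
    }
    consumed_umol = consumed_substrate_conc * volume  # µmol in the reactor
    shares["hydrogen"] = (
        species_constants("hydrogen").electron_equiv
        * panel.hydrogen
        / (20.0 * consumed_umol)
        * 100.0
    )
    if c_i is not None:
        shares["current"] = abs(c_i) / (FARADAY * 20.0 * consumed_umol * 1e-6) * 100.0
    return shares


def balance_report(
    spec: ReactorSpec,
    panel: MetabolitePanel,
    trace: tuple[Sequence[float], Sequence[float]] | None = None,
    c_i: float | None = None,
) -> BalanceReport:
    """Compose the full balance for one reactor.

    ``c_i`` overrides charge integration (for runs where only the integrated
    charge was recorded); otherwise it is integrated from ``trace``.  With
    neither, CE, r_CAT and the current share are reported as not applicable.
    """
    if c_i is None and trace is not None:
        c_i = integrate_current(*trace)

    frac = panel.consumed_fraction(spec)
    consumed_conc = consumed_molar_conc(
        spec.initial_substrate, frac, spec.substrate_molar_mass
    )

    coulombs: dict[str, float] = {
        "ethanol": coulombs_from_metabolite(panel.ethanol, spec.liquid_volume, "ethanol"),
        "acetate": coulombs_from_metabolite(panel.acetate, spec.liquid_volume, "acetate"),
        "hydrogen": coulombs_from_h2(panel.hydrogen),
    }
    if consumed_conc > 0:
        coulombs["xylose"] = coulombs_from_metabolite(
            consumed_conc, spec.liquid_volume, "xylose"
        )
    if c_i is not None:
        coulombs["c_i"] = c_i

    if consumed_conc == 0:
        return BalanceReport(
            reactor_id=spec.reactor_id,
            applied_potential=spec.applied_potential,
            consumption_rate_pct=0.0,
            consumed_conc_umol_per_l=0.0,
            yields={},
            coulombs=coulombs,
            ce_pct=None,
            r_cat_pct=None,
            cce_shares={},
            ece_shares={},
            cce_total_pct=0.0,
            ece_total_pct=0.0,
        )

    yields = {
        pool: product_yield(conc, consumed_conc)
        for pool, conc in _pool_concs(panel).items()
    }

    cce = carbon_shares(panel, consumed_conc)
    ece = electron_shares(panel, consumed_conc, spec.liquid_volume, c_i=c_i)
    cce_total = sum(cce.values())
    # The current share is charge *exported*, not a fermentation product pool.
    ece_total = sum(v for k, v in ece.items() if k != "current")

    ce = r_cat = None
    if c_i is not None and c_i != 0:
        consumed_mass = frac * spec.initial_substrate * spec.liquid_volume
        ce = coulombic_efficiency(
            c_i,
            consumed_mass,
            spec.substrate_molar_mass,
            species_constants("xylose").electron_equiv,
        )
        r_cat = cathodic_gas_recovery(coulombs["hydrogen"], c_i)

    overaccounted = cce_total > 100.0 or ece_total > 100.0
    if overaccounted:
        warnings.warn(
            f"{spec.reactor_id}: assigned shares exceed 100 % "
            f"(CCE {cce_total:.1f} %, ECE {ece_total:.1f} %)",
            stacklevel=2,
        )

    return BalanceReport(
        reactor_id=spec.reactor_id,
        applied_potential=spec.applied_potential,
        consumption_rate_pct=frac * 100.0,
        consumed_conc_umol_per_l=consumed_conc,
        yields=yields,
        coulombs=coulombs,
        ce_pct=ce,
        r_cat_pct=r_cat,
        cce_shares=cce,
        ece_shares=ece,
        cce_total_pct=cce_total,
        ece_total_pct=ece_total,
        overaccounted=overaccounted,
    )
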