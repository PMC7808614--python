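"""Flux-force reversibility model of the dissimilatory sulfate reduction chain.

Each enzymatic step of the pathway (sulfate uptake, activation by ATP
sulfurylase, APS reduction, sulfite reduction) has a reversibility

    x = backward rate / forward rate = e^{ΔG/RT}

and the net isotope fractionation of the chain follows the recursion

    ε_net(i) = ε_f(i) + x_i · (ε_net(i+1) − ε_b(i)),   ε_net(last) = ε_f(last)

so near-equilibrium steps (x → 1) transmit the downstream fractionation while
irreversible steps (x → 0) expose only their own kinetic isotope effect.

The solver allocates per-step free energies under two exact constraints:
every step carries the same net rate (the cell-specific sulfate reduction
rate, csSRR) through the flux-force law v = v_max·(1 − e^{ΔG/RT}), and the
per-step ΔG sum to the total free-energy budget set by the donor and acceptor
half-reaction potentials.  Both constraints are met by one-dimensional
root-finding on a shared enzyme-activity scale with per-step inversion of the
flux-force law.  A consequence of this rate law worth stating plainly: with
both constraints exact, the per-step reversibilities depend on the operating
point only through the total budget ΔG_total — the csSRR input governs the
absolute expressed capacities and feasibility (a rate above capacity, or a
budget too weak to sustain it, is an error), while the donor potential moves
every ΔG_i and hence the expressed fractionation.  Under richer rate laws
(substrate saturation) the rate would enter the allocation directly; that
refinement is deliberately out of scope.

Default step fractionations and the effective acceptor-side potential are
calibration choices (see docs/methods.md), tuned so the model reproduces two
anchor regimes: a slow, weakly driven culture (ΔG of APS reduction ≈ −3
kJ/mol, reversibility ≈ 0.3, ε_net ≈ 36‰) and a fast, strongly driven one
(APS reduction practically irreversible, ε_net ≈ 10‰).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "GAS_CONSTANT_KJ",
    "FARADAY_KJ_PER_V",
    "ELECTRONS_PER_SULFATE",
    "ReactionStep",
    "ModelConditions",
    "ChainSolution",
    "ChainCapacityError",
    "InsufficientDrivingForceError",
    "reversibility",
    "chain_net_epsilon",
    "total_delta_g",
    "solve_chain",
    "scan_grid",
    "default_chain",
]

GAS_CONSTANT_KJ = 8.314e-3  # kJ·mol⁻¹·K⁻¹
FARADAY_KJ_PER_V = 96.485  # kJ·V⁻¹·mol⁻¹
ELECTRONS_PER_SULFATE = 8

#: Effective standard potential (V) of the acceptor-side (reductive branch)
#: half reaction, per mole sulfate.  A calibration parameter, not a measured
#: constant: it lumps the APS- and sulfite-reduction couples with the ATP
#: investment of sulfate activation, and is tuned so the −140…−70 mV donor
#: window spans the observed fractionation range (see docs/methods.md).
E_ACCEPTOR_STD_V = -0.0656


@dataclass(frozen=True)
class ReactionStep:
    """One pathway step with its isotope effects and flux-force state.

    ``eps_forward``/``eps_backward`` are the kinetic fractionations of the
    forward and backward unidirectional reactions (‰); their difference is
    the step's equilibrium fractionation.  ``delta_g`` (kJ·mol⁻¹ sulfate)
    and ``reversibility`` are filled in by :func:`solve_chain`.
    """

    name: str
    eps_forward: float  # ‰
    eps_backward: float  # ‰
    v_max: float  # fmol·cell⁻¹·day⁻¹ (capacity; scaled by solve_chain)
    delta_g: float = float("nan")  # kJ·mol⁻¹, ≤ 0 once solved
    reversibility: float = float("nan")  # e^{ΔG/RT} ∈ [0, 1)

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ValueError(f"step {self.name!r}: v_max must be positive")

    @property
    def eps_equilibrium(self) -> float:
        return self.eps_forward - self.eps_backward


@dataclass(frozen=True)
class ModelConditions:
    """Operating point of the chain model."""

    cs_srr: float  # fmol sulfate · cell⁻¹ · day⁻¹
    donor_potential_mV: float  # effective potential of the e⁻-donating half reaction
    sulfate_mM: float = 15.0
    sulfide_mM: float = 5.0
    temperature_K: float = 293.15

    def __post_init__(self) -> None:
        if self.cs_srr <= 0:
            raise ValueError("cs_srr must be positive")
        if self.sulfate_mM <= 0 or self.sulfide_mM <= 0:
            raise ValueError("sulfate and sulfide concentrations must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")


class ChainCapacityError(ValueError):
    """The requested rate meets or exceeds the chain's limiting capacity."""


class InsufficientDrivingForceError(ValueError):
    """The free-energy budget cannot sustain the requested rate."""


def default_chain() -> list[ReactionStep]:
    """Shipped 4-step chain with calibrated defaults.

    Fractionations (‰): uptake 3 forward / 0 backward; activation 0/0; APS
    reduction 7 forward with equilibrium fractionation 20 (backward −13);
    sulfite reduction 79.7 forward (terminal step; its backward fractionation
    never enters the recursion).  Capacities (fmol·cell⁻¹·day⁻¹): fast
    uptake/activation (5×10⁴) and a limiting reductive capacity of 10³.
    All values are overridable calibration choices.
    """
    return [
        ReactionStep("uptake", 3.0, 0.0, 5.0e4),
        ReactionStep("activation", 0.0, 0.0, 5.0e4),
        ReactionStep("APS_reduction", 7.0, -13.0, 1.0e3),
        ReactionStep("sulfite_reduction", 79.7, 0.0, 1.0e3),
    ]


def reversibility(delta_g: float, temperature: float = 293.15) -> float:
    """Eq-of-state of a step: x = e^{ΔG/RT}, for ΔG ≤ 0."""
    if delta_g > 0:
        raise ValueError(
            "a net-forward step cannot have positive free energy change "
            f"(got ΔG = {delta_g} kJ/mol)"
        )
    return math.exp(delta_g / (GAS_CONSTANT_KJ * temperature))


def chain_net_epsilon(steps: list[ReactionStep]) -> float:
    """Net ³⁴ε (‰) of an ordered chain via the reversibility recursion.

    ``ε_net(i) = ε_f(i) + x_i·(ε_net(i+1) − ε_b(i))`` with
    ``ε_net(last) = ε_f(last)``; the last step's own reversibility does not
    enter (its product pool is a sink).
    """
    if not steps:
        raise ValueError("empty reaction chain")
    eps = steps[-1].eps_forward
    for step in reversed(steps[:-1]):
        x = step.reversibility
        if not np.isfinite(x):
            raise ValueError(f"step {step.name!r} has no reversibility; run solve_chain")
        eps = step.eps_forward + x * (eps - step.eps_backward)
    return float(eps)


def total_delta_g(
    conditions: ModelConditions,
    e_acceptor_std: float = E_ACCEPTOR_STD_V,
    n_electrons: int = ELECTRONS_PER_SULFATE,
) -> float:
    """Total free-energy budget (kJ per mole sulfate).

    ΔG_total = −n·F·(E_acceptor − E_donor), with the acceptor-side potential
    adjusted from its standard value by a Nernst term in the sulfate/sulfide
    concentrations:  E_acc = E°_acc + (RT/nF)·ln([SO₄²⁻]/[HS⁻]).
    """
    rt_over_nf = (
        GAS_CONSTANT_KJ * conditions.temperature_K / (n_electrons * FARADAY_KJ_PER_V)
    )
    e_acc = e_acceptor_std + rt_over_nf * math.log(
        conditions.sulfate_mM / conditions.sulfide_mM
    )
    e_don = conditions.donor_potential_mV / 1000.0
    return -n_electrons * FARADAY_KJ_PER_V * (e_acc - e_don)


@dataclass(frozen=True)
class ChainSolution:
    """Solved chain state at one operating point."""

    steps: list[ReactionStep]
    delta_g_total: float  # kJ·mol⁻¹
    activity: float  # shared expression scale a ∈ (0, 1]
    flux: float  # fmol·cell⁻¹·day⁻¹, equal across steps
    conditions: ModelConditions

    @property
    def epsilon(self) -> float:
        return chain_net_epsilon(self.steps)

    def step(self, name: str) -> ReactionStep:
        for s in self.steps:
            if s.name == name:
                return s
        raise KeyError(name)


def solve_chain(
    conditions: ModelConditions,
    chain: list[ReactionStep] | None = None,
    e_acceptor_std: float = E_ACCEPTOR_STD_V,
) -> ChainSolution:
    """Allocate per-step ΔG at the given operating point.

    Finds the shared activity scale ``a`` such that every step, running at
    effective capacity ``a·v_max``, carries the net rate csSRR:

        (a·v_max,i)·(1 − e^{ΔG_i/RT}) = csSRR   (per-step inversion)

    while Σ ΔG_i equals the total budget exactly.  Monotonicity: a more
    negative donor potential makes ΔG_total, and with it every ΔG_i, more
    negative.

    Raises :class:`ChainCapacityError` when csSRR ≥ the limiting capacity
    and :class:`InsufficientDrivingForceError` when even full expression
    (a = 1) would dissipate more free energy than the budget provides.
    """
    if chain is None:
        chain = default_chain()
    if not chain:
        raise ValueError("empty reaction chain")
    rt = GAS_CONSTANT_KJ * conditions.temperature_K
    budget = total_delta_g(conditions, e_acceptor_std)
    if budget >= 0:
        raise InsufficientDrivingForceError(
            f"total ΔG must be negative (got {budget:.3f} kJ/mol); "
            "the donor potential does not drive the reaction forward"
        )
    cs = conditions.cs_srr
    vmax = np.array([s.v_max for s in chain])
    v_min = float(vmax.min())
    if cs >= v_min:
        raise ChainCapacityError(
            f"rate exceeds capacity: csSRR = {cs} ≥ limiting v_max = {v_min}"
        )
    # dissipation at full expression (a = 1): the least negative achievable sum
    d_full = float(np.sum(rt * np.log1p(-cs / vmax)))
    if budget > d_full:
        raise InsufficientDrivingForceError(
            f"insufficient driving force: budget {budget:.3f} kJ/mol is weaker than "
            f"the minimum chain dissipation {d_full:.3f} kJ/mol at csSRR = {cs}"
        )

    # Root-find on w = ln(1 − u_min), the log-space ΔG/RT of the limiting
    # step, where u_i = cs/(a·v_max,i) = u_min·v_min/v_max,i.  This stays
    # well-conditioned when the limiting step is deeply irreversible.
    ratios = v_min / vmax  # ∈ (0, 1]

    def budget_residual(w: float) -> float:
        u_min = -math.expm1(w)  # 1 − e^w
        terms = np.log1p(-u_min * ratios)
        bottleneck = np.isclose(ratios, 1.0)
        terms = np.where(bottleneck, w, terms)  # exact for the limiting step(s)
        return float(rt * np.sum(terms)) - budget

    w_hi = math.log1p(-cs / v_min)  # a = 1
    w_lo = budget / rt  # sum ≤ RT·w via the limiting step alone
    w = brentq(budget_residual, w_lo, w_hi, xtol=1e-15, rtol=8.9e-16)

    u_min = -math.expm1(w)
    activity = cs / (u_min * v_min)
    u = u_min * ratios
    delta_g = rt * np.log1p(-u)
    limiting = np.isclose(ratios, 1.0)
    delta_g = np.where(limiting, rt * w, delta_g)
    # exact conservation: absorb the root-finder residual into the limiting step
    residual = float(np.sum(delta_g)) - budget
    first_lim = int(np.argmax(limiting))
    delta_g[first_lim] -= residual

    solved = [
        replace(
            s,
            delta_g=float(dg),
            reversibility=float(math.exp(dg / rt)),
            v_max=float(activity * s.v_max),
        )
        for s, dg in zip(chain, delta_g)
    ]
    return ChainSolution(solved, budget, float(activity), cs, conditions)


def scan_grid(
    cs_srr_values,
    donor_potential_mV_values,
    sulfate_mM: float = 15.0,
    sulfide_mM: float = 5.0,
    temperature_K: float = 293.15,
    chain: list[ReactionStep] | None = None,
    e_acceptor_std: float = E_ACCEPTOR_STD_V,
) -> pd.DataFrame:
    """Dense grid evaluation of the chain model (tidy table for contouring).

    Columns: csSRR, donor potential, net ε, ΔG and reversibility of APS
    reduction, and the total ΔG.  Operating points outside the feasible
    region are kept with NaN model outputs and a ``status`` note.
    """
    rows = []
    for cs in np.atleast_1d(cs_srr_values):
        for e_don in np.atleast_1d(donor_potential_mV_values):
            cond = ModelConditions(
                float(cs), float(e_don), sulfate_mM, sulfide_mM, temperature_K
            )
            row = {
                "cs_srr": float(cs),
                "donor_potential_mV": float(e_don),
                "delta_g_total_kJ": total_delta_g(cond, e_acceptor_std),
                "epsilon_permil": np.nan,
                "delta_g_aps_kJ": np.nan,
                "reversibility_aps": np.nan,
                "status": "ok",
            }
            try:
                sol = solve_chain(cond, chain, e_acceptor_std)
            except (ChainCapacityError, InsufficientDrivingForceError) as err:
                row["status"] = type(err).__name__
            else:
                aps = sol.step("APS_reduction")
                row["epsilon_permil"] = sol.epsilon
                row["delta_g_aps_kJ"] = aps.delta_g
                row["reversibility_aps"] = aps.reversibility
            rows.append(row)
    return pd.DataFrame(rows)
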