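"""Nernst / detailed-balance (thermodynamic-consistency) constraint.

The measured reversal potential of a K+-selective channel equals the Nernst
potential E_K once electrode drift has been corrected, so the model current
must change sign exactly at E_K.  For a pure-cycle model this pins two
combinations of parameters:

(a) at 0 mV the product of forward base rates around the transport cycle
    equals the product of backward base rates (the cycle is at equilibrium
    when no driving force remains); one backward base rate is eliminated in
    favour of the others, and

(b) the characteristic voltages of the cycle's Eyring groups satisfy
    sum_g 1/V_g = F/(R T) = 1/V_T, so that one full cycle carries exactly
    one elementary charge across the whole electric field.

Together with binding steps proportional to a_in (forward) and a_out
(backward), the forward/backward cycle-product ratio becomes
(a_in/a_out) * exp(V/V_T), which is one exactly at V = E_K.
"""

from __future__ import annotations

from .constants import T_DEFAULT_C, thermal_voltage_mV
from .models import ModelSpec, RateParameterSet, EyringBarrier

__all__ = [
    "cycle_binding_stoichiometry",
    "cycle_base_rate_ratio",
    "cycle_vchar_deficit",
    "apply_nernst_constraint",
]


def cycle_binding_stoichiometry(model: ModelSpec) -> tuple[int, int]:
    """Net (internal, external) binding counts along the forward cycle.

    Internal bindings on forward edges count +1 and on backward edges -1
    (and likewise for external).  The constraint machinery requires (+1, -1):
    one ion taken up from the internal side and one delivered to the
    external side per forward cycle.
    """
    n_in = n_out = 0
    for s, t in model.cycle_pairs():
        fwd = model.edge(s, t)
        bwd = model.edge(t, s)
        n_in += (fwd.kind == "bind_internal") - (bwd.kind == "bind_internal")
        n_out += (fwd.kind == "bind_external") - (bwd.kind == "bind_external")
    return n_in, n_out


def cycle_base_rate_ratio(model: ModelSpec, params: RateParameterSet) -> float:
    """Ratio of forward to backward cycle products of *base* rates at 0 mV."""
    num = den = 1.0
    for s, t in model.cycle_pairs():
        num *= params.base_rates[model.edge(s, t).param]
        den *= params.base_rates[model.edge(t, s).param]
    return num / den


def cycle_vchar_deficit(
    model: ModelSpec, params: RateParameterSet, T: float = T_DEFAULT_C
) -> float:
    """sum_g 1/V_g - 1/V_T over the cycle's Eyring groups (0 when satisfied)."""
    inv = sum(1.0 / params.eyring[g].v_char for g in model.eyring_groups())
    return inv - 1.0 / thermal_voltage_mV(T)


def apply_nernst_constraint(
    model: ModelSpec,
    params: RateParameterSet,
    adjust_group: str | None = None,
    T: float = T_DEFAULT_C,
) -> RateParameterSet:
    """Return a copy of ``params`` satisfying the reversal constraint exactly.

    The model's designated backward base rate is recomputed from the other
    cycle rates (part a), and the characteristic voltage of ``adjust_group``
    (default: the last Eyring group of the cycle) is set so the inverse
    characteristic voltages sum to 1/V_T (part b).  Raises ``ValueError``
    when the topology cannot support the constraint (wrong binding
    stoichiometry, or the remaining groups already exhaust 1/V_T).
    """
    stoich = cycle_binding_stoichiometry(model)
    if stoich != (1, -1):
        raise ValueError(
            f"cycle binding stoichiometry {stoich} != (1, -1); "
            "the Nernst constraint requires one internal uptake and one "
            "external release per forward cycle"
        )
    elim = model.constraint_eliminated_rate
    if elim is None:
        raise ValueError(f"model {model.name!r} designates no eliminated rate")
    out = params.copy()
    # part (a): set eliminated backward rate so the 0 mV cycle products match
    num = den = 1.0
    elim_on_backward = False
    for s, t in model.cycle_pairs():
        fwd_p = model.edge(s, t).param
        bwd_p = model.edge(t, s).param
        if bwd_p == elim:
            elim_on_backward = True
            num *= out.base_rates[fwd_p]
        else:
            num *= out.base_rates[fwd_p]
            den *= out.base_rates[bwd_p]
    if not elim_on_backward:
        raise ValueError(f"eliminated rate {elim!r} is not a backward cycle rate")
    out.base_rates[elim] = num / den
    # part (b): adjust one characteristic voltage
    groups = list(model.eyring_groups())
    if groups:
        if adjust_group is None:
            adjust_group = groups[-1]
        if adjust_group not in groups:
            raise ValueError(f"{adjust_group!r} is not an Eyring group of the cycle")
        inv_rest = sum(
            1.0 / out.eyring[g].v_char for g in groups if g != adjust_group
        )
        inv_needed = 1.0 / thermal_voltage_mV(T) - inv_rest
        if inv_needed <= 0:
            raise ValueError(
                "remaining characteristic voltages already exceed the one-charge "
                "budget; increase them before applying the constraint"
            )
        s_keep = out.eyring[adjust_group].s
        out.eyring[adjust_group] = EyringBarrier(s=s_keep, v_char=1.0 / inv_needed)
    return out
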