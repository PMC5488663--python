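"""The toy circuits used throughout the package and its tests.

All three share the inhibitory signal coupling dy/dt = 0.25*(25 - Z*y):
the tissue clears its own input, so at steady state Z*y = 25.

* ``monophasic()``      lambda_plus = y/10, lambda_minus = 0.5
                        (one fixed point: y* = 5, Z* = 5, stable)
* ``biphasic()``        lambda_plus = 4.8/(1+(7/y)^5),
                        lambda_minus = 6/(1+(8/y)^5) + 0.1
                        (stable y ~ 4.06, unstable y ~ 8.26; delta ~ 1.04)
* ``biphasic_narrow()`` lambda_plus = 4.8/(1+(5.5/y)^6),
                        lambda_minus = 6/(1+(6.3/y)^6) + 0.3
                        (sharper sensing: smaller gap delta ~ 0.53, hence
                        higher evolutionary stability but a narrower basin)
"""

from __future__ import annotations

from homeostat.core_dynamics import (
    ACTIVATES,
    CircuitModel,
    GrowthLaw,
    HillTerm,
    SignalCoupling,
)

__all__ = ["monophasic", "biphasic", "biphasic_narrow", "monophasic_activating"]

_DEFAULT_COUPLING = SignalCoupling(sign="tissue_inhibits_signal", turnover=0.25, scale=25.0)


def monophasic() -> CircuitModel:
    """Monophasic toy circuit: growth rises linearly with the signal."""
    law = GrowthLaw(proliferation_linear=0.1, removal_offset=0.5)
    return CircuitModel(growth_law=law, coupling=_DEFAULT_COUPLING, name="monophasic")


def biphasic() -> CircuitModel:
    """Biphasic toy circuit with the wide stable-unstable gap."""
    law = GrowthLaw(
        proliferation=(HillTerm(amplitude=4.8, threshold=7.0, exponent=5.0),),
        removal=(HillTerm(amplitude=6.0, threshold=8.0, exponent=5.0),),
        removal_offset=0.1,
    )
    return CircuitModel(growth_law=law, coupling=_DEFAULT_COUPLING, name="biphasic")


def biphasic_narrow() -> CircuitModel:
    """Biphasic circuit with steeper Hill terms and a smaller relative gap.

    Trades dynamic stability (a narrow perturbation range) for evolutionary
    stability (only mild mis-sensing mutants can invade).
    """
    law = GrowthLaw(
        proliferation=(HillTerm(amplitude=4.8, threshold=5.5, exponent=6.0),),
        removal=(HillTerm(amplitude=6.0, threshold=6.3, exponent=6.0),),
        removal_offset=0.3,
    )
    return CircuitModel(growth_law=law, coupling=_DEFAULT_COUPLING, name="biphasic_narrow")


def monophasic_activating() -> CircuitModel:
    """Monophasic circuit with tissue-activates-signal coupling (y = Z at
    steady state): the signal reads out tissue mass, so stability needs a
    growth rate that *falls* with the signal (removal rises as y/10)."""
    law = GrowthLaw(proliferation_offset=0.5, removal_linear=0.1)
    coupling = SignalCoupling(sign=ACTIVATES, turnover=0.25, scale=1.0)
    return CircuitModel(growth_law=law, coupling=coupling, name="monophasic_activating")
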