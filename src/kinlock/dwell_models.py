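"""Kinetic laws for dwell times of a binder-coupled fluctuating hairpin.

A two-state DNA hairpin held under tension opens and closes stochastically
with rates ``k_u`` (opening/unfolding) and ``k_f`` (closing/folding), so
free dwell times are exponential.  When a ligand (oligonucleotide or
protein) can bind the transiently exposed strand, the hairpin is "kinetically
locked" in that phase for the duration of the binding event.  The dwell time
in the locked phase is then the absorption time of a two-state transient
Markov chain {free, bound}:

* from *free* the chain escapes (hairpin switches phase) at rate ``a``,
  or binds at the pseudo-first-order rate ``b = c * k_on``;
* from *bound* it unbinds at rate ``d = k_off``.

The absorption time follows a phase-type distribution that reduces to a
two-exponential mixture

    f(t) = w * lam_plus * exp(-lam_plus * t) + (1 - w) * lam_minus * exp(-lam_minus * t)

with eigenvalues ``lam_pm = ((a+b+d) +/- sqrt((a+b+d)^2 - 4 a d)) / 2`` and
mixture weight ``w = (a - lam_minus) / (lam_plus - lam_minus)``.  Its mean,

    T_mean(c) = (1 + c * k_on / k_off) / a = (1 + c * Ka) / a,

grows linearly with the binder concentration; the slope measures the
association constant ``Ka = k_on / k_off`` and hence the standard binding
free energy ``dG0 = -kT * ln(Ka * c0)`` with ``c0 = 1 M``.

Unit policy (applied throughout the package): rates in s^-1, concentrations
in nM, ``k_on`` in nM^-1 s^-1.  Conversion to molar happens only here, in
:func:`deltaG_from_Ka` / :func:`Ka_from_deltaG`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "TwoStateRates",
    "BindingRates",
    "ThermoContext",
    "PhaseTypeOpenModel",
    "open_time_pdf_exact",
    "mean_open_time",
    "mean_closed_time_legf",
    "fast_exchange_rate",
    "deltaG_from_Ka",
    "Ka_from_deltaG",
]

#: Molar gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.98720425e-3

#: nM -> M conversion for association constants.
_NM_TO_M = 1e-9


@dataclass(frozen=True)
class TwoStateRates:
    """Hairpin transition rates: ``k_f`` closes (folds), ``k_u`` opens."""

    k_f: float
    k_u: float

    def __post_init__(self) -> None:
        if self.k_f <= 0 or self.k_u <= 0:
            raise ValueError("two-state rates k_f and k_u must be > 0")


@dataclass(frozen=True)
class BindingRates:
    """Binder association/dissociation rates (k_on in nM^-1 s^-1)."""

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if self.k_on < 0:
            raise ValueError("k_on must be >= 0")
        if self.k_off <= 0:
            raise ValueError("k_off must be > 0")

    @property
    def Ka(self) -> float:
        """Association constant k_on / k_off in nM^-1."""
        return self.k_on / self.k_off


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and reference state for free-energy conversions.

    The standard concentration ``c0`` is fixed at 1 M by the definition of
    the standard binding free energy.
    """

    temperature: float = 298.15  # K
    c0: float = 1.0  # M, exact by convention

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.c0 != 1.0:
            raise ValueError("c0 is 1 M by the standard-state convention")

    @property
    def kT(self) -> float:
        """R*T in kcal mol^-1."""
        return GAS_CONSTANT_KCAL * self.temperature


@dataclass(frozen=True)
class PhaseTypeOpenModel:
    """Exact dwell law for a lockable phase: mixture of two exponentials.

    Parameters
    ----------
    escape_rate :
        Rate ``a`` of leaving the phase when unbound (``k_f`` for open
        dwells; ``k_u`` for closed dwells of a gapped-fork probe).
    bind_rate :
        Pseudo-first-order binding rate ``b = c * k_on`` (s^-1).
    unbind_rate :
        Dissociation rate ``d = k_off`` (s^-1).
    """

    escape_rate: float
    bind_rate: float
    unbind_rate: float
    lam_plus: float = field(init=False)
    lam_minus: float = field(init=False)
    weight: float = field(init=False)

    def __post_init__(self) -> None:
        a, b, d = self.escape_rate, self.bind_rate, self.unbind_rate
        if a <= 0:
            raise ValueError("escape_rate must be > 0")
        if b < 0:
            raise ValueError("bind_rate must be >= 0")
        if d <= 0:
            raise ValueError("unbind_rate must be > 0")
        s = a + b + d
        disc = math.sqrt(max(s * s - 4.0 * a * d, 0.0))
        lam_plus = 0.5 * (s + disc)
        # computed via the product identity to avoid cancellation
        lam_minus = a * d / lam_plus
        if lam_plus > lam_minus:
            w = (a - lam_minus) / (lam_plus - lam_minus)
        else:  # b == 0 and a == d: degenerate single exponential
            w = 1.0
        object.__setattr__(self, "lam_plus", lam_plus)
        object.__setattr__(self, "lam_minus", lam_minus)
        object.__setattr__(self, "weight", min(max(w, 0.0), 1.0))

    def pdf(self, t):
        """Density of the dwell time at ``t`` (s^-1); f(0) = escape_rate."""
        t = np.asarray(t, dtype=float)
        lp, lm, w = self.lam_plus, self.lam_minus, self.weight
        out = w * lp * np.exp(-lp * t) + (1.0 - w) * lm * np.exp(-lm * t)
        return np.where(t < 0, 0.0, out)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        lp, lm, w = self.lam_plus, self.lam_minus, self.weight
        out = 1.0 - w * np.exp(-lp * t) - (1.0 - w) * np.exp(-lm * t)
        return np.where(t < 0, 0.0, out)

    def sf(self, t):
        t = np.asarray(t, dtype=float)
        lp, lm, w = self.lam_plus, self.lam_minus, self.weight
        out = w * np.exp(-lp * t) + (1.0 - w) * np.exp(-lm * t)
        return np.where(t < 0, 1.0, out)

    @property
    def mean(self) -> float:
        """(1 + b/d) / a, the locked-phase mean dwell."""
        return (1.0 + self.bind_rate / self.unbind_rate) / self.escape_rate


def open_time_pdf_exact(model: PhaseTypeOpenModel, t):
    """Exact open-time density of the locking model (s^-1)."""
    return model.pdf(t)


def mean_open_time(rates: TwoStateRates, binding: BindingRates, c: float) -> float:
    """Mean open dwell at binder concentration ``c`` (nM).

    T_open(c) = (1 + c * Ka) / k_f — the titration line whose slope carries
    the hybridization free energy.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    return (1.0 + c * binding.Ka) / rates.k_f


def mean_closed_time_legf(rates: TwoStateRates, binding: BindingRates, c: float) -> float:
    """Mean closed dwell of a gapped-fork probe whose binder locks the
    closed state: the mirrored law (1 + c * Ka) / k_u."""
    if c < 0:
        raise ValueError("concentration must be >= 0")
    return (1.0 + c * binding.Ka) / rates.k_u


def fast_exchange_rate(rates: TwoStateRates, binding: BindingRates, c: float) -> float:
    """Effective single-exponential escape rate in the fast-exchange limit.

    When binding and unbinding are much faster than the frame time the two
    exponentials collapse and the dwell distribution stays single-exponential
    with rate k_eff = k_f / (1 + c * Ka); individual rates are then not
    separately identifiable, but the mean still follows the titration line.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    return rates.k_f / (1.0 + c * binding.Ka)


def deltaG_from_Ka(Ka: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Standard binding free energy (kcal mol^-1) from Ka in nM^-1.

    dG0 = -kT * ln(Ka / c0) with Ka converted to M^-1.
    """
    if Ka <= 0:
        raise ValueError("Ka must be > 0")
    return -ctx.kT * math.log(Ka / _NM_TO_M / ctx.c0)


def Ka_from_deltaG(dG0: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Inverse of :func:`deltaG_from_Ka`: Ka in nM^-1 from dG0 (kcal mol^-1)."""
    return math.exp(-dG0 / ctx.kT) * _NM_TO_M * ctx.c0
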