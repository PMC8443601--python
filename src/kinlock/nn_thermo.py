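"""Nearest-neighbor prediction of short-duplex hybridization free energies.

The standard free energy of a perfect Watson-Crick duplex is assembled as a
sum over its L-1 nearest-neighbor stacks plus per-terminal initiation
terms (with a penalty for terminal A·T pairs), using the unified
oligonucleotide parameter set with two corrected entropies,
dS(TA/AT) = -21.3 e.u. and dS(GG/CC) = -19.9 e.u.  The 1 M NaCl reference
entropy is then shifted to the working buffer by an entropic salt
correction,

    dS = dS_1M + 0.368 * (N_bp - 1) * ln([mon+]_eff),

where the effective monovalent concentration folds the stabilizing effect
of Mg2+ into the monovalent scale.  Two mappings are provided; the default
([mon+]_eff in mM = [mon+] + 140 * sqrt([Mg2+])) was selected by
calibrating against reference predictions for three short duplexes in
100 mM KCl + 3 mM MgCl2 (see scripts/salt_calibration.py), which it
reproduces to better than 0.02 kcal/mol at 25 C.

Terminal dye/intercalator modifications (e.g. 5'-Cy3) shift the duplex
stability in a sequence-dependent way; :func:`terminal_modification_correction`
applies a user-supplied parameter table — no modification parameters are
bundled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

from .dwell_models import ThermoContext

__all__ = [
    "NNParameterSet",
    "SaltConditions",
    "DuplexPrediction",
    "HYBRIDIZATION_BUFFER",
    "load_default_parameters",
    "predict_duplex_dG",
    "salt_corrected_entropy",
    "effective_monovalent",
    "terminal_modification_correction",
    "ExternalParametersRequired",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (5'->3' in, 5'->3' out)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ExternalParametersRequired(ValueError):
    """A correction needs a parameter table the package does not bundle."""


@dataclass(frozen=True)
class NNParameterSet:
    """Unified NN stacks (dH kcal/mol, dS e.u.) plus initiation terms.

    ``stacks`` holds the ten unique Watson-Crick stacks keyed by the
    5'->3' top-strand dinucleotide; symmetric stacks are resolved through
    the reverse complement.  Initiation is per terminal base pair.
    """

    stacks: dict[str, tuple[float, float]]
    init_gc: tuple[float, float]
    init_at: tuple[float, float]
    provenance: str = ""

    def stack(self, dinuc: str) -> tuple[float, float]:
        if dinuc in self.stacks:
            return self.stacks[dinuc]
        rc = revcomp(dinuc)
        if rc in self.stacks:
            return self.stacks[rc]
        raise KeyError(f"no NN parameters for stack {dinuc!r}")


@dataclass(frozen=True)
class SaltConditions:
    """Ionic conditions of the hybridization buffer (molar units)."""

    monovalent: float = 0.1  # M, Na+ + K+
    magnesium: float = 0.0  # M
    correction_scheme: str = "mono_mg_sqrt"  # or "mono_only"
    mg_factor: float = 140.0  # mM^(1/2) weight of sqrt(Mg) in the effective monovalent

    def __post_init__(self) -> None:
        if self.monovalent < 0 or self.magnesium < 0:
            raise ValueError("salt concentrations must be >= 0")
        if self.correction_scheme not in ("mono_mg_sqrt", "mono_only"):
            raise ValueError(f"unknown salt correction scheme {self.correction_scheme!r}")


#: Buffer of the oligonucleotide titration assays: 100 mM KCl, 3 mM MgCl2.
HYBRIDIZATION_BUFFER = SaltConditions(monovalent=0.100, magnesium=0.003)


@dataclass(frozen=True)
class DuplexPrediction:
    """Predicted duplex thermodynamics under stated conditions.

    ``dS`` is already salt-corrected; ``dG == dH - T * dS / 1000`` exactly
    (dS in e.u., dG and dH in kcal/mol).
    """

    sequence: str
    dH: float
    dS: float
    dG: float
    temperature: float
    salt: SaltConditions
    modifications: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isclose(self.dG, self.dH - self.temperature * self.dS / 1000.0,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError("inconsistent dG: must equal dH - T*dS/1000")


def load_default_parameters() -> NNParameterSet:
    """Load the bundled corrected unified NN table."""
    stacks: dict[str, tuple[float, float]] = {}
    init_gc = init_at = None
    text = resources.files("kinlock").joinpath("data/nn_unified_corrected.tsv").read_text()
    provenance = ""
    for line in text.splitlines():
        if line.startswith("#"):
            if "provenance:" in line:
                provenance = line.split("provenance:", 1)[1].strip()
            continue
        parts = line.split("\t")
        if len(parts) != 3 or parts[0] == "entry":
            continue
        key, dh, ds = parts[0], float(parts[1]), float(parts[2])
        if key == "init_GC":
            init_gc = (dh, ds)
        elif key == "init_AT":
            init_at = (dh, ds)
        else:
            stacks[key] = (dh, ds)
    assert init_gc is not None and init_at is not None and len(stacks) == 10
    return NNParameterSet(stacks=stacks, init_gc=init_gc, init_at=init_at,
                          provenance=provenance)


_DEFAULT_PARAMS: NNParameterSet | None = None


def _default_params() -> NNParameterSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_default_parameters()
    return _DEFAULT_PARAMS


def effective_monovalent(salt: SaltConditions) -> float:
    """Effective monovalent concentration (M) for the entropic correction."""
    mon_mM = salt.monovalent * 1e3
    if salt.correction_scheme == "mono_only":
        eff_mM = mon_mM
    else:  # mono_mg_sqrt
        eff_mM = mon_mM + salt.mg_factor * math.sqrt(salt.magnesium * 1e3)
    if eff_mM <= 0:
        raise ValueError("effective monovalent concentration must be > 0 (log divergence)")
    return eff_mM * 1e-3


def salt_corrected_entropy(dS_1M: float, n_bp: int, salt: SaltConditions) -> float:
    """Shift a 1 M NaCl duplex entropy (e.u.) to the working buffer.

    dS = dS_1M + 0.368 * (N_bp - 1) * ln([mon+]_eff / 1 M).
    """
    if n_bp < 2:
        raise ValueError("n_bp must be >= 2")
    ceff = effective_monovalent(salt)
    return dS_1M + 0.368 * (n_bp - 1) * math.log(ceff)


def predict_duplex_dG(
    seq: str,
    ctx: ThermoContext = ThermoContext(),
    salt: SaltConditions = HYBRIDIZATION_BUFFER,
    params: NNParameterSet | None = None,
) -> DuplexPrediction:
    """Predict dH, dS and dG(T) of ``seq`` against its perfect complement.

    ``seq`` is the 5'->3' top strand, ACGT alphabet, length >= 2.
    """
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("duplex needs at least 2 base pairs")
    if set(seq) - set("ACGT"):
        raise ValueError(f"sequence contains non-ACGT symbols: {seq!r}")
    if params is None:
        params = _default_params()
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = params.stack(seq[i : i + 2])
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        h, s = params.init_at if end in "AT" else params.init_gc
        dh += h
        ds += s
    ds = salt_corrected_entropy(ds, len(seq), salt)
    dg = dh - ctx.temperature * ds / 1000.0
    return DuplexPrediction(sequence=seq, dH=dh, dS=ds, dG=dg,
                            temperature=ctx.temperature, salt=salt)


def terminal_modification_correction(
    base_prediction: DuplexPrediction,
    modification: str,
    params: dict[str, tuple[float, float]] | None,
) -> DuplexPrediction:
    """Apply a sequence-dependent 5'-terminal modification correction.

    ``params`` maps the 5'-terminal dinucleotide of the modified strand to
    (ddH kcal/mol, ddS e.u.); such tables (e.g. for Cy3) are external and
    must be supplied by the caller.  An empty table is an explicit identity;
    ``None`` raises :class:`ExternalParametersRequired`.  Re-applying the
    same modification raises (idempotence guard).
    """
    if params is None:
        raise ExternalParametersRequired(
            f"no parameter table supplied for modification {modification!r}; "
            "terminal-modification corrections require external parameters"
        )
    if modification in base_prediction.modifications:
        raise ValueError(f"modification {modification!r} already applied")
    if not params:
        return replace(base_prediction,
                       modifications=base_prediction.modifications + (modification,))
    context = base_prediction.sequence[:2]
    if context not in params:
        raise KeyError(
            f"modification table lacks an entry for terminal context {context!r}"
        )
    ddh, dds = params[context]
    dh = base_prediction.dH + ddh
    ds = base_prediction.dS + dds
    dg = dh - base_prediction.temperature * ds / 1000.0
    return replace(
        base_prediction,
        dH=dh,
        dS=ds,
        dG=dg,
        modifications=base_prediction.modifications + (modification,),
    )
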