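"""Ground-truth simulation of fluctuating-hairpin experiments.

Builds labeled continuous-time Markov chains for a two-state hairpin coupled
to a binder, simulates exact (Gillespie) state paths, and renders them into
camera-like extension traces: a ~10 nm two-level signal sampled at 1300 Hz
with i.i.d. Gaussian noise.  Every downstream stage (detection, inference)
is exercised against these synthetic experiments.

Scheme topologies
-----------------
``build_oligo_scheme`` / ``build_recq_nf_scheme``
    3 states {C, O, O·B}: the binder hybridizes/binds the strand exposed in
    the open state and transiently blocks closing.
``build_recq_legf_scheme``
    4 states {C, O, C·B, O·B}: the binder reaches a single-stranded gap that
    is available in both phases, so it also locks the closed (hybridized)
    state; bound states cannot change hairpin phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "State",
    "KineticScheme",
    "ProbeGeometry",
    "StatePath",
    "ExtensionTrace",
    "build_two_state_scheme",
    "build_oligo_scheme",
    "build_recq_nf_scheme",
    "build_recq_legf_scheme",
    "gillespie_path",
    "render_trace",
    "apply_force_scaling",
    "path_phase_dwells",
]

OPEN = "open"
CLOSED = "closed"


@dataclass(frozen=True)
class State:
    """A labeled chain state: which hairpin phase, and is a binder attached."""

    label: str
    hairpin_phase: str  # "open" | "closed"
    bound: bool = False

    def __post_init__(self) -> None:
        if self.hairpin_phase not in (OPEN, CLOSED):
            raise ValueError(f"hairpin_phase must be 'open' or 'closed', got {self.hairpin_phase!r}")


@dataclass(frozen=True)
class KineticScheme:
    """Labeled CTMC over hairpin/binder states.

    ``rates`` maps directed edges (from_label, to_label) to rates in s^-1.
    ``concentration_scaled`` marks edges whose rate is the pseudo-first-order
    product c * k_on (metadata; the product is already stored in ``rates``).
    """

    states: tuple[State, ...]
    rates: dict[tuple[str, str], float]
    concentration_scaled: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate state labels")
        by_label = {s.label: s for s in self.states}
        for (src, dst), rate in self.rates.items():
            if src == dst:
                raise ValueError(f"self-edge {src}->{dst} not allowed")
            if src not in by_label or dst not in by_label:
                raise ValueError(f"edge {src}->{dst} references unknown state")
            if rate < 0:
                raise ValueError(f"negative rate on edge {src}->{dst}")
            a, b = by_label[src], by_label[dst]
            if a.bound and a.hairpin_phase != b.hairpin_phase:
                raise ValueError(
                    f"edge {src}->{dst} changes hairpin phase from a bound state; "
                    "binding locks the hairpin"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    def state(self, label: str) -> State:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(label)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def generator(self) -> np.ndarray:
        """Infinitesimal generator Q (rows sum to zero)."""
        n = len(self.states)
        idx = {lab: i for i, lab in enumerate(self.labels)}
        q = np.zeros((n, n))
        for (src, dst), rate in self.rates.items():
            q[idx[src], idx[dst]] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def exit_rates(self) -> np.ndarray:
        return -np.diag(self.generator())

    def phases(self) -> np.ndarray:
        """1 where the state's hairpin phase is open, else 0."""
        return np.array([1 if s.hairpin_phase == OPEN else 0 for s in self.states])


@dataclass(frozen=True)
class ProbeGeometry:
    """Rendering geometry of the probe and its force response.

    ``opening_doubling_force`` is the force increment that doubles the
    opening rate (0.7 pN for the 10-bp probe).
    """

    extension_closed: float = 0.0  # nm
    extension_open: float = 10.0  # nm
    noise_sd: float = 1.5  # nm
    sampling_rate: float = 1300.0  # Hz
    force: float = 10.0  # pN
    force_ref: float = 10.0  # pN
    opening_doubling_force: float = 0.7  # pN

    def __post_init__(self) -> None:
        if self.extension_open <= self.extension_closed:
            raise ValueError("extension_open must exceed extension_closed")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.opening_doubling_force <= 0:
            raise ValueError("opening_doubling_force must be > 0")


@dataclass(frozen=True)
class StatePath:
    """Piecewise-constant chain trajectory.

    ``entry_times[i]`` is when the chain entered ``labels[state_indices[i]]``;
    the last visit is truncated at ``total_duration``.
    """

    labels: tuple[str, ...]
    state_indices: np.ndarray
    entry_times: np.ndarray
    total_duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.entry_times, dtype=float)
        if len(t) == 0:
            raise ValueError("empty path")
        if t[0] != 0.0:
            raise ValueError("first entry must be at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("entry times must be strictly increasing")
        if t[-1] >= self.total_duration:
            raise ValueError("last entry must precede total_duration")

    def __len__(self) -> int:
        return len(self.entry_times)

    @property
    def state_labels(self) -> list[str]:
        return [self.labels[i] for i in self.state_indices]

    def states_at(self, times: np.ndarray) -> np.ndarray:
        """State index occupied at each query time."""
        pos = np.searchsorted(self.entry_times, times, side="right") - 1
        return self.state_indices[np.clip(pos, 0, len(self) - 1)]


@dataclass(frozen=True)
class ExtensionTrace:
    """Uniformly sampled extension signal, optionally with its ground truth."""

    times: np.ndarray
    extensions: np.ndarray
    sampling_rate: float
    truth: StatePath | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.extensions):
            raise ValueError("times and extensions must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return len(self) / self.sampling_rate


def build_two_state_scheme(k_f: float, k_u: float) -> KineticScheme:
    """Free hairpin: C <-> O with closing rate k_f and opening rate k_u."""
    _check_nonneg(k_f=k_f, k_u=k_u)
    states = (State("C", CLOSED), State("O", OPEN))
    return KineticScheme(states, {("C", "O"): k_u, ("O", "C"): k_f})


def build_oligo_scheme(k_f: float, k_u: float, k_on: float, k_off: float, c: float) -> KineticScheme:
    """Oligonucleotide locking: binding only from the open state.

    States {C, O, O·B}; the O -> O·B rate is the pseudo-first-order product
    c (nM) * k_on (nM^-1 s^-1).
    """
    _check_nonneg(k_f=k_f, k_u=k_u, k_on=k_on, k_off=k_off, c=c)
    states = (State("C", CLOSED), State("O", OPEN), State("O·B", OPEN, bound=True))
    rates = {
        ("C", "O"): k_u,
        ("O", "C"): k_f,
        ("O", "O·B"): c * k_on,
        ("O·B", "O"): k_off,
    }
    return KineticScheme(states, rates, frozenset({("O", "O·B")}))


def build_recq_nf_scheme(k_f: float, k_u: float, k_on: float, k_off: float, c: float) -> KineticScheme:
    """Protein binding the fluctuating single strand (no-fork probe).

    Topologically identical to the oligo scheme: the binder is only
    accommodated while the hairpin is open and blocks closing.
    """
    return build_oligo_scheme(k_f, k_u, k_on, k_off, c)


def build_recq_legf_scheme(k_f: float, k_u: float, k_on: float, k_off: float, c: float) -> KineticScheme:
    """Gapped-fork probe: the binding site is exposed in both phases.

    States {C, O, C·B, O·B}; binding at c * k_on from either phase, and a
    bound hairpin cannot change phase, so the closed state is transiently
    stabilized (long closed dwells).
    """
    _check_nonneg(k_f=k_f, k_u=k_u, k_on=k_on, k_off=k_off, c=c)
    states = (
        State("C", CLOSED),
        State("O", OPEN),
        State("C·B", CLOSED, bound=True),
        State("O·B", OPEN, bound=True),
    )
    b = c * k_on
    rates = {
        ("C", "O"): k_u,
        ("O", "C"): k_f,
        ("C", "C·B"): b,
        ("O", "O·B"): b,
        ("C·B", "C"): k_off,
        ("O·B", "O"): k_off,
    }
    return KineticScheme(states, rates, frozenset({("C", "C·B"), ("O", "O·B")}))


def gillespie_path(
    scheme: KineticScheme,
    duration: float,
    seed: int | np.random.Generator | np.random.SeedSequence,
    start: str | None = None,
) -> StatePath:
    """Exact stochastic simulation of the scheme for ``duration`` seconds.

    Holding times are exponential with the state's total exit rate and the
    next state is chosen proportionally to the outgoing edge rates.
    Reproducible: the same seed yields a bit-identical path.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = len(scheme.states)
    idx = {lab: i for i, lab in enumerate(scheme.labels)}

    exit_rate = np.zeros(n)
    # per-state cumulative jump probabilities and destinations
    dests: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(n)]
    cumprob: list[np.ndarray] = [np.empty(0) for _ in range(n)]
    per_state: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for (src, dst), rate in scheme.rates.items():
        if rate > 0:
            per_state[idx[src]].append((idx[dst], rate))
    for i, edges in enumerate(per_state):
        if edges:
            d, r = zip(*edges)
            r = np.asarray(r, dtype=float)
            exit_rate[i] = r.sum()
            dests[i] = np.asarray(d, dtype=np.int64)
            cumprob[i] = np.cumsum(r) / r.sum()

    state = idx[start] if start is not None else 0
    if exit_rate[state] == 0:
        raise RuntimeError(f"start state {scheme.labels[state]} is absorbing")

    # block-drawn randomness keeps the per-jump cost low
    block = 1 << 14
    holds = rng.exponential(size=block)
    picks = rng.random(size=block)
    k = 0

    states_out = [state]
    times_out = [0.0]
    t = 0.0
    while True:
        if k >= block:
            holds = rng.exponential(size=block)
            picks = rng.random(size=block)
            k = 0
        t += holds[k] / exit_rate[state]
        if t >= duration:
            break
        state = int(dests[state][np.searchsorted(cumprob[state], picks[k])])
        k += 1
        if exit_rate[state] == 0:
            raise RuntimeError(
                f"absorbing state {scheme.labels[state]} reached; scheme is mis-specified"
            )
        states_out.append(state)
        times_out.append(t)

    return StatePath(
        labels=scheme.labels,
        state_indices=np.asarray(states_out, dtype=np.int64),
        entry_times=np.asarray(times_out, dtype=float),
        total_duration=float(duration),
    )


def render_trace(
    path: StatePath,
    geometry: ProbeGeometry,
    seed: int | np.random.Generator | np.random.SeedSequence,
    scheme: KineticScheme | None = None,
    phase_open: np.ndarray | None = None,
    metadata: dict | None = None,
) -> ExtensionTrace:
    """Sample a state path on the camera grid and add Gaussian noise.

    Bound states render at the level of their hairpin phase.  The open/closed
    phase of each chain state is taken from ``scheme`` (or an explicit
    ``phase_open`` indicator); paths from two-state schemes default to
    (C -> closed, O -> open) by label.
    """
    if phase_open is None:
        if scheme is not None:
            phase_open = scheme.phases()
        else:
            phase_open = np.array([1 if lab.startswith("O") else 0 for lab in path.labels])
    rng = np.random.default_rng(seed)
    n_samples = int(np.floor(path.total_duration * geometry.sampling_rate))
    times = np.arange(n_samples) / geometry.sampling_rate
    open_at = phase_open[path.states_at(times)]
    levels = np.where(open_at == 1, geometry.extension_open, geometry.extension_closed)
    extensions = levels.astype(float)
    if geometry.noise_sd > 0:
        extensions = extensions + rng.normal(0.0, geometry.noise_sd, size=n_samples)
    meta = dict(metadata or {})
    meta.setdefault("force_pN", geometry.force)
    meta.setdefault("sampling_rate_Hz", geometry.sampling_rate)
    return ExtensionTrace(
        times=times,
        extensions=extensions,
        sampling_rate=geometry.sampling_rate,
        truth=path,
        metadata=meta,
    )


def apply_force_scaling(
    scheme: KineticScheme,
    geometry: ProbeGeometry,
    new_force: float,
    mode: str = "symmetric",
    scale_binding: bool = False,
    valid_band: tuple[float, float] = (8.0, 15.0),
) -> KineticScheme:
    """Rescale hairpin rates for a new pulling force.

    The opening rate doubles every ``geometry.opening_doubling_force`` pN:
    k_u *= 2^(dF/F2).  In the default ``symmetric`` mode the closing rate
    receives the inverse factor (the force tilts the folding landscape);
    ``mode="ku_only"`` leaves k_f untouched.  Binding/unbinding rates are
    force-independent unless ``scale_binding`` is set (not implemented —
    the supported observation is that dissociation is force-insensitive).
    """
    if mode not in ("symmetric", "ku_only"):
        raise ValueError("mode must be 'symmetric' or 'ku_only'")
    if scale_binding:
        raise NotImplementedError("force-dependent binding rates are not supported")
    if not (valid_band[0] <= new_force <= valid_band[1]):
        warnings.warn(
            f"force {new_force} pN outside the validated band {valid_band}; "
            "extrapolating the doubling law",
            stacklevel=2,
        )
    factor = 2.0 ** ((new_force - geometry.force_ref) / geometry.opening_doubling_force)
    by_label = {s.label: s for s in scheme.states}
    new_rates = {}
    for (src, dst), rate in scheme.rates.items():
        a, b = by_label[src], by_label[dst]
        binding_edge = a.bound != b.bound
        if binding_edge:
            new_rates[(src, dst)] = rate
        elif a.hairpin_phase == CLOSED and b.hairpin_phase == OPEN:
            new_rates[(src, dst)] = rate * factor  # opening
        elif a.hairpin_phase == OPEN and b.hairpin_phase == CLOSED:
            new_rates[(src, dst)] = rate / factor if mode == "symmetric" else rate
        else:
            new_rates[(src, dst)] = rate
    return replace(scheme, rates=new_rates)


def path_phase_dwells(path: StatePath, phase_open: np.ndarray, drop_censored: bool = True):
    """Collapse a chain path to alternating open/closed phase dwells.

    Bound states merge into their hairpin phase, which is exactly what the
    extension signal (and hence the detector) sees.  Returns
    ``(states, starts, durations)`` arrays with states as "open"/"closed"
    strings; the first and last (censored) dwells are dropped by default.
    """
    phase = np.asarray(phase_open)[path.state_indices]
    keep = np.concatenate([[True], np.diff(phase) != 0])
    starts = path.entry_times[keep]
    phases = phase[keep]
    bounds = np.concatenate([starts, [path.total_duration]])
    durations = np.diff(bounds)
    states = np.where(phases == 1, OPEN, CLOSED)
    if drop_censored:
        states, starts, durations = states[1:-1], starts[1:-1], durations[1:-1]
    return states, starts, durations


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")
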