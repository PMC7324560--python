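"""Deterministic ODE model of the ventricular action potential.

One set of channel kinetics is shared by every species; what distinguishes
human, dog, zebrafish, rabbit and guinea pig parameterizations is the vector
of effective maximal conductances (mS/uF, or uA/uF for the pump/exchanger
magnitudes) together with the fixed ionic concentrations.  Each current is
of the form

    I_x = b_x * g_x * o_x * (v - E_x)

with ``o_x`` the open probability (a product of Hodgkin-Huxley gates or an
instantaneous rectification function), ``E_x`` the Nernst equilibrium
potential at the fixed concentrations, and ``b_x`` in (0, 1] a drug block
factor.  The L-type calcium current uses a GHK-style flux driving force
instead of the linear ohmic term; the sodium-potassium pump, the
sodium-calcium exchanger and the sarcolemmal calcium pump use standard
voltage-dependent saturation forms scaled by their maximal magnitudes.

Intracellular and extracellular concentrations are held constant, so the
model state is the membrane potential plus twelve gating variables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import _kernels as _k

__all__ = [
    "CHANNELS",
    "GATE_NAMES",
    "SpeciesParams",
    "GatingState",
    "CellState",
    "StimulusProtocol",
    "PacedTrace",
    "SolverConfig",
    "nernst",
    "ttype_gate_functions",
    "channel_current",
    "rhs",
    "resting_state",
    "simulate_paced",
    "species_defaults",
    "shipped_species",
    "scale_conductances",
]

#: Canonical channel identifiers, in kernel order.
CHANNELS = (
    "I_Na",
    "I_NaL",
    "I_CaL",
    "I_CaT",
    "I_to",
    "I_Kr",
    "I_Ks",
    "I_KL",
    "I_NaCa",
    "I_NaK",
    "I_pCa",
    "I_bCl",
    "I_bCa",
)

#: Map channel id -> SpeciesParams attribute holding its magnitude.
CHANNEL_PARAM = {
    "I_Na": "g_Na",
    "I_NaL": "g_NaL",
    "I_CaL": "g_CaL",
    "I_CaT": "g_CaT",
    "I_to": "g_to",
    "I_Kr": "g_Kr",
    "I_Ks": "g_Ks",
    "I_KL": "g_KL",
    "I_NaCa": "Ibar_NaCa",
    "I_NaK": "Ibar_NaK",
    "I_pCa": "Ibar_pCa",
    "I_bCl": "g_bCl",
    "I_bCa": "g_bCa",
}

GATE_NAMES = ("m", "h", "mL", "hL", "d", "f", "a", "i", "xr", "xs", "dT", "fT")

_R = 8.314462618  # J/(mol K)
_F = 96485.33212  # C/mol

_DEFAULT_CONCENTRATIONS = {
    "Na": (10.0, 140.0),
    "K": (120.0, 5.4),
    "Ca": (1.0e-4, 1.8),
    "Cl": (24.0, 150.0),
}

# NaK pump saturation constants (mM)
_KM_NA_NAK = 11.0
_KM_K_NAK = 1.5
# sarcolemmal Ca pump half-saturation (mM)
_KM_PCA = 5.0e-4


def nernst(valence: int, c_in: float, c_out: float, temperature: float = 310.0) -> float:
    """Nernst equilibrium potential in mV.

    Parameters are the ion valence, intracellular and extracellular
    concentrations (mM, any common unit) and the absolute temperature (K).
    """
    if valence == 0:
        raise ValueError("valence must be nonzero")
    if c_in <= 0 or c_out <= 0:
        raise ValueError(
            f"concentrations must be positive, got c_in={c_in}, c_out={c_out}"
        )
    return 1e3 * _R * temperature / (valence * _F) * math.log(c_out / c_in)


def ttype_gate_functions(v: float) -> tuple[float, float, float, float]:
    """T-type calcium gate steady states and time constants at voltage v.

    Returns ``(d_inf, tau_d, f_inf, tau_f)`` with times in ms.  Activation is
    a sigmoid with midpoint -26.3 mV; inactivation has midpoint -61.7 mV.
    """
    d_inf, tau_d = _k.ttype_d(float(v))
    f_inf, tau_f = _k.ttype_f(float(v))
    return float(d_inf), float(tau_d), float(f_inf), float(tau_f)


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species effective maximal conductances and fixed concentrations.

    Conductances are in mS/uF except ``g_CaL`` (nL/(uF*ms), a permeability
    scale for the GHK flux) and the pump/exchanger magnitudes ``Ibar_*``
    (uA/uF).  ``ion_concentrations`` maps ion name to (intracellular mM,
    extracellular mM).
    """

    species_name: str
    g_Kr: float
    g_CaL: float
    g_Na: float
    g_Ks: float
    g_KL: float
    g_to: float
    g_NaL: float
    Ibar_NaCa: float
    Ibar_NaK: float
    g_bCl: float
    g_bCa: float
    Ibar_pCa: float
    g_CaT: float = 0.0
    ion_concentrations: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CONCENTRATIONS)
    )
    temperature: float = 310.0
    stim_amplitude: float | None = None  # frozen default pacing amplitude, A/F

    def __post_init__(self):
        for ch, attr in CHANNEL_PARAM.items():
            val = getattr(self, attr)
            if val < 0:
                raise ValueError(f"{attr} must be >= 0, got {val}")
        for ion, (ci, co) in self.ion_concentrations.items():
            if ci <= 0 or co <= 0:
                raise ValueError(f"non-positive concentration for {ion}")

    # -- derived quantities -------------------------------------------------

    def magnitude(self, channel_id: str) -> float:
        _check_channel(channel_id)
        return getattr(self, CHANNEL_PARAM[channel_id])

    def conductance_vector(self) -> np.ndarray:
        return np.array([self.magnitude(ch) for ch in CHANNELS])

    def equilibrium_potential(self, ion: str) -> float:
        ci, co = self.ion_concentrations[ion]
        z = {"Na": 1, "K": 1, "Ca": 2, "Cl": -1}[ion]
        return nernst(z, ci, co, self.temperature)

    def consts_vector(self) -> np.ndarray:
        """Pack equilibrium potentials and saturation factors for the kernel."""
        na_i, na_o = self.ion_concentrations["Na"]
        k_o = self.ion_concentrations["K"][1]
        ca_i, ca_o = self.ion_concentrations["Ca"]
        vt = 1e3 * _R * self.temperature / _F
        q_ncx = (na_i / na_o) ** 3 * (ca_o / ca_i)
        f_nak_sat = (1.0 / (1.0 + (_KM_NA_NAK / na_i) ** 1.5)) * (
            k_o / (k_o + _KM_K_NAK)
        )
        sigma = (math.exp(na_o / 67.3) - 1.0) / 7.0
        f_pca = ca_i / (ca_i + _KM_PCA)
        return np.array(
            [
                self.equilibrium_potential("Na"),
                self.equilibrium_potential("K"),
                self.equilibrium_potential("Ca"),
                self.equilibrium_potential("Cl"),
                vt,
                ca_i,
                ca_o,
                q_ncx,
                f_nak_sat,
                sigma,
                f_pca,
            ]
        )


def scale_conductances(
    params: SpeciesParams, factors: Mapping[str, float]
) -> SpeciesParams:
    """Return a copy with channel magnitudes multiplied by per-channel factors.

    Keys of ``factors`` are channel ids (``I_Kr`` ...); missing channels keep
    their shipped value.  This is how both the inversion's adjustment factors
    (lambda) and synthetic "individual" perturbations enter the model.
    """
    updates = {}
    for ch, lam in factors.items():
        _check_channel(ch)
        if lam <= 0:
            raise ValueError(f"adjustment factor for {ch} must be > 0, got {lam}")
        attr = CHANNEL_PARAM[ch]
        updates[attr] = getattr(params, attr) * lam
    return replace(params, **updates)


@dataclass
class GatingState:
    """Twelve unitless gating variables in kernel order (each in [0, 1])."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (_k.N_GATES,):
            raise ValueError(f"expected {_k.N_GATES} gates, got {self.values.shape}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(GATE_NAMES, map(float, self.values)))

    @classmethod
    def steady_state(cls, v: float) -> "GatingState":
        inf, _ = _k.gate_steady_tau(float(v))
        return cls(inf.copy())


@dataclass
class CellState:
    v: float
    gates: GatingState
    t: float = 0.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Pacing protocol: a periodic depolarizing current pulse."""

    period: float = 1000.0  # ms (1 Hz)
    stimulus_duration: float = 5.0  # ms
    stimulus_amplitude: float | None = None  # A/F; None -> species default
    n_beats: int = 100
    record_beat: int | None = None  # 0-based; None -> final beat

    def __post_init__(self):
        if not (self.period > self.stimulus_duration > 0):
            raise ValueError("require period > stimulus_duration > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive Rush-Larsen/Heun step control.

    ``dv_max`` (mV) bounds the voltage change per step, ``dt_max``/``dt_min``
    (ms) bound the step itself; the step is additionally capped at 0.05 ms
    during the first 20 ms of each beat so the upstroke is densely sampled.
    """

    dt_min: float = 0.002
    dt_max: float = 0.25
    dv_max: float = 0.2


@dataclass
class PacedTrace:
    """A single-beat transmembrane-voltage time series plus metadata."""

    time: np.ndarray  # ms, strictly increasing, starting at 0
    voltage: np.ndarray  # mV
    metadata: dict

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape:
            raise ValueError("time and voltage must have equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


def _check_channel(channel_id: str) -> None:
    if channel_id not in CHANNEL_PARAM:
        raise KeyError(
            f"unknown channel {channel_id!r}; valid ids: {', '.join(CHANNELS)}"
        )


def _blocks_vector(blocks: Mapping[str, float] | None) -> np.ndarray:
    vec = np.ones(_k.N_CURRENTS)
    if blocks:
        for ch, b in blocks.items():
            _check_channel(ch)
            if not (0 < b <= 1):
                raise ValueError(f"block factor for {ch} must be in (0, 1], got {b}")
            vec[CHANNELS.index(ch)] = b
    return vec


def channel_current(
    channel_id: str,
    state: CellState,
    params: SpeciesParams,
    block_factor: float = 1.0,
) -> float:
    """Membrane current of one channel (A/F, outward positive) at a state."""
    _check_channel(channel_id)
    if not (0 < block_factor <= 1):
        raise ValueError(f"block_factor must be in (0, 1], got {block_factor}")
    blocks = np.ones(_k.N_CURRENTS)
    cur = _k.currents(
        float(state.v),
        state.gates.values,
        params.conductance_vector(),
        blocks,
        params.consts_vector(),
    )
    return block_factor * float(cur[CHANNELS.index(channel_id)])


def rhs(
    state: CellState,
    params: SpeciesParams,
    blocks: Mapping[str, float] | None = None,
    stimulus: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Time derivatives (dv/dt, dgates/dt) of the cell state.

    ``dv/dt = -sum_x I_x + stimulus`` with the stimulus a depolarizing
    current in A/F; gates relax as ``(x_inf - x)/tau_x``.
    """
    if not np.isfinite(state.v) or not np.all(np.isfinite(state.gates.values)):
        if np.isfinite(state.v):
            bad = ", ".join(
                name
                for name, val in zip(GATE_NAMES, state.gates.values)
                if not np.isfinite(val)
            )
            bad = f"gates: {bad}"
        else:
            bad = "v"
        raise ValueError(f"non-finite state ({bad})")
    bvec = _blocks_vector(blocks)
    dv = _k.dv_dt(
        float(state.v),
        state.gates.values,
        params.conductance_vector(),
        bvec,
        params.consts_vector(),
        float(stimulus),
    )
    inf, tau = _k.gate_steady_tau(float(state.v))
    return float(dv), (inf - state.gates.values) / tau


def resting_state(params: SpeciesParams, v0: float = -85.0) -> CellState:
    """Quiescent state: gates at steady state for the initial voltage."""
    return CellState(v=v0, gates=GatingState.steady_state(v0), t=0.0)


# pacing convergence: |APD90(last) - APD90(last-1)| below this is "converged"
CONVERGENCE_TOL_MS = 0.5


def simulate_paced(
    params: SpeciesParams,
    blocks: Mapping[str, float] | None = None,
    protocol: StimulusProtocol | None = None,
    solver: SolverConfig | None = None,
    initial_state: CellState | None = None,
) -> PacedTrace:
    """Pace the model and return the voltage trace of the recorded beat.

    The cell starts from the quiescent resting state (or ``initial_state``)
    and is paced for ``protocol.n_beats`` cycles; the trace of
    ``protocol.record_beat`` (default: final beat) is returned with the
    pacing metadata and a convergence metric
    ``|APD90(recorded) - APD90(previous)|`` in ``metadata['apd90_delta_ms']``
    (NaN when either beat has no measurable action potential).  A
    non-converged metric is recorded as a warning in the metadata, never
    raised.
    """
    protocol = protocol or StimulusProtocol()
    solver = solver or SolverConfig()
    amp = protocol.stimulus_amplitude
    if amp is None:
        amp = params.stim_amplitude
    if amp is None:
        raise ValueError(
            "no stimulus amplitude: set protocol.stimulus_amplitude or use a "
            "species with a shipped default"
        )
    record = protocol.record_beat
    if record is None:
        record = protocol.n_beats - 1
    if not (0 <= record < protocol.n_beats):
        raise ValueError("record_beat out of range")

    state = initial_state or resting_state(params)
    status, tp, vp, n_prev, tr, vr, n_rec, v_end, gates_end = _k.pace(
        float(state.v),
        state.gates.values,
        params.conductance_vector(),
        _blocks_vector(blocks),
        params.consts_vector(),
        protocol.period,
        protocol.stimulus_duration,
        float(amp),
        protocol.n_beats,
        record,
        solver.dt_min,
        solver.dt_max,
        solver.dv_max,
    )
    if status != 0:
        raise RuntimeError(
            f"solver failure (non-finite state); last valid v = {v_end:.3f} mV"
        )

    metadata = {
        "species_name": params.species_name,
        "protocol": {
            "period": protocol.period,
            "stimulus_duration": protocol.stimulus_duration,
            "stimulus_amplitude": float(amp),
            "n_beats": protocol.n_beats,
            "record_beat": record,
        },
        "solver": {
            "dt_min": solver.dt_min,
            "dt_max": solver.dt_max,
            "dv_max": solver.dv_max,
        },
        "blocks": dict(blocks) if blocks else {},
        "final_state": {
            "v": float(v_end),
            "gates": [float(x) for x in gates_end],
        },
    }
    trace = PacedTrace(tr[:n_rec].copy(), vr[:n_rec].copy(), metadata)

    # beat-to-beat convergence metric
    delta = float("nan")
    if n_prev > 0:
        from . import biomarkers as _bm

        prev = PacedTrace(tp[:n_prev].copy(), vp[:n_prev].copy(), {})
        try:
            a_prev = _bm.compute_biomarkers(prev).apd[90]
            a_rec = _bm.compute_biomarkers(trace).apd[90]
            delta = abs(a_rec - a_prev)
        except ValueError:
            delta = float("nan")
    metadata["apd90_delta_ms"] = delta
    if not (delta <= CONVERGENCE_TOL_MS):
        metadata["convergence_warning"] = (
            f"beat-to-beat APD90 change {delta:.3g} ms exceeds "
            f"{CONVERGENCE_TOL_MS} ms (or is undefined)"
        )
    return trace


def final_cell_state(trace: PacedTrace) -> CellState:
    """Reconstruct the end-of-simulation state stored in a trace's metadata."""
    fs = trace.metadata["final_state"]
    return CellState(v=fs["v"], gates=GatingState(np.array(fs["gates"])), t=0.0)


# ---------------------------------------------------------------------------
# Shipped species parameterizations
# ---------------------------------------------------------------------------


def shipped_species() -> tuple[str, ...]:
    return ("human", "dog", "zebrafish", "rabbit", "guinea_pig")


def species_defaults(name: str) -> SpeciesParams:
    """Load one of the five shipped species parameterizations."""
    if name not in shipped_species():
        raise KeyError(
            f"unknown species {name!r}; shipped species: "
            + ", ".join(shipped_species())
        )
    text = resources.files("aptrans").joinpath("data", f"{name}.yaml").read_text()
    return species_from_dict(yaml.safe_load(text))


def species_from_dict(doc: Mapping) -> SpeciesParams:
    """Build SpeciesParams from a parsed species YAML document."""
    conc = {
        ion: (float(pair[0]), float(pair[1]))
        for ion, pair in doc.get("ion_concentrations", _DEFAULT_CONCENTRATIONS).items()
    }
    kwargs = {attr: float(doc[attr]) for attr in CHANNEL_PARAM.values() if attr in doc}
    missing = set(CHANNEL_PARAM.values()) - set(kwargs)
    if missing:
        raise ValueError(f"species file missing parameters: {sorted(missing)}")
    return SpeciesParams(
        species_name=str(doc["species_name"]),
        ion_concentrations=conc,
        temperature=float(doc.get("temperature", 310.0)),
        stim_amplitude=(
            float(doc["stim_amplitude"]) if doc.get("stim_amplitude") is not None else None
        ),
        **kwargs,
    )


def species_to_dict(params: SpeciesParams) -> dict:
    doc = {"species_name": params.species_name}
    for attr in CHANNEL_PARAM.values():
        doc[attr] = float(getattr(params, attr))
    doc["ion_concentrations"] = {
        ion: [float(ci), float(co)]
        for ion, (ci, co) in params.ion_concentrations.items()
    }
    doc["temperature"] = float(params.temperature)
    if params.stim_amplitude is not None:
        doc["stim_amplitude"] = float(params.stim_amplitude)
    return doc


def diastolic_threshold(
    params: SpeciesParams,
    duration: float = 5.0,
    lo: float = 0.5,
    hi: float = 100.0,
    tol: float = 0.5,
) -> float:
    """Minimal 5 ms stimulus amplitude (A/F) that elicits an action potential
    from rest, found by bisection.  Used once per species to freeze the
    shipped pacing amplitude at 1.5x this threshold.
    """
    from . import biomarkers as _bm

    def fires(amp: float) -> bool:
        proto = StimulusProtocol(
            stimulus_duration=duration, stimulus_amplitude=amp, n_beats=1
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trace = simulate_paced(params, protocol=proto)
        try:
            bm = _bm.compute_biomarkers(trace)
        except ValueError:
            return False
        return bm.v_max > 0.0

    if not fires(hi):
        raise RuntimeError(f"no action potential even at {hi} A/F")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi
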