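"""Markov gating model of KCNQ1 with a Ca2+-calmodulin-starved state layer.

The wild-type scheme has eight states.  The "normal" layer is a five-state
scheme with two sequentially activated voltage-sensor states, each of which
can open the pore:

    RC = IC = AC        (voltage-sensor resting / intermediate / activated)
         |    |
         IO   AO        (intermediate-open and activated-open, conducting)

with an additional IO = AO edge mirroring the sensor step among the open
states.  The "starved" layer (RC*, IC*, AC*) holds channels whose bound
calmodulin lacks Ca2+; starred states are non-conducting, their own
activation is shallowly voltage dependent, and the IC* -> AC* rate is small,
so channels accumulate in IC* during depolarizations at low Ca2+.  Vertical
transitions X <-> X* carry the Ca2+ dependence: entry into the starved layer
scales with (1 - f(Ca)) and exit with f(Ca), where f is a Hill function of
the intracellular free Ca2+.  The IC -> IO opening rate is additionally
scaled by f(Ca) (partial block of the intermediate opening pathway at low
Ca2+).

Disease variants (R116L, V185M, P369L) are modelled with the starved layer
functionally disabled (f pinned to 1); V185M additionally has slowed
voltage-sensor activation.

Convention: the generator matrix is column-stochastic, Q[i, j] = rate from
state j to state i for i != j, columns sum to zero, and occupancancy evolves
as dp/dt = Q p with p a column vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm

from .protocols import VoltageProtocol, Segment

# physical constants
R_GAS = 8.31446  # J/(mol K)
FARADAY = 96485.33  # C/mol
DEFAULT_TEMPERATURE_K = 294.15  # 21 C, matching the chelator calculations

VARIANTS = ("WT", "R116L", "V185M", "P369L")

#: maximum sub-step for ramp segments (ms)
RAMP_SUBSTEP_MS = 0.1


class GatingError(ValueError):
    """Raised for invalid schemes, variants or simulation inputs."""


def thermal_voltage_mV(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT/F in millivolts."""
    return 1000.0 * R_GAS * temperature_K / FARADAY


@dataclass(frozen=True)
class CaSensor:
    """Hill-type Ca2+-CaM occupancy sensor, f(Ca) in [0, 1]."""

    kd: float = 100e-9  # molar
    hill_n: float = 2.0

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.hill_n < 1:
            raise GatingError("CaSensor requires kd > 0 and hill_n >= 1")

    def f(self, ca: float | np.ndarray) -> float | np.ndarray:
        ca = np.asarray(ca, dtype=float)
        if np.any(ca < 0) or not np.all(np.isfinite(ca)):
            raise GatingError("ca must be finite and >= 0")
        x = (ca / self.kd) ** self.hill_n
        out = x / (1.0 + x)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RateLaw:
    """Single-exponential voltage dependence k(V) = k0 * exp(z V / (RT/F)).

    ``ca_scaling`` multiplies the rate by f(Ca) ("up_with_ca") or by
    1 - f(Ca) ("down_with_ca").  For "up_with_ca", ``ca_floor`` turns the
    modulation into a partial facilitation, floor + (1 - floor) * f(Ca),
    expressing transitions that proceed without Ca2+-CaM but are accelerated
    by it.
    """

    k0: float  # 1/ms at 0 mV
    z: float = 0.0  # effective charge, signed
    ca_scaling: str = "none"  # none | up_with_ca | down_with_ca
    ca_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise GatingError(f"rate k0 must be > 0, got {self.k0}")
        if self.ca_scaling not in ("none", "up_with_ca", "down_with_ca"):
            raise GatingError(f"unknown ca_scaling {self.ca_scaling!r}")
        if not 0.0 <= self.ca_floor <= 1.0:
            raise GatingError("ca_floor must be in [0, 1]")

    def __call__(self, v_mV: float, f_ca: float, vt_mV: float) -> float:
        k = self.k0 * np.exp(self.z * v_mV / vt_mV)
        if self.ca_scaling == "up_with_ca":
            k *= self.ca_floor + (1.0 - self.ca_floor) * f_ca
        elif self.ca_scaling == "down_with_ca":
            k *= 1.0 - f_ca
        return k


@dataclass(frozen=True)
class State:
    name: str
    conducting_weight: float = 0.0
    layer: str = "normal"  # normal | starved

    def __post_init__(self) -> None:
        if self.conducting_weight < 0:
            raise GatingError("conducting_weight must be >= 0")
        if self.layer not in ("normal", "starved"):
            raise GatingError(f"unknown layer {self.layer!r}")
        if self.layer == "starved" and self.conducting_weight != 0:
            raise GatingError("starved-layer states must be non-conducting")


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    rate_law: RateLaw


@dataclass(frozen=True)
class GatingScheme:
    """State graph plus voltage/Ca2+-dependent rate laws."""

    states: tuple[State, ...]
    transitions: tuple[Transition, ...]
    ca_sensor: CaSensor | None = CaSensor()  # None pins f(Ca) to 1
    temperature_K: float = DEFAULT_TEMPERATURE_K
    name: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise GatingError("state names must be unique")
        for tr in self.transitions:
            if tr.source not in names or tr.target not in names:
                raise GatingError(
                    f"transition endpoint {tr.source}->{tr.target} not in states"
                )

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def conducting_weights(self) -> np.ndarray:
        return np.array([s.conducting_weight for s in self.states])

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    def f_ca(self, ca: float) -> float:
        if self.ca_sensor is None:
            if not (np.isfinite(ca) and ca >= 0):
                raise GatingError("ca must be finite and >= 0")
            return 1.0
        return float(self.ca_sensor.f(ca))

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "temperature_K": self.temperature_K,
            "ca_sensor": (
                None
                if self.ca_sensor is None
                else {"kd": self.ca_sensor.kd, "n": self.ca_sensor.hill_n}
            ),
            "states": [
                {"name": s.name, "weight": s.conducting_weight, "layer": s.layer}
                for s in self.states
            ],
            "transitions": [
                {
                    "from": t.source,
                    "to": t.target,
                    "k0": t.rate_law.k0,
                    "z": t.rate_law.z,
                    "ca_scaling": t.rate_law.ca_scaling,
                    "ca_floor": t.rate_law.ca_floor,
                }
                for t in self.transitions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GatingScheme":
        sensor = d.get("ca_sensor")
        return cls(
            states=tuple(
                State(s["name"], s.get("weight", 0.0), s.get("layer", "normal"))
                for s in d["states"]
            ),
            transitions=tuple(
                Transition(
                    t["from"],
                    t["to"],
                    RateLaw(
                        t["k0"],
                        t.get("z", 0.0),
                        t.get("ca_scaling", "none"),
                        t.get("ca_floor", 0.0),
                    ),
                )
                for t in d["transitions"]
            ),
            ca_sensor=None if sensor is None else CaSensor(sensor["kd"], sensor["n"]),
            temperature_K=d.get("temperature_K", DEFAULT_TEMPERATURE_K),
            name=d.get("name", ""),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GatingScheme":
        return cls.from_dict(json.loads(s))


@dataclass
class OccupancyTrace:
    """Per-state occupancy over time for one sweep."""

    time_ms: np.ndarray
    occupancy: np.ndarray  # (n_time, n_states)
    voltage_mV: np.ndarray
    ca_molar: np.ndarray
    state_names: list[str]


# ---------------------------------------------------------------------------
# default parameterization


def default_parameters() -> dict:
    """The calibrated default rate set (see analysis/02_calibrate_gating.py)."""
    with resources.files("kcnq1ca.data").joinpath("default_rates.json").open() as fh:
        return json.load(fh)


def scheme_from_parameters(
    params: dict,
    variant: str = "WT",
    include_starved_layer: bool = True,
) -> GatingScheme:
    """Assemble a GatingScheme from a flat rate-parameter dictionary."""
    if variant not in VARIANTS:
        raise GatingError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    p = dict(params)
    mut = p.get("variants", {}).get(variant, {})
    act_scale = mut.get("activation_scale", 1.0)
    deact_scale = mut.get("deactivation_scale", 1.0)

    w_io = p["w_IO"]
    states = [
        State("RC"),
        State("IC"),
        State("AC"),
        State("IO", conducting_weight=w_io),
        State("AO", conducting_weight=1.0),
    ]
    # the IO=AO edge mirrors the sensor step; its rates are tied to the
    # IC=AC step so that the IC-AC-AO-IO cycle satisfies detailed balance
    a2o_0 = p["a2_0"] * (p["ko2_0"] / p["ko1_0"])
    b2o_0 = p["b2_0"] * (p["kc2_0"] / p["kc1_0"])
    a2_floor = p.get("a2_ca_floor", 1.0)  # Ca2+-CaM facilitation of IC->AC
    transitions = [
        Transition("RC", "IC", RateLaw(p["a1_0"] * act_scale, p["z_a1"])),
        Transition("IC", "RC", RateLaw(p["b1_0"] * deact_scale, -p["z_b1"])),
        Transition(
            "IC",
            "AC",
            RateLaw(
                p["a2_0"] * act_scale, p["z_a2"],
                ca_scaling="up_with_ca" if a2_floor < 1.0 else "none",
                ca_floor=a2_floor if a2_floor < 1.0 else 0.0,
            ),
        ),
        Transition("AC", "IC", RateLaw(p["b2_0"] * deact_scale, -p["z_b2"])),
        Transition(
            "IC",
            "IO",
            RateLaw(p["ko1_0"], 0.0, ca_scaling="up_with_ca",
                    ca_floor=p.get("ko1_ca_floor", 0.0)),
        ),
        Transition("IO", "IC", RateLaw(p["kc1_0"], 0.0)),
        Transition("AC", "AO", RateLaw(p["ko2_0"], 0.0)),
        Transition("AO", "AC", RateLaw(p["kc2_0"], 0.0)),
        Transition(
            "IO",
            "AO",
            RateLaw(
                a2o_0 * act_scale, p["z_a2"],
                ca_scaling="up_with_ca" if a2_floor < 1.0 else "none",
                ca_floor=a2_floor if a2_floor < 1.0 else 0.0,
            ),
        ),
        Transition("AO", "IO", RateLaw(b2o_0 * deact_scale, -p["z_b2"])),
    ]

    sensor: CaSensor | None = CaSensor(p["ca_kd"], p["ca_hill_n"])
    if variant != "WT" or mut.get("pin_ca", False):
        # mutants have lost the Ca2+-CaM dependence: f(Ca) pinned to 1, which
        # makes the starved layer unreachable and lifts the IC->IO block
        sensor = None

    if include_starved_layer:
        zs = p["z_s"]
        states += [
            State("RC*", layer="starved"),
            State("IC*", layer="starved"),
            State("AC*", layer="starved"),
        ]
        transitions += [
            Transition("RC*", "IC*", RateLaw(p["a1s_0"], zs)),
            Transition("IC*", "RC*", RateLaw(p["b1s_0"], -zs)),
            # limited possibility of exit from IC* towards the activated end
            Transition("IC*", "AC*", RateLaw(p["a2s_0"], zs)),
            Transition("AC*", "IC*", RateLaw(p["b2s_0"], -zs)),
        ]
        for x in ("RC", "IC", "AC"):
            transitions += [
                Transition(
                    x, x + "*",
                    RateLaw(p[f"kon_{x}"], p.get(f"z_kon_{x}", 0.0),
                            ca_scaling="down_with_ca"),
                ),
                Transition(
                    x + "*", x, RateLaw(p[f"koff_{x}"], 0.0, ca_scaling="up_with_ca")
                ),
            ]

    return GatingScheme(
        states=tuple(states),
        transitions=tuple(transitions),
        ca_sensor=sensor,
        temperature_K=p.get("temperature_K", DEFAULT_TEMPERATURE_K),
        name=f"{variant}-{'8state' if include_starved_layer else '5state'}",
    )


def build_default_scheme(
    variant: str = "WT", include_starved_layer: bool = True
) -> GatingScheme:
    """The calibrated default scheme for a channel variant.

    WT with the starved layer included is the full 8-state model; mutants are
    effectively 5-state models (their starred states are unreachable because
    f(Ca) is pinned to 1), returned as 5-state schemes unless the starved
    layer is explicitly requested.
    """
    params = default_parameters()
    if variant != "WT":
        # mutants default to the plain 5-state scheme
        return scheme_from_parameters(params, variant, include_starved_layer)
    return scheme_from_parameters(params, variant, include_starved_layer)


# ---------------------------------------------------------------------------
# simulation


def rate_matrix(scheme: GatingScheme, v: float, ca: float) -> np.ndarray:
    """Column-stochastic generator Q (1/ms); dp/dt = Q p."""
    if not np.isfinite(v):
        raise GatingError("voltage must be finite")
    if not (np.isfinite(ca) and ca >= 0):
        raise GatingError("ca must be finite and >= 0")
    f = scheme.f_ca(ca)
    vt = thermal_voltage_mV(scheme.temperature_K)
    n = scheme.n_states
    idx = {s.name: i for i, s in enumerate(scheme.states)}
    Q = np.zeros((n, n))
    for tr in scheme.transitions:
        k = tr.rate_law(v, f, vt)
        Q[idx[tr.target], idx[tr.source]] += k
    Q[np.diag_indices(n)] -= Q.sum(axis=0)
    return Q


def steady_state(scheme: GatingScheme, v: float, ca: float) -> np.ndarray:
    """Stationary occupancy p with Q p = 0, p >= 0, sum(p) = 1."""
    Q = rate_matrix(scheme, v, ca)
    n = scheme.n_states
    A = np.vstack([Q, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = float(np.max(np.abs(Q @ p)))
    if resid > 1e-10 or np.min(p) < -1e-9:
        raise GatingError(
            f"steady-state solve failed (residual {resid:.2e}, min p {p.min():.2e})"
        )
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _as_ca_fn(ca: float | Callable[[float], float]) -> Callable[[float], float]:
    if callable(ca):
        return ca
    return lambda t_s, _c=float(ca): _c


def simulate(
    scheme: GatingScheme,
    protocol: VoltageProtocol,
    ca: float | Callable[[float], float] = 100e-9,
    dt_out: float = 1.0,
    p0: np.ndarray | None = None,
    carryover: bool = True,
) -> list[OccupancyTrace]:
    """Deterministic occupancy simulation of a protocol.

    Piecewise-constant segments are propagated with the matrix exponential of
    Q*dt; ramp segments are sub-stepped with dt <= 0.1 ms using the midpoint
    voltage.  ``ca`` is either a constant (molar) or a function of absolute
    time in seconds (evaluated once per segment; the intracellular Ca2+
    dynamics of interest are orders of magnitude slower than a sweep).

    The first sweep starts from the steady state at the holding potential
    (or from ``p0``); with ``carryover`` the occupancy is propagated through
    the inter-sweep interval at holding, otherwise every sweep restarts from
    the holding steady state at its own Ca2+ level.
    """
    if dt_out <= 0:
        raise GatingError("dt_out must be > 0")
    ca_fn = _as_ca_fn(ca)
    starts_s = protocol.sweep_start_times_s()
    traces: list[OccupancyTrace] = []
    p = None
    for isw in range(protocol.n_sweeps):
        t0_s = starts_s[isw]
        ca_now = ca_fn(t0_s)
        if isw == 0:
            p = p0.copy() if p0 is not None else steady_state(
                scheme, protocol.holding_mV, ca_now
            )
        elif not carryover:
            p = steady_state(scheme, protocol.holding_mV, ca_now)
        elif protocol.inter_sweep_interval_ms > 0:
            Qh = rate_matrix(scheme, protocol.holding_mV, ca_now)
            p = expm(Qh * protocol.inter_sweep_interval_ms) @ p

        t_grid = np.arange(0.0, protocol.sweep_duration_ms, dt_out)
        occ = np.empty((t_grid.size, scheme.n_states))
        vts = np.empty(t_grid.size)
        onsets = protocol.segment_onsets_ms()
        k = 0  # index into the output grid
        for seg, onset in zip(protocol.sweeps[isw], onsets):
            ca_seg = ca_fn(t0_s + onset / 1000.0)
            n_pts = int(round(seg.dur_ms / dt_out))
            seg_t = t_grid[k : k + n_pts] - onset
            if not seg.is_ramp:
                Q = rate_matrix(scheme, seg.v0_mV, ca_seg)
                P = expm(Q * dt_out)
                for j in range(n_pts):
                    occ[k + j] = p
                    vts[k + j] = seg.v0_mV
                    p = P @ p
            else:
                n_sub = max(1, int(np.ceil(dt_out / RAMP_SUBSTEP_MS)))
                dt_sub = dt_out / n_sub
                for j in range(n_pts):
                    occ[k + j] = p
                    vts[k + j] = seg.voltage_at(seg_t[j])
                    for m in range(n_sub):
                        v_mid = seg.voltage_at(seg_t[j] + (m + 0.5) * dt_sub)
                        Q = rate_matrix(scheme, v_mid, ca_seg)
                        p = expm(Q * dt_sub) @ p
            k += n_pts
        # numerical guard: renormalize drift below 1e-9
        occ = np.clip(occ, 0.0, None)
        occ /= occ.sum(axis=1, keepdims=True)
        traces.append(
            OccupancyTrace(
                time_ms=t_grid,
                occupancy=occ,
                voltage_mV=vts,
                ca_molar=np.full(t_grid.size, ca_fn(t0_s)),
                state_names=scheme.state_names,
            )
        )
    return traces


def current_from_occupancy(
    occ: OccupancyTrace, g_max: float, e_k: float, weights: np.ndarray | None = None
) -> np.ndarray:
    """Whole-cell current (pA): I = g_max * sum_i w_i p_i * (V - E_K).

    ``g_max`` in nS, voltages in mV; conducting weights default to the ones
    implied by the trace's scheme ordering and must be supplied otherwise.
    """
    if g_max <= 0:
        raise GatingError("g_max must be > 0")
    if weights is None:
        raise GatingError("conducting weights must be provided")
    w = np.asarray(weights, dtype=float)
    open_frac = occ.occupancy @ w
    return g_max * open_frac * (occ.voltage_mV - e_k)


def conducting_fraction(scheme: GatingScheme, occ: OccupancyTrace) -> np.ndarray:
    """Weighted conducting occupancy over time."""
    return occ.occupancy @ scheme.conducting_weights


def simulate_current(
    scheme: GatingScheme,
    protocol: VoltageProtocol,
    ca: float | Callable[[float], float] = 100e-9,
    g_max: float = 20.0,
    e_k: float = -86.0,
    dt_out: float = 1.0,
    carryover: bool = True,
) -> tuple[list[OccupancyTrace], np.ndarray]:
    """Convenience wrapper: occupancy traces plus the (n_sweeps, n_t) current."""
    traces = simulate(scheme, protocol, ca=ca, dt_out=dt_out, carryover=carryover)
    w = scheme.conducting_weights
    cur = np.vstack(
        [current_from_occupancy(tr, g_max, e_k, weights=w) for tr in traces]
    )
    return traces, cur
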