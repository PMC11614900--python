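"""Density-matrix simulation of SABRE spin-order-transfer (SOT) sequences.

Simulates phINEPT+ and ESOTHERIC pulse sequences on small spin-1/2 systems
(two parahydrogen-derived Ir hydrides plus one or two equatorial ``15N``
nuclei), producing the ``15N`` polarization as a function of the sequence
delays (tau1, tau2).  Chemical exchange during the SOT block is accounted
for by a multiplicative survival factor exp(-k_d * t_tot).

Conventions
-----------
* Rotating frame on both RF channels; all offsets default to zero (pulses
  on resonance with the hydrides / the equatorial substrate).
* Heteronuclear couplings are truncated to their secular 2*pi*J*Iz*Sz part
  (high-field approximation); homonuclear H-H coupling is kept as the full
  isotropic scalar term because the two hydrides are chemically equivalent
  and therefore strongly coupled.
* Pulses are ideal, instantaneous rotations; a flip angle ``theta`` about
  phase ``phi`` applies U = exp(-i*theta*(Fx*cos(phi) + Fy*sin(phi))) to
  every spin of the addressed channel, so a +90deg pulse of phase x takes
  Iz -> -Iy.
* The parahydrogen-derived initial condition is the zz-projected singlet
  rho = 2**-n * (E - 4*I1z*I2z): exchange of the chemically equivalent but
  magnetically inequivalent hydrides averages the singlet, leaving the
  observable antiphase zz order.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpinSystem",
    "DensityState",
    "PulseSequence",
    "PolarizationMap",
    "Pulse",
    "Delay",
    "CoherenceFilter",
    "build_spin_system",
    "preset_system",
    "initial_hydride_order",
    "initial_singlet_order",
    "apply_pulse",
    "evolve_free",
    "apply_filter",
    "make_sequence",
    "run_sot",
    "run_sequence",
    "sot_map",
    "optimize_sot",
    "total_time",
]

CHANNELS = ("H", "N")


# ---------------------------------------------------------------------------
# spin operators

@functools.lru_cache(maxsize=8)
def _single_spin_ops() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sx = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
    sy = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
    sz = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
    return sx, sy, sz


@functools.lru_cache(maxsize=16)
def spin_operators(n: int) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]:
    """Cartesian operators (Ix, Iy, Iz) for each of ``n`` spins-1/2.

    Built by Kronecker products; operator ``k`` acts on the ``k``-th tensor
    factor of the 2**n dimensional Hilbert space.
    """
    ops = []
    eye2 = np.eye(2, dtype=complex)
    for k in range(n):
        triple = []
        for s in _single_spin_ops():
            op = np.array([[1.0 + 0j]])
            for j in range(n):
                op = np.kron(op, s if j == k else eye2)
            triple.append(op)
        ops.append(tuple(triple))
    return tuple(ops)


# ---------------------------------------------------------------------------
# spin system

class SpinSystem:
    """An ordered set of spin-1/2 nuclei with a scalar-coupling network.

    Parameters
    ----------
    labels:
        Spin labels, e.g. ``("H1", "H2", "N1")``.  The RF channel of each
        spin is the leading letter of its label (``H`` or ``N``).
    couplings:
        Symmetric (n, n) array of scalar couplings J_ij in Hz (signed),
        zero diagonal.
    offsets:
        Per-spin rotating-frame offsets in Hz; default all zero.
    """

    def __init__(self, labels: Sequence[str], couplings: np.ndarray,
                 offsets: Sequence[float] | None = None):
        self.labels = tuple(str(l) for l in labels)
        n = len(self.labels)
        if n == 0:
            raise ValueError("at least one spin required")
        self.channels = tuple(l[0].upper() for l in self.labels)
        for ch, lab in zip(self.channels, self.labels):
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel for spin label {lab!r}; "
                                 f"labels must start with one of {CHANNELS}")
        J = np.asarray(couplings, dtype=float)
        if J.shape != (n, n):
            raise ValueError(f"coupling table must be {n}x{n}, got {J.shape}")
        if not np.allclose(J, J.T, atol=1e-12):
            raise ValueError("coupling table must be symmetric (J_ij = J_ji)")
        if not np.allclose(np.diag(J), 0.0):
            raise ValueError("coupling table must have zero diagonal")
        self.couplings = 0.5 * (J + J.T)
        self.offsets = (np.zeros(n) if offsets is None
                        else np.asarray(offsets, dtype=float))
        if self.offsets.shape != (n,):
            raise ValueError("offsets must have one entry per spin")
        self._cache: dict = {}

    # -- basic protocol ---------------------------------------------------
    @property
    def n_spins(self) -> int:
        return len(self.labels)

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SpinSystem(labels={self.labels})"

    def channel_indices(self, channel: str) -> tuple[int, ...]:
        channel = channel.upper()
        return tuple(i for i, c in enumerate(self.channels) if c == channel)

    def index(self, spin: "int | str") -> int:
        if isinstance(spin, str):
            return self.labels.index(spin)
        return int(spin)

    # -- operators --------------------------------------------------------
    @property
    def ops(self):
        return spin_operators(self.n_spins)

    def op(self, spin: "int | str", axis: str) -> np.ndarray:
        return self.ops[self.index(spin)]["xyz".index(axis)]

    def hamiltonian(self) -> np.ndarray:
        """Free-evolution Hamiltonian in Hz (divide of 2*pi taken out).

        H/2pi = sum_i nu_i*Iiz
              + sum_{i<j, same channel} J_ij (Ii . Ij)          (strong coupling)
              + sum_{i<j, cross channel} J_ij Iiz Ijz           (secular)
        """
        if "H0" in self._cache:
            return self._cache["H0"]
        n, ops = self.n_spins, self.ops
        H = np.zeros((self.dim, self.dim), dtype=complex)
        for i in range(n):
            if self.offsets[i]:
                H += self.offsets[i] * ops[i][2]
        for i in range(n):
            for j in range(i + 1, n):
                J = self.couplings[i, j]
                if J == 0.0:
                    continue
                if self.channels[i] == self.channels[j]:
                    H += J * (ops[i][0] @ ops[j][0] + ops[i][1] @ ops[j][1]
                              + ops[i][2] @ ops[j][2])
                else:
                    H += J * (ops[i][2] @ ops[j][2])
        self._cache["H0"] = H
        return H

    def _eig(self):
        if "eig" not in self._cache:
            w, V = np.linalg.eigh(self.hamiltonian())
            self._cache["eig"] = (w, V)
        return self._cache["eig"]

    def propagator_free(self, duration: float) -> np.ndarray:
        """Unitary for free evolution of ``duration`` seconds."""
        if duration < 0:
            raise ValueError("duration must be non-negative")
        key = ("U", round(duration, 12))
        if key in self._cache:
            return self._cache[key]
        w, V = self._eig()
        phase = np.exp(-2j * np.pi * w * duration)
        U = (V * phase) @ V.conj().T
        if len(self._cache) < 4096:  # keep repeated grid delays cheap
            self._cache[key] = U
        return U

    def propagator_pulse(self, channel: str, flip_deg: float,
                         phase_deg: float) -> np.ndarray:
        key = ("P", channel.upper(), round(flip_deg, 9), round(phase_deg, 9))
        if key not in self._cache:
            idx = self.channel_indices(channel)
            if not idx:
                raise ValueError(f"system has no spins on channel {channel!r}")
            theta = math.radians(flip_deg)
            phi = math.radians(phase_deg)
            F = sum(math.cos(phi) * self.ops[i][0] + math.sin(phi) * self.ops[i][1]
                    for i in idx)
            w, V = np.linalg.eigh(F)
            self._cache[key] = (V * np.exp(-1j * theta * w)) @ V.conj().T
        return self._cache[key]


def build_spin_system(labels: Sequence[str],
                      couplings: "np.ndarray | Mapping | None" = None,
                      offsets: Sequence[float] | None = None) -> SpinSystem:
    """Construct a validated :class:`SpinSystem`.

    ``couplings`` may be a full symmetric matrix (Hz) or a mapping
    ``{(label_i, label_j): J_ij}``; unspecified pairs default to zero.
    """
    labels = list(labels)
    n = len(labels)
    if couplings is None:
        J = np.zeros((n, n))
    elif isinstance(couplings, Mapping):
        J = np.zeros((n, n))
        for (a, b), val in couplings.items():
            i, j = labels.index(a), labels.index(b)
            if i == j:
                raise ValueError("self-coupling is not allowed")
            J[i, j] = J[j, i] = float(val)
    else:
        J = np.asarray(couplings, dtype=float)
    return SpinSystem(labels, J, offsets)


#: Couplings of the symmetric Ir-dihydride model systems (Hz): hydride-hydride
#: J_HH = -8, trans hydride-15N J_NHt = -22, cis hydride-15N J_NHc = 0.
J_HH = -8.0
J_NHT = -22.0
J_NHC = 0.0


def preset_system(name: str) -> SpinSystem:
    """Built-in model systems.

    ``threeSpin``: two hydrides + one 15N (natural-abundance substrate case);
    ``fourSpin``: two hydrides + two 15N, each 15N trans-coupled to one
    hydride (fully labeled, two equatorial ligands).
    """
    key = name.replace("-", "").replace("_", "").lower()
    if key == "threespin":
        return build_spin_system(
            ["H1", "H2", "N1"],
            {("H1", "H2"): J_HH, ("H1", "N1"): J_NHT, ("H2", "N1"): J_NHC})
    if key == "fourspin":
        return build_spin_system(
            ["H1", "H2", "N1", "N2"],
            {("H1", "H2"): J_HH,
             ("H1", "N1"): J_NHT, ("H2", "N1"): J_NHC,
             ("H2", "N2"): J_NHT, ("H1", "N2"): J_NHC,
             ("N1", "N2"): 0.0})
    raise ValueError(f"unknown preset {name!r}; use 'threeSpin' or 'fourSpin'")


# ---------------------------------------------------------------------------
# density states

@dataclass
class DensityState:
    """A trace-one Hermitian density operator tied to a :class:`SpinSystem`."""

    rho: np.ndarray
    system: SpinSystem

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=complex)
        if self.rho.shape != (self.system.dim, self.system.dim):
            raise ValueError("density matrix dimension does not match system")

    def expect(self, op: np.ndarray) -> complex:
        return complex(np.trace(self.rho @ op))

    def expect_spin(self, spin: "int | str", axis: str) -> float:
        return self.expect(self.system.op(spin, axis)).real

    @property
    def trace(self) -> float:
        return float(np.trace(self.rho).real)

    @property
    def purity(self) -> float:
        return float(np.trace(self.rho @ self.rho).real)

    def copy(self) -> "DensityState":
        return DensityState(self.rho.copy(), self.system)


def initial_hydride_order(system: SpinSystem,
                          hydride_pair: Sequence["int | str"] | None = None
                          ) -> DensityState:
    """Exchange-averaged parahydrogen order: rho = 2**-n (E - 4 I1z I2z).

    The two hydrides carry pure antiphase zz correlation and every other
    spin is unpolarized.
    """
    i, j = _hydride_pair(system, hydride_pair)
    n = system.n_spins
    rho = (np.eye(system.dim, dtype=complex)
           - 4.0 * system.ops[i][2] @ system.ops[j][2]) / system.dim
    return DensityState(rho, system)


def initial_singlet_order(system: SpinSystem,
                          hydride_pair: Sequence["int | str"] | None = None
                          ) -> DensityState:
    """Full two-spin singlet on the hydride pair: rho = 2**-n (E - 4 I1.I2).

    Provided for sensitivity checks against the default zz-projected order.
    """
    i, j = _hydride_pair(system, hydride_pair)
    ops = system.ops
    dot = sum(ops[i][a] @ ops[j][a] for a in range(3))
    rho = (np.eye(system.dim, dtype=complex) - 4.0 * dot) / system.dim
    return DensityState(rho, system)


def _hydride_pair(system: SpinSystem, pair) -> tuple[int, int]:
    if pair is None:
        h = system.channel_indices("H")
        if len(h) < 2:
            raise ValueError("system needs two H-channel spins for "
                             "parahydrogen-derived order")
        return h[0], h[1]
    i, j = (system.index(p) for p in pair)
    if i == j:
        raise ValueError("hydride pair must be two distinct spins")
    for k in (i, j):
        if system.channels[k] != "H":
            raise ValueError(f"spin {system.labels[k]} is not on the H channel")
    return i, j


# ---------------------------------------------------------------------------
# events and evolution

@dataclass(frozen=True)
class Pulse:
    """Ideal hard pulse: simultaneous rotation of all spins of a channel."""
    channel: str
    flip: float   # degrees
    phase: float  # degrees; 0 = x, 90 = y


@dataclass(frozen=True)
class Delay:
    duration: float  # seconds

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("delays must be non-negative")


@dataclass(frozen=True)
class CoherenceFilter:
    """Pulsed-field-gradient style filter.

    Projects the density operator onto the identity plus the longitudinal
    single-spin terms of the N channel, discarding all residual (multi-)
    quantum coherences and proton order.
    """


Event = "Pulse | Delay | CoherenceFilter"


def apply_pulse(state: DensityState, channel: str, flip_deg: float,
                phase_deg: float) -> DensityState:
    """Ideal instantaneous rotation of every spin on ``channel``."""
    U = state.system.propagator_pulse(channel, flip_deg, phase_deg)
    return DensityState(U @ state.rho @ U.conj().T, state.system)


def evolve_free(state: DensityState, duration: float) -> DensityState:
    """Unitary free evolution under the system Hamiltonian."""
    if duration == 0:
        return state.copy()
    U = state.system.propagator_free(duration)
    return DensityState(U @ state.rho @ U.conj().T, state.system)


def apply_filter(state: DensityState) -> DensityState:
    system = state.system
    n = system.n_spins
    rho = np.eye(system.dim, dtype=complex) / system.dim
    norm = system.dim / 4.0  # tr(Iz @ Iz) for one spin in 2**n space
    for i in system.channel_indices("N"):
        Iz = system.ops[i][2]
        rho = rho + (np.trace(state.rho @ Iz).real / norm) * Iz
    return DensityState(rho, system)


# ---------------------------------------------------------------------------
# pulse sequences

_SEQUENCE_ALIASES = {
    "phinept+": "phINEPT+", "phinept": "phINEPT+",
    "esotheric": "ESOTHERIC",
    "sabre-inept": "SABRE-INEPT", "sabreinept": "SABRE-INEPT",
    "sabre-esotheric": "SABRE-ESOTHERIC", "sabreesotheric": "SABRE-ESOTHERIC",
}


@dataclass(frozen=True)
class PulseSequence:
    """An ordered list of ideal events with the delays tau1 and tau2."""

    name: str
    tau1: float
    tau2: float
    events: tuple = ()
    exchange_delay: float = 0.0

    @property
    def t_tot(self) -> float:
        return total_time(self.name, self.tau1, self.tau2)


def total_time(name: str, tau1: float, tau2: float) -> float:
    """Total SOT block duration.

    t_tot = 2*(tau1 + tau2) for phINEPT+ and 2*(2*tau1 + tau2) for
    ESOTHERIC (the SABRE- variants inherit the time of their SOT block;
    the storage interval tau_e is not part of t_tot).
    """
    base = _SEQUENCE_ALIASES.get(name.lower())
    if base is None:
        raise ValueError(f"unknown sequence {name!r}")
    if base in ("phINEPT+", "SABRE-INEPT"):
        return 2.0 * (tau1 + tau2)
    return 2.0 * (2.0 * tau1 + tau2)


def _echo(tau: float, channels: Iterable[str], phase: float = 0.0) -> list:
    """tau -- 180(channels) -- tau refocusing block of total duration 2*tau."""
    ev: list = [Delay(tau)]
    ev += [Pulse(c, 180.0, phase) for c in channels]
    ev.append(Delay(tau))
    return ev


def make_sequence(name: str, tau1: float, tau2: float,
                  exchange_delay: float = 0.0) -> PulseSequence:
    """Build the event list of a named SOT sequence.

    phINEPT+ : 45x(H) excitation; tau1-echo refocusing both channels;
    simultaneous 90x(H)+90x(N) transfer pulses; tau2-echo; 90x(H) purge.
    The echo halves are tau1 (tau2) long, so t_tot = 2*(tau1 + tau2).
    The 45deg excitation converts the hydride zz order into the
    single-quantum antiphase terms an INEPT step can transfer (a 90deg
    pulse leaves only untransferable zero/double-quantum order).

    ESOTHERIC : echo-based full-transfer variant; same skeleton with a
    doubled tau1 echo block, the two echoes separated by an extra 90x(H)
    pulse; t_tot = 2*(2*tau1 + tau2).  The second echo plus the relay
    pulse also converts the two-spin order an INEPT-type step leaves
    behind, roughly doubling the attainable 15N polarization.

    Pulse phases follow the convention that maximizes three-spin transfer
    (all rotations about x); with ideal pulses, common phase shifts of
    whole pulse groups only change the phase of the final transverse
    magnetization, not its magnitude.

    SABRE-INEPT / SABRE-ESOTHERIC : the corresponding SOT block followed
    by a 90(N) pulse storing the 15N magnetization along z, the coherence
    filter (which keeps only longitudinal 15N terms, so it must come after
    the storage pulse), the exchange interval tau_e (``exchange_delay``)
    and a 90(N) read pulse.
    """
    if tau1 < 0 or tau2 < 0 or exchange_delay < 0:
        raise ValueError("delays must be non-negative")
    base = _SEQUENCE_ALIASES.get(name.lower())
    if base is None:
        raise ValueError(f"unknown sequence {name!r}")

    if base in ("phINEPT+", "SABRE-INEPT"):
        ev: list = [Pulse("H", 45.0, 0.0)]               # 45x excitation
        ev += _echo(tau1, ("H", "N"))
    else:
        ev = [Pulse("H", 90.0, 0.0)]                     # 90x excitation
        ev += _echo(tau1, ("H", "N"))
        ev += [Pulse("H", 90.0, 0.0)]                    # relay pulse
        ev += _echo(tau1, ("H", "N"))
    ev += [Pulse("H", 90.0, 0.0), Pulse("N", 90.0, 0.0)]  # transfer pulses
    ev += _echo(tau2, ("H", "N"))
    ev += [Pulse("H", 90.0, 0.0)]                         # purge pulse

    if base in ("SABRE-INEPT", "SABRE-ESOTHERIC"):
        # store the in-phase (x) 15N magnetization along z, dephase what is
        # left with the gradient filter, wait out the exchange interval,
        # read back out
        ev += [Pulse("N", 90.0, 90.0), CoherenceFilter(),
               Delay(exchange_delay), Pulse("N", 90.0, 90.0)]
    return PulseSequence(base, float(tau1), float(tau2), tuple(ev),
                         float(exchange_delay))


def run_sequence(state: DensityState, sequence: PulseSequence) -> DensityState:
    """Propagate a state through every event of a sequence."""
    for event in sequence.events:
        if isinstance(event, Pulse):
            state = apply_pulse(state, event.channel, event.flip, event.phase)
        elif isinstance(event, Delay):
            state = evolve_free(state, event.duration)
        elif isinstance(event, CoherenceFilter):
            state = apply_filter(state)
        else:  # pragma: no cover - defensive
            raise TypeError(f"unknown event {event!r}")
    return state


def _target_indices(system: SpinSystem, target_spins) -> tuple[int, ...]:
    if target_spins is None:
        idx = system.channel_indices("N")
        if not idx:
            raise ValueError("system has no N-channel spins")
        return idx
    idx = tuple(system.index(t) for t in target_spins)
    for i in idx:
        if system.channels[i] != "N":
            raise ValueError(f"target spin {system.labels[i]} is not on the "
                             "N channel")
    return idx


def run_sot(system: SpinSystem, sequence: PulseSequence,
            target_spins: Sequence["int | str"] | None = None) -> float:
    """Polarization transferred to the 15N spins by one SOT execution.

    Starts from the hydride antiphase zz order, runs the sequence with
    ideal pulses and no relaxation, and returns the per-spin single-quantum
    polarization magnitude P = 2*|<I+>| (equivalently 2*|<Iz>| after a
    storage pulse), averaged over ``target_spins`` (default: all 15N).
    Polarization is reported as a magnitude because the sign merely tracks
    the parahydrogen spin-order sign convention.
    """
    idx = _target_indices(system, target_spins)
    state = run_sequence(initial_hydride_order(system), sequence)
    total = 0.0
    for i in idx:
        ops = system.ops[i]
        sx = np.trace(state.rho @ ops[0]).real
        sy = np.trace(state.rho @ ops[1]).real
        sz = np.trace(state.rho @ ops[2]).real
        total += 2.0 * max(math.hypot(sx, sy), abs(sz))
    return total / len(idx)


# ---------------------------------------------------------------------------
# maps and optimization

@dataclass
class PolarizationMap:
    """15N polarization over a (tau1, tau2) grid, exchange-damped."""

    tau1: np.ndarray
    tau2: np.ndarray
    P: np.ndarray            # shape (len(tau1), len(tau2)), fraction
    k_d: float
    sequence: str

    def max(self) -> tuple[float, float, float]:
        """(tau1*, tau2*, P*) of the best grid point."""
        i, j = np.unravel_index(int(np.argmax(self.P)), self.P.shape)
        return float(self.tau1[i]), float(self.tau2[j]), float(self.P[i, j])

    def to_frame(self):
        import pandas as pd

        t1, t2 = np.meshgrid(self.tau1, self.tau2, indexing="ij")
        return pd.DataFrame({"tau1_s": t1.ravel(), "tau2_s": t2.ravel(),
                             "polarization": self.P.ravel()})


def _damped(system: SpinSystem, name: str, tau1: float, tau2: float,
            k_d: float) -> float:
    seq = make_sequence(name, tau1, tau2)
    return run_sot(system, seq) * math.exp(-k_d * seq.t_tot)


def sot_map(system: SpinSystem, sequence_name: str,
            tau1_grid: Sequence[float], tau2_grid: Sequence[float],
            k_d: float = 0.0) -> PolarizationMap:
    """Damped polarization map P[i, j] = P(tau1_i, tau2_j)*exp(-k_d*t_tot)."""
    if k_d < 0:
        raise ValueError("k_d must be non-negative")
    t1 = np.asarray(tau1_grid, dtype=float)
    t2 = np.asarray(tau2_grid, dtype=float)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("grids must be non-empty")
    P = np.empty((t1.size, t2.size))
    for i, a in enumerate(t1):
        for j, b in enumerate(t2):
            P[i, j] = _damped(system, sequence_name, a, b, k_d)
    name = _SEQUENCE_ALIASES[sequence_name.lower()]
    return PolarizationMap(t1, t2, P, float(k_d), name)


def optimize_sot(system: SpinSystem, sequence_name: str,
                 bounds: tuple = ((1e-3, 0.040), (1e-3, 0.040)),
                 k_d: float = 0.0, grid_step: float = 1e-3,
                 refine: bool = True) -> tuple[float, float, float]:
    """Maximize the (damped) 15N polarization over (tau1, tau2).

    A coarse grid search (default 1 ms step over 1-40 ms, matching the
    delay raster used experimentally) seeds a Nelder-Mead refinement
    clipped to ``bounds``.  Deterministic for fixed bounds and grid.

    Returns ``(tau1*, tau2*, P*)``.
    """
    (lo1, hi1), (lo2, hi2) = bounds
    if hi1 <= lo1 or hi2 <= lo2:
        raise ValueError("bounds must be non-empty intervals")
    g1 = np.arange(lo1, hi1 + 0.5 * grid_step, grid_step)
    g2 = np.arange(lo2, hi2 + 0.5 * grid_step, grid_step)
    pmap = sot_map(system, sequence_name, g1, g2, k_d)
    t1, t2, best = pmap.max()
    if refine:
        from scipy.optimize import minimize

        def neg(x):
            a = min(max(x[0], lo1), hi1)
            b = min(max(x[1], lo2), hi2)
            return -_damped(system, sequence_name, a, b, k_d)

        res = minimize(neg, x0=[t1, t2], method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10,
                                "maxiter": 400})
        if -res.fun >= best:
            best = -res.fun
            t1 = min(max(res.x[0], lo1), hi1)
            t2 = min(max(res.x[1], lo2), hi2)
    return float(t1), float(t2), float(best)
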