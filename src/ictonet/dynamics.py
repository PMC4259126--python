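"""Bistable oscillator dynamics on networks.

Each node is the normal-form oscillator

    dZ/dt = (a|Z|^4 + b|Z|^2 + c + i*omega) Z + noise,

a complex-valued unit whose noise-free radial flow ``dr/dt = r*(a r^4 + b r^2
+ c)`` can place a stable fixed point at the origin (the "background" state)
next to a stable limit cycle (the "seizure" state).  Networks couple nodes
linearly, ``+ sum_j G_ij Z_j``, through a weighted adjacency matrix scaled by
a uniform factor (default 0.1) that keeps noise-driven transitions between the
two attractors possible.  Integration is Euler--Maruyama with independent
complex Gaussian increments per node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NodeParameters",
    "NoiseSpec",
    "CouplingMatrix",
    "SimulationConfig",
    "ComplexTrajectory",
    "SimulationDivergedError",
    "drift",
    "radial_equilibria",
    "sample_node_frequencies",
    "simulate_network",
]

#: default guard radius beyond which the integrator reports divergence
DIVERGENCE_GUARD = 10.0


class SimulationDivergedError(RuntimeError):
    """Raised when a trajectory exceeds the divergence guard radius."""

    def __init__(self, step: int, node: int, radius: float, replicate: int = 0):
        self.step = step
        self.node = node
        self.radius = radius
        self.replicate = replicate
        super().__init__(
            f"trajectory diverged at step {step}, node {node}, "
            f"replicate {replicate} (|Z| = {radius:.3g})"
        )


@dataclass(frozen=True)
class NodeParameters:
    """Coefficients of a single bistable unit.

    Parameters
    ----------
    a : float
        Quartic-term coefficient. Must be nonzero (and negative for a
        globally contracting flow).
    b : float
        Quadratic-term coefficient.
    c : float
        Real part of the complex linear coefficient; its sign sets the
        stability of the origin.
    omega : float
        Imaginary part of the linear coefficient: the angular frequency of
        rotation, in radians per unit model time.
    """

    a: float = -1.0
    b: float = 2.0
    c: float = -0.9
    omega: float = 1.0

    def __post_init__(self):
        vals = (self.a, self.b, self.c, self.omega)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite node parameters: {vals}")

    def is_bistable(self) -> bool:
        """True when the noise-free node has a stable origin *and* a stable
        limit cycle (coexisting background and seizure attractors)."""
        eq = radial_equilibria(self)
        stable = [r for r, s in eq if s == "stable"]
        return len(stable) >= 2 and stable[0] == 0.0


@dataclass(frozen=True)
class NoiseSpec:
    """Complex white-noise specification.

    ``sigma`` is the per-unit-time standard deviation of each of the real and
    imaginary Gaussian increments (so an Euler--Maruyama step of size ``dt``
    adds ``sigma*sqrt(dt)*(eta1 + i*eta2)``).  The default 0.3 is calibrated
    so that a single uncoupled node at the default parameters has a finite
    but non-trivial mean escape time from the background state (see
    ``scripts/calibrate_noise.py``).
    """

    sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma}")


@dataclass
class CouplingMatrix:
    """Weighted undirected coupling structure.

    ``weights`` must be square, symmetric, non-negative with a zero diagonal;
    ``scale`` (default 0.1) multiplies all weights uniformly before
    simulation so that coupling perturbs rather than overwhelms the
    single-node bistability.
    """

    weights: np.ndarray
    scale: float = 0.1
    labels: list[str] | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] < 1:
            raise ValueError(f"weights must be a square N x N matrix, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric (undirected network)")
        self.weights = w
        if self.labels is None:
            self.labels = [f"n{i}" for i in range(w.shape[0])]
        elif len(self.labels) != w.shape[0]:
            raise ValueError("labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def scaled(self) -> np.ndarray:
        return self.scale * self.weights

    @classmethod
    def uncoupled(cls, n: int) -> "CouplingMatrix":
        """N isolated nodes (zero adjacency)."""
        return cls(np.zeros((n, n)))


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    ``init_mode`` chooses the initial condition: ``at_steady_state`` (all
    nodes at the origin), ``on_limit_cycle`` (all nodes on the stable
    limit-cycle radius at random phases), or ``random_disk`` (independent
    uniform draws from the disk of radius ``init_radius``, covering both
    basins at the default radius 1.5).
    """

    dt: float = 0.01
    duration: float = 500.0
    init_mode: str = "random_disk"
    init_radius: float = 1.5
    seed: int = 0

    _MODES = ("at_steady_state", "on_limit_cycle", "random_disk")

    def __post_init__(self):
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.duration < self.dt or self.n_steps < 1:
            raise ValueError("duration must allow at least 2 samples")
        if self.init_mode not in self._MODES:
            raise ValueError(f"init_mode must be one of {self._MODES}")
        if self.init_radius < 0:
            raise ValueError("init_radius must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(math.floor(self.duration / self.dt))


@dataclass
class ComplexTrajectory:
    """Simulated node states: ``states[i, k]`` is node ``i`` at time ``k*dt``."""

    states: np.ndarray  # (N, T) complex
    dt: float
    node_frequencies: np.ndarray  # (N,) angular frequencies actually used

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=complex)
        if self.states.ndim != 2 or self.states.shape[1] < 2:
            raise ValueError("states must be N x T with T >= 2")
        if not (np.all(np.isfinite(self.states.real)) and np.all(np.isfinite(self.states.imag))):
            raise ValueError("trajectory contains non-finite values")
        self.node_frequencies = np.asarray(self.node_frequencies, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.states.shape[0]

    @property
    def n_samples(self) -> int:
        return self.states.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_samples)


def drift(z, params: NodeParameters, coupling_input=0j):
    """Deterministic part of the node vector field.

    Returns ``(a|z|^4 + b|z|^2 + c + i*omega)*z + coupling_input``; accepts
    scalars or arrays (broadcast elementwise).
    """
    z = np.asarray(z, dtype=complex)
    coupling_input = np.asarray(coupling_input, dtype=complex)
    if not np.all(np.isfinite(z.real)) or not np.all(np.isfinite(z.imag)):
        raise ValueError("non-finite state passed to drift")
    u = z.real * z.real + z.imag * z.imag
    out = (params.a * u * u + params.b * u + params.c + 1j * params.omega) * z
    out = out + coupling_input
    return out if out.ndim else complex(out)


def radial_equilibria(params: NodeParameters) -> list[tuple[float, str]]:
    """Radial fixed points of the noise-free uncoupled node.

    The radial flow is ``dr/dt = r * g(r^2)`` with ``g(u) = a*u^2 + b*u + c``.
    Returns ``(radius, stability)`` pairs sorted by radius: the origin (stable
    iff ``c < 0``) plus the square roots of the positive real roots of ``g``,
    each a circular limit cycle, stable iff ``g`` is decreasing there.
    """
    a, b, c = params.a, params.b, params.c
    if a == 0:
        raise ValueError("quartic coefficient a must be nonzero")
    # origin: sign of g just above u=0
    origin_sign = c if c != 0 else (b if b != 0 else a)
    out = [(0.0, "stable" if origin_sign < 0 else "unstable")]
    disc = b * b - 4 * a * c
    if disc >= 0:
        sq = math.sqrt(disc)
        for u in sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a))):
            if u > 0:
                slope = 2 * a * u + b  # g'(u); degenerate root -> semi-stable
                out.append((math.sqrt(u), "stable" if slope < 0 else "unstable"))
    return out


def stable_limit_cycle_radius(params: NodeParameters) -> float:
    """Radius of the outermost stable limit cycle; error if none exists."""
    stable = [r for r, s in radial_equilibria(params) if s == "stable" and r > 0]
    if not stable:
        raise ValueError("node parameters admit no stable limit cycle")
    return max(stable)


def sample_node_frequencies(
    omega0: float, half_width: float, n: int, seed=None
) -> np.ndarray:
    """Draw ``n`` angular frequencies uniformly from
    ``[omega0 - half_width, omega0 + half_width]``.

    Heterogeneous frequencies avoid artificial phase locking between
    identical units; ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return omega0 + rng.uniform(-half_width, half_width, size=n)


def _initial_states(
    mode: str, radius: float, params: NodeParameters, shape, rng
) -> np.ndarray:
    if mode == "at_steady_state":
        return np.zeros(shape, dtype=complex)
    if mode == "on_limit_cycle":
        r = stable_limit_cycle_radius(params)
        return r * np.exp(1j * rng.uniform(0.0, 2 * np.pi, size=shape))
    # random_disk: area-uniform over the disk of the given radius
    r = radius * np.sqrt(rng.uniform(size=shape))
    return r * np.exp(1j * rng.uniform(0.0, 2 * np.pi, size=shape))


def _integrate_batch(
    z0: np.ndarray,
    coupling_scaled: np.ndarray,
    params: NodeParameters,
    omegas: np.ndarray,
    sigma: float,
    dt: float,
    n_steps: int,
    noise_rng,
    record: bool = False,
    occupancy_threshold: float | None = None,
    guard: float = DIVERGENCE_GUARD,
    noise_chunk: int = 256,
):
    """Euler--Maruyama integration of a (batch, N) array of network states.

    Returns ``(final_states, history, occupancy)``: ``history`` is the full
    (batch, N, n_steps+1) record when ``record`` is true, and ``occupancy``
    counts, per trajectory and node, the samples (including the initial one)
    with ``|Z|`` above ``occupancy_threshold``.
    """
    z = np.array(z0, dtype=complex)
    batch, n = z.shape
    a, b, c = params.a, params.b, params.c
    om = np.asarray(omegas, dtype=float)
    gt = np.ascontiguousarray(coupling_scaled.T)
    guard2 = guard * guard
    sq = sigma * math.sqrt(dt)

    history = None
    if record:
        history = np.empty((batch, n, n_steps + 1), dtype=complex)
        history[:, :, 0] = z
    occ = None
    thr2 = None
    if occupancy_threshold is not None:
        thr2 = occupancy_threshold * occupancy_threshold
        occ = (z.real**2 + z.imag**2 > thr2).astype(np.int64)

    # noise is drawn in chunks: one generator call per `noise_chunk` steps
    eta = None
    for k in range(n_steps):
        u = z.real * z.real + z.imag * z.imag
        dz = (a * u * u + b * u + c + 1j * om) * z + z @ gt
        if sigma > 0:
            j = k % noise_chunk
            if j == 0:
                m = min(noise_chunk, n_steps - k)
                raw = noise_rng.standard_normal((m, 2, batch, n))
                eta = sq * (raw[:, 0] + 1j * raw[:, 1])
            z = z + dt * dz + eta[j]
        else:
            z = z + dt * dz
        u = z.real * z.real + z.imag * z.imag
        if np.any(u > guard2):
            bi, ni = np.unravel_index(int(np.argmax(u)), u.shape)
            raise SimulationDivergedError(
                k + 1, int(ni), math.sqrt(u[bi, ni]), replicate=int(bi)
            )
        if record:
            history[:, :, k + 1] = z
        if occ is not None:
            occ += u > thr2
    return z, history, occ


def simulate_network(
    params: NodeParameters,
    coupling: CouplingMatrix,
    noise: NoiseSpec,
    config: SimulationConfig,
    frequencies=None,
    guard: float = DIVERGENCE_GUARD,
) -> ComplexTrajectory:
    """Simulate the coupled network and record the full trajectory.

    Initial conditions and any frequency draw use ``config.seed``; the noise
    stream uses ``noise.seed``, with one child stream per node so that an
    uncoupled node's realization is independent of the network size.  When
    ``frequencies`` is omitted the per-node angular frequencies are drawn as
    ``params.omega + Uniform[-0.2, 0.2]``.
    """
    n = coupling.n_nodes
    init_rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if frequencies is None:
        frequencies = sample_node_frequencies(params.omega, 0.2, n, init_rng)
    else:
        frequencies = np.asarray(frequencies, dtype=float)
        if frequencies.shape != (n,):
            raise ValueError(f"expected {n} frequencies, got {frequencies.shape}")
    z0 = _initial_states(config.init_mode, config.init_radius, params, (1, n), init_rng)

    n_steps = config.n_steps
    # per-node noise streams: child i of the noise seed drives node i only
    if noise.sigma > 0:
        children = np.random.SeedSequence(noise.seed).spawn(n)
        eta = np.empty((n_steps, 2, 1, n))
        for i, ss in enumerate(children):
            eta[:, :, 0, i] = np.random.default_rng(ss).standard_normal((n_steps, 2))
        noise_rng = _PregeneratedNormals(eta)
    else:
        noise_rng = np.random.default_rng(noise.seed)

    _, history, _ = _integrate_batch(
        z0,
        coupling.scaled,
        params,
        frequencies,
        noise.sigma,
        config.dt,
        n_steps,
        noise_rng,
        record=True,
        guard=guard,
        noise_chunk=n_steps if noise.sigma > 0 else 256,
    )
    return ComplexTrajectory(history[0], config.dt, frequencies)


class _PregeneratedNormals:
    """Replays a fixed array of standard normals through the generator API."""

    def __init__(self, values: np.ndarray):
        self._values = values
        self._cursor = 0

    def standard_normal(self, shape):
        m = shape[0]
        out = self._values[self._cursor : self._cursor + m]
        if out.shape != tuple(shape):
            raise ValueError("pregenerated noise shape mismatch")
        self._cursor += m
        return out
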