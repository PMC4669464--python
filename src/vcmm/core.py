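"""Variance-corrected Michaelis-Menten (MM) kinetics under fluctuating substrate.

The classical Michaelis-Menten equation (MME) gives the rate of an
enzyme-catalysed reaction as a hyperbolic function of the substrate
concentration,

    v0(rho) = rho / (rho + K_M),        v = v_max * v0,

where ``v0`` is the rate normalised by its maximum and ``K_M`` the Michaelis
constant.  Inside a cell the substrate concentration ``rho(t)`` is a stochastic
process -- substrate molecules arrive in bursts, transcription factors are
expressed in translational bursts of tens of copies -- and the population-level
reaction rate is the *ensemble average* ``<v0(rho(t))>``, which can differ
substantially from the naive ``v0(<rho(t)>)``.

Because ``v0`` is concave, Jensen's inequality makes the MME evaluated at the
mean an upper bound on the true averaged rate.  Evaluating the integral-form
remainder of Taylor's theorem and using ``rho >= 0`` gives the sharpest lower
bound expressible through the mean and variance alone:

    <rho>/(<rho>+K_M) - Var(rho)/(<rho>+K_M)^2  <=  <v0>  <=  <rho>/(<rho>+K_M)

The second-order Taylor truncation between those bounds is the
variance-corrected Michaelis-Menten equation (VCMME):

    v0_vc = <rho>/(<rho>+K_M) - K_M Var(rho)/(<rho>+K_M)^3.

This module implements, in the order the method runs:

1.  **Rate laws** -- the MME, both optimal bounds, the VCMME, arbitrary-order
    Taylor truncations in central moments, and a brute-force oracle that
    averages the MME exactly over a discrete concentration distribution.
2.  **Stochastic simulation** -- exact (direct-method Gillespie) simulators for
    a bursty-substrate enzymatic reaction and for a transcription-factor (TF)
    expression cascade with operator binding, plus reproducible ensembles and
    their summary statistics.
3.  **TF analytics** -- the exact solution for the TF concentration under
    delayed, burst-driven expression: the hypoexponential maturation-delay
    density, the Laplace functional ``<exp(-lambda rho(t))>`` of the shot-noise
    concentration driven by an mRNA immigration-death process, the mean and
    variance time courses, and operator-occupancy predictions (exact integral,
    MME, VCMME, Poissonian approximation).
4.  **Workbench** -- named parameter fixtures, experiment configs, TSV export
    with reproducibility sidecars, and drivers that compare the estimators.

Units: time in seconds, volume in cubic micrometres (um^3), concentration in
copies per um^3.  All rate-law computations are in the normalised rate ``v0``;
``v_max`` only de-normalises at the presentation layer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import random as _pyrandom
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.polynomial.legendre import leggauss
from scipy import integrate, interpolate, linalg

logger = logging.getLogger("vcmm")

# ---------------------------------------------------------------------------
# Numerical configuration
# ---------------------------------------------------------------------------
#: tolerance for closed-form rate-law identities (no quadrature involved)
RATE_LAW_TOL = 1e-12
#: absolute tolerance for inner (convolution) quadratures
QUAD_INNER_TOL = 1e-11
#: absolute tolerance for the outer occupancy integral
QUAD_OUTER_TOL = 1e-7
#: relative tolerance of the Laplace-functional ODE integration
ODE_RTOL = 1e-10
ODE_ATOL = 1e-13
#: number of w-grid points per Laplace-functional evaluation
_LAPLACE_GRID_MIN = 800
_LAPLACE_GRID_MAX = 6000
#: rates closer than this (relative) are treated as equal in the delay density
DELAY_EQUAL_RTOL = 1e-6


# ===========================================================================
# Section 1: rate laws
# ===========================================================================


@dataclass(frozen=True)
class RateParameters:
    """Michaelis constant and maximal rate of a hyperbolic rate law.

    ``michaelis_constant`` is in concentration units (same as the substrate);
    ``v_max`` de-normalises ``v0`` into a dimensional rate and takes no part in
    the internal computations.
    """

    michaelis_constant: float
    v_max: float = 1.0

    def __post_init__(self) -> None:
        if not (self.michaelis_constant > 0):
            raise ValueError("michaelis_constant must be > 0")
        if not (self.v_max > 0):
            raise ValueError("v_max must be > 0")


@dataclass(frozen=True)
class ConcentrationMoments:
    """Mean, variance and optional higher central moments of a concentration.

    ``higher_central_moments[k]`` is the central moment of order ``k + 3``.
    """

    mean: float
    variance: float
    higher_central_moments: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("mean concentration must be >= 0")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.mean == 0 and self.variance > 0:
            raise ValueError("zero mean implies zero variance for rho >= 0")

    def central_moment(self, order: int) -> float:
        if order == 0:
            return 1.0
        if order == 1:
            return 0.0
        if order == 2:
            return self.variance
        if self.higher_central_moments is None or order - 3 >= len(
            self.higher_central_moments
        ):
            raise ValueError(
                f"central moment of order {order} was not supplied"
            )
        return self.higher_central_moments[order - 3]


@dataclass(frozen=True)
class DiscreteConcentrationDistribution:
    """Finitely supported concentration distribution (oracle input)."""

    support: tuple[float, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.support, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if s.shape != p.shape or s.ndim != 1 or s.size == 0:
            raise ValueError("support and probabilities must be equal-length 1-D")
        if np.any(s < 0):
            raise ValueError("support values must be nonnegative")
        if len(set(s.tolist())) != s.size:
            raise ValueError("support values must be distinct")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be >= 0 and sum to 1 (tol 1e-12)")

    @property
    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.asarray(self.support, dtype=float),
            np.asarray(self.probabilities, dtype=float),
        )

    def mean(self) -> float:
        s, p = self._arrays
        return float(np.dot(p, s))

    def central_moment(self, order: int) -> float:
        s, p = self._arrays
        return float(np.dot(p, (s - self.mean()) ** order))

    def to_moments(self, max_order: int = 2) -> ConcentrationMoments:
        higher = tuple(
            self.central_moment(k) for k in range(3, max_order + 1)
        ) or None
        return ConcentrationMoments(
            mean=self.mean(),
            variance=self.central_moment(2),
            higher_central_moments=higher,
        )


def mme(mean: float, params: RateParameters) -> float:
    """Normalised Michaelis-Menten rate ``v0 = mean/(mean + K_M)``.

    Multiplying by ``params.v_max`` gives the dimensional rate.
    """
    if mean < 0:
        raise ValueError("mean concentration must be >= 0")
    return mean / (mean + params.michaelis_constant)


def jensen_upper_bound(
    moments: ConcentrationMoments, params: RateParameters
) -> float:
    """Optimal upper bound on ``<v0(rho)>``: the MME at the mean.

    By Jensen's inequality for the concave ``v0``, this bounds the exact
    ensemble-averaged rate from above for every nonnegative concentration
    distribution with the given mean; it is attained by the degenerate
    (deterministic) distribution.
    """
    return mme(moments.mean, params)


def optimal_lower_bound(
    moments: ConcentrationMoments, params: RateParameters
) -> float:
    """Optimal mean/variance lower bound on ``<v0(rho)>``.

    From the integral-remainder form of Taylor's theorem around the mean,
    ``v0(rho) = v0(m) + v0'(m)(rho - m) - K_M (rho - m)^2 / ((K_M+m)^2 (K_M+rho))``
    exactly; bounding ``K_M + rho >= K_M`` (which is where ``rho >= 0`` enters)
    and averaging gives

        <v0>  >=  m/(m + K_M) - Var(rho)/(m + K_M)^2.

    The bound reduces to the MME when the variance vanishes and is the
    sharpest possible in terms of mean and variance alone.
    """
    m, km = moments.mean, params.michaelis_constant
    return mme(m, params) - moments.variance / (m + km) ** 2


def vcmme(moments: ConcentrationMoments, params: RateParameters) -> float:
    """Variance-corrected Michaelis-Menten rate.

    ``v0 = m/(m+K_M) - K_M Var/(m+K_M)^3`` -- the second-order Taylor
    truncation of the averaged rate.  It always lies between
    :func:`optimal_lower_bound` and :func:`jensen_upper_bound` and equals
    their midpoint at ``m = K_M``.  The raw value is returned without
    clamping at zero: the optimal bounds, not a clamp, delimit its validity.
    """
    m, km = moments.mean, params.michaelis_constant
    return mme(m, params) - km * moments.variance / (m + km) ** 3


def taylor_rate(
    moments: ConcentrationMoments, params: RateParameters, order: int
) -> float:
    """Taylor-series estimate of ``<v0>`` truncated at central-moment order ``order``.

    The series in central moments ``mu_n = <(rho - m)^n>`` is

        <v0> = m/(m+K_M) + sum_{n>=2} (-1)^(n+1) K_M mu_n / (m+K_M)^(n+1),

    typically alternating for right-skewed concentration distributions.
    ``order = 2`` coincides with :func:`vcmme`.
    """
    if order < 2:
        raise ValueError("order must be >= 2")
    m, km = moments.mean, params.michaelis_constant
    total = mme(m, params)
    for n in range(2, order + 1):
        mu_n = moments.central_moment(n)  # raises if not supplied
        total += (-1) ** (n + 1) * km * mu_n / (m + km) ** (n + 1)
    return total


def exact_ensemble_rate(
    dist: DiscreteConcentrationDistribution, params: RateParameters
) -> float:
    """Exact ``<v0(rho)> = sum_i p_i rho_i/(rho_i + K_M)`` (brute-force oracle)."""
    s, p = dist._arrays
    return float(np.dot(p, s / (s + params.michaelis_constant)))


# ===========================================================================
# Section 2: stochastic simulation (direct-method Gillespie)
# ===========================================================================


@dataclass(frozen=True)
class EnzymeSystemSpec:
    """Bursty-substrate enzymatic reaction network.

    Substrate molecules enter the reaction volume in batches of
    ``batch_size`` at Poisson rate ``input_rate``; binding, unbinding and
    catalysis follow mass action with ``k_on`` (per concentration per time),
    ``k_off`` and ``k_cat`` (per time).  Catalysis is the only pathway that
    removes substrate.
    """

    k_on: float
    k_off: float
    k_cat: float
    batch_size: int
    input_rate: float
    n_enzymes: int = 1
    volume: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_cat", "input_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_enzymes < 1:
            raise ValueError("n_enzymes must be >= 1")
        if not (self.volume > 0):
            raise ValueError("volume must be > 0")

    @property
    def michaelis_constant(self) -> float:
        """Quasi-steady-state Michaelis constant ``(k_off + k_cat)/k_on``."""
        return (self.k_off + self.k_cat) / self.k_on

    @property
    def v_max(self) -> float:
        return self.k_cat * self.n_enzymes


@dataclass(frozen=True)
class GeneRegSystemSpec:
    """TF expression cascade with operator binding.

    Transcription at ``a_tf`` (zero before time zero), per-mRNA decay
    ``gamma_m``, per-mRNA translation ``v_tf``, ``kappa`` sequential
    maturation steps with rates ``maturation_rates``, dilution ``gamma_p`` of
    free mature TF, and TF-DNA binding around one or more operator regions.

    ``ns_binding = (on, off)``: nonspecific association (per concentration per
    time) and dissociation (per time).  ``sp_binding = (on, off)``:
    interconversion between the nonspecifically bound state and the
    operator-bound state (both per time).  ``binding_model``:

    * ``"sequential"`` -- the operator can only be reached through the
      nonspecifically bound intermediate (sliding search);
    * ``"independent"`` -- the TF additionally binds the operator directly
      from solution, with rates chosen to preserve the equilibrium constant
      ``K = (ns_on/ns_off) * (sp_on/sp_off)``, so binding equilibrates fast.
    * ``"none"`` -- expression only (used by the analytics oracles).
    """

    a_tf: float
    gamma_m: float
    v_tf: float
    maturation_rates: tuple[float, ...] = ()
    gamma_p: float = 0.0
    volume: float = 1.0
    ns_binding: tuple[float, float] = (0.0, 0.0)
    sp_binding: tuple[float, float] = (0.0, 0.0)
    binding_model: str = "none"
    n_operators: int = 1

    def __post_init__(self) -> None:
        for name in ("a_tf", "gamma_m", "v_tf", "gamma_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(r <= 0 for r in self.maturation_rates):
            raise ValueError("maturation_rates must be > 0")
        if self.binding_model not in ("sequential", "independent", "none"):
            raise ValueError("binding_model must be sequential|independent|none")
        if self.n_operators < 1:
            raise ValueError("n_operators must be >= 1")
        if not (self.volume > 0):
            raise ValueError("volume must be > 0")

    @property
    def burst_size(self) -> float:
        """Mean translational burst size ``b = v_tf/gamma_m``."""
        return self.v_tf / self.gamma_m if self.gamma_m > 0 else math.inf

    @property
    def binding_constant(self) -> float:
        """Combined equilibrium constant ``K = K_NS * K_SP`` (volume units)."""
        ns_on, ns_off = self.ns_binding
        sp_on, sp_off = self.sp_binding
        if ns_off == 0 or sp_off == 0:
            return 0.0
        return (ns_on / ns_off) * (sp_on / sp_off)


ENZYME_COLUMNS = ("substrate", "complex", "product")
GENEREG_COLUMNS = ("mRNA", "immature", "tf_free", "tf_bound", "op_specific")


@dataclass
class Trajectory:
    """One stochastic path, sampled right-continuously.

    ``times`` either holds event times (event-resolved mode) or the requested
    sample grid; ``states`` has one row per time, columns per species.
    """

    times: np.ndarray
    states: np.ndarray
    columns: tuple[str, ...]
    seed: int
    kind: str
    spec: EnzymeSystemSpec | GeneRegSystemSpec
    horizon: float

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]


@dataclass
class TrajectoryEnsemble:
    """Independent SSA runs on a common sample grid."""

    runs: list[Trajectory]
    time_grid: np.ndarray
    seeds: tuple[int, ...]
    spec: EnzymeSystemSpec | GeneRegSystemSpec
    kind: str
    horizon: float

    @property
    def data(self) -> np.ndarray:
        """(n_runs, n_times, n_species) stacked sampled states."""
        return np.stack([r.states for r in self.runs])


@dataclass
class EnsembleSummary:
    """Across-run statistics on the ensemble's sample grid."""

    time_grid: np.ndarray
    mean_concentration: np.ndarray
    variance_concentration: np.ndarray
    occupancy: np.ndarray
    rate_estimate: np.ndarray
    n_runs: int


def _derive_run_seeds(base_seed: int, n_runs: int) -> tuple[int, ...]:
    """Counter-based per-run seeds: order-independent, reproducible."""
    children = np.random.SeedSequence(base_seed).spawn(n_runs)
    return tuple(int(c.generate_state(1, np.uint32)[0]) for c in children)


def _exp_variate(rng: _pyrandom.Random, rate: float) -> float:
    u = rng.random()
    while u <= 0.0:  # pragma: no cover - probability ~1e-300
        u = rng.random()
    return -math.log(u) / rate

def _check_horizon(horizon: float) -> None:
    if not (horizon > 0) or not math.isfinite(horizon):
        raise ValueError("horizon must be positive and finite")


def simulate_enzyme(
    spec: EnzymeSystemSpec,
    horizon: float,
    seed: int,
    sample_times: Sequence[float] | None = None,
) -> Trajectory:
    """Exact SSA run of the bursty-substrate enzyme system.

    Events: batch arrival (``S += batch_size`` at ``input_rate``), binding
    (``S + E -> SE`` at ``k_on S E / V``), unbinding (``SE -> S + E`` at
    ``k_off SE``) and catalysis (``SE -> E``, product counter incremented, at
    ``k_cat SE``).  With ``sample_times`` given, the state is recorded
    right-continuously on that grid; otherwise every event is recorded.
    """
    _check_horizon(horizon)
    rng = _pyrandom.Random(seed)
    kon_v = spec.k_on / spec.volume
    koff, kcat = spec.k_off, spec.k_cat
    ain, batch, n_enz = spec.input_rate, spec.batch_size, spec.n_enzymes

    sampled = sample_times is not None
    if sampled:
        grid = np.asarray(sample_times, dtype=float)
        if grid.size and grid[-1] > horizon + 1e-9:
            raise ValueError("sample_times extend beyond the simulated horizon")
        out = np.empty((grid.size, 3), dtype=np.int64)
        gi = 0
    else:
        ev_times: list[float] = [0.0]
        ev_states: list[tuple[int, int, int]] = [(0, 0, 0)]

    t = 0.0
    S = C = P = 0
    while True:
        a_bind = kon_v * S * (n_enz - C)
        a_unb = koff * C
        a_cat = kcat * C
        a0 = ain + a_bind + a_unb + a_cat
        if not math.isfinite(a0):
            raise RuntimeError(
                f"nonfinite total propensity at t={t:.6g} (S={S}, SE={C})"
            )
        t_next = horizon + 1.0 if a0 <= 0.0 else t + _exp_variate(rng, a0)
        if sampled:
            while gi < grid.size and grid[gi] < t_next:
                out[gi, 0], out[gi, 1], out[gi, 2] = S, C, P
                gi += 1
        if t_next > horizon:
            break
        t = t_next
        u = rng.random() * a0
        if u < ain:
            S += batch
        elif u < ain + a_bind:
            S -= 1
            C += 1
        elif u < ain + a_bind + a_unb:
            S += 1
            C -= 1
        else:
            C -= 1
            P += 1
        if not sampled:
            ev_times.append(t)
            ev_states.append((S, C, P))

    if sampled:
        times, states = grid, out
    else:
        times = np.asarray(ev_times)
        states = np.asarray(ev_states, dtype=np.int64)
    return Trajectory(times, states, ENZYME_COLUMNS, seed, "enzyme", spec, horizon)


def simulate_generegulation(
    spec: GeneRegSystemSpec,
    horizon: float,
    seed: int,
    sample_times: Sequence[float] | None = None,
) -> Trajectory:
    """Exact SSA run of the TF expression cascade with operator binding.

    Starts from the empty state (no mRNA, no protein, operator free), which
    represents switching transcription on at time zero.  Bound TF (either
    binding mode) is sequestered from the free pool and not diluted; the total
    mature TF count is conserved by binding/unbinding events.
    """
    _check_horizon(horizon)
    rng = _pyrandom.Random(seed)
    a_tx, gm, vt, gp = spec.a_tf, spec.gamma_m, spec.v_tf, spec.gamma_p
    deltas = spec.maturation_rates
    kappa = len(deltas)
    vol = spec.volume
    ns_on, ns_off = spec.ns_binding
    sp_on, sp_off = spec.sp_binding
    model = spec.binding_model
    n_ops = spec.n_operators
    has_binding = model != "none" and ns_on > 0
    # independent mode: direct specific binding with the same association rate
    # as the nonspecific search and an off rate preserving K = K_NS * K_SP
    if model == "independent" and has_binding:
        d_on = ns_on
        d_off = ns_off / (sp_on / sp_off) if sp_off > 0 else 0.0

    sampled = sample_times is not None
    if sampled:
        grid = np.asarray(sample_times, dtype=float)
        if grid.size and grid[-1] > horizon + 1e-9:
            raise ValueError("sample_times extend beyond the simulated horizon")
        out = np.empty((grid.size, 5), dtype=np.int64)
        gi = 0
    else:
        ev_times = [0.0]
        ev_states = [(0, 0, 0, 0, 0)]

    t = 0.0
    m = 0
    imm = [0] * kappa
    n_free = 0
    ops = [0] * n_ops  # 0 free, 1 nonspecific, 2 operator-bound
    while True:
        props: list[float] = [a_tx, gm * m, vt * m]
        props.extend(d * imm[i] for i, d in enumerate(deltas))
        props.append(gp * n_free)
        if has_binding:
            for st in ops:
                if st == 0:
                    props.append(ns_on * n_free / vol)
                    if model == "independent":
                        props.append(d_on * n_free / vol)
                elif st == 1:
                    props.append(ns_off)
                    if model == "sequential":
                        props.append(sp_on)
                else:
                    props.append(sp_off if model == "sequential" else d_off)
        a0 = math.fsum(props)
        if not math.isfinite(a0):
            raise RuntimeError(f"nonfinite total propensity at t={t:.6g}")
        t_next = horizon + 1.0 if a0 <= 0.0 else t + _exp_variate(rng, a0)
        if sampled:
            n_bound = sum(1 for s in ops if s > 0)
            n_sp = sum(1 for s in ops if s == 2)
            row = (m, sum(imm), n_free, n_bound, n_sp)
            while gi < grid.size and grid[gi] < t_next:
                out[gi] = row
                gi += 1
        if t_next > horizon:
            break
        t = t_next
        u = rng.random() * a0
        idx = 0
        acc = 0.0
        for idx, p in enumerate(props):
            acc += p
            if u < acc:
                break
        if idx == 0:
            m += 1
        elif idx == 1:
            m -= 1
        elif idx == 2:
            if kappa:
                imm[0] += 1
            else:
                n_free += 1
        elif idx < 3 + kappa:
            i = idx - 3
            imm[i] -= 1
            if i + 1 < kappa:
                imm[i + 1] += 1
            else:
                n_free += 1
        elif idx == 3 + kappa:
            n_free -= 1
        else:
            # binding reactions, in the order appended above
            j = idx - (4 + kappa)
            for k, st in enumerate(ops):
                if st == 0:
                    n_here = 2 if model == "independent" else 1
                elif st == 1:
                    n_here = 2 if model == "sequential" else 1
                else:
                    n_here = 1
                if j < n_here:
                    if st == 0:
                        ops[k] = 1 if (model == "sequential" or j == 0) else 2
                        n_free -= 1
                    elif st == 1:
                        if model == "sequential" and j == 1:
                            ops[k] = 2
                        else:
                            ops[k] = 0
                            n_free += 1
                    else:
                        if model == "sequential":
                            ops[k] = 1
                        else:
                            ops[k] = 0
                            n_free += 1
                    break
                j -= n_here
        if not sampled:
            ev_times.append(t)
            ev_states.append(
                (
                    m,
                    sum(imm),
                    n_free,
                    sum(1 for s in ops if s > 0),
                    sum(1 for s in ops if s == 2),
                )
            )

    if sampled:
        times, states = grid, out
    else:
        times = np.asarray(ev_times)
        states = np.asarray(ev_states, dtype=np.int64)
    return Trajectory(times, states, GENEREG_COLUMNS, seed, "genereg", spec, horizon)


def run_ensemble(
    spec: EnzymeSystemSpec | GeneRegSystemSpec,
    horizon: float,
    n_runs: int,
    base_seed: int,
    sample_times: Sequence[float] | None = None,
) -> TrajectoryEnsemble:
    """Simulate ``n_runs`` independent runs with counter-derived seeds.

    The ensemble is bit-reproducible from ``base_seed``; per-run seeds are
    derived with a counter-based scheme so runs share no generator state.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    _check_horizon(horizon)
    if sample_times is None:
        sample_times = np.linspace(0.0, horizon, 201)
    grid = np.asarray(sample_times, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("sample_times must be strictly increasing, length >= 2")
    seeds = _derive_run_seeds(base_seed, n_runs)
    sim = simulate_enzyme if isinstance(spec, EnzymeSystemSpec) else simulate_generegulation
    runs = [sim(spec, horizon, s, sample_times=grid) for s in seeds]
    return TrajectoryEnsemble(runs, grid, seeds, spec, runs[0].kind, horizon)


def sample_trajectory(traj: Trajectory, grid: Sequence[float]) -> np.ndarray:
    """Right-continuous state at ``grid`` times from an event-resolved run."""
    g = np.asarray(grid, dtype=float)
    if g.size and g[-1] > traj.horizon + 1e-9:
        raise ValueError("grid extends beyond the simulated horizon")
    idx = np.searchsorted(traj.times, g, side="right") - 1
    return traj.states[np.clip(idx, 0, None)]


def ensemble_stats(ens: TrajectoryEnsemble) -> EnsembleSummary:
    """Across-run mean/variance of concentration, occupancy and rate.

    The concentration is free substrate (enzyme system) or the conserved
    mature TF pool, free plus bound (gene regulation), divided by the volume.
    Variance uses the unbiased ``n - 1`` estimator.  The occupancy is the
    fraction of runs with an enzyme-substrate complex (averaged over enzymes)
    or with the operator specifically bound.  The rate estimate is the
    central difference of the mean cumulative product count (enzyme only).
    """
    if not ens.runs or ens.time_grid.size == 0:
        raise ValueError("ensemble must contain runs and a nonempty time grid")
    data = ens.data.astype(float)
    n = len(ens.runs)
    vol = ens.spec.volume
    if ens.kind == "enzyme":
        conc = data[:, :, 0] / vol
        occ = data[:, :, 1].mean(axis=0) / ens.spec.n_enzymes
        rate = np.gradient(data[:, :, 2].mean(axis=0), ens.time_grid)
    else:
        conc = (data[:, :, 2] + data[:, :, 3]) / vol
        occ = data[:, :, 4].mean(axis=0) / ens.spec.n_operators
        rate = np.full(ens.time_grid.shape, np.nan)
    return EnsembleSummary(
        time_grid=ens.time_grid,
        mean_concentration=conc.mean(axis=0),
        variance_concentration=conc.var(axis=0, ddof=1),
        occupancy=occ,
        rate_estimate=rate,
        n_runs=n,
    )


def stationary_moments(
    ens: TrajectoryEnsemble, window_start: float
) -> dict[str, float]:
    """Stationary mean/variance/rate from time-and-ensemble averaging.

    Per-run time averages over ``[window_start, horizon]`` give independent
    replicates; the standard errors are across-run SEs of those replicates
    (runs are independent, so the SEs are valid even though samples within a
    run are autocorrelated).
    """
    mask = ens.time_grid >= window_start
    if mask.sum() < 2:
        raise ValueError("stationary window contains fewer than 2 grid points")
    data = ens.data.astype(float)
    vol = ens.spec.volume
    n = len(ens.runs)
    if ens.kind == "enzyme":
        conc = data[:, mask, 0] / vol
    else:
        conc = (data[:, mask, 2] + data[:, mask, 3]) / vol
    run_means = conc.mean(axis=1)
    pooled = conc.ravel()
    out = {
        "mean": float(run_means.mean()),
        "se_mean": float(run_means.std(ddof=1) / math.sqrt(n)),
        "variance": float(pooled.var(ddof=1)),
    }
    run_vars = conc.var(axis=1, ddof=1)
    out["se_variance"] = float(run_vars.std(ddof=1) / math.sqrt(n))
    if ens.kind == "enzyme":
        t0 = ens.time_grid[mask][0]
        t1 = ens.time_grid[-1]
        i0 = int(np.argmax(mask))
        per_run_rate = (data[:, -1, 2] - data[:, i0, 2]) / (t1 - t0)
        out["rate"] = float(per_run_rate.mean())
        out["se_rate"] = float(per_run_rate.std(ddof=1) / math.sqrt(n))
    return out


# ===========================================================================
# Section 3: TF analytics (exact model for the delayed, bursty cascade)
# ===========================================================================


@dataclass(frozen=True)
class MaturationDelay:
    """Sum of ``kappa`` independent exponential maturation stages."""

    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.rates):
            raise ValueError("maturation rates must be > 0")

    @property
    def kappa(self) -> int:
        return len(self.rates)

    @property
    def mean(self) -> float:
        return sum(1.0 / r for r in self.rates)

    @property
    def cutoff(self) -> float:
        """Time beyond which the delay density carries negligible (<1e-14) mass."""
        if not self.rates:
            return 0.0
        return self.mean + 35.0 / min(self.rates)


def delay_density(delay: MaturationDelay, t) -> np.ndarray | float:
    """Density of the total maturation delay (hypoexponential family).

    Pairwise-distinct rates use the partial-fraction form
    ``f(t) = sum_i c_i d_i exp(-d_i t)`` with
    ``c_i = prod_{j != i} d_j/(d_j - d_i)``; all-equal rates use the Erlang
    closed form; mixed near-equal rates (relative gap below
    ``DELAY_EQUAL_RTOL``) fall back to the exact phase-type matrix
    exponential, which is stable in the confluent limit.  Zero for ``t < 0``.
    """
    if delay.kappa == 0:
        raise ValueError("delay density undefined for zero maturation steps")
    tt = np.asarray(t, dtype=float)
    scalar = tt.ndim == 0
    tt = np.atleast_1d(tt)
    out = np.zeros_like(tt)
    pos = tt >= 0
    r = np.asarray(delay.rates, dtype=float)
    k = r.size
    rel = np.abs(r[:, None] - r[None, :]) / r[:, None]
    distinct = np.all(rel[~np.eye(k, dtype=bool)] >= DELAY_EQUAL_RTOL) if k > 1 else True
    if k == 1:
        out[pos] = r[0] * np.exp(-r[0] * tt[pos])
    elif np.all(rel < DELAY_EQUAL_RTOL):
        d = float(r.mean())
        out[pos] = (
            d**k * tt[pos] ** (k - 1) * np.exp(-d * tt[pos]) / math.gamma(k)
        )
    elif distinct:
        with np.errstate(over="ignore"):
            for i in range(k):
                ci = np.prod(r[np.arange(k) != i] / (r[np.arange(k) != i] - r[i]))
                out[pos] += ci * r[i] * np.exp(-r[i] * tt[pos])
        out[pos] = np.maximum(out[pos], 0.0)
    else:
        # defensive confluent branch: exact phase-type density
        T = np.diag(-r) + np.diag(r[:-1], 1)
        exit_vec = np.zeros(k)
        exit_vec[-1] = r[-1]
        alpha = np.zeros(k)
        alpha[0] = 1.0
        vals = np.array(
            [alpha @ linalg.expm(T * x) @ exit_vec for x in tt[pos]]
        )
        out[pos] = vals
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class DiffusionKernel:
    """Concentration contribution ``phi(t)`` of one mature TF emerging at t=0.

    ``evaluator`` must be vectorised, nonnegative, integrable on ``[0, inf)``
    and zero for negative times (causality).  ``tail_rate`` (the asymptotic
    exponential decay rate) guides improper-integral truncation.
    """

    evaluator: Callable[[np.ndarray], np.ndarray]
    tail_rate: float

    def __call__(self, t) -> np.ndarray:
        tt = np.asarray(t, dtype=float)
        return np.where(tt >= 0, self.evaluator(np.maximum(tt, 0.0)), 0.0)

    @property
    def cutoff(self) -> float:
        return 40.0 / self.tail_rate

    def integral(self, power: int = 1) -> float:
        """``int_0^inf phi(t)^power dt`` by adaptive quadrature."""
        val, _ = integrate.quad(
            lambda x: self(x) ** power, 0.0, self.cutoff,
            epsabs=0.0, epsrel=1e-12, limit=400,
        )
        return val


def homogeneous_kernel(gamma_p: float, volume: float) -> DiffusionKernel:
    """Well-mixed cell: ``phi(t) = exp(-gamma_p t)/V`` for ``t >= 0``.

    One mature TF raises the concentration around the operator by ``1/V`` and
    is diluted at the protein dilution rate ``gamma_p`` (efflux, growth and
    division lumped into first-order decay).
    """
    if not (gamma_p > 0 and volume > 0):
        raise ValueError("gamma_p and volume must be > 0")
    return DiffusionKernel(
        evaluator=lambda t: np.exp(-gamma_p * t) / volume, tail_rate=gamma_p
    )


@dataclass(frozen=True)
class TFModelParams:
    """Parameter bundle of the analytical TF model.

    ``binding_constant`` is the combined constant ``K`` of the
    Michaelis-Menten-type occupancy law ``p0 = K rho/(1 + K rho)`` (the
    strong-specific-binding approximation); ``k_sp`` optionally supplies the
    specific-binding equilibrium constant for the un-approximated law.
    """

    a_tf: float
    gamma_m: float
    v_tf: float
    delay: MaturationDelay
    kernel: DiffusionKernel
    volume: float
    binding_constant: float
    k_sp: float | None = None

    def __post_init__(self) -> None:
        for name in ("a_tf", "gamma_m", "v_tf", "volume", "binding_constant"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.k_sp is not None and not (self.k_sp > 0):
            raise ValueError("k_sp must be > 0 when given")

    @property
    def burst_size(self) -> float:
        """Mean translational burst size ``b = v_tf/gamma_m``."""
        return self.v_tf / self.gamma_m

    @classmethod
    def from_sim_spec(
        cls, spec: GeneRegSystemSpec, binding_constant: float | None = None
    ) -> "TFModelParams":
        """Analytical counterpart of a simulation spec (homogeneous kernel)."""
        k = binding_constant if binding_constant is not None else spec.binding_constant
        sp_on, sp_off = spec.sp_binding
        return cls(
            a_tf=spec.a_tf,
            gamma_m=spec.gamma_m,
            v_tf=spec.v_tf,
            delay=MaturationDelay(tuple(spec.maturation_rates)),
            kernel=homogeneous_kernel(spec.gamma_p, spec.volume),
            volume=spec.volume,
            binding_constant=k,
            k_sp=(sp_on / sp_off) if sp_off > 0 else None,
        )


# -- building blocks --------------------------------------------------------


def _delayed_kernel(params: TFModelParams, w, power: int = 1) -> np.ndarray:
    """``psi(w) = (f_Delta * phi^power)(w)``: kernel smeared by the delay."""
    ww = np.atleast_1d(np.asarray(w, dtype=float))
    delay, phi = params.delay, params.kernel
    if delay.kappa == 0:
        return phi(ww) ** power if power > 1 else phi(ww)

    def one(wv: float) -> float:
        if wv <= 0:
            return 0.0
        hi = min(wv, delay.cutoff)
        if hi <= 0:
            return 0.0
        val, _ = integrate.quad(
            lambda x: delay_density(delay, x) * phi(wv - x) ** power,
            0.0,
            hi,
            epsabs=QUAD_INNER_TOL * 1e-2,
            epsrel=1e-10,
            limit=200,
        )
        return val

    return np.array([one(v) for v in ww])


def mean_concentration(t: float, params: TFModelParams) -> float:
    """Mean TF concentration ``<rho(t)>``.

    The mean is the convolution of three causal factors, each one stage of the
    cascade, scaled by the transcription rate and burst size:

        <rho(t)> = a_tf b_tf [(1 - e^{-gamma_m s}) * f_Delta * phi](t).

    ``t = inf`` returns the stationary limit ``a_tf b_tf int_0^inf phi``
    (equal to ``a_tf b_tf/(gamma_p V)`` for the homogeneous kernel).  At small
    times the mean grows like ``t^(kappa+2)``: one power per stochastic stage
    (transcript equilibration, each maturation step, kernel onset).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    ab = params.a_tf * params.burst_size
    if math.isinf(t):
        return ab * params.kernel.integral(1)
    if t == 0:
        return 0.0
    gm = params.gamma_m
    # psi = f_Delta * phi is negligible beyond the delay+kernel support, so
    # the integration range may be truncated for very large t
    hi = min(t, params.kernel.cutoff + params.delay.cutoff + 40.0 / gm)
    val, _ = integrate.quad(
        lambda w: (-math.expm1(-gm * (t - w))) * _delayed_kernel(params, w)[0],
        0.0,
        hi,
        epsabs=1e-300,
        epsrel=1e-10,
        limit=400,
    )
    return ab * val


def _psi_spline(params: TFModelParams, t: float, power: int = 1):
    """Cubic spline of ``(f_Delta * phi^power)(w)`` on [0, t] (for variance)."""
    n = int(min(4000, max(600, 4 * t * params.gamma_m + 200)))
    w = np.linspace(0.0, t, n)
    vals = _gl_delayed_kernel(params, w, power)
    return interpolate.CubicSpline(w, vals)


def _gl_delayed_kernel(params: TFModelParams, w_grid: np.ndarray, power: int = 1):
    """Vectorised Gauss-Legendre evaluation of ``f_Delta * phi^power``."""
    delay, phi = params.delay, params.kernel
    if delay.kappa == 0:
        return phi(w_grid) ** power
    nodes, wts = leggauss(48)
    hi = np.minimum(w_grid, delay.cutoff)
    # two panels per point for the possibly long delay support
    out = np.zeros_like(w_grid)
    for lo_f, hi_f in ((0.0, 0.5), (0.5, 1.0)):
        a = hi * lo_f
        b = hi * hi_f
        x = 0.5 * (b - a)[:, None] * (nodes[None, :] + 1.0) + a[:, None]
        fd = delay_density(delay, x.ravel()).reshape(x.shape)
        ph = phi((w_grid[:, None] - x).ravel()).reshape(x.shape) ** power
        out += 0.5 * (b - a) * ((fd * ph) @ wts)
    return out


def variance_concentration(t: float, params: TFModelParams) -> float:
    """Variance of the TF concentration at time ``t``.

    From the second lambda-derivative of the Laplace functional; with
    ``psi = f_Delta * phi`` and ``psi2 = f_Delta * phi^2``:

        Var rho(t) = a b [(1 - e^{-gamma_m s}) * psi2](t)
                   + 2 a b^2 gamma_m int_0^t dx psi(x)
                       int_x^t dy psi(y) (e^{-gamma_m (y-x)} - e^{-gamma_m (t-x)}).

    The first term is the shot-noise (single-molecule) contribution, the
    second the translational-burst covariance of proteins sharing an mRNA.
    Sigmoidal in time; the concave instantaneous-burst limit
    ``a b (2 b + 1) int_0^t phi^2`` is recovered as ``gamma_m, v_tf -> inf``
    at fixed ``b`` with no maturation delay.  ``t = inf`` evaluates the
    stationary limit.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0
    gm = params.gamma_m
    a, b = params.a_tf, params.burst_size
    if math.isinf(t):
        t = params.kernel.cutoff + params.delay.cutoff + 40.0 / gm
    psi = _psi_spline(params, t, power=1)
    psi2 = _psi_spline(params, t, power=2)

    term1, _ = integrate.quad(
        lambda w: (-math.expm1(-gm * (t - w))) * float(psi2(w)),
        0.0, t, epsabs=1e-300, epsrel=1e-10, limit=400,
    )
    term1 *= a * b

    def inner(x: float) -> float:
        val, _ = integrate.quad(
            lambda y: float(psi(y))
            * (math.exp(-gm * (y - x)) - math.exp(-gm * (t - x))),
            x, t, epsabs=1e-300, epsrel=1e-9, limit=200,
        )
        return val

    term2, _ = integrate.quad(
        lambda x: float(psi(x)) * inner(x),
        0.0, t, epsabs=1e-300, epsrel=1e-8, limit=400,
    )
    term2 *= 2.0 * a * b * b * gm
    return term1 + term2


def _F_matrix(
    lams: np.ndarray, w_grid: np.ndarray, params: TFModelParams
) -> np.ndarray:
    """``F(lambda, w) = E_Delta[1 - exp(-lambda phi(w - Delta))]`` on a grid.

    This is the delay-smeared single-event exponential deficit, the inner
    convolution of the Laplace functional.  Returns shape (n_w, n_lambda).
    """
    delay, phi = params.delay, params.kernel
    if delay.kappa == 0:
        ph = phi(w_grid)
        return -np.expm1(-np.outer(ph, lams))
    nodes, wts = leggauss(32)
    hi = np.minimum(w_grid, delay.cutoff)
    out = np.zeros((w_grid.size, lams.size))
    for lo_f, hi_f in ((0.0, 0.25), (0.25, 0.6), (0.6, 1.0)):
        aa = hi * lo_f
        bb = hi * hi_f
        x = 0.5 * (bb - aa)[:, None] * (nodes[None, :] + 1.0) + aa[:, None]
        fd = delay_density(delay, x.ravel()).reshape(x.shape)
        ph = phi((w_grid[:, None] - x).ravel()).reshape(x.shape)
        q = -np.expm1(-ph[:, :, None] * lams[None, None, :])
        out += 0.5 * (bb - aa)[:, None] * np.einsum(
            "wn,wn,wnl->wl", fd, np.broadcast_to(wts, fd.shape), q
        )
    return out


def _laplace_multi(lams: np.ndarray, t: float, params: TFModelParams) -> np.ndarray:
    """``<exp(-lambda rho(t))>`` for a vector of lambdas (shared ODE solve).

    A mature-TF synthesis event at time ``s`` with delay ``Delta`` contributes
    ``phi(t - s - Delta)`` to ``rho(t)``.  Conditioned on the mRNA path, the
    synthesis times are Poisson with intensity ``v_tf N_mRNA(s)``, and the
    mRNA count is an immigration-death process (birth ``a_tf``, death
    ``gamma_m`` per molecule), i.e. an M/M/inf queue whose molecules are the
    points of a Poisson random measure.  Averaging molecule by molecule gives

        <e^{-lambda rho(t)}> = exp(-a_tf int_0^t (1 - g(u)) du),

    where ``g(u)`` is the expected exponential deficit of one mRNA born at
    ``u`` over its exponential lifetime; ``g`` solves the backward equation
    ``g'(u) = (v_tf F(lambda, t-u) + gamma_m) g(u) - gamma_m`` with
    ``g(t) = 1``.  The system is integrated once for all lambdas.
    """
    lams = np.asarray(lams, dtype=float)
    res = np.ones_like(lams)
    active = lams > 0
    if t <= 0 or not np.any(active):
        return res
    la = lams[active]
    # resolve the fastest analytic feature scale of F on the w-grid
    fastest = max(
        params.gamma_m,
        params.kernel.tail_rate,
        max(params.delay.rates, default=0.0),
    )
    n = int(min(_LAPLACE_GRID_MAX, max(_LAPLACE_GRID_MIN, 24.0 * t * fastest)))
    w_grid = np.linspace(0.0, t, n)
    F = _F_matrix(la, w_grid, params)  # (n_w, n_lam)
    F_spl = interpolate.CubicSpline(w_grid, F)
    gm, v, a = params.gamma_m, params.v_tf, params.a_tf
    m = la.size

    def rhs(u: float, y: np.ndarray) -> np.ndarray:
        g = y[:m]
        h = v * F_spl(t - u)
        dg = (h + gm) * g - gm
        dI = -(1.0 - g)
        return np.concatenate([dg, dI])

    y0 = np.concatenate([np.ones(m), np.zeros(m)])
    sol = integrate.solve_ivp(
        rhs, (t, 0.0), y0, method="DOP853", rtol=ODE_RTOL, atol=ODE_ATOL
    )
    if not sol.success:
        raise RuntimeError(
            f"Laplace-functional ODE integration failed: {sol.message}"
        )
    I0 = sol.y[m:, -1]
    res[active] = np.exp(-a * I0)
    return res


def laplace_transform(lambda_, t: float, params: TFModelParams):
    """Laplace functional ``<exp(-lambda rho(t))>`` of the TF concentration.

    Equals 1 at ``lambda = 0`` and at ``t = 0`` (the cell starts without
    transcripts), is nonincreasing and convex in ``lambda``, and its
    derivatives at ``lambda -> 0`` generate the concentration moments.
    Accepts a scalar or an array of lambdas (one shared solve).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    lam = np.asarray(lambda_, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda must be >= 0")
    out = _laplace_multi(np.atleast_1d(lam), t, params)
    return float(out[0]) if lam.ndim == 0 else out


def laplace_moments_fd(t: float, params: TFModelParams) -> tuple[float, float]:
    """Mean and variance from finite differences of the Laplace functional.

    Differentiates the cumulant functional ``Lambda = -log <e^{-lambda rho}>``
    at ``lambda -> 0`` with one-sided second-order stencils and one Richardson
    extrapolation step (``Lambda(0) = 0`` exactly).  This is the
    cross-check route, numerically independent of the convolution formulas.
    """
    m_ref = mean_concentration(t, params)
    if m_ref <= 0:
        return 0.0, 0.0
    # step scale 0.025/mean: truncation ~1e-5 relative, still far above the
    # quadrature/ODE noise floor of the functional itself
    h = 0.025 / m_ref
    lams = np.array([0.5 * h, h, 1.5 * h, 2 * h, 3 * h])
    lam_vals = _laplace_multi(lams, t, params)
    L = dict(zip(lams, -np.log(lam_vals)))

    def d1(step: float) -> float:
        return (4.0 * L[step] - L[2 * step]) / (2.0 * step)

    def d2(step: float) -> float:
        return (-5.0 * L[step] + 4.0 * L[2 * step] - L[3 * step]) / step**2

    mean_fd = (4.0 * d1(0.5 * h) - d1(h)) / 3.0
    var_fd = -(4.0 * d2(0.5 * h) - d2(h)) / 3.0
    return mean_fd, var_fd


# -- occupancy --------------------------------------------------------------


def _occupancy_constants(
    params: TFModelParams, strong_binding: bool
) -> tuple[float, float]:
    """(K_eff, prefactor): the averaged occupancy is pre * <K' rho/(1+K' rho)>.

    With strong specific binding (``K_SP >> 1``) the occupancy law is
    ``p0 = K rho/(1 + K rho)``.  The un-approximated two-state law
    ``p0 = K rho/(1 + K(1 + 1/K_SP) rho)`` is the same hyperbola with
    ``K' = K (1 + 1/K_SP)`` scaled by ``K/K'``.
    """
    K = params.binding_constant
    if strong_binding or params.k_sp is None:
        return K, 1.0
    kp = K * (1.0 + 1.0 / params.k_sp)
    return kp, K / kp


def occupancy_p0(rho: float, params: TFModelParams, strong_binding: bool = True) -> float:
    """Deterministic occupancy law ``p0(rho)`` at a fixed concentration."""
    keff, pre = _occupancy_constants(params, strong_binding)
    return pre * keff * rho / (1.0 + keff * rho)


_GL32 = leggauss(32)


def _unit_interval_nodes() -> tuple[np.ndarray, np.ndarray]:
    """Panelled Gauss-Legendre nodes/weights on (0, 1) for the occupancy integral.

    The substitution ``z = y^4`` regularises the algebraic endpoint behaviour
    ``z^(K rho)`` of the integrand at ``z -> 0`` for weak effective binding,
    making the rule exact to machine precision on point-mass surrogates.
    """
    xs, ws = [], []
    for a, b in ((0.0, 0.25), (0.25, 0.6), (0.6, 1.0)):
        n, w = _GL32
        y = 0.5 * (b - a) * (n + 1.0) + a
        xs.append(y**4)
        ws.append(0.5 * (b - a) * w * 4.0 * y**3)
    return np.concatenate(xs), np.concatenate(ws)


_Z_NODES, _Z_WEIGHTS = _unit_interval_nodes()


def occupancy_exact(
    t: float, params: TFModelParams, strong_binding: bool = True
) -> float:
    """Exact averaged occupancy ``<p0(rho(t))>`` via the Laplace functional.

    Using ``x/(1+x) = 1 - int_0^inf e^{-u} e^{-u x} du`` termwise,

        <K rho/(1 + K rho)> = 1 - int_0^1 <exp(K ln(z) rho(t))> dz,

    where the substitution ``z = e^{-u}`` maps the semi-infinite integral to
    the unit interval (integrated with panelled Gauss-Legendre rules).
    Monotone nondecreasing in the binding constant.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0
    keff, pre = _occupancy_constants(params, strong_binding)
    lams = -keff * np.log(_Z_NODES)
    lvals = _laplace_multi(lams, t, params)
    return pre * (1.0 - float(np.dot(_Z_WEIGHTS, lvals)))


def occupancy_mme(
    t: float, params: TFModelParams, strong_binding: bool = True
) -> float:
    """Deterministic (MME-type) occupancy at the mean concentration."""
    return occupancy_p0(mean_concentration(t, params), params, strong_binding)


def occupancy_vcmme(
    t: float,
    params: TFModelParams,
    strong_binding: bool = True,
    moments: tuple[float, float] | None = None,
) -> float:
    """Variance-corrected occupancy.

    Applies :func:`vcmme` with ``K_M = 1/K_eff`` and the analytic mean and
    variance time courses; precomputed ``(mean, variance)`` may be passed to
    avoid recomputation.  Never exceeds the MME occupancy (the correction is
    nonnegative).
    """
    keff, pre = _occupancy_constants(params, strong_binding)
    if moments is None:
        moments = (
            mean_concentration(t, params),
            variance_concentration(t, params),
        )
    m, v = moments
    if m == 0:
        return 0.0
    rp = RateParameters(michaelis_constant=1.0 / keff)
    return pre * vcmme(ConcentrationMoments(mean=m, variance=v), rp)


def occupancy_poisson(
    t: float,
    params: TFModelParams,
    strong_binding: bool = True,
    method: str = "integral",
    mean_count: float | None = None,
) -> float:
    """Occupancy under purely Poissonian TF-number fluctuations.

    The TF copy number is modelled as Poisson with mean
    ``m = <rho(t)> V``; the occupancy averages ``p0(n/V)`` over that law.
    ``method="integral"`` uses the Poisson Laplace functional,
    ``1 - int_0^1 exp(-m (1 - z^(K_eff/V))) dz``; ``method="sum"`` sums the
    probability mass function directly (truncated at ``m + 20 sqrt(m) + 20``),
    as an independent route to the same number.  In the strong-binding limit
    ``K -> inf`` both reduce to ``1 - e^{-m}``, the probability of at least
    one TF molecule.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    keff, pre = _occupancy_constants(params, strong_binding)
    m = (
        mean_count
        if mean_count is not None
        else mean_concentration(t, params) * params.volume
    )
    if m == 0:
        return 0.0
    s = keff / params.volume
    if method == "sum":
        n_max = int(m + 20.0 * math.sqrt(m) + 20.0)
        n = np.arange(0, n_max + 1)
        logpmf = n * math.log(m) - m - np.array([math.lgamma(k + 1) for k in n])
        pmf = np.exp(logpmf)
        return pre * float(np.dot(pmf, s * n / (1.0 + s * n)))
    if method != "integral":
        raise ValueError("method must be 'integral' or 'sum'")
    val, _ = integrate.quad(
        lambda z: math.exp(-m * (-math.expm1(s * math.log(z)) if z > 0 else 1.0)),
        0.0, 1.0, epsabs=QUAD_OUTER_TOL * 1e-2, epsrel=1e-10, limit=200,
    )
    return pre * (1.0 - val)


def correction_difference(
    t: float, params: TFModelParams, strong_binding: bool = True
) -> float:
    """Jensen gap ``p0(<rho>) - <p0(rho)>`` of the occupancy (always >= 0).

    At small times the gap rises proportionally to the concentration
    variance (leading term ``K_eff^2 Var rho/(1 + K_eff <rho>)^3``), reaches
    an interior maximum during the transient, and relaxes to a small
    stationary value set by the stationary mean and variance.
    """
    return occupancy_mme(t, params, strong_binding) - occupancy_exact(
        t, params, strong_binding
    )


def correction_ratio(
    t: float, params: TFModelParams, strong_binding: bool = True
) -> float:
    """Relative occupancy ``<p0(rho)>/p0(<rho>)`` in [0, 1]; NaN at ``t = 0``.

    The ratio is undefined where the deterministic occupancy vanishes (no TF
    yet); ``float('nan')`` is returned there as the documented sentinel.
    """
    denom = occupancy_mme(t, params, strong_binding)
    if denom == 0:
        return float("nan")
    return occupancy_exact(t, params, strong_binding) / denom


def growth_exponent(
    params: TFModelParams, t_lo: float = 0.25, t_hi: float = 1.0, n: int = 6
) -> float:
    """Fitted small-time log-log slope of the mean concentration.

    Equals ``kappa + 2`` for ``kappa`` maturation steps: transcript
    equilibration and kernel onset contribute one power of ``t`` each, and
    every maturation stage adds one more.
    """
    ts = np.geomspace(t_lo, t_hi, n)
    ms = np.array([mean_concentration(x, params) for x in ts])
    slope = np.polyfit(np.log(ts), np.log(ms), 1)[0]
    return float(slope)


# ===========================================================================
# Section 4: workbench (fixtures, configs, drivers, I/O)
# ===========================================================================

#: Named parameter sets: biologically plausible regimes in which the
#: variance correction matters (bursty substrate input; a lowly expressed
#: bacterial repressor) plus a large-copy control.  See docs/methods.md for
#: how each value was chosen.
FIXTURES: dict[str, dict] = {
    # Single enzyme, substrate arriving in batches of 40.  K_M = 100 copies
    # per volume; the input flux is calibrated with the package's own
    # variance-corrected flux balance (linear-noise variance estimate) so the
    # stationary substrate count is 117.6 molecules -- the defining condition
    # of this regime, with the substrate pool of order K_M.
    "fig1a_like": {
        "kind": "enzyme",
        "k_on": 0.02,
        "k_off": 1.0,
        "k_cat": 1.0,
        "batch_size": 40,
        "input_rate": 0.0123479,
        "n_enzymes": 1,
        "volume": 1.0,
    },
    # E. coli-like TF cascade: one lowly transcribed repressor gene
    # (one mRNA per 5 min, 2 min mRNA lifetime, burst size 6), two maturation
    # steps of 50 s, 30 min dilution time, ~36 stationary copies in 1 um^3,
    # and strong operator binding (K_NS K_SP = 1/3 um^3, K_SP = 100).
    "fig1b_like": {
        "kind": "genereg",
        "a_tf": 1.0 / 300.0,
        "gamma_m": 1.0 / 120.0,
        "v_tf": 0.05,
        "maturation_rates": (0.02, 0.02),
        "gamma_p": 1.0 / 1800.0,
        "volume": 1.0,
        "ns_binding": (0.1, 30.0),
        "sp_binding": (30.0, 0.3),
        "binding_model": "sequential",
        "n_operators": 1,
    },
    # Large-copy control: 20 enzymes, single-molecule input at high flux,
    # K_M = 1000 -- concentration fluctuations are relatively tiny and every
    # estimator collapses onto the MME.
    "deterministic_limit": {
        "kind": "enzyme",
        "k_on": 0.002,
        "k_off": 1.0,
        "k_cat": 1.0,
        "batch_size": 1,
        "input_rate": 10.0,
        "n_enzymes": 20,
        "volume": 1.0,
    },
}


def fixture(name: str) -> EnzymeSystemSpec | GeneRegSystemSpec:
    """Instantiate a named fixture parameter set."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    d = dict(FIXTURES[name])
    kind = d.pop("kind")
    if kind == "enzyme":
        return EnzymeSystemSpec(**d)
    d["maturation_rates"] = tuple(d.get("maturation_rates", ()))
    d["ns_binding"] = tuple(d.get("ns_binding", (0.0, 0.0)))
    d["sp_binding"] = tuple(d.get("sp_binding", (0.0, 0.0)))
    return GeneRegSystemSpec(**d)


_SCENARIOS = ("enzyme_burst", "genereg_analytics", "genereg_sim", "comparison")


@dataclass
class ExperimentConfig:
    """Fully explicit, reproducible experiment description.

    ``parameters`` is either a fixture name or a parameter mapping with a
    ``kind`` key; seeds are always explicit (no wall-clock seeding).
    ``grid = (start, stop, n)`` fixes the output time grid so analytic and
    simulated columns align; ``batch_sizes`` applies to the enzyme sweep,
    which holds the substrate input flux fixed while the batch size varies.
    """

    scenario: str
    parameters: str | dict
    base_seed: int = 0
    n_runs: int = 200
    horizon: float = 0.0
    grid: tuple[float, float, int] | None = None
    batch_sizes: tuple[int, ...] = (1, 5, 10, 20, 40)
    window_start: float | None = None
    strong_binding: bool = True
    out: str | None = None

    def resolve_spec(self) -> EnzymeSystemSpec | GeneRegSystemSpec:
        if isinstance(self.parameters, str):
            return fixture(self.parameters)
        d = dict(self.parameters)
        kind = d.pop("kind", None)
        if kind == "enzyme":
            return EnzymeSystemSpec(**d)
        if kind == "genereg":
            for key in ("maturation_rates", "ns_binding", "sp_binding"):
                if key in d:
                    d[key] = tuple(d[key])
            return GeneRegSystemSpec(**d)
        raise ValueError("parameters must name a fixture or carry kind=enzyme|genereg")

    def validate(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(
                f"invalid field 'scenario': {self.scenario!r} not in {_SCENARIOS}"
            )
        spec = self.resolve_spec()
        needs_sim = self.scenario in ("enzyme_burst", "genereg_sim", "comparison")
        if needs_sim and self.n_runs < 2:
            raise ValueError("invalid field 'n_runs': must be >= 2 for simulation")
        if needs_sim and not (self.horizon > 0):
            raise ValueError("invalid field 'horizon': must be > 0 for simulation")
        if self.scenario != "enzyme_burst" and self.grid is None:
            raise ValueError("invalid field 'grid': required for this scenario")
        if self.scenario == "enzyme_burst":
            if not isinstance(spec, EnzymeSystemSpec):
                raise ValueError("invalid field 'parameters': enzyme spec required")
            if any(b < 1 for b in self.batch_sizes):
                raise ValueError("invalid field 'batch_sizes': must be >= 1")
        elif not isinstance(spec, GeneRegSystemSpec):
            raise ValueError("invalid field 'parameters': genereg spec required")

    def time_grid(self) -> np.ndarray:
        start, stop, n = self.grid
        return np.linspace(start, stop, int(n))


def load_config(path: str) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from YAML (JSON is valid YAML)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"invalid config field(s): {sorted(unknown)}")
    if "grid" in raw and raw["grid"] is not None:
        raw["grid"] = tuple(raw["grid"])
    if "batch_sizes" in raw:
        raw["batch_sizes"] = tuple(raw["batch_sizes"])
    cfg = ExperimentConfig(**raw)
    cfg.validate()
    return cfg


def write_table(df: pd.DataFrame, path: str, sidecar: dict | None = None) -> None:
    """Write a TSV with full float round-trip precision plus a YAML sidecar."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if sidecar is not None:
        with open(str(path) + ".meta.yaml", "w") as fh:
            yaml.safe_dump(_plain(sidecar), fh, sort_keys=False)


def read_table(path: str) -> pd.DataFrame:
    # round_trip parsing restores the exact binary floats written at %.17g
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def _plain(obj):
    """Recursively convert dataclasses/numpy scalars for YAML serialisation."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if isinstance(obj, (DiffusionKernel,)):
            return {"tail_rate": float(obj.tail_rate)}
        return {
            f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _enzyme_rate_params(spec: EnzymeSystemSpec) -> RateParameters:
    return RateParameters(
        michaelis_constant=spec.michaelis_constant / spec.volume,
        v_max=spec.v_max,
    )


def enzyme_batch_sweep(
    spec: EnzymeSystemSpec,
    batch_sizes: Iterable[int],
    n_runs: int,
    horizon: float,
    base_seed: int,
    window_start: float | None = None,
) -> pd.DataFrame:
    """Stationary rate vs batch size at fixed substrate input flux.

    The flux ``input_rate * batch_size`` of the supplied spec is held
    constant; larger batches mean rarer, larger concentration jumps.  For
    each batch size the stationary mean/variance of the free-substrate
    concentration, the simulated normalised rate, and the MME / VCMME /
    lower-bound predictions at the empirical moments are tabulated.
    """
    flux = spec.input_rate * spec.batch_size
    window = horizon / 2.0 if window_start is None else window_start
    rp = _enzyme_rate_params(spec)
    grid = np.linspace(0.0, horizon, 241)
    rows = []
    for i, b in enumerate(batch_sizes):
        spec_b = dataclasses.replace(spec, batch_size=int(b), input_rate=flux / b)
        ens = run_ensemble(spec_b, horizon, n_runs, base_seed + 1000 * i, grid)
        st = stationary_moments(ens, window)
        mom = ConcentrationMoments(mean=st["mean"], variance=st["variance"])
        v0_sim = st["rate"] / spec.v_max
        se_v0 = st["se_rate"] / spec.v_max
        row = {
            "batch_size": int(b),
            "mean_concentration": st["mean"],
            "se_mean": st["se_mean"],
            "variance_concentration": st["variance"],
            "v0_sim": v0_sim,
            "se_v0_sim": se_v0,
            "v0_mme": jensen_upper_bound(mom, rp),
            "v0_vcmme": vcmme(mom, rp),
            "v0_lower": optimal_lower_bound(mom, rp),
        }
        row["dev_mme"] = row["v0_mme"] - v0_sim
        row["dev_vcmme"] = row["v0_vcmme"] - v0_sim
        row["dev_lower"] = row["v0_lower"] - v0_sim
        # propagate the Monte-Carlo uncertainty of the empirical moments
        # through the VCMME prediction (first-order) and combine with the
        # rate-estimate SE
        m, km, var = st["mean"], rp.michaelis_constant, st["variance"]
        dvdm = km / (m + km) ** 2 + 3.0 * km * var / (m + km) ** 4
        dvdv = km / (m + km) ** 3
        row["se_dev_vcmme"] = math.sqrt(
            se_v0**2
            + (dvdm * st["se_mean"]) ** 2
            + (dvdv * st["se_variance"]) ** 2
        )
        rows.append(row)
        logger.info(
            "batch %d: mean=%.2f var=%.1f v0_sim=%.4f mme=%.4f vcmme=%.4f",
            b, st["mean"], st["variance"], v0_sim, row["v0_mme"], row["v0_vcmme"],
        )
    return pd.DataFrame(rows)


def analytics_table(
    params: TFModelParams,
    time_grid: np.ndarray,
    strong_binding: bool = True,
) -> pd.DataFrame:
    """Analytic TF statistics and occupancy estimators on a time grid.

    Columns: mean and variance of the TF concentration, the exact averaged
    occupancy, the MME / VCMME / Poissonian estimates, the Jensen gap
    (``difference``) and the relative correction (``ratio``).
    """
    rows = []
    for t in np.asarray(time_grid, dtype=float):
        m = mean_concentration(t, params)
        v = variance_concentration(t, params)
        exact = occupancy_exact(t, params, strong_binding)
        det = occupancy_p0(m, params, strong_binding)
        vc = occupancy_vcmme(t, params, strong_binding, moments=(m, v))
        poi = occupancy_poisson(
            t, params, strong_binding, mean_count=m * params.volume
        )
        rows.append(
            {
                "time": t,
                "mean": m,
                "variance": v,
                "occupancy_exact": exact,
                "occupancy_mme": det,
                "occupancy_vcmme": vc,
                "occupancy_poisson": poi,
                "difference": det - exact,
                "ratio": exact / det if det > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def simulation_table(
    spec: GeneRegSystemSpec,
    time_grid: np.ndarray,
    n_runs: int,
    base_seed: int,
) -> pd.DataFrame:
    """Ensemble statistics of the gene-regulation SSA on a time grid."""
    horizon = float(np.max(time_grid))
    ens = run_ensemble(spec, horizon, n_runs, base_seed, time_grid)
    st = ensemble_stats(ens)
    n = st.n_runs
    occ = st.occupancy
    return pd.DataFrame(
        {
            "time": st.time_grid,
            "mean_sim": st.mean_concentration,
            "variance_sim": st.variance_concentration,
            "occupancy_sim": occ,
            "se_mean_sim": np.sqrt(st.variance_concentration / n),
            "se_occupancy_sim": np.sqrt(np.maximum(occ * (1 - occ), 0.0) / n),
            "n_runs": n,
        }
    )


def compare_methods(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Aligned per-time comparison of the five occupancy/rate estimators.

    For gene regulation: exact analytic, MME, VCMME, Poissonian and SSA
    occupancies on the config grid.  For the enzyme sweep: simulated rate vs
    MME/VCMME/bounds per batch size.  Returns the table plus summary rows
    (maximum deviations, their times, stationary values).
    """
    config.validate()
    spec = config.resolve_spec()
    if config.scenario == "enzyme_burst":
        df = enzyme_batch_sweep(
            spec, config.batch_sizes, config.n_runs, config.horizon,
            config.base_seed, config.window_start,
        )
        summary = {
            "max_abs_dev_mme": float(df["dev_mme"].abs().max()),
            "max_abs_dev_vcmme": float(df["dev_vcmme"].abs().max()),
        }
        return df, summary
    params = TFModelParams.from_sim_spec(spec)
    grid = config.time_grid()
    df = analytics_table(params, grid, config.strong_binding)
    if config.scenario == "comparison":
        sim = simulation_table(spec, grid, config.n_runs, config.base_seed)
        df = df.merge(sim, on="time")
    imax = int(df["difference"].idxmax())
    summary = {
        "max_difference_mme": float(df["difference"].max()),
        "time_of_max_difference": float(df.loc[imax, "time"]),
        "max_abs_dev_vcmme": float(
            (df["occupancy_vcmme"] - df["occupancy_exact"]).abs().max()
        ),
        "max_abs_dev_poisson": float(
            (df["occupancy_poisson"] - df["occupancy_exact"]).abs().max()
        ),
        "stationary_mean": mean_concentration(math.inf, params),
        "final_occupancy_exact": float(df["occupancy_exact"].iloc[-1]),
    }
    return df, summary


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Dispatch a config to its driver; write TSV plus metadata sidecar."""
    config.validate()
    spec = config.resolve_spec()
    logger.info("scenario=%s seed=%d", config.scenario, config.base_seed)
    if config.scenario == "enzyme_burst":
        df, _ = compare_methods(config)
    elif config.scenario == "genereg_analytics":
        df = analytics_table(
            TFModelParams.from_sim_spec(spec), config.time_grid(),
            config.strong_binding,
        )
    elif config.scenario == "genereg_sim":
        df = simulation_table(
            spec, config.time_grid(), config.n_runs, config.base_seed
        )
    else:
        df, _ = compare_methods(config)
    if config.out:
        sidecar = {
            "config": _plain(config),
            "spec": _plain(spec),
            "seeds": list(
                _derive_run_seeds(config.base_seed, config.n_runs)
            )
            if config.scenario != "genereg_analytics"
            else [],
        }
        write_table(df, config.out, sidecar)
        logger.info("wrote %s", config.out)
    return df
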