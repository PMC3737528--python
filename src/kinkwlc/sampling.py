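"""Equilibrium conformational sampling of discrete kinkable wormlike chains.

Linear chains are sampled exactly: the joint bend angles are independent,
drawn from ``p(theta) ~ sin(theta) exp(-E(theta))`` by tabulated
inverse-CDF lookup, with uniform azimuths.  Circular chains are sampled by
closure-preserving Metropolis Monte Carlo with crankshaft moves (see
:mod:`kinkwlc._kernels`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .potentials import BendPotential, ChainSpec, bend_energy, potentials_for_spec

__all__ = [
    "Conformation",
    "EnsembleRun",
    "CircularEnsemble",
    "JointAngleSampler",
    "sample_joint_angle",
    "sample_linear_chain",
    "sample_circular_chain",
    "linear_end_states",
    "EquilibrationWarning",
]


class EquilibrationWarning(UserWarning):
    """Raised when the energy trace of an MC run still shows a trend."""


@dataclass
class Conformation:
    """Ordered unit tangents of one chain conformation."""

    tangents: np.ndarray  # (n_segments, 3)
    topology: str = "linear"

    def __post_init__(self):
        self.tangents = np.asarray(self.tangents, dtype=float)
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("tangents must be unit vectors (within 1e-9)")

    @property
    def joint_angles(self) -> np.ndarray:
        u = self.tangents
        if self.topology == "circular":
            v = np.roll(u, -1, axis=0)
            c = np.einsum("ij,ij->i", u, v)
            c = np.roll(c, 1)  # joint k between segments k-1 and k
        else:
            c = np.einsum("ij,ij->i", u[:-1], u[1:])
        return np.arccos(np.clip(c, -1.0, 1.0))

    def closure_defect(self, l: float = 1.0) -> float:
        return float(np.linalg.norm(self.tangents.sum(axis=0))) * l

    def vertices(self, l: float) -> np.ndarray:
        """Vertex positions in nm, first vertex at the origin."""
        r = np.zeros((self.tangents.shape[0] + 1, 3))
        np.cumsum(self.tangents * l, axis=0, out=r[1:])
        return r

    def to_xyz(self, path, l: float, comment: str = "") -> None:
        """Write vertex positions as plain text, one 'x y z' line (nm) per vertex."""
        r = self.vertices(l)
        with open(path, "w") as fh:
            fh.write(f"# {len(r)} vertices, topology={self.topology} {comment}\n")
            for p in r:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")

    def bending_energy(self, spec: ChainSpec) -> float:
        th = self.joint_angles
        return float(
            sum(bend_energy(spec.potential_at(k), th[k]) for k in range(len(th)))
        )


@dataclass
class EnsembleRun:
    """Monte Carlo run configuration (circular chains).

    ``n_replicas``/``h_scale_min``/``h_scale_max`` control Hamiltonian
    replica exchange on the kink energy: the replicas carry kink energies
    scaled by factors spanning [h_scale_min, h_scale_max]; the replica
    whose scale is (forced to) 1 is the recorded target ensemble, and
    neighbour swaps ferry kink-branch creation (from cheap-kink replicas)
    and annihilation (from costly-kink replicas, when h_scale_max > 1)
    into it.  Set ``n_replicas=0`` for automatic choice (1 for purely
    harmonic chains, 6 when kinkable joints are present), 1 to disable
    exchange.
    """

    n_samples: int = 10_000
    burn_in: int = 10_000
    thinning: int = 1
    rng_seed: int = 0
    delta0: float = 0.6
    wild_frac: float = 0.25
    target_frac: float = 0.2
    n_replicas: int = 0
    h_scale_min: float = 0.3
    h_scale_max: float = 1.0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass
class CircularEnsemble:
    """Output of a circular-chain MC run (per retained sweep)."""

    spec: ChainSpec
    energy: np.ndarray
    n_kinks: np.ndarray
    monitor_theta: np.ndarray
    monitor_kinked: np.ndarray
    acceptance_rate: float
    delta: float
    final: Conformation
    equilibrated: bool = True
    n_swaps: int = 0
    energy_alt: np.ndarray | None = None

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_index": np.arange(len(self.energy)),
                "total_energy_kT": self.energy,
                "n_kinks": self.n_kinks,
                "nick_kinked": self.monitor_kinked.astype(int),
            }
        )


# ---------------------------------------------------------------------------
# joint-angle sampling
# ---------------------------------------------------------------------------


class JointAngleSampler:
    """Tabulated inverse-CDF sampler for p(theta) ~ sin(theta) exp(-E(theta))."""

    def __init__(self, pot: BendPotential, n_grid: int = 4096):
        theta = np.linspace(0.0, math.pi, n_grid)
        w = np.sin(theta) * np.exp(-np.asarray(bend_energy(pot, theta)))
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(theta))])
        if cdf[-1] <= 0:
            raise FloatingPointError("degenerate joint density")
        self.theta = theta
        self.cdf = cdf / cdf[-1]
        self.pot = pot

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return np.interp(rng.random(size), self.cdf, self.theta)


def sample_joint_angle(pot: BendPotential, rng: np.random.Generator, size=None):
    """Draw bend angles from the equilibrium one-joint density."""
    return JointAngleSampler(pot).sample(rng, size)


# ---------------------------------------------------------------------------
# linear chains: exact direct sampling
# ---------------------------------------------------------------------------


def _propagate(t: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate batch tangents ``t`` (N,3) by polar angle theta, azimuth phi."""
    # orthonormal frame perpendicular to t, immune to near-parallel reference
    ref = np.zeros_like(t)
    use_x = np.abs(t[:, 0]) < 0.9
    ref[use_x, 0] = 1.0
    ref[~use_x, 1] = 1.0
    e1 = np.cross(t, ref)
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    e2 = np.cross(t, e1)
    st = np.sin(theta)[:, None]
    return (
        t * np.cos(theta)[:, None]
        + (e1 * np.cos(phi)[:, None] + e2 * np.sin(phi)[:, None]) * st
    )


def sample_linear_chain(
    spec: ChainSpec, n_samples: int, rng_seed: int = 0
) -> np.ndarray:
    """Exact ensemble of linear-chain tangent arrays, shape (n_samples, n_segments, 3).

    The first segment points along +z; joints are drawn independently from
    their one-joint densities and azimuths uniformly.
    """
    if spec.topology != "linear":
        raise ValueError("sample_linear_chain requires linear topology")
    rng = np.random.default_rng(rng_seed)
    n_seg = spec.n_segments
    samplers = _samplers_for(spec.joint_potentials())
    u = np.zeros((n_samples, n_seg, 3))
    u[:, 0, 2] = 1.0
    t = u[:, 0, :].copy()
    for k in range(1, n_seg):
        theta = samplers[k - 1].sample(rng, n_samples)
        phi = rng.uniform(0.0, 2.0 * math.pi, n_samples)
        t = _propagate(t, theta, phi)
        u[:, k, :] = t
    return u


def _samplers_for(pots: list[BendPotential]) -> list[JointAngleSampler]:
    cache: dict[int, JointAngleSampler] = {}
    out = []
    for p in pots:
        key = id(p)
        if key not in cache:
            cache[key] = JointAngleSampler(p)
        out.append(cache[key])
    return out


def linear_end_states(
    pots: list[BendPotential],
    n_samples: int,
    rng: np.random.Generator,
    batch: int = 1_000_000,
):
    """Stream (displacement, end-tangent) pairs for a chain grown from +z.

    The chain starts with an (implicit) segment along +z; ``pots`` lists
    the joint potentials in growth order.  Yields ``(x, w)`` batches where
    ``x`` (N,3) is the sum of the grown unit segments (multiply by l for
    nm) and ``w`` (N,3) is the final segment direction.  Used by the
    half-chain j-factor estimators, which need ends only.
    """
    # one tabulated CDF per distinct potential, evaluated on a shared grid
    uniq: dict[int, int] = {}
    tables = []
    joint_table = np.empty(len(pots), dtype=np.int64)
    grid = None
    for k, p in enumerate(pots):
        key = id(p)
        if key not in uniq:
            s = JointAngleSampler(p)
            uniq[key] = len(tables)
            tables.append(s.cdf)
            grid = s.theta
        joint_table[k] = uniq[key]
    cdf_tables = np.ascontiguousarray(np.vstack(tables))
    m = len(pots)
    batch = min(batch, max(100_000, int(6.0e7 / m)))  # cap trig-buffer memory
    done = 0
    while done < n_samples:
        nb = min(batch, n_samples - done)
        theta = np.empty((nb, m))
        for row in range(cdf_tables.shape[0]):
            cols = np.nonzero(joint_table == row)[0]
            theta[:, cols] = np.interp(
                rng.random((nb, len(cols))), cdf_tables[row], grid
            )
        phi = rng.random((nb, m)) * (2.0 * math.pi)
        ct = np.cos(theta)
        st = np.sin(theta, out=theta)
        cp = np.cos(phi)
        sp = np.sin(phi, out=phi)
        x, w = _kernels.grow_chain_ends_trig(ct, st, cp, sp)
        done += nb
        yield x, w


# ---------------------------------------------------------------------------
# circular chains: crankshaft Metropolis MC
# ---------------------------------------------------------------------------


def regular_polygon(n: int) -> np.ndarray:
    """Tangents of the regular planar n-gon (every joint angle = 2 pi / n)."""
    ang = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])


def _trend_zscore(x: np.ndarray) -> float:
    """z-score of the first-half/second-half mean difference, block-robust."""
    n = len(x)
    if n < 20:
        return 0.0
    half = n // 2
    a, b = x[:half], x[half:]
    nblk = 10
    ba = np.array_split(a, nblk)
    bb = np.array_split(b, nblk)
    ma = np.array([v.mean() for v in ba])
    mb = np.array([v.mean() for v in bb])
    se = math.sqrt(ma.var(ddof=1) / nblk + mb.var(ddof=1) / nblk)
    if se == 0:
        return 0.0
    return float((mb.mean() - ma.mean()) / se)


def sample_circular_chain(
    spec: ChainSpec, run: EnsembleRun, alt_h_scale: float | None = None
) -> CircularEnsemble:
    """Crankshaft Metropolis MC over closed conformations of a circular chain.

    The initial state is the regular polygon.  If the chain carries a nick
    joint, a fraction of the moves anchors one pivot at the nick so its
    branch occupancy mixes at a useful rate.  The move set preserves
    closure exactly; tangents are renormalised periodically.
    """
    if spec.topology != "circular":
        raise ValueError("sample_circular_chain requires circular topology")
    if spec.n_bp < 12:
        raise ValueError("circles below 12 bp are outside the harmonic regime")
    fam, g, h, tc, gw = potentials_for_spec(spec)
    has_kinks = bool(np.any(fam == 2))
    K = run.n_replicas if run.n_replicas > 0 else (6 if has_kinks else 1)
    if not has_kinks:
        K = 1
    scales = np.linspace(run.h_scale_max, run.h_scale_min, K)
    record = int(np.argmin(np.abs(scales - 1.0)))
    scales[record] = 1.0  # the recorded replica is always the unscaled target
    hs = h[None, :] * scales[:, None]
    us = np.broadcast_to(regular_polygon(spec.n_bp), (K, spec.n_bp, 3)).copy()
    target = spec.nick_index if spec.nick_index is not None else -1
    monitor = spec.nick_index if spec.nick_index is not None else 0
    h_alt = h * (1.0 if alt_h_scale is None else alt_h_scale)
    e, e_alt, k, th, kf, acc, delta, swaps0 = _kernels.run_crankshaft(
        us,
        fam,
        g,
        hs,
        tc,
        gw,
        run.n_samples * run.thinning,
        run.burn_in,
        run.thinning,
        run.delta0,
        run.wild_frac,
        target,
        run.target_frac if target >= 0 else 0.0,
        monitor,
        h_alt,
        record,
        int(run.rng_seed) % (2**31 - 1),
    )
    z = _trend_zscore(e)
    ok = abs(z) <= 4.0
    if not ok:
        warnings.warn(
            f"energy trace still trends (z = {z:.1f}); increase burn_in",
            EquilibrationWarning,
            stacklevel=2,
        )
    return CircularEnsemble(
        spec=spec,
        energy=e,
        n_kinks=k,
        monitor_theta=th,
        monitor_kinked=kf,
        acceptance_rate=acc,
        delta=delta,
        final=Conformation(us[0], topology="circular"),
        equilibrated=ok,
        n_swaps=int(swaps0),
        energy_alt=e_alt,
    )
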