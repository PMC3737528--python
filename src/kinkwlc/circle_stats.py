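"""Kink statistics in circular DNA and supercoil-equivalence arithmetic.

Covers the two minicircle observables of interest — the probability that a
nicked circle is kinked at its nick, and the mean number of kinked (open)
joints per covalently closed circle — together with the one-joint kink
free energy and the twist/writhe bookkeeping that converts a minicircle
superhelix density into its large-DNA equivalent.

Torsional stress is not modelled: a covalently closed circle is treated as
a bending-only ring, and a nicked circle as the same ring with one soft
joint.  The circle sizes swept by default cover 63-700 bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .potentials import (
    KT_KCAL_PER_MOL,
    BendPotential,
    ChainSpec,
    Family,
    calibrate_rigidity,
    joint_partition_function,
)
from .sampling import EnsembleRun, sample_circular_chain

__all__ = [
    "DEFAULT_CIRCLE_SIZES",
    "KinkStats",
    "SupercoilContext",
    "nick_kink_probability",
    "mean_kinks_per_circle",
    "kink_free_energy",
    "unstressed_kink_probability",
    "equivalent_sigma",
]

#: Minicircle sizes (bp) covering the range where bending stress matters.
DEFAULT_CIRCLE_SIZES = (63, 70, 85, 100, 150, 200, 300, 450, 600, 700)


@dataclass
class KinkStats:
    """Kink statistics of one circle size."""

    circle_size_bp: int
    p_nick_kink: float
    p_nick_kink_se: float
    mean_kinks: float
    mean_kinks_se: float
    n_samples: int
    potential: BendPotential
    acceptance_rate: float = math.nan
    equilibrated: bool = True

    def __post_init__(self):
        assert 0.0 <= self.p_nick_kink <= 1.0 or math.isnan(self.p_nick_kink)
        assert self.mean_kinks >= 0.0 or math.isnan(self.mean_kinks)


@dataclass(frozen=True)
class SupercoilContext:
    """Superhelix density and the twist/writhe partition of large DNA.

    Minicircles stay essentially flat when underwound, so their linking
    number deficit goes entirely into twist; in large circular DNA writhe
    absorbs about 75% of the supercoiling.
    """

    sigma: float
    writhe_fraction: float = 0.75

    def __post_init__(self):
        if not 0.0 <= self.writhe_fraction < 1.0:
            raise ValueError("writhe_fraction must lie in [0, 1)")


def equivalent_sigma(ctx: SupercoilContext) -> float:
    """Large-DNA superhelix density with the same twist change as the minicircle.

    A flat minicircle converts all of sigma into twist; large DNA converts
    only the fraction (1 - writhe_fraction).  The equivalent large-DNA
    density is therefore sigma / (1 - writhe_fraction).
    """
    return ctx.sigma / (1.0 - ctx.writhe_fraction)


def _se_autocorr(x: np.ndarray) -> float:
    """Standard error of the mean allowing for autocorrelation (capped window)."""
    n = len(x)
    if n < 10:
        return float("inf")
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    var = float(xc @ xc) / n
    if var == 0:
        return 0.0
    tau = 1.0
    for lag in range(1, min(n // 4, 5000)):
        rho = float(xc[:-lag] @ xc[lag:]) / ((n - lag) * var)
        if rho < 0.02:
            break
        tau += 2.0 * rho
    return math.sqrt(var * tau / n)


def _run_circle(spec: ChainSpec, run: EnsembleRun) -> KinkStats:
    ens = sample_circular_chain(spec, run)
    kf = ens.monitor_kinked.astype(float)
    nk = ens.n_kinks.astype(float)
    return KinkStats(
        circle_size_bp=spec.n_bp,
        p_nick_kink=float(kf.mean()),
        p_nick_kink_se=_se_autocorr(kf),
        mean_kinks=float(nk.mean()),
        mean_kinks_se=_se_autocorr(nk),
        n_samples=len(kf),
        potential=spec.potential_at(spec.nick_index or 0),
        acceptance_rate=ens.acceptance_rate,
        equilibrated=ens.equilibrated,
    )


def nick_kink_probability(
    circle_size_bp: int,
    run: EnsembleRun | None = None,
    h: float = 8.0,
    b: float = 1.0,
    a: float = 48.0,
    l: float = 0.34,
) -> KinkStats:
    """Probability that the nick joint of a nicked circle is kinked.

    The circle carries harmonic joints calibrated to persistence length
    ``a`` except for one nick joint with the kink potential (h = 8 kT,
    bends up to 180 deg, the 0.2 M NaCl calibration).  In small circles
    bending stress drives the nick-kink probability to ~1; it decays
    towards the unstressed one-joint value as the circle grows.
    """
    if circle_size_bp < 30:
        raise ValueError("circle must be at least 30 bp")
    stack = calibrate_rigidity(Family.QUADRATIC, a, l)
    nick = BendPotential(family=Family.NICK, g=stack.g, h=h, b=b)
    spec = ChainSpec(
        n_bp=circle_size_bp,
        l=l,
        a=a,
        topology="circular",
        joint_potential=stack,
        nick_potential=nick,
        nick_index=0,
    )
    run = run or EnsembleRun()
    return _run_circle(spec, run)


def mean_kinks_per_circle(
    circle_size_bp: int,
    run: EnsembleRun | None = None,
    h: float = 16.0,
    b: float = 0.3,
    a: float = 48.0,
    l: float = 0.34,
) -> KinkStats:
    """Mean number of kinked (open) joints per covalently closed circle.

    Every joint carries the kinkable potential (default h = 16 kT, the
    ~7 kcal/mol base-pair opening free energy; kinks up to ~90 deg).
    Torsional stress is ignored: the covalently closed circle is modelled
    as a bending-only ring.  The stack rigidity is calibrated harmonically
    to the persistence length ``a`` of intact DNA and the kink branch is
    attached on top (for h >= 12 this matches the exact joint calibration
    to better than 0.5%; for cheap kinks the exact calibration has no
    solution because the kink branch caps the attainable stiffness).
    """
    if circle_size_bp < 30:
        raise ValueError("circle must be at least 30 bp")
    stack = calibrate_rigidity(Family.QUADRATIC, a, l)
    pot = BendPotential(family=Family.KINKABLE, g=stack.g, h=h, b=b)
    spec = ChainSpec(
        n_bp=circle_size_bp, l=l, a=a, topology="circular", joint_potential=pot
    )
    run = run or EnsembleRun()
    return _run_circle(spec, run)


def unstressed_kink_probability(pot: BendPotential) -> float:
    """Kink-branch probability of one unconstrained joint (the large-circle limit)."""
    zk = joint_partition_function(pot, "kink")
    zs = joint_partition_function(pot, "stack")
    return zk / (zk + zs)


def kink_free_energy(kink_pot: BendPotential, stack_pot: BendPotential | None = None):
    """Kink formation free energy dF = -kT ln(Z_kink / Z_stack).

    ``stack_pot`` defaults to the stack branch of ``kink_pot`` itself.
    Returns (dF in kT, dF in kcal/mol at 25 C).  Because the kink branch
    is angularly much wider than the narrow harmonic well, dF is several
    kT below the kink energy h.
    """
    zk = joint_partition_function(kink_pot, "kink")
    if stack_pot is None:
        zs = joint_partition_function(kink_pot, "stack")
    else:
        zs = joint_partition_function(stack_pot, "stack")
    if zk == 0.0:
        return math.inf, math.inf
    df = -math.log(zk / zs)
    return df, df * KT_KCAL_PER_MOL
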