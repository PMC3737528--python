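"""Bending-energy laws at a single inter-base-pair joint.

A discrete wormlike chain assigns an energy (in units of kT) to the bend
angle theta at every joint between successive segments.  Four potential
families are supported:

``quadratic``
    The classical wormlike chain, ``E = (g/2) theta**2`` with dimensionless
    rigidity ``g``.
``linear``
    ``E = alpha * theta``; a non-harmonic control used to probe how little
    the small-angle shape of the potential matters for fragments longer
    than a helical turn.
``kinkable``
    A harmonic stack that can yield into a kink: a flat plateau of height
    ``h`` (the kink energy, in kT) extending up to ``theta_cut``, with a
    harmonic wall beyond.  The joint energy is the minimum of the two
    branches, so small bends cost ``(g/2) theta**2`` and large bends cost
    ``h`` (Crick-Klug kink / opened base pair).
``nick``
    Same functional form as ``kinkable`` but conventionally carries the
    single-strand-break parametrisation (h = 8, bends up to 180 degrees);
    kept as a separate family tag so chain builders can address it.

The angular-range parameter ``b`` maps onto the maximum kink bend angle
``theta_cut``: b = 0.3 allows kinks up to ~90 degrees, b = 1.0 (a nick)
up to 180 degrees; intermediate b interpolate linearly between the anchors.

Thermodynamics of one joint follow from the partition function
``Z = integral_0^pi exp(-E(theta)) sin(theta) dtheta`` (the sin(theta)
factor counts the azimuthal degeneracy of a bend in 3-D).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "Family",
    "BendPotential",
    "ChainSpec",
    "bend_energy",
    "kink_branch_energy",
    "stack_branch_energy",
    "is_kinked",
    "theta_crossover",
    "joint_partition_function",
    "mean_cos_theta",
    "persistence_length",
    "calibrate_rigidity",
    "theta_cut_from_b",
    "KT_KCAL_PER_MOL",
]

#: kT at 25 C in kcal/mol, used for free-energy unit conversions.
KT_KCAL_PER_MOL = 0.593


class Family(str, enum.Enum):
    QUADRATIC = "quadratic"
    LINEAR = "linear"
    KINKABLE = "kinkable"
    NICK = "nick"


def theta_cut_from_b(b: float) -> float:
    """Maximum kink bend angle (rad) for angular-range parameter ``b``.

    Anchored at b = 0.3 -> pi/2 (kinks up to ~90 deg) and b = 1.0 -> pi
    (a nick bends freely); linear in b between and beyond, clipped to
    (0, pi].
    """
    if b <= 0:
        raise ValueError(f"kink range parameter b must be positive, got {b}")
    theta = math.pi * (b + 0.4) / 1.4
    return float(min(theta, math.pi))


@dataclass(frozen=True)
class BendPotential:
    """Bending-energy law at one joint.  Energies are in units of kT.

    Parameters
    ----------
    family : Family
        Potential family (see module docstring).
    g : float
        Dimensionless harmonic rigidity; also the wall rigidity of the
        kinkable/nick families.
    alpha : float
        Slope of the linear potential (linear family only).
    h : float
        Kink energy in kT (kinkable/nick families).
    b : float
        Kink angular-range parameter; determines ``theta_cut`` and the
        wall softness.
    theta_cut : float
        Maximum kink bend angle in radians.  Derived from ``b`` unless
        given explicitly.
    g_wall : float
        Rigidity of the harmonic wall that closes the kink plateau beyond
        ``theta_cut``.  Defaults to the stack rigidity ``g``; a softer
        wall (for instance the kink's own angular scale ``b**2 * g``) can
        be set explicitly to let kinks bend further past ``theta_cut``.
        For b = 1.0 (a nick) theta_cut = pi and the wall never engages.
    """

    family: Family = Family.QUADRATIC
    g: float = 0.0
    alpha: float = 0.0
    h: float = 0.0
    b: float = 0.3
    theta_cut: float = field(default=None)  # type: ignore[assignment]
    g_wall: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.theta_cut is None:
            object.__setattr__(self, "theta_cut", theta_cut_from_b(self.b))
        if self.g_wall is None:
            object.__setattr__(self, "g_wall", self.g)
        if self.g_wall < 0:
            raise ValueError("wall rigidity g_wall must be non-negative")
        if self.g < 0:
            raise ValueError("rigidity g must be non-negative")
        if self.h < 0:
            raise ValueError("kink energy h must be non-negative")
        if not 0.0 < self.theta_cut <= math.pi + 1e-12:
            raise ValueError("theta_cut must lie in (0, pi]")
        if not isinstance(self.family, Family):
            object.__setattr__(self, "family", Family(self.family))

    @property
    def kinkable(self) -> bool:
        return self.family in (Family.KINKABLE, Family.NICK)

    # -- config serialisation -------------------------------------------------

    def to_config(self) -> dict:
        """Lossless plain-dict form (suitable for YAML/TOML blocks)."""
        return {
            "family": self.family.value,
            "g": float(self.g),
            "alpha": float(self.alpha),
            "h": float(self.h),
            "b": float(self.b),
            "theta_cut": float(self.theta_cut),
            "g_wall": float(self.g_wall),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "BendPotential":
        cfg = dict(cfg)
        fam = Family(cfg.pop("family"))
        return cls(family=fam, **cfg)


@dataclass(frozen=True)
class ChainSpec:
    """Discrete chain description.

    A chain of ``n_bp`` base pairs is modelled as ``n_bp`` segments of
    length ``l`` nm.  A linear chain has ``n_bp - 1`` joints; a circular
    one has ``n_bp`` joints (cyclic).  Each joint carries a
    :class:`BendPotential`; a designated ``nick_index`` joint may carry a
    distinct (nick) potential.
    """

    n_bp: int
    l: float = 0.34
    a: float = 48.0
    topology: str = "linear"
    joint_potential: BendPotential | None = None
    nick_potential: BendPotential | None = None
    nick_index: int | None = None

    def __post_init__(self):
        if self.n_bp < 2:
            raise ValueError("chain needs at least 2 base pairs")
        if self.l <= 0 or self.a <= 0:
            raise ValueError("segment and persistence lengths must be positive")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.nick_index is not None and not 0 <= self.nick_index < self.n_joints:
            raise ValueError("nick_index does not address a valid joint")
        if self.joint_potential is None:
            object.__setattr__(
                self, "joint_potential", calibrate_rigidity(Family.QUADRATIC, self.a, self.l)
            )

    @property
    def n_segments(self) -> int:
        return self.n_bp

    @property
    def n_joints(self) -> int:
        return self.n_bp if self.topology == "circular" else self.n_bp - 1

    @property
    def contour_length(self) -> float:
        return self.n_segments * self.l

    def potential_at(self, joint: int) -> BendPotential:
        if self.nick_index is not None and joint == self.nick_index:
            assert self.nick_potential is not None
            return self.nick_potential
        return self.joint_potential

    def joint_potentials(self) -> list[BendPotential]:
        return [self.potential_at(k) for k in range(self.n_joints)]

    def with_nick(self, nick_potential: BendPotential, nick_index: int = 0) -> "ChainSpec":
        return replace(self, nick_potential=nick_potential, nick_index=nick_index)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------


def stack_branch_energy(pot: BendPotential, theta):
    """Energy of the stacked (non-kink) branch at bend angle theta."""
    theta = np.asarray(theta, dtype=float)
    if pot.family is Family.LINEAR:
        return pot.alpha * theta
    return 0.5 * pot.g * theta**2


def kink_branch_energy(pot: BendPotential, theta):
    """Energy of the kink branch: plateau at h up to theta_cut, harmonic wall beyond."""
    theta = np.asarray(theta, dtype=float)
    excess = np.clip(theta - pot.theta_cut, 0.0, None)
    return pot.h + 0.5 * pot.g_wall * excess**2


def bend_energy(pot: BendPotential, theta):
    """Joint bending energy in kT at bend angle ``theta`` (radians).

    For kinkable families the energy is the minimum of the stacked and
    kink branches.  Raises for theta outside [0, pi].
    """
    arr = np.asarray(theta, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > math.pi + 1e-12):
        raise ValueError("bend angle must lie in [0, pi]")
    arr = np.clip(arr, 0.0, math.pi)
    e_stack = stack_branch_energy(pot, arr)
    if not pot.kinkable:
        return e_stack if arr.shape else float(e_stack)
    e = np.minimum(e_stack, kink_branch_energy(pot, arr))
    return e if arr.shape else float(e)


def is_kinked(pot: BendPotential, theta):
    """True where the kink branch lies strictly below the stacked branch."""
    arr = np.asarray(theta, dtype=float)
    if not pot.kinkable:
        out = np.zeros(arr.shape, dtype=bool)
        return out if arr.shape else False
    out = kink_branch_energy(pot, arr) < stack_branch_energy(pot, arr)
    return out if arr.shape else bool(out)


def theta_crossover(pot: BendPotential) -> float:
    """Bend angle where the kink branch first undercuts the stacked branch.

    For the harmonic stack this is ``sqrt(2 h / g)`` (capped at pi); a
    joint is classified as kinked for theta beyond the crossover.
    """
    if not pot.kinkable:
        return math.inf
    if pot.h == 0.0:
        return 0.0
    if pot.g == 0.0:
        return math.inf
    cross = math.sqrt(2.0 * pot.h / pot.g)
    if cross > pot.theta_cut:
        # plateau never undercuts the stack; find where the wall branch does:
        # h + (gw/2)(t - tc)^2 = (g/2) t^2
        gw, tc, g, h = pot.g_wall, pot.theta_cut, pot.g, pot.h
        aa = 0.5 * (g - gw)
        bb = gw * tc
        cc = -(h + 0.5 * gw * tc * tc)
        if abs(aa) < 1e-12:
            cross = -cc / bb if bb > 0 else math.inf
        else:
            disc = bb * bb - 4.0 * aa * cc
            if disc < 0:
                return math.inf
            cross = (-bb + math.sqrt(disc)) / (2.0 * aa)
    return min(cross, math.pi)


# ---------------------------------------------------------------------------
# one-joint thermodynamics
# ---------------------------------------------------------------------------


def _quad(f, lo: float, hi: float) -> float:
    if hi <= lo:
        return 0.0
    val, _ = integrate.quad(f, lo, hi, limit=200)
    return val


def joint_partition_function(pot: BendPotential, branch: str = "all") -> float:
    """One-joint partition function Z = int_0^pi exp(-E) sin(theta) dtheta.

    ``branch`` restricts the integral to the region where the requested
    branch ("kink" or "stack") attains the minimum in :func:`bend_energy`;
    "all" integrates the full Boltzmann weight of the minimum branch.
    """
    if branch not in ("all", "kink", "stack"):
        raise ValueError(f"unknown branch {branch!r}")
    cross = theta_crossover(pot) if pot.kinkable else math.pi

    def w_stack(t):
        return math.exp(-float(stack_branch_energy(pot, t))) * math.sin(t)

    def w_kink(t):
        return math.exp(-float(kink_branch_energy(pot, t))) * math.sin(t)

    z_stack = _quad(w_stack, 0.0, min(cross, math.pi))
    z_kink = 0.0
    if pot.kinkable and cross < math.pi:
        z_kink = _quad(w_kink, cross, pot.theta_cut) + _quad(
            w_kink, max(cross, pot.theta_cut), math.pi
        )
    if branch == "stack":
        return z_stack
    if branch == "kink":
        return z_kink
    return z_stack + z_kink


def mean_cos_theta(pot: BendPotential) -> float:
    """<cos theta> under p(theta) ~ sin(theta) exp(-E(theta))."""

    def w(t):
        return math.exp(-float(bend_energy(pot, t))) * math.sin(t)

    def wc(t):
        return w(t) * math.cos(t)

    z = _quad(w, 0.0, math.pi)
    if not math.isfinite(z) or z <= 0.0:
        raise FloatingPointError("joint partition function is not finite and positive")
    return _quad(wc, 0.0, math.pi) / z


def persistence_length(pot: BendPotential, l: float) -> float:
    """Persistence length a = l / (1 - <cos theta>) of a chain of such joints."""
    c = mean_cos_theta(pot)
    if c >= 1.0:
        raise FloatingPointError("<cos theta> >= 1; persistence length diverges")
    return l / (1.0 - c)


def calibrate_rigidity(
    family: Family | str,
    a: float,
    l: float = 0.34,
    h: float | None = None,
    b: float = 0.3,
) -> BendPotential:
    """Set the rigidity of ``family`` so the chain persistence length equals ``a``.

    Solves ``<cos theta> = 1 - l/a`` by root-finding on the rigidity
    parameter (g for quadratic/kinkable/nick, alpha for linear).  In the
    stiff limit of the quadratic family this reduces to g ~ a/l.  For
    kinkable families the kink branch (``h``, ``b``) is part of the
    potential being calibrated, although for h >= 8 its weight is far too
    small to shift the persistence length noticeably.
    """
    family = Family(family)
    if a < l:
        raise ValueError("persistence length below the segment length is infeasible")
    target = 1.0 - l / a

    def build(x: float) -> BendPotential:
        if family is Family.LINEAR:
            return BendPotential(family=family, alpha=x)
        kw = {}
        if family in (Family.KINKABLE, Family.NICK):
            kw = {"h": 8.0 if h is None else h, "b": b}
        return BendPotential(family=family, g=x, **kw)

    if target <= 0.0:
        return build(0.0)

    def objective(x: float) -> float:
        return mean_cos_theta(build(x)) - target

    # bracket: rigidity ~ a/l in the stiff limit
    hi = max(4.0 * a / l, 8.0)
    while objective(hi) < 0.0:
        hi *= 4.0
        if hi > 1e9:
            raise FloatingPointError(
                "rigidity calibration is infeasible: the kink branch caps "
                "<cos theta> below the target; calibrate the stack "
                "harmonically (quadratic family) and attach the kink branch"
            )
    x = optimize.brentq(objective, 0.0, hi, xtol=1e-12, rtol=1e-10)
    pot = build(x)
    # contract: relative tolerance 1e-6 on the realised persistence length
    assert abs(persistence_length(pot, l) - a) <= 1e-6 * a
    return pot


def kink_statistics(pot: BendPotential) -> dict:
    """Unstressed one-joint kink thermodynamics.

    Returns the kink-branch occupation probability and the kink formation
    free energy dF = -ln(Z_kink / Z_stack), in kT and kcal/mol (25 C).
    """
    z_kink = joint_partition_function(pot, "kink")
    z_stack = joint_partition_function(pot, "stack")
    p = z_kink / (z_kink + z_stack)
    df = -math.log(z_kink / z_stack) if z_kink > 0 else math.inf
    return {
        "p_kink": p,
        "delta_f_kt": df,
        "delta_f_kcal_mol": df * KT_KCAL_PER_MOL,
    }


def potentials_for_spec(
    spec: ChainSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-joint parameter arrays (family, g, h, theta_cut, g_wall) for kernels.

    Family codes: 0 quadratic, 1 linear (g slot holds alpha), 2 kinkable/nick.
    """
    n = spec.n_joints
    fam = np.zeros(n, dtype=np.int64)
    g = np.zeros(n)
    hh = np.zeros(n)
    tc = np.full(n, math.pi)
    gw = np.zeros(n)
    for k in range(n):
        p = spec.potential_at(k)
        if p.family is Family.LINEAR:
            fam[k], g[k] = 1, p.alpha
        elif p.kinkable:
            fam[k], g[k], hh[k], tc[k], gw[k] = 2, p.g, p.h, p.theta_cut, p.g_wall
        else:
            fam[k], g[k] = 0, p.g
    return fam, g, hh, tc, gw
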