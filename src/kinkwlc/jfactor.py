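"""Cyclization j-factors of linear chains and the end-tangent distribution.

The j-factor is the effective equilibrium molar concentration of one end of
a fragment in the reaction volume of the other, optionally conditioned on
axial alignment of the two terminal tangents.  It is estimated here by the
half-chain convolution method: the two halves of the chain, conditioned on
the direction of the middle segment, are statistically independent, so the
density of end-to-end juxtaposition is the convolution of two half-chain
end densities — sampling N half-chains gives N^2 effective closure trials.

Concretely, with the middle segment along +z, the end-to-end vector is
``R = l z_hat + x_f + x_b`` where ``x_f`` (forward half) and ``x_b``
(backward half, sampled in reversed order, which leaves the statistics
unchanged) are independent and azimuthally symmetric.  Their (rho, z)
densities are histogrammed and convolved analytically over the free
azimuth to give the probability of landing in a capture shell of radius
r0; shrinking shells extrapolate to the contact density.  The axial
condition is evaluated on explicitly matched sample pairs found by spatial
hashing: pairs whose ends juxtapose are draws from the contact-conditioned
ensemble, and the fraction with end tangents within a cap angle gamma,
normalised by the uniform-cap measure (1 - cos gamma)/2, converges to the
alignment density factor as gamma -> 0.

A number density of 1 molecule/nm^3 equals 1e24/N_A ~ 1.6606 mol/L.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .potentials import BendPotential, ChainSpec
from .sampling import linear_end_states

__all__ = [
    "MOLAR_PER_NM3",
    "EndCondition",
    "JFactorResult",
    "ThetaDistribution",
    "theta_distribution",
    "jfactor_mc",
    "jfactor_sticky",
    "jfactor_sy",
]

#: mol/L corresponding to a number density of one molecule per nm^3.
MOLAR_PER_NM3 = 1.0e24 / 6.02214076e23


@dataclass(frozen=True)
class EndCondition:
    """End-capture contract for a j-factor estimate.

    ``axial`` is "free" (any mutual orientation, as for long sticky ends)
    or "aligned" (terminal tangents within ``gamma`` radians, the
    short-sticky-end / ring-closure convention, normalised so that
    uncorrelated tangents give a factor of 1).  ``extrapolate`` shrinks
    the capture radius (and cap angle) towards zero by Richardson-style
    polynomial fits; otherwise the finite-r0 shell value is reported.
    """

    r0: float = 5.0
    axial: str = "free"
    gamma: float = math.radians(30.0)
    extrapolate: bool = True

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("capture radius must be positive")
        if not 0.0 < self.gamma <= math.pi:
            raise ValueError("gamma must lie in (0, pi]")
        if self.axial not in ("free", "aligned"):
            raise ValueError(f"unknown axial condition {self.axial!r}")


@dataclass
class JFactorResult:
    """A j-factor estimate in mol/L with its Monte Carlo standard error."""

    j: float
    stderr: float
    end_condition: EndCondition
    n_samples: int
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __str__(self):
        return (
            f"j = {self.j:.3e} +/- {self.stderr:.3e} mol/L "
            f"({self.method}, n={self.n_samples:.0e})"
        )


@dataclass
class ThetaDistribution:
    """Histogram of the angle between the first and last segment tangents."""

    edges: np.ndarray
    mass: np.ndarray
    n_joints: int
    tag: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def density(self) -> np.ndarray:
        return self.mass / np.diff(self.edges)

    def total_variation(self, other: "ThetaDistribution") -> float:
        if not np.allclose(self.edges, other.edges):
            raise ValueError("histograms must share bin edges")
        return 0.5 * float(np.abs(self.mass - other.mass).sum())


def theta_distribution(
    spec: ChainSpec, n_samples: int = 200_000, rng_seed: int = 0, bins: int = 90
) -> ThetaDistribution:
    """End-tangent angle distribution rho(Theta) of a linear chain.

    Theta is the angle between the tangents of the first and last segments;
    the sin(Theta) measure puts the maximum at nonzero Theta for any
    finite rigidity.
    """
    if spec.topology != "linear":
        raise ValueError("theta_distribution requires linear topology")
    rng = np.random.default_rng(rng_seed)
    edges = np.linspace(0.0, math.pi, bins + 1)
    counts = np.zeros(bins)
    for _, w in linear_end_states(spec.joint_potentials(), n_samples, rng):
        theta = np.arccos(np.clip(w[:, 2], -1.0, 1.0))
        counts += np.histogram(theta, bins=edges)[0]
    return ThetaDistribution(edges, counts / counts.sum(), spec.n_joints, tag=str(spec.n_bp))


# ---------------------------------------------------------------------------
# Shimada-Yamakawa closed form
# ---------------------------------------------------------------------------


def jfactor_sy(L: float, a: float) -> float:
    """Shimada-Yamakawa ring-closure j-factor of a wormlike chain, in mol/L.

    Closed-form fit for the end-contact probability density (ends
    juxtaposed, orientations free):

        G(L) = 28.01 N^-5 exp(0.492 N - 7.027 / N)   per (2 a)^3,

    with N = L / (2 a) the contour length in Kuhn lengths, valid for
    contour lengths of roughly 0.1 to 10 persistence lengths.  The
    exponential constant is the teardrop ground-state bending energy
    14.055 kT a/L; at large N the expression approaches the
    Gaussian-chain contact density (3/(4 pi a L))^1.5.  Conditioning on
    axial alignment of the end tangents costs a further factor
    ~exp(-5.68 a/L) (circle minus teardrop energy), which this closed
    form deliberately excludes; compare it with free-end Monte Carlo
    estimates.

    Parameters are the contour length ``L`` and persistence length ``a``,
    both in nm.
    """
    t = L / a
    if not 0.1 <= t <= 10.0:
        raise ValueError("Shimada-Yamakawa form is valid for 0.1 <= L/a <= 10")
    n_kuhn = 0.5 * t
    g_per_kuhn3 = 28.01 * n_kuhn**-5 * math.exp(0.492 * n_kuhn - 7.027 / n_kuhn)
    return MOLAR_PER_NM3 * g_per_kuhn3 / (2.0 * a) ** 3


# ---------------------------------------------------------------------------
# half-chain convolution machinery
# ---------------------------------------------------------------------------


def _split_potentials(spec: ChainSpec) -> tuple[list[BendPotential], list[BendPotential]]:
    """Joint potentials of the backward and forward halves, in growth order.

    The chain's joints 1..n-1 (joint k between segments k-1 and k) are
    split at the middle segment s: the backward half grows joints
    s, s-1, ..., 1 and the forward half joints s+1, ..., n-1.
    """
    pots = spec.joint_potentials()  # joints, in chain order
    s = (len(pots) + 1) // 2
    back = [pots[k] for k in range(s - 1, -1, -1)]
    fwd = [pots[k] for k in range(s, len(pots))]
    return back, fwd


class _HalfEnsemble:
    """Streamed half-chain end states: (rho, z) histograms plus stored samples.

    Both halves of a pair must share ``lim`` so their z-grids coincide and
    the azimuthal convolution reduces to lattice correlations.
    """

    N_RHO = 200
    N_Z = 400

    def __init__(self, lim: float, l: float, n_blocks: int = 10, store_max: int = 4_000_000):
        self.l = l
        self.lim = lim
        self.z_edges = np.linspace(-self.lim, self.lim, self.N_Z + 1)
        self.r_edges = np.linspace(0.0, self.lim, self.N_RHO + 1)
        self.dz = self.z_edges[1] - self.z_edges[0]
        self.dr = self.r_edges[1] - self.r_edges[0]
        self.hist = np.zeros((n_blocks, self.N_RHO, self.N_Z))  # (block, rho, z)
        self.n = 0
        self.n_blocks = n_blocks
        self._block = 0
        self.store_max = store_max
        self._x_parts: list[np.ndarray] = []
        self._w_parts: list[np.ndarray] = []
        self.n_seen_for_store = 0

    def add(self, x: np.ndarray, w: np.ndarray, rng: np.random.Generator):
        rho = np.hypot(x[:, 0], x[:, 1])
        # spread every batch over all blocks so block scatter estimates the
        # Monte Carlo error even for single-batch runs
        bounds = np.linspace(0, len(x), self.n_blocks + 1).astype(int)
        for i in range(self.n_blocks):
            sl = slice(bounds[i], bounds[i + 1])
            hh, _, _ = np.histogram2d(
                rho[sl], x[sl, 2], bins=(self.r_edges, self.z_edges)
            )
            self.hist[(self._block + i) % self.n_blocks] += hh
        self._block = (self._block + 1) % self.n_blocks
        self.n += len(x)
        # reservoir-style capped storage for pair matching
        self.n_seen_for_store += len(x)
        stored = sum(len(p) for p in self._x_parts)
        if stored < self.store_max:
            room = self.store_max - stored
            if len(x) <= room:
                sel = slice(None)
            else:
                sel = rng.choice(len(x), size=room, replace=False)
            self._x_parts.append(x[sel].astype(np.float32))
            self._w_parts.append(w[sel].astype(np.float32))

    def stored(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Stored (x, w) and the fraction of all samples they represent."""
        x = np.concatenate(self._x_parts) if self._x_parts else np.empty((0, 3), np.float32)
        w = np.concatenate(self._w_parts) if self._w_parts else np.empty((0, 3), np.float32)
        frac = len(x) / self.n if self.n else 0.0
        return x, w, frac

    def marginal(self, blocks=None) -> np.ndarray:
        h = self.hist if blocks is None else self.hist[blocks]
        return h.sum(axis=0)


def _shell_probability(
    F: _HalfEnsemble, G: _HalfEnsemble, l: float, r0: np.ndarray
) -> np.ndarray:
    """P(|l z_hat + x_f + x_b| < r0) from the two (rho, z) histograms."""
    return _shell_probability_from(F.marginal() / F.n, G.marginal() / G.n, F, G, l, r0)


def _shell_probability_from(Fm, Gm, F, G, l, r0) -> np.ndarray:
    """Azimuthal shell convolution of two (rho, z) end-density histograms.

    For bins at (rho_f, z_f) and (rho_b, z_b) the squared end distance is
    zeta^2 + rho_f^2 + rho_b^2 + 2 rho_f rho_b cos(dphi) with
    zeta = l + z_f + z_b and dphi uniform; the azimuth fraction inside the
    shell is 1 - arccos(q)/pi with q = (r0^2 - ...)/(2 rho_f rho_b).
    Because both grids share the z lattice, zeta takes lattice values
    indexed by s = i_zf + i_zb, so the sum factorises into per-s
    correlation matrices C_s[rho_f, rho_b] contracted with closed-form
    azimuth kernels K_s.
    """
    r0 = np.atleast_1d(np.asarray(r0, dtype=float))
    rmax = float(r0.max())
    rho_f = 0.5 * (F.r_edges[:-1] + F.r_edges[1:])
    rho_b = 0.5 * (G.r_edges[:-1] + G.r_edges[1:])
    z_f = 0.5 * (F.z_edges[:-1] + F.z_edges[1:])
    nz = len(z_f)
    dz = F.dz
    zlo = z_f[0]

    out = np.zeros(len(r0))
    rf = rho_f[:, None]
    rb = rho_b[None, :]
    base = rf**2 + rb**2
    denom = 2.0 * rf * rb
    for s in range(2 * nz - 1):
        zeta = l + 2.0 * zlo + s * dz
        if abs(zeta) > rmax + dz:
            continue
        i0 = max(0, s - nz + 1)
        i1 = min(nz - 1, s)
        idx_f = np.arange(i0, i1 + 1)
        Fsub = Fm[:, idx_f]
        Gsub = Gm[:, s - idx_f]
        if not (Fsub.any() and Gsub.any()):
            continue
        C = Fsub @ Gsub.T  # (rho_f, rho_b)
        c2 = zeta * zeta + base
        for ir, rr in enumerate(r0):
            q = (rr * rr - c2) / denom
            frac = 1.0 - np.arccos(np.clip(q, -1.0, 1.0)) / math.pi
            out[ir] += float((C * frac).sum())
    return out


def _match_pairs(
    xf: np.ndarray,
    wf: np.ndarray,
    xb: np.ndarray,
    wb: np.ndarray,
    l: float,
    r0: float,
    max_pairs: int = 5_000_000,
):
    """End-tangent cosines of all stored sample pairs juxtaposed within r0.

    Pairs are found by hashing backward ends on a cubic grid of cell size
    r0 and probing the 27 cells around each forward end's required partner
    position -l*z_hat - x_f.
    """
    if len(xf) == 0 or len(xb) == 0:
        return np.empty(0, dtype=np.float32)
    cell = np.float32(r0)
    lim = max(np.abs(xb).max(), np.abs(xf).max()) + 2 * r0
    ncell = int(2 * lim / cell) + 3
    org = np.float32(-lim - cell)

    def cid(p):
        i = ((p - org) / cell).astype(np.int64)
        return (i[:, 0] * ncell + i[:, 1]) * ncell + i[:, 2]

    ids_b = cid(xb)
    order = np.argsort(ids_b, kind="stable")
    ids_sorted = ids_b[order]

    target = -xf.copy()
    target[:, 2] -= np.float32(l)
    base = cid(target)
    cos_parts = []
    n_pairs = 0
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                probe = base + (dx * ncell + dy) * ncell + dz
                lo = np.searchsorted(ids_sorted, probe, side="left")
                hi = np.searchsorted(ids_sorted, probe, side="right")
                cnt = hi - lo
                sel = np.nonzero(cnt)[0]
                if len(sel) == 0:
                    continue
                reps = cnt[sel]
                fi = np.repeat(sel, reps)
                bi = order[
                    np.concatenate([np.arange(a, b) for a, b in zip(lo[sel], hi[sel])])
                ]
                d = xf[fi] + xb[bi]
                d[:, 2] += np.float32(l)
                ok = np.einsum("ij,ij->i", d, d) < r0 * r0
                if ok.any():
                    cos_parts.append(np.einsum("ij,ij->i", wf[fi[ok]], wb[bi[ok]]))
                    n_pairs += int(ok.sum())
                if n_pairs > max_pairs:
                    return np.concatenate(cos_parts)
    return (
        np.concatenate(cos_parts) if cos_parts else np.empty(0, dtype=np.float32)
    )


def _axial_factor(cos_e: np.ndarray, gamma: float, extrapolate: bool) -> tuple[float, float]:
    """Alignment density factor and its standard error from contact pairs.

    The factor is P(Theta_e < gamma | contact) / [(1 - cos gamma)/2],
    i.e. the enhancement of the end-tangent density near Theta_e = 0 over
    an isotropic ensemble.  With ``extrapolate``, the cumulative aligned
    fraction p(cap) over shrinking caps (which must vanish with the cap
    measure c = (1 - cos gamma)/2) is fitted as p = a c + b c^2 and the
    gamma -> 0 factor is the slope a at the origin.
    """
    n = len(cos_e)
    if n == 0:
        return math.nan, math.inf

    def p_at(gam):
        p = float((cos_e > math.cos(gam)).mean())
        if p == 0.0:
            # no aligned pair observed: report the rule-of-three style
            # upper bound so downstream ratios stay conservative
            p = 1.0 / (n + 1)
        se = math.sqrt(max(p * (1 - p), 1.0 / n) / n)
        return p, se

    cap1 = 0.5 * (1.0 - math.cos(gamma))
    p1, s1 = p_at(gamma)
    if not extrapolate or n < 2000 or p1 * n < 50:
        return p1 / cap1, s1 / cap1
    gams = np.array([0.6 * gamma, 0.8 * gamma, gamma, 1.3 * gamma])
    caps = 0.5 * (1.0 - np.cos(gams))
    ps = np.array([p_at(g)[0] for g in gams])
    X = np.column_stack([caps, caps**2])
    a, b = np.linalg.lstsq(X, ps, rcond=None)[0]
    if a <= 0.0:
        # density keeps falling towards Theta = 0; report the smallest
        # resolvable cap ratio (an upper bound on the limit)
        g_min = gams[0]
        p_min, s_min = p_at(g_min)
        c_min = 0.5 * (1.0 - math.cos(g_min))
        return p_min / c_min, s_min / c_min
    return float(a), s1 / cap1


def jfactor_mc(
    spec: ChainSpec,
    end: EndCondition,
    n_samples: int = 1_000_000,
    rng_seed: int = 0,
    batch: int = 500_000,
    store_max: int = 4_000_000,
) -> JFactorResult:
    """Monte Carlo j-factor of a linear chain by half-chain convolution.

    ``n_samples`` half-chains are drawn per side.  The contact density is
    obtained from shrinking capture shells (Richardson extrapolation in
    the shell radius) unless ``end.extrapolate`` is false, in which case
    the plain shell concentration at ``end.r0`` is reported (the long
    sticky-end convention).  The axial alignment factor, if requested,
    comes from explicitly matched contact pairs.
    """
    if spec.topology != "linear":
        raise ValueError("jfactor_mc requires linear topology")
    rng = np.random.default_rng(rng_seed)
    back, fwd = _split_potentials(spec)
    l = spec.l
    lim = (max(len(back), len(fwd) + 1)) * l + l  # shared grid for both halves

    ens = {}
    for tag, pots in (("b", back), ("f", fwd)):
        e = _HalfEnsemble(lim, l, store_max=store_max)
        for x, w in linear_end_states(pots, n_samples, rng, batch=batch):
            e.add(x * l, w, rng)
        ens[tag] = e
    F, G = ens["f"], ens["b"]

    # --- capture shells
    cl = spec.contour_length
    if end.extrapolate:
        r_base = min(0.08 * cl, 2.0, end.r0)
        shells = np.array([r_base, 1.35 * r_base, 1.7 * r_base])
    else:
        shells = np.array([end.r0])
    P = _shell_probability(F, G, l, shells)
    vol = 4.0 / 3.0 * math.pi * shells**3
    W = P / vol  # density per nm^3

    # block scatter -> standard error (diagonal blocks are independent)
    nb = F.n_blocks
    west = []
    for i in range(nb):
        Fi = F.hist[i] / (F.n / nb)
        Gi = G.hist[i] / (G.n / nb)
        Pi = _shell_probability_from(Fi, Gi, F, G, l, shells[-1:])
        west.append(Pi[0] / vol[-1])
    west = np.asarray(west)
    w_se = west.std(ddof=1) / math.sqrt(nb) if west.std() > 0 else 0.0

    if end.extrapolate:
        coef = np.polyfit(shells**2, W, 1)
        w0 = float(np.polyval(coef, 0.0))
        if w0 <= 0:
            w0 = float(W[0])
    else:
        w0 = float(W[0])

    j = MOLAR_PER_NM3 * w0
    j_se = MOLAR_PER_NM3 * w_se
    diags = {
        "shells_nm": shells.tolist(),
        "shell_density_nm3": W.tolist(),
        "contact_density_nm3": w0,
    }

    # --- axial alignment factor from matched pairs
    if end.axial == "aligned":
        xf, wf, frac_f = F.stored()
        xb, wb, frac_b = G.stored()
        r_pair = shells[-1]
        r_cap = 0.3 * cl
        cos_e = _match_pairs(xf, wf, xb, wb, l, r_pair)
        tries = 0
        while len(cos_e) < 200 and tries < 3 and r_pair < r_cap:
            r_pair = min(1.6 * r_pair, r_cap)
            cos_e = _match_pairs(xf, wf, xb, wb, l, r_pair)
            tries += 1
        fac, fac_se = _axial_factor(cos_e, end.gamma, end.extrapolate)
        diags["n_contact_pairs"] = int(len(cos_e))
        diags["pair_radius_nm"] = float(r_pair)
        diags["axial_factor"] = fac
        if not math.isfinite(fac):
            warnings.warn(
                "no contact pairs found for the axial condition; "
                "j-factor is reported with infinite standard error",
                stacklevel=2,
            )
            return JFactorResult(0.0, math.inf, end, n_samples, "half-chain", diags)
        rel = math.sqrt((j_se / j) ** 2 + (fac_se / fac) ** 2) if j > 0 else math.inf
        j *= fac
        j_se = j * rel
    if j <= 0 or (j_se / j if j > 0 else math.inf) > 0.5:
        warnings.warn(
            "few juxtaposition events in the capture shell; the j-factor "
            "standard error is large",
            stacklevel=2,
        )
    return JFactorResult(j, j_se, end, n_samples, "half-chain", diags)


def jfactor_sticky(
    spec: ChainSpec,
    r0: float = 5.0,
    n_samples: int = 1_000_000,
    rng_seed: int = 0,
    **kw,
) -> JFactorResult:
    """Orientation-free j-factor with a finite capture radius (long sticky ends).

    Long single-stranded ends (>= 8 nt) join at any mutual axial and
    torsional orientation and can bridge a notable gap r0 between the
    duplex ends, so the j-factor is simply the equilibrium concentration
    of one end within the capture sphere of the other.
    """
    end = EndCondition(r0=r0, axial="free", extrapolate=False)
    return jfactor_mc(spec, end, n_samples=n_samples, rng_seed=rng_seed, **kw)
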