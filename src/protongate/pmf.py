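"""Umbrella-sampling free-energy reconstruction and pKa conversion.

The proton-transport coordinate is the signed projection of the excess
charge center (CEC) onto the transport direction, measured from the
nearer carboxylate oxygen of the donor glutamate. Harmonic umbrella
windows along that coordinate are unbiased with the standard
self-consistent WHAM iteration into a 1-D potential of mean force W(x)
(kcal/mol, anchored to min 0), with per-bin uncertainties from a
contiguous block analysis (5 blocks by default).

A PMF with a flat bulk plateau converts to a site pKa through the 1-D
binding-constant expression

    K = C° · π·r_cyl² · ∫_site exp(−[W(x) − W_bulk]/kT) dx,
    pKa = log10 K,

with C° the standard concentration (1/1661 Å⁻³) and r_cyl the radius of
the cylinder sampled orthogonally to the transport axis. The additive
PMF offset cancels via the bulk subtraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "UmbrellaWindow",
    "PMFCurve",
    "PKaSettings",
    "CECGeometry",
    "project_cec",
    "WhamSolver",
    "wham",
    "block_pmf_error",
    "pka_from_pmf",
]


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias center/strength plus CV samples (Å)."""

    center: float
    kappa: float
    samples: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"force constant must be > 0 (got {self.kappa})")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError(f"window at {self.center} Å has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"window at {self.center} Å has non-finite samples")


@dataclass
class PMFCurve:
    """W(x) on a grid of bin centers, anchored to min 0 over sampled bins."""

    x: np.ndarray
    W: np.ndarray
    kT: float
    block_sd: np.ndarray | None = None
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("PMF grid must be strictly ascending")

    def shifted(self, offset: float) -> "PMFCurve":
        return PMFCurve(
            x=self.x.copy(),
            W=self.W + offset,
            kT=self.kT,
            block_sd=None if self.block_sd is None else self.block_sd.copy(),
            counts=None if self.counts is None else self.counts.copy(),
        )


@dataclass
class PKaSettings:
    """Constants of the PMF → pKa conversion.

    kT in kcal/mol (0.616 at 310 K); C° the standard concentration in
    1/Å³; r_cyl the orthogonal sampling-cylinder radius in Å (its value
    is a stated convention, roughly ±0.3 pKa units per factor of two);
    site and bulk ranges along the CV in Å, disjoint.
    """

    kT: float = 0.616
    c_standard: float = 1.0 / 1661.0
    r_cyl: float = 2.5
    site_range: tuple = (0.0, 4.0)
    bulk_range: tuple = (13.0, 15.0)

    def __post_init__(self) -> None:
        for name in ("kT", "c_standard", "r_cyl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (got {getattr(self, name)})")
        (s0, s1), (b0, b1) = self.site_range, self.bulk_range
        if not (s0 < s1 and b0 < b1):
            raise ValueError("site and bulk ranges must be non-empty intervals")
        if max(s0, b0) < min(s1, b1):
            raise ValueError(
                f"site range {self.site_range} and bulk range {self.bulk_range} overlap"
            )


@dataclass
class CECGeometry:
    """Donor-oxygen pair, CEC position and transport direction (Å)."""

    oxygen_a: np.ndarray
    oxygen_b: np.ndarray
    cec: np.ndarray
    e_pt: np.ndarray

    def __post_init__(self) -> None:
        self.oxygen_a = np.asarray(self.oxygen_a, dtype=float)
        self.oxygen_b = np.asarray(self.oxygen_b, dtype=float)
        self.cec = np.asarray(self.cec, dtype=float)
        self.e_pt = np.asarray(self.e_pt, dtype=float)


def project_cec(geometry: CECGeometry) -> float:
    """Signed CV value: (CEC − closer oxygen) · e_PT.

    The unit vector is checked, not silently normalized.
    """
    norm = float(np.linalg.norm(geometry.e_pt))
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"e_PT must be a unit vector (|e_PT| = {norm:.12f})")
    da = np.linalg.norm(geometry.cec - geometry.oxygen_a)
    db = np.linalg.norm(geometry.cec - geometry.oxygen_b)
    oxygen = geometry.oxygen_a if da <= db else geometry.oxygen_b
    return float(np.dot(geometry.cec - oxygen, geometry.e_pt))


class WhamSolver(BaseEstimator):
    """Self-consistent WHAM for 1-D harmonic umbrella windows.

    Iterates the unbiased bin probabilities and per-window free energies
    f_i until max|Δf_i| < ``tol`` (kcal/mol) or ``max_iter``; the PMF is
    W(x) = −kT·ln ρ(x) anchored to min 0 over sampled bins, with NaN in
    empty bins. Adjacent windows sharing < 5% histogram overlap trigger a
    warning (poor overlap is the classic WHAM failure mode).

    Attributes (after ``fit``): ``pmf_`` (:class:`PMFCurve`),
    ``f_`` (per-window free energies), ``n_iter_``, ``converged_``.
    """

    def __init__(
        self,
        kT: float = 0.616,
        bin_width: float = 0.1,
        tol: float = 1e-8,
        max_iter: int = 100_000,
        bin_edges: np.ndarray | None = None,
    ):
        self.kT = kT
        self.bin_width = bin_width
        self.tol = tol
        self.max_iter = max_iter
        self.bin_edges = bin_edges

    def fit(self, windows: Sequence[UmbrellaWindow], y=None):
        if len(windows) == 0:
            raise ValueError("WHAM requires at least one window")
        if self.kT <= 0:
            raise ValueError(f"kT must be > 0 (got {self.kT})")
        windows = sorted(windows, key=lambda w: w.center)

        if self.bin_edges is not None:
            edges = np.asarray(self.bin_edges, dtype=float)
        else:
            lo = min(w.samples.min() for w in windows)
            hi = max(w.samples.max() for w in windows)
            n_bins = max(1, int(np.ceil((hi - lo) / self.bin_width)))
            edges = np.linspace(lo, hi, n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])

        counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows]).astype(float)
        n_samples = counts.sum(axis=1)
        total = counts.sum(axis=0)

        self._warn_poor_overlap(windows, counts)

        # bias Boltzmann factors c_il = exp(-u_il / kT)
        centers_w = np.array([w.center for w in windows])[:, None]
        kappas = np.array([w.kappa for w in windows])[:, None]
        bias = 0.5 * kappas * (centers[None, :] - centers_w) ** 2
        c = np.exp(-bias / self.kT)

        f = np.zeros(len(windows))
        converged = False
        history = []
        for it in range(self.max_iter):
            g = np.exp(f / self.kT)  # g_i = e^{f_i/kT}
            denom = (n_samples[:, None] * g[:, None] * c).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                rho = np.where(denom > 0, total / denom, 0.0)
            z = c @ rho
            f_new = -self.kT * np.log(z)
            f_new -= f_new[0]
            delta = float(np.max(np.abs(f_new - f)))
            history.append(delta)
            f = f_new
            if delta < self.tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"WHAM did not converge in {self.max_iter} iterations; "
                f"last Δf values: {history[-5:]}"
            )

        with np.errstate(divide="ignore"):
            W = np.where(total > 0, -self.kT * np.log(np.where(total > 0, rho, 1.0)), np.nan)
        W = W - np.nanmin(W)
        self.pmf_ = PMFCurve(x=centers, W=W, kT=self.kT, counts=total)
        self.f_ = f
        self.n_iter_ = it + 1
        self.converged_ = True
        self.bin_edges_ = edges
        return self

    @staticmethod
    def _warn_poor_overlap(windows, counts) -> None:
        for i in range(len(windows) - 1):
            hi, hj = counts[i], counts[i + 1]
            si, sj = hi.sum(), hj.sum()
            if si == 0 or sj == 0:
                continue
            overlap = np.minimum(hi / si, hj / sj).sum()
            if overlap < 0.05:
                warnings.warn(
                    f"windows at {windows[i].center} and {windows[i + 1].center} Å share "
                    f"{overlap * 100:.1f}% histogram overlap (< 5%); the PMF may be unreliable",
                    stacklevel=3,
                )


def wham(
    windows: Sequence[UmbrellaWindow],
    kT: float = 0.616,
    bin_width: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    bin_edges: np.ndarray | None = None,
) -> PMFCurve:
    """Thin functional wrapper over :class:`WhamSolver`."""
    return (
        WhamSolver(kT=kT, bin_width=bin_width, tol=tol, max_iter=max_iter, bin_edges=bin_edges)
        .fit(windows)
        .pmf_
    )


def block_pmf_error(
    windows: Sequence[UmbrellaWindow],
    n_blocks: int = 5,
    kT: float = 0.616,
    bin_width: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> PMFCurve:
    """WHAM with per-bin SD from a contiguous block analysis.

    Each window's sample sequence is cut into ``n_blocks`` contiguous
    blocks; WHAM runs per block on a shared grid; each block PMF is
    re-anchored to min 0 and the per-bin SD across blocks is attached to
    the full-data PMF.
    """
    if n_blocks < 2:
        raise ValueError(f"n_blocks must be ≥ 2 (got {n_blocks})")
    for w in windows:
        if len(w.samples) < n_blocks:
            raise ValueError(
                f"window at {w.center} Å has {len(w.samples)} samples, "
                f"fewer than n_blocks={n_blocks}"
            )
    solver = WhamSolver(kT=kT, bin_width=bin_width, tol=tol, max_iter=max_iter).fit(windows)
    full = solver.pmf_
    edges = solver.bin_edges_

    block_pmfs = []
    for b in range(n_blocks):
        sub = [
            UmbrellaWindow(
                center=w.center,
                kappa=w.kappa,
                samples=np.array_split(w.samples, n_blocks)[b],
            )
            for w in windows
        ]
        pw = wham(sub, kT=kT, tol=tol, max_iter=max_iter, bin_edges=edges)
        block_pmfs.append(pw.W - np.nanmin(pw.W))
    stack = np.vstack(block_pmfs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        sd = np.nanstd(stack, axis=0, ddof=1)
    full.block_sd = sd
    return full


def pka_from_pmf(pmf: PMFCurve, settings: PKaSettings | None = None) -> float:
    """Convert a proton-transport PMF to the donor-site pKa.

    W_bulk is the mean PMF over the bulk reference range; the binding
    constant integrates exp(−ΔW/kT) over the site range (trapezoid rule)
    times the orthogonal cylinder cross-section and the standard
    concentration. Invariant to any additive PMF offset.
    """
    settings = settings or PKaSettings()
    x, W = pmf.x, pmf.W
    kT = settings.kT

    def range_mask(lo, hi):
        return (x >= lo) & (x <= hi)

    site = range_mask(*settings.site_range)
    bulk = range_mask(*settings.bulk_range)
    if not site.any():
        raise ValueError(f"site range {settings.site_range} covers no PMF bins")
    if not bulk.any():
        raise ValueError(f"bulk range {settings.bulk_range} covers no PMF bins")
    if np.any(~np.isfinite(W[site])):
        raise ValueError("site range contains undefined (unsampled) PMF bins")
    if np.any(~np.isfinite(W[bulk])):
        raise ValueError("bulk range contains undefined (unsampled) PMF bins")

    w_bulk = float(np.mean(W[bulk]))
    integrand = np.exp(-(W[site] - w_bulk) / kT)
    integral = float(np.trapezoid(integrand, x[site]))
    k_bind = settings.c_standard * np.pi * settings.r_cyl**2 * integral
    return float(np.log10(k_bind))
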