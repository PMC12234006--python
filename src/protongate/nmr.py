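"""NMR observables of alternating access and protonation.

Two analyses live here.

**ZZ-exchange rate extraction.** Slow two-site conformational exchange
(the two protomers swapping environments) produces, at mixing delay t,
two auto peaks I_AA, I_BB and two cross peaks I_AB, I_BA. For symmetric
exchange at rate k with shared longitudinal relaxation, the composite
ratio

    I_AB·I_BA / (I_AA·I_BB − I_AB·I_BA) = k²t²  (small kt)

cancels the initial intensities and the relaxation decay, so pooling
the ratio over residues and fitting k²t² yields the alternating-access
rate directly.

**Global pKa titration fitting.** In the NMR fast-exchange limit a
titrating site moves a resonance along the population-weighted average
shift; with shared pKa values across residues,

    δ(pH) = δ_end + Σ_j Δδ_j · 10^(pKa_j−pH) / (1 + 10^(pKa_j−pH)),

Hill coefficient fixed at 1. The global fit shares one or two pKa
values across all residue/nucleus curves while each curve keeps its own
endpoint and amplitudes; amplitudes are linear and are profiled out, so
the optimization runs over the pKa values alone before a final full
refinement for uncertainties.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "PeakQuartet",
    "ExchangeRateFitter",
    "zz_ratio",
    "fit_exchange_rate",
    "TitrationModel",
    "GlobalTitrationFitter",
    "titration_model_eval",
    "fit_titration_global",
    "model_select",
    "classify_pka_sensitivity",
    "SensitivityClass",
]


# ---------------------------------------------------------------------------
# ZZ-exchange
# ---------------------------------------------------------------------------

@dataclass
class PeakQuartet:
    """One residue's four ZZ-exchange peak intensities at one mixing delay."""

    residue: str
    t: float
    I_AA: float
    I_BB: float
    I_AB: float
    I_BA: float

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError(f"mixing delay must be > 0 (got {self.t})")


def zz_ratio(quartet) -> float:
    """Composite peak-intensity ratio I_AB·I_BA / (I_AA·I_BB − I_AB·I_BA).

    Scale-invariant (degree-0 homogeneous) and, under the exact symmetric
    two-site model, independent of relaxation. Raises when the denominator
    is non-positive — the signature of exchange too fast for the small-kt
    regime at this delay.
    """
    num = quartet.I_AB * quartet.I_BA
    den = quartet.I_AA * quartet.I_BB - num
    if den <= 0:
        raise ValueError(
            f"non-positive denominator for residue {quartet.residue} at "
            f"t={quartet.t}: exchange too fast for this delay"
        )
    return float(num / den)


def exact_zz_ratio(k: float, t) -> np.ndarray:
    """Closed-form ratio of the exact symmetric two-site model.

    With ε = e^(−2kt): ratio = (1−ε)² / (4ε). The k²t² fit model is its
    small-kt expansion.
    """
    eps = np.exp(-2.0 * k * np.asarray(t, dtype=float))
    return (1.0 - eps) ** 2 / (4.0 * eps)


class ExchangeRateFitter(BaseEstimator):
    """Least-squares fit of pooled ZZ-exchange ratios to k²t².

    Parameters
    ----------
    max_kt:
        Validity cap of the small-kt model: after an initial fit, points
        with fitted k·t > max_kt are excluded and the fit repeated once.
    pooling:
        ``composite`` pools every residue's points into one fit;
        ``per_residue`` fits each residue separately and averages.
    n_bootstrap:
        Residue-level bootstrap resamples for the uncertainty cross-check
        (run when ≥ 4 residues are available).

    Attributes (after ``fit``)
    --------------------------
    k_ : fitted exchange rate (1/s)
    sigma_k_ : rate uncertainty from the fit covariance (1/s)
    sigma_k_bootstrap_ : residue-bootstrap SD of k (1/s), or None
    k_per_residue_ : per-residue rates (per_residue pooling or diagnostics)
    excluded_ : list of (residue, t, reason) for dropped points
    """

    def __init__(
        self,
        max_kt: float = 0.5,
        pooling: str = "composite",
        n_bootstrap: int = 200,
        random_state: int = 0,
    ):
        self.max_kt = max_kt
        self.pooling = pooling
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    @staticmethod
    def _ratios(df: pd.DataFrame):
        rows, excluded = [], []
        for _, row in df.iterrows():
            q = PeakQuartet(
                residue=str(row["residue"]),
                t=float(row["t_s"]),
                I_AA=float(row["I_AA"]),
                I_BB=float(row["I_BB"]),
                I_AB=float(row["I_AB"]),
                I_BA=float(row["I_BA"]),
            )
            try:
                rows.append((q.residue, q.t, zz_ratio(q)))
            except ValueError as exc:
                excluded.append((q.residue, q.t, str(exc)))
        return rows, excluded

    @staticmethod
    def _fit_k(t: np.ndarray, r: np.ndarray):
        k0 = float(np.sqrt(max(np.sum(r * t**2), 1e-30) / np.sum(t**4)))
        popt, pcov = optimize.curve_fit(
            lambda tt, k: (k * tt) ** 2, t, r, p0=[k0], maxfev=10000
        )
        k = abs(float(popt[0]))
        sigma = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan
        return k, sigma

    def fit(self, quartets: pd.DataFrame, y=None):
        if self.pooling not in ("composite", "per_residue"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        rows, excluded = self._ratios(quartets)
        if len(rows) < 3:
            raise ValueError(
                f"need ≥ 3 usable (residue, delay) points, got {len(rows)}; "
                f"exclusion log: {excluded}"
            )
        data = pd.DataFrame(rows, columns=["residue", "t", "ratio"])

        def fit_with_cap(sub: pd.DataFrame):
            t = sub["t"].to_numpy()
            r = sub["ratio"].to_numpy()
            k, sigma = self._fit_k(t, r)
            keep = k * t <= self.max_kt
            dropped = sub[~keep]
            if 0 < (~keep).sum() < len(sub):
                k, sigma = self._fit_k(t[keep], r[keep])
            return k, sigma, sub[keep], dropped

        if self.pooling == "composite":
            k, sigma, used, dropped = fit_with_cap(data)
        else:
            ks = []
            used_parts, dropped_parts = [], []
            for res, sub in data.groupby("residue", sort=False):
                kr, _, u, d = fit_with_cap(sub)
                ks.append((res, kr))
                used_parts.append(u)
                dropped_parts.append(d)
            k = float(np.mean([v for _, v in ks]))
            sigma = float(np.std([v for _, v in ks], ddof=1)) if len(ks) > 1 else np.nan
            used = pd.concat(used_parts)
            dropped = pd.concat(dropped_parts) if dropped_parts else data.iloc[:0]
        if len(used) == 0:
            raise ValueError(
                "all points excluded by the kt validity cap; exclusion log: "
                f"{excluded + [(r.residue, r.t, 'kt beyond cap') for r in dropped.itertuples()]}"
            )
        excluded = excluded + [
            (r.residue, r.t, f"fitted k·t > {self.max_kt}") for r in dropped.itertuples()
        ]

        self.k_ = k
        self.sigma_k_ = sigma
        self.residues_ = sorted(data["residue"].unique().tolist())
        self.delays_ = sorted(used["t"].unique().tolist())
        self.n_points_ = int(len(used))
        resid = used["ratio"].to_numpy() - (k * used["t"].to_numpy()) ** 2
        self.residual_sd_ = float(resid.std(ddof=1)) if len(resid) > 1 else 0.0
        self.excluded_ = excluded
        self.k_per_residue_ = {
            res: self._fit_k(sub["t"].to_numpy(), sub["ratio"].to_numpy())[0]
            for res, sub in used.groupby("residue", sort=False)
            if len(sub) >= 2
        }

        self.sigma_k_bootstrap_ = None
        if len(self.residues_) >= 4 and self.n_bootstrap > 0:
            rng = np.random.default_rng(self.random_state)
            boot = []
            groups = {res: sub for res, sub in used.groupby("residue", sort=False)}
            res_list = list(groups)
            for _ in range(self.n_bootstrap):
                picks = rng.choice(res_list, size=len(res_list), replace=True)
                sub = pd.concat([groups[r] for r in picks])
                try:
                    kb, _ = self._fit_k(sub["t"].to_numpy(), sub["ratio"].to_numpy())
                    boot.append(kb)
                except Exception:
                    continue
            if len(boot) >= 10:
                self.sigma_k_bootstrap_ = float(np.std(boot, ddof=1))
        return self


def fit_exchange_rate(
    quartets: pd.DataFrame, max_kt: float = 0.5, pooling: str = "composite", **kwargs
) -> ExchangeRateFitter:
    """Thin functional wrapper over :class:`ExchangeRateFitter`."""
    return ExchangeRateFitter(max_kt=max_kt, pooling=pooling, **kwargs).fit(quartets)


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------

def _frac(pka: float, ph: np.ndarray) -> np.ndarray:
    # protonated fraction 10^(pKa−pH)/(1+10^(pKa−pH)), overflow-safe
    z = np.clip(np.asarray(ph, dtype=float) - pka, -300.0, 300.0)
    return 1.0 / (1.0 + np.power(10.0, z))


@dataclass
class TitrationModel:
    """A fitted global titration model.

    ``curves`` maps (residue, nucleus) to {'endpoint': ppm,
    'amplitudes': [Δδ per pKa, ppm]}; pKa values are shared, ascending.
    """

    n_pka: int
    pka: list
    pka_sd: list
    curves: dict
    rss: float = np.nan
    n_points: int = 0
    n_params: int = 0
    data_checksum: str = ""
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


def titration_model_eval(model: TitrationModel, residue: str, nucleus: str, ph) -> np.ndarray:
    """Evaluate a fitted titration curve at the given pH value(s) (ppm)."""
    key = (residue, nucleus)
    if key not in model.curves:
        raise KeyError(f"no fitted curve for residue {residue!r}, nucleus {nucleus!r}")
    c = model.curves[key]
    ph_arr = np.asarray(ph, dtype=float)
    out = np.full_like(ph_arr, float(c["endpoint"]), dtype=float)
    for amp, p in zip(c["amplitudes"], model.pka):
        out = out + amp * _frac(p, ph_arr)
    return float(out) if np.isscalar(ph) or ph_arr.ndim == 0 else out


def _table_checksum(df: pd.DataFrame) -> str:
    cols = ["residue", "nucleus", "pH", "shift_ppm"]
    payload = df[cols].round(9).to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


class GlobalTitrationFitter(BaseEstimator):
    """Error-weighted global fit of shared pKa values across titration curves.

    For fixed pKa values each curve's endpoint and amplitudes are linear
    and solved exactly (weighted least squares), so the search runs over
    the pKa values alone: a multi-start grid (default 4.5–9.0, step 0.5)
    followed by simplex refinement, with pKa₁ < pKa₂ enforced through an
    ordered (pKa₁, log-gap) parameterization. Uncertainties come from the
    Jacobian of the full weighted residual at the optimum.

    Attributes (after ``fit``): ``model_`` (:class:`TitrationModel`),
    ``pka_``, ``pka_sd_``, ``rss_``, ``aic_``.
    """

    def __init__(
        self,
        n_pka: int = 2,
        grid_lo: float = 4.5,
        grid_hi: float = 9.0,
        grid_step: float = 0.5,
        default_err: Mapping | None = None,
    ):
        self.n_pka = n_pka
        self.grid_lo = grid_lo
        self.grid_hi = grid_hi
        self.grid_step = grid_step
        self.default_err = default_err

    def _prepare(self, table: pd.DataFrame):
        defaults = dict(self.default_err or {"H": 0.01, "N": 0.05})
        curves = []
        for (res, nuc), sub in table.groupby(["residue", "nucleus"], sort=False):
            sub = sub.sort_values("pH")
            ph = sub["pH"].to_numpy(dtype=float)
            if len(np.unique(ph)) < 2:
                raise ValueError(f"curve {res}/{nuc} has < 2 distinct pH points")
            shift = sub["shift_ppm"].to_numpy(dtype=float)
            err = sub["err_ppm"].to_numpy(dtype=float) if "err_ppm" in sub else np.full_like(ph, np.nan)
            fallback = float(defaults.get(str(nuc), 1.0))
            err = np.where(np.isfinite(err) & (err > 0), err, fallback)
            curves.append(((str(res), str(nuc)), ph, shift, err))
        return curves

    @staticmethod
    def _profiled_rss(pkas: np.ndarray, curves) -> tuple[float, dict]:
        """Weighted RSS with per-curve linear parameters solved exactly."""
        total = 0.0
        solved = {}
        for key, ph, shift, err in curves:
            basis = np.column_stack(
                [np.ones_like(ph)] + [_frac(p, ph) for p in pkas]
            )
            w = 1.0 / err
            coef, *_ = np.linalg.lstsq(basis * w[:, None], shift * w, rcond=None)
            resid = (shift - basis @ coef) * w
            total += float(resid @ resid)
            solved[key] = {"endpoint": float(coef[0]), "amplitudes": coef[1:].tolist()}
        return total, solved

    def fit(self, table: pd.DataFrame, y=None):
        if self.n_pka not in (1, 2):
            raise ValueError(f"n_pka must be 1 or 2 (got {self.n_pka})")
        curves = self._prepare(table)
        if len({key[0] for key, *_ in curves}) < 2:
            raise ValueError("global fit requires ≥ 2 residues")

        grid = np.arange(self.grid_lo, self.grid_hi + 1e-9, self.grid_step)
        if self.n_pka == 1:
            starts = [(p,) for p in grid]
        else:
            starts = [(p1, p2) for i, p1 in enumerate(grid) for p2 in grid[i + 1 :]]
        scored = [(self._profiled_rss(np.array(s), curves)[0], s) for s in starts]
        scored.sort(key=lambda x: x[0])
        best_rss, best_start = scored[0]

        # ordered parameterization: (pKa1, log gap) keeps pKa strictly ascending
        def to_theta(pkas):
            if self.n_pka == 1:
                return np.array([pkas[0]])
            return np.array([pkas[0], np.log(max(pkas[1] - pkas[0], 1e-6))])

        def from_theta(theta):
            if self.n_pka == 1:
                return np.array([theta[0]])
            return np.array([theta[0], theta[0] + np.exp(theta[1])])

        res = optimize.minimize(
            lambda th: self._profiled_rss(from_theta(th), curves)[0],
            to_theta(np.array(best_start)),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 4000},
        )
        pkas = np.sort(from_theta(res.x))
        rss, solved = self._profiled_rss(pkas, curves)
        if not res.success and rss > best_rss + 1e-9:
            raise RuntimeError(
                "titration fit failed to converge from the best grid start; "
                f"grid diagnostics (top 5): {scored[:5]}"
            )

        # covariance of shared pKa values from the full weighted Jacobian
        keys = [key for key, *_ in curves]
        amp_index = {key: i for i, key in enumerate(keys)}
        n_lin = 1 + self.n_pka

        def full_residuals(x):
            pk = x[: self.n_pka]
            out = []
            for key, ph, shift, err in curves:
                off = self.n_pka + amp_index[key] * n_lin
                coef = x[off : off + n_lin]
                basis = np.column_stack([np.ones_like(ph)] + [_frac(p, ph) for p in pk])
                out.append((shift - basis @ coef) / err)
            return np.concatenate(out)

        x0 = np.concatenate(
            [pkas]
            + [
                [solved[key]["endpoint"], *solved[key]["amplitudes"]]
                for key in keys
            ]
        )
        ls = optimize.least_squares(full_residuals, x0, method="lm", max_nfev=20000)
        pkas_final = np.sort(ls.x[: self.n_pka])
        jac = ls.jac
        n_pts = len(ls.fun)
        n_par = len(x0)
        try:
            cov = np.linalg.inv(jac.T @ jac)
            dof = max(n_pts - n_par, 1)
            scale = 2.0 * ls.cost / dof  # residuals already error-weighted
            pka_sd = np.sqrt(np.diag(cov)[: self.n_pka] * scale)
        except np.linalg.LinAlgError:
            pka_sd = np.full(self.n_pka, np.nan)
        rss_final, solved_final = self._profiled_rss(pkas_final, curves)

        boundary = bool(
            np.any(np.isclose(pkas_final, self.grid_lo)) or np.any(np.isclose(pkas_final, self.grid_hi))
        )
        self.pka_ = pkas_final.tolist()
        self.pka_sd_ = pka_sd.tolist()
        self.rss_ = rss_final
        self.n_points_ = n_pts
        self.n_params_ = n_par
        self.aic_ = n_pts * np.log(rss_final / n_pts) + 2 * n_par
        self.model_ = TitrationModel(
            n_pka=self.n_pka,
            pka=self.pka_,
            pka_sd=self.pka_sd_,
            curves=solved_final,
            rss=rss_final,
            n_points=n_pts,
            n_params=n_par,
            data_checksum=_table_checksum(table),
            converged=True,
            diagnostics={
                "grid_best_start": list(best_start),
                "grid_best_rss": best_rss,
                "at_grid_boundary": boundary,
            },
        )
        return self


def fit_titration_global(table: pd.DataFrame, n_pka: int = 2, **kwargs) -> TitrationModel:
    """Thin functional wrapper over :class:`GlobalTitrationFitter`."""
    return GlobalTitrationFitter(n_pka=n_pka, **kwargs).fit(table).model_


def model_select(fit1: TitrationModel, fit2: TitrationModel) -> dict:
    """F-test + AIC comparison of a 1-pKa and a 2-pKa fit on identical data.

    Returns a dict with the preferred model, the F statistic and p-value
    (extra-sum-of-squares test on the parameter-count difference) and
    both AIC values.
    """
    if fit1.data_checksum != fit2.data_checksum:
        raise ValueError("model_select requires both fits to use identical data")
    simple, complex_ = (fit1, fit2) if fit1.n_params <= fit2.n_params else (fit2, fit1)
    df_num = complex_.n_params - simple.n_params
    df_den = complex_.n_points - complex_.n_params
    if df_num == 0 or np.isclose(simple.rss, complex_.rss):
        f_stat = 0.0
        p = 1.0
    else:
        f_stat = ((simple.rss - complex_.rss) / df_num) / (complex_.rss / df_den)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    aic = {
        m.n_pka: m.n_points * np.log(m.rss / m.n_points) + 2 * m.n_params
        for m in (simple, complex_)
    }
    preferred = complex_ if p < 0.05 else simple
    return {
        "preferred": preferred,
        "preferred_n_pka": preferred.n_pka,
        "F": float(f_stat),
        "p": float(p),
        "aic": aic,
    }


@dataclass
class SensitivityClass:
    """Per-residue pKa sensitivity labels and amplitude fractions."""

    labels: dict
    fractions: dict
    composite: dict


def classify_pka_sensitivity(
    model: TitrationModel, min_amplitude: float = 0.05, nitrogen_weight: float = 0.2
) -> SensitivityClass:
    """Label residues by which shared pKa they sense.

    Per residue and pKa j the composite amplitude pools nuclei as
    √(Δδ_H² + (w·Δδ_N)²) with nitrogen weight w (the usual chemical-shift
    perturbation convention, w ≈ 0.1–0.2). Labels: ``low_only``,
    ``high_only``, ``both`` or ``insensitive`` against ``min_amplitude``.
    """
    if model.n_pka != 2:
        raise ValueError("sensitivity classification requires a fitted 2-pKa model")
    residues = sorted({res for res, _ in model.curves})
    labels, fractions, composite = {}, {}, {}
    for res in residues:
        comp = []
        for j in range(2):
            dh = model.curves.get((res, "H"), {}).get("amplitudes", [0.0, 0.0])[j]
            dn = model.curves.get((res, "N"), {}).get("amplitudes", [0.0, 0.0])[j]
            comp.append(float(np.hypot(dh, nitrogen_weight * dn)))
        composite[res] = comp
        total = sum(comp)
        fractions[res] = [c / total for c in comp] if total > 0 else [0.0, 0.0]
        low, high = (c >= min_amplitude for c in comp)
        labels[res] = (
            "both" if (low and high) else "low_only" if low else "high_only" if high else "insensitive"
        )
    return SensitivityClass(labels=labels, fractions=fractions, composite=composite)
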