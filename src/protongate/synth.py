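"""Seeded synthetic-data generators for every pipeline input class.

Each generator draws from an explicit :func:`numpy.random.default_rng`
stream (no global state) and records its ground-truth parameters in
metadata — a table's ``attrs``/JSON sidecar or a trace's metadata dict —
never in the data columns, so downstream fits cannot see it.

The generators emulate the statistical structure of the real inputs only:

* water-oxygen chains with tunable hydrogen-bond spacing, and wet/dry
  trajectories mimicking an intermittently connected water wire;
* symmetric two-site ZZ-exchange peak quartets with longitudinal
  relaxation and multiplicative intensity noise;
* fast-exchange chemical-shift titration curves sharing one or two pKa
  values across residues;
* i.i.d. Boltzmann samples from a known 1-D free-energy profile under
  harmonic umbrella biases (inverse-CDF on a fine grid);
* pyranine fluorescence and SSME current traces with burst and
  steady-state phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .frames import Frame

__all__ = [
    "ScenarioConfig",
    "PRESETS",
    "get_preset",
    "make_water_chain",
    "make_wire_trajectory",
    "make_zz_dataset",
    "make_titration_dataset",
    "make_umbrella_dataset",
    "make_assay_traces",
    "true_pmf",
]


@dataclass
class ScenarioConfig:
    """A named, seeded scenario: generator parameters plus reproducibility.

    ``parameters`` holds the generator-specific values (rates in 1/s,
    shifts in ppm, energies in kcal/mol, lengths in Å). A fixed seed makes
    every generator call byte-identical.
    """

    name: str
    seed: int
    parameters: dict = field(default_factory=dict)

    def with_seed(self, seed: int | None) -> "ScenarioConfig":
        return self if seed is None else replace(self, seed=int(seed))

    def require(self, key: str):
        if key not in self.parameters:
            raise KeyError(f"scenario {self.name!r} missing parameter {key!r}")
        return self.parameters[key]


def _positive(value, name: str):
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be > 0 (got {value})")
    return value


# ---------------------------------------------------------------------------
# water chains / wire trajectories
# ---------------------------------------------------------------------------

def make_water_chain(
    n_waters: int,
    spacing: float,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> Frame:
    """A linear chain of water oxygens bridging a glutamate-like source and
    a backbone-pair sink.

    Waters sit at x = spacing, 2·spacing, …, n·spacing with isotropic
    Gaussian jitter. The source is a two-oxygen carboxylate-like pair whose
    nearer oxygen is exactly at the origin; the sink is a two-CA pair whose
    midpoint lies one spacing beyond the last water. True spacing is
    recorded in frame metadata.
    """
    if n_waters < 1:
        raise ValueError(f"n_waters must be ≥ 1 (got {n_waters})")
    _positive(spacing, "spacing")
    if jitter_sd < 0:
        raise ValueError(f"jitter_sd must be ≥ 0 (got {jitter_sd})")
    rng = np.random.default_rng(seed)

    sink_x = (n_waters + 1) * spacing
    water_pos = np.zeros((n_waters, 3))
    water_pos[:, 0] = spacing * np.arange(1, n_waters + 1)
    if jitter_sd > 0:
        water_pos += rng.normal(0.0, jitter_sd, size=water_pos.shape)

    names = ["OE1", "OE2"] + ["O"] * n_waters + ["CA", "CA"]
    resnames = ["GLU", "GLU"] + ["HOH"] * n_waters + ["ARG", "GLY"]
    resids = [14, 14] + list(range(101, 101 + n_waters)) + [102, 57]
    subunits = ["B", "B"] + ["W"] * n_waters + ["A", "A"]
    positions = np.vstack(
        [
            [0.0, 0.0, 0.0],          # OE1: on-axis, defines source distance
            [-1.1, 1.9, 0.0],         # OE2: carboxylate partner, off-axis
            water_pos,
            [sink_x, 3.0, 0.0],       # CA of R102(A)
            [sink_x, -3.0, 0.0],      # CA of G57(A); midpoint is the sink
        ]
    )
    return Frame(
        names=names,
        resnames=resnames,
        resids=resids,
        subunits=subunits,
        positions=positions,
        metadata={
            "generator": "make_water_chain",
            "spacing": float(spacing),
            "jitter_sd": float(jitter_sd),
            "n_waters": int(n_waters),
            "seed": int(seed),
        },
    )


def make_wire_trajectory(
    n_frames: int,
    wet_fraction: float,
    chain_params: Mapping | None = None,
    seed: int = 0,
) -> tuple[list[Frame], list[bool]]:
    """Frames alternating between a connected ('wet') and a broken ('dry')
    water chain.

    Each frame is independently wet with probability ``wet_fraction``; a
    dry frame has one randomly chosen gap widened to ``spacing_dry``.
    Returns the frames and the per-frame wet labels (ground truth).
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be ≥ 1 (got {n_frames})")
    if not 0.0 <= wet_fraction <= 1.0:
        raise ValueError(f"wet_fraction must be in [0, 1] (got {wet_fraction})")
    params = dict(chain_params or {})
    n_waters = int(params.get("n_waters", 6))
    spacing = float(params.get("spacing", 2.8))
    spacing_dry = float(params.get("spacing_dry", 6.0))
    jitter_sd = float(params.get("jitter_sd", 0.1))
    _positive(spacing, "spacing")
    _positive(spacing_dry, "spacing_dry")

    rng = np.random.default_rng(seed)
    frames: list[Frame] = []
    labels: list[bool] = []
    for i in range(n_frames):
        wet = bool(rng.random() < wet_fraction)
        frame = make_water_chain(
            n_waters, spacing, jitter_sd, seed=int(rng.integers(0, 2**31 - 1))
        )
        if not wet:
            # widen one gap: shift everything beyond it along +x
            gap = int(rng.integers(0, n_waters + 1))  # 0 = source–water1 gap
            shift = spacing_dry - spacing
            moved = np.zeros(frame.n_atoms, dtype=bool)
            moved[2 + gap : 2 + n_waters] = True   # waters after the gap
            moved[2 + n_waters :] = True           # sink pair
            frame.positions[moved, 0] += shift
            frame.metadata["dry_gap"] = gap
        frame.index = i
        frame.metadata["wet"] = wet
        frames.append(frame)
        labels.append(wet)
    return frames, labels


# ---------------------------------------------------------------------------
# ZZ-exchange quartets
# ---------------------------------------------------------------------------

def zz_quartet_model(k: float, t: np.ndarray, r1: float, i0: float):
    """Exact symmetric two-site ZZ intensities (auto, cross) at delays t."""
    t = np.asarray(t, dtype=float)
    decay = np.exp(-r1 * t) * i0
    eps = np.exp(-2.0 * k * t)
    auto = 0.5 * (1.0 + eps) * decay
    cross = 0.5 * (1.0 - eps) * decay
    return auto, cross


def make_zz_dataset(config: ScenarioConfig) -> pd.DataFrame:
    """Peak quartets (I_AA, I_BB, I_AB, I_BA) per residue per mixing delay.

    Exact symmetric two-site model with longitudinal relaxation, then
    multiplicative Gaussian noise on each intensity. Ground truth (k_true,
    R1, reference intensities) goes into ``df.attrs['ground_truth']``.
    """
    k_true = float(_positive(config.require("k_true"), "k_true"))
    r1 = float(_positive(config.require("r1"), "r1"))
    delays = np.asarray(config.require("delays"), dtype=float)
    residues = list(config.require("residues"))
    noise = float(config.parameters.get("noise_frac", 0.0))
    i0_map = config.parameters.get("i0", {})

    if len(residues) == 0:
        raise ValueError("residue list must be non-empty")
    if len(delays) == 0:
        raise ValueError("delay list must be non-empty")
    _positive(delays, "delays")
    if np.any(np.diff(delays) <= 0):
        raise ValueError("delays must be strictly increasing")
    if noise < 0:
        raise ValueError(f"noise_frac must be ≥ 0 (got {noise})")

    rng = np.random.default_rng(config.seed)
    rows = []
    for res in residues:
        i0 = float(i0_map.get(res, 1.0))
        auto, cross = zz_quartet_model(k_true, delays, r1, i0)
        for j, t in enumerate(delays):
            vals = np.array([auto[j], auto[j], cross[j], cross[j]])
            if noise > 0:
                vals = vals * (1.0 + rng.normal(0.0, noise, size=4))
            rows.append(
                {
                    "residue": res,
                    "t_s": float(t),
                    "I_AA": vals[0],
                    "I_BB": vals[1],
                    "I_AB": vals[2],
                    "I_BA": vals[3],
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = {
        "k_true": k_true,
        "r1": r1,
        "i0": {res: float(i0_map.get(res, 1.0)) for res in residues},
        "noise_frac": noise,
    }
    df.attrs["config"] = {"name": config.name, "seed": config.seed}
    return df


# ---------------------------------------------------------------------------
# titration curves
# ---------------------------------------------------------------------------

def _protonated_fraction(pka: float, ph: np.ndarray) -> np.ndarray:
    z = np.clip(np.asarray(ph, dtype=float) - pka, -300.0, 300.0)
    return 1.0 / (1.0 + np.power(10.0, z))


def make_titration_dataset(config: ScenarioConfig) -> pd.DataFrame:
    """Fast-exchange chemical-shift titration table over a pH grid.

    Per residue and nucleus: shift(pH) = endpoint + Σ_j Δδ_j · f_j(pH)
    with f_j the protonated fraction for shared pKa_j, plus additive
    Gaussian noise (per-nucleus SD). Ground truth lives in ``attrs``.
    """
    pka = list(np.asarray(config.require("pka_true"), dtype=float))
    if len(pka) not in (1, 2):
        raise ValueError(f"pka_true must have length 1 or 2 (got {len(pka)})")
    if len(pka) == 2 and not pka[0] < pka[1]:
        raise ValueError(f"pka_true must be strictly ascending (got {pka})")
    ph_grid = np.asarray(config.require("ph_grid"), dtype=float)
    if len(ph_grid) < 6:
        raise ValueError(f"pH grid needs ≥ 6 points (got {len(ph_grid)})")
    if np.any(np.diff(ph_grid) <= 0):
        raise ValueError("pH grid must be strictly increasing")

    curves: Mapping = config.require("curves")
    noise_sd: Mapping = config.parameters.get("noise_sd", {"H": 0.0, "N": 0.0})

    rng = np.random.default_rng(config.seed)
    rows = []
    for (residue, nucleus), spec_c in curves.items():
        endpoint = float(spec_c.get("endpoint", 0.0))
        amps = list(np.asarray(spec_c["amplitudes"], dtype=float))
        if len(amps) != len(pka):
            raise ValueError(
                f"curve {residue}/{nucleus}: {len(amps)} amplitudes for {len(pka)} pKa values"
            )
        sd = float(noise_sd.get(nucleus, 0.0))
        shift = np.full_like(ph_grid, endpoint)
        for a, p in zip(amps, pka):
            shift = shift + a * _protonated_fraction(p, ph_grid)
        if sd > 0:
            shift = shift + rng.normal(0.0, sd, size=shift.shape)
        for ph, s in zip(ph_grid, shift):
            rows.append(
                {
                    "residue": residue,
                    "nucleus": nucleus,
                    "pH": float(ph),
                    "shift_ppm": float(s),
                    "err_ppm": sd if sd > 0 else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = {
        "pka_true": pka,
        "curves": {f"{r}/{n}": dict(c) for (r, n), c in curves.items()},
        "noise_sd": dict(noise_sd),
    }
    df.attrs["config"] = {"name": config.name, "seed": config.seed}
    return df


# ---------------------------------------------------------------------------
# umbrella-sampling windows
# ---------------------------------------------------------------------------

def true_pmf(x: np.ndarray, form: str, params: Mapping) -> np.ndarray:
    """Evaluate a registered ground-truth free-energy profile (kcal/mol)."""
    x = np.asarray(x, dtype=float)
    if form == "zero":
        return np.zeros_like(x)
    if form == "harmonic":
        k = float(params.get("k", 1.0))
        x0 = float(params.get("x0", 0.0))
        return 0.5 * k * (x - x0) ** 2
    if form == "double_well":
        # minima at center ± half_sep (W = 0), barrier of height h at center
        h = float(params.get("barrier", 3.0))
        c = float(params.get("center", 5.0))
        w = float(params.get("half_sep", 5.0))
        u = (x - c) / w
        return h * (u**2 - 1.0) ** 2
    raise ValueError(f"unknown PMF form {form!r}; known: zero, harmonic, double_well")


def make_umbrella_dataset(config: ScenarioConfig) -> list:
    """Boltzmann samples from W_true under harmonic biases, one window per
    center, drawn i.i.d. by inverse-CDF on a fine grid (default 10⁻³ Å).

    Returns :class:`protongate.pmf.UmbrellaWindow` objects; the true PMF
    specification is recorded in each window's metadata.
    """
    from .pmf import UmbrellaWindow

    centers = np.asarray(config.require("centers"), dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centers must be strictly increasing")
    kappas = np.asarray(config.require("kappa"), dtype=float)
    if kappas.ndim == 0:
        kappas = np.full_like(centers, float(kappas))
    if np.any(kappas <= 0):
        raise ValueError(f"force constants must be > 0 (got {kappas})")
    n_samples = int(config.require("n_samples"))
    if n_samples < 100:
        raise ValueError(f"samples per window must be ≥ 100 (got {n_samples})")
    kt = float(_positive(config.require("kT"), "kT"))
    form = config.parameters.get("pmf_form", "zero")
    form_params = config.parameters.get("pmf_params", {})
    grid_step = float(config.parameters.get("grid_step", 1e-3))
    margin = float(config.parameters.get("margin", 3.0))

    lo = centers.min() - margin
    hi = centers.max() + margin
    grid = np.arange(lo, hi + grid_step, grid_step)
    w_true = true_pmf(grid, form, form_params)

    rng = np.random.default_rng(config.seed)
    truth = {
        "pmf_form": form,
        "pmf_params": dict(form_params),
        "kT": kt,
        "grid_lo": lo,
        "grid_hi": hi,
    }
    windows = []
    for center, kappa in zip(centers, kappas):
        energy = w_true + 0.5 * kappa * (grid - center) ** 2
        log_dens = -(energy - energy.min()) / kt
        dens = np.exp(log_dens)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]))])
        cdf /= cdf[-1]
        u = rng.random(n_samples)
        samples = np.interp(u, cdf, grid)
        windows.append(
            UmbrellaWindow(
                center=float(center),
                kappa=float(kappa),
                samples=samples,
                metadata=dict(truth),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# assay traces
# ---------------------------------------------------------------------------

def make_assay_traces(kind: str, config: ScenarioConfig) -> list:
    """Synthetic proteoliposome assay traces with recorded ground truth.

    ``pyranine``: transport trace F0·(1 + burst + A·(1 − e^(−rate·t))) plus
    a flat no-gradient baseline trace, both with additive noise. The burst
    is an instantaneous offset present from the first read (it develops in
    the dead time between dilution and acquisition).

    ``ssme``: a biexponential capacitive current A1·e^(−t/τ1) − A2·e^(−t/τ2)
    inside a perfusion window, flanked by baseline segments.
    """
    from .assays import AssayTrace

    if kind not in ("pyranine", "ssme"):
        raise ValueError(f"unknown assay kind {kind!r}; valid kinds: pyranine, ssme")
    p = config.parameters
    duration = float(_positive(p.get("duration", 1800.0 if kind == "pyranine" else 3.0), "duration"))
    rng = np.random.default_rng(config.seed)

    if kind == "pyranine":
        dt = float(p.get("dt", 5.0))
        t = np.arange(0.0, duration + dt / 2, dt)
        f0 = float(p.get("f0", 1000.0))
        burst = float(p.get("burst", 0.0))
        amp = float(p.get("amplitude", 0.2))
        rate = float(p.get("rate", 0.002))
        noise_sd = float(p.get("noise_sd", 0.0))
        truth = {
            "f0": f0,
            "burst": burst,
            "amplitude": amp,
            "rate": rate,
            "noise_sd": noise_sd,
        }
        transport = f0 * (1.0 + burst + amp * (1.0 - np.exp(-rate * t)))
        baseline = np.full_like(t, f0)
        if noise_sd > 0:
            transport = transport + rng.normal(0.0, noise_sd * f0, size=t.shape)
            baseline = baseline + rng.normal(0.0, noise_sd * f0, size=t.shape)
        meta = {"construct": config.name, "ground_truth": truth}
        return [
            AssayTrace(time=t, signal=transport, metadata={**meta, "condition": "transport"}),
            AssayTrace(time=t, signal=baseline, metadata={**meta, "condition": "no_gradient"}),
        ]

    # ssme
    dt = float(p.get("dt", 1e-3))
    t = np.arange(0.0, duration + dt / 2, dt)
    t0 = float(p.get("perfusion_start", 1.0))
    t1 = float(p.get("perfusion_end", 2.0))
    if not 0.0 <= t0 < t1 <= duration:
        raise ValueError(f"perfusion window [{t0}, {t1}] must lie inside [0, {duration}]")
    a1 = float(p.get("a1", 1.0))
    tau1 = float(_positive(p.get("tau1", 0.05), "tau1"))
    a2 = float(p.get("a2", 0.3))
    tau2 = float(_positive(p.get("tau2", 0.4), "tau2"))
    offset = float(p.get("baseline_offset", 0.0))
    noise_sd = float(p.get("noise_sd", 0.0))
    span = t1 - t0
    charge_true = a1 * tau1 * (1.0 - np.exp(-span / tau1)) - a2 * tau2 * (
        1.0 - np.exp(-span / tau2)
    )
    current = np.full_like(t, offset)
    mask = (t >= t0) & (t <= t1)
    tp = t[mask] - t0
    current[mask] += a1 * np.exp(-tp / tau1) - a2 * np.exp(-tp / tau2)
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=t.shape)
    truth = {
        "a1": a1,
        "tau1": tau1,
        "a2": a2,
        "tau2": tau2,
        "baseline_offset": offset,
        "noise_sd": noise_sd,
        "perfusion": [t0, t1],
        "charge_true": float(charge_true),
    }
    return [
        AssayTrace(
            time=t,
            signal=current,
            metadata={"construct": config.name, "condition": "ssme", "ground_truth": truth},
        )
    ]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _tpp_titration_curves() -> dict:
    """12 residues with designed mixed pKa sensitivity (4 low-only, 4
    high-only, 4 both), H and N nuclei each."""
    curves: dict = {}
    residues = [f"R{i}" for i in range(1, 13)]
    # amplitude designs in ppm: (H_low, H_high), N scaled ~6x
    designs = (
        [(0.45, 0.0)] * 4 + [(0.0, 0.55)] * 4 + [(0.30, 0.35)] * 4
    )
    for idx, (res, (h_lo, h_hi)) in enumerate(zip(residues, designs)):
        sign = 1.0 if idx % 2 == 0 else -1.0
        curves[(res, "H")] = {
            "endpoint": 8.0 + 0.05 * idx,
            "amplitudes": [sign * h_lo, sign * h_hi],
        }
        curves[(res, "N")] = {
            "endpoint": 118.0 + 0.4 * idx,
            "amplitudes": [sign * 6.0 * h_lo, sign * 6.0 * h_hi],
        }
    return curves


PRESETS: dict[str, ScenarioConfig] = {
    "zz_low_pH": ScenarioConfig(
        name="zz_low_pH",
        seed=1,
        parameters={
            "k_true": 4.0,
            "r1": 1.5,
            "delays": np.linspace(0.01, 0.2, 8).tolist(),
            "residues": ["F78", "G80", "R82", "L83", "R106"],
            "noise_frac": 0.02,
        },
    ),
    "zz_high_pH": ScenarioConfig(
        name="zz_high_pH",
        seed=2,
        parameters={
            "k_true": 17.0,
            "r1": 1.5,
            "delays": np.linspace(0.005, 0.1, 8).tolist(),
            "residues": ["G80", "R82", "L83", "R106"],
            "noise_frac": 0.02,
        },
    ),
    "tpp_titration": ScenarioConfig(
        name="tpp_titration",
        seed=3,
        parameters={
            "pka_true": [5.6, 7.1],
            "ph_grid": np.linspace(4.5, 9.0, 12).tolist(),
            "curves": _tpp_titration_curves(),
            "noise_sd": {"H": 0.01, "N": 0.05},
        },
    ),
    "pmf_toy": ScenarioConfig(
        name="pmf_toy",
        seed=5,
        parameters={
            "pmf_form": "double_well",
            "pmf_params": {"barrier": 3.0, "center": 5.0, "half_sep": 5.0},
            "centers": np.linspace(0.0, 10.0, 21).tolist(),
            "kappa": 40.0,
            "n_samples": 2000,
            "kT": 0.596,
        },
    ),
    "wt_leak": ScenarioConfig(
        name="wt_leak",
        seed=21,
        parameters={
            "duration": 1800.0,
            "dt": 5.0,
            "f0": 1000.0,
            "burst": 0.02,
            "amplitude": 0.15,
            "rate": 0.0012,
            "noise_sd": 0.002,
        },
    ),
    "d107_leak": ScenarioConfig(
        name="d107_leak",
        seed=22,
        parameters={
            "duration": 1800.0,
            "dt": 5.0,
            "f0": 1000.0,
            "burst": 0.06,
            "amplitude": 0.35,
            "rate": 0.008,
            "noise_sd": 0.002,
        },
    ),
    "wt_ssme": ScenarioConfig(
        name="wt_ssme",
        seed=31,
        parameters={
            "duration": 3.0,
            "dt": 1e-3,
            "perfusion_start": 1.0,
            "perfusion_end": 2.0,
            "a1": 0.4,
            "tau1": 0.05,
            "a2": 0.1,
            "tau2": 0.4,
            "noise_sd": 0.004,
        },
    ),
    "d107_ssme": ScenarioConfig(
        name="d107_ssme",
        seed=32,
        parameters={
            "duration": 3.0,
            "dt": 1e-3,
            "perfusion_start": 1.0,
            "perfusion_end": 2.0,
            "a1": 1.2,
            "tau1": 0.05,
            "a2": 0.3,
            "tau2": 0.4,
            "noise_sd": 0.004,
        },
    ),
}


def get_preset(name: str, seed: int | None = None) -> ScenarioConfig:
    """Look up a preset scenario, optionally overriding its seed."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name].with_seed(seed)
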