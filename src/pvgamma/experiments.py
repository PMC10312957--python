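"""Trial-averaged in-silico experiments: release-probability sweep, nadir
detection, and the inhibitory-strength x release-probability synergy analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netmodel import NetworkConfig, simulate_trial
from .spectral_metrics import GAMMA_BAND, trial_metrics

__all__ = [
    "SweepResult",
    "SynergyResult",
    "NadirEstimate",
    "run_trials",
    "rp_sweep",
    "detect_nadir",
    "synergy_analysis",
]


@dataclass
class SweepResult:
    parameter: str
    values: np.ndarray
    gamma_power: np.ndarray
    gamma_power_sem: np.ndarray
    rate_pyramidal: np.ndarray
    rate_pyramidal_sem: np.ndarray
    rate_pvi: np.ndarray
    rate_pvi_sem: np.ndarray
    cv_isi: np.ndarray
    cv_isi_sem: np.ndarray
    n_trials: int
    master_seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.parameter: self.values,
            "gamma_power": self.gamma_power,
            "gamma_power_sem": self.gamma_power_sem,
            "rate_pyramidal": self.rate_pyramidal,
            "rate_pyramidal_sem": self.rate_pyramidal_sem,
            "rate_pvi": self.rate_pvi,
            "rate_pvi_sem": self.rate_pvi_sem,
            "cv_isi": self.cv_isi,
            "cv_isi_sem": self.cv_isi_sem,
        })


@dataclass
class SynergyResult:
    weights: np.ndarray  # % of baseline, descending from 100
    reduction_g: np.ndarray
    reduction_rp: np.ndarray
    expected: np.ndarray  # reduction_g + reduction_rp, exact identity
    joint: np.ndarray
    baseline_power: float
    crossover_percent: float  # largest % lowering with joint > expected
    n_trials: int
    master_seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "weight_percent": self.weights,
            "reduction_g": self.reduction_g,
            "reduction_rp": self.reduction_rp,
            "reduction_expected": self.expected,
            "reduction_joint": self.joint,
        })


@dataclass
class NadirEstimate:
    onset: float
    tolerance: float
    degenerate: bool = False


def _trial_seed(master_seed: int, trial: int) -> int:
    # keyed by trial index only, so the same trial shares its noise stream
    # across parameter values (variance reduction for curve shapes)
    return int(np.random.SeedSequence([master_seed, trial]).generate_state(1)[0])


def run_trials(config: NetworkConfig, n_trials: int, master_seed: int,
               band: tuple = GAMMA_BAND, mode: str = "peak",
               segment_ms: float = 1250.0) -> pd.DataFrame:
    """Simulate ``n_trials`` independent trials; one metrics row per trial."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rows = []
    for t in range(n_trials):
        res = simulate_trial(config, seed=_trial_seed(master_seed, t))
        m = trial_metrics(res, band=band, segment_ms=min(segment_ms, (config.duration_ms - config.transient_ms) / 2))
        power = m.gamma.peak_gamma_power if mode == "peak" else m.gamma.band_integral
        rows.append({
            "trial": t, "gamma_power": power,
            "peak_frequency": m.gamma.peak_frequency,
            "rate_pyramidal": m.rate_pyramidal, "rate_pvi": m.rate_pvi,
            "cv_isi": m.cv_isi,
        })
    return pd.DataFrame(rows)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(np.nanstd(x, ddof=1) / np.sqrt(np.sum(np.isfinite(x))))


def rp_sweep(config: NetworkConfig, rp_values, n_trials: int = 20,
             master_seed: int = 0, band: tuple = GAMMA_BAND,
             mode: str = "peak") -> SweepResult:
    """Trial-averaged metrics for each release-probability value."""
    rp_values = np.asarray(rp_values, dtype=float)
    if rp_values.size < 2:
        raise ValueError("need at least two sweep values")
    if np.any((rp_values < 0) | (rp_values > 1)):
        raise ValueError("release probabilities must lie in [0, 1]")
    agg = {k: ([], []) for k in
           ("gamma_power", "rate_pyramidal", "rate_pvi", "cv_isi")}
    for rp in rp_values:
        cfg = dataclasses.replace(config, rp_ie=float(rp))
        df = run_trials(cfg, n_trials, master_seed, band=band, mode=mode)
        for k, (means, sems) in agg.items():
            means.append(float(np.nanmean(df[k])))
            sems.append(_sem(df[k].to_numpy()))
    return SweepResult(
        parameter="rp_ie", values=rp_values,
        gamma_power=np.array(agg["gamma_power"][0]),
        gamma_power_sem=np.array(agg["gamma_power"][1]),
        rate_pyramidal=np.array(agg["rate_pyramidal"][0]),
        rate_pyramidal_sem=np.array(agg["rate_pyramidal"][1]),
        rate_pvi=np.array(agg["rate_pvi"][0]),
        rate_pvi_sem=np.array(agg["rate_pvi"][1]),
        cv_isi=np.array(agg["cv_isi"][0]),
        cv_isi_sem=np.array(agg["cv_isi"][1]),
        n_trials=n_trials, master_seed=master_seed,
    )


def detect_nadir(values: np.ndarray, powers: np.ndarray,
                 tolerance: float = 0.05) -> NadirEstimate:
    """Plateau onset of a power curve sampled over ascending parameter values.

    Onset = the largest parameter value v such that every power at or below v
    is within ``tolerance`` x (max - min) of the curve minimum. A constant
    curve is flagged degenerate with onset at the largest value; a curve whose
    first point already exceeds the tolerance yields the smallest value,
    flagged.
    """
    values = np.asarray(values, dtype=float)
    powers = np.asarray(powers, dtype=float)
    if values.size != powers.size or values.size < 2:
        raise ValueError("need matched values/powers with >= 2 points")
    if np.any(np.diff(values) <= 0):
        raise ValueError("sweep values must be strictly ascending")
    rng = powers.max() - powers.min()
    if rng == 0:
        return NadirEstimate(onset=float(values[-1]), tolerance=tolerance,
                             degenerate=True)
    near_min = powers <= powers.min() + tolerance * rng
    onset_idx = -1
    for i in range(values.size):
        if near_min[: i + 1].all():
            onset_idx = i
        else:
            break
    if onset_idx < 0:
        return NadirEstimate(onset=float(values[0]), tolerance=tolerance,
                             degenerate=True)
    return NadirEstimate(onset=float(values[onset_idx]), tolerance=tolerance)


def synergy_analysis(config: NetworkConfig, weights=None, n_trials: int = 20,
                     master_seed: int = 0, band: tuple = GAMMA_BAND,
                     mode: str = "peak") -> SynergyResult:
    """Gamma-power reduction from lowering G_I->E alone, RP_I->E alone, their
    sum (additive expectation), and both together.

    ``weights`` are percentages of the baseline parameter values, descending
    from 100%. The crossover is the largest percentage lowering (100 - w) such
    that the joint reduction exceeds the additive expectation at every sampled
    weight in [w, 100).
    """
    if weights is None:
        weights = np.arange(100.0, 69.9, -2.5)
    weights = np.asarray(weights, dtype=float)
    if weights[0] != 100.0:
        raise ValueError("weight grid must start at the 100% baseline")
    if np.any(np.diff(weights) >= 0):
        raise ValueError("weights must be strictly descending")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive percentages")

    g0 = config.syn.g_ie
    rp0 = config.rp_ie

    def power_at(g: float, rp: float) -> tuple[float, float]:
        syn = dataclasses.replace(config.syn, g_ie=g)
        cfg = dataclasses.replace(config, syn=syn, rp_ie=min(rp, 1.0))
        df = run_trials(cfg, n_trials, master_seed, band=band, mode=mode)
        return float(df.gamma_power.mean()), _sem(df.gamma_power.to_numpy())

    baseline, base_sem = power_at(g0, rp0)
    red_g, red_rp, red_joint = [0.0], [0.0], [0.0]
    sem_g, sem_rp, sem_joint = [0.0], [0.0], [0.0]
    for w in weights[1:]:
        f = w / 100.0
        for reds, sems, args in ((red_g, sem_g, (g0 * f, rp0)),
                                 (red_rp, sem_rp, (g0, rp0 * f)),
                                 (red_joint, sem_joint, (g0 * f, rp0 * f))):
            p, s = power_at(*args)
            reds.append(max(baseline - p, 0.0))
            sems.append(s)
    red_g = np.array(red_g)
    red_rp = np.array(red_rp)
    red_joint = np.array(red_joint)
    expected = red_g + red_rp

    # Contiguous run from the baseline where the joint curve is not
    # meaningfully below the additive expectation. Near-baseline points have
    # ~zero true reduction and the largest relative sampling noise, so a
    # deficit within 2 SEM of (joint - expected) counts as a tie and does not
    # end the run. The crossover is the largest lowering in that run at which
    # the joint reduction strictly exceeds the expectation.
    sem_diff = np.sqrt(np.array(sem_g) ** 2 + np.array(sem_rp) ** 2
                       + np.array(sem_joint) ** 2 + base_sem ** 2)
    crossover = 0.0
    for i in range(1, weights.size):
        if red_joint[i] < expected[i] - 2.0 * sem_diff[i]:
            break
        if red_joint[i] > expected[i]:
            crossover = 100.0 - weights[i]
    return SynergyResult(
        weights=weights, reduction_g=red_g, reduction_rp=red_rp,
        expected=expected, joint=red_joint, baseline_power=baseline,
        crossover_percent=float(crossover), n_trials=n_trials,
        master_seed=master_seed,
    )
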