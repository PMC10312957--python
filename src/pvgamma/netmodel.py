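"""Quadratic integrate-and-fire network of pyramidal cells and PVIs.

80 regular-spiking pyramidal neurons and 20 fast-spiking PVIs, all-to-all
connected without self-connections. Excitatory synapses carry AMPA and NMDA
conductances (NMDA with a sigmoidal magnesium block), inhibitory synapses
carry GABA conductance. PVI->pyramidal transmission is gated by an
independent Bernoulli release draw per (presynaptic spike, pyramidal target);
PVI->PVI synapses always transmit.

Membrane dynamics (Euler-Maruyama):

    dv/dt = (v - v_rest)(v - v_thresh) / (tau_m * (v_thresh - v_rest))
            + (I_syn + I_appl) / C + noise

with a spike recorded when v crosses ``v_peak``, reset to ``v_reset`` and an
absolute refractory period. Synaptic gates are difference-of-exponentials
(fast rise, slower decay), incremented by one per transmitted presynaptic
spike and normalized by the presynaptic population size.

The integrator is JIT-compiled with numba; one 2 s trial at dt = 0.05 ms runs
in well under a second.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "NeuronParams",
    "SynapticConductances",
    "NetworkConfig",
    "SimResult",
    "SimulationError",
    "simulate_trial",
    "bernoulli_release",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class NeuronParams:
    tau_m: float  # ms, linearized membrane time constant at rest
    v_rest: float  # mV
    v_thresh: float  # mV, unstable fixed point of the quadratic nullcline
    v_peak: float  # mV, spike cutoff
    v_reset: float  # mV
    t_ref: float  # ms
    capacitance: float = 1.0  # current-scaling constant (model units)

    def validate(self) -> None:
        if not self.v_reset < self.v_thresh < self.v_peak:
            raise ValueError("need v_reset < v_thresh < v_peak")
        if self.tau_m <= 0 or self.capacitance <= 0 or self.t_ref < 0:
            raise ValueError("tau_m, capacitance must be > 0 and t_ref >= 0")
        if not self.v_rest < self.v_thresh:
            raise ValueError("need v_rest < v_thresh")


# Default parameters place the deterministic network in a PING regime whose
# stability margin sits just above the baseline inhibition G_I->E = 0.7: the
# rhythm collapses when the effective inhibition (G x RP) falls ~15-30% below
# baseline. The capacitance fixes the overall current scale so that the
# collapse midpoint lands at ~84% of baseline in these units.
_CAPACITANCE = 9.1


def _default_exc() -> NeuronParams:
    return NeuronParams(tau_m=10.0, v_rest=-65.0, v_thresh=-50.0,
                        v_peak=20.0, v_reset=-62.0, t_ref=2.0,
                        capacitance=_CAPACITANCE)


def _default_inh() -> NeuronParams:
    return NeuronParams(tau_m=8.0, v_rest=-63.0, v_thresh=-50.0,
                        v_peak=20.0, v_reset=-60.0, t_ref=1.0,
                        capacitance=_CAPACITANCE)


@dataclass
class SynapticConductances:
    """Population-level maximal conductances (already summed over the
    presynaptic population; per-synapse strength is G / n_presyn)."""

    g_ee: float = 0.182  # AMPA onto pyramidal
    g_ne: float = 0.091  # NMDA onto pyramidal
    g_ei: float = 7.28  # AMPA onto PVI
    g_ni: float = 0.091  # NMDA onto PVI
    g_ie: float = 0.7  # GABA onto pyramidal (paired with release probability)
    g_ii: float = 0.91  # GABA onto PVI
    ampa_rise: float = 0.5
    ampa_decay: float = 2.0
    nmda_rise: float = 2.0
    nmda_decay: float = 100.0
    gaba_rise: float = 0.5
    gaba_decay: float = 6.5
    e_exc: float = 0.0  # mV, excitatory reversal
    e_inh: float = -70.0  # mV, inhibitory reversal

    def validate(self) -> None:
        for name in ("g_ee", "g_ne", "g_ei", "g_ni", "g_ie", "g_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for rec in ("ampa", "nmda", "gaba"):
            rise, decay = getattr(self, f"{rec}_rise"), getattr(self, f"{rec}_decay")
            if not 0 < rise < decay:
                raise ValueError(f"{rec}: need 0 < rise < decay")


@dataclass
class NetworkConfig:
    n_exc: int = 80
    n_inh: int = 20
    exc: NeuronParams = field(default_factory=_default_exc)
    inh: NeuronParams = field(default_factory=_default_inh)
    syn: SynapticConductances = field(default_factory=SynapticConductances)
    rp_ie: float = 1.0  # release probability on PVI->pyramidal synapses
    i_appl_mean: float = 6.825  # external drive to pyramidal cells (model units)
    i_appl_spread: float = 0.455  # heterogeneity SD across pyramidal cells
    i_appl_inh: float = 0.0
    noise_sd: float = 0.2  # voltage noise amplitude, mV / sqrt(ms)
    noise_sd_inh: float = 0.2
    dt_ms: float = 0.05
    duration_ms: float = 3000.0
    transient_ms: float = 500.0
    release_mode: str = "per_target"  # or "global": one draw per PVI spike
    psd_include_nmda: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_exc < 1 or self.n_inh < 1:
            raise ValueError("need at least one neuron per population")
        if not 0.0 <= self.rp_ie <= 1.0:
            raise ValueError(f"release probability {self.rp_ie} outside [0, 1]")
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if not 0 <= self.transient_ms < self.duration_ms:
            raise ValueError("need 0 <= transient < duration")
        if self.release_mode not in ("per_target", "global"):
            raise ValueError(f"unknown release_mode {self.release_mode!r}")
        self.exc.validate()
        self.inh.validate()
        self.syn.validate()

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "exc" in d and isinstance(d["exc"], dict):
            d["exc"] = NeuronParams(**d["exc"])
        if "inh" in d and isinstance(d["inh"], dict):
            d["inh"] = NeuronParams(**d["inh"])
        if "syn" in d and isinstance(d["syn"], dict):
            d["syn"] = SynapticConductances(**d["syn"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "NetworkConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class SimResult:
    spike_times: np.ndarray  # ms, post-transient only
    spike_ids: np.ndarray  # 0..n_exc-1 pyramidal, n_exc.. PVI
    exc_current: np.ndarray  # summed excitatory current into pyramidal cells
    dt_ms: float
    duration_ms: float
    transient_ms: float
    n_exc: int
    n_inh: int
    seed: int

    def spike_trains(self, population: str) -> list[np.ndarray]:
        if population == "E":
            ids = range(self.n_exc)
        elif population == "I":
            ids = range(self.n_exc, self.n_exc + self.n_inh)
        else:
            raise ValueError("population must be 'E' or 'I'")
        return [self.spike_times[self.spike_ids == i] for i in ids]


def bernoulli_release(n_events: int, rp: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli transmission mask for (spike, target) events."""
    if not 0.0 <= rp <= 1.0:
        raise ValueError(f"release probability {rp} outside [0, 1]")
    return rng.random(n_events) < rp


def _peak_norm(rise: float, decay: float) -> float:
    """Increment scaling making a single spike's gate transient peak at 1."""
    t_star = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = rise / (rise - decay) * (np.exp(-t_star / rise) - np.exp(-t_star / decay))
    return 1.0 / peak


@njit(cache=True)
def _simulate_core(dt, n_steps, rec_start,
                   n_e, n_i,
                   # neuron params: [tau, vr, vt, vpeak, vreset, tref, C]
                   pe, pi,
                   g_ee, g_ne, g_ei, g_ni, g_ie, g_ii,
                   tr_a, td_a, tr_n, td_n, tr_g, td_g,
                   inc_a, inc_n, inc_g,
                   e_exc, e_inh,
                   rp, per_target,
                   i_appl_e, i_appl_i,
                   noise_e, noise_i,  # pre-scaled additive voltage noise
                   v0_e, v0_i,
                   release_seed, include_nmda,
                   max_spikes):
    np.random.seed(release_seed)

    tau_e, vr_e, vt_e, vpk_e, vrs_e, ref_e, c_e = pe
    tau_i, vr_i, vt_i, vpk_i, vrs_i, ref_i, c_i = pi
    dv_e = vt_e - vr_e
    dv_i = vt_i - vr_i

    vE = v0_e.copy()
    vI = v0_i.copy()
    refE = np.zeros(n_e)
    refI = np.zeros(n_i)
    xA = np.zeros(n_e); sA = np.zeros(n_e)
    xN = np.zeros(n_e); sN = np.zeros(n_e)
    xGI = np.zeros(n_i); sGI = np.zeros(n_i)
    xGE = np.zeros(n_e); sGE = np.zeros(n_e)

    spike_t = np.empty(max_spikes)
    spike_id = np.empty(max_spikes, dtype=np.int32)
    n_spk = 0
    rec = np.zeros(n_steps - rec_start)

    inv_ne1 = 1.0 / max(n_e - 1, 1)
    inv_ne = 1.0 / n_e
    inv_ni1 = 1.0 / max(n_i - 1, 1)
    inv_ni = 1.0 / n_i

    for step in range(n_steps):
        t = (step + 1) * dt

        # gate decay (Euler)
        for j in range(n_e):
            sA[j] += dt * (xA[j] - sA[j]) / td_a
            xA[j] -= dt * xA[j] / tr_a
            sN[j] += dt * (xN[j] - sN[j]) / td_n
            xN[j] -= dt * xN[j] / tr_n
            sGE[j] += dt * (xGE[j] - sGE[j]) / td_g
            xGE[j] -= dt * xGE[j] / tr_g
        for i in range(n_i):
            sGI[i] += dt * (xGI[i] - sGI[i]) / td_g
            xGI[i] -= dt * xGI[i] / tr_g

        TA = sA.sum()
        TN = sN.sum()
        TGI = sGI.sum()

        # pyramidal population
        rec_val = 0.0
        for j in range(n_e):
            v = vE[j]
            mg = 1.0 / (1.0 + 0.28 * np.exp(-0.062 * v))
            g_a = g_ee * (TA - sA[j]) * inv_ne1
            g_n = g_ne * mg * (TN - sN[j]) * inv_ne1
            i_exc = (g_a + g_n) * (e_exc - v)
            if include_nmda:
                rec_val += i_exc
            else:
                rec_val += g_a * (e_exc - v)
            i_inh = g_ie * sGE[j] * inv_ni * (e_inh - v)
            if refE[j] > 0.0:
                refE[j] -= dt
                vE[j] = vrs_e
            else:
                dv = dt * ((v - vr_e) * (v - vt_e) / (tau_e * dv_e)
                           + (i_exc + i_inh + i_appl_e[j]) / c_e)
                v = v + dv + noise_e[step, j]
                if v >= vpk_e:
                    if n_spk >= max_spikes:
                        return spike_t, spike_id, rec, -1
                    spike_t[n_spk] = t
                    spike_id[n_spk] = j
                    n_spk += 1
                    xA[j] += inc_a
                    xN[j] += inc_n
                    v = vrs_e
                    refE[j] = ref_e
                elif v < -150.0:
                    return spike_t, spike_id, rec, -2
                vE[j] = v
        if step >= rec_start:
            rec[step - rec_start] = rec_val

        # PVI population
        for i in range(n_i):
            v = vI[i]
            mg = 1.0 / (1.0 + 0.28 * np.exp(-0.062 * v))
            i_exc = (g_ei * TA * inv_ne
                     + g_ni * mg * TN * inv_ne) * (e_exc - v)
            i_inh = g_ii * (TGI - sGI[i]) * inv_ni1 * (e_inh - v)
            if refI[i] > 0.0:
                refI[i] -= dt
                vI[i] = vrs_i
            else:
                dv = dt * ((v - vr_i) * (v - vt_i) / (tau_i * dv_i)
                           + (i_exc + i_inh + i_appl_i[i]) / c_i)
                v = v + dv + noise_i[step, i]
                if v >= vpk_i:
                    if n_spk >= max_spikes:
                        return spike_t, spike_id, rec, -1
                    spike_t[n_spk] = t
                    spike_id[n_spk] = n_e + i
                    n_spk += 1
                    xGI[i] += inc_g
                    # Bernoulli release onto each pyramidal target
                    if per_target:
                        for j in range(n_e):
                            if np.random.random() < rp:
                                xGE[j] += inc_g
                    else:
                        if np.random.random() < rp:
                            for j in range(n_e):
                                xGE[j] += inc_g
                    v = vrs_i
                    refI[i] = ref_i
                elif v < -150.0:
                    return spike_t, spike_id, rec, -2
                vI[i] = v
    return spike_t[:n_spk], spike_id[:n_spk], rec, 0


def simulate_trial(config: NetworkConfig, seed: int | None = None) -> SimResult:
    """Integrate one trial of the network and return its SimResult.

    The master seed spawns three independent streams (initial conditions,
    drive noise, release draws), so changing the release probability does not
    perturb the shared noise realization.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    ss_init, ss_noise, ss_rel = ss.spawn(3)
    rng_init = np.random.default_rng(ss_init)
    rng_noise = np.random.default_rng(ss_noise)
    release_seed = int(ss_rel.generate_state(1)[0] % np.iinfo(np.int32).max)

    n_steps = int(round(config.duration_ms / config.dt_ms))
    rec_start = int(round(config.transient_ms / config.dt_ms))
    n_e, n_i = config.n_exc, config.n_inh

    pe = np.array([config.exc.tau_m, config.exc.v_rest, config.exc.v_thresh,
                   config.exc.v_peak, config.exc.v_reset, config.exc.t_ref,
                   config.exc.capacitance])
    pi = np.array([config.inh.tau_m, config.inh.v_rest, config.inh.v_thresh,
                   config.inh.v_peak, config.inh.v_reset, config.inh.t_ref,
                   config.inh.capacitance])

    i_appl_e = rng_init.normal(config.i_appl_mean, config.i_appl_spread, n_e)
    i_appl_i = np.full(n_i, config.i_appl_inh)
    v0_e = rng_init.uniform(config.exc.v_rest, config.exc.v_thresh, n_e)
    v0_i = rng_init.uniform(config.inh.v_rest, config.inh.v_thresh, n_i)

    sqdt = np.sqrt(config.dt_ms)
    noise_e = (config.noise_sd * sqdt
               * rng_noise.standard_normal((n_steps, n_e)))
    noise_i = (config.noise_sd_inh * sqdt
               * rng_noise.standard_normal((n_steps, n_i)))

    # cap assumes < 250 Hz mean population rate
    max_spikes = int((n_e + n_i) * config.duration_ms / 1000.0 * 250) + 1000

    s = config.syn
    spike_t, spike_id, rec, status = _simulate_core(
        config.dt_ms, n_steps, rec_start, n_e, n_i, pe, pi,
        s.g_ee, s.g_ne, s.g_ei, s.g_ni, s.g_ie, s.g_ii,
        s.ampa_rise, s.ampa_decay, s.nmda_rise, s.nmda_decay,
        s.gaba_rise, s.gaba_decay,
        _peak_norm(s.ampa_rise, s.ampa_decay),
        _peak_norm(s.nmda_rise, s.nmda_decay),
        _peak_norm(s.gaba_rise, s.gaba_decay),
        s.e_exc, s.e_inh,
        config.rp_ie, config.release_mode == "per_target",
        i_appl_e, i_appl_i, noise_e, noise_i, v0_e, v0_i,
        release_seed, config.psd_include_nmda, max_spikes,
    )
    if status == -1:
        raise SimulationError("spike buffer overflow: runaway network activity")
    if status == -2:
        raise SimulationError(
            f"numerical blow-up (|v| > 150 mV) at dt={config.dt_ms} ms")

    keep = spike_t > config.transient_ms
    return SimResult(
        spike_times=spike_t[keep], spike_ids=spike_id[keep],
        exc_current=rec, dt_ms=config.dt_ms, duration_ms=config.duration_ms,
        transient_ms=config.transient_ms, n_exc=n_e, n_inh=n_i, seed=seed,
    )
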