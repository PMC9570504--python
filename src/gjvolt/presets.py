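"""Published gating parameters of Cx46, Cx50 and their NT-domain variants.

Boltzmann parameters (Gmin, V0 in mV, A in 1/mV, per Vj polarity) and slope
unitary conductances (pS) are the reported values for homotypic gap
junctions of the two lens connexins and the eight amino-terminal point
variants (residues 10, 13, 14, 15 exchanged between Cx46 and Cx50).

Two conflicting values were reported for the Cx46 A14V unitary conductance
(158 pS in the text, 94 pS in a figure caption); both are available, as
``Cx46-A14V`` and ``Cx46-A14V-alt``, and neither is adjudicated here.

Kinetic parameters (k0, p_fullclose) are not experimentally constrained;
they are calibration choices of the simulator (see docs/methods.md): k0 is
2/s in the macroscopic regime and 0.5/s in the single-channel regime, where
slower gating leaves the first ~2 s of a step dominated by the initial open
level, as in published single-channel records.
"""

from __future__ import annotations

from .sim import GatingModel, RecordingNoise, StepProtocol

__all__ = [
    "BOLTZMANN",
    "GAMMA_PS",
    "PRESET_NAMES",
    "get_preset",
    "macro_protocol",
    "single_channel_protocol",
    "default_noise",
]

# name -> polarity -> (Gmin, V0 [mV], A [1/mV])
BOLTZMANN: dict[str, dict[str, tuple[float, float, float]]] = {
    "Cx46": {"+": (0.24, 39.1, 0.09), "-": (0.23, 38.6, 0.11)},
    "Cx46-L10I": {"+": (0.22, 56.1, 0.06), "-": (0.22, 56.1, 0.06)},  # (-) not fit
    "Cx46-N13E": {"+": (0.17, 33.6, 0.16), "-": (0.17, 32.9, 0.15)},
    "Cx46-A14V": {"+": (0.24, 35.1, 0.19), "-": (0.15, 37.1, 0.14)},
    "Cx46-Q15N": {"+": (0.27, 37.3, 0.06), "-": (0.25, 32.3, 0.09)},
    "Cx50": {"+": (0.20, 41.5, 0.07), "-": (0.25, 43.6, 0.07)},
    "Cx50-I10L": {"+": (0.22, 33.0, 0.11), "-": (0.22, 33.7, 0.17)},
    "Cx50-E13N": {"+": (0.16, 33.2, 0.10), "-": (0.29, 30.0, 0.10)},
    "Cx50-V14A": {"+": (0.23, 45.4, 0.13), "-": (0.23, 37.8, 0.14)},
    "Cx50-N15Q": {"+": (0.23, 37.1, 0.08), "-": (0.18, 30.6, 0.09)},
}

# slope unitary conductance presets (pS)
GAMMA_PS: dict[str, float] = {
    "Cx46": 192.0,
    "Cx46-L10I": 188.0,
    "Cx46-N13E": 93.0,
    "Cx46-A14V": 158.0,
    "Cx46-A14V-alt": 94.0,
    "Cx46-Q15N": 187.0,
    "Cx50": 220.0,
    "Cx50-I10L": 204.0,
    "Cx50-E13N": 193.0,
    "Cx50-V14A": 234.0,
    "Cx50-N15Q": 162.0,
}

PRESET_NAMES = tuple(GAMMA_PS)

_K0 = {"macro": 2.0, "single": 0.5}


def get_preset(
    name: str, regime: str = "macro", p_fullclose: float = 0.2
) -> GatingModel:
    """Gating model for a named construct.

    ``regime`` selects the kinetic rate scale: "macro" (k0 = 2/s) for
    many-channel macroscopic simulations, "single" (k0 = 0.5/s) for unitary
    recordings.
    """
    if regime not in _K0:
        raise ValueError(f"unknown regime {name!r}; expected 'macro' or 'single'")
    boltz_name = name[:-4] if name.endswith("-alt") else name
    if name not in GAMMA_PS or boltz_name not in BOLTZMANN:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(GAMMA_PS)}")
    gmin_pos, v0_pos, a_pos = BOLTZMANN[boltz_name]["+"]
    _, v0_neg, a_neg = BOLTZMANN[boltz_name]["-"]
    gamma_main = GAMMA_PS[name]
    return GatingModel(
        v0_pos=v0_pos,
        v0_neg=v0_neg,
        a_pos=a_pos,
        a_neg=a_neg,
        k0=_K0[regime],
        gamma_main=gamma_main,
        gamma_res=gmin_pos * gamma_main,
        p_fullclose=p_fullclose,
    )


def macro_protocol(
    step_duration: float = 5.0, sampling_rate: float = 10_000.0
) -> StepProtocol:
    """The +/-20..100 mV, 20 mV increment step protocol."""
    steps = [v for v in range(20, 101, 20)] + [-v for v in range(20, 101, 20)]
    return StepProtocol(
        vj_steps=tuple(float(v) for v in steps),
        step_duration=step_duration,
        sampling_rate=sampling_rate,
        pre_step_baseline=0.5,
    )


def single_channel_protocol(
    step_duration: float = 2.5,
    sampling_rate: float = 10_000.0,
    vj_steps: tuple[float, ...] = (40.0, 60.0, 80.0, -40.0, -60.0, -80.0),
    sweeps: int = 1,
) -> StepProtocol:
    """Step protocol for unitary-current recordings (histogram window ~2 s).

    ``sweeps`` repeats the whole Vj schedule; replicate sweeps let the
    analysis reject windows in which the channel deactivated before the
    main open level was sampled.
    """
    return StepProtocol(
        vj_steps=vj_steps * sweeps,
        step_duration=step_duration,
        sampling_rate=sampling_rate,
        pre_step_baseline=0.3,
    )


def default_noise() -> RecordingNoise:
    """2 pA white noise at 10 kHz, low-passed at the 1 kHz acquisition
    cutoff (~0.9 pA r.m.s. stored; ~0.4 pA after the 200 Hz analysis
    filter)."""
    return RecordingNoise(sigma=2.0, acquisition_cutoff=1000.0)
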