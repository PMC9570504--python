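"""Shared fixtures: toy PDB builders and simulation helpers."""

from __future__ import annotations

import numpy as np
import pytest

from gjvolt.sim import GatingModel, StepProtocol, Trace


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    element: str,
    occupancy: float = 1.0,
    altloc: str = " ",
) -> str:
    """One fixed-column PDB v3.3 ATOM record."""
    return (
        f"ATOM  {serial:>5} {name:<4}{altloc}{resname:<3} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}          "
        f"{element:>2}"
    )


def write_pdb(path, lines: list[str]) -> str:
    path.write_text("\n".join(lines) + "\nEND\n")
    return str(path)


@pytest.fixture
def toy_pdb(tmp_path):
    """Factory writing a toy PDB from (serial, name, resname, chain, resnum,
    x, y, z, element[, occupancy, altloc]) tuples."""

    def build(atoms, filename="toy.pdb"):
        lines = [pdb_atom_line(*a) for a in atoms]
        return write_pdb(tmp_path / filename, lines)

    return build


def flat_trace(
    value: float,
    vj: float = 40.0,
    duration: float = 1.0,
    sampling_rate: float = 10_000.0,
    baseline_s: float = 0.0,
) -> Trace:
    """Noise-free constant-current trace (baseline samples are zero)."""
    n_base = int(round(baseline_s * sampling_rate))
    n_step = int(round(duration * sampling_rate))
    samples = np.concatenate([np.zeros(n_base), np.full(n_step, value)])
    return Trace(
        vj=vj,
        samples=samples,
        sampling_rate=sampling_rate,
        baseline_s=baseline_s,
        step_s=duration,
        metadata={"construct": "flat", "seed": 0, "n_channels": 1},
    )


def symmetric_model(
    v0: float = 40.0,
    a: float = 0.1,
    k0: float = 2.0,
    gamma_main: float = 192.0,
    g_min: float = 0.24,
    p_fullclose: float = 0.2,
) -> GatingModel:
    return GatingModel(
        v0_pos=v0,
        v0_neg=v0,
        a_pos=a,
        a_neg=a,
        k0=k0,
        gamma_main=gamma_main,
        gamma_res=g_min * gamma_main,
        p_fullclose=p_fullclose,
    )


def one_step(
    vj: float,
    duration: float,
    sampling_rate: float = 10_000.0,
    baseline_s: float = 0.0,
) -> StepProtocol:
    return StepProtocol(
        vj_steps=(vj,),
        step_duration=duration,
        sampling_rate=sampling_rate,
        pre_step_baseline=baseline_s,
    )
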