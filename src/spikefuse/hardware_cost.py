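"""Analytic cost model for crossbar neuromorphic chips.

Power decomposes as P = P_leak + P_idle * f_clk + E_SOP * r_SOP; the last
term is the dynamic power.  Each synaptic operation (SOP) takes
``cycles_per_sop`` clock cycles, so a core saturates at
r_SOP = f_clk / cycles_per_sop.  On a crossbar core every incoming spike
addresses all neurons in the core, so a spike costs ``neurons_per_core``
total SOPs of which only the connected fan-out is useful; single-SOP AER
remap events (used when feeding a fusion head) carry no dummy overhead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from spikefuse.aer_io import ValidationError
from spikefuse.snn_core import DenseLayer, NetworkSpec


@dataclass(frozen=True)
class ChipModel:
    """Static description of one modelled chip."""

    name: str
    neurons_per_core: int
    n_cores: int
    e_sop_pj: float            # energy per SOP
    f_clk_hz: float
    cycles_per_sop: int = 2
    p_leak_mw: float = 0.0     # static terms default to 0 (dynamic-only model)
    p_idle_mw_per_mhz: float = 0.0
    crossbar: bool = True

    def __post_init__(self) -> None:
        if self.e_sop_pj <= 0 or self.f_clk_hz <= 0:
            raise ValidationError("E_SOP and f_clk must be positive")

    @property
    def total_neurons(self) -> int:
        return self.neurons_per_core * self.n_cores

    @property
    def max_sop_rate(self) -> float:
        """Per-core saturation SOP rate, f_clk / cycles_per_sop."""
        return self.f_clk_hz / self.cycles_per_sop

    def static_power_mw(self) -> float:
        return self.p_leak_mw + self.p_idle_mw_per_mhz * self.f_clk_hz / 1e6


# low-power operating points at minimum supply voltage
ODIN = ChipModel("odin", neurons_per_core=256, n_cores=1, e_sop_pj=8.4, f_clk_hz=75e6)
MORPHIC = ChipModel("morphic", neurons_per_core=512, n_cores=4, e_sop_pj=30.0, f_clk_hz=55e6)

CHIP_PRESETS = {"odin": ODIN, "morphic": MORPHIC}

# Loihi per-inference energy/time are measured quantities, not modelled;
# they are stored for report assembly and EDP computation only.
LOIHI_MEASURED = {
    "emg": {"energy_uj": 173.2, "time_ms": 5.89},
    "dvs": {"energy_uj": 815.3, "time_ms": 6.64},
    "fusion": {"energy_uj": 1104.5, "time_ms": 7.75},
}


@dataclass
class SopEntry:
    """Spikes entering one target layer on one core."""

    n_spikes: int
    fanout: int
    core: int = 0
    single_sop: bool = False  # AER remap: one SOP per connected synapse


@dataclass
class SopCount:
    total: int
    useful: int
    per_core: np.ndarray  # total SOPs processed by each core

    def __iter__(self):
        return iter((self.total, self.useful))


@dataclass
class CostReport:
    """Cost of one inference on one modelled chip."""

    chip: str
    sop_total: int
    sop_useful: int
    dynamic_power_mw: float
    energy_uj: float
    processing_time_ms: float
    edp_uj_s: float
    utilization_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sop_useful > self.sop_total:
            raise ValidationError("useful SOPs cannot exceed total SOPs")


# ---------------------------------------------------------------------------
# SOP accounting
# ---------------------------------------------------------------------------

def count_sops(entries: Iterable[SopEntry], chip: ChipModel) -> SopCount:
    """Crossbar SOP totals: every spike entering a core is processed by all
    of its neurons; only the connected fan-out is useful.

    Non-crossbar chips (and single-SOP remap entries) cost exactly the
    fan-out.
    """
    per_core = np.zeros(chip.n_cores, dtype=np.int64)
    total = useful = 0
    for e in entries:
        if e.fanout > chip.neurons_per_core:
            raise ValidationError(
                f"fan-out {e.fanout} exceeds core size {chip.neurons_per_core}")
        if not 0 <= e.core < chip.n_cores:
            raise ValidationError(f"core index {e.core} out of range for {chip.name}")
        cost = e.fanout if (e.single_sop or not chip.crossbar) else chip.neurons_per_core
        total += e.n_spikes * cost
        useful += e.n_spikes * e.fanout
        per_core[e.core] += e.n_spikes * cost
    return SopCount(total, useful, per_core)


def sop_entries_for(spec: NetworkSpec, layer_in_spikes: Sequence[int],
                    fusion_remap: bool = False) -> list[SopEntry]:
    """Build SOP entries for a network mapped core-per-branch.

    ``layer_in_spikes`` lists, for each dense layer in traversal order
    (branches first, then head layers), the number of spikes entering it.
    With ``fusion_remap`` the final head layer is fed by single-SOP AER
    events, avoiding the crossbar dummy overhead.
    """
    dense: list[tuple[int, DenseLayer]] = []
    if spec.branches:
        for core, b in enumerate(spec.branches):
            for lyr in b.layers:
                if isinstance(lyr, DenseLayer):
                    dense.append((core if len(spec.branches) > 1 else 0, lyr))
    for lyr in spec.layers:
        if isinstance(lyr, DenseLayer):
            dense.append((0, lyr))
    if len(dense) != len(layer_in_spikes):
        raise ValidationError(
            f"{spec.name}: expected {len(dense)} spike counts, got {len(layer_in_spikes)}")
    entries = []
    n_head = sum(isinstance(l, DenseLayer) for l in spec.layers)
    for i, ((core, lyr), n) in enumerate(zip(dense, layer_in_spikes)):
        is_head = i >= len(dense) - n_head and n_head > 0
        entries.append(SopEntry(int(n), lyr.units, core,
                                single_sop=fusion_remap and is_head))
    return entries


def fusion_sop_remap(entries: Sequence[SopEntry], head_index: int = -1) -> list[SopEntry]:
    """Mark the head entry as single-SOP AER remapped (no dummy overhead)."""
    out = [replace(e) for e in entries]
    out[head_index] = replace(out[head_index], single_sop=True)
    return out


# ---------------------------------------------------------------------------
# Power, energy, time, EDP
# ---------------------------------------------------------------------------

def dynamic_power(chip: ChipModel, r_sop: float, n_cores: int = 1) -> float:
    """Dynamic power E_SOP * r_SOP in mW, summed over ``n_cores`` active
    cores each running at per-core rate ``r_sop`` (SOP/s)."""
    if r_sop < 0:
        raise ValidationError("SOP rate must be non-negative")
    if r_sop > chip.max_sop_rate * (1 + 1e-12):
        raise ValidationError(
            f"r_SOP {r_sop:.3g} exceeds max rate f_clk/{chip.cycles_per_sop} "
            f"= {chip.max_sop_rate:.3g} SOP/s")
    if not 1 <= n_cores <= chip.n_cores:
        raise ValidationError(f"{chip.name} has {chip.n_cores} cores")
    return chip.e_sop_pj * 1e-12 * r_sop * n_cores * 1e3


def energy_and_time(chip: ChipModel, sops: SopCount) -> tuple[float, float]:
    """(energy uJ, processing time ms) for the dynamic part of an inference.

    Cores run in parallel at the max SOP rate, so time follows the
    busiest core; energy counts every SOP on every core.
    """
    energy_uj = chip.e_sop_pj * sops.total * 1e-6
    busiest = int(sops.per_core.max()) if len(sops.per_core) else 0
    time_ms = chip.cycles_per_sop * busiest / chip.f_clk_hz * 1e3
    return energy_uj, time_ms


def edp(energy_uj: float, time_ms: float) -> float:
    """Energy-delay product in uJ*s."""
    if energy_uj < 0 or time_ms < 0:
        raise ValidationError("energy and time must be non-negative")
    return energy_uj * time_ms / 1000.0


def utilization(n_neurons: int, chip: ChipModel) -> float:
    """Percentage of the chip's neuron resources used."""
    if n_neurons < 0 or n_neurons > chip.total_neurons:
        raise ValidationError(
            f"{n_neurons} neurons do not fit on {chip.name} ({chip.total_neurons})")
    return 100.0 * n_neurons / chip.total_neurons


def spec_utilization(spec: NetworkSpec, chip: ChipModel,
                     include_output: bool = True) -> float:
    """Utilization of a network's hidden (+ output) neurons on a chip.

    ``include_output=False`` models fusion configurations where the output
    layer lives on another chip.
    """
    n = spec.hidden_and_output_units()
    if not include_output:
        outs = [b.layers[-1].units for b in (spec.branches or [spec])]
        n -= sum(outs)
    return utilization(n, chip)


def cost_report(chip: ChipModel, entries: Sequence[SopEntry],
                n_neurons: Optional[int] = None) -> CostReport:
    """Assemble the full cost report for one inference trace on one chip."""
    sops = count_sops(entries, chip)
    energy_uj, time_ms = energy_and_time(chip, sops)
    active = int(np.sum(sops.per_core > 0)) or 1
    power = dynamic_power(chip, chip.max_sop_rate, n_cores=active)
    return CostReport(
        chip=chip.name, sop_total=sops.total, sop_useful=sops.useful,
        dynamic_power_mw=power, energy_uj=energy_uj,
        processing_time_ms=time_ms, edp_uj_s=edp(energy_uj, time_ms),
        utilization_pct=None if n_neurons is None else utilization(n_neurons, chip))


def loihi_report(energy_uj: float, time_ms: float) -> CostReport:
    """Report for a Loihi inference from measured energy/time inputs."""
    return CostReport(chip="loihi", sop_total=0, sop_useful=0,
                      dynamic_power_mw=energy_uj / time_ms if time_ms else 0.0,
                      energy_uj=energy_uj, processing_time_ms=time_ms,
                      edp_uj_s=edp(energy_uj, time_ms))
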