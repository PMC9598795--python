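"""Flat YAML configuration and CSV helpers.

Configuration files are flat key-value mappings whose keys match the
dataclass field names of the geometry, numerics and noise types, e.g.::

    fine_spacing: 0.00025
    convective_coefficient: 5.0
    temp_noise_sd: 0.05
    duration: 120.0

Keys are routed to whichever configuration object declares them;
unknown keys raise, so typos do not pass silently.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fast import Waveform
from .geometry import (NumericsConfig, PhantomGeometry, ProbeGeometry,
                       standard_conditions)
from .pipeline import NoiseModel, RunConfig

__all__ = ["load_config", "build_run_config", "read_waveform_csv",
           "write_waveform_csv", "write_spectrum_csv"]


def load_config(path) -> dict:
    """Read a flat key-value YAML file (empty dict for an empty file)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key-value mapping")
    return data


def _apply(cls_default, overrides: dict, used: set):
    names = {f.name for f in dataclasses.fields(cls_default)}
    kwargs = {k: v for k, v in overrides.items() if k in names}
    used.update(kwargs)
    return dataclasses.replace(cls_default, **kwargs) if kwargs else cls_default


def build_run_config(overrides: dict | None = None,
                     output_dir=None) -> tuple[RunConfig, NoiseModel]:
    """Build a RunConfig and NoiseModel from flat overrides.

    Condition-level keys (``duration``, ``burst_on_time``,
    ``burst_period``) apply to every treatment group; ``replicates`` and
    ``conditions`` (list of group names) shape the study design.
    """
    overrides = dict(overrides or {})
    used: set = set()
    probe = _apply(ProbeGeometry(), overrides, used)
    phantom = _apply(PhantomGeometry(), overrides, used)
    numerics = _apply(NumericsConfig(), overrides, used)
    noise = _apply(NoiseModel(), overrides, used)

    conds = standard_conditions()
    if "conditions" in overrides:
        names = list(overrides.pop("conditions"))
        unknown = [n for n in names if n not in conds]
        if unknown:
            raise ValueError(f"unknown condition names: {unknown}")
        conds = {n: conds[n] for n in names}
        used.add("conditions")
    cond_keys = {"duration", "burst_on_time", "burst_period"}
    cond_over = {k: float(overrides[k]) for k in cond_keys if k in overrides}
    if cond_over:
        conds = {n: dataclasses.replace(c, **cond_over)
                 for n, c in conds.items()}
        used.update(cond_over)
    replicates = int(overrides.get("replicates", 5))
    used.add("replicates")

    unknown = set(overrides) - used
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(conditions=conds, replicates=replicates, probe=probe,
                    phantom=phantom, numerics=numerics,
                    output_dir=output_dir)
    return cfg, noise


def read_waveform_csv(path) -> tuple[Waveform, Waveform]:
    """Read `time_s,voltage_V,current_A` into (voltage, current)."""
    df = pd.read_csv(path)
    missing = {"time_s", "voltage_V", "current_A"} - set(df.columns)
    if missing:
        raise ValueError(f"waveform CSV missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("waveform needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("waveform must be uniformly sampled")
    rate = 1.0 / dt[0]
    return (Waveform(rate, df["voltage_V"].to_numpy(float)),
            Waveform(rate, df["current_A"].to_numpy(float)))


def write_waveform_csv(path, voltage: Waveform, current: Waveform) -> None:
    pd.DataFrame({"time_s": voltage.time, "voltage_V": voltage.samples,
                  "current_A": current.samples}).to_csv(path, index=False)


def write_spectrum_csv(path, spectrum) -> None:
    """Write `freq_hz,Re_Z,Im_Z` for the usable peak bins."""
    z = spectrum.peak_impedance
    pd.DataFrame({"freq_hz": spectrum.peak_frequencies,
                  "Re_Z": z.real, "Im_Z": z.imag}).to_csv(path, index=False)
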