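"""Plain-text waveform files, metric reports and JSON helpers.

Waveform format: comment header lines starting ``#`` carrying the grid
timings and the amplitude scale, then one row per sample with three
whitespace-separated normalized physical-gradient components in [-1, 1]::

    # gradwave waveform v1
    # dt_us= 500
    # delta1_ms= 33
    # gap_ms= 8
    # delta2_ms= 27
    # scale_mTm= 80
    0 0 0
    ...

Rows are in the *physical* convention (no refocusing sign absorbed); the
sign profile implied by the header timings converts to the effective
convention on read.  Writing then reading then writing again is
byte-identical.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grid import TimeGrid
from .units import GAMMA_H, maxwell_from_si
from .waveform import (EffectiveWaveform, compute_btensor, compute_moment,
                       efficiency, max_amplitude, max_slew, maxwell_index)

__all__ = ["read_waveform", "write_waveform", "describe", "dump_json"]

_HEADER_KEYS = ("dt_us", "delta1_ms", "gap_ms", "delta2_ms", "scale_mTm")
_FMT = "%.12g"


class WaveformParseError(ValueError):
    """Malformed waveform file; carries the offending line number."""


def write_waveform(w: EffectiveWaveform, path, scale_mTm: float | None = None) -> None:
    """Write a waveform file (normalized physical-gradient convention)."""
    phys = w.physical
    if scale_mTm is None:
        peak = np.abs(phys).max() * 1e3
        scale_mTm = float(peak) if peak > 0 else 1.0
    rows = phys / (scale_mTm * 1e-3)
    if np.abs(rows).max() > 1.0 + 1e-9:
        raise ValueError("scale_mTm smaller than the waveform peak amplitude")
    g = w.grid
    lines = ["# gradwave waveform v1"]
    for key, val in zip(_HEADER_KEYS, (g.dt * 1e6, g.delta1 * 1e3, g.gap * 1e3,
                                       g.delta2 * 1e3, scale_mTm)):
        lines.append(f"# {key}= {_FMT % val}")
    for r in rows:
        lines.append(" ".join(_FMT % v for v in r))
    Path(path).write_text("\n".join(lines) + "\n")


def read_waveform(path, gamma: float = GAMMA_H) -> EffectiveWaveform:
    """Read a waveform file; exact inverse of :func:`write_waveform`."""
    header = {}
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key in _HEADER_KEYS:
                    try:
                        header[key] = float(val)
                    except ValueError as exc:
                        raise WaveformParseError(
                            f"line {lineno}: bad header value {val!r}") from exc
            continue
        parts = line.split()
        if len(parts) != 3:
            raise WaveformParseError(
                f"line {lineno}: expected 3 gradient components, got "
                f"{len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise WaveformParseError(
                f"line {lineno}: non-numeric sample") from exc
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise WaveformParseError(f"missing header keys: {', '.join(missing)}")
    dt = header["dt_us"] * 1e-6
    grid = TimeGrid.from_timings(header["delta1_ms"] * 1e-3,
                                 header["gap_ms"] * 1e-3,
                                 header["delta2_ms"] * 1e-3, dt)
    rows = np.asarray(rows, dtype=float)
    if rows.shape[0] != grid.n_samples:
        raise WaveformParseError(
            f"expected {grid.n_samples} sample rows for the header timings, "
            f"got {rows.shape[0]}")
    if np.abs(rows).max() > 1.0 + 1e-9:
        raise WaveformParseError("normalized samples must lie in [-1, 1]")
    phys = rows * header["scale_mTm"] * 1e-3
    g_eff = grid.sign_profile[:, None] * phys
    return EffectiveWaveform(grid=grid, g=g_eff, gamma=gamma)


def describe(w: EffectiveWaveform, gmax: float | None = None,
             max_moment_order: int = 4) -> dict:
    """Aggregate encoding metrics of a waveform as a JSON-friendly dict.

    b and its eigenvalues are reported in ms/um^2, moments in rad s^n/m
    (SI), the Maxwell index in (mT/m)^2 ms, amplitude in mT/m and slew in
    T/m/s.  ``gmax`` (T/m) sets the amplitude bound used in the efficiency
    factor; by default the waveform's own peak per-axis amplitude.
    """
    B = compute_btensor(w)
    amp = max_amplitude(w)
    gref = gmax if gmax is not None else (amp if amp > 0 else 1.0)
    eff = efficiency(w, gref)
    return {
        "b_ms_um2": B.b_ms_um2,
        "b_eigenvalues_ms_um2": [v / 1e9 for v in B.eigenvalues],
        "shape": B.shape_label,
        "moment_magnitudes": {
            f"m{n}": compute_moment(w, n).magnitude
            for n in range(max_moment_order + 1)},
        "maxwell_index": maxwell_from_si(maxwell_index(w)),
        "kappa": eff.kappa,
        "self_balanced": eff.self_balanced,
        "crusher_moment_per_m": eff.crusher_moment,
        "amplitude_max_mTm": amp * 1e3,
        "slew_max_T_m_s": max_slew(w),
        "duration_ms": w.grid.tau * 1e3,
        "delta1_ms": w.grid.delta1 * 1e3,
        "gap_ms": w.grid.gap * 1e3,
        "delta2_ms": w.grid.delta2 * 1e3,
    }


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    return obj


def dump_json(obj: dict, path) -> None:
    """Serialize a metrics dict with floats at 12 significant digits."""
    Path(path).write_text(json.dumps(_round_floats(obj), indent=2) + "\n")
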