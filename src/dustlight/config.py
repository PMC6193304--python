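"""Flat YAML configuration for the null-model simulation.

Keys map one-to-one onto :class:`~dustlight.sampling_model.ParamRanges`
fields plus run-level settings (``n_iter``, ``seed``, ``abundance_axis``).
Range fields use ``<name>_min`` / ``<name>_max`` pairs so the file stays a
flat key/value document, e.g.::

    s_min: 500
    s_max: 5000
    mu_min: 0.0
    mu_max: 3.0
    depth: 50000
    n_iter: 10000
    seed: 0
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from dustlight.sampling_model import ParamRanges

_RANGE_FIELDS = {
    "s": "s_range",
    "mu": "mu_range",
    "sigma": "sigma_range",
    "phi": "phi_range",
    "lam": "lam_range",
    "k": "k_range",
    "chi0_quantile": "chi0_quantile_range",
    "removal": "removal_range",
}
_SCALAR_FIELDS = ("depth", "pseudocount")
_RUN_DEFAULTS = {"n_iter": 10_000, "seed": 0, "abundance_axis": "living"}


def simulation_config(path=None) -> tuple[ParamRanges, dict]:
    """Load (ParamRanges, run settings) from a flat YAML file.

    With ``path=None`` returns the packaged defaults.  Unknown keys raise,
    so typos in config files fail loudly.
    """
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    known = (
        {f"{k}_min" for k in _RANGE_FIELDS}
        | {f"{k}_max" for k in _RANGE_FIELDS}
        | set(_SCALAR_FIELDS)
        | set(_RUN_DEFAULTS)
    )
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    defaults = ParamRanges()
    kwargs = {}
    for short, field_name in _RANGE_FIELDS.items():
        lo, hi = getattr(defaults, field_name)
        kwargs[field_name] = (
            raw.get(f"{short}_min", lo),
            raw.get(f"{short}_max", hi),
        )
    for name in _SCALAR_FIELDS:
        kwargs[name] = raw.get(name, getattr(defaults, name))
    run = {k: raw.get(k, v) for k, v in _RUN_DEFAULTS.items()}
    return ParamRanges(**kwargs), run


def write_default_config(path) -> None:
    """Write the packaged defaults as an editable flat YAML file."""
    defaults = ParamRanges()
    flat: dict = {}
    for short, field_name in _RANGE_FIELDS.items():
        lo, hi = getattr(defaults, field_name)
        flat[f"{short}_min"], flat[f"{short}_max"] = lo, hi
    for name in _SCALAR_FIELDS:
        flat[name] = getattr(defaults, name)
    flat.update(_RUN_DEFAULTS)
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=False))
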