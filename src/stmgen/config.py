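"""Flat key-value configuration files for the command-line interface.

A config file is a YAML mapping whose keys mirror the CLI flag names with
underscores (e.g. ``depth_db: 20``).  Values given explicitly on the
command line always override values from the file.
"""

from __future__ import annotations

from pathlib import Path

import click
import yaml

__all__ = ["load_config", "apply_config"]


def load_config(path) -> dict:
    """Load a flat YAML mapping; rejects nested structures."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a flat mapping")
    for key, value in data.items():
        if isinstance(value, (dict, set)):
            raise ValueError(f"config key {key!r} must be a scalar or list")
    return data


def apply_config(ctx: click.Context, params: dict, config_path) -> dict:
    """Merge file values under explicitly given command-line flags."""
    if config_path is None:
        return params
    cfg = load_config(config_path)
    merged = dict(params)
    for key, value in cfg.items():
        if key not in params:
            raise click.UsageError(f"unknown config key {key!r} in {config_path}")
        source = ctx.get_parameter_source(key)
        if source is not None and source.name == "COMMANDLINE":
            continue  # explicit flag wins
        if isinstance(value, list):
            value = ",".join(str(v) for v in value)
        merged[key] = value
    return merged
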