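"""YAML run configuration.

Schema (all blocks optional; defaults in parentheses):

.. code-block:: yaml

    mcmc:
      chains: 3            # (3)
      iterations: 20000    # (20000)
      thin: 10             # (10)
      burn_in: 1000        # post-thinning draws discarded (1000)
      seed: 1              # master seed, required unless seeds given
      seeds: [11, 12, 13]  # explicit per-chain seeds
      init_jitter: 0.3
    priors:
      slope_sd: 1.5
      baseline_sd: 10.0
      init_var_factor: 10.0
      rw_shape: 2.0
    model:
      s2_counts: null        # override the repeated-count estimate
      forced_off: []         # e.g. ["surv:P", "prod:A"]
      process_likelihood: normal
    data:
      counts: counts.csv
      covariates: covariates.csv
      survival: survival.csv   # optional
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .inference import MCMCConfig, ModelOptions, PriorConfig

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending field."""


@dataclass
class RunConfig:
    mcmc: MCMCConfig
    priors: PriorConfig
    options: ModelOptions
    data: dict[str, str] = field(default_factory=dict)
    raw: dict = field(default_factory=dict)


def _take(block: dict, cls, name: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(f"unknown field(s) in {name!r}: {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {name!r} block: {exc}") from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config, applying dotted-key overrides such as
    ``{"mcmc.iterations": 500}`` (command-line overrides win)."""
    raw: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        raw = loaded
    for key, val in (overrides or {}).items():
        parts = key.split(".")
        node = raw
        for p in parts[:-1]:
            node = node.setdefault(p, {})
            if not isinstance(node, dict):
                raise ConfigError(f"cannot override through non-mapping field {p!r}")
        node[parts[-1]] = val

    mcmc_block = dict(raw.get("mcmc", {}))
    model_block = dict(raw.get("model", {}))
    if "forced_off" in model_block and model_block["forced_off"] is not None:
        model_block["forced_off"] = frozenset(model_block["forced_off"])
    if model_block.get("s2_counts", "x") is None:
        model_block.pop("s2_counts")
    cfg = RunConfig(
        mcmc=_take(mcmc_block, MCMCConfig, "mcmc"),
        priors=_take(dict(raw.get("priors", {})), PriorConfig, "priors"),
        options=_take(model_block, ModelOptions, "model"),
        data={k: str(v) for k, v in dict(raw.get("data", {})).items()},
        raw=raw,
    )
    return cfg
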