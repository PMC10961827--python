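"""Run configuration: analysis thresholds with their literature defaults.

Config files are plain ``key = value`` text; unknown keys are rejected
with a suggestion, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import difflib
import json
import os
from dataclasses import dataclass, asdict, field


@dataclass
class RunConfig:
    rog_boundary_nm: float = 0.37          # folded/unfolded channel-RoG split
    sasa_boundary_nm2: float = 1.63        # stacked/exposed 3'-thymine split
    helicity_dead_zone_deg: float = 5.0    # |twist| below which helicity is
                                           # left indeterminate
    hbond_max_da_A: float = 3.5            # donor-acceptor distance cutoff
    hbond_min_dha_deg: float = 135.0       # D-H-A angle cutoff
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


_TYPES = {f: t for f, t in RunConfig.__annotations__.items()}


def load_config(path: str | None) -> RunConfig:
    """Parse a key=value config file; missing file fields keep defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in _TYPES:
                hint = difflib.get_close_matches(key, _TYPES, n=1)
                extra = f"; did you mean '{hint[0]}'?" if hint else ""
                raise ValueError(f"{path}:{ln}: unknown key '{key}'{extra}")
            typ = int if _TYPES[key] == "int" else float
            try:
                setattr(cfg, key, typ(val))
            except ValueError:
                raise ValueError(
                    f"{path}:{ln}: cannot parse '{val}' as {typ.__name__} "
                    f"for key '{key}'")
    return cfg


def write_manifest(out_dir: str, command: str, cfg: RunConfig,
                   params: dict) -> str:
    """Echo the effective configuration and parameters next to outputs."""
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "run_manifest.json")
    with open(path, "w") as fh:
        json.dump({"command": command, "config": asdict(cfg),
                   "parameters": params}, fh, indent=2, sort_keys=True,
                  default=str)
        fh.write("\n")
    return path
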