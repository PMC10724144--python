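"""Shared configuration of the analysis runs.

One mid-size world (24 x 40 cells at 0.5 deg, one 365-day year, 80 stations,
10 countries, 36% AOD missingness) is used by every numbered script; it is
generated once and cached under scratch/ so the scripts can run in any order
after 01_simulate.py, or standalone (each regenerates on a cache miss --
generation is deterministic, so results are identical either way).
"""

from __future__ import annotations

import json
import pathlib

from gaplesspm import synthworld

ROOT = pathlib.Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

WORLD_CONFIG = synthworld.WorldConfig(
    n_lat=24, n_lon=40, n_stations=80, n_countries=10, seed=42
)

#: PM scale of the lockdown-year companion world (emission-reduction stand-in).
LOCKDOWN_PM_SCALE = 0.85


def get_world(config: synthworld.WorldConfig = WORLD_CONFIG,
              name: str = "world") -> synthworld.WorldBundle:
    """Load the cached bundle, or generate and cache it."""
    path = SCRATCH / name
    if (path / "grids.nc").exists():
        try:
            bundle = synthworld.read_bundle(path)
            if bundle.config == config:
                return bundle
        except synthworld.BundleFormatError:
            pass
    bundle = synthworld.generate_world(config)
    SCRATCH.mkdir(exist_ok=True)
    synthworld.write_bundle(bundle, path)
    return bundle


def save_json(obj, name: str) -> pathlib.Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, default=float)
    return path
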