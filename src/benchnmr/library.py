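"""Shipped metabolite spin-system library.

The library is a human-editable YAML file (``data/metabolites.yaml``)
holding the proton networks of the 19-metabolite fecal panel assigned at
60 MHz, the internal standards (TSP, formate), and the two non-panel
metabolites that carry treated-group effects (succinate, taurine). Each
group records whether its shift/J was printed in the study or taken from
standard aqueous references.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .spin import SpinGroup, SpinSystem

INTERNAL_STANDARDS_MM = {"tsp": 0.5, "formate": 1.0}


def load_library(path: str | Path | None = None) -> dict[str, SpinSystem]:
    """Load spin systems keyed by metabolite name.

    With no path, the packaged default library is used.
    """
    if path is None:
        text = (resources.files("benchnmr") / "data" / "metabolites.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    systems: dict[str, SpinSystem] = {}
    for name, entry in raw.items():
        groups = [SpinGroup(float(g["shift_ppm"]), int(g["n"]))
                  for g in entry["groups"]]
        ng = len(groups)
        J = np.zeros((ng, ng))
        for a, b, j in entry.get("couplings") or []:
            J[a, b] = J[b, a] = float(j)
        systems[name] = SpinSystem(name, groups, J)
    return systems


def panel_names(path: str | Path | None = None) -> list[str]:
    """Names flagged as members of the assigned 60 MHz panel."""
    if path is None:
        text = (resources.files("benchnmr") / "data" / "metabolites.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return [n for n, e in raw.items() if e.get("panel", False)]
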