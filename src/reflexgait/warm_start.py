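"""Packaged warm-start design vector.

A controller parameter set + initial conditions that produce stable level
walking with the default model; used to seed scenario optimizations and the
closed-loop smoke tests. Produced by CMA-ES runs on the level, unloaded
scenario and stored as JSON package data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np


@dataclass(frozen=True)
class WarmStart:
    vector: np.ndarray
    meta: dict


def load_warm_start() -> WarmStart:
    text = (resources.files("reflexgait") / "config/warm_start.json").read_text()
    data = json.loads(text)
    x = np.asarray(data["x"], dtype=float)
    meta = {k: v for k, v in data.items() if k != "x"}
    return WarmStart(vector=x, meta=meta)
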