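"""Model specification files (YAML or JSON).

A specification names an alphabet, an exchangeability preset or explicit
matrix, a composition mode, and optional gamma ASRV, e.g.::

    alphabet: AA
    exchangeabilities: poisson      # jc69 | jc2 | poisson | lg | matrix
    composition:
      mode: mixture                 # single | mixture | branch
      profiles: profiles.txt        # whitespace-delimited K x c rows
      weights: uniform              # or explicit list
    asrv: {shape: 0.935, ncats: 4}
    free: [branch_lengths, alpha, weights]
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import yaml

from .alphabets import get_alphabet
from .errors import UsageError
from .models import (
    BranchComposition,
    BranchCompositionMap,
    GammaASRV,
    MixtureComposition,
    ProfileSet,
    SingleComposition,
    SubstitutionModel,
    lg_exchangeabilities,
    uniform_exchangeabilities,
)

__all__ = ["model_from_dict", "load_model_spec"]

_PRESETS = {"jc69", "jc2", "poisson", "lg"}


def _exchange(spec, c):
    ex = spec.get("exchangeabilities", "poisson")
    if isinstance(ex, str):
        if ex not in _PRESETS:
            raise UsageError(f"unknown exchangeability preset {ex!r}")
        if ex == "lg":
            return lg_exchangeabilities()[0]
        return uniform_exchangeabilities(c)
    return np.asarray(ex, dtype=float)


def _composition(spec, c, base_dir):
    comp = spec.get("composition", {"mode": "single"})
    mode = comp.get("mode", "single")
    if mode == "single":
        pi = comp.get("pi", "uniform")
        pi = np.full(c, 1.0 / c) if pi == "uniform" else np.asarray(pi, float)
        return SingleComposition(pi)
    if mode == "mixture":
        prof = comp["profiles"]
        profiles = (ProfileSet.from_file(base_dir / prof)
                    if isinstance(prof, str) else ProfileSet(np.asarray(prof)))
        w = comp.get("weights", "uniform")
        weights = (np.full(profiles.K, 1.0 / profiles.K) if w == "uniform"
                   else np.asarray(w, float))
        return MixtureComposition(profiles, weights)
    if mode == "branch":
        bmap = BranchCompositionMap(
            pool=np.asarray(comp["pool"], float),
            assignment={tuple(k.split()): v
                        for k, v in comp["assignment"].items()},
            root_index=int(comp["root_index"]),
            mode=comp.get("map_mode", "NDCH"),
        )
        return BranchComposition(bmap)
    raise UsageError(f"unknown composition mode {mode!r}")


def model_from_dict(spec: dict, base_dir=".") -> tuple:
    """Build (SubstitutionModel, free-parameter tuple) from a spec dict."""
    alphabet = get_alphabet(spec.get("alphabet", "DNA"))
    c = alphabet.size
    R = _exchange(spec, c)
    comp = _composition(spec, c, pathlib.Path(base_dir))
    asrv = spec.get("asrv")
    gamma = None if asrv is None else GammaASRV(float(asrv["shape"]),
                                                int(asrv.get("ncats", 4)))
    model = SubstitutionModel(alphabet, R, comp, gamma,
                              name=spec.get("name", ""))
    free = tuple(spec.get("free", ("branch_lengths",)))
    return model, free


def load_model_spec(path) -> tuple:
    path = pathlib.Path(path)
    text = path.read_text()
    spec = (json.loads(text) if path.suffix == ".json"
            else yaml.safe_load(text))
    return model_from_dict(spec, base_dir=path.parent)
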