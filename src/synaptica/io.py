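"""Plain-text readers/writers for pattern sets, masks, and configs.

Pattern files hold one side of a memory set: a header line ``m n M side``
followed by one line per pattern listing the sorted active indices
(0-based).  Masks and weight matrices are stored as coordinate lists with an
``m n`` header and one ``i j`` pair per line, or as dense CSV for small
nets.  Configs are JSON with strict key validation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .patterns import ParameterError, PatternSet


def save_pattern_side(path, patterns: PatternSet, side: str = "u") -> None:
    """Write one side ('u' or 'v') of a pattern set as index-list text."""
    if side not in ("u", "v"):
        raise ParameterError("side must be 'u' or 'v'")
    vecs = patterns.u if side == "u" else patterns.v
    size = patterns.m if side == "u" else patterns.n
    with open(path, "w") as fh:
        fh.write(f"{patterns.m} {patterns.n} {patterns.M} {side}\n")
        for a in vecs:
            fh.write(" ".join(str(int(i)) for i in a) + "\n")


def load_pattern_side(path):
    """Read one side of a pattern set; returns (m, n, M, side, list of arrays)."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 4:
            raise ParameterError(f"bad pattern header in {path}")
        m, n, M = int(header[0]), int(header[1]), int(header[2])
        side = header[3]
        vecs = []
        for line in fh:
            line = line.strip()
            vecs.append(np.array(sorted(int(x) for x in line.split()), dtype=np.int64)
                        if line else np.array([], dtype=np.int64))
    if len(vecs) != M:
        raise ParameterError(f"{path}: expected {M} patterns, found {len(vecs)}")
    return m, n, M, side, vecs


def load_patterns(u_path, v_path=None, k: Optional[float] = None,
                  l: Optional[float] = None) -> PatternSet:
    """Assemble a PatternSet from one (auto-association) or two side files."""
    m, n, M, _, us = load_pattern_side(u_path)
    if v_path is None:
        vs = us
    else:
        m2, n2, M2, _, vs = load_pattern_side(v_path)
        if (m2, n2, M2) != (m, n, M):
            raise ParameterError("u and v files disagree on dimensions")
    k = k if k is not None else (float(np.mean([len(a) for a in us])) if M else 1.0)
    l = l if l is not None else (float(np.mean([len(a) for a in vs])) if M else 1.0)
    return PatternSet(m=m, n=n, u=us, v=vs, k=k, l=l)


def save_matrix_coords(path, mat: np.ndarray) -> None:
    """Write a binary matrix as an ``m n`` header plus ``i j`` lines for
    nonzero entries."""
    mat = np.asarray(mat)
    with open(path, "w") as fh:
        fh.write(f"{mat.shape[0]} {mat.shape[1]}\n")
        for i, j in zip(*np.nonzero(mat)):
            fh.write(f"{i} {j}\n")


def load_matrix_coords(path) -> np.ndarray:
    with open(path) as fh:
        m, n = (int(x) for x in fh.readline().split())
        mat = np.zeros((m, n), dtype=np.uint8)
        for line in fh:
            if line.strip():
                i, j = (int(x) for x in line.split())
                mat[i, j] = 1
    return mat


# -- configs ----------------------------------------------------------------

_CONFIG_KEYS = {
    "m", "n", "k", "l", "M", "seed", "engine", "model",
    "P", "P_pot", "P_1_init", "P_1S",
    "p_c0", "p_c1", "p_e0", "p_e1", "p_d0", "p_d1", "p_g",
    "schedule", "T", "homeostasis",
    "eps", "P_eff", "P1", "target_P1", "rule",
    "t1", "tr2", "gaps", "retention_intervals", "peff1",
}

_DEFAULTS = {
    "engine": "macro", "model": "A", "seed": 0,
    "p_c0": 0.0, "p_c1": 1.0, "p_e1": 0.0, "p_d1": 0.0, "p_g": None,
    "homeostasis": "exact",
}


def parse_config(path) -> dict:
    """Load a JSON run config, rejecting unknown keys and invalid values;
    defaults are filled in explicitly so outputs can echo the full config."""
    with open(path) as fh:
        cfg = json.load(fh)
    unknown = sorted(set(cfg) - _CONFIG_KEYS)
    if unknown:
        raise ParameterError(f"unknown config keys: {', '.join(unknown)}")
    for key, val in cfg.items():
        if key.startswith("p_") and val is not None and not 0 <= val <= 1:
            raise ParameterError(f"config key {key} = {val} outside [0, 1]")
    out = dict(_DEFAULTS)
    out.update(cfg)
    return out


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- named fixture presets ---------------------------------------------------

PRESETS = {
    # spaced rehearsal of 20 memories in a 1000x1000 net, full potential connectivity
    "spaced-rehearsal": {"m": 1000, "n": 1000, "k": 50, "l": 50, "M": 20,
              "P": 0.1, "P_pot": 1.0, "P_1_init": 0.0,
              "p_e0": 0.01, "p_d0": 0.0, "model": "A",
              "schedule": [[0, 4], [100, 104], [200, 204], [300, 304]], "T": 405},
    # two-session study protocol with moderate turnover
    "two-session": {"P": 0.1, "P_pot": 0.4, "P_1_init": 0.0, "P_1S": 0.1,
              "p_e0": 0.1, "p_d0": 0.005, "model": "B",
              "schedule": [[0, 9], [30, 30]], "T": 91},
    # cortical macrocolumn: n = 1e5 neurons, filling fraction P/P_pot = 0.2
    "macrocolumn": {"m": 100000, "n": 100000, "P": 0.1, "P_pot": 0.5,
                    "eps": 0.01, "k": 50, "l": 50},
}
for _panel, (_pe, _pd) in zip("abcdef", [(0.1, 0.0001), (0.01, 0.0001), (0.001, 0.0001),
                                         (0.1, 0.001), (0.01, 0.001), (0.001, 0.001)]):
    PRESETS[f"study-grid-{_panel}"] = {
        "P": 0.1, "P_pot": 0.4, "P_1_init": 0.02, "P_1S": 0.001,
        "p_e0": _pe, "p_d0": _pd, "t1": 10, "tr2": 1, "model": "B",
        # RIs of 7, 35, 70, 350 days at one step per hour
        "retention_intervals": [168, 840, 1680, 8400],
    }


def make_fixture(kind: str, params: Optional[dict] = None, seed: int = 0) -> dict:
    """Return a config dict for a named preset (optionally overridden)."""
    if kind not in PRESETS:
        raise ParameterError(f"unknown preset {kind!r}; have {sorted(PRESETS)}")
    cfg = dict(PRESETS[kind])
    cfg["seed"] = seed
    if params:
        unknown = sorted(set(params) - _CONFIG_KEYS)
        if unknown:
            raise ParameterError(f"unknown config keys: {', '.join(unknown)}")
        cfg.update(params)
    return cfg
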