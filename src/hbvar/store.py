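"""Plain-text persistence of posterior draws.

A draw store is a directory holding one CSV per parameter per chain plus a
``manifest.json`` recording shapes, the sampler configuration and a content
hash, so a fit can be reloaded (or re-verified bit-for-bit) later.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np

from .hier_gibbs import PosteriorDraws

__all__ = ["save_draws", "load_draws"]

_STORED = ["w", "v", "alpha", "Lambda", "two_tau2", "lam1", "lam2",
           "theta_raw", "theta_v", "v_star", "w_n"]


def _digest(draws: PosteriorDraws) -> str:
    h = hashlib.sha256()
    for name in _STORED:
        for arr in draws.per_chain(name):
            h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def save_draws(draws: PosteriorDraws, path: str) -> str:
    """Write the store; returns the content hash."""
    os.makedirs(path, exist_ok=True)
    shapes = {}
    for name in _STORED:
        for c, arr in enumerate(draws.per_chain(name)):
            shapes[f"{name}.{c}"] = list(arr.shape)
            flat = arr.reshape(arr.shape[0], -1)
            np.savetxt(os.path.join(path, f"{name}.chain{c}.csv"), flat,
                       delimiter=",", fmt="%.17g")
    manifest = {
        "R": draws.R, "p": draws.p, "N": draws.N,
        "patient_ids": draws.patient_ids,
        "sampler_config": draws.sampler_config,
        "shapes": shapes,
        "hash": _digest(draws),
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest["hash"]


def load_draws(path: str) -> PosteriorDraws:
    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    chains: dict = {name: [] for name in _STORED}
    n_chains = manifest["sampler_config"]["chains"]
    for name in _STORED:
        for c in range(n_chains):
            shape = manifest["shapes"][f"{name}.{c}"]
            flat = np.loadtxt(os.path.join(path, f"{name}.chain{c}.csv"),
                              delimiter=",", ndmin=2)
            chains[name].append(flat.reshape(shape))
    return PosteriorDraws(
        chains=chains, R=manifest["R"], p=manifest["p"], N=manifest["N"],
        patient_ids=manifest["patient_ids"],
        sampler_config=manifest["sampler_config"],
    )
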