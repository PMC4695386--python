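"""Small shared helpers: seeded substreams, smoothing, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Named, reproducible random substream derived from one master seed.

    Each distinct key tuple yields an independent generator, so stages can
    be re-run or re-ordered without perturbing one another's draws.
    """
    digest = hashlib.blake2s(
        ("/".join(str(k) for k in keys)).encode(), digest_size=8
    ).digest()
    # keep every derived entropy word below 2**31
    words = [int.from_bytes(digest[i : i + 4], "little") % (2**31) for i in (0, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *words]))


def gaussian_smooth(x: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Gaussian smoothing in units of bins; sigma 0 is the identity."""
    if sigma_bins <= 0:
        return np.asarray(x, dtype=float)
    return gaussian_filter1d(np.asarray(x, dtype=float), sigma_bins, mode="nearest")


def config_hash(cfg: object) -> str:
    """Stable short hash of a configuration object (dataclass or mapping)."""
    if is_dataclass(cfg) and not isinstance(cfg, type):
        payload = asdict(cfg)
    else:
        payload = dict(cfg)  # type: ignore[arg-type]
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def mc_pvalue(observed: float, null_scores: np.ndarray, tol: float = 1e-12) -> float:
    """Monte-Carlo p-value with the plus-one rule; never exactly zero."""
    null_scores = np.asarray(null_scores, dtype=float)
    k = int(np.sum(null_scores >= observed - tol))
    return (1.0 + k) / (null_scores.size + 1.0)
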