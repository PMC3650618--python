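"""Shared test utilities."""

import numpy as np


def segment_turns(points: np.ndarray) -> np.ndarray:
    """Per-step turn angles (degrees) along a streamline."""
    seg = np.diff(np.asarray(points, dtype=float), axis=0)
    seg /= np.linalg.norm(seg, axis=1, keepdims=True)
    d = np.clip(np.sum(seg[:-1] * seg[1:], axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(d))


def step_lengths(points: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(np.asarray(points, dtype=float), axis=0), axis=1)


def random_sparse_weights(rng, n_atoms=162, max_atoms=3):
    """Random non-negative sparse weight vector (a plausible fiber mixture)."""
    w = np.zeros(n_atoms)
    k = rng.integers(1, max_atoms + 1)
    idx = rng.choice(n_atoms, size=k, replace=False)
    w[idx] = rng.uniform(0.2, 1.0, size=k)
    return w
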