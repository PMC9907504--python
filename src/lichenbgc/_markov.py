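"""Order-2 Markov nucleotide chain, GC-calibrated, with a numba inner loop."""

from __future__ import annotations

import numpy as np
from numba import njit

# base encoding: 0=A, 1=C, 2=G, 3=T; context = 4*previous + current
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@njit(cache=True)
def _run_chain(cum: np.ndarray, start_ctx: int, u: np.ndarray) -> np.ndarray:
    n = u.shape[0]
    out = np.empty(n, dtype=np.int8)
    ctx = start_ctx
    for i in range(n):
        r = u[i]
        b = 0
        while b < 3 and r > cum[ctx, b]:
            b += 1
        out[i] = b
        ctx = (ctx % 4) * 4 + b
    return out


class MarkovSequenceModel:
    """Per-organism compositional signature.

    A seeded bias tensor fixes how GC splits into G vs C (and AT into A vs T)
    per dinucleotide context, plus small per-context GC offsets, giving each
    organism a tetranucleotide signature distinct from its mean GC. For a given
    target GC the per-context GC share is shifted globally so that the chain's
    stationary GC equals the target (solved by bisection on the 16-state
    context chain).
    """

    def __init__(self, markov_seed: int):
        rng = np.random.default_rng(markov_seed)
        self.bias = rng.gamma(5.0, size=(16, 4))
        delta = rng.normal(0.0, 0.05, size=16)
        self.delta = delta - delta.mean()

    def _probs(self, q: np.ndarray) -> np.ndarray:
        """(16, 4) transition probabilities given per-context GC share q."""
        b = self.bias
        p = np.empty((16, 4))
        at = b[:, 0] + b[:, 3]
        gc = b[:, 1] + b[:, 2]
        p[:, 0] = (1 - q) * b[:, 0] / at
        p[:, 3] = (1 - q) * b[:, 3] / at
        p[:, 1] = q * b[:, 1] / gc
        p[:, 2] = q * b[:, 2] / gc
        return p

    @staticmethod
    def _stationary(p: np.ndarray) -> np.ndarray:
        """Stationary distribution over the 16 contexts (power iteration)."""
        m = np.zeros((16, 16))
        for ctx in range(16):
            base_new = (ctx % 4) * 4
            for b in range(4):
                m[ctx, base_new + b] = p[ctx, b]
        pi = np.full(16, 1.0 / 16)
        for _ in range(200):
            nxt = pi @ m
            if np.abs(nxt - pi).max() < 1e-13:
                pi = nxt
                break
            pi = nxt
        return pi

    def calibrated_probs(self, target_gc: float) -> tuple[np.ndarray, np.ndarray]:
        """Transition probabilities whose stationary GC equals target_gc."""
        if not 0.0 < target_gc < 1.0:
            raise ValueError(f"target GC {target_gc} outside (0, 1)")

        def gc_of(shift: float) -> tuple[float, np.ndarray, np.ndarray]:
            q = np.clip(target_gc + shift + self.delta, 0.01, 0.99)
            p = self._probs(q)
            pi = self._stationary(p)
            return float(pi @ q), p, pi

        lo, hi = -0.5, 0.5
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            gc, p, pi = gc_of(mid)
            if gc < target_gc:
                lo = mid
            else:
                hi = mid
        return p, pi

    def sample(self, length: int, target_gc: float, rng: np.random.Generator) -> str:
        p, pi = self.calibrated_probs(target_gc)
        cum = np.cumsum(p, axis=1)
        cum[:, -1] = 1.0
        start_ctx = int(rng.choice(16, p=pi / pi.sum()))
        u = rng.random(length)
        codes = _run_chain(cum, start_ctx, u)
        return bytes(_BASES[codes.astype(np.intp)]).decode("ascii")
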