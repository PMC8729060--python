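"""Reproducible random-number streams for paired-arm simulation.

Every stochastic quantity in the simulator is drawn from a named *purpose*
stream (age at diagnosis, stage, other-cause survival, latent breast-cancer
exponential, one occurrence/onset stream per adverse-event type).  Streams
are counter-stable: the draw for woman ``i`` under purpose ``p`` depends only
on ``(master_seed, p, i)``, never on how many women are simulated, which
other purposes exist, or how the run is chunked.  Both treatment arms read
the same streams, which is what makes the 5- vs 10-year comparison a
common-random-numbers (CRN) design.
"""

from __future__ import annotations

import numpy as np

# Women are mapped onto fixed-size blocks; each (purpose, block) pair owns an
# independent Philox stream.  Fixed block size is what makes draws invariant
# to the caller's chunking.
BLOCK = 1 << 18

# Purpose codes.  Never renumber: results are reproducible across versions
# only if these stay put.
AGE_DX = 0
STAGE = 1
OTHER_CAUSE = 2
BC_LATENT = 3
GRADE12_OCC = 4
# Grade 3-4 events get occurrence streams 10..19 and onset streams 30..39,
# grade 1-2 onset uses 29 (deterministic onsets in the base model, reserved).
AE_OCC_BASE = 10
AE_ONSET_BASE = 30

_SALT = 0x656E646F  # stream-family tag, keeps purposes disjoint from other uses


def _block_generator(master_seed: int, purpose: int, block: int) -> np.random.Generator:
    ss = np.random.SeedSequence((_SALT, int(master_seed), int(purpose), int(block)))
    return np.random.Generator(np.random.Philox(ss))


def uniforms(master_seed: int, purpose: int, start: int, stop: int) -> np.ndarray:
    """Uniform(0,1) draws for women ``start..stop-1`` under one purpose.

    Open interval is enforced (no exact 0 or 1) so downstream inverse
    transforms never hit a boundary.
    """
    if stop < start:
        raise ValueError("stop < start")
    out = np.empty(stop - start, dtype=np.float64)
    pos = 0
    b0, b1 = start // BLOCK, (max(stop, start + 1) - 1) // BLOCK
    for b in range(b0, b1 + 1):
        lo = max(start, b * BLOCK)
        hi = min(stop, (b + 1) * BLOCK)
        if hi <= lo:
            continue
        g = _block_generator(master_seed, purpose, b)
        u = g.random(BLOCK)  # draw the full block; slice keeps counter stability
        out[pos:pos + (hi - lo)] = u[lo - b * BLOCK:hi - b * BLOCK]
        pos += hi - lo
    tiny = np.finfo(np.float64).tiny
    np.clip(out, tiny, 1.0 - 1e-16, out=out)
    return out
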