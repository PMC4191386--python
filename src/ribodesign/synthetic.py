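"""Synthetic fixture generators.

Two generators back the test-bench: seed-alignment emulation (columns
with controllable per-position conservation) and cleavage time series
(first-order plateau kinetics plus Gaussian noise).  Both are fully
seeded, so identical calls produce identical fixtures.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .iofmt import AlignmentBlock, NUCLEOTIDES
from .kinetics import CleavageSeries


def generate_synthetic_alignment(
    n_seqs: int,
    length: int,
    conservation_map: Mapping[int, tuple[str, float]],
    seed: int,
    ref_id: str = "ref",
    gap_prob: float = 0.0,
) -> AlignmentBlock:
    """An alignment whose column frequencies match a conservation map.

    ``conservation_map`` assigns selected 1-based positions a
    (top nucleotide, frequency) pair; the remaining probability mass is
    spread uniformly over the other three nucleotides, and unmapped
    columns draw uniformly.  The reference row is emitted first,
    ungapped, carrying the top nucleotide at every mapped position.
    """
    if n_seqs < 1 or length < 1:
        raise ValueError("n_seqs and length must be positive")
    for pos, (nt, freq) in conservation_map.items():
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside 1..{length}")
        if nt not in NUCLEOTIDES:
            raise ValueError(f"invalid nucleotide {nt!r}")
        if not 0.0 <= freq <= 1.0:
            raise ValueError(f"infeasible frequency {freq} at position {pos}")
    rng = np.random.default_rng(seed)
    col_probs = np.full((length, 4), 0.25)
    ref_row = []
    for pos in range(1, length + 1):
        if pos in conservation_map:
            nt, freq = conservation_map[pos]
            k = NUCLEOTIDES.index(nt)
            col_probs[pos - 1] = (1.0 - freq) / 3.0
            col_probs[pos - 1, k] = freq
            ref_row.append(nt)
        else:
            ref_row.append(NUCLEOTIDES[rng.integers(4)])
    records = [(ref_id, "".join(ref_row))]
    for s in range(n_seqs - 1):
        chars = []
        for pos in range(length):
            if gap_prob and rng.random() < gap_prob:
                chars.append("-")
            else:
                chars.append(NUCLEOTIDES[rng.choice(4, p=col_probs[pos])])
        records.append((f"syn{s + 1}", "".join(chars)))
    return AlignmentBlock(tuple(records))


def generate_synthetic_kinetics(
    k_obs: float,
    f_max: float,
    f0: float,
    noise_sd: float,
    times: Sequence[float],
    replicates: int,
    seed: int,
) -> list[CleavageSeries]:
    """Cleavage series from the plateau model plus Gaussian noise.

    F(t) = F_max - (F_max - F0) exp(-K_obs t), noise clipped to [0, 1].
    """
    if k_obs < 0 or not 0 <= f0 <= f_max <= 1 or noise_sd < 0 or replicates < 1:
        raise ValueError("invalid kinetics parameters")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    clean = f_max - (f_max - f0) * np.exp(-k_obs * t)
    out = []
    for r in range(replicates):
        noisy = clean + (rng.normal(0.0, noise_sd, t.size) if noise_sd else 0.0)
        out.append(
            CleavageSeries(
                replicate=f"rep{r + 1}",
                times=tuple(t),
                fractions=tuple(np.clip(noisy, 0.0, 1.0)),
            )
        )
    return out
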