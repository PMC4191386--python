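"""Independent brute-force oracles for the toy thermodynamic model.

Everything here is deliberately written from the definitions, with a
different decomposition (recursion on the LAST position) than any code
path in the package, so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

MIN_LOOP = 3
PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


@lru_cache(maxsize=None)
def all_structures(i: int, j: int) -> tuple[frozenset, ...]:
    """All nested pair sets over positions [i, j], recursing on j."""
    if j - i < MIN_LOOP + 1:
        return (frozenset(),)
    out = [s for s in all_structures(i, j - 1)]  # j unpaired
    for k in range(i, j - MIN_LOOP):
        for left in all_structures(i, k - 1):
            for inner in all_structures(k + 1, j - 1):
                out.append(left | inner | frozenset({(k, j)}))
    return tuple(out)


def formable(seq: str, pairs: frozenset) -> bool:
    return all((seq[i - 1], seq[j - 1]) in PAIRS for i, j in pairs)


def ensemble(seq: str, rt: float):
    """(structures, weights, Z) of the -1/pair model for ``seq``."""
    n = len(seq)
    structs = [s for s in all_structures(1, n) if formable(seq, s)]
    weights = [math.exp(len(s) / rt) for s in structs]
    return structs, weights, sum(weights)


def mfe_energy(seq: str) -> float:
    structs = [s for s in all_structures(1, len(seq)) if formable(seq, s)]
    return -max(len(s) for s in structs)


def pair_probability_matrix(seq: str, rt: float):
    """(n+1)x(n+1) matrix of pair/unpaired probabilities via enumeration."""
    n = len(seq)
    structs, weights, z = ensemble(seq, rt)
    m = [[0.0] * (n + 1) for _ in range(n + 1)]
    for s, w in zip(structs, weights):
        paired = set()
        for i, j in s:
            m[i][j] += w
            m[j][i] += w
            paired.update((i, j))
        for i in range(1, n + 1):
            if i not in paired:
                m[i][i] += w
    for i in range(n + 1):
        for j in range(n + 1):
            m[i][j] /= z
    return m


def state_entropy(seq: str, rt: float, base: float = 2.0):
    """Per-position Shannon entropy of the pairing-state distribution."""
    n = len(seq)
    m = pair_probability_matrix(seq, rt)
    out = []
    for i in range(1, n + 1):
        h = 0.0
        for j in range(1, n + 1):
            p = m[i][j]
            if p > 0:
                h -= p * math.log(p, base)
        out.append(h)
    return out


def boltzmann_ensemble_defect(seq: str, target_pairs: frozenset, rt: float) -> float:
    """Boltzmann-weighted expected per-position pairing-state mismatch."""
    n = len(seq)
    structs, weights, z = ensemble(seq, rt)
    tpartner = {}
    for i, j in target_pairs:
        tpartner[i] = j
        tpartner[j] = i
    total = 0.0
    for s, w in zip(structs, weights):
        partner = {}
        for i, j in s:
            partner[i] = j
            partner[j] = i
        mism = sum(
            1 for i in range(1, n + 1) if partner.get(i, i) != tpartner.get(i, i)
        )
        total += w * mism
    return total / z


def boltzmann_bp_distance(seq: str, target_pairs: frozenset, rt: float) -> float:
    structs, weights, z = ensemble(seq, rt)
    return sum(w * len(s ^ target_pairs) for s, w in zip(structs, weights)) / z


def pairwise_diversity(seq: str, rt: float) -> float:
    """Expected bp distance between two independent ensemble draws."""
    structs, weights, z = ensemble(seq, rt)
    total = 0.0
    for (s1, w1), (s2, w2) in itertools.product(zip(structs, weights), repeat=2):
        total += w1 * w2 * len(s1 ^ s2)
    return total / (z * z)


def density_of_states(seq: str, reference_pairs: frozenset, rt: float):
    """k -> Z_k / Z via enumeration."""
    structs, weights, z = ensemble(seq, rt)
    out: dict[int, float] = {}
    for s, w in zip(structs, weights):
        k = len(s ^ reference_pairs)
        out[k] = out.get(k, 0.0) + w / z
    return out


def structure_probabilities(seq: str, rt: float) -> dict[str, float]:
    """Dot-bracket text -> exact Boltzmann probability."""
    n = len(seq)
    structs, weights, z = ensemble(seq, rt)
    out = {}
    for s, w in zip(structs, weights):
        chars = ["."] * n
        for i, j in s:
            chars[i - 1], chars[j - 1] = "(", ")"
        out["".join(chars)] = w / z
    return out


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGU")) for _ in range(length))
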