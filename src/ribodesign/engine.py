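"""Pluggable thermodynamic backends.

Two backends implement a common contract (MFE structure, structure free
energy, partition function with base-pair probabilities, Boltzmann
sampling):

* ``turner1999`` / ``turner2004`` — delegate to the ViennaRNA bindings,
  loaded with the corresponding Turner nearest-neighbour parameter set.
* ``toy`` — a Nussinov-style model awarding -1.0 kcal/mol per base pair
  (AU/UA/CG/GC/GU/UG, hairpin loops >= 3 unpaired).  Its sole purpose is
  to make exhaustive-enumeration oracles trivial, so every quantity it
  reports can be checked against brute force on short sequences.

Dangling-end treatment matters for reproducing published ensemble
quantities and is therefore part of ``EngineConfig``; the default
(``dangles=2``) is the mode selected by calibrating ensemble defect and
positional entropy against the ten published hammerhead designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .iofmt import DotBracket, MIN_HAIRPIN_LOOP, RnaSequence

#: Gas constant * 310.15 K in kcal/mol (Vienna convention at 37 C).
RT_37 = 0.61632

GAS_CONSTANT = 0.00198717  # kcal/(mol*K)

ALLOWED_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)


class EngineError(RuntimeError):
    """Backend configuration or evaluation failure."""


class InvalidStructureError(ValueError):
    """A structure is not formable by the sequence (non-complementary pair)."""


@dataclass(frozen=True)
class EngineConfig:
    """Thermodynamic model selection.

    temperature is in degrees Celsius; RT is derived from it.  ``dangles``
    follows the ViennaRNA convention (0/1/2/3) and is ignored by the toy
    backend.
    """

    parameter_set: str = "turner1999"
    temperature: float = 37.0
    dangles: int = 2

    def __post_init__(self) -> None:
        if self.parameter_set not in ("turner1999", "turner2004", "toy"):
            raise EngineError(f"unknown parameter set {self.parameter_set!r}")

    @property
    def rt(self) -> float:
        """kcal/mol at the configured temperature (0.61632 at 37 C)."""
        return GAS_CONSTANT * (self.temperature + 273.15)


@dataclass
class BasePairProbabilityMatrix:
    """p*(i,j) pair probabilities with p*(i,i) the unpaired probability.

    Stored 1-indexed in an (n+1, n+1) symmetric array; matrix[i, i] holds
    the probability that i is unpaired, so every row sums to 1.
    """

    matrix: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0] - 1

    def p(self, i: int, j: int) -> float:
        return float(self.matrix[i, j])

    def row(self, i: int) -> np.ndarray:
        """p*(i, .) over j = 1..n (index 0 dropped)."""
        return self.matrix[i, 1:]

    def validate(self, tol: float = 1e-6) -> None:
        sums = self.matrix[1:, 1:].sum(axis=1)
        if np.any(np.abs(sums - 1.0) > tol):
            worst = int(np.argmax(np.abs(sums - 1.0))) + 1
            raise EngineError(
                f"row {worst} of base-pair probability matrix sums to {sums[worst - 1]:.8f}"
            )

    @classmethod
    def from_pair_probs(cls, n: int, pair_probs: dict[tuple[int, int], float]):
        m = np.zeros((n + 1, n + 1))
        for (i, j), p in pair_probs.items():
            m[i, j] = m[j, i] = p
        for i in range(1, n + 1):
            m[i, i] = max(0.0, 1.0 - (m[i, 1:].sum() - m[i, i]))
        return cls(m)


def _check_structure(seq: str, db: DotBracket) -> None:
    if len(seq) != len(db):
        raise InvalidStructureError(
            f"structure length {len(db)} != sequence length {len(seq)}"
        )
    for i, j in db.pairs:
        if (seq[i - 1], seq[j - 1]) not in ALLOWED_PAIRS:
            raise InvalidStructureError(
                f"pair ({i},{j}) = {seq[i - 1]}-{seq[j - 1]} is not AU/CG/GU"
            )


# ---------------------------------------------------------------------------
# Vienna backend
# ---------------------------------------------------------------------------

_LOADED_PARAMS: list[str | None] = [None]


def _load_params(parameter_set: str) -> None:
    # ViennaRNA keeps parameters in process-global state; reload only on change
    import RNA

    if _LOADED_PARAMS[0] == parameter_set:
        return
    if parameter_set == "turner1999":
        RNA.params_load_RNA_Turner1999()
    elif parameter_set == "turner2004":
        RNA.params_load_RNA_Turner2004()
    else:  # pragma: no cover - guarded by EngineConfig
        raise EngineError(parameter_set)
    _LOADED_PARAMS[0] = parameter_set


class ViennaEngine:
    """Turner nearest-neighbour backend delegating to ViennaRNA."""

    def __init__(self, config: EngineConfig):
        if config.parameter_set == "toy":
            raise EngineError("use ToyEngine for the toy parameter set")
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise EngineError("ViennaRNA python bindings unavailable") from exc
        self.config = config

    def _fold_compound(self, seq: str):
        import RNA

        _load_params(self.config.parameter_set)
        md = RNA.md()
        md.temperature = self.config.temperature
        md.dangles = self.config.dangles
        md.uniq_ML = 1
        return RNA.fold_compound(seq, md)

    def _kT(self) -> float:
        import RNA

        md = RNA.md()
        md.temperature = self.config.temperature
        return RNA.exp_param(md).kT / 1000.0

    def mfe(self, seq: RnaSequence) -> tuple[DotBracket, float]:
        fc = self._fold_compound(seq.residues)
        structure, energy = fc.mfe()
        return DotBracket(structure), float(energy)

    def free_energy(self, seq: RnaSequence, structure: DotBracket) -> float:
        _check_structure(seq.residues, structure)
        fc = self._fold_compound(seq.residues)
        return float(fc.eval_structure(structure.text))

    def partition(self, seq: RnaSequence) -> tuple[float, BasePairProbabilityMatrix]:
        fc = self._fold_compound(seq.residues)
        _, e_mfe = fc.mfe()
        fc.exp_params_rescale(e_mfe)
        _, ensemble_fe = fc.pf()
        n = len(seq)
        raw = fc.bpp()
        m = np.zeros((n + 1, n + 1))
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                m[i, j] = m[j, i] = raw[i][j]
        for i in range(1, n + 1):
            m[i, i] = max(0.0, 1.0 - (m[i, 1:].sum() - m[i, i]))
        return float(ensemble_fe), BasePairProbabilityMatrix(m)

    def boltzmann_probability(self, seq: RnaSequence, structure: DotBracket) -> float:
        _check_structure(seq.residues, structure)
        fc = self._fold_compound(seq.residues)
        _, e_mfe = fc.mfe()
        fc.exp_params_rescale(e_mfe)
        _, ensemble_fe = fc.pf()
        e = fc.eval_structure(structure.text)
        return min(1.0, math.exp((ensemble_fe - e) / self._kT()))

    def sample_structures(self, seq: RnaSequence, count: int, seed: int) -> list[DotBracket]:
        import RNA

        if count < 1:
            raise ValueError("count must be >= 1")
        fc = self._fold_compound(seq.residues)
        _, e_mfe = fc.mfe()
        fc.exp_params_rescale(e_mfe)
        fc.pf()
        RNA.init_rand(int(seed) % (2**31 - 1) or 1)
        return [DotBracket(s) for s in fc.pbacktrack(count)]


# ---------------------------------------------------------------------------
# Toy backend: -1 kcal/mol per pair, exact DP
# ---------------------------------------------------------------------------

TOY_MAX_N = 30  # O(n^5) pair-probability recursion; ample for oracle work

PAIR_ENERGY = -1.0


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in ALLOWED_PAIRS


class ToyEngine:
    """Exact DP over the homopolymer-style -1/pair model.

    MFE by Nussinov recursion with a deterministic traceback (prefer the
    5' position unpaired; otherwise the smallest admissible partner), the
    partition function by the unambiguous first-position decomposition,
    pair probabilities by conditioning (Z with (i,j) forced, over Z), and
    sampling by stochastic backtracking on the partition DP.
    """

    def __init__(self, config: EngineConfig | None = None):
        self.config = config or EngineConfig(parameter_set="toy")
        if self.config.parameter_set != "toy":
            raise EngineError("ToyEngine requires parameter_set='toy'")

    # -- helpers -----------------------------------------------------------

    def _guard(self, seq: RnaSequence) -> str:
        if len(seq) == 0:
            raise EngineError("empty sequence")
        if len(seq) > TOY_MAX_N:
            raise EngineError(f"toy backend limited to n <= {TOY_MAX_N}")
        return seq.residues

    # -- MFE ---------------------------------------------------------------

    def mfe(self, seq: RnaSequence) -> tuple[DotBracket, float]:
        s = self._guard(seq)
        n = len(s)
        W = _nussinov_table(s)
        struct = ["."] * n
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if j - i <= MIN_HAIRPIN_LOOP:
                continue
            if W[i][j] == W[i + 1][j]:
                stack.append((i + 1, j))
                continue
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if _can_pair(s[i], s[k]):
                    inner = W[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    outer = W[k + 1][j] if k + 1 <= j else 0
                    if inner + outer + 1 == W[i][j]:
                        struct[i], struct[k] = "(", ")"
                        stack.append((i + 1, k - 1))
                        stack.append((k + 1, j))
                        break
        db = DotBracket("".join(struct))
        return db, PAIR_ENERGY * len(db.pairs)

    def free_energy(self, seq: RnaSequence, structure: DotBracket) -> float:
        _check_structure(self._guard(seq), structure)
        return PAIR_ENERGY * len(structure.pairs)

    # -- partition function ------------------------------------------------

    def _z_segments(self, s: str, orig: tuple[int, ...]) -> float:
        """Partition over the positions ``orig`` (original 0-based indices);
        loop-length checks use original coordinates so split regions around
        a forced pair are handled correctly."""
        x = math.exp(-PAIR_ENERGY / self.config.rt)
        m = len(orig)

        @lru_cache(maxsize=None)
        def Q(a: int, b: int) -> float:
            if b < a:
                return 1.0
            total = Q(a + 1, b)  # position a unpaired
            for k in range(a + 1, b + 1):
                if orig[k] - orig[a] > MIN_HAIRPIN_LOOP and _can_pair(s[orig[a]], s[orig[k]]):
                    total += x * Q(a + 1, k - 1) * Q(k + 1, b)
            return total

        z = Q(0, m - 1)
        Q.cache_clear()
        return z

    def partition(self, seq: RnaSequence) -> tuple[float, BasePairProbabilityMatrix]:
        s = self._guard(seq)
        n = len(s)
        full = tuple(range(n))
        z = self._z_segments(s, full)
        x = math.exp(-PAIR_ENERGY / self.config.rt)
        probs: dict[tuple[int, int], float] = {}
        for i in range(n):
            for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
                if not _can_pair(s[i], s[j]):
                    continue
                inside = self._z_segments(s, tuple(range(i + 1, j)))
                outside = self._z_segments(s, tuple(range(i)) + tuple(range(j + 1, n)))
                probs[(i + 1, j + 1)] = x * inside * outside / z
        ensemble_fe = -self.config.rt * math.log(z)
        return ensemble_fe, BasePairProbabilityMatrix.from_pair_probs(n, probs)

    def boltzmann_probability(self, seq: RnaSequence, structure: DotBracket) -> float:
        s = self._guard(seq)
        _check_structure(s, structure)
        z = self._z_segments(s, tuple(range(len(s))))
        e = PAIR_ENERGY * len(structure.pairs)
        return math.exp(-e / self.config.rt) / z

    # -- sampling ----------------------------------------------------------

    def sample_structures(self, seq: RnaSequence, count: int, seed: int) -> list[DotBracket]:
        if count < 1:
            raise ValueError("count must be >= 1")
        s = self._guard(seq)
        n = len(s)
        x = math.exp(-PAIR_ENERGY / self.config.rt)

        @lru_cache(maxsize=None)
        def Q(a: int, b: int) -> float:
            if b < a:
                return 1.0
            total = Q(a + 1, b)
            for k in range(a + MIN_HAIRPIN_LOOP + 1, b + 1):
                if _can_pair(s[a], s[k]):
                    total += x * Q(a + 1, k - 1) * Q(k + 1, b)
            return total

        rng = np.random.default_rng(seed)
        out: list[DotBracket] = []
        for _ in range(count):
            struct = ["."] * n
            stack = [(0, n - 1)]
            while stack:
                a, b = stack.pop()
                if b < a:
                    continue
                r = rng.random() * Q(a, b)
                acc = Q(a + 1, b)
                if r < acc:
                    stack.append((a + 1, b))
                    continue
                chosen = None
                for k in range(a + MIN_HAIRPIN_LOOP + 1, b + 1):
                    if _can_pair(s[a], s[k]):
                        acc += x * Q(a + 1, k - 1) * Q(k + 1, b)
                        if r < acc:
                            chosen = k
                            break
                if chosen is None:  # numerical edge: take last admissible k
                    chosen = max(
                        k
                        for k in range(a + MIN_HAIRPIN_LOOP + 1, b + 1)
                        if _can_pair(s[a], s[k])
                    )
                struct[a], struct[chosen] = "(", ")"
                stack.append((a + 1, chosen - 1))
                stack.append((chosen + 1, b))
            out.append(DotBracket("".join(struct)))
        Q.cache_clear()
        return out


def _nussinov_table(s: str) -> list[list[int]]:
    n = len(s)
    W = [[0] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i + 1][j]
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if _can_pair(s[i], s[k]):
                    inner = W[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    outer = W[k + 1][j] if k + 1 <= j else 0
                    best = max(best, inner + outer + 1)
            W[i][j] = best
    return W


def get_engine(config: EngineConfig):
    """Instantiate the backend named by ``config.parameter_set``."""
    if config.parameter_set == "toy":
        return ToyEngine(config)
    return ViennaEngine(config)
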