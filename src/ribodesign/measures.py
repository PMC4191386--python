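"""Ensemble-derived selection measures.

Everything here is a function of the base-pair probability matrix
p*(i,j) (with p*(i,i) the unpaired probability):

* full positional entropy     H(i)  = -sum_j p*(i,j) log p*(i,j)
* binary positional entropy   Hb(i) = -(q log q + (1-q) log(1-q)),  q = p*(i,i)
* ensemble defect             ED    = sum_i (1 - p*(i, pi(i)))
* expected base-pair distance EBPD  = sum_{(i,j) in T} (1-p*(i,j))
                                      + sum_{(i,j) not in T} p*(i,j)
* Vienna diversity            sum_{i<j} 2 p*(i,j)(1 - p*(i,j))
* Morgan-Higgs diversity      sum_i (1 - sum_j p*(i,j)^2)

where pi(i) is the partner of i in the target T (or i itself when
unpaired).  Discrepancy measures compare a candidate's per-position
profile against a reference molecule's and take the maximum absolute
difference over a position set (whole molecule, or the 16-position
conserved site of the 54-nt hammerhead design).

Entropies default to bits (base-2); the published selection tables for
the hammerhead designs are reproduced with natural logarithms, which the
calibration constant in :mod:`ribodesign.fixtures` records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np

from .engine import BasePairProbabilityMatrix, EngineConfig, get_engine
from .iofmt import DotBracket, RnaSequence

#: The 16 catalytic-core positions of the 54-nt hammerhead design.
CONSERVED_SITE: tuple[int, ...] = (6, 7, 8, 22, 23, 24, 25, 27, 28, 29,
                                   44, 45, 46, 47, 48, 49)

_P_FLOOR = 1e-300


def _xlogx(p: np.ndarray, base: float) -> np.ndarray:
    q = np.clip(p, _P_FLOOR, None)
    out = p * np.log(q) / math.log(base)
    out[p <= 0.0] = 0.0  # 0 log 0 := 0
    return out


def positional_entropy(
    bppm: BasePairProbabilityMatrix, mode: str = "full", base: float = 2.0
) -> np.ndarray:
    """Per-position structural entropy, length-n vector (1-based position i
    at index i-1).

    ``mode='full'`` is the Shannon entropy of the pairing-state
    distribution (partner j, or unpaired); ``mode='binary'`` collapses the
    states to paired/unpaired.  ``mode='full_printed'`` additionally adds
    the complementary terms -(1-p)log(1-p) for every state, a variant that
    appears in some published formulations.
    """
    bppm.validate()
    n = bppm.n
    m = bppm.matrix[1:, 1:]
    if mode == "full":
        return -_xlogx(m, base).sum(axis=1)
    if mode == "full_printed":
        return -(_xlogx(m, base) + _xlogx(1.0 - m, base)).sum(axis=1)
    if mode == "binary":
        q = np.diagonal(m).copy()
        return -(_xlogx(q, base) + _xlogx(1.0 - q, base))
    raise ValueError(f"unknown entropy mode {mode!r}")


def _position_index(positions: Iterable[int] | None, n: int) -> np.ndarray:
    if positions is None:
        return np.arange(1, n + 1)
    pos = np.asarray(sorted(set(positions)), dtype=int)
    if pos.size == 0 or pos[0] < 1 or pos[-1] > n:
        raise ValueError(f"positions must lie within 1..{n}")
    return pos


def ensemble_defect(
    bppm: BasePairProbabilityMatrix,
    target: DotBracket,
    positions: Iterable[int] | None = None,
) -> float:
    """Expected number of positions whose pairing state differs from the
    target, optionally restricted to a position subset."""
    bppm.validate()
    if len(target) != bppm.n:
        raise ValueError("target length differs from matrix size")
    partner = target.partner()
    pos = _position_index(positions, bppm.n)
    return float(sum(1.0 - bppm.p(i, partner.get(i, i)) for i in map(int, pos)))


def normalized_ensemble_defect(
    bppm: BasePairProbabilityMatrix,
    target: DotBracket,
    positions: Iterable[int] | None = None,
) -> float:
    pos = _position_index(positions, bppm.n)
    return ensemble_defect(bppm, target, positions) / len(pos)


def ebpd_profile(bppm: BasePairProbabilityMatrix, target: DotBracket) -> np.ndarray:
    """Per-position contribution d(i) to the expected base-pair distance.

    Each target pair contributes (1 - p*) at both endpoints and each
    non-target pair contributes p* at both endpoints, so
    sum_i d(i) = 2 * EBPD(whole molecule).
    """
    bppm.validate()
    n = bppm.n
    if len(target) != n:
        raise ValueError("target length differs from matrix size")
    in_target = np.zeros((n + 1, n + 1), dtype=bool)
    for i, j in target.pairs:
        in_target[i, j] = in_target[j, i] = True
    d = np.zeros(n)
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if j == i:
                continue
            p = bppm.p(i, j)
            d[i - 1] += (1.0 - p) if in_target[i, j] else p
    return d


def expected_bp_distance(
    bppm: BasePairProbabilityMatrix,
    target: DotBracket,
    positions: Iterable[int] | None = None,
) -> float:
    """Boltzmann-expected base-pair distance to the target.

    Whole-molecule value counts each pair once; a position-restricted
    value sums the per-position contributions d(i) over the subset.
    """
    if positions is None:
        n = bppm.n
        total = 0.0
        seen = set()
        for i, j in target.pairs:
            total += 1.0 - bppm.p(i, j)
            seen.add((i, j))
        m = bppm.matrix
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if (i, j) not in seen:
                    total += m[i, j]
        return float(total)
    d = ebpd_profile(bppm, target)
    pos = _position_index(positions, bppm.n)
    return float(d[pos - 1].sum())


def structural_diversity(bppm: BasePairProbabilityMatrix, variant: str = "vienna") -> float:
    """Ensemble diversity scalars.

    ``vienna`` is the expected base-pair distance between two independent
    ensemble draws; ``morgan_higgs`` sums per-position collision
    complements 1 - sum_j p*(i,j)^2.
    """
    bppm.validate()
    m = bppm.matrix[1:, 1:]
    if variant == "vienna":
        upper = np.triu(m, k=1)
        return float((2.0 * upper * (1.0 - upper))[np.triu_indices_from(m, k=1)].sum())
    if variant == "morgan_higgs":
        return float((1.0 - (m**2).sum(axis=1)).sum())
    raise ValueError(f"unknown diversity variant {variant!r}")


def discrepancy(
    candidate_profile: Sequence[float],
    reference_profile: Sequence[float],
    positions: Iterable[int] | None = None,
) -> float:
    """max_i |candidate(i) - reference(i)| over the given position set."""
    a = np.asarray(candidate_profile, dtype=float)
    b = np.asarray(reference_profile, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profile length mismatch")
    pos = _position_index(positions, a.size)
    return float(np.abs(a - b)[pos - 1].max())


@dataclass(frozen=True)
class EnsembleProfile:
    """Per-position ensemble descriptors of one sequence."""

    entropy_full: np.ndarray
    entropy_binary: np.ndarray
    ebpd: np.ndarray

    @property
    def n(self) -> int:
        return self.entropy_full.size


def ensemble_profile(
    bppm: BasePairProbabilityMatrix, target: DotBracket, base: float = 2.0
) -> EnsembleProfile:
    return EnsembleProfile(
        entropy_full=positional_entropy(bppm, "full", base),
        entropy_binary=positional_entropy(bppm, "binary", base),
        ebpd=ebpd_profile(bppm, target),
    )


@dataclass(frozen=True)
class MeasureRecord:
    """All scalar selection measures for one candidate sequence."""

    id: str
    sequence: str
    gc_percent: float
    prob_target: float
    pos_entropy: float
    pos_entropy_site: float
    binary_entropy: float
    binary_entropy_site: float
    ensemble_defect: float
    ensemble_defect_site: float
    ebpd: float
    ebpd_site: float
    vienna_diversity: float
    morgan_higgs_diversity: float
    entropy_disc: float = math.nan
    entropy_disc_site: float = math.nan
    binary_entropy_disc: float = math.nan
    binary_entropy_disc_site: float = math.nan
    ebpd_disc_site: float = math.nan

    def as_dict(self) -> dict[str, object]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: MeasureRecord fields usable as selection objectives.
OBJECTIVE_FIELDS = tuple(
    f.name
    for f in fields(MeasureRecord)
    if f.name not in ("id", "sequence")
)


def measure_suite(
    seq: RnaSequence,
    target: DotBracket,
    conserved_site: Sequence[int] = CONSERVED_SITE,
    reference_profile: EnsembleProfile | None = None,
    engine_config: EngineConfig | None = None,
    base: float = 2.0,
) -> MeasureRecord:
    """Compute every selection measure for one candidate.

    ``reference_profile`` (usually the wild-type molecule's) enables the
    discrepancy columns; without it they are NaN.
    """
    from .iofmt import gc_percent as _gc

    from .engine import InvalidStructureError

    cfg = engine_config or EngineConfig()
    eng = get_engine(cfg)
    _, bppm = eng.partition(seq)
    prof = ensemble_profile(bppm, target, base)
    site = tuple(conserved_site)
    try:
        prob = eng.boltzmann_probability(seq, target)
    except InvalidStructureError:
        prob = 0.0  # sequence cannot even form the target's pairs
    rec = dict(
        id=seq.id,
        sequence=seq.residues,
        gc_percent=_gc(seq),
        prob_target=prob,
        pos_entropy=float(prof.entropy_full.mean()),
        pos_entropy_site=float(prof.entropy_full[np.asarray(site) - 1].mean()),
        binary_entropy=float(prof.entropy_binary.mean()),
        binary_entropy_site=float(prof.entropy_binary[np.asarray(site) - 1].mean()),
        ensemble_defect=ensemble_defect(bppm, target),
        ensemble_defect_site=ensemble_defect(bppm, target, site),
        ebpd=expected_bp_distance(bppm, target),
        ebpd_site=expected_bp_distance(bppm, target, site),
        vienna_diversity=structural_diversity(bppm, "vienna"),
        morgan_higgs_diversity=structural_diversity(bppm, "morgan_higgs"),
    )
    if reference_profile is not None:
        rec.update(
            entropy_disc=discrepancy(prof.entropy_full, reference_profile.entropy_full),
            entropy_disc_site=discrepancy(
                prof.entropy_full, reference_profile.entropy_full, site
            ),
            binary_entropy_disc=discrepancy(
                prof.entropy_binary, reference_profile.entropy_binary
            ),
            binary_entropy_disc_site=discrepancy(
                prof.entropy_binary, reference_profile.entropy_binary, site
            ),
            ebpd_disc_site=discrepancy(prof.ebpd, reference_profile.ebpd, site),
        )
    return MeasureRecord(**rec)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of calibrating the ensemble model against a published
    measure table: the dangle mode and entropy log base minimizing the
    worst-case relative error, with those errors recorded."""

    dangles: int
    entropy_log_base: float
    max_rel_err_pos_entropy: float
    max_rel_err_ensemble_defect: float

    @property
    def score(self) -> float:
        return max(self.max_rel_err_pos_entropy, self.max_rel_err_ensemble_defect)


def calibrate_table_reproduction(
    sequences: dict[str, RnaSequence],
    target: DotBracket,
    table: dict[str, dict[str, float]],
    parameter_set: str = "turner1999",
    dangle_modes: Sequence[int] = (0, 2),
    log_bases: Sequence[float] = (2.0, math.e),
) -> CalibrationResult:
    """Select the dangle mode and entropy log base that best reproduce a
    published (pos_entropy, ensemble_defect) table.

    The partition function distinguishes only dangle classes 0 and 2
    (modes 1/3 fall back to 2), so those two are scanned by default.  The
    winner minimizes the worse of the two worst-case relative errors.
    """
    best: CalibrationResult | None = None
    for d in dangle_modes:
        eng = get_engine(EngineConfig(parameter_set, dangles=d))
        matrices = {rid: eng.partition(seq)[1] for rid, seq in sequences.items()}
        err_ed = max(
            abs(ensemble_defect(m, target) - table[rid]["ensemble_defect"])
            / table[rid]["ensemble_defect"]
            for rid, m in matrices.items()
        )
        for base in log_bases:
            err_h = max(
                abs(
                    float(positional_entropy(m, "full", base).mean())
                    - table[rid]["pos_entropy"]
                )
                / table[rid]["pos_entropy"]
                for rid, m in matrices.items()
            )
            cand = CalibrationResult(d, base, err_h, err_ed)
            if best is None or cand.score < best.score:
                best = cand
    return best
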