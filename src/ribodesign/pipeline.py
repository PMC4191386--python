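"""End-to-end orchestration: conserve -> design -> measure -> rank (-> dos).

Every stage writes its outputs under the report directory and appends to
a provenance log (engine configuration, seeds, package version) that
suffices to re-run any stage bit-identically.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .conserve import SelectionCriterion, select_candidates
from .engine import EngineConfig
from .iofmt import DotBracket, IupacPattern, write_fasta, write_tsv
from .measures import CONSERVED_SITE, MeasureRecord, ensemble_profile, measure_suite
from .search import DesignProblem, SearchStatus, enumerate_designs


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    target: DotBracket
    pattern: IupacPattern
    engine: EngineConfig = field(default_factory=lambda: EngineConfig("toy"))
    gc_window: tuple[float, float] | None = None
    max_solutions: int | None = 50
    criteria: tuple[SelectionCriterion, ...] = (
        SelectionCriterion(objective="ensemble_defect"),
    )
    conserved_site: tuple[int, ...] = CONSERVED_SITE
    reference_seq: object | None = None  # RnaSequence for discrepancy columns
    seed: int = 0
    out_dir: Path = Path("ribodesign-report")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the design pipeline and return the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict[str, object] = {
        "version": __version__,
        "python": platform.python_version(),
        "engine": {
            "parameter_set": config.engine.parameter_set,
            "temperature": config.engine.temperature,
            "dangles": config.engine.dangles,
        },
        "seed": config.seed,
        "target": config.target.text,
        "pattern": config.pattern.codes,
        "gc_window": config.gc_window,
    }

    stage = "design"
    try:
        problem = DesignProblem(
            target=config.target,
            pattern=config.pattern,
            gc_window=config.gc_window,
            max_solutions=config.max_solutions,
            engine=config.engine,
        )
        outcome = enumerate_designs(problem)
        log["search"] = {
            "status": outcome.status.value,
            "nodes_explored": outcome.nodes_explored,
            "engine_calls": outcome.engine_calls,
            "n_solutions": len(outcome.solutions),
        }
        write_fasta(outcome.solutions, out / "designs.fasta")
        if outcome.status is SearchStatus.UNSAT:
            _write_log(out, log)
            return out
    except Exception as exc:
        _write_log(out, log)
        raise PipelineError(stage, str(exc)) from exc

    stage = "measure"
    try:
        site = [p for p in config.conserved_site if p <= len(config.target)]
        ref_profile = None
        if config.reference_seq is not None:
            from .engine import get_engine

            _, ref_bppm = get_engine(config.engine).partition(config.reference_seq)
            ref_profile = ensemble_profile(ref_bppm, config.target)
        records: list[MeasureRecord] = [
            measure_suite(
                s, config.target, site or (1,), ref_profile, config.engine
            )
            for s in outcome.solutions
        ]
        table = pd.DataFrame([r.as_dict() for r in records])
        write_tsv(table, out / "measures.tsv")
    except Exception as exc:
        _write_log(out, log)
        raise PipelineError(stage, str(exc)) from exc

    stage = "rank"
    try:
        ranked_ids = {}
        for crit in config.criteria:
            winners = select_candidates(records, crit)
            ranked_ids[crit.objective + (":max" if crit.maximize else ":min")] = [
                w.id for w in winners[:10]
            ]
        log["ranking"] = ranked_ids
    except Exception as exc:
        _write_log(out, log)
        raise PipelineError(stage, str(exc)) from exc

    _write_log(out, log)
    return out


def _write_log(out: Path, log: dict) -> None:
    (out / "provenance.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
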