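"""End-to-end orchestration: score -> rank -> consensus -> evaluate.

One :func:`run` call takes a descriptor panel (read from disk or freshly
simulated), scores every target--solvent pair with the requested methods,
builds individual and consensus rank tables, evaluates them against the
confirmed-outcome panel, and writes a reproducible report bundle:

- ``scores.csv``       long-format method scores
- ``ranks_long.csv``   fractional positions + underlying statistic
- ``ranks_wide.csv``   solvent x method grid of positions
- ``evaluation.csv``   one row per (compound, method) with the mean rank
- ``manifest.json``    config, seed, input hashes and package version

Fixed inputs and seed produce byte-identical outputs.  Any stage failure
aborts with a stage-named error and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import EvaluationResult, mean_rank, results_to_frame
from .io import DescriptorBundle, OutcomePanel, builtin_outcomes, read_panel, \
    validate_outcomes, write_panel
from .ranking import COMBINATIONS, RankTable, all_combinations, combo_label, \
    consensus, rank_scores, rank_tables_to_long, rank_tables_to_wide
from .scoring import METHODS, score_panel
from .synthetic import PanelConfig, generate_panel, null_panel

__all__ = ["RunConfig", "PipelineError", "run", "replicate_evaluation"]

logger = logging.getLogger("solvscreen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``input_dir`` (a directory of descriptor CSVs) or
    ``simulate`` (a synthetic panel configuration) must be given.
    ``outcomes`` selects the ground truth: ``"bundle"`` (the panel's own
    outcome table), ``"builtin"`` (the curated curcuminoid fixture) or a
    path to an outcome CSV.
    """

    out_dir: str | Path
    input_dir: str | Path | None = None
    simulate: PanelConfig | None = None
    methods: tuple[str, ...] = METHODS
    combinations: tuple[tuple[str, ...], ...] = COMBINATIONS
    outcomes: str | Path = "bundle"
    exclude_ambiguous: bool = False
    verbosity: int = logging.INFO

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of input_dir or simulate must be provided"
            )
        if not self.methods:
            raise ValueError("at least one method must be enabled")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        if tuple(self.combinations) == COMBINATIONS and set(
            self.methods
        ) != set(METHODS):
            # default combination list with a reduced method set: keep the
            # combinations the enabled methods can support
            object.__setattr__(
                self,
                "combinations",
                tuple(c for c in COMBINATIONS
                      if set(c) <= set(self.methods)),
            )
        for combo in self.combinations:
            missing = set(combo) - set(self.methods)
            if missing:
                raise ValueError(
                    f"combination {combo_label(combo)} uses disabled "
                    f"method(s): {sorted(missing)}"
                )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_outcomes(config: RunConfig, bundle: DescriptorBundle) -> OutcomePanel:
    if config.outcomes == "builtin":
        return builtin_outcomes()
    if config.outcomes == "bundle":
        if bundle.outcomes is None:
            raise ValueError("panel carries no outcome table")
        return bundle.outcomes
    return OutcomePanel(validate_outcomes(pd.read_csv(config.outcomes)))


def _stage(name: str):
    """Wrap stage execution so failures carry the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.debug("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the written report paths."""
    logging.basicConfig(level=config.verbosity)
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        with _stage("load"):
            if config.simulate is not None:
                bundle, _truth = generate_panel(config.simulate)
                input_hashes: dict[str, str] = {}
            else:
                bundle = read_panel(config.input_dir)
                input_hashes = {
                    p.name: _sha256(p)
                    for p in sorted(Path(config.input_dir).glob("*.csv"))
                }
            outcomes = _load_outcomes(config, bundle)

        with _stage("score"):
            frames = [
                score_panel(bundle, target, methods=config.methods)
                for target in bundle.target_ids()
            ]
            scores = pd.concat(frames, ignore_index=True)

        with _stage("rank"):
            tables: dict[str, dict[str, RankTable]] = {}
            for target in bundle.target_ids():
                sub = scores[scores["target_id"] == target]
                tables[target] = {
                    m: rank_scores(sub, m) for m in config.methods
                }

        with _stage("consensus"):
            combo_tables: dict[str, dict[str, RankTable]] = {}
            for target, individual in tables.items():
                if set(config.methods) == set(METHODS) and tuple(
                    config.combinations
                ) == COMBINATIONS:
                    combo_tables[target] = all_combinations(individual)
                else:
                    combo_tables[target] = {
                        combo_label(c): consensus(
                            [individual[m] for m in c],
                            combo_name=combo_label(c),
                        )
                        for c in config.combinations
                    }

        with _stage("evaluate"):
            results: list[EvaluationResult] = []
            for target, individual in tables.items():
                confirmed = outcomes.confirmed_solvents(
                    target, include_ambiguous=not config.exclude_ambiguous
                )
                if not confirmed:
                    logger.warning(
                        "no confirmed formers for %s; skipping evaluation",
                        target,
                    )
                    continue
                panel = set(next(iter(individual.values())).solvents())
                missing = confirmed - panel
                if missing:
                    raise ValueError(
                        f"outcome table names solvent(s) absent from the "
                        f"panel for {target}: {sorted(missing)}"
                    )
                for t in list(individual.values()) + list(
                    combo_tables[target].values()
                ):
                    results.append(mean_rank(t, confirmed, compound_id=target))

        with _stage("write"):
            scores_path = out_dir / "scores.csv"
            scores.to_csv(scores_path, index=False)
            written["scores"] = scores_path

            flat = [
                t
                for target in tables
                for t in list(tables[target].values())
                + list(combo_tables[target].values())
            ]
            long_path = out_dir / "ranks_long.csv"
            rank_tables_to_long(flat).to_csv(long_path, index=False)
            written["ranks_long"] = long_path
            # wide grid is per-target; stack targets with a column
            wide_frames = []
            for target in tables:
                w = rank_tables_to_wide(
                    list(tables[target].values())
                    + list(combo_tables[target].values())
                )
                w.insert(0, "target_id", target)
                wide_frames.append(w.reset_index())
            wide_path = out_dir / "ranks_wide.csv"
            pd.concat(wide_frames, ignore_index=True).to_csv(
                wide_path, index=False
            )
            written["ranks_wide"] = wide_path

            eval_path = out_dir / "evaluation.csv"
            results_to_frame(
                sorted(results, key=lambda r: (r.compound_id, r.mean_rank,
                                               r.method_id))
            ).to_csv(eval_path, index=False)
            written["evaluation"] = eval_path

            manifest = {
                "package": "solvscreen",
                "version": __version__,
                "config": {
                    "input_dir": str(config.input_dir)
                    if config.input_dir else None,
                    "simulate": asdict(config.simulate)
                    if config.simulate else None,
                    "methods": list(config.methods),
                    "combinations": [
                        combo_label(c) for c in config.combinations
                    ],
                    "outcomes": str(config.outcomes),
                    "exclude_ambiguous": config.exclude_ambiguous,
                },
                "input_hashes": input_hashes,
            }
            manifest_path = out_dir / "manifest.json"
            manifest_path.write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n"
            )
            written["manifest"] = manifest_path
    except Exception:
        # remove partial outputs before propagating
        for path in written.values():
            path.unlink(missing_ok=True)
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise
    return written


def _child_seed(base_seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    return int(np.random.default_rng([base_seed, replicate]).integers(2**31))


def replicate_evaluation(
    config: PanelConfig,
    n_replicates: int,
    base_seed: int = 0,
    null: bool = False,
    methods: Sequence[str] = METHODS,
    combos: Sequence[tuple[str, ...]] = (),
) -> pd.DataFrame:
    """Replicate the simulate -> score -> rank -> evaluate loop.

    Generates ``n_replicates`` independent panels from ``config`` (seeds
    derived deterministically from ``base_seed``), evaluates the requested
    individual methods and consensus combinations against each panel's
    planted formers, and returns one row per (replicate, method) with the
    mean-rank statistic.  ``null=True`` uses the signal-free generator.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    generate = null_panel if null else generate_panel
    rows = []
    for rep in range(n_replicates):
        cfg = replace(config, seed=_child_seed(base_seed, rep))
        bundle, truth = generate(cfg)
        scores = score_panel(bundle, cfg.target_id, methods=methods)
        individual = {m: rank_scores(scores, m) for m in methods}
        tables: dict[str, RankTable] = dict(individual)
        for c in combos:
            label = combo_label(c)
            tables[label] = consensus([individual[m] for m in c],
                                      combo_name=label)
        confirmed = set(truth.formers)
        for label, table in tables.items():
            r = mean_rank(table, confirmed, compound_id=cfg.target_id)
            rows.append((rep, label, r.mean_rank, r.n_confirmed, r.n_panel))
    return pd.DataFrame(
        rows,
        columns=["replicate", "method_id", "mean_rank", "n_confirmed",
                 "n_panel"],
    )
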