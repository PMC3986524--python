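"""Map-reduce execution of the permutation inference.

The inference is embarrassingly parallel: one map task scores a block of
``permutations_per_task`` consecutive permutations for one phenotype (the
block containing permutation 0 also yields the observed statistic).  The
reduce — filling the per-permutation score table and taking the
per-permutation maximum over phenotypes for the Westfall-Young correction —
is associative and commutative, so results can arrive out of order, from
any number of workers, and the final table is identical to a serial run.

Fault tolerance is a local, file-backed analogue of a cloud task queue: a
completed map result is appended to a newline-delimited JSON ledger (with a
checksum) before it is acknowledged.  Maps are pure and idempotent, so a
restart skips ledgered tasks and re-queues the rest; at-least-once task
execution plus idempotent maps gives exactly-once results.
"""

from __future__ import annotations

import hashlib
import json
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .config import InferenceDescriptor
from .estimator import compile_pipeline
from .exceptions import IntegrityError, RunInterrupted
from .linstats import ResidualTarget, make_permutation, permuted_target, residualize
from .scoring import cv_score, make_splits

__all__ = [
    "TaskSpec",
    "MapResult",
    "NullTable",
    "split_tasks",
    "run_map",
    "reduce_results",
    "run_inference",
    "read_ledger",
]

LEDGER_SCHEMA = "cvperm-ledger-v1"


@dataclass(frozen=True)
class TaskSpec:
    """One unit of work: a block of permutation ids for one phenotype."""

    task_id: str
    phenotype_index: int
    permutation_ids: tuple[int, ...]
    base_seed: int


@dataclass(frozen=True)
class MapResult:
    """Scores produced by one task: (phenotype, permutation, cv_r2) triples."""

    task_id: str
    scores: tuple[tuple[int, int, float], ...]


@dataclass
class NullTable:
    """Observed statistics plus the permutation null for all phenotypes.

    ``null_scores[b - 1, j]`` holds the statistic of permutation ``b`` for
    phenotype ``j`` (NaN until filled); ``max_null`` is the per-permutation
    maximum over phenotypes, the reference distribution for family-wise
    error correction.
    """

    observed: np.ndarray  # (p,)
    null_scores: np.ndarray  # (B, p)

    @classmethod
    def empty(cls, p: int, B: int) -> "NullTable":
        return cls(observed=np.full(p, np.nan), null_scores=np.full((B, p), np.nan))

    @property
    def B(self) -> int:
        return self.null_scores.shape[0]

    @property
    def p(self) -> int:
        return self.null_scores.shape[1]

    @property
    def max_null(self) -> np.ndarray:
        return np.max(self.null_scores, axis=1)

    @property
    def complete(self) -> bool:
        return not (
            np.isnan(self.observed).any() or np.isnan(self.null_scores).any()
        )

    def add(self, phenotype: int, permutation_id: int, value: float) -> None:
        if permutation_id == 0:
            if not np.isnan(self.observed[phenotype]):
                raise IntegrityError(
                    f"duplicate observed statistic for phenotype {phenotype}"
                )
            self.observed[phenotype] = value
        else:
            if not np.isnan(self.null_scores[permutation_id - 1, phenotype]):
                raise IntegrityError(
                    f"duplicate cell (phenotype={phenotype}, "
                    f"permutation={permutation_id})"
                )
            self.null_scores[permutation_id - 1, phenotype] = value


def split_tasks(p: int, B: int, per_task: int, base_seed: int) -> list[TaskSpec]:
    """Tile {phenotypes} x {permutations 1..B} into blocks of ``per_task``.

    Returns ``p * B / per_task`` tasks; the first block of each phenotype
    additionally carries permutation id 0 (the observed statistic), so the
    tiling of all (phenotype, permutation) cells is exact.
    """
    if B % per_task != 0:
        raise ValueError(
            f"n_permutations={B} not divisible by permutations_per_task={per_task}"
        )
    tasks = []
    for j in range(p):
        for start in range(1, B + 1, per_task):
            block = tuple(range(start, start + per_task))
            if start == 1:
                block = (0,) + block
            tasks.append(
                TaskSpec(
                    task_id=f"ph{j:05d}_b{start:07d}",
                    phenotype_index=j,
                    permutation_ids=block,
                    base_seed=base_seed,
                )
            )
    return tasks


def run_map(
    task: TaskSpec,
    dataset,
    descriptor: InferenceDescriptor,
    registry: Mapping[str, type] | None = None,
) -> MapResult:
    """Execute one map task: score every permutation id in the block.

    Pure function of (task, dataset, descriptor): re-execution yields an
    identical result, which makes at-least-once scheduling safe.
    """
    Z = dataset.Z if descriptor.with_covariates else dataset.Z[:, :1]
    n = dataset.Y.shape[0]
    y = dataset.Y[:, task.phenotype_index]
    r = residualize(y, Z, source_phenotype=task.phenotype_index)
    folds = make_splits(
        n, descriptor.cv.n_iter, descriptor.cv.test_fraction, descriptor.cv.seed
    )
    spec = compile_pipeline(
        descriptor.pipeline,
        descriptor.grid.axes if descriptor.grid else None,
        registry,
    )
    per_fold = descriptor.covariate_mode == "per_fold"
    scores = []
    for b in task.permutation_ids:
        if b == 0:
            target = (
                ResidualTarget(values=y, source_phenotype=task.phenotype_index)
                if per_fold
                else r
            )
        else:
            perm = make_permutation(b, task.base_seed, n)
            target = ResidualTarget(
                values=permuted_target(r, perm, Z).values,
                source_phenotype=task.phenotype_index,
                permutation_id=b,
            )
        result = cv_score(
            target,
            dataset.X,
            spec,
            folds,
            Z=Z if per_fold else None,
            covariate_mode=descriptor.covariate_mode if b == 0 else "full_sample",
        )
        scores.append((task.phenotype_index, b, result.cv_r2))
    return MapResult(task_id=task.task_id, scores=tuple(scores))


def reduce_results(
    partials: Iterable[MapResult],
    accumulator: NullTable | None = None,
    *,
    p: int | None = None,
    B: int | None = None,
) -> NullTable:
    """Fold map results into a null table.

    Associative and commutative: any grouping or ordering of the partial
    results yields a bit-identical table.  Duplicate cells are integrity
    errors.
    """
    if accumulator is None:
        if p is None or B is None:
            raise ValueError("need (p, B) to create a fresh accumulator")
        accumulator = NullTable.empty(p, B)
    for partial in partials:
        for phenotype, b, value in partial.scores:
            accumulator.add(phenotype, b, value)
    return accumulator


# ---------------------------------------------------------------------------
# Ledger
# ---------------------------------------------------------------------------

def _checksum(task_id: str, scores) -> str:
    payload = json.dumps({"task_id": task_id, "scores": scores}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _append_ledger(path: str, result: MapResult) -> None:
    scores = [[int(a), int(b), float(v)] for a, b, v in result.scores]
    record = {
        "schema": LEDGER_SCHEMA,
        "task_id": result.task_id,
        "scores": scores,
        "checksum": _checksum(result.task_id, scores),
    }
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(record) + "\n")
        fh.flush()
        os.fsync(fh.fileno())


def read_ledger(path: str) -> dict[str, MapResult]:
    """Load completed tasks from a ledger, discarding corrupt records.

    A record with a wrong checksum, bad JSON or an unknown schema is
    dropped silently (its task will simply be re-queued).
    """
    done: dict[str, MapResult] = {}
    if not os.path.exists(path):
        return done
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError:
                continue
            if record.get("schema") != LEDGER_SCHEMA:
                continue
            scores = record.get("scores")
            task_id = record.get("task_id")
            if (
                not isinstance(task_id, str)
                or record.get("checksum") != _checksum(task_id, scores)
            ):
                continue
            done[task_id] = MapResult(
                task_id=task_id,
                scores=tuple((int(a), int(b), float(v)) for a, b, v in scores),
            )
    return done


def _worker(args) -> MapResult:
    task, dataset, descriptor = args
    return run_map(task, dataset, descriptor)


def run_inference(
    dataset,
    descriptor: InferenceDescriptor,
    n_workers: int = 1,
    ledger_path: str | None = None,
    base_seed: int = 0,
    stop_after_tasks: int | None = None,
    progress=None,
) -> NullTable:
    """Run every map task and reduce into a complete :class:`NullTable`.

    ``stop_after_tasks`` interrupts the run after that many newly-completed
    tasks (ledger preserved), raising :class:`RunInterrupted`; it exists to
    exercise and test the resume path.  ``progress`` is an optional callback
    ``(done, total) -> None``.
    """
    p = dataset.Y.shape[1]
    B = descriptor.n_permutations
    tasks = split_tasks(p, B, descriptor.permutations_per_task, base_seed)
    done = read_ledger(ledger_path) if ledger_path else {}
    done = {tid: res for tid, res in done.items() if tid in {t.task_id for t in tasks}}
    pending = [t for t in tasks if t.task_id not in done]
    if stop_after_tasks is not None:
        to_run, interrupted = pending[:stop_after_tasks], len(pending) > stop_after_tasks
    else:
        to_run, interrupted = pending, False

    results: list[MapResult] = list(done.values())
    n_done = len(results)
    total = len(tasks)

    def _note(res: MapResult) -> None:
        nonlocal n_done
        if ledger_path:
            _append_ledger(ledger_path, res)
        results.append(res)
        n_done += 1
        if progress:
            progress(n_done, total)

    if n_workers <= 1:
        for task in to_run:
            _note(run_map(task, dataset, descriptor))
    else:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            for res in pool.map(
                _worker,
                ((t, dataset, descriptor) for t in to_run),
                chunksize=max(1, len(to_run) // (4 * n_workers)),
            ):
                _note(res)

    if interrupted:
        raise RunInterrupted(
            f"stopped after {len(to_run)} tasks; {len(pending) - len(to_run)} "
            f"pending — resume with the same ledger"
        )
    table = reduce_results(results, p=p, B=B)
    if not table.complete:
        raise IntegrityError("inference finished with missing cells")
    return table
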