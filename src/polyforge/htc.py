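"""High-throughput utilities: folder bookkeeping, dispatch, external engines.

Batch polymer studies generate many small jobs whose inputs must each live
in their own directory before an external calculator touches them.  This
module creates collision-free directories, relocates files by extension,
runs independent tasks concurrently with per-task error capture, and
assembles (never executes) the command lines for the supported semiempirical
engines.
"""

from __future__ import annotations

import logging
import secrets
import shlex
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Optional, Sequence

from .exceptions import EngineError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DispatchPlan:
    """Worker threads for task management × cores handed to each task."""

    n_workers: int = 1
    cores_per_task: int = 1

    def __post_init__(self) -> None:
        if self.n_workers < 1 or self.cores_per_task < 1:
            raise ValueError("n_workers and cores_per_task must be >= 1")


@dataclass(frozen=True)
class TaskResult:
    """Outcome slot of one dispatched task; ``error`` is set on failure."""

    value: Any = None
    error: Optional[BaseException] = None

    @property
    def ok(self) -> bool:
        return self.error is None


def create_unique_folders(n: int, root: str | Path) -> list[Path]:
    """Create ``n`` new directories with unique random names under ``root``.

    Names are 128-bit hex tokens, so collisions are vanishingly unlikely;
    the impossible collision is retried rather than clobbered.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    out: list[Path] = []
    for _ in range(n):
        while True:
            cand = root / secrets.token_hex(16)
            try:
                cand.mkdir()
            except FileExistsError:  # pragma: no cover - 2^-128 event
                continue
            break
        out.append(cand)
    return out


def files_to_dirs(
    extension: str, root: str | Path
) -> dict[Path, Path]:
    """Move every ``*.extension`` file directly under ``root`` into its own
    fresh unique directory.

    Returns the bijective file → directory mapping; each target directory
    ends up holding exactly one matching file.  Zero matches is not an
    error (empty mapping, no directories created).
    """
    root = Path(root)
    ext = extension.lstrip(".")
    matches = sorted(
        p for p in root.iterdir() if p.is_file() and p.suffix == f".{ext}"
    )
    if not matches:
        return {}
    dirs = create_unique_folders(len(matches), root)
    mapping: dict[Path, Path] = {}
    for src, d in zip(matches, dirs):
        dest = d / src.name
        src.rename(dest)
        mapping[src] = d
        log.info("relocated %s -> %s", src.name, d.name)
    return mapping


def parallel_map(
    tasks: Sequence[Callable[[], Any]],
    plan: Optional[DispatchPlan] = None,
) -> list[TaskResult]:
    """Run zero-argument tasks concurrently; results stay in task order.

    A failing task records its exception in its own slot without aborting
    siblings, so one bad molecule never sinks a batch.
    """
    plan = plan or DispatchPlan()

    def guarded(task: Callable[[], Any]) -> TaskResult:
        try:
            return TaskResult(value=task())
        except BaseException as exc:  # noqa: BLE001 - captured per slot
            log.error("task failed: %s", exc)
            return TaskResult(error=exc)

    if plan.n_workers == 1:
        return [guarded(t) for t in tasks]
    with ThreadPoolExecutor(max_workers=plan.n_workers) as pool:
        return list(pool.map(guarded, tasks))


#: engine id → (program, method flags)
_ENGINES = {
    "gfn2-xtb": ("xtb", ("--gfn", "2")),
    "gfn-ff": ("xtb", ("--gfnff",)),
    "scf-engine": ("python", ("-m", "pyscf_driver")),
}


def assemble_calculator_command(
    engine: str, input_file: str | Path, cores: int = 1
) -> list[str]:
    """Build the argv for an external calculator without running it.

    Keeping assembly separate from execution lets whole workflows be
    validated on machines with no quantum-chemistry binaries installed.
    """
    if engine not in _ENGINES:
        raise EngineError(
            f"unknown engine {engine!r}; supported: "
            + ", ".join(sorted(_ENGINES))
        )
    if cores < 1:
        raise ValueError("cores must be >= 1")
    input_file = Path(input_file)
    if not input_file.exists():
        raise FileNotFoundError(input_file)
    program, method = _ENGINES[engine]
    argv = [program, *method, str(input_file), "--parallel", str(cores)]
    return argv


def command_to_shell(argv: Sequence[str]) -> str:
    """Render an argv as a copy-pasteable shell line."""
    return shlex.join(argv)
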