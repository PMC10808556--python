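"""Deterministic parallel execution over independent tasks.

Results are returned in task order whatever the worker count, so a sweep's
output is identical to serial execution in content and order; worker count
affects wall time only.  A crashed task is retried once before the failure
is surfaced.
"""

from __future__ import annotations

import logging

log = logging.getLogger(__name__)


def _run_with_retry(fn, task):
    try:
        return fn(task)
    except Exception:
        log.debug("task failed, retrying once", exc_info=True)
        return fn(task)


def parallel_map(fn, tasks, n_workers: int = 1) -> list:
    """Apply ``fn`` to every task, preserving task order in the results."""
    tasks = list(tasks)
    if n_workers == 1 or len(tasks) <= 1:
        return [_run_with_retry(fn, t) for t in tasks]
    from joblib import Parallel, delayed
    return Parallel(n_jobs=n_workers, backend="loky")(
        delayed(_run_with_retry)(fn, t) for t in tasks)
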