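"""Order-preserving parallel execution of independent section jobs.

Sections produced by the chunk planner are independent by construction
(halo-padded, no shared mutable state), so results must be identical to
sequential execution regardless of worker count or completion order.
joblib returns results in submission order, which preserves that contract;
``n_jobs=1`` bypasses joblib entirely.
"""

from __future__ import annotations

from joblib import Parallel, delayed


class SectionError(RuntimeError):
    """A worker failed; carries the index of the originating section."""

    def __init__(self, index: int, cause: BaseException):
        self.index = index
        self.cause = cause
        super().__init__(f"section {index} failed: {cause!r}")


def _run_one(func, index, item):
    try:
        return func(item)
    except Exception as exc:  # surface the section id with the failure
        raise SectionError(index, exc) from exc


def parallel_map(func, items, n_jobs: int = 1) -> list:
    """Apply ``func`` to every item, in order, optionally across processes."""
    items = list(items)
    if not items:
        return []
    if n_jobs == 1:
        return [_run_one(func, i, it) for i, it in enumerate(items)]
    return Parallel(n_jobs=n_jobs)(
        delayed(_run_one)(func, i, it) for i, it in enumerate(items)
    )
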