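"""Shared helpers: time units, seeding, canonical JSON."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from typing import Any, Iterable

import numpy as np

#: Days in one (mean Gregorian) month. All month-valued durations in the
#: package are real-valued multiples of this.
DAYS_PER_MONTH = 30.4375


def months_between(later: dt.date, earlier: dt.date) -> float:
    """Signed duration from ``earlier`` to ``later`` in months."""
    return (later - earlier).days / DAYS_PER_MONTH


def add_months(date: dt.date, months: float) -> dt.date:
    """Date ``months`` (possibly fractional) after ``date``, day resolution."""
    return date + dt.timedelta(days=round(months * DAYS_PER_MONTH))


def fork_seeds(seed: int, n: int, *, label: str = "") -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed.

    ``label`` decorrelates streams used for different purposes under the
    same master seed.
    """
    salt = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([int(seed), salt])
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]


def rng_from(seed: int, label: str = "") -> np.random.Generator:
    return np.random.default_rng(fork_seeds(seed, 1, label=label)[0])


def canonical_json(obj: Any) -> str:
    """Deterministic JSON rendering (sorted keys, fixed separators)."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=_json_default)


def _json_default(o: Any):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, dt.date):
        return o.isoformat()
    raise TypeError(f"not JSON serializable: {type(o)}")


def config_hash(obj: Any) -> str:
    return hashlib.sha256(canonical_json(obj).encode()).hexdigest()[:16]


def round_floats(obj: Any, ndigits: int = 4) -> Any:
    """Recursively round floats, for byte-stable report output."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, ndigits) for v in obj]
    return obj
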