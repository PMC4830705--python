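"""Privacy transforms applied before records leave the care zone.

Four transforms, applied together by :func:`deidentify`:

1. **Pseudonymization** — patient ids are replaced by a keyed hash of
   (seed, source, id): stable within one run, unlinkable across runs with
   different seeds.
2. **Birth-date generalization** — the common model already carries birth
   year only; the transform asserts nothing finer survives.
3. **Coherent date shifting** — one uniform offset per patient, drawn from
   [-shift_range_days, +shift_range_days], applied to every dated statement
   of that patient.  All intra-patient intervals are preserved exactly, so
   interval-based eligibility (windowed temporal criteria) is unchanged by
   the transform.  Offset 0 is allowed: excluding it would itself leak
   information about the true dates.
4. **Rare-code elimination** — statements whose code occurs in fewer than
   ``rare_threshold`` distinct patients source-wide (rare diseases, orphan
   drugs) are removed.  Removal is statement-level, not patient-level, and
   every removal is counted in the audit.

The audit summary reports aggregate counts and the offset *distribution*,
never per-patient offsets (which would invert the shift).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from datetime import timedelta
from typing import Iterable

from .common_model import PatientRecord

__all__ = ["DeidConfig", "DeidError", "deidentify", "pseudonym"]


class DeidError(Exception):
    pass


@dataclass(frozen=True)
class DeidConfig:
    shift_range_days: int = 30
    rare_threshold: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift_range_days < 1:
            raise DeidError("shift_range_days must be >= 1")
        if self.rare_threshold < 1:
            raise DeidError("rare_threshold must be >= 1")


def _keyed_int(seed: int, *parts: str) -> int:
    h = hashlib.sha256(("\x1f".join((str(seed),) + parts)).encode()).digest()
    return int.from_bytes(h[:8], "big")


def pseudonym(seed: int, source_id: str, patient_id: str) -> str:
    """Keyed, truncated pseudonym; deterministic per (seed, source, id)."""
    return format(_keyed_int(seed, "pseudonym", source_id, patient_id), "016x")


def _offset(seed: int, source_id: str, patient_id: str, range_days: int) -> int:
    # Hash-derived, so the offset is independent of record order and of
    # whatever else consumed the RNG.  Uniform over [-R, +R].
    span = 2 * range_days + 1
    return _keyed_int(seed, "offset", source_id, patient_id) % span - range_days


def deidentify(
    records: Iterable[PatientRecord], config: DeidConfig, source_id: str = ""
) -> tuple[list[PatientRecord], dict]:
    """Apply all transforms; returns (de-identified records, audit summary)."""
    records = list(records)

    # Rare-code census over the whole source (distinct patients per code).
    carriers: dict[tuple[str, str], set[str]] = {}
    for r in records:
        for s in r.statements:
            carriers.setdefault(s.code.ref, set()).add(r.patient_id)
    rare = {code for code, pats in carriers.items() if len(pats) < config.rare_threshold}

    out: list[PatientRecord] = []
    seen_pseudonyms: dict[str, str] = {}
    removed_statements = 0
    offset_hist: dict[int, int] = {}
    for r in records:
        pid = pseudonym(config.seed, source_id, r.patient_id)
        if pid in seen_pseudonyms and seen_pseudonyms[pid] != r.patient_id:
            raise DeidError(f"pseudonym collision for {pid!r}")
        seen_pseudonyms[pid] = r.patient_id
        off = _offset(config.seed, source_id, r.patient_id, config.shift_range_days)
        offset_hist[off] = offset_hist.get(off, 0) + 1
        shift = timedelta(days=off)
        stmts = []
        for s in r.statements:
            if s.code.ref in rare:
                removed_statements += 1
                continue
            stmts.append(
                replace(
                    s,
                    effective_start=s.effective_start + shift if s.effective_start else None,
                    effective_end=s.effective_end + shift if s.effective_end else None,
                )
            )
        out.append(replace(r, patient_id=pid, statements=tuple(stmts)))

    audit = {
        "patients": len(out),
        "removed_statements": removed_statements,
        "removed_codes": len(rare),
        "rare_threshold": config.rare_threshold,
        "shift_range_days": config.shift_range_days,
        "offset_distribution": {str(k): offset_hist[k] for k in sorted(offset_hist)},
    }
    return out, audit
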