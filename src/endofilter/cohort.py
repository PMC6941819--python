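"""Stage 1 of the noise filter: cohort recurrence with whitelist rescue.

Artifacts introduced by endonuclease fragmentation hit the same genomic sites
(hairpin centers) in many libraries, so a call recurring across a pooled
cohort of enzymatically fragmented samples is suspect — unless it is a known
genuine variant (whitelisted, emulating COSMIC registration), in which case it
is returned to the stage-2 classifier rather than removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import VariantCall

Key = tuple[str, int, str, str]


@dataclass
class RecurrenceTable:
    """Per-key sets of cohort samples carrying the identical call."""

    samples_by_key: dict[Key, frozenset[str]]
    cohort_size: int

    def count(self, key: Key, exclude_sample: str | None = None) -> int:
        samples = self.samples_by_key.get(key)
        if not samples:
            return 0
        if exclude_sample is not None and exclude_sample in samples:
            return len(samples) - 1
        return len(samples)


@dataclass(frozen=True)
class StageOneDecision:
    variant: VariantCall
    recurrence_count: int
    whitelisted: bool
    removed: bool
    reason: str  # recurrent_not_whitelisted | passed | rescued_whitelist


def build_recurrence(call_tables: Sequence[Sequence[VariantCall]]) -> RecurrenceTable:
    """Tally, per variant key, the distinct samples carrying it.

    Each table holds one sample's calls; duplicate listings within a sample
    contribute once. A sample id appearing in two tables is an error.
    """
    seen_samples: set[str] = set()
    acc: dict[Key, set[str]] = {}
    for table in call_tables:
        if not table:
            continue
        sids = {c.sample_id for c in table}
        if len(sids) != 1:
            raise ValueError(f"mixed sample ids in one call table: {sorted(sids)}")
        (sid,) = sids
        if sid in seen_samples:
            raise ValueError(f"duplicate sample id {sid!r} in cohort")
        seen_samples.add(sid)
        for key in {c.key for c in table}:
            acc.setdefault(key, set()).add(sid)
    return RecurrenceTable(
        {k: frozenset(v) for k, v in acc.items()}, cohort_size=len(seen_samples)
    )


def stage_one_filter(
    calls: Iterable[VariantCall],
    table: RecurrenceTable,
    whitelist: frozenset[Key] = frozenset(),
    recurrence_min: int = 2,
    leave_one_out: bool = True,
) -> list[StageOneDecision]:
    """Remove cohort-recurrent calls unless whitelisted.

    A call is removed iff it recurs in at least ``recurrence_min`` cohort
    samples (by default not counting the query sample itself) and is not on
    the whitelist. Whitelisted recurrent calls are rescued: they pass on to
    the stage-2 classifier, not auto-accepted.
    """
    decisions = []
    for call in calls:
        count = table.count(call.key, exclude_sample=call.sample_id if leave_one_out else None)
        wl = call.key in whitelist
        recurrent = count >= recurrence_min
        if recurrent and not wl:
            reason, removed = "recurrent_not_whitelisted", True
        elif recurrent and wl:
            reason, removed = "rescued_whitelist", False
        else:
            reason, removed = "passed", False
        decisions.append(StageOneDecision(call, count, wl, removed, reason))
    return decisions
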