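"""Experimental design: samples, conditions, replicates.

The study design has six conditions — a beads-only control, an
unmodified-cytidine bait control (``C``) and four modified baits —
each run in independent biological replicates (three in the original
screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The four modified baits whose readers the screen looks for.
MODIFICATIONS: tuple[str, ...] = ("m5C", "hm5C", "hm5Cm", "f5C")

#: All six pulldown conditions (two controls + four baits).
CONDITIONS: tuple[str, ...] = ("beads", "C") + MODIFICATIONS


class DesignError(ValueError):
    """Raised for an invalid sample design."""


@dataclass(frozen=True)
class SampleDesign:
    """Mapping of sample identifiers to (condition, replicate).

    Parameters
    ----------
    samples
        Sequence of ``(sample_id, condition, replicate)`` tuples.
        Sample ids must be unique, conditions must come from
        :data:`CONDITIONS`, every condition must be present at least
        once, and replicate numbers must be positive integers.
    """

    samples: tuple[tuple[str, str, int], ...]
    _by_condition: dict[str, list[str]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        by_condition: dict[str, list[str]] = {c: [] for c in CONDITIONS}
        for sample_id, condition, replicate in self.samples:
            if sample_id in seen:
                raise DesignError(f"duplicate sample_id {sample_id!r}")
            seen.add(sample_id)
            if condition not in CONDITIONS:
                raise DesignError(
                    f"unknown condition {condition!r} for sample {sample_id!r}; "
                    f"expected one of {', '.join(CONDITIONS)}"
                )
            if not isinstance(replicate, int) or replicate < 1:
                raise DesignError(
                    f"replicate for sample {sample_id!r} must be a positive "
                    f"integer, got {replicate!r}"
                )
            by_condition[condition].append(sample_id)
        missing = [c for c in CONDITIONS if not by_condition[c]]
        if missing:
            raise DesignError(f"design missing condition(s): {', '.join(missing)}")
        object.__setattr__(self, "_by_condition", by_condition)

    @property
    def sample_ids(self) -> list[str]:
        """Sample ids in design order."""
        return [s for s, _, _ in self.samples]

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids belonging to ``condition``, in design order."""
        if condition not in CONDITIONS:
            raise DesignError(f"unknown condition {condition!r}")
        return list(self._by_condition[condition])

    def condition_of(self, sample_id: str) -> str:
        for s, c, _ in self.samples:
            if s == sample_id:
                return c
        raise DesignError(f"unknown sample_id {sample_id!r}")

    def n_replicates(self, condition: str) -> int:
        return len(self.samples_of(condition))
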